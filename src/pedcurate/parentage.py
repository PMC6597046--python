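"""Parentage verification and search from Mendelian-inconsistent counts.

Two statistics drive everything here.  A parent-child (PC) error is a
marker where parent and child are opposing homozygotes (AA vs BB): for
biallelic codominant calls this is exactly the "no shared allele"
condition.  A parent-parent-child (PPC) error is a marker where no choice
of one transmitted allele per parent explains the child -- the full
transmission-feasibility test, which also catches AA x AA -> AB and
AA x BB -> AA, cases invisible to either single-parent comparison.

Rejection thresholds are calibrated per data set: true parent-child pairs
accumulate only sporadic miscalls while unrelated pairs accumulate
opposing homozygotes in proportion to allele frequencies, so the two count
distributions separate and a midway point rejects recorded parentage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import AA, AB, BB, MISSING, GenotypeMatrix, Pedigree, is_placeholder

# ---------------------------------------------------------------------------
# single-marker transmission feasibility
# ---------------------------------------------------------------------------

def _gametes(call: int) -> tuple[int, ...]:
    return {AA: (0,), AB: (0, 1), BB: (1,)}[call]


#: FEASIBLE[m, f, c] -- can parents with dosages (m, f) produce child dosage c?
FEASIBLE = np.zeros((3, 3, 3), dtype=bool)
for _m in (AA, AB, BB):
    for _f in (AA, AB, BB):
        for _am in _gametes(_m):
            for _af in _gametes(_f):
                FEASIBLE[_m, _f, _am + _af] = True


def pc_errors(child: np.ndarray, parent: np.ndarray) -> int:
    """Opposing-homozygote count over co-called markers (symmetric)."""
    child = np.asarray(child)
    parent = np.asarray(parent)
    return int(
        (((child == AA) & (parent == BB)) | ((child == BB) & (parent == AA))).sum()
    )


def ppc_errors(child: np.ndarray, mother: np.ndarray, father: np.ndarray) -> int:
    """Markers where no transmitted-allele assignment explains the child."""
    child = np.asarray(child)
    mother = np.asarray(mother)
    father = np.asarray(father)
    ok = (child != MISSING) & (mother != MISSING) & (father != MISSING)
    if not ok.any():
        return 0
    feasible = FEASIBLE[mother[ok], father[ok], child[ok]]
    return int((~feasible).sum())


# ---------------------------------------------------------------------------
# threshold calibration
# ---------------------------------------------------------------------------

@dataclass
class PcCalibration:
    threshold: int
    known_counts: np.ndarray
    random_counts: np.ndarray
    known_percentile: float
    random_percentile: float
    overlap: bool = False


def calibrate_pc_threshold(
    gm: GenotypeMatrix,
    known_pc_pairs: list[tuple[str, str]],
    n_random: int = 1000,
    seed: int | np.random.Generator = 0,
    percentiles: tuple[float, float] = (99.0, 1.0),
    min_known: int = 20,
) -> PcCalibration:
    """Midway threshold between known-PC and random-pair error counts.

    The threshold is the rounded midpoint between the upper percentile
    (default 99th) of the known-pair distribution and the lower percentile
    (default 1st) of the random no-recorded-relation pair distribution.
    Counts at or above the threshold reject the parentage.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    usable = [
        (c, p)
        for c, p in known_pc_pairs
        if c in gm.individuals and p in gm.individuals
    ]
    if len(usable) < min_known:
        raise ValueError(
            f"need >= {min_known} known parent-child pairs, got {len(usable)}"
        )
    known_counts = np.array(
        [pc_errors(gm.individual_calls(c), gm.individual_calls(p)) for c, p in usable]
    )
    related = {frozenset(pair) for pair in usable}
    inds = gm.individuals
    random_counts = []
    attempts = 0
    while len(random_counts) < n_random and attempts < 50 * n_random:
        attempts += 1
        i, j = rng.choice(len(inds), size=2, replace=False)
        if frozenset((inds[i], inds[j])) in related:
            continue
        random_counts.append(pc_errors(gm.calls[:, i], gm.calls[:, j]))
    random_counts = np.array(random_counts)
    hi_known = float(np.percentile(known_counts, percentiles[0]))
    lo_random = float(np.percentile(random_counts, percentiles[1]))
    threshold = int(round((hi_known + lo_random) / 2))
    threshold = max(threshold, 1)
    overlap = hi_known >= lo_random
    if overlap:
        warnings.warn(
            "known-PC and random-pair error distributions overlap at the "
            f"calibration percentiles ({hi_known:.1f} >= {lo_random:.1f})"
        )
    return PcCalibration(
        threshold, known_counts, random_counts, hi_known, lo_random, overlap
    )


def calibrate_ppc_threshold(ppc_counts_confirmed: list[int] | np.ndarray) -> int:
    """110% of the largest PPC count among confirmed trios, rounded up."""
    counts = np.asarray(ppc_counts_confirmed)
    if counts.size == 0:
        raise ValueError("no confirmed trios to calibrate the PPC threshold")
    return int(math.ceil(1.10 * float(counts.max())))


# ---------------------------------------------------------------------------
# verification, search, grandparents
# ---------------------------------------------------------------------------

@dataclass
class ParentageVerdict:
    child: str
    relation: str  # PC_mother | PC_father | PPC
    counterpart: tuple[str, ...]
    error_count: int | None
    threshold: int | None
    verdict: str  # confirmed | rejected | untestable


def verify_pedigree(
    gm: GenotypeMatrix,
    ped: Pedigree,
    pc_threshold: int,
    ppc_threshold: int | None = None,
) -> list[ParentageVerdict]:
    """Check every recorded parent-child and trio relation in the pedigree.

    PC relations are confirmed when the error count is strictly below the
    rejection threshold; trios (only tested when both PC relations are
    confirmed) are confirmed when PPC errors do not exceed the PPC
    threshold.  A relation with an ungenotyped party is untestable.
    """
    verdicts: list[ParentageVerdict] = []
    genotyped = set(gm.individuals)
    for ind in ped:
        pc_ok: dict[str, bool] = {}
        for relation, parent in (("PC_mother", ind.mother), ("PC_father", ind.father)):
            if parent is None:
                continue
            if ind.id not in genotyped or parent not in genotyped:
                verdicts.append(
                    ParentageVerdict(ind.id, relation, (parent,), None, None, "untestable")
                )
                continue
            n = pc_errors(gm.individual_calls(ind.id), gm.individual_calls(parent))
            verdict = "confirmed" if n < pc_threshold else "rejected"
            pc_ok[relation] = verdict == "confirmed"
            verdicts.append(
                ParentageVerdict(ind.id, relation, (parent,), n, pc_threshold, verdict)
            )
        if (
            ppc_threshold is not None
            and ind.mother is not None
            and ind.father is not None
            and pc_ok.get("PC_mother")
            and pc_ok.get("PC_father")
        ):
            n = ppc_errors(
                gm.individual_calls(ind.id),
                gm.individual_calls(ind.mother),
                gm.individual_calls(ind.father),
            )
            verdict = "confirmed" if n <= ppc_threshold else "rejected"
            verdicts.append(
                ParentageVerdict(
                    ind.id,
                    "PPC",
                    (ind.mother, ind.father),
                    n,
                    ppc_threshold,
                    verdict,
                )
            )
    return verdicts


def verdicts_frame(verdicts: list[ParentageVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "child": v.child,
                "relation": v.relation,
                "counterpart": "+".join(v.counterpart),
                "error_count": v.error_count,
                "threshold": v.threshold,
                "verdict": v.verdict,
            }
            for v in verdicts
        ]
    )


def search_parents(
    gm: GenotypeMatrix,
    child: str,
    candidates: list[str],
    pc_threshold: int,
    full_sib_ids: set[str] | None = None,
    birth_order: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Rank candidate parents of ``child`` by ascending PC error count.

    Only candidates strictly below the rejection threshold are returned.
    Full sibs of the child can masquerade as parents (they share both
    parental genomes), so known sibs are flagged rather than excluded.
    Candidates born after the child are excluded when birth-order metadata
    is present.
    """
    child_calls = gm.individual_calls(child)
    rows = []
    for cand in candidates:
        if cand == child or cand not in gm.individuals:
            continue
        if (
            birth_order is not None
            and cand in birth_order
            and child in birth_order
            and birth_order[cand] > birth_order[child]
        ):
            continue
        n = pc_errors(child_calls, gm.individual_calls(cand))
        if n < pc_threshold:
            rows.append(
                {
                    "candidate": cand,
                    "pc_errors": n,
                    "full_sib_flag": bool(full_sib_ids and cand in full_sib_ids),
                }
            )
    frame = pd.DataFrame(rows, columns=["candidate", "pc_errors", "full_sib_flag"])
    return frame.sort_values(["pc_errors", "candidate"], kind="mergesort").reset_index(
        drop=True
    )


def grandparent_test(
    child: np.ndarray,
    known_parent: np.ndarray,
    gp1: np.ndarray,
    gp2: np.ndarray,
) -> int:
    """AB+AA-AA style count against a candidate grandparent pair.

    Where the child's obligate allele from its ungenotyped parent is
    determinable (child homozygous; or child heterozygous with a homozygous
    known parent), count the markers at which neither candidate grandparent
    carries that allele.  The canonical failing configuration is an AB child
    with an AA known parent facing an AA/AA grandparent pair: the obligate B
    has no grandparental source.
    """
    child = np.asarray(child)
    known_parent = np.asarray(known_parent)
    gp1 = np.asarray(gp1)
    gp2 = np.asarray(gp2)

    # obligate allele from the ungenotyped parent: 0 (A), 1 (B), or -1 (n/a)
    obligate = np.full(child.shape, -1, dtype=np.int8)
    obligate[child == AA] = 0
    obligate[child == BB] = 1
    het = child == AB
    obligate[het & (known_parent == AA)] = 1
    obligate[het & (known_parent == BB)] = 0

    ok = (obligate >= 0) & (gp1 != MISSING) & (gp2 != MISSING)
    gp1_lacks = np.where(obligate == 0, gp1 == BB, gp1 == AA)
    gp2_lacks = np.where(obligate == 0, gp2 == BB, gp2 == AA)
    return int((ok & gp1_lacks & gp2_lacks).sum())


def recorded_pc_pairs(ped: Pedigree, gm: GenotypeMatrix) -> list[tuple[str, str]]:
    """All genotyped (child, recorded parent) pairs, placeholders excluded."""
    pairs = []
    genotyped = set(gm.individuals)
    for ind in ped:
        for parent in ind.parents:
            if (
                parent is not None
                and not is_placeholder(parent)
                and ind.id in genotyped
                and parent in genotyped
            ):
                pairs.append((ind.id, parent))
    return pairs
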