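"""Pedigree-wide Mendelian-consistency checking by genotype elimination.

Each individual starts with the set of genotypes compatible with its
observed call (all three when missing).  Sweeping over nuclear families, a
parental genotype pair survives only if every child in the family retains a
genotype it could produce, and a child genotype survives only if some
surviving parental pair can produce it; iterating to a fixpoint propagates
constraints across generations, so an error shows up even when the
intermediate individual is ungenotyped.  An empty set certifies a
Mendelian inconsistency.  Because set propagation alone can miss joint
infeasibility in looped (inbred) pedigrees, a nonempty fixpoint is
certified by a depth-first search for one complete consistent assignment.

Missing calls whose surviving set is a singleton are forced by the
pedigree and can be imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix, Pedigree
from .parentage import FEASIBLE

ALL_GENOTYPES = 0b111

#: FEAS_MASK[m][f] -- bitmask of child dosages producible by parents (m, f)
FEAS_MASK = [
    [sum(1 << c for c in range(3) if FEASIBLE[m, f, c]) for f in range(3)]
    for m in range(3)
]


@dataclass
class _Workspace:
    """Pedigree wiring shared by all markers."""

    individuals: list[str]  # all pedigree members plus extra genotyped ids
    index: dict[str, int]
    families: list[tuple[int, int, list[int]]]  # (mother, father, children)
    topo: list[int]
    parents: list[tuple[int, int] | None]
    genotyped_cols: list[tuple[int, int]]  # (workspace index, matrix column)


def build_workspace(ped: Pedigree, gm: GenotypeMatrix) -> _Workspace:
    ids = list(
        dict.fromkeys(
            [*ped.ids, *[p for ind in ped for p in ind.parents if p], *gm.individuals]
        )
    )
    index = {s: k for k, s in enumerate(ids)}
    families = [
        (index[m], index[f], [index[c] for c in children])
        for (m, f), children in ped.nuclear_families()
    ]
    order = ped.topological_order()
    topo = [index[s] for s in order] + [
        index[s] for s in ids if s not in set(order)
    ]
    parents: list[tuple[int, int] | None] = [None] * len(ids)
    for ind in ped:
        if ind.mother is not None and ind.father is not None:
            parents[index[ind.id]] = (index[ind.mother], index[ind.father])
    genotyped_cols = [
        (index[s], j) for j, s in enumerate(gm.individuals) if s in index
    ]
    return _Workspace(ids, index, families, topo, parents, genotyped_cols)


def _initial_masks(ws: _Workspace, gm: GenotypeMatrix) -> np.ndarray:
    masks = np.full((gm.n_markers, len(ws.individuals)), ALL_GENOTYPES, dtype=np.uint8)
    for k, j in ws.genotyped_cols:
        col = gm.calls[:, j]
        observed = col != MISSING
        masks[observed, k] = np.left_shift(
            np.uint8(1), col[observed].astype(np.uint8)
        )
    return masks


def _propagate(masks: np.ndarray, families) -> np.ndarray:
    """Vectorized Lange-Goradia sweep to fixpoint; sets only shrink."""
    n_ind = masks.shape[1]
    for _ in range(3 * max(n_ind, 1)):
        changed = False
        for mi, fi, children in families:
            mm = masks[:, mi]
            fm = masks[:, fi]
            allowed_m = np.zeros(masks.shape[0], dtype=np.uint8)
            allowed_f = np.zeros_like(allowed_m)
            contrib = {ci: np.zeros_like(allowed_m) for ci in children}
            for g_m in range(3):
                bit_m = np.uint8(1 << g_m)
                has_m = (mm & bit_m) != 0
                if not has_m.any():
                    continue
                for g_f in range(3):
                    bit_f = np.uint8(1 << g_f)
                    ok = has_m & ((fm & bit_f) != 0)
                    if not ok.any():
                        continue
                    fe = np.uint8(FEAS_MASK[g_m][g_f])
                    for ci in children:
                        ok = ok & ((masks[:, ci] & fe) != 0)
                        if not ok.any():
                            break
                    else:
                        allowed_m |= np.where(ok, bit_m, np.uint8(0))
                        allowed_f |= np.where(ok, bit_f, np.uint8(0))
                        for ci in children:
                            contrib[ci] |= np.where(ok, fe, np.uint8(0))
            for k, allowed in ((mi, allowed_m), (fi, allowed_f)):
                new = masks[:, k] & allowed
                if not np.array_equal(new, masks[:, k]):
                    masks[:, k] = new
                    changed = True
            for ci, allowed in contrib.items():
                new = masks[:, ci] & allowed
                if not np.array_equal(new, masks[:, ci]):
                    masks[:, ci] = new
                    changed = True
        if not changed:
            break
    return masks


def eliminate_genotypes(ped: Pedigree, gm: GenotypeMatrix) -> pd.DataFrame:
    """Feasible genotype sets per (marker, individual) after elimination.

    Returned as a DataFrame of bitmasks (bit g set = dosage g feasible)
    indexed by marker, one column per pedigree/genotyped individual.
    """
    ws = build_workspace(ped, gm)
    masks = _propagate(_initial_masks(ws, gm), ws.families)
    return pd.DataFrame(masks, index=gm.markers, columns=ws.individuals)


def _propagate_scalar(families, row: list[int]) -> list[int]:
    """Pure-Python single-marker elimination (fast path for re-checks)."""
    changed = True
    while changed:
        changed = False
        for mi, fi, children in families:
            mm, fm = row[mi], row[fi]
            am = af = 0
            contrib = 0
            per_child = [0] * len(children)
            for g_m in range(3):
                if not mm >> g_m & 1:
                    continue
                for g_f in range(3):
                    if not fm >> g_f & 1:
                        continue
                    fe = FEAS_MASK[g_m][g_f]
                    ok = True
                    for ci in children:
                        if not row[ci] & fe:
                            ok = False
                            break
                    if ok:
                        am |= 1 << g_m
                        af |= 1 << g_f
                        for t in range(len(children)):
                            per_child[t] |= fe
            for k, allowed in ((mi, am), (fi, af)):
                new = row[k] & allowed
                if new != row[k]:
                    row[k] = new
                    changed = True
            for t, ci in enumerate(children):
                new = row[ci] & per_child[t]
                if new != row[ci]:
                    row[ci] = new
                    changed = True
    return row


def _certify(ws: _Workspace, row_masks) -> bool:
    """Is there a complete assignment consistent with every trio?

    Depth-first search in ancestors-first order; with propagated sets the
    first branch almost always succeeds, but backtracking makes the verdict
    exact even for looped pedigrees.
    """
    row = [int(x) for x in row_masks]
    if 0 in row:
        return False
    order = ws.topo
    n = len(order)
    choice = [-1] * len(row)

    def dfs(pos: int) -> bool:
        if pos == n:
            return True
        k = order[pos]
        m = row[k]
        par = ws.parents[k]
        if par is not None and choice[par[0]] >= 0 and choice[par[1]] >= 0:
            m &= FEAS_MASK[choice[par[0]]][choice[par[1]]]
        for g in range(3):
            if m >> g & 1:
                choice[k] = g
                if dfs(pos + 1):
                    return True
        choice[k] = -1
        return False

    return dfs(0)


def _scalar_consistent(ws: _Workspace, row: list[int]) -> bool:
    row = _propagate_scalar(ws.families, list(row))
    if 0 in row:
        return False
    return _certify(ws, row)


@dataclass
class ConsistencyReport:
    flags: list[tuple[str, str]] = field(default_factory=list)  # (marker, individual)
    per_marker: dict[str, int] = field(default_factory=dict)
    per_individual: dict[str, int] = field(default_factory=dict)
    imputable: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def n_errors(self) -> int:
        return len(self.flags)

    def long_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.flags, columns=["marker", "individual"])


def find_inconsistencies(
    ped: Pedigree,
    gm: GenotypeMatrix,
    attribute_to_parent: bool = False,
) -> ConsistencyReport:
    """Locate Mendelian-inconsistent errors across the whole pedigree.

    For each marker whose elimination fixpoint is infeasible, the minimal
    conflicting set is localized by leave-one-out re-elimination over the
    observed members of the affected nuclear families; all members of that
    set are flagged (``attribute_to_parent`` restricts each flagged set to
    its eldest member for comparison with tools that report the parent).
    Imputable cells (missing call, singleton surviving set) are collected
    on the way.
    """
    ws = build_workspace(ped, gm)
    masks = _propagate(_initial_masks(ws, gm), ws.families)
    report = ConsistencyReport()
    # per-marker observation lists: (workspace index, call)
    obs_by_marker: list[list[tuple[int, int]]] = [[] for _ in gm.markers]
    for k, j in ws.genotyped_cols:
        col = gm.calls[:, j]
        for i in np.nonzero(col != MISSING)[0]:
            obs_by_marker[i].append((k, int(col[i])))
    topo_rank = {k: r for r, k in enumerate(ws.topo)}

    for i, marker in enumerate(gm.markers):
        row = masks[i]
        empty = np.nonzero(row == 0)[0]
        if empty.size == 0 and _certify(ws, row):
            observed_here = {k for k, _ in obs_by_marker[i]}
            for k in np.nonzero((row == 1) | (row == 2) | (row == 4))[0]:
                if k not in observed_here and ws.individuals[k] in gm._iidx:
                    report.imputable.append(
                        (marker, ws.individuals[k], int(row[k]).bit_length() - 1)
                    )
            continue
        flagged = _localize(ws, set(empty.tolist()), obs_by_marker[i])
        if attribute_to_parent and flagged:
            flagged = [min(flagged, key=lambda k: topo_rank.get(k, 1 << 30))]
        for k in sorted(flagged):
            report.flags.append((marker, ws.individuals[k]))

    for marker, ind in report.flags:
        report.per_marker[marker] = report.per_marker.get(marker, 0) + 1
        report.per_individual[ind] = report.per_individual.get(ind, 0) + 1
    return report


def _family_locally_consistent(
    obs: dict[int, int], mi: int, fi: int, children: list[int]
) -> bool:
    """Can some parental pair explain every observed child of this family?"""
    mm = 1 << obs[mi] if mi in obs else ALL_GENOTYPES
    fm = 1 << obs[fi] if fi in obs else ALL_GENOTYPES
    observed_children = [1 << obs[c] for c in children if c in obs]
    for g_m in range(3):
        if not mm >> g_m & 1:
            continue
        for g_f in range(3):
            if not fm >> g_f & 1:
                continue
            fe = FEAS_MASK[g_m][g_f]
            if all(cm & fe for cm in observed_children):
                return True
    return False


def _localize(
    ws: _Workspace,
    empty: set[int],
    observations: list[tuple[int, int]],
) -> list[int]:
    """Minimal conflicting sets for one marker.

    Independent errors usually make their own nuclear family locally
    inconsistent, so each locally inconsistent family is resolved first by
    leave-one-out within the family.  Conflicts that only materialize
    across generations (every family locally fine) fall back to global
    leave-one-out re-elimination over the members of the affected
    families.
    """
    obs = dict(observations)
    flagged: set[int] = set()
    for mi, fi, children in ws.families:
        if _family_locally_consistent(obs, mi, fi, children):
            continue
        members = [k for k in (mi, fi, *children) if k in obs]
        loo = []
        for k in members:
            reduced = {x: c for x, c in obs.items() if x != k}
            if _family_locally_consistent(reduced, mi, fi, children):
                loo.append(k)
        flagged.update(loo or members)
    if flagged:
        return sorted(flagged)

    # cross-generation conflict: no family is locally inconsistent
    if empty:
        affected = [
            fam for fam in ws.families if empty & ({fam[0], fam[1]} | set(fam[2]))
        ]
    else:
        affected = ws.families  # certification failure without empty sets (loops)
    members = {k for mi, fi, children in affected for k in (mi, fi, *children)}
    candidates = sorted(k for k in obs if k in members)

    def row_without(drop: int | None) -> list[int]:
        row = [ALL_GENOTYPES] * len(ws.individuals)
        for k, call in obs.items():
            if k != drop:
                row[k] = 1 << call
        return row

    minimal = [k for k in candidates if _scalar_consistent(ws, row_without(k))]
    if minimal:
        return minimal
    # no single observation explains the conflict; flag the affected members
    return candidates


def impute_forced(
    ped: Pedigree, gm: GenotypeMatrix, apply: bool = False
) -> list[tuple[str, str, int]]:
    """Missing calls forced to a single genotype by the pedigree.

    Returns (marker, individual, dosage) triples; with ``apply`` they are
    written into the matrix with reason ``mendel_impute``.  Imputation only
    happens at markers with a consistent fixpoint, so it can never create a
    new inconsistency.
    """
    report = find_inconsistencies(ped, gm)
    if apply:
        for marker, ind, call in report.imputable:
            gm.set_call(marker, ind, call, "mendel_impute")
    return report.imputable


def repair_inconsistencies(
    gm: GenotypeMatrix,
    ped: Pedigree,
    max_iter: int = 10,
    reason: str = "mendel_inconsistent",
) -> ConsistencyReport:
    """Blank flagged calls and re-check until no inconsistency remains.

    Each round sets every member of each minimal conflicting set to
    missing; convergence is guaranteed because observations only disappear.
    Returns the report of the first round (the detected errors).
    """
    first: ConsistencyReport | None = None
    for _ in range(max_iter):
        report = find_inconsistencies(ped, gm)
        if first is None:
            first = report
        if not report.flags:
            break
        for marker, ind in report.flags:
            if ind in gm._iidx:
                gm.set_call(marker, ind, MISSING, reason)
    return first if first is not None else ConsistencyReport()


# ---------------------------------------------------------------------------
# generic multi-allelic elimination (used for haploblock alleles)
# ---------------------------------------------------------------------------

def eliminate_multiallelic(
    ped: Pedigree,
    genotypes: dict[str, tuple[int, int] | None],
    allele_universe: set[int],
    max_candidate_alleles: int = 8,
) -> tuple[dict[str, set[tuple[int, int]] | None], bool]:
    """Set elimination for one k-allelic locus (haplotype codes).

    ``genotypes`` maps individual id to an unordered code pair or ``None``
    (missing).  Missing individuals range over all pairs built from the
    alleles observed in their family neighbourhood; when that candidate
    space is larger than ``max_candidate_alleles`` alleles the individual
    is treated as an unconstrained wildcard (``None`` in the result) --
    sets stay small and the verdict stays sound, at the price of weaker
    propagation through very poorly resolved individuals.  Returns the
    surviving pair-sets and a consistency verdict.
    """

    def pairs_from(alleles: set[int]) -> set[tuple[int, int]]:
        srt = sorted(alleles)
        return {(a, b) for ai, a in enumerate(srt) for b in srt[ai:]}

    ids = list(dict.fromkeys([*ped.ids, *genotypes]))
    fams = ped.nuclear_families()
    neighbourhood: dict[str, set[int]] = {s: set() for s in ids}
    for (m, f), children in fams:
        fam_alleles: set[int] = set()
        for member in (m, f, *children):
            gt = genotypes.get(member)
            if gt is not None:
                fam_alleles |= set(gt)
        for member in (m, f, *children):
            neighbourhood.setdefault(member, set()).update(fam_alleles)

    # None = wildcard (unconstrained)
    sets: dict[str, set[tuple[int, int]] | None] = {}
    for s in ids:
        gt = genotypes.get(s)
        if gt is not None:
            sets[s] = {tuple(sorted(gt))}
        else:
            alleles = neighbourhood.get(s) or set(allele_universe)
            if not alleles or len(alleles) > max_candidate_alleles:
                sets[s] = None
            else:
                sets[s] = pairs_from(alleles)

    def alleles_of(pairs: set[tuple[int, int]] | None) -> set[int] | None:
        if pairs is None:
            return None
        return {a for p in pairs for a in p}

    changed = True
    guard = 0
    while changed and guard < 3 * max(len(ids), 1):
        changed = False
        guard += 1
        for (m, f), children in fams:
            sm, sf = sets.get(m), sets.get(f)
            kids = [c for c in children if c in sets]
            if sm is None and sf is None:
                continue  # nothing to constrain against
            if sm is None or sf is None:
                # one wildcard parent: the concrete parent must share an
                # allele with every constrained child, and vice versa
                concrete, conc_id = (sf, f) if sm is None else (sm, m)
                ok_parent: set[tuple[int, int]] = set()
                ok_kids = {c: set() for c in kids}
                for pp in concrete:
                    palleles = set(pp)
                    fine = True
                    for c in kids:
                        if sets[c] is None:
                            continue
                        if not any(set(cp) & palleles for cp in sets[c]):
                            fine = False
                            break
                    if fine:
                        ok_parent.add(pp)
                        for c in kids:
                            if sets[c] is not None:
                                ok_kids[c] |= {
                                    cp for cp in sets[c] if set(cp) & palleles
                                }
                for s, allowed in ((conc_id, ok_parent), *ok_kids.items()):
                    if sets.get(s) is not None:
                        new = sets[s] & allowed
                        if new != sets[s]:
                            sets[s] = new
                            changed = True
                continue
            ok_m: set[tuple[int, int]] = set()
            ok_f: set[tuple[int, int]] = set()
            ok_c: dict[str, set[tuple[int, int]]] = {c: set() for c in kids}
            for gm_pair in sm:
                for gf_pair in sf:
                    feasible = {
                        tuple(sorted((a, b))) for a in gm_pair for b in gf_pair
                    }
                    child_ok = {}
                    fine = True
                    for c in kids:
                        if sets[c] is None:
                            continue
                        hit = sets[c] & feasible
                        if not hit:
                            fine = False
                            break
                        child_ok[c] = hit
                    if fine:
                        ok_m.add(gm_pair)
                        ok_f.add(gf_pair)
                        for c, v in child_ok.items():
                            ok_c[c] |= v
            for s, allowed in ((m, ok_m), (f, ok_f), *ok_c.items()):
                if sets.get(s) is not None:
                    new = sets[s] & allowed
                    if new != sets[s]:
                        sets[s] = new
                        changed = True
    consistent = all(sets[s] is None or sets[s] for s in ids)
    return sets, consistent
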