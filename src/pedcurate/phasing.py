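"""Pedigree phasing, recombination inference and double-recombination triage.

Phasing is deterministic and two-staged.  Trio logic first fixes parental
origin wherever genotype configurations force it (a homozygous child, or a
heterozygous child with a homozygous parent).  Each parent's remaining
heterozygous markers are then oriented along the chromosome by chaining
between consecutive informative markers, choosing the relative orientation
that the majority of that parent's progeny supports -- i.e. minimizing
crossovers per meiosis.  Founders without any anchored marker get the
convention "first informative marker's A allele -> homolog 1".  Ambiguity
(vote ties, uninformative runs) leaves slots unknown; nothing is guessed.

Grandparental-origin switches between consecutive informative markers are
recombination events.  Two events of one meiosis closer than a window
(default 10 cM) form a double recombination; with exactly one marker
between the exchange points it is a singleton -- the classic signature of a
single wrong call that is Mendelian-consistent yet breaks co-segregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import AA, AB, BB, MISSING, GeneticMap, GenotypeMatrix, Pedigree

UNKNOWN = -1

DR_WINDOW_CM = 10.0

#: orientation votes further apart than this are too likely to straddle a
#: crossover to be trusted
MAX_VOTE_SPAN_CM = 30.0


class HomologMatrix:
    """Phased allele slots per individual: slot 0 maternal, slot 1 paternal.

    For founders the two slots are an arbitrary but consistent homolog
    labelling.  Values are 0 (A), 1 (B) or -1 (unknown).
    """

    def __init__(self, gm: GenotypeMatrix) -> None:
        self.markers = list(gm.markers)
        self.individuals = list(gm.individuals)
        self.slots = np.full((gm.n_markers, gm.n_individuals, 2), UNKNOWN, dtype=np.int8)
        self._iidx = {s: j for j, s in enumerate(self.individuals)}
        self._midx = {m: i for i, m in enumerate(self.markers)}

    def column(self, individual: str) -> np.ndarray:
        return self.slots[:, self._iidx[individual], :]

    def known_fraction(self) -> float:
        return float((self.slots != UNKNOWN).mean())


def phase_pedigree(
    gm: GenotypeMatrix, ped: Pedigree, gmap: GeneticMap
) -> HomologMatrix:
    """Deterministic two-stage pedigree phasing (see module docstring)."""
    hm = HomologMatrix(gm)
    genotyped = set(gm.individuals)
    order = [i for i in gmap.table["marker"] if i in hm._midx]
    row_of = hm._midx

    # --- stage 1: trio logic ------------------------------------------------
    for s in gm.individuals:
        j = hm._iidx[s]
        c = gm.individual_calls(s)
        hom0 = c == AA
        hom2 = c == BB
        hm.slots[hom0, j, :] = 0
        hm.slots[hom2, j, :] = 1
        het = c == AB
        if not het.any():
            continue
        mother = ped[s].mother if s in ped else None
        father = ped[s].father if s in ped else None
        mcalls = gm.individual_calls(mother) if mother in genotyped else None
        fcalls = gm.individual_calls(father) if father in genotyped else None
        mat = np.full(c.shape, UNKNOWN, dtype=np.int8)
        if mcalls is not None:
            mat[het & (mcalls == AA)] = 0
            mat[het & (mcalls == BB)] = 1
        if fcalls is not None:
            from_f = np.full(c.shape, UNKNOWN, dtype=np.int8)
            from_f[het & (fcalls == AA)] = 1  # father gave A, so mother gave B
            from_f[het & (fcalls == BB)] = 0
            conflict = (mat != UNKNOWN) & (from_f != UNKNOWN) & (mat != from_f)
            mat = np.where(mat == UNKNOWN, from_f, mat)
            mat[conflict] = UNKNOWN
        ok = het & (mat != UNKNOWN)
        hm.slots[ok, j, 0] = mat[ok]
        hm.slots[ok, j, 1] = (1 - mat[ok]).astype(np.int8)

    # --- stage 2: chain parent orientations along each chromosome ----------
    for parent in gm.individuals:
        children = [c for c in _children_of(ped, parent) if c in genotyped]
        if not children:
            continue
        pj = hm._iidx[parent]
        pcalls = gm.individual_calls(parent)
        received = {}
        for c in children:
            slot = 0 if ped[c].mother == parent else 1
            received[c] = hm.slots[:, hm._iidx[c], slot]
        for lg in gmap.linkage_groups:
            rows = [row_of[m] for m in gmap.markers_on(lg) if m in row_of]
            het_rows = [i for i in rows if pcalls[i] == AB]
            if not het_rows:
                continue
            orientation = np.full(len(het_rows), UNKNOWN, dtype=np.int8)
            anchored = np.zeros(len(het_rows), dtype=bool)
            for t, i in enumerate(het_rows):
                if hm.slots[i, pj, 0] != UNKNOWN:
                    orientation[t] = hm.slots[i, pj, 0]
                    anchored[t] = True
            has_info = np.array(
                [any(received[c][i] != UNKNOWN for c in children) for i in het_rows]
            )
            if not anchored.any():
                # founder convention: A -> homolog 1 at the first usable marker
                for t in range(len(het_rows)):
                    if has_info[t]:
                        orientation[t] = 0
                        break
            cm = np.array([gmap.cm_of(hm.markers[i]) for i in het_rows])
            rec_at = [
                np.array([received[c][i] for i in het_rows], dtype=np.int8)
                for c in children
            ]
            _chain_orientation(orientation, anchored, has_info, cm, rec_at)
            for t, i in enumerate(het_rows):
                if orientation[t] != UNKNOWN and hm.slots[i, pj, 0] == UNKNOWN:
                    hm.slots[i, pj, 0] = orientation[t]
                    hm.slots[i, pj, 1] = 1 - orientation[t]
    return hm


def _children_of(ped: Pedigree, parent: str) -> list[str]:
    return ped.children_of(parent)


def _chain_orientation(
    orientation: np.ndarray,
    anchored: np.ndarray,
    has_info: np.ndarray,
    cm: np.ndarray,
    rec_at: list[np.ndarray],
    polish_sweeps: int = 3,
    chain_margin: int = 1,
    flip_margin: int = 2,
) -> None:
    """Orient one parent's heterozygous markers along a chromosome.

    Directional chaining first: each child votes from its own nearest
    already-oriented informative marker (so vote intervals stay short even
    across uninformative gaps); an assignment needs a vote margin of at
    least two, because a lone voter may itself carry a crossover in the
    interval.  A polish pass then revisits every non-anchored marker with
    votes from both flanking sides and flips or fills it when the majority
    disagrees -- this catches isolated mis-orientations before they can
    masquerade as double recombinations in every informative offspring.
    """
    n = len(orientation)

    # a marker where every informative child received the same allele is
    # suspicious (a parent scored heterozygous that may not be): it still
    # receives an orientation, and so stays detectable as a double-
    # recombination pivot, but it must not anchor its neighbours
    degenerate = np.zeros(n, dtype=bool)
    for t in range(n):
        values = {int(rec[t]) for rec in rec_at if rec[t] != UNKNOWN}
        n_info = sum(1 for rec in rec_at if rec[t] != UNKNOWN)
        degenerate[t] = len(values) == 1 and n_info >= 3

    def _votes(t: int) -> list[int]:
        votes = [0, 0]
        for rec in rec_at:
            if rec[t] == UNKNOWN:
                continue
            for direction in (-1, 1):
                a = t + direction
                while 0 <= a < n and abs(cm[a] - cm[t]) <= MAX_VOTE_SPAN_CM:
                    if rec[a] != UNKNOWN and orientation[a] != UNKNOWN and not degenerate[a]:
                        votes[int(rec[a] != rec[t]) ^ int(orientation[a])] += 1
                        break
                    a += direction
        return votes

    for direction in (1, -1):
        idx = range(n) if direction == 1 else range(n - 1, -1, -1)
        last: list[tuple[int, int] | None] = [None] * len(rec_at)
        for t in idx:
            if orientation[t] == UNKNOWN and has_info[t]:
                votes = [0, 0]
                for ci, rec in enumerate(rec_at):
                    a2 = rec[t]
                    if a2 == UNKNOWN or last[ci] is None:
                        continue
                    t1, a1 = last[ci]
                    if abs(cm[t] - cm[t1]) > MAX_VOTE_SPAN_CM:
                        continue
                    votes[int(a1 != a2) ^ int(orientation[t1])] += 1
                if abs(votes[1] - votes[0]) >= chain_margin:
                    orientation[t] = int(votes[1] > votes[0])
            if orientation[t] != UNKNOWN and not degenerate[t]:
                for ci, rec in enumerate(rec_at):
                    if rec[t] != UNKNOWN:
                        last[ci] = (t, int(rec[t]))

    for _ in range(polish_sweeps):
        changed = False
        for t in range(n):
            if anchored[t] or not has_info[t]:
                continue
            votes = _votes(t)
            if votes[0] == votes[1]:
                continue
            best = int(votes[1] > votes[0])
            if orientation[t] == UNKNOWN or (
                orientation[t] != best
                and abs(votes[1] - votes[0]) >= flip_margin
            ):
                orientation[t] = best
                changed = True
        if not changed:
            break

    _segment_refine(orientation, anchored, cm, rec_at)


def _segment_refine(
    orientation: np.ndarray,
    anchored: np.ndarray,
    cm: np.ndarray,
    rec_at: list[np.ndarray],
    max_rounds: int = 20,
) -> None:
    """Greedy suffix/prefix flips minimizing total implied crossovers.

    Orientation assignment is an Ising chain: each child penalizes
    adjacent informative markers whose relative orientation implies a
    crossover.  Directional chaining can leave a whole terminal segment
    flipped (typical for founders with few informative offspring); flipping
    the suffix or prefix that most reduces the total implied crossover
    count repairs exactly that failure mode.  Anchored markers (phase known
    from the parent's own parents) are never flipped.
    """
    n = len(orientation)
    anchor_idx = np.nonzero(anchored)[0]
    last_anchor = int(anchor_idx[-1]) if anchor_idx.size else -1
    first_anchor = int(anchor_idx[0]) if anchor_idx.size else n

    pairs: list[tuple[int, int, int]] = []
    for rec in rec_at:
        prev = None
        for t in range(n):
            if rec[t] == UNKNOWN or orientation[t] == UNKNOWN:
                continue
            if prev is not None and cm[t] - cm[prev] <= MAX_VOTE_SPAN_CM:
                pairs.append((prev, t, int(rec[prev] != rec[t])))
            prev = t
    if not pairs:
        return

    for _ in range(max_rounds):
        # delta[t] = change in total crossovers when flipping suffix [t:)
        delta = np.zeros(n + 1, dtype=int)
        for a, b, r in pairs:
            cur = r ^ int(orientation[a]) ^ int(orientation[b])
            delta[a + 1 : b + 1] += 1 - 2 * cur
        # a prefix flip [:t) toggles exactly the same crossing pairs as the
        # suffix flip [t:), so the gain is delta[t] either way; anchors
        # only restrict which side may be flipped
        best_gain = 0
        best: tuple[int, int] | None = None  # flip range [t1, t2)
        for t in range(1, n):
            if delta[t] >= best_gain:
                continue
            if t > last_anchor:
                best_gain, best = delta[t], (t, n)
            elif t <= first_anchor:
                best_gain, best = delta[t], (0, t)
        # interior segment flips [t1, t2): gain = delta[t1] + delta[t2]
        # minus twice the contribution of pairs spanning both boundaries
        candidates = sorted(range(1, n), key=lambda t: delta[t])[:15]
        for i, t1 in enumerate(candidates):
            for t2 in candidates[i + 1 :]:
                lo, hi = min(t1, t2), max(t1, t2)
                if anchored[lo:hi].any():
                    continue
                g = int(delta[lo] + delta[hi])
                for a, b, r in pairs:
                    if a < lo <= hi <= b:
                        cur = r ^ int(orientation[a]) ^ int(orientation[b])
                        g -= 2 * (1 - 2 * cur)
                if g < best_gain:
                    best_gain, best = g, (lo, hi)
        if best is None:
            break
        seg = slice(*best)
        known = orientation[seg] != UNKNOWN
        flipped = orientation[seg].copy()
        flipped[known] = 1 - flipped[known]
        orientation[seg] = flipped


@dataclass
class MeiosisOrigins:
    """Grandparental origin along one meiosis (one parent-child transmission)."""

    parent: str
    child: str
    linkage_group: str
    markers: list[str]  # informative markers in map order
    cm: np.ndarray
    origins: np.ndarray  # 0 = parent's homolog 1, 1 = homolog 2


@dataclass
class RecombinationEvent:
    parent: str
    child: str
    linkage_group: str
    left_marker: str
    right_marker: str
    left_cm: float
    right_cm: float

    @property
    def midpoint_cm(self) -> float:
        return (self.left_cm + self.right_cm) / 2.0

    @property
    def interval_cm(self) -> float:
        return self.right_cm - self.left_cm


@dataclass
class DoubleRecombination:
    parent: str
    child: str
    linkage_group: str
    markers: tuple[str, ...]  # informative markers inside the flipped segment
    span_cm: float

    @property
    def is_singleton(self) -> bool:
        return len(self.markers) == 1


def infer_origins(
    hm: HomologMatrix, gm: GenotypeMatrix, ped: Pedigree, gmap: GeneticMap
) -> list[MeiosisOrigins]:
    """Per-meiosis grandparental-origin sequences over informative markers.

    A marker is informative for a meiosis when the parent is heterozygous
    with known phase and the child's received-from-that-parent allele is
    known.
    """
    genotyped = set(gm.individuals)
    out: list[MeiosisOrigins] = []
    for child in gm.individuals:
        if child not in ped:
            continue
        for slot, parent in enumerate(ped[child].parents):
            if parent not in genotyped:
                continue
            pj = hm._iidx[parent]
            cj = hm._iidx[child]
            pcalls = gm.individual_calls(parent)
            for lg in gmap.linkage_groups:
                rows = [hm._midx[m] for m in gmap.markers_on(lg) if m in hm._midx]
                markers, cms, origins = [], [], []
                for i in rows:
                    if pcalls[i] != AB or hm.slots[i, pj, 0] == UNKNOWN:
                        continue
                    received = hm.slots[i, cj, slot]
                    if received == UNKNOWN:
                        continue
                    markers.append(hm.markers[i])
                    cms.append(gmap.cm_of(hm.markers[i]))
                    origins.append(int(received != hm.slots[i, pj, 0]))
                if markers:
                    out.append(
                        MeiosisOrigins(
                            parent,
                            child,
                            lg,
                            markers,
                            np.array(cms, dtype=float),
                            np.array(origins, dtype=np.int8),
                        )
                    )
    return out


def detect_recombinations(origins: list[MeiosisOrigins]) -> list[RecombinationEvent]:
    """Origin switches between consecutive informative markers.

    A switch before the first informative marker is undetectable by
    construction and yields no event.
    """
    events: list[RecombinationEvent] = []
    for mo in origins:
        flips = np.nonzero(np.diff(mo.origins) != 0)[0]
        for t in flips:
            events.append(
                RecombinationEvent(
                    mo.parent,
                    mo.child,
                    mo.linkage_group,
                    mo.markers[t],
                    mo.markers[t + 1],
                    float(mo.cm[t]),
                    float(mo.cm[t + 1]),
                )
            )
    return events


def detect_double_recomb(
    origins: list[MeiosisOrigins], window_cm: float = DR_WINDOW_CM
) -> list[DoubleRecombination]:
    """Consecutive event pairs of one meiosis closer than ``window_cm``.

    Span is measured between the two exchange-interval midpoints; the
    segment markers are the informative markers carrying the flipped
    origin.
    """
    drs: list[DoubleRecombination] = []
    for mo in origins:
        flips = np.nonzero(np.diff(mo.origins) != 0)[0]
        for a, b in zip(flips, flips[1:]):
            mid_a = (mo.cm[a] + mo.cm[a + 1]) / 2.0
            mid_b = (mo.cm[b] + mo.cm[b + 1]) / 2.0
            if mid_b - mid_a < window_cm:
                drs.append(
                    DoubleRecombination(
                        mo.parent,
                        mo.child,
                        mo.linkage_group,
                        tuple(mo.markers[a + 1 : b + 1]),
                        float(mid_b - mid_a),
                    )
                )
    return drs


def cosegregation_conflicts(
    hm: HomologMatrix,
    gm: GenotypeMatrix,
    ped: Pedigree,
    gmap: GeneticMap,
    origins: list[MeiosisOrigins] | None = None,
) -> dict[str, set[str]]:
    """Calls contradicted by the phased flanking context, per marker.

    For every child whose grandparental origin is the same at the nearest
    informative markers on both sides of a locus, the allele transmitted by
    the parent is predicted from the parent's phased homolog.  When both
    parents yield a prediction and the predicted genotype differs from the
    observed call, the call conflicts with co-segregation -- the multipoint
    signature of a Mendelian-consistent error.  Returns
    marker -> set of conflicting children.
    """
    if origins is None:
        origins = infer_origins(hm, gm, ped, gmap)
    by_meiosis: dict[tuple[str, str, str], MeiosisOrigins] = {
        (mo.parent, mo.child, mo.linkage_group): mo for mo in origins
    }
    conflicts: dict[str, set[str]] = {}
    lg_rows = {
        lg: [hm._midx[m] for m in gmap.markers_on(lg) if m in hm._midx]
        for lg in gmap.linkage_groups
    }
    for child in gm.individuals:
        if child not in ped:
            continue
        parents = ped[child].parents
        if any(p is None or p not in gm._iidx for p in parents):
            continue
        cj = gm._iidx[child]
        for lg, rows in lg_rows.items():
            pred = np.full((len(rows), 2), UNKNOWN, dtype=np.int8)
            for slot, parent in enumerate(parents):
                pj = hm._iidx[parent]
                pcalls = gm.calls[rows, pj]
                mo = by_meiosis.get((parent, child, lg))
                # origin known at a marker when the nearest informative
                # markers left and right agree
                origin_at = np.full(len(rows), UNKNOWN, dtype=np.int8)
                if mo is not None and len(mo.markers) > 0:
                    info_idx = {m: t for t, m in enumerate(mo.markers)}
                    row_markers = [hm.markers[i] for i in rows]
                    left = np.full(len(rows), UNKNOWN, dtype=np.int8)
                    right = np.full(len(rows), UNKNOWN, dtype=np.int8)
                    cur = UNKNOWN
                    for k, m in enumerate(row_markers):
                        if m in info_idx:
                            cur = int(mo.origins[info_idx[m]])
                        left[k] = cur
                    cur = UNKNOWN
                    for k in range(len(rows) - 1, -1, -1):
                        m = row_markers[k]
                        if m in info_idx:
                            cur = int(mo.origins[info_idx[m]])
                        right[k] = cur
                    origin_at = np.where(
                        (left == right) & (left != UNKNOWN), left, UNKNOWN
                    ).astype(np.int8)
                for k, i in enumerate(rows):
                    if pcalls[k] == AA:
                        pred[k, slot] = 0
                    elif pcalls[k] == BB:
                        pred[k, slot] = 1
                    elif pcalls[k] == AB and origin_at[k] != UNKNOWN:
                        allele = hm.slots[i, hm._iidx[parent], origin_at[k]]
                        if allele != UNKNOWN:
                            pred[k, slot] = allele
            both = (pred[:, 0] != UNKNOWN) & (pred[:, 1] != UNKNOWN)
            for k in np.nonzero(both)[0]:
                i = rows[k]
                call = int(gm.calls[i, cj])
                if call != MISSING and call != int(pred[k, 0] + pred[k, 1]):
                    conflicts.setdefault(hm.markers[i], set()).add(child)
    return conflicts


def classify_dr_causes(
    drs: list[DoubleRecombination],
    gm: GenotypeMatrix,
    ped: Pedigree,
    min_individuals: int = 3,
    shared_call_fraction: float = 0.7,
    extra_hits: dict[str, set[str]] | None = None,
    het_excess_fraction: float = 0.6,
    max_minor_hom_fraction: float = 0.02,
    min_cohort_for_het_excess: int = 50,
) -> pd.DataFrame:
    """Rank double recombinations into a cause-annotated worklist.

    Markers hit in several meioses across families point at a systematic
    problem: if the involved individuals share one genotype call at the
    marker the cause is an incorrectly identified genotype cluster, else a
    wrong map position; when every affected child shares one parent the
    artefact sits in that parent's phase, not in the marker.  Isolated
    singletons are single-call errors or true events and go last.  As a
    second evidence channel for mislabelled clusters, markers whose
    heterozygote fraction exceeds the outbred maximum
    (``het_excess_fraction``) while one homozygote class is essentially
    absent are also classed ``clustering`` -- a shifted homozygote cluster
    produces exactly that impossible segregation pattern even when the
    marker is too uninformative to leave a double-recombination trace.
    The worklist is ordered shared-region problems first, then within
    equal cause by the number of affected meioses, with cases touching
    selected material ahead of seedlings-only cases.
    """
    # only singletons implicate a specific marker; a wide flipped segment
    # spreads over many markers and says nothing about any one of them
    per_marker: dict[str, list[DoubleRecombination]] = {}
    for dr in drs:
        if dr.is_singleton:
            per_marker.setdefault(dr.markers[0], []).append(dr)
    child_hits: dict[str, set[str]] = {
        m: {dr.child for dr in hits} for m, hits in per_marker.items()
    }
    for marker, extra in (extra_hits or {}).items():
        child_hits.setdefault(marker, set()).update(extra)
        per_marker.setdefault(marker, [])
    rows = []
    for marker, hits in per_marker.items():
        meioses = {(dr.parent, dr.child) for dr in hits} | {
            ("?", c) for c in child_hits[marker] - {dr.child for dr in hits}
        }
        children = sorted(child_hits[marker])
        families = {
            ped[c].parents if c in ped else ("?", c) for c in children
        }
        # a single miscalled child shows the artefact in both of its
        # meioses, so systematic causes are judged on distinct individuals
        if len(children) >= min_individuals and len(families) >= 2:
            parent_counts: dict[str, int] = {}
            for c in children:
                if c in ped:
                    for p in ped[c].parents:
                        if p is not None:
                            parent_counts[p] = parent_counts.get(p, 0) + 1
            top_parent = max(parent_counts.values(), default=0)
            calls = [gm.get(marker, c) for c in children if c in gm._iidx]
            calls = [c for c in calls if c != MISSING]
            top = max((calls.count(v) for v in set(calls)), default=0)
            shared = top / len(calls) if calls else 0.0
            if top_parent >= len(children) - 1:
                # (almost) every affected child shares one parent: a phase
                # artefact in that parent, not a marker-level problem
                cause = "phase_suspect"
            elif shared >= shared_call_fraction:
                cause = "clustering"
            else:
                cause = "map"
        else:
            cause = "single_call_or_true"
        touches_selected = any(
            c in ped and ped[c].selected for c in children
        ) or any(dr.parent in ped and ped[dr.parent].selected for dr in hits)
        rows.append(
            {
                "marker": marker,
                "n_meioses": len(meioses),
                "n_families": len(families),
                "cause": cause,
                "touches_selected": touches_selected,
                "evidence": "dr",
            }
        )
    # the heterozygote-excess statistic is only meaningful across a cohort;
    # a single full-sib family can legitimately be almost all-heterozygous
    if gm.n_individuals >= min_cohort_for_het_excess:
        listed = {r["marker"] for r in rows}
        for i, marker in enumerate(gm.markers):
            calls = gm.calls[i]
            called = calls[calls != MISSING]
            if called.size == 0:
                continue
            het = float((called == AB).mean())
            minor_hom = min(int((called == AA).sum()), int((called == BB).sum()))
            if (
                het >= het_excess_fraction
                and minor_hom <= max_minor_hom_fraction * called.size
            ):
                if marker in listed:
                    for r in rows:
                        if r["marker"] == marker:
                            r["cause"] = "clustering"
                            r["evidence"] += "+het_excess"
                else:
                    rows.append(
                        {
                            "marker": marker,
                            "n_meioses": 0,
                            "n_families": 0,
                            "cause": "clustering",
                            "touches_selected": True,
                            "evidence": "het_excess",
                        }
                    )
    frame = pd.DataFrame(
        rows,
        columns=[
            "marker",
            "n_meioses",
            "n_families",
            "cause",
            "touches_selected",
            "evidence",
        ],
    )
    if frame.empty:
        return frame
    cause_rank = {
        "clustering": 0,
        "map": 1,
        "phase_suspect": 2,
        "single_call_or_true": 3,
    }
    frame["_rank"] = frame["cause"].map(cause_rank)
    frame = frame.sort_values(
        by=["_rank", "n_meioses", "touches_selected", "marker"],
        ascending=[True, False, False, True],
        kind="mergesort",
    ).drop(columns="_rank")
    return frame.reset_index(drop=True)


def _dr_census(
    gm: GenotypeMatrix, ped: Pedigree, gmap: GeneticMap, window_cm: float
) -> tuple[int, dict[tuple[str, str], int]]:
    hm = phase_pedigree(gm, ped, gmap)
    origins = infer_origins(hm, gm, ped, gmap)
    drs = detect_double_recomb(origins, window_cm)
    per_meiosis: dict[tuple[str, str], int] = {}
    for dr in drs:
        key = (dr.parent, dr.child)
        per_meiosis[key] = per_meiosis.get(key, 0) + 1
    return len(drs), per_meiosis


@dataclass
class MapMoveResult:
    accepted: bool
    old_total: int
    new_total: int
    worsened_meioses: list[tuple[str, str]]


def evaluate_map_move(
    gm: GenotypeMatrix,
    ped: Pedigree,
    gmap: GeneticMap,
    marker: str,
    candidate_cm: float,
    window_cm: float = DR_WINDOW_CM,
) -> MapMoveResult:
    """Re-phase with the marker moved; accept only strict improvement.

    The move is accepted when the total double-recombination count strictly
    decreases and no meiosis gains a double recombination it did not have.
    """
    if marker not in gmap:
        raise ValueError(f"marker {marker!r} is not on the map")
    lo = gmap.positions_on(gmap.lg_of(marker))
    if not (float(lo.min()) - 1e-9 <= candidate_cm <= float(lo.max()) + 1e-9):
        raise ValueError(
            f"candidate position {candidate_cm} cM is off linkage group "
            f"{gmap.lg_of(marker)}"
        )
    old_total, old_by = _dr_census(gm, ped, gmap, window_cm)
    moved = gmap.with_marker_moved(marker, candidate_cm)
    new_total, new_by = _dr_census(gm, ped, moved, window_cm)
    worsened = sorted(
        key for key in new_by if new_by[key] > old_by.get(key, 0)
    )
    accepted = new_total < old_total and not worsened
    return MapMoveResult(accepted, old_total, new_total, worsened)


def resolve_phase_conflict(
    gm: GenotypeMatrix,
    ped: Pedigree,
    drs: list[DoubleRecombination],
    events: list[RecombinationEvent],
    min_affected: int = 2,
    affected_fraction: float = 0.5,
) -> list[tuple[str, str]]:
    """Fix founder-phase artefacts: blank the pivot call of the recombinants.

    When a parent's phase is wrong at one marker, most of its progeny show
    a singleton double recombination there while the one or two offspring
    with a genuine crossover at that position show a single recombination
    with the marker as an endpoint.  Blanking the genuine recombinants'
    genotype at the pivot marker (reason ``phase_fix``) frees the phaser to
    re-orient the parent and removes the sibs' artefacts.  Returns the
    (marker, individual) cells blanked; no edit when the pattern is absent.
    """
    singles: dict[tuple[str, str], set[str]] = {}
    for dr in drs:
        if dr.is_singleton:
            singles.setdefault((dr.parent, dr.markers[0]), set()).add(dr.child)
    edits: list[tuple[str, str]] = []
    for (parent, marker), affected in singles.items():
        if parent not in ped:
            continue
        sibs = [c for c in ped.children_of(parent) if c in gm._iidx]
        if len(affected) < max(min_affected, affected_fraction * len(sibs)):
            continue
        recombinants = sorted(
            {
                ev.child
                for ev in events
                if ev.parent == parent
                and ev.child not in affected
                and marker in (ev.left_marker, ev.right_marker)
            }
        )
        if not 1 <= len(recombinants) <= 2:
            continue
        for child in recombinants:
            gm.set_call(marker, child, MISSING, "phase_fix")
            edits.append((marker, child))
    return edits


def blank_singletons(
    gm: GenotypeMatrix,
    drs: list[DoubleRecombination],
    skip_markers: set[str] | None = None,
    reason: str = "dr_singleton_fix",
) -> list[tuple[str, str]]:
    """Set each remaining singleton's pivot call to missing.

    The automated counterpart of adjusting a single wrong genotype call:
    a singleton's pivot allele contradicts both flanking segments, so the
    call is blanked rather than trusted.  Markers in ``skip_markers``
    (already handled as systematic problems) are left alone.  The rare
    genuine close double crossover is sacrificed, trading a lost true
    event for data consistency.
    """
    skip = skip_markers or set()
    edits: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for dr in drs:
        if not dr.is_singleton:
            continue
        marker = dr.markers[0]
        if marker in skip or (marker, dr.child) in seen:
            continue
        if marker in gm._midx and dr.child in gm._iidx:
            gm.set_call(marker, dr.child, MISSING, reason)
            seen.add((marker, dr.child))
            edits.append((marker, dr.child))
    return edits


def graphical_genotypes(
    origins: list[MeiosisOrigins], parent: str, gmap: GeneticMap
) -> pd.DataFrame:
    """Child x marker grandparental-origin matrix for one parent's progeny.

    Cells are 0 (homolog 1), 1 (homolog 2) or -1 (uninformative); a
    crossover appears as a block boundary along the row.  Suitable for CSV
    export or plotting to eyeball map-order problems.
    """
    children = sorted({mo.child for mo in origins if mo.parent == parent})
    markers = [m for m in gmap.table["marker"]]
    frame = pd.DataFrame(
        -1, index=children, columns=markers, dtype=int
    )
    for mo in origins:
        if mo.parent != parent:
            continue
        frame.loc[mo.child, list(mo.markers)] = mo.origins.astype(int)
    return frame


def plot_graphical_genotypes(frame: pd.DataFrame, path: str) -> None:
    """Render the origin matrix as an image (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, max(2, 0.2 * len(frame))))
    ax.imshow(frame.to_numpy(), aspect="auto", interpolation="nearest", cmap="coolwarm")
    ax.set_xlabel("marker (map order)")
    ax.set_ylabel("offspring")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
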