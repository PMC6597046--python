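"""Pedigree phasing, recombination events, and double-recombination triage."""

import numpy as np
import pytest

from pedcurate.datamodel import (
    AA,
    AB,
    BB,
    MISSING,
    GeneticMap,
    GenotypeMatrix,
    Individual,
    Pedigree,
)
from pedcurate.phasing import (
    MeiosisOrigins,
    classify_dr_causes,
    cosegregation_conflicts,
    detect_double_recomb,
    detect_recombinations,
    evaluate_map_move,
    graphical_genotypes,
    infer_origins,
    phase_pedigree,
    resolve_phase_conflict,
)


def informative_family(n_children=6, n_markers=30, seed=0, crossovers=None):
    """One fully informative family: father het everywhere, mother AA.

    ``crossovers`` maps child index -> marker index at which the paternal
    gamete switches homolog (before that marker: homolog 1).
    """
    rng = np.random.default_rng(seed)
    markers = [f"m{i:03d}" for i in range(n_markers)]
    gmap = GeneticMap.from_positions(markers, ["1"] * n_markers, list(range(n_markers)))
    h1 = rng.integers(0, 2, n_markers).astype(np.int8)
    h2 = (1 - h1).astype(np.int8)
    individuals = ["dad", "mom"] + [f"kid{i}" for i in range(n_children)]
    calls = np.zeros((n_markers, len(individuals)), dtype=np.int8)
    calls[:, 0] = AB
    calls[:, 1] = AA
    truth = {}
    crossovers = crossovers or {}
    for c in range(n_children):
        start = int(rng.integers(2))  # independent gamete per meiosis
        switch = crossovers.get(c, n_markers)
        homolog = np.where(np.arange(n_markers) < switch, start, 1 - start)
        received = np.where(homolog == 0, h1, h2).astype(np.int8)
        truth[f"kid{c}"] = received
        calls[:, 2 + c] = received  # mother always gives A (0)
    gm = GenotypeMatrix(markers, individuals, calls)
    ped = Pedigree(
        [Individual("dad", selected=True), Individual("mom", selected=True)]
        + [Individual(f"kid{i}", mother="mom", father="dad") for i in range(n_children)]
    )
    return gm, ped, gmap, h1, truth


class TestPhasePedigree:
    def test_homozygous_parent_forces_child_slot(self):
        gm, ped, gmap, h1, truth = informative_family()
        hm = phase_pedigree(gm, ped, gmap)
        for c in range(6):
            mat = hm.column(f"kid{c}")[:, 0]
            assert (mat == 0).all()  # AA mother transmits A everywhere

    def test_fully_informative_phase_matches_generator_truth(self):
        gm, ped, gmap, h1, truth = informative_family(crossovers={2: 15})
        hm = phase_pedigree(gm, ped, gmap)
        dad = hm.column("dad")
        # father's homolog labelling is arbitrary: allow a global swap
        direct = (dad[:, 0] == h1).all()
        swapped = (dad[:, 0] == 1 - h1).all()
        assert direct or swapped
        for c in range(6):
            pat = hm.column(f"kid{c}")[:, 1]
            assert (pat == truth[f"kid{c}"]).all()

    def test_uninformative_runs_stay_unknown(self):
        gm, ped, gmap, h1, truth = informative_family()
        # make mother heterozygous at 20% of markers: a het child with two
        # het parents is phase-ambiguous there
        rng = np.random.default_rng(1)
        amb = rng.choice(gm.n_markers, gm.n_markers // 5, replace=False)
        for i in amb:
            gm.calls[i, 1] = AB
            # child calls must stay genotype-consistent: A from mother
        hm = phase_pedigree(gm, ped, gmap)
        for c in range(6):
            col = hm.column(f"kid{c}")
            het = gm.calls[:, 2 + c] == AB
            known = col[:, 1] != -1
            # no incorrect assignment: where known, it equals the truth
            ok = col[het & known, 1] == truth[f"kid{c}"][het & known]
            assert ok.all()


class TestRecombinationEvents:
    def test_single_crossover_yields_one_containing_event(self):
        gm, ped, gmap, h1, truth = informative_family(crossovers={0: 12})
        hm = phase_pedigree(gm, ped, gmap)
        events = [
            e
            for e in detect_recombinations(infer_origins(hm, gm, ped, gmap))
            if e.child == "kid0"
        ]
        assert len(events) == 1
        assert events[0].left_cm <= 12 <= events[0].right_cm

    def test_no_crossover_no_event(self):
        gm, ped, gmap, h1, truth = informative_family()
        hm = phase_pedigree(gm, ped, gmap)
        assert detect_recombinations(infer_origins(hm, gm, ped, gmap)) == []

    def test_error_free_cohort_events_track_truth(self, clean_sim):
        ds = clean_sim
        hm = phase_pedigree(ds.gm, ds.pedigree, ds.gmap)
        origins = infer_origins(hm, ds.gm, ds.pedigree, ds.gmap)
        events = detect_recombinations(origins)
        truth = {
            (m.parent, m.child, m.linkage_group): m.crossover_cm
            for m in ds.truth.meioses
        }
        contained = sum(
            1
            for e in events
            if any(
                e.left_cm <= x <= e.right_cm
                for x in truth.get((e.parent, e.child, e.linkage_group), [])
            )
        )
        assert contained / len(events) >= 0.95
        from collections import Counter

        det = Counter((e.parent, e.child, e.linkage_group) for e in events)
        excess = sum(
            1 for k, v in det.items() if v > len(truth.get(k, []))
        )
        assert excess / len(origins) <= 0.05


def origins_with_flips(flip_at, n=40, spacing=1.0):
    markers = [f"m{i:03d}" for i in range(n)]
    cm = np.arange(n) * spacing
    origin = np.zeros(n, dtype=np.int8)
    for t in flip_at:
        origin[t:] = 1 - origin[t:]
    return MeiosisOrigins("p", "c", "1", markers, cm, origin)


class TestDoubleRecomb:
    def test_close_event_pair_is_one_dr(self):
        mo = origins_with_flips([10, 14])
        (dr,) = detect_double_recomb([mo])
        assert dr.span_cm == pytest.approx(4.0)
        assert not dr.is_singleton

    def test_distant_events_are_not_dr(self):
        assert detect_double_recomb([origins_with_flips([10, 25])]) == []

    def test_injected_miscall_appears_as_singleton(self):
        gm, ped, gmap, h1, truth = informative_family()
        # flip kid0's call at marker 10: its received allele now contradicts
        # both flanking segments
        gm.calls[10, 2] = AB if gm.calls[10, 2] != AB else AA
        hm = phase_pedigree(gm, ped, gmap)
        drs = detect_double_recomb(infer_origins(hm, gm, ped, gmap))
        singles = [d for d in drs if d.child == "kid0" and d.is_singleton]
        assert any(d.markers == ("m010",) for d in singles)


class TestCauseClassification:
    def test_cluster_shift_marker_tops_worklist(self, default_sim, default_run):
        state = default_run
        reg = default_sim.truth.registry
        shifted = set(reg.loc[reg.kind == "cluster_shift", "marker"])
        tagged = {
            m for m, tags in state.ledger.tags.items() if "cluster_shift" in tags
        }
        assert len(tagged & shifted) / len(shifted) >= 0.95

    def test_isolated_singleton_ranked_last(self):
        gm, ped, gmap, h1, truth = informative_family(n_children=8)
        gm.calls[10, 2] = AB if gm.calls[10, 2] != AB else AA
        hm = phase_pedigree(gm, ped, gmap)
        drs = detect_double_recomb(infer_origins(hm, gm, ped, gmap))
        wl = classify_dr_causes(drs, gm, ped)
        if not wl.empty:
            assert set(wl["cause"]) <= {"single_call_or_true", "phase_suspect"}

    def test_wrong_map_position_flagged_from_drs(self, clean_sim):
        ds = clean_sim
        marker = ds.gmap.markers_on("1")[60]
        bad_map = ds.gmap.with_marker_moved(marker, ds.gmap.cm_of(marker) + 40.0)
        hm = phase_pedigree(ds.gm, ds.pedigree, bad_map)
        origins = infer_origins(hm, ds.gm, ds.pedigree, bad_map)
        drs = detect_double_recomb(origins)
        wl = classify_dr_causes(drs, ds.gm, ds.pedigree)
        hits = wl.loc[wl["marker"] == marker]
        assert not hits.empty
        assert hits.iloc[0]["cause"] in ("map", "clustering")


class TestMapMove:
    def test_moving_misplaced_marker_back_is_accepted(self, clean_sim):
        ds = clean_sim
        marker = ds.gmap.markers_on("1")[60]
        true_cm = ds.gmap.cm_of(marker)
        bad_map = ds.gmap.with_marker_moved(marker, true_cm + 40.0)
        res = evaluate_map_move(ds.gm, ds.pedigree, bad_map, marker, true_cm)
        assert res.accepted
        assert res.new_total < res.old_total

    def test_moving_to_current_position_is_rejected(self, clean_sim):
        ds = clean_sim
        marker = ds.gmap.markers_on("1")[60]
        res = evaluate_map_move(
            ds.gm, ds.pedigree, ds.gmap, marker, ds.gmap.cm_of(marker)
        )
        assert not res.accepted

    def test_off_linkage_group_position_rejected(self, clean_sim):
        ds = clean_sim
        marker = ds.gmap.markers_on("1")[0]
        with pytest.raises(ValueError, match="off linkage group"):
            evaluate_map_move(ds.gm, ds.pedigree, ds.gmap, marker, 1e6)


class TestPhaseConflict:
    def _family_with_founder_phase_error(self):
        gm, ped, gmap, h1, truth = informative_family(
            n_children=6, crossovers={5: 10}
        )
        hm = phase_pedigree(gm, ped, gmap)
        # engineer the failure mode of interval-minimizing phasers: the
        # founder's phase is flipped at the crossover child's pivot marker
        pj = hm._iidx["dad"]
        hm.slots[10, pj, 0], hm.slots[10, pj, 1] = (
            hm.slots[10, pj, 1],
            hm.slots[10, pj, 0],
        )
        origins = infer_origins(hm, gm, ped, gmap)
        events = detect_recombinations(origins)
        drs = detect_double_recomb(origins)
        return gm, ped, events, drs

    def test_recombinant_child_call_blanked(self):
        gm, ped, events, drs = self._family_with_founder_phase_error()
        # most sibs show a singleton at the pivot
        singles = [d for d in drs if d.is_singleton and d.markers == ("m010",)]
        assert len(singles) >= 3
        edits = resolve_phase_conflict(gm, ped, drs, events)
        assert ("m010", "kid5") in edits
        assert gm.get("m010", "kid5") == MISSING
        assert gm.edit_log[-1].reason == "phase_fix"

    def test_no_pattern_no_edits(self):
        gm, ped, gmap, h1, truth = informative_family()
        hm = phase_pedigree(gm, ped, gmap)
        origins = infer_origins(hm, gm, ped, gmap)
        edits = resolve_phase_conflict(
            gm, ped, detect_double_recomb(origins), detect_recombinations(origins)
        )
        assert edits == []


class TestCosegregationConflicts:
    def test_injected_miscall_is_a_conflict(self):
        gm, ped, gmap, h1, truth = informative_family()
        original = gm.get("m010", "kid1")
        gm.set_call("m010", "kid1", AB if original != AB else BB, "inject")
        hm = phase_pedigree(gm, ped, gmap)
        conflicts = cosegregation_conflicts(hm, gm, ped, gmap)
        assert "kid1" in conflicts.get("m010", set())

    def test_clean_family_has_no_conflicts(self):
        gm, ped, gmap, h1, truth = informative_family()
        hm = phase_pedigree(gm, ped, gmap)
        assert cosegregation_conflicts(hm, gm, ped, gmap) == {}


class TestGraphicalGenotypes:
    def test_origin_matrix_shows_crossover_block_boundary(self):
        gm, ped, gmap, h1, truth = informative_family(crossovers={1: 12})
        hm = phase_pedigree(gm, ped, gmap)
        origins = infer_origins(hm, gm, ped, gmap)
        frame = graphical_genotypes(origins, "dad", gmap)
        row = frame.loc["kid1"].to_numpy()
        informative = row >= 0
        values = row[informative]
        switches = np.sum(np.diff(values) != 0)
        assert switches == 1
        # kid0 has no crossover: constant origin
        row0 = frame.loc["kid0"].to_numpy()
        assert len(set(row0[row0 >= 0])) == 1
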