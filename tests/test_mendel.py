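"""Genotype elimination, inconsistency localization and forced imputation."""

import numpy as np
import pytest

from pedcurate.datamodel import AA, AB, BB, MISSING, GenotypeMatrix, Individual, Pedigree
from pedcurate.mendel import (
    ConsistencyReport,
    eliminate_genotypes,
    eliminate_multiallelic,
    find_inconsistencies,
    impute_forced,
    repair_inconsistencies,
)
from pedcurate.simulate import SimulationConfig, simulate_dataset

from conftest import make_matrix


def bits(*genotypes):
    return sum(1 << g for g in genotypes)


class TestEliminate:
    def test_impossible_trio_empties_child_set(self, trio_ped):
        gm = make_matrix({"m1": {"mom": "AA", "dad": "AA", "kid": "AB"}})
        sets = eliminate_genotypes(trio_ped, gm)
        assert (sets.loc["m1"] == 0).any()

    def test_conflict_detected_through_ungenotyped_generation(self):
        # grandparents AA x AA -> parent must be AA; with an AA spouse the
        # grandchild cannot be BB, even though the parent is ungenotyped
        ped = Pedigree(
            [
                Individual("gm"),
                Individual("gf"),
                Individual("parent", mother="gm", father="gf"),
                Individual("spouse"),
                Individual("kid", mother="parent", father="spouse"),
            ]
        )
        gm = make_matrix(
            {"m1": {"gm": "AA", "gf": "AA", "spouse": "AA", "kid": "BB"}}
        )
        sets = eliminate_genotypes(ped, gm)
        assert (sets.loc["m1"] == 0).any()

    def test_ungenotyped_parent_forced_to_carry_b_when_child_het(self):
        ped = Pedigree(
            [Individual("p"), Individual("q")]
            + [Individual(f"c{i}", mother="p", father="q") for i in range(10)]
        )
        calls = {"m1": {"q": "AA"}}
        calls["m1"].update({f"c{i}": "AB" if i == 0 else "AA" for i in range(10)})
        gm = make_matrix(calls)
        sets = eliminate_genotypes(ped, gm)
        # p is unobserved but must carry a B allele (AB or BB)
        assert sets.at["m1", "p"] & bits(AA) == 0
        assert sets.at["m1", "p"] != 0

    def test_sets_only_shrink_from_observations(self, clean_sim):
        ds = clean_sim
        sub = ds.gm.subset(markers=ds.gm.markers[:30])
        sets = eliminate_genotypes(ds.pedigree, sub)
        for marker in sub.markers:
            for ind in sub.individuals:
                observed = sub.get(marker, ind)
                mask = int(sets.at[marker, ind])
                if observed != MISSING:
                    assert mask & ~bits(observed) == 0


class TestFindInconsistencies:
    def test_error_free_simulation_has_zero_flags(self, clean_sim):
        ds = clean_sim
        report = find_inconsistencies(ds.pedigree, ds.gm)
        assert report.n_errors == 0

    def test_single_injected_miscall_flags_its_own_trio(self, clean_sim):
        ds = clean_sim
        gm = ds.gm.copy()
        ped = ds.pedigree
        child = next(s for s in gm.individuals if ped[s].mother is not None)
        marker = next(
            m
            for m in gm.markers
            if gm.get(m, ped[child].mother) == AA and gm.get(m, ped[child].father) == AA
        )
        gm.set_call(marker, child, BB, "inject")
        report = find_inconsistencies(ped, gm)
        flagged = {(m, i) for m, i in report.flags}
        assert (marker, child) in flagged
        trio = {child, ped[child].mother, ped[child].father}
        assert all(m == marker and i in trio for m, i in flagged)

    def test_counts_equal_flag_totals(self, clean_sim):
        ds = clean_sim
        gm = ds.gm.copy()
        ped = ds.pedigree
        child = next(s for s in gm.individuals if ped[s].mother is not None)
        gm.set_call(gm.markers[0], child, BB if gm.get(gm.markers[0], child) != BB else AA, "inject")
        report = find_inconsistencies(ped, gm)
        assert sum(report.per_marker.values()) == report.n_errors
        assert sum(report.per_individual.values()) == report.n_errors

    def test_miscall_localization_recall(self):
        """Most markers carrying one detectable miscall flag the true cell."""
        ds = simulate_dataset(
            SimulationConfig(
                seed=17,
                n_founders=30,
                generation_sizes=(50, 80),
                n_linkage_groups=2,
                n_markers_per_lg=250,
                random_miscall_rate=0.005,
                missing_rate=0.0,
                cluster_shift_fraction=0.0,
                n_wrong_parents=0,
                n_duplicate_pairs=0,
                n_triploids=0,
                n_bad_quality=0,
            )
        )
        reg = ds.truth.registry
        miscalls = reg.loc[reg.kind == "random_miscall"]
        per_marker = miscalls.groupby("marker")["individual"].apply(set)
        report = find_inconsistencies(ds.pedigree, ds.gm)
        # no false positives: flagged markers all carry an injected miscall
        assert set(report.per_marker) <= set(per_marker.index)
        # localization: where a single-miscall marker is flagged, the
        # flagged set contains the miscalled cell's nuclear neighbourhood
        hit = miss = 0
        flagged = {}
        for m, i in report.flags:
            flagged.setdefault(m, set()).add(i)
        for marker, inds in flagged.items():
            truth_inds = per_marker[marker]
            if len(truth_inds) != 1:
                continue
            (true_ind,) = truth_inds
            family = {true_ind}
            if true_ind in ds.pedigree:
                family |= {p for p in ds.pedigree[true_ind].parents if p}
                family |= set(ds.pedigree.children_of(true_ind))
            if inds & family:
                hit += 1
            else:
                miss += 1
        assert hit / (hit + miss) >= 0.95


class TestRepairAndImpute:
    def test_repair_reaches_zero_inconsistencies(self, clean_sim):
        ds = clean_sim
        gm = ds.gm.copy()
        ped = ds.pedigree
        rng = np.random.default_rng(2)
        for idx in rng.choice(gm.n_markers, 20, replace=False):
            j = int(rng.integers(gm.n_individuals))
            gm.calls[idx, j] = (gm.calls[idx, j] + 1) % 3
        repair_inconsistencies(gm, ped)
        assert find_inconsistencies(ped, gm).n_errors == 0
        assert all(e.reason == "mendel_inconsistent" for e in gm.edit_log)

    def test_no_missing_data_no_imputations(self, clean_sim):
        ds = clean_sim
        assert impute_forced(ds.pedigree, ds.gm.copy()) == []

    def test_withheld_individual_imputations_match_truth(self, clean_sim):
        ds = clean_sim
        gm = ds.gm.copy()
        ped = ds.pedigree
        # blank a mid-generation individual entirely and re-impute
        victim = next(
            s
            for s in gm.individuals
            if ped[s].mother is not None and ped.children_of(s)
        )
        truth = gm.individual_calls(victim).copy()
        j = gm.individual_index(victim)
        gm.calls[:, j] = MISSING
        imputed = impute_forced(ped, gm, apply=True)
        ours = [(m, c) for m, ind, c in imputed if ind == victim]
        assert len(ours) > 0
        correct = sum(
            1 for m, c in ours if truth[gm.marker_index(m)] == c
        )
        assert correct / len(ours) >= 0.99
        # imputation never creates a new inconsistency
        assert find_inconsistencies(ped, gm).n_errors == 0


class TestMultiallelic:
    @pytest.fixture
    def ped(self, trio_ped):
        return trio_ped

    def test_unexplained_child_code_is_inconsistent(self, ped):
        genotypes = {"mom": (1, 2), "dad": (4, 5), "kid": (1, 3)}
        _, ok = eliminate_multiallelic(ped, genotypes, {1, 2, 3, 4, 5})
        assert not ok

    def test_feasible_trio_is_consistent(self, ped):
        genotypes = {"mom": (1, 2), "dad": (4, 5), "kid": (2, 4)}
        _, ok = eliminate_multiallelic(ped, genotypes, {1, 2, 4, 5})
        assert ok

    def test_missing_parent_is_unconstrained(self, ped):
        genotypes = {"mom": (1, 2), "dad": None, "kid": (2, 9)}
        _, ok = eliminate_multiallelic(ped, genotypes, {1, 2, 9})
        assert ok

    def test_conflict_through_missing_intermediate(self):
        # grandparents carry {1,2}; the ungenotyped parent must pass 1 or 2,
        # so a grandchild code pair without either (given spouse (5,6)) fails
        ped = Pedigree(
            [
                Individual("gm"),
                Individual("gf"),
                Individual("p", mother="gm", father="gf"),
                Individual("sp"),
                Individual("kid", mother="p", father="sp"),
            ]
        )
        genotypes = {
            "gm": (1, 1),
            "gf": (2, 2),
            "p": None,
            "sp": (5, 6),
            "kid": (3, 5),
        }
        _, ok = eliminate_multiallelic(ped, genotypes, {1, 2, 3, 5, 6})
        assert not ok
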