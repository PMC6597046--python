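"""Parent-child and parent-pair error counting, calibration and search."""

import itertools

import numpy as np
import pytest

from pedcurate.datamodel import AA, AB, BB, MISSING
from pedcurate.parentage import (
    FEASIBLE,
    calibrate_pc_threshold,
    calibrate_ppc_threshold,
    grandparent_test,
    pc_errors,
    ppc_errors,
    recorded_pc_pairs,
    search_parents,
    verify_pedigree,
)
from pedcurate.simulate import SimulationConfig, simulate_dataset


def arr(*calls):
    return np.array(calls, dtype=np.int8)


class TestPcErrors:
    def test_opposing_homozygotes_counted(self):
        assert pc_errors(arr(BB), arr(AA)) == 1
        assert pc_errors(arr(AA), arr(BB)) == 1
        assert pc_errors(arr(AB), arr(AA)) == 0
        assert pc_errors(arr(AA, MISSING), arr(BB, BB)) == 1

    def test_self_comparison_is_zero(self):
        rng = np.random.default_rng(0)
        x = rng.integers(-1, 3, 500).astype(np.int8)
        assert pc_errors(x, x) == 0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = rng.integers(-1, 3, 500).astype(np.int8)
        b = rng.integers(-1, 3, 500).astype(np.int8)
        assert pc_errors(a, b) == pc_errors(b, a)

    def test_unrelated_pair_matches_closed_form_expectation(self):
        # two unrelated individuals, HW at allele frequency p: opposing
        # homozygotes occur at rate 2 p^2 q^2 per marker
        p, n, reps = 0.3, 1000, 200
        rng = np.random.default_rng(42)
        counts = []
        for _ in range(reps):
            a = rng.binomial(2, p, n).astype(np.int8)
            b = rng.binomial(2, p, n).astype(np.int8)
            counts.append(pc_errors(a, b))
        expected = 2 * (p**2) * ((1 - p) ** 2) * n
        per_marker = 2 * (p**2) * ((1 - p) ** 2)
        se = np.sqrt(n * per_marker * (1 - per_marker) / reps)
        assert abs(np.mean(counts) - expected) < 3 * se


def brute_force_ppc(m, f, c):
    """Independent oracle: enumerate transmitted-allele assignments."""
    gametes = {AA: (0,), AB: (0, 1), BB: (1,)}
    return int(
        all(am + af != c for am in gametes[m] for af in gametes[f])
    )


class TestPpcErrors:
    def test_canonical_infeasible_triplets(self):
        assert ppc_errors(arr(AB), arr(AA), arr(AA)) == 1
        assert ppc_errors(arr(AA), arr(AA), arr(BB)) == 1  # full feasibility
        for c in (AA, AB, BB):
            assert ppc_errors(arr(c), arr(AB), arr(AB)) == 0

    def test_feasibility_table_matches_brute_force_over_27_triplets(self):
        for m, f, c in itertools.product((AA, AB, BB), repeat=3):
            assert ppc_errors(arr(c), arr(m), arr(f)) == brute_force_ppc(m, f, c)

    def test_ppc_at_least_max_single_parent_errors(self):
        for m, f, c in itertools.product((AA, AB, BB), repeat=3):
            ppc = ppc_errors(arr(c), arr(m), arr(f))
            assert ppc >= max(pc_errors(arr(c), arr(m)), pc_errors(arr(c), arr(f)))

    def test_missing_calls_not_counted(self):
        assert ppc_errors(arr(AB), arr(MISSING), arr(AA)) == 0


class TestCalibration:
    def test_simulated_pedigree_separates_cleanly(self, default_sim):
        ds = default_sim
        gm, ped = ds.gm, ds.truth.pedigree  # true pedigree: all pairs real
        reg = ds.truth.registry
        anomalous = set(reg.loc[reg.kind.isin(["bad_quality", "triploid"]), "individual"])
        pairs = [
            (c, p)
            for c, p in recorded_pc_pairs(ped, gm)
            if c not in anomalous and p not in anomalous
        ]
        cal = calibrate_pc_threshold(gm, pairs, n_random=500, seed=3)
        assert not cal.overlap
        assert cal.known_counts.max() < cal.threshold
        assert (cal.random_counts >= cal.threshold).mean() > 0.99

    def test_fixed_seed_reproducible(self, default_sim):
        ds = default_sim
        pairs = recorded_pc_pairs(ds.truth.pedigree, ds.gm)
        t1 = calibrate_pc_threshold(ds.gm, pairs, n_random=200, seed=9).threshold
        t2 = calibrate_pc_threshold(ds.gm, pairs, n_random=200, seed=9).threshold
        assert t1 == t2

    def test_error_free_data_keeps_threshold_at_least_one(self, clean_sim):
        ds = clean_sim
        pairs = recorded_pc_pairs(ds.pedigree, ds.gm)
        cal = calibrate_pc_threshold(ds.gm, pairs, n_random=200, seed=0)
        assert cal.known_counts.max() == 0
        assert cal.threshold >= 1

    @pytest.mark.parametrize("max_obs,expected", [(10, 11), (0, 0), (19, 21)])
    def test_ppc_threshold_is_110_percent_rounded_up(self, max_obs, expected):
        assert calibrate_ppc_threshold([0, max_obs]) == expected

    def test_ppc_threshold_requires_trios(self):
        with pytest.raises(ValueError):
            calibrate_ppc_threshold([])


class TestSearchAndVerify:
    def test_hidden_true_parent_ranked_first(self, default_sim):
        ds = default_sim
        gm, ped = ds.gm, ds.truth.pedigree
        cal = calibrate_pc_threshold(
            gm, recorded_pc_pairs(ped, gm), n_random=300, seed=1
        )
        child = next(s for s in gm.individuals if ped[s].mother is not None and not s.endswith("_dup"))
        true_mother = ped[child].mother
        candidates = [s for s in gm.individuals if s != child]
        ranked = search_parents(gm, child, candidates, cal.threshold)
        assert not ranked.empty
        top_group = set(
            ranked.loc[ranked["pc_errors"] == ranked["pc_errors"].min(), "candidate"]
        )
        assert true_mother in top_group

    def test_no_candidate_passing_returns_empty(self, default_sim):
        ds = default_sim
        gm = ds.gm
        child = gm.individuals[0]
        ranked = search_parents(gm, child, gm.individuals[1:], pc_threshold=0)
        assert ranked.empty

    def test_untestable_when_parent_ungenotyped(self, default_sim):
        ds = default_sim
        from pedcurate.datamodel import Individual, Pedigree

        ped = Pedigree(
            [Individual("ghost"), Individual(ds.gm.individuals[0], mother="ghost")]
        )
        verdicts = verify_pedigree(ds.gm, ped, pc_threshold=20)
        assert verdicts[0].verdict == "untestable"


class TestGrandparentTest:
    def test_obligate_allele_missing_from_both_grandparents(self):
        # AB child + AA known parent -> obligate B; AA/AA grandparents lack it
        assert grandparent_test(arr(AB), arr(AA), arr(AA), arr(AA)) == 1
        assert grandparent_test(arr(AB), arr(AA), arr(AB), arr(AA)) == 0
        assert grandparent_test(arr(AA), arr(AA), arr(BB), arr(BB)) == 1

    def test_true_grandparents_have_minimal_count(self, clean_sim):
        ds = clean_sim
        gm, ped = ds.gm, ds.pedigree
        child = next(
            s
            for s in gm.individuals
            if ped[s].mother is not None
            and ped[ped[s].mother].mother is not None
        )
        mother = ped[child].mother
        father = ped[child].father
        gm1, gm2 = ped[mother].parents
        true_count = grandparent_test(
            gm.individual_calls(child),
            gm.individual_calls(father),
            gm.individual_calls(gm1),
            gm.individual_calls(gm2),
        )
        rng = np.random.default_rng(0)
        founders = [f for f in ped.founders() if f not in (gm1, gm2)]
        random_counts = []
        for _ in range(50):
            a, b = rng.choice(founders, 2, replace=False)
            random_counts.append(
                grandparent_test(
                    gm.individual_calls(child),
                    gm.individual_calls(father),
                    gm.individual_calls(a),
                    gm.individual_calls(b),
                )
            )
        assert true_count <= min(random_counts)
        assert true_count == 0  # error-free data


class TestTriploidCaveat:
    def test_unreduced_gamete_hides_pc_errors_up_to_grandparents(self):
        ds = simulate_dataset(
            SimulationConfig(
                seed=31,
                n_founders=12,
                generation_sizes=(20, 20),
                n_linkage_groups=2,
                n_markers_per_lg=150,
                missing_rate=0.0,
                random_miscall_rate=0.0,
                cluster_shift_fraction=0.0,
                n_wrong_parents=0,
                n_duplicate_pairs=0,
                n_triploids=1,
                n_bad_quality=0,
            )
        )
        reg = ds.truth.registry
        row = reg.loc[reg.kind == "triploid"].iloc[0]
        tri = row["individual"]
        mother = row["detail"].split("=")[1]  # the unreduced-gamete parent
        gm, ped = ds.gm, ds.pedigree
        tri_calls = gm.individual_calls(tri)
        assert pc_errors(tri_calls, gm.individual_calls(mother)) == 0
        # the transmitting parent's own parents also show zero PC errors
        for gp in ped[mother].parents:
            assert pc_errors(tri_calls, gm.individual_calls(gp)) == 0
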