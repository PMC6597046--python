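"""Haploblock borders, haplotype coding and haplotype-level checks."""

import numpy as np
import pytest

from pedcurate.datamodel import GeneticMap, Individual, Pedigree
from pedcurate.haploblock import (
    HaploblockSet,
    assign_haplotypes,
    define_borders,
    family_haplo_violations,
    find_split_point,
    haplo_mendel_check,
    haplotype_snp_crosscheck,
    haplotypes_to_phased,
    resolve_all_missing,
    resolve_missing_haplotype,
    screen_recombinant_haplotypes,
    split_block,
)
from pedcurate.phasing import (
    RecombinationEvent,
    detect_recombinations,
    infer_origins,
    phase_pedigree,
)


def simple_map(n=20, spacing=2.0, lg="1"):
    markers = [f"m{i:02d}" for i in range(n)]
    return GeneticMap.from_positions(markers, [lg] * n, [i * spacing for i in markers and range(n)])


def ev(left, right, gmap, parent="p", child="c", lg="1"):
    return RecombinationEvent(
        parent, child, lg, left, right, gmap.cm_of(left), gmap.cm_of(right)
    )


class TestDefineBorders:
    def test_single_event_cut_at_midpoint(self):
        gmap = simple_map()
        # event between markers at 10 and 14 cM -> border at 12 cM
        blocks = define_borders([ev("m05", "m07", gmap)], gmap)
        assert len(blocks) == 2
        first, second = blocks.blocks
        assert first.markers[-1] == "m05"
        assert second.markers[0] == "m06"

    def test_overlapping_events_share_one_border(self):
        gmap = simple_map()
        events = [
            ev("m05", "m08", gmap, child="c1"),
            ev("m06", "m09", gmap, child="c2"),
        ]
        blocks = define_borders(events, gmap)
        assert len(blocks) == 2  # one cut suffices for both

    def test_adjacent_marker_event_cuts_that_boundary(self):
        gmap = simple_map()
        blocks = define_borders([ev("m03", "m04", gmap)], gmap)
        assert blocks.blocks[0].markers[-1] == "m03"

    def test_unselected_events_ignored(self):
        gmap = simple_map()
        blocks = define_borders(
            [ev("m05", "m07", gmap, child="seedling")], gmap, selected_ids={"cv"}
        )
        assert len(blocks) == 1

    def test_partition_invariant(self, clean_sim):
        ds = clean_sim
        hm = phase_pedigree(ds.gm, ds.pedigree, ds.gmap)
        events = detect_recombinations(infer_origins(hm, ds.gm, ds.pedigree, ds.gmap))
        selected = set(ds.pedigree.selected_ids())
        blocks = define_borders(events, ds.gmap, selected)
        for lg in ds.gmap.linkage_groups:
            covered = [m for b in blocks.on(lg) for m in b.markers]
            assert covered == ds.gmap.markers_on(lg)

    def test_no_selected_event_inside_any_block(self, clean_sim):
        ds = clean_sim
        hm = phase_pedigree(ds.gm, ds.pedigree, ds.gmap)
        events = detect_recombinations(infer_origins(hm, ds.gm, ds.pedigree, ds.gmap))
        selected = set(ds.pedigree.selected_ids())
        blocks = define_borders(events, ds.gmap, selected)
        for e in events:
            if e.child not in selected:
                continue
            left_block = blocks.block_of_marker[e.left_marker]
            right_block = blocks.block_of_marker[e.right_marker]
            assert left_block != right_block


class TestSplitBlock:
    def test_split_divides_markers(self):
        gmap = simple_map(6)
        blocks = define_borders([], gmap)
        out = split_block(blocks, blocks.blocks[0].id, "m02", gmap)
        assert [len(b.markers) for b in out.blocks] == [3, 3]

    def test_split_point_must_be_interior(self):
        gmap = simple_map(6)
        blocks = define_borders([], gmap)
        with pytest.raises(ValueError):
            split_block(blocks, blocks.blocks[0].id, "m05", gmap)


@pytest.fixture(scope="module")
def phased_cohort(clean_sim):
    ds = clean_sim
    hm = phase_pedigree(ds.gm, ds.pedigree, ds.gmap)
    events = detect_recombinations(infer_origins(hm, ds.gm, ds.pedigree, ds.gmap))
    selected = set(ds.pedigree.selected_ids())
    blocks = define_borders(events, ds.gmap, selected)
    ht = assign_haplotypes(hm, blocks)
    return ds, hm, blocks, ht


class TestAssignHaplotypes:
    def test_identical_strings_share_codes_deterministically(self, phased_cohort):
        ds, hm, blocks, ht = phased_cohort
        ht2 = assign_haplotypes(hm, blocks)
        assert np.array_equal(ht.codes, ht2.codes)
        for bi in range(len(blocks.blocks)):
            strings = {}
            for j in range(len(ht.individuals)):
                for s in range(2):
                    code = int(ht.codes[bi, j, s])
                    if code:
                        strings.setdefault(ht.strings[bi, j, s], set()).add(code)
            assert all(len(codes) == 1 for codes in strings.values())

    def test_child_codes_drawn_from_parents_outside_crossover_blocks(
        self, phased_cohort
    ):
        ds, hm, blocks, ht = phased_cohort
        truth = {
            (m.parent, m.child, m.linkage_group): m.crossover_cm
            for m in ds.truth.meioses
        }
        checked = violations = 0
        for bi, block in enumerate(blocks.blocks):
            for child in ht.individuals:
                ped = ds.pedigree
                if ped[child].mother is None:
                    continue
                for slot, parent in enumerate(ped[child].parents):
                    xs = truth.get((parent, child, block.linkage_group), [])
                    if any(block.cm_start <= x <= block.cm_end for x in xs):
                        continue  # block overlaps a true crossover
                    code = int(ht.codes[bi, ht._iidx[child], slot])
                    p_codes = {
                        int(ht.codes[bi, ht._iidx[parent], s]) for s in range(2)
                    }
                    if code and 0 not in p_codes:
                        checked += 1
                        if code not in p_codes:
                            violations += 1
        assert checked > 100
        assert violations / checked < 0.02  # residual phase noise only

    def test_previous_dictionary_reused_for_unchanged_blocks(self, phased_cohort):
        ds, hm, blocks, ht = phased_cohort
        again = assign_haplotypes(hm, blocks, previous=ht)
        assert all(
            again.dictionaries[bi] == ht.dictionaries[bi]
            for bi in range(len(blocks.blocks))
        )

    def test_round_trip_to_phased_alleles(self, phased_cohort):
        ds, hm, blocks, ht = phased_cohort
        decoded = haplotypes_to_phased(ht, hm)
        known = decoded != -1
        assert known.any()
        assert np.array_equal(decoded[known], hm.slots[known])
        assert haplotype_snp_crosscheck(ht, hm) == []


class TestResolveMissing:
    def _tiny_ht(self, child_string, parent_strings):
        gmap = simple_map(4)
        blocks = define_borders([], gmap)
        ped = Pedigree(
            [
                Individual("mom"),
                Individual("dad"),
                Individual("kid", mother="mom", father="dad"),
            ]
        )
        from pedcurate.phasing import HomologMatrix
        from pedcurate.datamodel import GenotypeMatrix

        gm = GenotypeMatrix(
            [f"m{i:02d}" for i in range(4)],
            ["mom", "dad", "kid"],
            np.zeros((4, 3), dtype=np.int8),
        )
        hm = HomologMatrix(gm)
        ht = assign_haplotypes(hm, blocks)
        bi = 0
        # mother carries the candidate strings; child slot 0 is incomplete
        for s, string in enumerate(parent_strings):
            ht.strings[bi, 0, s] = string
            if "-" not in string:
                from pedcurate.haploblock import _adopt

                _adopt(ht, bi, 0, s, string)
        ht.strings[bi, 2, 0] = child_string
        ht.codes[bi, 2, 0] = 0
        return ht, ped

    def test_unique_parental_match_adopted(self):
        ht, ped = self._tiny_ht("A-BA", ["AABA", "ABBB"])
        code = resolve_missing_haplotype(ht, ped, "kid", 0, 0)
        assert code and ht.dictionaries[0][code] == "AABA"

    def test_no_parental_match_stays_unresolved(self):
        ht, ped = self._tiny_ht("B-BA", ["AABA", "ABBB"])
        assert resolve_missing_haplotype(ht, ped, "kid", 0, 0) == 0

    def test_ambiguous_match_without_flanking_info_unresolved(self):
        ht, ped = self._tiny_ht("A-BA", ["AABA", "ABBA"])
        assert resolve_missing_haplotype(ht, ped, "kid", 0, 0) == 0


class TestHaploMendel:
    def test_unexplained_code_flagged(self, trio_ped):
        genotypes = {"mom": (1, 2), "dad": (4, 5), "kid": (1, 3)}
        assert family_haplo_violations(trio_ped, genotypes) == ["kid"]

    def test_error_free_cohort_checks_clean_after_screening(self, phased_cohort):
        ds, hm, blocks, ht = phased_cohort
        selected = set(ds.pedigree.selected_ids())
        resolve_all_missing(ht, ds.pedigree)
        for _ in range(10):
            blanked, cands = screen_recombinant_haplotypes(ht, ds.pedigree, selected)
            if not blanked and not cands:
                break
            for block_id, ind, slot in cands:
                bi = [b.id for b in blocks.blocks].index(block_id)
                ht.codes[bi, ht._iidx[ind], slot] = 0
        report = haplo_mendel_check(ds.pedigree, ht)
        # phase noise may leave a few flags, but nothing systematic
        assert len(report.flags) <= 0.01 * ht.codes.size

    def test_injected_snp_miscall_traced_to_its_block(self, clean_sim):
        ds = clean_sim
        gm = ds.gm.copy()
        ped = ds.pedigree
        hm0 = phase_pedigree(gm, ped, ds.gmap)
        events = detect_recombinations(infer_origins(hm0, gm, ped, ds.gmap))
        blocks = define_borders(events, ds.gmap, set(ped.selected_ids()))
        # flip one call of a multi-marker block's child
        block = next(b for b in blocks.blocks if len(b.markers) >= 3)
        child = next(s for s in gm.individuals if ped[s].mother is not None)
        marker = block.markers[1]
        gm.set_call(marker, child, (gm.get(marker, child) + 1) % 3, "inject")
        hm = phase_pedigree(gm, ped, ds.gmap)
        ht = assign_haplotypes(hm, blocks)
        resolve_all_missing(ht, ped)
        genotypes, _ = (
            __import__("pedcurate.haploblock", fromlist=["_block_genotypes"])
            ._block_genotypes(ht, blocks.blocks.index(block))
        )
        violations = family_haplo_violations(ped, genotypes)
        # the miscall corrupts this child's haplotype in this block
        assert child in violations or int(
            ht.codes[blocks.blocks.index(block), ht._iidx[child]].min()
        ) == 0


class TestFindSplitPoint:
    def test_recombinant_haplotype_locates_crossover(self):
        gmap = simple_map(6)
        blocks = define_borders([], gmap)
        ped = Pedigree(
            [
                Individual("mom", selected=True),
                Individual("dad", selected=True),
                Individual("kid", mother="mom", father="dad", selected=True),
            ]
        )
        from pedcurate.datamodel import GenotypeMatrix
        from pedcurate.haploblock import _adopt
        from pedcurate.phasing import HomologMatrix

        gm = GenotypeMatrix(
            [f"m{i:02d}" for i in range(6)],
            ["mom", "dad", "kid"],
            np.zeros((6, 3), dtype=np.int8),
        )
        hm = HomologMatrix(gm)
        ht = assign_haplotypes(hm, blocks)
        _adopt(ht, 0, 0, 0, "AAAAAA")
        _adopt(ht, 0, 0, 1, "BBBBBB")
        _adopt(ht, 0, 2, 0, "AAABBB")  # maternal recombinant after m02
        assert find_split_point(ht, blocks.blocks[0].id, "kid", 0, ped) == "m02"
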