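"""Haploblock borders, integer-coded haplotypes, and haplotype-level checks.

A haploblock is a contiguous map segment within which no recombination was
observed in selected material (cultivars, selections, parents); it is then
treated as one multi-allelic locus whose alleles -- haplotypes -- are the
phased SNP allele strings, represented by small integer codes.  Borders
are placed sequentially, smallest recombination interval first, at the
interval's cM midpoint snapped between the two flanking markers; an event
whose interval already contains a border is skipped, so one border can
account for several overlapping events (a minimal cut set).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import GeneticMap, Pedigree
from .mendel import eliminate_multiallelic
from .phasing import UNKNOWN, HomologMatrix, RecombinationEvent

_ALLELE_CHAR = {0: "A", 1: "B", UNKNOWN: "-"}
_CHAR_ALLELE = {v: k for k, v in _ALLELE_CHAR.items()}


@dataclass
class Haploblock:
    id: str
    linkage_group: str
    markers: list[str]
    cm_start: float
    cm_end: float


class HaploblockSet:
    def __init__(self, blocks: list[Haploblock]) -> None:
        self.blocks = blocks
        self.by_id = {b.id: b for b in blocks}
        self.block_of_marker = {
            m: b.id for b in blocks for m in b.markers
        }

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)

    def on(self, linkage_group: str) -> list[Haploblock]:
        return [b for b in self.blocks if b.linkage_group == linkage_group]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "block": b.id,
                    "linkage_group": b.linkage_group,
                    "cm_start": b.cm_start,
                    "cm_end": b.cm_end,
                    "n_markers": len(b.markers),
                    "markers": ";".join(b.markers),
                }
                for b in self.blocks
            ]
        )


def _blocks_from_cuts(
    gmap: GeneticMap, cuts: dict[str, set[int]]
) -> HaploblockSet:
    blocks: list[Haploblock] = []
    for lg in gmap.linkage_groups:
        markers = gmap.markers_on(lg)
        cms = [gmap.cm_of(m) for m in markers]
        cut_positions = sorted(g for g in cuts.get(lg, set()) if 0 < g < len(markers))
        bounds = [0, *cut_positions, len(markers)]
        for ordinal, (a, b) in enumerate(zip(bounds, bounds[1:]), start=1):
            blocks.append(
                Haploblock(
                    id=f"{lg}_{ordinal:03d}",
                    linkage_group=lg,
                    markers=markers[a:b],
                    cm_start=cms[a],
                    cm_end=cms[b - 1],
                )
            )
    return HaploblockSet(blocks)


def define_borders(
    events: list[RecombinationEvent],
    gmap: GeneticMap,
    selected_ids: set[str] | None = None,
) -> HaploblockSet:
    """Partition each linkage group so no selected-material event is inside
    a block.

    Events are processed smallest interval first; an event not already cut
    gains a border at the cM midpoint of its interval, snapped to the
    marker gap containing it (ties toward the lower-cM side).  A
    zero-length interval (adjacent markers) is cut at that marker boundary.
    """
    if selected_ids is not None:
        events = [e for e in events if e.child in selected_ids]
    events = sorted(
        events,
        key=lambda e: (e.interval_cm, e.linkage_group, e.left_cm, e.parent, e.child),
    )
    lg_markers = {lg: gmap.markers_on(lg) for lg in gmap.linkage_groups}
    lg_cms = {
        lg: np.array([gmap.cm_of(m) for m in ms]) for lg, ms in lg_markers.items()
    }
    lg_index = {
        lg: {m: i for i, m in enumerate(ms)} for lg, ms in lg_markers.items()
    }
    cuts: dict[str, set[int]] = {lg: set() for lg in lg_markers}
    for e in events:
        lg = e.linkage_group
        idx = lg_index[lg]
        if e.left_marker not in idx or e.right_marker not in idx:
            continue
        lo = idx[e.left_marker]
        hi = idx[e.right_marker]
        if lo > hi:
            lo, hi = hi, lo
        covered = range(lo + 1, hi + 1)  # gap g = boundary between g-1 and g
        if any(g in cuts[lg] for g in covered):
            continue
        if len(covered) == 0:
            continue
        mid = (e.left_cm + e.right_cm) / 2.0
        cms = lg_cms[lg]
        g = int(np.searchsorted(cms, mid, side="left"))
        g = min(max(g, lo + 1), hi)
        cuts[lg].add(g)
    return _blocks_from_cuts(gmap, cuts)


def split_block(
    blocks: HaploblockSet,
    block_id: str,
    after_marker: str,
    gmap: GeneticMap | None = None,
) -> HaploblockSet:
    """Split one block after ``after_marker``; other blocks are untouched.

    Block ids are re-assigned per linkage group to keep the ordinal naming
    scheme consistent.
    """
    block = blocks.by_id.get(block_id)
    if block is None:
        raise ValueError(f"unknown block {block_id!r}")
    if after_marker not in block.markers or after_marker == block.markers[-1]:
        raise ValueError(
            f"split point {after_marker!r} is not an interior marker of {block_id}"
        )
    pos = block.markers.index(after_marker) + 1
    new_blocks: list[Haploblock] = []
    for b in blocks.blocks:
        if b.id != block_id:
            new_blocks.append(b)
            continue
        for part in (b.markers[:pos], b.markers[pos:]):
            if gmap is not None:
                start, end = gmap.cm_of(part[0]), gmap.cm_of(part[-1])
            else:
                start, end = b.cm_start, b.cm_end
            new_blocks.append(
                Haploblock(
                    id="pending",
                    linkage_group=b.linkage_group,
                    markers=part,
                    cm_start=start,
                    cm_end=end,
                )
            )
    # renumber per linkage group, preserving map order
    counter: dict[str, int] = {}
    for b in new_blocks:
        counter[b.linkage_group] = counter.get(b.linkage_group, 0) + 1
        b.id = f"{b.linkage_group}_{counter[b.linkage_group]:03d}"
    return HaploblockSet(new_blocks)


class HaplotypeMatrix:
    """Integer-coded haplotypes per individual per block.

    ``codes[b, j, s]`` is the code of individual ``j``'s slot ``s``
    haplotype in block ``b`` (0 = missing/unresolved); ``dictionaries[b]``
    maps code -> allele string over {A, B}; raw (possibly incomplete)
    strings are kept for resolution.
    """

    def __init__(
        self,
        blocks: HaploblockSet,
        individuals: list[str],
        codes: np.ndarray,
        dictionaries: list[dict[int, str]],
        strings: np.ndarray,
    ) -> None:
        self.blocks = blocks
        self.individuals = individuals
        self.codes = codes
        self.dictionaries = dictionaries
        self.strings = strings
        self._iidx = {s: j for j, s in enumerate(individuals)}

    def code_pair(self, individual: str, block_index: int) -> tuple[int, int]:
        j = self._iidx[individual]
        return tuple(int(c) for c in self.codes[block_index, j])

    def frame(self) -> pd.DataFrame:
        data = {
            b.id: [
                f"{self.codes[bi, j, 0]}|{self.codes[bi, j, 1]}"
                for j in range(len(self.individuals))
            ]
            for bi, b in enumerate(self.blocks.blocks)
        }
        return pd.DataFrame(data, index=self.individuals)

    def dictionary_frame(self) -> pd.DataFrame:
        rows = [
            {"block": b.id, "code": code, "haplotype": s}
            for bi, b in enumerate(self.blocks.blocks)
            for code, s in sorted(self.dictionaries[bi].items())
        ]
        return pd.DataFrame(rows, columns=["block", "code", "haplotype"])


def assign_haplotypes(
    hm: HomologMatrix,
    blocks: HaploblockSet,
    previous: "HaplotypeMatrix | None" = None,
) -> HaplotypeMatrix:
    """Map phased allele strings to integer codes, block by block.

    Codes are assigned in order of first appearance scanning individuals in
    input order (maternal then paternal slot), so the dictionary is
    deterministic.  Strings containing unknown alleles stay code 0 pending
    resolution.  When a previous matrix is supplied, blocks with unchanged
    marker composition reuse its code dictionary.
    """
    individuals = list(hm.individuals)
    n_blocks = len(blocks.blocks)
    codes = np.zeros((n_blocks, len(individuals), 2), dtype=np.int32)
    strings = np.empty((n_blocks, len(individuals), 2), dtype=object)
    dictionaries: list[dict[int, str]] = []
    prev_lookup: dict[tuple[str, ...], dict[int, str]] = {}
    if previous is not None:
        for bi, b in enumerate(previous.blocks.blocks):
            prev_lookup[tuple(b.markers)] = previous.dictionaries[bi]
    for bi, block in enumerate(blocks.blocks):
        rows = [hm._midx[m] for m in block.markers if m in hm._midx]
        lookup: dict[str, int] = {}
        dictionary: dict[int, str] = {}
        if tuple(block.markers) in prev_lookup:
            dictionary = dict(prev_lookup[tuple(block.markers)])
            lookup = {s: c for c, s in dictionary.items()}
        next_code = max(dictionary, default=0) + 1
        for j in range(len(individuals)):
            for s in range(2):
                chars = "".join(
                    _ALLELE_CHAR[int(hm.slots[i, j, s])] for i in rows
                )
                strings[bi, j, s] = chars
                if "-" in chars:
                    continue
                if chars not in lookup:
                    lookup[chars] = next_code
                    dictionary[next_code] = chars
                    next_code += 1
                codes[bi, j, s] = lookup[chars]
        dictionaries.append(dictionary)
    return HaplotypeMatrix(blocks, individuals, codes, dictionaries, strings)


def resolve_missing_haplotype(
    ht: HaplotypeMatrix,
    ped: Pedigree,
    individual: str,
    block_index: int,
    slot: int,
) -> int:
    """Resolve one incomplete haplotype string from the matching parent.

    If exactly one parental haplotype agrees with the known positions it is
    adopted; with several agreeing, the nearest resolved flanking blocks
    vote for the parental homolog that minimizes recombination; remaining
    ambiguity leaves the haplotype missing.  Returns the assigned code (0
    if unresolved).
    """
    j = ht._iidx[individual]
    s = ht.strings[block_index, j, slot]
    if s is None or "-" not in s:
        return int(ht.codes[block_index, j, slot])
    if individual not in ped:
        return 0
    parent = ped[individual].parents[slot]
    if parent is None or parent not in ht._iidx:
        return 0
    pj = ht._iidx[parent]
    candidates: list[tuple[int, str]] = []  # (parent slot, string)
    for ps in range(2):
        p_string = ht.strings[block_index, pj, ps]
        code = int(ht.codes[block_index, pj, ps])
        if code == 0 or p_string is None or "-" in p_string:
            continue
        if all(a == "-" or a == b for a, b in zip(s, p_string)):
            candidates.append((ps, p_string))
    unique_strings = sorted({c[1] for c in candidates})
    if len(unique_strings) == 1:
        return _adopt(ht, block_index, j, slot, unique_strings[0])
    if len(unique_strings) == 0:
        return 0
    # several parental haplotypes match: vote with flanking blocks
    lg = ht.blocks.blocks[block_index].linkage_group
    lg_indices = [
        bi for bi, b in enumerate(ht.blocks.blocks) if b.linkage_group == lg
    ]
    pos = lg_indices.index(block_index)
    votes: dict[int, int] = {ps: 0 for ps, _ in candidates}
    for direction in (-1, 1):
        t = pos + direction
        while 0 <= t < len(lg_indices):
            bi = lg_indices[t]
            child_code = int(ht.codes[bi, j, slot])
            p_codes = [int(ht.codes[bi, pj, ps2]) for ps2 in range(2)]
            if child_code and p_codes.count(child_code) == 1:
                origin = p_codes.index(child_code)
                if origin in votes:
                    votes[origin] += 1
                break
            t += direction
    best = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(best) > 1 and best[0][1] == best[1][1]:
        return 0
    chosen = dict(candidates).get(best[0][0])
    if chosen is None:
        return 0
    return _adopt(ht, block_index, j, slot, chosen)


def _adopt(ht: HaplotypeMatrix, bi: int, j: int, slot: int, string: str) -> int:
    lookup = {s: c for c, s in ht.dictionaries[bi].items()}
    code = lookup.get(string)
    if code is None:
        code = max(ht.dictionaries[bi], default=0) + 1
        ht.dictionaries[bi][code] = string
    ht.codes[bi, j, slot] = code
    ht.strings[bi, j, slot] = string
    return int(code)


def resolve_all_missing(ht: HaplotypeMatrix, ped: Pedigree) -> int:
    """Resolve every incomplete haplotype it can; returns the number fixed."""
    n = 0
    for bi in range(len(ht.blocks.blocks)):
        for ind in ht.individuals:
            j = ht._iidx[ind]
            for slot in range(2):
                if ht.codes[bi, j, slot] == 0 and "-" in (ht.strings[bi, j, slot] or "-"):
                    if resolve_missing_haplotype(ht, ped, ind, bi, slot):
                        n += 1
    return n


@dataclass
class HaploMendelReport:
    inconsistent_blocks: list[str] = field(default_factory=list)
    flags: list[tuple[str, str]] = field(default_factory=list)  # (block, individual)

    @property
    def n_errors(self) -> int:
        return len(self.flags)


def _block_genotypes(
    ht: HaplotypeMatrix, bi: int
) -> tuple[dict[str, tuple[int, int] | None], set[int]]:
    genotypes: dict[str, tuple[int, int] | None] = {}
    universe: set[int] = set()
    for ind in ht.individuals:
        j = ht._iidx[ind]
        c1, c2 = int(ht.codes[bi, j, 0]), int(ht.codes[bi, j, 1])
        if c1 and c2:
            genotypes[ind] = (c1, c2)
            universe |= {c1, c2}
        else:
            genotypes[ind] = None
    return genotypes, universe


def _pair_feasible(
    child: tuple[int, int],
    mother: tuple[int, int] | None,
    father: tuple[int, int] | None,
) -> bool:
    def gives(code: int, pair: tuple[int, int] | None) -> bool:
        return pair is None or code in pair

    c1, c2 = child
    return (gives(c1, mother) and gives(c2, father)) or (
        gives(c2, mother) and gives(c1, father)
    )


def family_haplo_violations(
    ped: Pedigree, genotypes: dict[str, tuple[int, int] | None]
) -> list[str]:
    """Children whose code pair cannot be split over their parents' pairs."""
    bad: list[str] = []
    for (m, f), children in ped.nuclear_families():
        mp = genotypes.get(m)
        fp = genotypes.get(f)
        if mp is None and fp is None:
            continue
        for c in children:
            cp = genotypes.get(c)
            if cp is not None and not _pair_feasible(cp, mp, fp):
                bad.append(c)
    return bad


def haplo_mendel_check(ped: Pedigree, ht: HaplotypeMatrix) -> HaploMendelReport:
    """Multi-allelic Mendelian check of the coded haplotypes.

    The SNP-level genotype elimination generalizes directly: each block is
    a k-allelic locus and a child must receive one code from each parent.
    Family-level transmission violations are reported per child; blocks
    that look family-clean are additionally run through cross-generation
    set elimination, with leave-one-out localization when it fails.
    """
    report = HaploMendelReport()
    for bi, block in enumerate(ht.blocks.blocks):
        genotypes, universe = _block_genotypes(ht, bi)
        violations = family_haplo_violations(ped, genotypes)
        if violations:
            report.inconsistent_blocks.append(block.id)
            for child in sorted(set(violations)):
                report.flags.append((block.id, child))
            continue
        sets, consistent = eliminate_multiallelic(ped, genotypes, universe)
        if consistent:
            continue
        report.inconsistent_blocks.append(block.id)
        empty = {s for s, v in sets.items() if v is not None and not v}
        fams = sorted(
            (
                fam
                for fam in ped.nuclear_families()
                if empty & ({fam[0][0], fam[0][1]} | set(fam[1]))
            ),
            key=lambda fam: len(fam[1]),
        )
        candidates = sorted(
            {
                member
                for (m, f), children in fams
                for member in (m, f, *children)
                if genotypes.get(member) is not None
            }
        )
        flagged = []
        for member in candidates:
            reduced = dict(genotypes)
            reduced[member] = None
            _, ok = eliminate_multiallelic(ped, reduced, universe)
            if ok:
                flagged.append(member)
        if not flagged and fams:
            # no single haplotype explains the conflict; report only the
            # members of the smallest affected family
            (m, f), children = fams[0]
            flagged = [
                member
                for member in (m, f, *children)
                if genotypes.get(member) is not None
            ]
        for member in flagged or candidates:
            report.flags.append((block.id, member))
    return report


def screen_recombinant_haplotypes(
    ht: HaplotypeMatrix,
    ped: Pedigree,
    selected_ids: set[str],
) -> tuple[int, list[tuple[str, str, int]]]:
    """Handle within-block recombinant haplotypes before the Mendel check.

    Haploblock borders only guarantee recombination-free blocks for
    selected material, so unselected seedlings legitimately carry novel
    recombinant haplotypes inside blocks; those are set to missing (the
    code cannot be assigned a parental origin).  A novel haplotype in a
    selected individual instead signals a recombination that should have
    split the block (e.g. in an ungenotyped progenitor); such cases are
    returned as split candidates ``(block id, individual, slot)``.
    Returns (number of codes blanked, split candidates).
    """
    blanked = 0
    split_candidates: list[tuple[str, str, int]] = []
    for bi, block in enumerate(ht.blocks.blocks):
        genotypes, _ = _block_genotypes(ht, bi)
        counts: dict[int, int] = {}
        for ind in ht.individuals:
            j = ht._iidx[ind]
            for slot in range(2):
                code = int(ht.codes[bi, j, slot])
                if code:
                    counts[code] = counts.get(code, 0) + 1
        for child in family_haplo_violations(ped, genotypes):
            if child not in ht._iidx:
                continue
            j = ht._iidx[child]
            # blank the rarer (novel) code of the violating pair
            pair = [(counts.get(int(ht.codes[bi, j, s]), 0), s) for s in range(2)]
            pair.sort()
            slot = pair[0][1]
            if child in selected_ids:
                split_candidates.append((block.id, child, slot))
                continue
            ht.codes[bi, j, slot] = 0
            ht.strings[bi, j, slot] = "-" * len(block.markers)
            blanked += 1
    return blanked, split_candidates


def find_split_point(
    ht: HaplotypeMatrix, block_id: str, individual: str, slot: int, ped: Pedigree
) -> str | None:
    """Locate the crossover explaining a recombinant haplotype.

    Returns the marker after which the block should be split so that the
    individual's haplotype is a prefix of one parental haplotype and a
    suffix of the other, or ``None`` when no single crossover explains it.
    """
    bi = [b.id for b in ht.blocks.blocks].index(block_id)
    block = ht.blocks.blocks[bi]
    j = ht._iidx[individual]
    s = ht.strings[bi, j, slot]
    if s is None or individual not in ped:
        return None
    parent = ped[individual].parents[slot]
    if parent is None or parent not in ht._iidx:
        return None
    pj = ht._iidx[parent]
    p_strings = [ht.strings[bi, pj, t] for t in range(2)]
    if any(p is None or "-" in p for p in p_strings):
        return None
    n = len(block.markers)
    for k in range(1, n):
        for a, b in ((0, 1), (1, 0)):
            if (
                s[:k] == p_strings[a][:k]
                and s[k:] == p_strings[b][k:]
                and s != p_strings[a]
                and s != p_strings[b]
            ):
                return block.markers[k - 1]
    return None


def haplotypes_to_phased(ht: HaplotypeMatrix, hm_template: HomologMatrix) -> np.ndarray:
    """Decode haplotype codes back to phased SNP alleles.

    Returns an array shaped like ``hm_template.slots``; positions covered
    by an unresolved (code 0) haplotype stay unknown.  Haplotype data is
    convertible back to phased, fully curated SNP data by construction.
    """
    out = np.full_like(hm_template.slots, UNKNOWN)
    for bi, block in enumerate(ht.blocks.blocks):
        rows = [hm_template._midx[m] for m in block.markers if m in hm_template._midx]
        for j in range(len(ht.individuals)):
            for slot in range(2):
                code = int(ht.codes[bi, j, slot])
                if code == 0:
                    continue
                string = ht.dictionaries[bi][code]
                for i, ch in zip(rows, string):
                    out[i, j, slot] = _CHAR_ALLELE[ch]
    return out


def haplotype_snp_crosscheck(
    ht: HaplotypeMatrix, hm: HomologMatrix
) -> list[tuple[str, str]]:
    """Blocks whose codes contradict the underlying phased SNP alleles."""
    decoded = haplotypes_to_phased(ht, hm)
    flags: list[tuple[str, str]] = []
    for bi, block in enumerate(ht.blocks.blocks):
        rows = [hm._midx[m] for m in block.markers if m in hm._midx]
        for j, ind in enumerate(ht.individuals):
            for slot in range(2):
                if int(ht.codes[bi, j, slot]) == 0:
                    continue
                a = decoded[rows, j, slot]
                b = hm.slots[rows, j, slot]
                known = (a != UNKNOWN) & (b != UNKNOWN)
                if np.any(a[known] != b[known]):
                    flags.append((block.id, ind))
                    break
    return flags
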