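"""Core data containers for pedigree-based SNP curation.

Genotype calls are biallelic and codominant.  Internally every call is an
``int8`` B-allele dosage: ``0`` = AA, ``1`` = AB, ``2`` = BB, ``-1`` =
missing.  All array-heavy modules work directly on the dosage matrix; the
string alphabet {"AA", "AB", "BB", "--"} only appears at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np
import pandas as pd

MISSING: int = -1
AA: int = 0
AB: int = 1
BB: int = 2

CALL_TO_STR = {AA: "AA", AB: "AB", BB: "BB", MISSING: "--"}
STR_TO_CALL = {"AA": AA, "AB": AB, "BB": BB, "--": MISSING}

#: prefixes used for placeholder (ungenotyped) parents of individuals with a
#: single recorded parent; one distinct placeholder per child, never shared.
MOTHER_PLACEHOLDER_PREFIX = "M_"
FATHER_PLACEHOLDER_PREFIX = "F_"
UNKNOWN_PLACEHOLDER_PREFIX = "UP_"

PLOIDY_CALLS = ("diploid", "triploid", "tetraploid_or_mixture", "aneuploid", "unknown")
QUALITY_CLASSES = ("good", "intermediate", "bad", "unknown")


@dataclass
class Individual:
    """One pedigree member.

    ``selected`` distinguishes cultivars, breeding selections and parents
    (whose historical recombinations define haploblock borders) from
    unselected seedlings.
    """

    id: str
    mother: str | None = None
    father: str | None = None
    selected: bool = False
    ploidy_call: str = "unknown"
    quality: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("individual id must be nonempty")
        if self.ploidy_call not in PLOIDY_CALLS:
            raise ValueError(f"unknown ploidy call {self.ploidy_call!r}")
        if self.quality not in QUALITY_CLASSES:
            raise ValueError(f"unknown quality class {self.quality!r}")

    @property
    def parents(self) -> tuple[str | None, str | None]:
        return (self.mother, self.father)

    @property
    def is_founder(self) -> bool:
        return self.mother is None and self.father is None


def is_placeholder(individual_id: str) -> bool:
    """True for placeholder parents introduced by :func:`normalize_pedigree`."""
    return individual_id.startswith(
        (MOTHER_PLACEHOLDER_PREFIX, FATHER_PLACEHOLDER_PREFIX, UNKNOWN_PLACEHOLDER_PREFIX)
    )


class PedigreeError(ValueError):
    pass


class Pedigree:
    """Directed acyclic individual -> parent structure.

    Insertion order of individuals is preserved; it fixes scan order in every
    downstream deterministic operation (haplotype code assignment, reports).
    """

    def __init__(self, individuals: Iterable[Individual] = ()) -> None:
        self._members: dict[str, Individual] = {}
        for ind in individuals:
            self.add(ind)

    def add(self, ind: Individual) -> None:
        if ind.id in self._members:
            raise PedigreeError(f"duplicate individual id {ind.id!r}")
        self._members[ind.id] = ind

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._members

    def __getitem__(self, individual_id: str) -> Individual:
        return self._members[individual_id]

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._members.values())

    def __len__(self) -> int:
        return len(self._members)

    @property
    def ids(self) -> list[str]:
        return list(self._members)

    def copy(self) -> "Pedigree":
        return Pedigree(replace(ind) for ind in self)

    def parents_of(self, individual_id: str) -> tuple[str | None, str | None]:
        return self._members[individual_id].parents

    def children_of(self, parent_id: str) -> list[str]:
        return [ind.id for ind in self if parent_id in (ind.mother, ind.father)]

    def founders(self) -> list[str]:
        return [ind.id for ind in self if ind.is_founder]

    def selected_ids(self) -> list[str]:
        return [ind.id for ind in self if ind.selected]

    def graph(self) -> nx.DiGraph:
        """Parent -> child digraph (parents may be absent as Individual rows)."""
        g = nx.DiGraph()
        g.add_nodes_from(self._members)
        for ind in self:
            for parent in ind.parents:
                if parent is not None:
                    g.add_edge(parent, ind.id)
        return g

    def validate(self) -> None:
        """Raise :class:`PedigreeError` listing the cycle if one exists."""
        g = self.graph()
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
        raise PedigreeError(f"pedigree contains a cycle: {path}")

    def topological_order(self) -> list[str]:
        """Ancestors-before-descendants order, stable across runs."""
        self.validate()
        g = self.graph()
        order = list(nx.lexicographical_topological_sort(g))
        return [i for i in order if i in self._members]

    def nuclear_families(self) -> list[tuple[tuple[str, str], list[str]]]:
        """Group children by (mother, father); only both-parent children."""
        fams: dict[tuple[str, str], list[str]] = {}
        for ind in self:
            if ind.mother is not None and ind.father is not None:
                fams.setdefault((ind.mother, ind.father), []).append(ind.id)
        return list(fams.items())

    def is_ancestor(self, ancestor_id: str, individual_id: str) -> bool:
        g = self.graph()
        if ancestor_id not in g or individual_id not in g:
            return False
        return nx.has_path(g, ancestor_id, individual_id)


def normalize_pedigree(
    ped: Pedigree, unknown_role: Iterable[str] = ()
) -> Pedigree:
    """Return a pedigree where every member has both parents or none.

    Individuals with exactly one recorded parent gain a placeholder parent
    named ``M_<child>``/``F_<child>`` after the missing role, or ``UP_<child>``
    for children listed in ``unknown_role`` (the known parent's role is then
    unspecified).  Placeholders are distinct per child: sharing one "dummy"
    across children would wrongly force a common parental genotype.
    Idempotent; raises on cyclic input.
    """
    ped.validate()
    unknown_role = set(unknown_role)
    out = Pedigree()
    placeholders: list[Individual] = []
    for ind in ped:
        mother, father = ind.mother, ind.father
        if (mother is None) != (father is None):
            if ind.id in unknown_role:
                prefix = UNKNOWN_PLACEHOLDER_PREFIX
            elif mother is None:
                prefix = MOTHER_PLACEHOLDER_PREFIX
            else:
                prefix = FATHER_PLACEHOLDER_PREFIX
            ph_id = prefix + ind.id
            placeholders.append(Individual(id=ph_id))
            if mother is None:
                mother = ph_id
            else:
                father = ph_id
        out.add(replace(ind, mother=mother, father=father))
    for ph in placeholders:
        if ph.id not in out:
            out.add(ph)
    out.validate()
    return out


@dataclass(frozen=True)
class Edit:
    """One audited genotype-call change."""

    marker: str
    individual: str
    original: int
    new: int
    reason: str


class GenotypeMatrix:
    """Marker x individual matrix of B-allele dosages with an edit ledger."""

    def __init__(
        self,
        markers: Sequence[str],
        individuals: Sequence[str],
        calls: np.ndarray,
        edit_log: list[Edit] | None = None,
    ) -> None:
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(markers), len(individuals)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(markers)} markers x {len(individuals)} individuals"
            )
        bad = ~np.isin(calls, (MISSING, AA, AB, BB))
        if bad.any():
            raise ValueError(f"{bad.sum()} call values outside {{-1,0,1,2}}")
        _check_unique(markers, "marker")
        _check_unique(individuals, "individual")
        self.markers = list(markers)
        self.individuals = list(individuals)
        self.calls = calls
        self.edit_log: list[Edit] = list(edit_log) if edit_log else []
        self._midx = {m: i for i, m in enumerate(self.markers)}
        self._iidx = {s: j for j, s in enumerate(self.individuals)}

    # -- basic access -----------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def marker_index(self, marker: str) -> int:
        return self._midx[marker]

    def individual_index(self, individual: str) -> int:
        return self._iidx[individual]

    def get(self, marker: str, individual: str) -> int:
        return int(self.calls[self._midx[marker], self._iidx[individual]])

    def marker_calls(self, marker: str) -> np.ndarray:
        return self.calls[self._midx[marker]]

    def individual_calls(self, individual: str) -> np.ndarray:
        return self.calls[:, self._iidx[individual]]

    def set_call(self, marker: str, individual: str, new: int, reason: str) -> None:
        """Edit one cell, recording original call and reason."""
        i, j = self._midx[marker], self._iidx[individual]
        old = int(self.calls[i, j])
        if old == new:
            return
        self.calls[i, j] = np.int8(new)
        self.edit_log.append(Edit(marker, individual, old, int(new), reason))

    # -- statistics -------------------------------------------------------
    def call_rate_per_marker(self) -> pd.Series:
        rate = (self.calls != MISSING).mean(axis=1)
        return pd.Series(rate, index=self.markers, name="call_rate")

    def call_rate_per_individual(self) -> pd.Series:
        rate = (self.calls != MISSING).mean(axis=0)
        return pd.Series(rate, index=self.individuals, name="call_rate")

    def edit_fraction_per_marker(self) -> pd.Series:
        counts = pd.Series(0, index=self.markers, dtype=float)
        for e in self.edit_log:
            if e.marker in counts.index:
                counts[e.marker] += 1
        return counts / max(self.n_individuals, 1)

    # -- derived matrices -------------------------------------------------
    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.markers, self.individuals, self.calls.copy(), list(self.edit_log)
        )

    def subset(
        self,
        markers: Sequence[str] | None = None,
        individuals: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        markers = self.markers if markers is None else list(markers)
        individuals = self.individuals if individuals is None else list(individuals)
        rows = [self._midx[m] for m in markers]
        cols = [self._iidx[s] for s in individuals]
        mset, iset = set(markers), set(individuals)
        log = [e for e in self.edit_log if e.marker in mset and e.individual in iset]
        return GenotypeMatrix(markers, individuals, self.calls[np.ix_(rows, cols)], log)

    def to_frame(self) -> pd.DataFrame:
        """String-call DataFrame (markers as rows, individuals as columns)."""
        data = np.empty(self.calls.shape, dtype=object)
        for code, s in CALL_TO_STR.items():
            data[self.calls == code] = s
        return pd.DataFrame(data, index=self.markers, columns=self.individuals)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GenotypeMatrix":
        calls = np.full(frame.shape, MISSING, dtype=np.int8)
        values = frame.to_numpy(dtype=object)
        for s, code in STR_TO_CALL.items():
            calls[values == s] = code
        return cls(list(frame.index), list(frame.columns), calls)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.markers == other.markers
            and self.individuals == other.individuals
            and np.array_equal(self.calls, other.calls)
        )


def _check_unique(items: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for x in items:
        if x in seen:
            dups.append(x)
        seen.add(x)
    if dups:
        raise ValueError(f"duplicated {what} ids: {sorted(set(dups))}")


class GeneticMap:
    """Ordered markers with linkage group, cM position and optional bp.

    Within a linkage group the stored order is the (cM, bp, marker id)
    lexicographic sort, which makes marker order total and deterministic even
    for co-locating markers.
    """

    def __init__(self, table: pd.DataFrame) -> None:
        required = {"marker", "linkage_group", "cm"}
        if not required.issubset(table.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        table = table.copy()
        if "bp" not in table.columns:
            table["bp"] = np.nan
        table["linkage_group"] = table["linkage_group"].astype(str)
        if (table["cm"] < 0).any():
            raise ValueError("cM positions must be nonnegative")
        _check_unique(list(table["marker"]), "marker")
        sort_bp = table["bp"].fillna(np.inf)
        table = (
            table.assign(_bp=sort_bp)
            .sort_values(["linkage_group", "cm", "_bp", "marker"], kind="mergesort")
            .drop(columns="_bp")
            .reset_index(drop=True)
        )
        self.table = table
        self._row = {m: i for i, m in enumerate(table["marker"])}

    @classmethod
    def from_positions(
        cls,
        markers: Sequence[str],
        linkage_groups: Sequence[str],
        cm: Sequence[float],
        bp: Sequence[float] | None = None,
    ) -> "GeneticMap":
        return cls(
            pd.DataFrame(
                {
                    "marker": list(markers),
                    "linkage_group": list(linkage_groups),
                    "cm": list(cm),
                    "bp": list(bp) if bp is not None else np.nan,
                }
            )
        )

    def __contains__(self, marker: str) -> bool:
        return marker in self._row

    def __len__(self) -> int:
        return len(self.table)

    @property
    def linkage_groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["linkage_group"]))

    def markers_on(self, linkage_group: str) -> list[str]:
        sel = self.table["linkage_group"] == str(linkage_group)
        return list(self.table.loc[sel, "marker"])

    def cm_of(self, marker: str) -> float:
        return float(self.table.at[self._row[marker], "cm"])

    def lg_of(self, marker: str) -> str:
        return str(self.table.at[self._row[marker], "linkage_group"])

    def positions_on(self, linkage_group: str) -> pd.Series:
        sel = self.table["linkage_group"] == str(linkage_group)
        sub = self.table.loc[sel]
        return pd.Series(sub["cm"].to_numpy(), index=list(sub["marker"]))

    def length_cm(self, linkage_group: str | None = None) -> float:
        if linkage_group is not None:
            pos = self.positions_on(linkage_group)
            return float(pos.max() - pos.min()) if len(pos) else 0.0
        return float(sum(self.length_cm(lg) for lg in self.linkage_groups))

    def subset(self, markers: Sequence[str]) -> "GeneticMap":
        keep = set(markers)
        return GeneticMap(self.table[self.table["marker"].isin(keep)])

    def with_marker_moved(self, marker: str, new_cm: float) -> "GeneticMap":
        table = self.table.copy()
        table.loc[table["marker"] == marker, "cm"] = float(new_cm)
        return GeneticMap(table)


class BafMatrix:
    """Marker x individual B-allele frequencies in [0, 1]; NaN = missing."""

    def __init__(self, frame: pd.DataFrame) -> None:
        values = frame.to_numpy(dtype=float)
        finite = values[np.isfinite(values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("B-allele frequencies must lie in [0, 1]")
        self.frame = frame.astype(float)

    @property
    def markers(self) -> list[str]:
        return list(self.frame.index)

    @property
    def individuals(self) -> list[str]:
        return list(self.frame.columns)

    def column(self, individual: str) -> pd.Series:
        return self.frame[individual]
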