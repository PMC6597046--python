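"""Duplicate-sample detection by pairwise genotype identity.

Clonally propagated material (cultivars, sports, resampled trees) appears
as near-identical genotype columns.  The screen computes the
identity-by-state fraction over co-called markers for every pair and groups
pairs above a threshold (default 0.97, chosen so that known duplicate pairs
sit above it) by transitive closure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix, Pedigree

DEFAULT_IDENTITY_THRESHOLD = 0.97
DEFAULT_MIN_SHARED = 500


def pairwise_identity(
    gm: GenotypeMatrix, a: str, b: str, min_shared: int = DEFAULT_MIN_SHARED
) -> float:
    """Fraction of co-called markers with identical calls; NaN below floor."""
    ca = gm.individual_calls(a)
    cb = gm.individual_calls(b)
    both = (ca != MISSING) & (cb != MISSING)
    n = int(both.sum())
    if n < min_shared:
        warnings.warn(
            f"only {n} co-called markers for ({a}, {b}); identity undefined"
        )
        return float("nan")
    return float((ca[both] == cb[both]).mean())


def identity_matrix(
    gm: GenotypeMatrix, min_shared: int = DEFAULT_MIN_SHARED
) -> pd.DataFrame:
    """All-pairs identity-by-state fractions (NaN where co-calls < floor)."""
    calls = gm.calls
    called = (calls != MISSING).astype(np.float64)
    co_called = called.T @ called
    matches = np.zeros_like(co_called)
    for g in (0, 1, 2):
        x = (calls == g).astype(np.float64)
        matches += x.T @ x
    with np.errstate(invalid="ignore", divide="ignore"):
        ident = matches / co_called
    ident[co_called < min_shared] = np.nan
    np.fill_diagonal(ident, 1.0)
    return pd.DataFrame(ident, index=gm.individuals, columns=gm.individuals)


def find_duplicate_groups(
    gm: GenotypeMatrix,
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    min_shared: int = DEFAULT_MIN_SHARED,
) -> list[list[str]]:
    """Transitive closure of pairs with identity above the threshold.

    Groups are returned sorted by member id, so output is invariant to
    input order.
    """
    ident = identity_matrix(gm, min_shared)
    g = nx.Graph()
    inds = list(ident.index)
    values = ident.to_numpy()
    for i in range(len(inds)):
        for j in range(i + 1, len(inds)):
            if values[i, j] > threshold:
                g.add_edge(inds[i], inds[j])
    groups = [sorted(c) for c in nx.connected_components(g)]
    return sorted(groups)


@dataclass
class DuplicateDecision:
    group: list[str]
    keep: list[str]
    drop: list[str]
    resample: list[str]
    rationale: str


def resolve_duplicates(
    groups: list[list[str]],
    ped: Pedigree,
    parent_confirmed: dict[str, bool] | None = None,
) -> list[DuplicateDecision]:
    """Decide which member of each duplicate group to keep.

    Matching pedigree records -> keep the first by id order (true
    duplicates/sports).  Divergent records -> keep the member whose recorded
    parents were confirmed, if exactly one was.  Two unselected seedlings of
    the same family -> both resampled (no way to tell which is
    true-to-type); any other undecidable case also flags every member for
    resampling.
    """
    parent_confirmed = parent_confirmed or {}
    decisions = []
    for group in groups:
        members = sorted(group)
        in_ped = [m for m in members if m in ped]
        records = {ped[m].parents for m in in_ped}
        same_family_seedlings = (
            len(in_ped) == len(members)
            and len(records) == 1
            and next(iter(records)) != (None, None)
            and all(not ped[m].selected for m in in_ped)
        )
        if same_family_seedlings:
            decisions.append(
                DuplicateDecision(
                    members, [], [], members, "same-family unselected seedlings"
                )
            )
            continue
        if len(records) <= 1:
            keep = members[0]
            decisions.append(
                DuplicateDecision(
                    members,
                    [keep],
                    [m for m in members if m != keep],
                    [],
                    "identical pedigree records; kept first by id",
                )
            )
            continue
        confirmed = [m for m in in_ped if parent_confirmed.get(m, False)]
        if len(confirmed) == 1:
            keep = confirmed[0]
            decisions.append(
                DuplicateDecision(
                    members,
                    [keep],
                    [m for m in members if m != keep],
                    [],
                    "kept member consistent with its recorded parents",
                )
            )
        else:
            decisions.append(
                DuplicateDecision(members, [], [], members, "undecidable records")
            )
    return decisions
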