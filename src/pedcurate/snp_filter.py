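"""Call-statistics SNP filtering into retained and discarded categories.

Markers are regrouped from their post-QC call statistics into five
categories: ``robust`` (no-call < 5%, all three genotype classes present),
``two_cluster`` (no-call < 5%, heterozygotes present but one homozygote
class absent -- typically a rare allele), ``monomorphic``, ``failed``
(no-call > 50%, or the undefined 5-50% band, treated conservatively), and
``null_suspect`` (recurrent opposing-homozygote contradictions in verified
parent-child duos, the classic null-allele signature).  Retained =
{robust, two_cluster}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import AA, AB, BB, MISSING, GenotypeMatrix

RETAINED_CATEGORIES = ("robust", "two_cluster")


@dataclass
class SnpCategory:
    marker: str
    category: str
    call_rate: float
    n_genotype_classes: int


def categorize_snp(
    calls: np.ndarray,
    no_call_max: float = 0.05,
    failed_no_call: float = 0.50,
) -> tuple[str, float, int]:
    """Category for one marker's call row; returns (category, call rate, n classes)."""
    calls = np.asarray(calls)
    n = calls.size
    if n == 0:
        return "failed", 0.0, 0
    genotyped = calls[calls != MISSING]
    call_rate = genotyped.size / n
    classes = {int(c) for c in np.unique(genotyped)}
    if genotyped.size == 0:
        return "failed", 0.0, 0
    no_call = 1.0 - call_rate
    if no_call > failed_no_call:
        return "failed", call_rate, len(classes)
    if len(classes) == 1:
        return "monomorphic", call_rate, 1
    if no_call >= no_call_max:
        return "failed", call_rate, len(classes)
    if classes == {AA, AB, BB}:
        return "robust", call_rate, 3
    if AB in classes and len(classes) == 2:
        return "two_cluster", call_rate, 2
    # AA and BB present without AB: inheritance-implausible clustering
    return "failed", call_rate, len(classes)


def opposing_duo_counts(
    gm: GenotypeMatrix, duos: list[tuple[str, str]], robust: bool = False
) -> pd.Series:
    """Per-marker count of verified duos showing opposing homozygotes.

    With ``robust`` each marker's count is discounted by the largest
    contribution of any single individual: one miscalled parent facing
    many offspring then no longer mimics a null allele, whose
    contradictions come from many unrelated duos.
    """
    usable = [
        (c, p) for c, p in duos if c in gm.individuals and p in gm.individuals
    ]
    counts = np.zeros(gm.n_markers, dtype=int)
    per_individual: dict[str, np.ndarray] = {}
    for child, parent in usable:
        c = gm.individual_calls(child)
        p = gm.individual_calls(parent)
        opposing = (((c == AA) & (p == BB)) | ((c == BB) & (p == AA))).astype(int)
        counts += opposing
        if robust:
            for who in (child, parent):
                acc = per_individual.setdefault(
                    who, np.zeros(gm.n_markers, dtype=int)
                )
                acc += opposing
    if robust and per_individual:
        max_single = np.max(np.stack(list(per_individual.values())), axis=0)
        counts = counts - max_single
    return pd.Series(counts, index=gm.markers, name="opposing_duos")


def adaptive_null_threshold(counts: pd.Series, min_duos: int = 3) -> int:
    """Duo-count threshold lifted above the sporadic-miscall background.

    Sporadic miscalls create opposing-homozygote duos at a roughly Poisson
    background shared by all markers; a null allele multiplies the count
    many-fold at its marker.  The threshold is the configured floor or five
    standard deviations above the mean background, whichever is larger, so
    it scales with the number of verified duos.
    """
    if counts.empty:
        return min_duos
    background = float(np.mean(counts))
    return max(min_duos, int(np.ceil(background + 5.0 * np.sqrt(background + 1.0))))


def detect_null_suspects(
    gm: GenotypeMatrix,
    duos: list[tuple[str, str]],
    min_duos: int = 3,
    adaptive: bool = False,
) -> set[str]:
    """Markers with opposing homozygotes in >= ``min_duos`` verified duos.

    A null allele makes hetero-with-null individuals look homozygous, so a
    true AB(null) parent scored AA can face a BB child; recurrence of that
    contradiction across verified parent-child duos is the marker-level
    signature.  ``duos`` are (child, parent) pairs whose relationship has
    been verified independently.  With ``adaptive`` the threshold is lifted
    above the sporadic-miscall background (see
    :func:`adaptive_null_threshold`), which matters for cohorts with many
    duos.
    """
    usable = [
        (c, p) for c, p in duos if c in gm.individuals and p in gm.individuals
    ]
    if not usable:
        import warnings

        warnings.warn("no verified duos available; null-allele scan is empty")
        return set()
    counts = opposing_duo_counts(gm, duos, robust=adaptive)
    threshold = adaptive_null_threshold(counts, min_duos) if adaptive else min_duos
    return set(counts.index[counts >= threshold])


def run_snp_filter(
    gm: GenotypeMatrix,
    verified_duos: list[tuple[str, str]] | None = None,
    no_call_max: float = 0.05,
    failed_no_call: float = 0.50,
    min_null_duos: int = 3,
) -> pd.DataFrame:
    """Categorize every marker; returns the snp_categories table.

    When verified duos are supplied, the null-allele scan overrides
    ``robust``/``two_cluster`` with ``null_suspect``.
    """
    rows = []
    for i, marker in enumerate(gm.markers):
        category, rate, n_classes = categorize_snp(
            gm.calls[i], no_call_max, failed_no_call
        )
        rows.append(
            {
                "marker": marker,
                "category": category,
                "call_rate": rate,
                "n_classes": n_classes,
            }
        )
    table = pd.DataFrame(rows).set_index("marker")
    if verified_duos:
        suspects = detect_null_suspects(gm, verified_duos, min_null_duos)
        override = table.index.isin(suspects) & table["category"].isin(
            RETAINED_CATEGORIES
        )
        table.loc[override, "category"] = "null_suspect"
    table["retained"] = table["category"].isin(RETAINED_CATEGORIES)
    return table
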