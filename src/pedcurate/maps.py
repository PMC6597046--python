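"""Genetic-map construction: physical->genetic scaling and interpolation.

Crops without a dense genetic map can approximate one from physical
positions, either with a genome-wide conversion factor (the peach default of
4 cM per Mb) or, marker by marker, by linear interpolation between flanking
anchor SNPs that carry both a genetic and a physical position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import GeneticMap

#: default genome-wide conversion: 1 Mb of physical distance ~ 4 cM
DEFAULT_CM_PER_MB = 4.0


def physical_to_genetic(
    bp_map: pd.DataFrame, cm_per_mb: float = DEFAULT_CM_PER_MB
) -> GeneticMap:
    """Scale physical positions to genetic ones: cm = bp / 1e6 * cm_per_mb.

    ``bp_map`` needs columns ``marker``, ``linkage_group``, ``bp``; bp are
    1-based and must be positive.
    """
    required = {"marker", "linkage_group", "bp"}
    if not required.issubset(bp_map.columns):
        raise ValueError(f"bp map needs columns {sorted(required)}")
    bp = pd.to_numeric(bp_map["bp"])
    if (bp <= 0).any():
        bad = list(bp_map.loc[bp <= 0, "marker"])
        raise ValueError(f"nonpositive bp positions for markers {bad}")
    return GeneticMap(
        pd.DataFrame(
            {
                "marker": bp_map["marker"],
                "linkage_group": bp_map["linkage_group"],
                "cm": bp / 1e6 * cm_per_mb,
                "bp": bp,
            }
        )
    )


@dataclass
class InterpolationResult:
    map: GeneticMap
    extrapolated: list[str] = field(default_factory=list)
    unplaceable: list[str] = field(default_factory=list)


def interpolate_map(
    anchors: GeneticMap,
    targets: pd.DataFrame,
    max_extrapolation_cm: float | None = None,
) -> InterpolationResult:
    """Place bp-only markers on the genetic map via flanking anchors.

    Anchors need both cM and bp.  Targets (columns ``marker``,
    ``linkage_group``, ``bp``) inside the anchor span are linearly
    interpolated between the flanking anchor pair; targets beyond a terminal
    anchor are extrapolated with the nearest anchor pair's local cM/bp slope
    (capped at ``max_extrapolation_cm`` beyond the terminal anchor when set)
    and reported as extrapolated.  Targets on a linkage group with fewer than
    two anchors are unplaceable (mapping-failure candidates).  Anchors are
    passed through unchanged.
    """
    required = {"marker", "linkage_group", "bp"}
    if not required.issubset(targets.columns):
        raise ValueError(f"targets need columns {sorted(required)}")

    anchor_tab = anchors.table.dropna(subset=["bp"])
    rows = [anchors.table.copy()]
    extrapolated: list[str] = []
    unplaceable: list[str] = []
    out_rows: list[dict] = []
    for row in targets.itertuples(index=False):
        lg = str(row.linkage_group)
        bp = float(row.bp)
        sub = anchor_tab[anchor_tab["linkage_group"] == lg].sort_values("bp")
        if len(sub) < 2:
            unplaceable.append(row.marker)
            continue
        abp = sub["bp"].to_numpy(dtype=float)
        acm = sub["cm"].to_numpy(dtype=float)
        if bp <= abp[0]:
            lo, hi = 0, 1
            extrapolate = bp < abp[0]
        elif bp >= abp[-1]:
            lo, hi = len(abp) - 2, len(abp) - 1
            extrapolate = bp > abp[-1]
        else:
            hi = int(np.searchsorted(abp, bp, side="left"))
            lo = hi - 1
            extrapolate = False
        slope = (acm[hi] - acm[lo]) / (abp[hi] - abp[lo])
        cm = acm[lo] + (bp - abp[lo]) * slope
        if extrapolate:
            extrapolated.append(row.marker)
            if max_extrapolation_cm is not None:
                cm = float(
                    np.clip(cm, acm[0] - max_extrapolation_cm, acm[-1] + max_extrapolation_cm)
                )
        out_rows.append(
            {"marker": row.marker, "linkage_group": lg, "cm": float(cm), "bp": bp}
        )
    if out_rows:
        rows.append(pd.DataFrame(out_rows))
    merged = pd.concat(rows, ignore_index=True)
    return InterpolationResult(GeneticMap(merged), extrapolated, unplaceable)
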