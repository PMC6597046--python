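"""Sample quality and ploidy screening from B-allele frequencies (BAF).

On a biallelic SNP assay the per-SNP BAF of a clean diploid concentrates at
0, 0.5 and 1.  DNA of poor quality spreads calls away from those modes; the
fraction of SNPs falling in the off-bands [0.125, 0.375] u [0.625, 0.875]
grades sample quality.  Non-diploid samples shift the heterozygous modes:
with ploidy p and b copies of the B allele the expected BAF is b/p, so a
triploid shows modes {0, 1/3, 2/3, 1} and a tetraploid (or a mixture of two
samples) {0, 1/4, 1/2, 3/4, 1}.  Whole-genome shifts mean polyploidy;
shifts confined to one chromosome mean aneuploidy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .datamodel import BafMatrix, GeneticMap

#: symmetric off-band intervals used for the quality grade
OFFBANDS = ((0.125, 0.375), (0.625, 0.875))

#: quality thresholds on the off-band fraction: <0.3% good, 0.3-3%
#: intermediate, >3% bad (boundary values go to the less severe class)
QUALITY_THRESHOLDS = (0.003, 0.03)

_TEMPLATES = {
    "diploid": (0.0, 0.5, 1.0),
    "triploid": (0.0, 1 / 3, 2 / 3, 1.0),
    "tetraploid_or_mixture": (0.0, 0.25, 0.5, 0.75, 1.0),
}


def expected_baf(ploidy: int, b_copies: int) -> float:
    """Expected B-allele frequency for ``b_copies`` B alleles among ``ploidy``."""
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    if not 0 <= b_copies <= ploidy:
        raise ValueError(f"b_copies {b_copies} outside [0, {ploidy}]")
    return b_copies / ploidy


def offband_fraction(values: np.ndarray | pd.Series) -> float:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return float("nan")
    hit = np.zeros(v.shape, dtype=bool)
    for lo, hi in OFFBANDS:
        hit |= (v >= lo) & (v <= hi)
    return float(hit.mean())


def classify_quality(
    values: np.ndarray | pd.Series,
    thresholds: tuple[float, float] = QUALITY_THRESHOLDS,
    min_n: int = 100,
) -> tuple[str, float]:
    """Grade one sample's BAF column; returns (quality, offband fraction)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < min_n:
        return "unknown", float("nan")
    frac = offband_fraction(v)
    lo, hi = thresholds
    if frac <= lo:
        return "good", frac
    if frac <= hi:
        return "intermediate", frac
    return "bad", frac


def find_baf_peaks(
    values: np.ndarray, bin_width: float = 0.02, min_fraction: float = 0.01
) -> np.ndarray:
    """Histogram-mode positions of a BAF column.

    Deterministic: fixed-width bins on [0, 1], local maxima with prominence
    of at least ``min_fraction`` of the observations; the histogram is
    zero-padded so boundary modes at 0 and 1 are found too.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    nbins = int(round(1.0 / bin_width))
    counts, edges = np.histogram(v, bins=nbins, range=(0.0, 1.0))
    padded = np.concatenate([[0], counts, [0]])
    idx, _ = find_peaks(padded, prominence=max(1.0, min_fraction * v.size))
    centers = (edges[:-1] + edges[1:]) / 2
    return centers[idx - 1]


@dataclass
class SampleQcResult:
    individual_id: str
    fraction_offband: float
    quality: str
    ploidy_call: str
    per_chromosome_pattern: dict[str, str] = field(default_factory=dict)


def _chromosome_pattern(
    values: np.ndarray, min_het: int = 10, tol: float = 0.08
) -> str:
    """Pattern of one chromosome: where do the heterozygous-range BAFs sit?"""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    het = v[(v > 0.15) & (v < 0.85)]
    if het.size < min_het:
        return "haploid_like"
    near_half = np.abs(het - 0.5) <= tol
    near_thirds = np.minimum(np.abs(het - 1 / 3), np.abs(het - 2 / 3)) <= tol
    if near_half.mean() >= 0.5:
        return "diploid_like"
    if near_thirds.mean() >= 0.5:
        return "polyploid_like"
    return "polyploid_like"


def classify_ploidy(
    values: np.ndarray | pd.Series,
    gmap: GeneticMap | None = None,
    markers: list[str] | None = None,
    tol: float = 0.05,
    strict: bool = False,
) -> tuple[str, dict[str, str]]:
    """Ploidy call for one sample from its BAF modes.

    More than three histogram modes marks a polyploid; the mode set decides
    between triploid and tetraploid-or-mixture patterns.  When a map is
    available, a per-chromosome scan separates aneuploids (one or a few
    chromosomes off-pattern) from genome-wide ploidy shifts.  With
    ``strict`` only a clean template match yields a polyploid call
    (appropriate for samples whose BAF is too noisy to trust extra modes).
    """
    v = np.asarray(values, dtype=float)
    finite = v[np.isfinite(v)]
    peaks = find_baf_peaks(v)

    def matches(template: tuple[float, ...]) -> bool:
        if peaks.size == 0:
            return False
        ok_peaks = all(min(abs(p - t) for t in template) <= tol for p in peaks)
        inner = [t for t in template if 0.0 < t < 1.0]
        inner_found = all(any(abs(p - t) <= tol for p in peaks) for t in inner)
        if strict and finite.size:
            # real extra modes are sharp: most of the mass must sit on them
            dist = np.min(
                np.abs(finite[:, None] - np.asarray(template)[None, :]), axis=1
            )
            if (dist <= tol).mean() < 0.8:
                return False
        return ok_peaks and inner_found

    if matches(_TEMPLATES["triploid"]) and len(peaks) > 3:
        call = "triploid"
    elif matches(_TEMPLATES["tetraploid_or_mixture"]) and len(peaks) > 3:
        call = "tetraploid_or_mixture"
    elif len(peaks) > 3:
        call = "unknown" if strict else "tetraploid_or_mixture"
    else:
        call = "diploid"

    patterns: dict[str, str] = {}
    if gmap is not None and markers is not None:
        per_marker = pd.Series(np.asarray(values, dtype=float), index=markers)
        for lg in gmap.linkage_groups:
            on_lg = [m for m in gmap.markers_on(lg) if m in per_marker.index]
            if on_lg:
                patterns[lg] = _chromosome_pattern(per_marker[on_lg].to_numpy())
        if patterns and not strict:
            # per-chromosome evidence overrides the pooled histogram: a
            # trisomy of even one large chromosome adds global modes
            n_poly = sum(1 for p in patterns.values() if p == "polyploid_like")
            if 0 < n_poly < len(patterns) and any(
                p == "diploid_like" for p in patterns.values()
            ):
                call = "aneuploid"
            elif n_poly == len(patterns) and call == "diploid":
                call = "triploid"
    return call, patterns


def run_sample_qc(
    baf: BafMatrix,
    gmap: GeneticMap | None = None,
    thresholds: tuple[float, float] = QUALITY_THRESHOLDS,
    min_n: int = 100,
) -> pd.DataFrame:
    """Quality + ploidy screen for every sample; one row per individual.

    A non-diploid sample necessarily fails the off-band quality grade (its
    heterozygous modes sit inside the off-bands), so a clean polyploid
    template match takes precedence: such samples are reported by their
    ploidy.  Samples graded bad without a clean polyploid pattern keep
    ploidy ``unknown`` -- their extra modes are noise, not chromosomes.
    """
    rows = []
    for ind in baf.individuals:
        col = baf.column(ind).to_numpy()
        quality, frac = classify_quality(col, thresholds, min_n)
        if quality == "unknown":
            call, patterns = "unknown", {}
        else:
            call, patterns = classify_ploidy(
                col, gmap, baf.markers, strict=quality == "bad"
            )
        flagged = ",".join(
            lg for lg, p in patterns.items() if p != "diploid_like"
        )
        rows.append(
            {
                "individual": ind,
                "fraction_offband": frac,
                "quality": quality,
                "ploidy_call": call,
                "flagged_chromosomes": flagged,
            }
        )
    return pd.DataFrame(rows).set_index("individual")


def excluded_samples(qc: pd.DataFrame) -> list[str]:
    """Samples to drop: bad quality, or a non-diploid/unknown-ploidy call."""
    drop = (qc["quality"] == "bad") | (
        ~qc["ploidy_call"].isin(["diploid"]) & (qc["quality"] != "unknown")
    )
    return list(qc.index[drop])


def segmental_scan(
    event_positions: pd.DataFrame,
    gmap: GeneticMap,
    window_cm: float = 20.0,
    multiple: float = 5.0,
    min_count: int = 5,
) -> pd.DataFrame:
    """Scan for chromosome segments with locally concentrated errors.

    Segmental aneuploids escape the genome-wide BAF screen but reveal
    themselves through parent-child conflicts and double recombinations
    piled onto one chromosomal segment.  ``event_positions`` needs columns
    ``individual``, ``linkage_group``, ``cm`` (pooled parent-child-error and
    double-recombination positions).  A half-overlapping sliding window is
    reported when its event count exceeds both ``min_count`` and
    ``multiple`` times the individual's genome-wide expectation for one
    window.
    """
    total_cm = max(gmap.length_cm(), 1e-9)
    out = []
    for ind, sub in event_positions.groupby("individual"):
        rate = len(sub) / total_cm
        threshold = max(min_count, multiple * rate * window_cm)
        for lg, lg_events in sub.groupby("linkage_group"):
            pos = np.sort(lg_events["cm"].to_numpy(dtype=float))
            lg_positions = gmap.positions_on(str(lg))
            if lg_positions.empty:
                continue
            start, stop = float(lg_positions.min()), float(lg_positions.max())
            step = window_cm / 2
            w = start
            while w <= stop:
                n = int(np.sum((pos >= w) & (pos < w + window_cm)))
                if n > threshold:
                    out.append(
                        {
                            "individual": ind,
                            "linkage_group": str(lg),
                            "window_start_cm": w,
                            "window_end_cm": w + window_cm,
                            "n_events": n,
                            "threshold": threshold,
                        }
                    )
                w += step
    frame = pd.DataFrame(
        out,
        columns=[
            "individual",
            "linkage_group",
            "window_start_cm",
            "window_end_cm",
            "n_events",
            "threshold",
        ],
    )
    if frame.empty:
        return frame
    # merge overlapping windows per individual/LG into maximal segments
    merged = []
    for (ind, lg), sub in frame.groupby(["individual", "linkage_group"]):
        sub = sub.sort_values("window_start_cm")
        cur = None
        for row in sub.itertuples(index=False):
            if cur is None or row.window_start_cm > cur["window_end_cm"]:
                if cur is not None:
                    merged.append(cur)
                cur = {
                    "individual": ind,
                    "linkage_group": lg,
                    "window_start_cm": row.window_start_cm,
                    "window_end_cm": row.window_end_cm,
                    "n_events": row.n_events,
                    "threshold": row.threshold,
                }
            else:
                cur["window_end_cm"] = max(cur["window_end_cm"], row.window_end_cm)
                cur["n_events"] = max(cur["n_events"], row.n_events)
        if cur is not None:
            merged.append(cur)
    return pd.DataFrame(merged)
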