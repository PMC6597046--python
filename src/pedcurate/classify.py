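"""Per-SNP curation ledger, type 1-7 classification, and the final bundle.

Every marker accumulates evidence tags while the workflow runs; at the end
each marker receives exactly one type:

* 1 -- clean: under 5% of its calls edited, no cluster-level evidence;
* 2 -- one genotype cluster was mislabelled (systematic relabel fixed or
  detected);
* 3 -- additional clusters / heavy call correction;
* 4 -- null allele present;
* 5 -- map position could not be determined;
* 6 -- monomorphic;
* 7 -- failed (unreliable calling, or removed as unresolvable).

Higher types take precedence.  Retention is recorded separately from type:
the type describes the cluster phenomenon, the retained flag the decision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import GenotypeMatrix, Pedigree
from .io import write_edit_log, write_genotype_table, write_map_csv, write_pedigree_csv

#: workflow stage order; later stages depend on all earlier ones
PIPELINE_STAGES = (
    "sample_qc",
    "snp_filter",
    "dedup",
    "parentage",
    "mendel",
    "phase_recomb",
    "haploblock",
    "classify",
)

_TYPE_TAGS = (
    (7, ("failed", "unresolvable")),
    (6, ("monomorphic",)),
    (5, ("unmapped", "map_unresolved")),
    (4, ("null_allele", "null_suspect")),
    (3, ("extra_cluster",)),
    (2, ("cluster_shift",)),
)


class CurationLedger:
    """Evidence tags, retention decisions and stage counts per marker."""

    def __init__(self, markers: list[str]) -> None:
        self.tags: dict[str, set[str]] = {m: set() for m in markers}
        self.retained: dict[str, bool] = {m: True for m in markers}
        self.stage_counts: list[dict] = []

    def tag(self, marker: str, tag: str) -> None:
        self.tags.setdefault(marker, set()).add(tag)

    def drop(self, marker: str, tag: str) -> None:
        self.tag(marker, tag)
        self.retained[marker] = False

    def record_stage(self, stage: str, n_in: int, n_retained: int) -> None:
        self.stage_counts.append(
            {
                "stage": stage,
                "markers_in": n_in,
                "retained": n_retained,
                "discarded": n_in - n_retained,
            }
        )

    def retained_markers(self) -> list[str]:
        return [m for m, keep in self.retained.items() if keep]


def classify_snps(
    ledger: CurationLedger,
    edit_fraction: pd.Series,
    edit_threshold: float = 0.05,
) -> pd.DataFrame:
    """One type per marker from the ledger (precedence 7 > 6 > ... > 1)."""
    rows = []
    for marker, tags in ledger.tags.items():
        if marker not in edit_fraction.index:
            frac = 0.0
        else:
            frac = float(edit_fraction[marker])
        snp_type = 1
        for t, needles in _TYPE_TAGS:
            if any(n in tags for n in needles):
                snp_type = t
                break
        if snp_type == 1 and frac >= edit_threshold:
            # heavy editing without marker-level evidence: treated as a
            # cluster-identification problem
            snp_type = 2
        rows.append(
            {
                "marker": marker,
                "type": snp_type,
                "edit_fraction": frac,
                "retained": ledger.retained[marker],
                "evidence": ";".join(sorted(tags)),
            }
        )
    return pd.DataFrame(rows).set_index("marker")


@dataclass
class RunManifest:
    stages_run: list[str]
    seed: int | None
    config: dict
    stage_counts: list[dict]
    n_individuals_final: int
    n_markers_final: int
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "stages_run": self.stages_run,
            "stage_order": list(PIPELINE_STAGES),
            "seed": self.seed,
            "config": self.config,
            "stage_counts": self.stage_counts,
            "n_individuals_final": self.n_individuals_final,
            "n_markers_final": self.n_markers_final,
            "notes": self.notes,
        }


def emit_final_dataset(
    outdir: str | Path,
    gm: GenotypeMatrix,
    ped: Pedigree,
    classifications: pd.DataFrame,
    manifest: RunManifest,
    gmap=None,
    phased_frame: pd.DataFrame | None = None,
    haplotype_frame: pd.DataFrame | None = None,
    code_dictionary: pd.DataFrame | None = None,
    reports: dict[str, pd.DataFrame] | None = None,
) -> None:
    """Write the curated bundle: data, reports and the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genotype_table(gm, outdir / "curated_genotypes.tsv")
    write_edit_log(gm.edit_log, outdir / "edit_log.csv")
    write_pedigree_csv(ped, outdir / "curated_pedigree.csv")
    if gmap is not None:
        write_map_csv(gmap, outdir / "curated_map.csv")
    classifications.to_csv(outdir / "snp_classification.csv")
    if phased_frame is not None:
        phased_frame.to_csv(outdir / "phased.tsv", sep="\t", index_label="marker")
    if haplotype_frame is not None:
        haplotype_frame.to_csv(
            outdir / "haplotypes.tsv", sep="\t", index_label="individual"
        )
    if code_dictionary is not None:
        code_dictionary.to_csv(outdir / "code_dictionary.csv", index=False)
    for name, frame in (reports or {}).items():
        frame.to_csv(outdir / f"{name}.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, default=str)
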