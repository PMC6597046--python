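"""Readers and writers for the tabular exchange formats.

Formats are deliberately plain text:

* genotype TSV -- header row of individual ids, first column marker id,
  cells in ``{AA, AB, BB, --}`` (extra missing codes configurable);
* PLINK PED/MAP -- one individual per PED row, two allele columns per
  marker, alleles coded ``A``/``B`` directly or via a per-marker
  nucleotide translation table, ``0`` = missing;
* pedigree CSV -- columns ``individual,mother,father,selected``;
* map CSV -- columns ``marker,linkage_group,cm[,bp]``;
* BAF TSV -- same layout as the genotype TSV with floats.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    AA,
    AB,
    BB,
    CALL_TO_STR,
    MISSING,
    STR_TO_CALL,
    BafMatrix,
    Edit,
    GeneticMap,
    GenotypeMatrix,
    Individual,
    Pedigree,
    _check_unique,
)

DEFAULT_MISSING_CODES = ("--", "NN", "NC", "")


def read_genotype_table(
    path: str | Path,
    dialect: str = "tsv",
    missing_codes: Sequence[str] = DEFAULT_MISSING_CODES,
    allele_translation: Mapping[str, Mapping[str, str]] | None = None,
) -> GenotypeMatrix:
    """Read a genotype matrix; ``dialect`` is ``"tsv"`` or ``"plink"``.

    For PLINK, ``path`` is the ``.ped`` file and the matching ``.map`` file
    must sit next to it.  Unknown tokens are mapped to missing and counted on
    the returned matrix as ``unknown_token_count`` (a warning is emitted).
    """
    if dialect == "tsv":
        return _read_genotype_tsv(Path(path), missing_codes)
    if dialect == "plink":
        ped = Path(path)
        return read_plink(ped, ped.with_suffix(".map"), allele_translation)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_genotype_table(
    gm: GenotypeMatrix,
    path: str | Path,
    dialect: str = "tsv",
    edit_log_path: str | Path | None = None,
) -> None:
    """Write a genotype matrix (column order fixed -> byte-stable output)."""
    if dialect == "tsv":
        _write_genotype_tsv(gm, Path(path))
    elif dialect == "plink":
        ped = Path(path)
        write_plink(gm, ped, ped.with_suffix(".map"))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if edit_log_path is not None:
        write_edit_log(gm.edit_log, edit_log_path)


def _read_genotype_tsv(path: Path, missing_codes: Sequence[str]) -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    markers = [str(m) for m in frame.index]
    individuals = [str(c) for c in frame.columns]
    _check_unique(markers, "marker")
    _check_unique(individuals, "individual")
    values = frame.to_numpy(dtype=object)
    calls = np.full(values.shape, MISSING, dtype=np.int8)
    known = np.zeros(values.shape, dtype=bool)
    for token, code in STR_TO_CALL.items():
        hit = values == token
        calls[hit] = code
        known |= hit
    for token in missing_codes:
        hit = values == token
        known |= hit
    unknown = int((~known).sum())
    if unknown:
        warnings.warn(f"{unknown} unknown genotype tokens mapped to missing")
    gm = GenotypeMatrix(markers, individuals, calls)
    gm.unknown_token_count = unknown
    return gm


def _write_genotype_tsv(gm: GenotypeMatrix, path: Path) -> None:
    gm.to_frame().to_csv(path, sep="\t", index_label="marker", lineterminator="\n")


def write_edit_log(edits: Sequence[Edit], path: str | Path) -> None:
    """One row per edited cell: marker, individual, original, new, reason."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["marker", "individual", "original", "new", "reason"])
        for e in edits:
            writer.writerow(
                [e.marker, e.individual, CALL_TO_STR[e.original], CALL_TO_STR[e.new], e.reason]
            )


# ---------------------------------------------------------------------------
# PLINK PED/MAP
# ---------------------------------------------------------------------------

_CALL_TO_ALLELES = {AA: ("A", "A"), AB: ("A", "B"), BB: ("B", "B"), MISSING: ("0", "0")}


def read_plink(
    ped_path: str | Path,
    map_path: str | Path,
    allele_translation: Mapping[str, Mapping[str, str]] | None = None,
) -> GenotypeMatrix:
    """Read PLINK text PED/MAP with A/B (or translated ACGT) alleles."""
    markers: list[str] = []
    with open(map_path) as fh:
        for line in fh:
            fields = line.split()
            if fields:
                markers.append(fields[1])
    _check_unique(markers, "marker")
    individuals: list[str] = []
    columns: list[np.ndarray] = []
    unknown = 0
    with open(ped_path) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * len(markers):
                raise ValueError(
                    f"PED row for {fields[1] if len(fields) > 1 else '?'} has "
                    f"{len(fields)} fields, expected {6 + 2 * len(markers)}"
                )
            individuals.append(fields[1])
            calls = np.full(len(markers), MISSING, dtype=np.int8)
            for k, marker in enumerate(markers):
                a1, a2 = fields[6 + 2 * k], fields[7 + 2 * k]
                if allele_translation and marker in allele_translation:
                    trans = allele_translation[marker]
                    a1 = trans.get(a1, a1)
                    a2 = trans.get(a2, a2)
                if a1 == "0" or a2 == "0":
                    continue
                if {a1, a2} <= {"A", "B"}:
                    calls[k] = (a1 == "B") + (a2 == "B")
                else:
                    unknown += 1
            columns.append(calls)
    _check_unique(individuals, "individual")
    if unknown:
        warnings.warn(f"{unknown} unknown PED allele pairs mapped to missing")
    data = (
        np.stack(columns, axis=1) if columns else np.empty((len(markers), 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(markers, individuals, data)
    gm.unknown_token_count = unknown
    return gm


def write_plink(
    gm: GenotypeMatrix,
    ped_path: str | Path,
    map_path: str | Path,
    gmap: GeneticMap | None = None,
) -> None:
    with open(map_path, "w") as fh:
        for marker in gm.markers:
            if gmap is not None and marker in gmap:
                lg, cm = gmap.lg_of(marker), gmap.cm_of(marker)
            else:
                lg, cm = "0", 0.0
            fh.write(f"{lg}\t{marker}\t{cm:g}\t0\n")
    with open(ped_path, "w") as fh:
        for j, ind in enumerate(gm.individuals):
            alleles = [
                a for call in gm.calls[:, j] for a in _CALL_TO_ALLELES[int(call)]
            ]
            fh.write("\t".join(["FAM1", ind, "0", "0", "0", "-9", *alleles]) + "\n")


# ---------------------------------------------------------------------------
# pedigree / map / BAF tables
# ---------------------------------------------------------------------------

def read_pedigree_csv(path: str | Path) -> Pedigree:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    ped = Pedigree()
    for row in frame.itertuples(index=False):
        ped.add(
            Individual(
                id=row.individual,
                mother=row.mother or None,
                father=row.father or None,
                selected=str(getattr(row, "selected", "0")) in ("1", "True", "true"),
            )
        )
    ped.validate()
    return ped


def write_pedigree_csv(ped: Pedigree, path: str | Path) -> None:
    rows = [
        {
            "individual": ind.id,
            "mother": ind.mother or "",
            "father": ind.father or "",
            "selected": int(ind.selected),
        }
        for ind in ped
    ]
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


def read_map_csv(path: str | Path) -> GeneticMap:
    frame = pd.read_csv(path)
    return GeneticMap(frame)


def write_map_csv(gmap: GeneticMap, path: str | Path) -> None:
    gmap.table.to_csv(path, index=False, lineterminator="\n")


def read_baf_tsv(path: str | Path) -> BafMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return BafMatrix(frame)


def write_baf_tsv(baf: BafMatrix, path: str | Path) -> None:
    baf.frame.to_csv(path, sep="\t", index_label="marker", lineterminator="\n")
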