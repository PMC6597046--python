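"""Synthetic multi-generation outbred germplasm with a truth ledger.

The generator emulates the study design this toolkit curates: a pedigreed
collection of a clonally propagated diploid outbreeder genotyped on a SNP
array.  Founders are unrelated with intermediate allele frequencies; later
generations arise from sampled parent pairs (with reuse, so half-sib
families occur); meioses follow the Haldane model (Poisson crossover
counts, uniform positions, no interference).  On top of the clean data the
error injector reproduces the error taxonomy the curation workflow must
catch: random miscalls, systematic cluster shifts, null alleles, wrong
pedigree records, duplicated samples, triploids from unreduced gametes,
low-quality samples, and segmental deletions.  Every injected error is
registered so tests can score recovery against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datamodel import (
    AA,
    AB,
    BB,
    MISSING,
    BafMatrix,
    GeneticMap,
    GenotypeMatrix,
    Individual,
    Pedigree,
)

NULL_ALLELE = 2  # haplotype allele code for a signal-free (null) allele


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    The defaults are the standard scenario used throughout the test suite:
    three generations totalling 200 diploid individuals, five 100-cM
    linkage groups of 200 evenly spaced markers each, 1% random miscalls,
    2% cluster-shifted markers, two wrong parent records, one duplicate
    pair, one triploid and two bad-quality samples.
    """

    seed: int
    n_founders: int = 40
    generation_sizes: tuple[int, ...] = (60, 100)
    family_size: int = 5
    selected_fraction_last: float = 0.0
    n_linkage_groups: int = 5
    n_markers_per_lg: int = 200
    lg_length_cm: float = 100.0
    founder_maf: tuple[float, float] = (0.1, 0.5)
    missing_rate: float = 0.005
    random_miscall_rate: float = 0.01
    cluster_shift_fraction: float = 0.02
    null_allele_fraction: float = 0.0
    null_allele_freq: float = 0.2
    n_wrong_parents: int = 2
    n_duplicate_pairs: int = 1
    duplicate_miscall_rate: float = 0.01
    n_triploids: int = 1
    n_bad_quality: int = 2
    bad_missing_rate: float = 0.10
    bad_miscall_rate: float = 0.05
    n_segmental_deletions: int = 0
    deletion_length_cm: float = 30.0
    baf_noise_sd: float = 0.02
    baf_noise_sd_bad: float = 0.12

    def __post_init__(self) -> None:
        for name in (
            "missing_rate",
            "random_miscall_rate",
            "cluster_shift_fraction",
            "null_allele_fraction",
            "null_allele_freq",
            "duplicate_miscall_rate",
            "bad_missing_rate",
            "bad_miscall_rate",
            "selected_fraction_last",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class Meiosis:
    parent: str
    child: str
    linkage_group: str
    crossover_cm: list[float]
    start_homolog: int


@dataclass
class TruthLedger:
    pedigree: Pedigree
    haplotypes: np.ndarray  # (markers, individuals, 2), allele codes
    meioses: list[Meiosis]
    registry: pd.DataFrame
    clean_calls: np.ndarray
    b_copies: np.ndarray  # float, NaN where no signal
    total_copies: np.ndarray
    individual_index: dict[str, int]
    marker_index: dict[str, int]

    def crossovers_of(self, parent: str, child: str, lg: str) -> list[float]:
        for m in self.meioses:
            if (m.parent, m.child, m.linkage_group) == (parent, child, lg):
                return m.crossover_cm
        return []


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    gmap: GeneticMap
    pedigree: Pedigree  # recorded pedigree (possibly corrupted)
    gm: GenotypeMatrix  # corrupted calls
    baf: BafMatrix
    truth: TruthLedger


# ---------------------------------------------------------------------------
# clean cohort
# ---------------------------------------------------------------------------

def simulate_map(config: SimulationConfig) -> GeneticMap:
    markers, lgs, cms = [], [], []
    n = config.n_markers_per_lg
    for g in range(1, config.n_linkage_groups + 1):
        step = config.lg_length_cm / max(n - 1, 1)
        for k in range(n):
            markers.append(f"LG{g}_M{k + 1:04d}")
            lgs.append(str(g))
            cms.append(k * step)
    return GeneticMap.from_positions(markers, lgs, cms)


def simulate_pedigree(
    config: SimulationConfig, rng: np.random.Generator
) -> Pedigree:
    """Founders plus sampled parent pairs; parent reuse yields half-sibs."""
    ped = Pedigree()
    founders = [f"F{k + 1:03d}" for k in range(config.n_founders)]
    for fid in founders:
        ped.add(Individual(fid, selected=True))
    previous = founders
    n_gens = len(config.generation_sizes)
    for gen, size in enumerate(config.generation_sizes, start=1):
        if len(previous) < 2:
            raise ValueError("infeasible family structure: fewer than 2 parents")
        last = gen == n_gens
        members: list[str] = []
        fam = 0
        while len(members) < size:
            fam += 1
            mother, father = rng.choice(len(previous), size=2, replace=False)
            n_children = min(config.family_size, size - len(members))
            for c in range(n_children):
                cid = f"G{gen}_{fam:02d}_{c + 1}"
                selected = (not last) or (
                    rng.random() < config.selected_fraction_last
                )
                ped.add(
                    Individual(
                        cid,
                        mother=previous[mother],
                        father=previous[father],
                        selected=selected,
                    )
                )
                members.append(cid)
        previous = members
    return ped


def simulate_meiosis(
    haplotypes: np.ndarray,
    cm_positions: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[float], int]:
    """One gamete from a phased parent under the Haldane model.

    Crossover count ~ Poisson(length/100), positions uniform in cM, no
    interference.  Returns (gamete alleles, crossover positions, starting
    homolog).
    """
    length = float(cm_positions[-1] - cm_positions[0]) if cm_positions.size else 0.0
    n_xo = rng.poisson(length / 100.0)
    positions = sorted(rng.uniform(cm_positions[0], cm_positions[0] + length, size=n_xo))
    start = int(rng.integers(2))
    # searchsorted counts crossovers left of each marker; parity flips homolog
    homolog = (start + np.searchsorted(positions, cm_positions, side="left")) % 2
    gamete = haplotypes[np.arange(haplotypes.shape[0]), homolog]
    return gamete, [float(p) for p in positions], start


def _calls_from_haplotypes(h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
    """Array calls for allele codes 0=A, 1=B, 2=null."""
    calls = np.full(h1.shape, MISSING, dtype=np.int8)
    n1, n2 = h1 == NULL_ALLELE, h2 == NULL_ALLELE
    both = ~n1 & ~n2
    calls[both] = (h1[both] + h2[both]).astype(np.int8)
    only1 = n1 & ~n2
    calls[only1] = np.where(h2[only1] == 1, BB, AA)
    only2 = ~n1 & n2
    calls[only2] = np.where(h1[only2] == 1, BB, AA)
    return calls  # both-null stays missing


@dataclass
class _CleanCohort:
    gmap: GeneticMap
    pedigree: Pedigree
    haplotypes: np.ndarray
    meioses: list[Meiosis]
    calls: np.ndarray
    individuals: list[str]
    null_markers: list[str]


def simulate_clean(
    config: SimulationConfig, rng: np.random.Generator
) -> _CleanCohort:
    gmap = simulate_map(config)
    ped = simulate_pedigree(config, rng)
    markers = list(gmap.table["marker"])
    m_index = {m: i for i, m in enumerate(markers)}
    individuals = ped.ids
    i_index = {s: j for j, s in enumerate(individuals)}
    n_m, n_i = len(markers), len(individuals)

    freqs = rng.uniform(*config.founder_maf, size=n_m)
    n_null = int(round(config.null_allele_fraction * n_m))
    null_rows = sorted(rng.choice(n_m, size=n_null, replace=False)) if n_null else []

    haplo = np.zeros((n_m, n_i, 2), dtype=np.int8)
    lg_slices = {
        lg: np.array([m_index[m] for m in gmap.markers_on(lg)])
        for lg in gmap.linkage_groups
    }
    meioses: list[Meiosis] = []
    for s in ped.topological_order():
        j = i_index[s]
        ind = ped[s]
        if ind.is_founder:
            draw = rng.random((n_m, 2))
            haplo[:, j, :] = (draw < freqs[:, None]).astype(np.int8)
            if null_rows:
                null_draw = rng.random((len(null_rows), 2))
                sub = haplo[null_rows, j, :]
                sub[null_draw < config.null_allele_freq] = NULL_ALLELE
                haplo[null_rows, j, :] = sub
        else:
            for slot, parent in enumerate((ind.mother, ind.father)):
                pj = i_index[parent]
                for lg, rows in lg_slices.items():
                    cms = gmap.table.loc[rows, "cm"].to_numpy(dtype=float)
                    gamete, xo, start = simulate_meiosis(
                        haplo[rows][:, pj, :], cms, rng
                    )
                    haplo[rows, j, slot] = gamete
                    meioses.append(Meiosis(parent, s, lg, xo, start))
    calls = _calls_from_haplotypes(haplo[:, :, 0], haplo[:, :, 1])
    return _CleanCohort(
        gmap, ped, haplo, meioses, calls, individuals,
        [markers[i] for i in null_rows],
    )


# ---------------------------------------------------------------------------
# error injection
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full synthetic data set: clean cohort + injected errors + BAF."""
    rng = np.random.default_rng(config.seed)
    clean = simulate_clean(config, rng)
    return inject_errors(clean, config, rng)


def inject_errors(
    clean: _CleanCohort, config: SimulationConfig, rng: np.random.Generator
) -> SimulatedDataset:
    gmap = clean.gmap
    markers = list(gmap.table["marker"])
    m_index = {m: i for i, m in enumerate(markers)}
    individuals = list(clean.individuals)
    i_index = {s: j for j, s in enumerate(individuals)}
    ped_true = clean.pedigree.copy()
    ped_recorded = clean.pedigree.copy()
    calls = clean.calls.copy()
    registry_rows: list[dict] = []
    n_m = len(markers)

    last_gen = [
        s for s in individuals if ped_true[s].mother is not None and not ped_true[s].selected
    ]
    if not last_gen:
        last_gen = [s for s in individuals if ped_true[s].mother is not None]
    anomaly_pool = list(last_gen)
    rng.shuffle(anomaly_pool)

    def take(n: int) -> list[str]:
        out = [anomaly_pool.pop() for _ in range(min(n, len(anomaly_pool)))]
        if len(out) < n:
            raise ValueError("not enough individuals for the requested anomalies")
        return out

    ploidy = np.full(len(individuals), 2, dtype=np.int8)
    quality_sd = np.full(len(individuals), config.baf_noise_sd, dtype=float)

    # per-locus allele copy counts feeding the BAF model (signal truth)
    b_copies = np.zeros((n_m, len(individuals)), dtype=float)
    total_copies = np.full((n_m, len(individuals)), 2, dtype=np.int8)
    signal = clean.haplotypes != NULL_ALLELE
    b_copies[:] = ((clean.haplotypes == 1) & signal).sum(axis=2)
    total_copies[:] = signal.sum(axis=2)

    for marker in clean.null_markers:
        registry_rows.append(
            {"kind": "null_allele", "individual": "", "marker": marker, "detail": ""}
        )

    # --- triploids: unreduced maternal gamete (both homologs, tail-swapped
    # by crossovers so the per-locus allele multiset is preserved) ---------
    for s in take(config.n_triploids):
        j = i_index[s]
        mother = ped_true[s].mother
        mj = i_index[mother]
        extra = np.empty((n_m, 3), dtype=np.int8)
        for lg in gmap.linkage_groups:
            rows = np.array([m_index[m] for m in gmap.markers_on(lg)])
            cms = gmap.table.loc[rows, "cm"].to_numpy(dtype=float)
            h1 = clean.haplotypes[rows, mj, 0].copy()
            h2 = clean.haplotypes[rows, mj, 1].copy()
            n_xo = rng.poisson((cms[-1] - cms[0]) / 100.0)
            for pos in sorted(rng.uniform(cms[0], cms[-1], size=n_xo)):
                tail = cms >= pos
                h1[tail], h2[tail] = h2[tail].copy(), h1[tail].copy()
            extra[rows, 0], extra[rows, 1] = h1, h2
        extra[:, 2] = clean.haplotypes[:, j, 1]  # paternal gamete kept
        dosage = (extra == 1).sum(axis=1)
        tri_calls = np.where(dosage == 0, AA, np.where(dosage == 3, BB, AB)).astype(np.int8)
        calls[:, j] = tri_calls
        ploidy[j] = 3
        b_copies[:, j] = dosage
        total_copies[:, j] = 3
        registry_rows.append(
            {"kind": "triploid", "individual": s, "marker": "", "detail": f"mother={mother}"}
        )

    # --- segmental deletions: one haplotype lost over a window -----------
    for s in take(config.n_segmental_deletions):
        j = i_index[s]
        lg = str(rng.choice(gmap.linkage_groups))
        rows = np.array([m_index[m] for m in gmap.markers_on(lg)])
        cms = gmap.table.loc[rows, "cm"].to_numpy(dtype=float)
        start = float(rng.uniform(cms[0], max(cms[-1] - config.deletion_length_cm, cms[0])))
        window = (cms >= start) & (cms <= start + config.deletion_length_cm)
        seg = rows[window]
        kept = clean.haplotypes[seg, j, 0]
        calls[seg, j] = np.where(kept == 1, BB, AA).astype(np.int8)
        calls[seg, j][kept == NULL_ALLELE] = MISSING
        b_copies[seg, j] = (kept == 1).astype(float)
        total_copies[seg, j] = 1
        registry_rows.append(
            {
                "kind": "segmental_deletion",
                "individual": s,
                "marker": "",
                "detail": f"lg={lg},start={start:.2f},end={start + config.deletion_length_cm:.2f}",
            }
        )

    # --- bad-quality samples ---------------------------------------------
    for s in take(config.n_bad_quality):
        j = i_index[s]
        quality_sd[j] = config.baf_noise_sd_bad
        mis = rng.random(n_m) < config.bad_miscall_rate
        calls[mis, j] = _random_other_calls(calls[mis, j], rng)
        gone = rng.random(n_m) < config.bad_missing_rate
        calls[gone, j] = MISSING
        registry_rows.append(
            {"kind": "bad_quality", "individual": s, "marker": "", "detail": ""}
        )

    # --- wrong pedigree records (recorded pedigree only) ------------------
    wrong_candidates = [s for s in anomaly_pool if ped_true[s].mother is not None]
    for s in wrong_candidates[: config.n_wrong_parents]:
        anomaly_pool.remove(s)
        ind = ped_recorded[s]
        side = "mother" if rng.random() < 0.5 else "father"
        true_parent = getattr(ind, side)
        pool = [
            x
            for x in individuals
            if x not in (s, ind.mother, ind.father)
            and not ped_true.is_ancestor(s, x)
        ]
        fake = str(rng.choice(pool))
        setattr(ind, side, fake)
        registry_rows.append(
            {
                "kind": "wrong_parent",
                "individual": s,
                "marker": "",
                "detail": f"{side}:recorded={fake},true={true_parent}",
            }
        )
    if config.n_wrong_parents > len(wrong_candidates):
        raise ValueError("not enough individuals for wrong-parent records")

    # --- cluster shifts: systematic relabel of the AA class --------------
    n_shift = int(round(config.cluster_shift_fraction * n_m))
    shift_rows = (
        sorted(rng.choice(n_m, size=n_shift, replace=False)) if n_shift else []
    )
    for i in shift_rows:
        calls[i, calls[i] == AA] = AB
        registry_rows.append(
            {"kind": "cluster_shift", "individual": "", "marker": markers[i], "detail": "AA->AB"}
        )

    # --- random miscalls ---------------------------------------------------
    miscall_mask = (rng.random(calls.shape) < config.random_miscall_rate) & (
        calls != MISSING
    )
    ii, jj = np.nonzero(miscall_mask)
    calls[ii, jj] = _random_other_calls(calls[ii, jj], rng)
    for i, j in zip(ii, jj):
        registry_rows.append(
            {
                "kind": "random_miscall",
                "individual": individuals[j],
                "marker": markers[i],
                "detail": "",
            }
        )

    # --- duplicates: copied column with its own miscalls ------------------
    dup_columns: list[tuple[str, np.ndarray, int]] = []
    for _ in range(config.n_duplicate_pairs):
        src = take(1)[0]
        j = i_index[src]
        dup_id = f"{src}_dup"
        col = calls[:, j].copy()
        mis = (rng.random(n_m) < config.duplicate_miscall_rate) & (col != MISSING)
        col[mis] = _random_other_calls(col[mis], rng)
        dup_columns.append((dup_id, col, j))
        src_ind = ped_true[src]
        for ped_obj in (ped_true, ped_recorded):
            ped_obj.add(
                Individual(
                    dup_id,
                    mother=src_ind.mother,
                    father=src_ind.father,
                    selected=src_ind.selected,
                )
            )
        registry_rows.append(
            {"kind": "duplicate", "individual": dup_id, "marker": "", "detail": f"of={src}"}
        )

    # --- random missingness ------------------------------------------------
    gone = rng.random(calls.shape) < config.missing_rate
    calls[gone] = MISSING

    all_individuals = individuals + [d[0] for d in dup_columns]
    if dup_columns:
        calls = np.concatenate(
            [calls] + [c[:, None] for _, c, _ in dup_columns], axis=1
        )
        b_copies = np.concatenate(
            [b_copies] + [b_copies[:, [j]] for _, _, j in dup_columns], axis=1
        )
        total_copies = np.concatenate(
            [total_copies] + [total_copies[:, [j]] for _, _, j in dup_columns], axis=1
        )
        ploidy = np.concatenate([ploidy, [ploidy[j] for _, _, j in dup_columns]])
        quality_sd = np.concatenate(
            [quality_sd, [quality_sd[j] for _, _, j in dup_columns]]
        )

    baf = simulate_baf(b_copies, total_copies, quality_sd, rng)
    registry = pd.DataFrame(
        registry_rows, columns=["kind", "individual", "marker", "detail"]
    )
    registry.insert(0, "error_id", range(len(registry)))

    gm = GenotypeMatrix(markers, all_individuals, calls)
    truth = TruthLedger(
        pedigree=ped_true,
        haplotypes=clean.haplotypes,
        meioses=clean.meioses,
        registry=registry,
        clean_calls=clean.calls,
        b_copies=b_copies,
        total_copies=total_copies,
        individual_index={s: j for j, s in enumerate(all_individuals)},
        marker_index=m_index,
    )
    baf_frame = pd.DataFrame(baf, index=markers, columns=all_individuals)
    return SimulatedDataset(
        config=replace(config),
        gmap=gmap,
        pedigree=ped_recorded,
        gm=gm,
        baf=BafMatrix(baf_frame),
        truth=truth,
    )


def _random_other_calls(current: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform draw over the two wrong calls for each cell."""
    offset = rng.integers(1, 3, size=current.shape)
    return ((current + offset) % 3).astype(np.int8)


def simulate_baf(
    b_copies: np.ndarray,
    total_copies: np.ndarray,
    noise_sd: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """BAF = b_copies / total_copies + Gaussian noise, truncated to [0, 1]."""
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = b_copies / total_copies
    noise = rng.normal(0.0, 1.0, size=mean.shape) * noise_sd[None, :]
    return np.clip(mean + noise, 0.0, 1.0)
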