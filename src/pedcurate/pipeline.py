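"""End-to-end curation pipeline in the mandated stage order.

Stages: sample QC -> SNP filter -> duplicates -> parentage -> Mendelian-
inconsistent repair -> phasing/double-recombination triage -> haploblocks
-> classification.  The order matters: inheritance checks on wrong samples
or wrong pedigree records flood every later stage with false errors, and
single-SNP inconsistencies must be resolved before haploblock-level checks
can be meaningful.  Each stage function takes and returns a
:class:`PipelineState`, so the CLI can run stages one at a time or all at
once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dedup as dedup_mod
from . import mendel, parentage, phasing, sample_qc, snp_filter
from .classify import CurationLedger, PIPELINE_STAGES, RunManifest, classify_snps
from .datamodel import MISSING as MISSING_CALL
from .datamodel import (
    BafMatrix,
    GeneticMap,
    GenotypeMatrix,
    Pedigree,
    is_placeholder,
    normalize_pedigree,
)
from .haploblock import (
    HaploblockSet,
    HaplotypeMatrix,
    assign_haplotypes,
    define_borders,
    find_split_point,
    haplo_mendel_check,
    haplotype_snp_crosscheck,
    resolve_all_missing,
    screen_recombinant_haplotypes,
    split_block,
)


@dataclass
class PipelineConfig:
    seed: int = 0
    pc_n_random: int = 1000
    pc_percentiles: tuple[float, float] = (99.0, 1.0)
    min_known_pc: int = 20
    dedup_threshold: float = dedup_mod.DEFAULT_IDENTITY_THRESHOLD
    dedup_min_shared: int = dedup_mod.DEFAULT_MIN_SHARED
    dr_window_cm: float = phasing.DR_WINDOW_CM
    dr_min_individuals: int = 3
    null_min_duos: int = 3
    mendel_max_iter: int = 10
    max_phase_rounds: int = 3


@dataclass
class PipelineState:
    gm: GenotypeMatrix
    ped: Pedigree
    gmap: GeneticMap
    baf: BafMatrix | None = None
    config: PipelineConfig = field(default_factory=PipelineConfig)
    ledger: CurationLedger | None = None
    completed: list[str] = field(default_factory=list)
    qc_table: pd.DataFrame | None = None
    excluded_samples: list[str] = field(default_factory=list)
    snp_categories: pd.DataFrame | None = None
    duplicate_groups: list[list[str]] = field(default_factory=list)
    duplicate_decisions: list = field(default_factory=list)
    pc_calibration: parentage.PcCalibration | None = None
    ppc_threshold: int | None = None
    parentage_verdicts: pd.DataFrame | None = None
    rejected_parents: list[tuple[str, str]] = field(default_factory=list)
    recovered_parents: list[tuple[str, str, str]] = field(default_factory=list)
    mendel_report: mendel.ConsistencyReport | None = None
    n_imputed: int = 0
    hm: phasing.HomologMatrix | None = None
    origins: list = field(default_factory=list)
    events: list = field(default_factory=list)
    drs: list = field(default_factory=list)
    dr_worklist: pd.DataFrame | None = None
    coseg_conflicts: dict = field(default_factory=dict)
    phase_fix_edits: list = field(default_factory=list)
    blocks: HaploblockSet | None = None
    haplotypes: HaplotypeMatrix | None = None
    haplo_report: object | None = None
    crosscheck_flags: list = field(default_factory=list)
    classifications: pd.DataFrame | None = None
    manifest: RunManifest | None = None

    def require(self, *stages: str) -> None:
        for s in stages:
            if s not in self.completed:
                raise RuntimeError(
                    f"stage {s!r} must run first (completed: {self.completed})"
                )

    def _ledger(self) -> CurationLedger:
        if self.ledger is None:
            self.ledger = CurationLedger(list(self.gm.markers))
        return self.ledger


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_sample_qc(state: PipelineState) -> PipelineState:
    """Drop bad-quality and non-diploid samples before anything else."""
    ledger = state._ledger()
    n_in = state.gm.n_markers
    if state.baf is not None:
        state.qc_table = sample_qc.run_sample_qc(state.baf, state.gmap)
        state.excluded_samples = [
            s for s in sample_qc.excluded_samples(state.qc_table)
            if s in state.gm.individuals
        ]
        keep = [s for s in state.gm.individuals if s not in set(state.excluded_samples)]
        state.gm = state.gm.subset(individuals=keep)
    ledger.record_stage("sample_qc", n_in, n_in)
    state.completed.append("sample_qc")
    return state


def stage_snp_filter(state: PipelineState) -> PipelineState:
    """Keep robust and two-cluster markers that sit on the map."""
    state.require("sample_qc")
    ledger = state._ledger()
    n_in = state.gm.n_markers
    state.snp_categories = snp_filter.run_snp_filter(state.gm)
    for marker, row in state.snp_categories.iterrows():
        if row["category"] == "failed":
            ledger.drop(marker, "failed")
        elif row["category"] == "monomorphic":
            ledger.drop(marker, "monomorphic")
    for marker in state.gm.markers:
        if marker not in state.gmap:
            ledger.drop(marker, "unmapped")
    keep = [m for m in state.gm.markers if ledger.retained[m]]
    state.gm = state.gm.subset(markers=keep)
    ledger.record_stage("snp_filter", n_in, len(keep))
    state.completed.append("snp_filter")
    return state


def stage_dedup(state: PipelineState) -> PipelineState:
    """Group near-identical samples; keep one true-to-type copy."""
    state.require("snp_filter")
    cfg = state.config
    # the co-call floor must stay attainable on small marker panels
    min_shared = min(cfg.dedup_min_shared, max(50, state.gm.n_markers // 2))
    state.duplicate_groups = dedup_mod.find_duplicate_groups(
        state.gm, cfg.dedup_threshold, min_shared
    )
    state.duplicate_decisions = dedup_mod.resolve_duplicates(
        state.duplicate_groups, state.ped
    )
    drop: set[str] = set()
    for d in state.duplicate_decisions:
        drop.update(d.drop)
        drop.update(d.resample)
    keep = [s for s in state.gm.individuals if s not in drop]
    state.gm = state.gm.subset(individuals=keep)
    state._ledger().record_stage("dedup", state.gm.n_markers, state.gm.n_markers)
    state.completed.append("dedup")
    return state


def stage_parentage(state: PipelineState) -> PipelineState:
    """Calibrate thresholds, verify records, search for rejected parents."""
    state.require("dedup")
    cfg = state.config
    ledger = state._ledger()
    n_in = state.gm.n_markers
    rng = np.random.default_rng(cfg.seed)
    known_pairs = parentage.recorded_pc_pairs(state.ped, state.gm)
    state.pc_calibration = parentage.calibrate_pc_threshold(
        state.gm,
        known_pairs,
        n_random=cfg.pc_n_random,
        seed=rng,
        percentiles=cfg.pc_percentiles,
        min_known=cfg.min_known_pc,
    )
    pc_threshold = state.pc_calibration.threshold

    verdicts = parentage.verify_pedigree(state.gm, state.ped, pc_threshold)
    genotyped = set(state.gm.individuals)
    for v in verdicts:
        if v.verdict != "rejected":
            continue
        child, wrong_parent = v.child, v.counterpart[0]
        state.rejected_parents.append((child, wrong_parent))
        ind = state.ped[child]
        side = "mother" if v.relation == "PC_mother" else "father"
        setattr(ind, side, None)
        # parent search: earlier material only (never the child's descendants)
        candidates = [
            c
            for c in state.gm.individuals
            if c != child
            and c != wrong_parent
            and not state.ped.is_ancestor(child, c)
        ]
        ranked = parentage.search_parents(state.gm, child, candidates, pc_threshold)
        for cand in ranked["candidate"]:
            other = ind.father if side == "mother" else ind.mother
            if cand == other:
                continue
            setattr(ind, side, str(cand))
            try:
                state.ped.validate()
            except Exception:
                setattr(ind, side, None)
                continue
            state.recovered_parents.append((child, side, str(cand)))
            break

    # PPC pass over trios whose PC relations survived
    confirmed_trios = [
        ind.id
        for ind in state.ped
        if ind.mother in genotyped
        and ind.father in genotyped
        and ind.id in genotyped
        and parentage.pc_errors(
            state.gm.individual_calls(ind.id), state.gm.individual_calls(ind.mother)
        )
        < pc_threshold
        and parentage.pc_errors(
            state.gm.individual_calls(ind.id), state.gm.individual_calls(ind.father)
        )
        < pc_threshold
    ]
    if confirmed_trios:
        counts = [
            parentage.ppc_errors(
                state.gm.individual_calls(c),
                state.gm.individual_calls(state.ped[c].mother),
                state.gm.individual_calls(state.ped[c].father),
            )
            for c in confirmed_trios
        ]
        state.ppc_threshold = parentage.calibrate_ppc_threshold(counts)
    verdicts = parentage.verify_pedigree(
        state.gm, state.ped, pc_threshold, state.ppc_threshold
    )
    state.parentage_verdicts = parentage.verdicts_frame(verdicts)

    # null-allele scan now that duos are verified
    verified_duos = [
        (v.child, v.counterpart[0])
        for v in verdicts
        if v.relation.startswith("PC_") and v.verdict == "confirmed"
    ]
    suspects = snp_filter.detect_null_suspects(
        state.gm, verified_duos, cfg.null_min_duos, adaptive=True
    )
    for marker in suspects:
        ledger.drop(marker, "null_suspect")
    keep = [m for m in state.gm.markers if ledger.retained[m]]
    state.gm = state.gm.subset(markers=keep)

    state.ped = normalize_pedigree(state.ped)
    ledger.record_stage("parentage", n_in, len(keep))
    state.completed.append("parentage")
    return state


def stage_mendel(state: PipelineState) -> PipelineState:
    """Repair Mendelian-inconsistent calls and impute forced genotypes."""
    state.require("parentage")
    cfg = state.config
    state.mendel_report = mendel.repair_inconsistencies(
        state.gm, state.ped, max_iter=cfg.mendel_max_iter
    )
    imputed = mendel.impute_forced(state.ped, state.gm, apply=True)
    state.n_imputed = len(imputed)
    state._ledger().record_stage("mendel", state.gm.n_markers, state.gm.n_markers)
    state.completed.append("mendel")
    return state


def _phase_and_detect(state: PipelineState):
    state.hm = phasing.phase_pedigree(state.gm, state.ped, state.gmap)
    state.origins = phasing.infer_origins(state.hm, state.gm, state.ped, state.gmap)
    state.events = phasing.detect_recombinations(state.origins)
    state.drs = phasing.detect_double_recomb(state.origins, state.config.dr_window_cm)
    state.coseg_conflicts = phasing.cosegregation_conflicts(
        state.hm, state.gm, state.ped, state.gmap, state.origins
    )


def stage_phase_recomb(state: PipelineState) -> PipelineState:
    """Phase, triage double recombinations, fix calls, drop systematic
    offenders.

    Shared-region double recombinations are resolved first: markers whose
    artefacts recur across individuals and families are dropped as
    cluster-identification (shared genotype call) or map problems.
    Founder-phase artefacts are repaired by blanking the genuine
    recombinant's pivot call.  Remaining isolated singletons have their
    pivot call blanked -- the automated counterpart of adjusting a single
    wrong genotype call.
    """
    state.require("mendel")
    cfg = state.config
    ledger = state._ledger()
    n_in = state.gm.n_markers
    for round_no in range(cfg.max_phase_rounds):
        _phase_and_detect(state)
        state.dr_worklist = phasing.classify_dr_causes(
            state.drs,
            state.gm,
            state.ped,
            min_individuals=cfg.dr_min_individuals,
            extra_hits=state.coseg_conflicts,
        )
        changed = False
        systematic: set[str] = set()
        phase_suspects: set[str] = set()
        if state.dr_worklist is not None and not state.dr_worklist.empty:
            for row in state.dr_worklist.itertuples(index=False):
                if row.cause == "clustering":
                    ledger.drop(row.marker, "cluster_shift")
                    systematic.add(row.marker)
                    changed = True
                elif row.cause == "map":
                    ledger.drop(row.marker, "map_unresolved")
                    systematic.add(row.marker)
                    changed = True
                elif row.cause == "phase_suspect":
                    # a parent's phase artefact, not a marker problem:
                    # leave the calls alone and let re-phasing settle it
                    phase_suspects.add(row.marker)
        edits = phasing.resolve_phase_conflict(
            state.gm, state.ped, state.drs, state.events
        )
        if edits:
            state.phase_fix_edits.extend(edits)
            changed = True
        if round_no > 0 and not changed:
            break
        # isolated singletons and co-segregation conflicts: blank the
        # contradicted call
        skip_blank = systematic | phase_suspects
        blanked = phasing.blank_singletons(state.gm, state.drs, skip_blank)
        for marker, children in state.coseg_conflicts.items():
            if marker in skip_blank or marker not in state.gm._midx:
                continue
            for child in children:
                if state.gm.get(marker, child) != MISSING_CALL:
                    state.gm.set_call(marker, child, MISSING_CALL, "coseg_fix")
                    blanked.append((marker, child))
        keep = [m for m in state.gm.markers if ledger.retained[m]]
        if len(keep) < state.gm.n_markers:
            state.gm = state.gm.subset(markers=keep)
        if not (changed or blanked):
            break
    # edits may have freed or created forced genotypes; keep matrix consistent
    mendel.repair_inconsistencies(state.gm, state.ped, max_iter=cfg.mendel_max_iter)
    _phase_and_detect(state)
    state.dr_worklist = phasing.classify_dr_causes(
        state.drs,
        state.gm,
        state.ped,
        min_individuals=cfg.dr_min_individuals,
        extra_hits=state.coseg_conflicts,
    )
    ledger.record_stage("phase_recomb", n_in, state.gm.n_markers)
    state.completed.append("phase_recomb")
    return state


def stage_haploblock(state: PipelineState) -> PipelineState:
    """Blocks from selected-material recombinations; haplotype-level checks."""
    state.require("phase_recomb")
    ledger = state._ledger()
    n_in = state.gm.n_markers
    selected = {
        s for s in state.ped.selected_ids() if s in set(state.gm.individuals)
    }
    gmap_used = state.gmap.subset(state.gm.markers)
    state.blocks = define_borders(state.events, gmap_used, selected)
    state.haplotypes = assign_haplotypes(state.hm, state.blocks)
    resolve_all_missing(state.haplotypes, state.ped)
    # recombinant haplotypes: blank in seedlings, split blocks for selected
    for _ in range(50):
        blanked, split_candidates = screen_recombinant_haplotypes(
            state.haplotypes, state.ped, selected
        )
        did_split = False
        for block_id, ind, slot in split_candidates:
            at = find_split_point(state.haplotypes, block_id, ind, slot, state.ped)
            if at is not None:
                state.blocks = split_block(state.blocks, block_id, at, gmap_used)
                state.haplotypes = assign_haplotypes(state.hm, state.blocks)
                resolve_all_missing(state.haplotypes, state.ped)
                did_split = True
                break
        if did_split:
            continue
        # selected recombinants that no single crossover explains: treat
        # like seedlings and make the haplotype missing
        for block_id, ind, slot in split_candidates:
            bi = [b.id for b in state.blocks.blocks].index(block_id)
            j = state.haplotypes._iidx[ind]
            state.haplotypes.codes[bi, j, slot] = 0
            state.haplotypes.strings[bi, j, slot] = "-" * len(
                state.blocks.blocks[bi].markers
            )
        if not blanked and not split_candidates:
            break
    state.haplo_report = haplo_mendel_check(state.ped, state.haplotypes)
    state.crosscheck_flags = haplotype_snp_crosscheck(state.haplotypes, state.hm)
    ledger.record_stage("haploblock", n_in, state.gm.n_markers)
    state.completed.append("haploblock")
    return state


def stage_classify(state: PipelineState) -> PipelineState:
    """Assign SNP types 1-7 and assemble the run manifest."""
    state.require("haploblock")
    ledger = state._ledger()
    state.classifications = classify_snps(ledger, state.gm.edit_fraction_per_marker())
    ledger.record_stage("classify", state.gm.n_markers, state.gm.n_markers)
    state.completed.append("classify")
    state.manifest = RunManifest(
        stages_run=list(state.completed),
        seed=state.config.seed,
        config={
            "pc_threshold": (
                state.pc_calibration.threshold if state.pc_calibration else None
            ),
            "ppc_threshold": state.ppc_threshold,
            "dedup_threshold": state.config.dedup_threshold,
            "dr_window_cm": state.config.dr_window_cm,
        },
        stage_counts=ledger.stage_counts,
        n_individuals_final=state.gm.n_individuals,
        n_markers_final=state.gm.n_markers,
        notes={
            "excluded_samples": state.excluded_samples,
            "duplicate_groups": state.duplicate_groups,
            "rejected_parents": state.rejected_parents,
            "recovered_parents": state.recovered_parents,
            "n_imputed": state.n_imputed,
            "n_blocks": len(state.blocks) if state.blocks else 0,
        },
    )
    return state


_STAGE_FUNCS = {
    "sample_qc": stage_sample_qc,
    "snp_filter": stage_snp_filter,
    "dedup": stage_dedup,
    "parentage": stage_parentage,
    "mendel": stage_mendel,
    "phase_recomb": stage_phase_recomb,
    "haploblock": stage_haploblock,
    "classify": stage_classify,
}


def run_stage(state: PipelineState, stage: str) -> PipelineState:
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; order is {PIPELINE_STAGES}")
    return _STAGE_FUNCS[stage](state)


def run_pipeline(
    gm: GenotypeMatrix,
    ped: Pedigree,
    gmap: GeneticMap,
    baf: BafMatrix | None = None,
    config: PipelineConfig | None = None,
) -> PipelineState:
    """Run every stage in order on in-memory inputs."""
    state = PipelineState(
        gm=gm.copy(),
        ped=ped.copy(),
        gmap=gmap,
        baf=baf,
        config=config or PipelineConfig(),
    )
    for stage in PIPELINE_STAGES:
        state = run_stage(state, stage)
    return state
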