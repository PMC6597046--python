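# pedcurate

Curation of SNP-array genotypes for **pedigreed, clonally propagated
diploid crops** (apple, peach, sweet cherry and similar outbreeders).
Raw array calls for such germplasm contain sample-level problems
(poor-quality DNA, unnoticed triploids and aneuploids, duplicated or
mislabelled trees), marker-level problems (failed or mislabelled genotype
clusters, null alleles, wrong map positions) and record-level problems
(wrong parentage).  Left uncorrected, each of these floods downstream
pedigree-based analyses — QTL mapping, haplotype tracking, allele-origin
assignment — with false signals.

`pedcurate` implements the complete curation workflow as a library plus a
CLI, using only simple inheritance principles, applied in an order that
minimizes rework:

1. **Sample QC / ploidy** — per-sample B-allele frequency (BAF) screening.
   With ploidy *p* and *b* copies of the B allele the expected BAF is
   *b/p*, so diploids show modes {0, ½, 1}, triploids {0, ⅓, ⅔, 1},
   tetraploids {0, ¼, ½, ¾, 1}; the fraction of SNPs in the off-bands
   [0.125, 0.375] ∪ [0.625, 0.875] grades quality (<0.3 % good, 0.3–3 %
   intermediate, >3 % bad).
2. **SNP filtering** — retain markers with <5 % no-calls and sound
   genotype classes (three clusters, or two with the heterozygote);
   discard failed, monomorphic and null-allele-suspect markers.
3. **Duplicates** — identity-by-state fraction over co-called markers;
   pairs above 0.97 are clones/resampled trees, resolved by pedigree.
4. **Parentage** — parent–child (PC) errors are opposing homozygotes,
   parent-pair–child (PPC) errors are transmission-infeasible triplets
   (e.g. AA × AA → AB).  Rejection thresholds are calibrated from the
   separation between known-pair and random-pair error distributions;
   rejected parents are searched for among the genotyped material.
5. **Mendelian-inconsistent errors** — pedigree-wide genotype elimination
   (Lange–Goradia set propagation with an exact satisfiability check)
   finds conflicts even across ungenotyped intermediates, localizes the
   minimal conflicting calls, blanks them and imputes genotypes that the
   pedigree forces.
6. **Mendelian-consistent errors** — deterministic pedigree phasing, then
   double recombinations within 10 cM (and their single-marker special
   case, *singletons*) are triaged by cause: mislabelled genotype cluster,
   wrong map position, parent-phase artefact, or isolated call error.
7. **Haploblocks** — map segments with no recombination in selected
   material (cultivars, selections, parents) become multi-allelic loci;
   phased SNP strings are coded as integer haplotypes, checked again for
   Mendelian consistency, and blocks are split where a recombination in a
   selected line demands it.
8. **Classification** — every marker ends up typed 1–7 (clean, shifted
   cluster, extra clusters, null allele, unmappable, monomorphic, failed)
   with a full per-cell edit ledger and a run manifest.

A first-class **simulator** generates multi-generation outbred cohorts
(Haldane meioses on a genetic map, founder allele frequencies, BAF with
noise) and injects every error class above with a truth ledger, so the
whole pipeline is testable end to end without proprietary array data.

## Worked example

```python
from pedcurate import (PipelineConfig, SimulationConfig,
                       run_pipeline, simulate_dataset)

ds = simulate_dataset(SimulationConfig(seed=42))   # standard scenario
state = run_pipeline(ds.gm, ds.pedigree, ds.gmap, ds.baf,
                     PipelineConfig(seed=42))

print("excluded samples:", state.excluded_samples)
print("duplicate groups:", state.duplicate_groups)
print("PC rejection threshold:", state.pc_calibration.threshold)
print("rejected parent records:", state.rejected_parents)
print("recovered parents:", state.recovered_parents)
print("markers retained:", state.gm.n_markers)
print("haploblocks:", len(state.blocks))
print("type counts:", state.classifications["type"].value_counts().sort_index().to_dict())
```

prints

```
excluded samples: ['G2_02_5', 'G2_05_2', 'G2_07_4']
duplicate groups: [['G2_19_5', 'G2_19_5_dup']]
PC rejection threshold: 16
rejected parent records: [('G2_09_2', 'G2_06_5'), ('G2_17_2', 'G2_02_4')]
recovered parents: [('G2_09_2', 'mother', 'G1_03_3'), ('G2_17_2', 'mother', 'G1_08_3')]
markers retained: 940
haploblocks: 242
type counts: {1: 885, 2: 85, 4: 2, 5: 28}
```

The three excluded samples are exactly the simulated triploid and the two
bad-quality samples; the duplicate pair is grouped; both corrupted parent
records are rejected *and* replaced by the true parents (the generator's
ledger confirms `G1_03_3` and `G1_08_3`); 940 of 1000 markers survive,
with the 20 cluster-shifted markers among the type-2 calls; and the final
matrix contains zero Mendelian inconsistencies.

The same run from the shell:

```
pedcurate simulate --seed 42 --workdir run42
pedcurate run-all  --seed 42 --workdir run42
```

Stage commands (`pedcurate sample-qc`, `snp-filter`, `dedup`,
`parentage`, `mendel`, `phase-recomb`, `haploblock`, `classify`) run one
step each and refuse to run out of order, because the order is the point:
wrong samples and wrong pedigree records must go before marker-level
checks, and all single-SNP inconsistencies before haploblock-level ones.

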