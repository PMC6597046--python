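# Methods

This note documents the models, algorithms, defaults and deliberate design
choices behind `pedcurate`, and what the synthetic-data tests do and do not
demonstrate about real array data.

## Data model

Genotype calls are biallelic and codominant, stored as B-allele dosages
(0 = AA, 1 = AB, 2 = BB, −1 = missing). Allele labels are the array
convention {A, B}; nucleotide translation is out of scope. Every call edit
is appended to a per-cell ledger (marker, individual, original, new,
reason), so the final matrix is fully auditable and the per-marker edit
fraction drives the type classification.

Pedigrees are directed acyclic structures; after normalization every
individual has either both parents recorded or none. A single known parent
is completed with a placeholder (`M_<child>`, `F_<child>`, or `UP_<child>`
when the known parent's role is unspecified), one placeholder per child.
Sharing one dummy across children would force a common parental genotype on
unrelated offspring and manufacture downstream errors, so it is never done.
Placeholders carry no genotype; the Mendelian machinery treats them as
ungenotyped founders, which is exactly what makes cross-generation
inference work.

Genetic maps order markers per linkage group by (cM, bp, marker id); the
lexicographic tie-break makes phasing and border placement deterministic
for co-locating markers. Maps can be built from physical positions either
with a genome-wide factor (default 4 cM/Mb, appropriate for peach-sized
genomes) or by linear interpolation between flanking anchor SNPs carrying
both coordinates; extrapolation beyond terminal anchors uses the nearest
anchor pair's local slope and is reported, with an optional distance cap
because far extrapolation on a nonlinear recombination landscape is
unreliable.

## Sample QC from B-allele frequencies

For ploidy *p* and *b* B-allele copies the expected BAF is *b/p*. Quality
is the fraction of SNPs in the off-bands [0.125, 0.375] ∪ [0.625, 0.875]:
≤0.3 % good, ≤3 % intermediate, worse is bad (boundaries go to the less
severe class; the off-band interval pair is kept symmetric). Modes are
found on a fixed 0.02-wide histogram with a prominence floor of 1 % of the
observations, zero-padded so boundary modes at 0 and 1 register; the method
is deliberately deterministic rather than adaptive. More than three modes
signals polyploidy, and the mode set is matched against the triploid
{0, ⅓, ⅔, 1} and tetraploid-or-mixture {0, ¼, ½, ¾, 1} templates with a
0.05 tolerance.

Two interactions need care. First, a genuine polyploid always fails the
off-band quality grade (its heterozygous modes *are* in the off-bands), so
a clean template match takes precedence over the quality gate. Second, a
noisy bad-quality sample can chance-match a template; for bad samples the
match additionally requires ≥80 % of the BAF mass within 0.05 of the
template ("strict" mode), because real extra modes are sharp. When a map is
available a per-chromosome scan classifies each linkage group as
diploid-like, haploid-like or polyploid-like from where its heterozygous
BAFs sit; mixed patterns make the sample an aneuploid even when the pooled
histogram looks polyploid (one trisomic chromosome adds global modes).
Segmental aneuploids escape BAF screening entirely and are instead exposed
later by locally concentrated PC errors and double recombinations; a
half-overlapping 20 cM sliding window flags segments whose event count
exceeds five times the individual's genome-wide expectation (and an
absolute floor of 5, so sparse noise cannot trigger it).

## SNP filtering

Categories from post-QC call statistics: >50 % no-calls → failed; a single
observed genotype class → monomorphic; <5 % no-calls with all three
classes → robust; <5 % with heterozygotes but one homozygote class absent →
two-cluster (typically a rare allele; retained); the undefined 5–50 %
no-call band is failed conservatively, as is the inheritance-implausible
AA+BB-without-AB pattern. Null alleles are detected from verified
parent–child duos: a null makes A/null individuals score AA, so an
AA-scored parent can face a BB child. The spec-level operation uses a fixed
duo-count threshold (default 3); the pipeline uses a robust variant because
sporadic miscalls also create opposing-homozygote duos — the count is
discounted by the largest single-individual contribution (one miscalled
parent facing many offspring is not a null) and the threshold is lifted
five standard deviations above the mean background, so it scales with duo
number.

## Duplicates

Identity is the identity-by-state fraction over co-called markers
(requiring ≥500 co-calls by default; the pipeline caps the floor at half
the marker panel so small panels remain usable). The 0.97 grouping
threshold reflects how near-identical clones and resampled trees behave:
their disagreement rate is bounded by twice the per-sample error rate.
Groups are transitive closures, resolved by pedigree: identical records
keep the first member by id, divergent records keep the member whose
recorded parents verify, and two unselected seedlings of one family are
both flagged for resampling since neither can be shown true-to-type.

## Parentage

PC errors are opposing homozygotes — for biallelic codominant calls
exactly the "no shared allele" condition. PPC errors use the full
transmission-feasibility table over parental genotype pairs, which also
catches AA × AA → AB and AA × BB → AA, invisible to single-parent
comparison (the table is verified against brute-force enumeration of all
27 triplets, and PPC ≥ max of the two PC counts on all of them).

The rejection threshold is calibrated per data set: counts for all recorded
parent–child pairs versus 1000 random unrelated pairs; the threshold is the
rounded midpoint between the 99th percentile of the known distribution and
the 1st percentile of the random distribution (percentiles configurable),
with counts at or above it rejecting parentage. Percentile endpoints rather
than min/max keep the midpoint robust to a few corrupted records in the
"known" set — which is the normal situation, since calibration runs before
verification. Full sibs of a child can pass the PC test (they share both
parental genomes); the parent search flags known sibs instead of excluding
them, and candidates born after the child are excluded when birth-order
metadata exists. For ungenotyped parents with genotyped grandparents, the
grandparent test counts markers where the child's obligate allele from the
missing parent (determinable when the child is homozygous, or heterozygous
with a homozygous known parent) is absent from both candidate grandparents.
A caveat inherited from the biology: a triploid from an unreduced gamete
shares a full allele set not only with the transmitting parent but with
that parent's own parents, so grandparents also show zero PC errors and
only the PPC-style pair test identifies the true couple.

## Mendelian-inconsistency engine

Per marker, each individual starts with the genotype set compatible with
its call (all three if missing) and nuclear-family sweeps remove genotypes
no surviving parental pair can support, to a fixpoint (Lange–Goradia).
Propagation alone is incomplete on looped (inbred) pedigrees, so a nonempty
fixpoint is certified by a depth-first search for one globally consistent
assignment (ancestors-first order, so each assignment is checked against
its parents exactly once); with propagated sets the first branch almost
always succeeds, and the verdict becomes exact for arbitrary loops. The
suite checks verdict equality with exhaustive 3^n enumeration on 1000
random pedigrees of up to eight members.

Localization runs a family-local pass first: each locally inconsistent
nuclear family is resolved by leave-one-out among its own observed members
(independent errors almost always surface this way), and only conflicts
that materialize purely across generations fall back to global leave-one-out
over the affected families. The flagged minimal set is reported in full; a
compatibility mode attributes each set to its eldest member for comparison
with tools that report the parent. Repair blanks the flagged calls and
re-checks to a fixpoint; imputation fills missing calls whose surviving set
is a singleton, which by construction can never introduce a new
inconsistency.

## Phasing and double-recombination triage

Phasing is deterministic, in two stages. Trio logic fixes slots wherever
genotypes force them (homozygous child; heterozygous child with a
homozygous parent). Each parent's remaining heterozygous markers are then
oriented along the chromosome: every child votes from its own nearest
already-oriented informative marker (capped at 30 cM — a longer interval
is too likely to straddle a crossover), majority wins, ties stay unknown.
Markers where all informative children received the same allele are
excluded from anchoring: that unanimity is the signature of a parent
falsely scored heterozygous (a shifted cluster), and letting such a marker
anchor its neighbours corrupts the phase of a whole region. A polish pass
revisits non-anchored markers with votes from both sides, and a final
refinement treats orientation as an Ising chain and greedily flips the
prefix/suffix/interior segment that most reduces the total implied
crossover count — the failure mode it repairs (a flipped terminal segment)
is typical for founders with few informative offspring. Founders without
any anchor get the convention "first informative marker's A → homolog 1".
Remaining ambiguity is left unknown, never guessed.

Grandparental-origin switches between consecutive informative markers are
recombination events; switches before the first informative marker are
undetectable by construction. Two events of one meiosis with midpoint
separation under 10 cM form a double recombination (DR); a singleton is a
DR whose flipped segment contains exactly one marker. Cause triage keys on
singleton pivots only — a wide flipped segment smears over many markers and
implicates none — and counts distinct individuals (one miscalled child
shows the artefact in both its meioses). Markers hit in ≥3 individuals
across ≥2 families are systematic: a shared genotype call among the hit
individuals (≥70 %) indicates a mislabelled cluster, assorted calls a map
problem, and when (almost) all hit children share one parent the artefact
is that parent's phase, handled by re-phasing rather than by dropping the
marker. Two additional channels close gaps the event-level view cannot
see: (1) a multipoint co-segregation check predicts each child's genotype
from its flanking origins and the parents' phased alleles and flags
contradicted calls — this is what catches shifted markers whose few
trio-informative meioses would otherwise hide them; (2) a cohort-level
heterozygote-excess screen (het fraction ≥0.6 — above the outbred maximum
of 0.5 — with an essentially absent homozygote class, ≤2 %) catches
shifted markers that carry *no* inheritance signal at all, e.g. a
low-frequency marker scored ~97 % AB. The excess screen is suppressed for
cohorts under 50 individuals, where single-family segregation legitimately
produces extreme heterozygosity.

Isolated singletons and co-segregation conflicts have their pivot call
blanked — the automated counterpart of manually adjusting a single wrong
call. This deliberately sacrifices the rare genuine close double crossover
(under Haldane meiosis they occur at a few percent per meiosis per
chromosome) in exchange for a consistent matrix; the loss only affects
unselected seedlings' event lists, not haploblock borders, which are built
from selected material. Map moves are evaluated by full re-phasing and are
accepted only if the total DR count strictly decreases and no meiosis
gains a DR it did not have. The founder-phase conflict rule follows the
observed failure pattern of interval-minimizing phasers: when most sibs
show a singleton at one marker and one or two siblings have a genuine
single recombination with that marker as an endpoint, the recombinants'
pivot calls are blanked, which re-widens their recombination interval and
lets re-phasing settle the founder.

## Haploblocks and haplotypes

Borders are placed from recombination events whose child is selected
material, smallest interval first; an event whose interval already
contains a border is skipped (one border can explain several overlapping
events, a minimal cut set), otherwise a border goes at the interval's cM
midpoint snapped between the two flanking markers, ties toward the
lower-cM side. The result partitions each linkage group so no selected
event lies inside a block.

Phased allele strings per block are coded as small integers, assigned in
first-appearance order over individuals (deterministic dictionary);
strings with unknown positions stay uncoded pending resolution. An
incomplete haplotype is resolved by its matching parent when exactly one
parental haplotype agrees with the known positions; with several matches
the nearest resolved flanking blocks vote for the parental homolog that
minimizes recombination, and residual ambiguity stays missing. Unchanged
blocks can reuse a previous code dictionary, so re-blocking does not
invalidate published haplotype names.

Unselected seedlings legitimately carry novel within-block recombinant
haplotypes (borders only protect selected material); these are set to
missing rather than flagged as errors. A novel haplotype in a *selected*
individual signals a recombination that should have split the block
(e.g. in an ungenotyped progenitor): the crossover is located by
prefix/suffix matching against the parental haplotypes and the block is
split there; unexplainable cases are blanked. The Mendelian check then
generalizes genotype elimination to k alleles: family-level transmission
violations are reported per child, family-clean blocks run through
cross-generation set elimination with leave-one-out localization.
Individuals whose candidate pair-space would exceed 8 alleles are treated
as unconstrained wildcards — sets stay small and the verdict stays sound,
at the price of weaker propagation through very poorly resolved
individuals. Haplotype codes decode back to phased SNP alleles; a
cross-check flags any block whose codes contradict the underlying phased
calls.

## Classification and reporting

Types follow precedence 7 (failed/unresolvable) > 6 (monomorphic) > 5
(unmappable) > 4 (null allele) > 3 (extra clusters) > 2 (shifted cluster)
> 1 (clean, <5 % of calls edited). Retention is recorded separately from
type: the type describes the cluster phenomenon, the retained flag the
decision (null-allele markers, for instance, may be retained or dropped
depending on curation effort). Heavy editing without marker-level evidence
is typed 2, treating it as an unrecognized cluster-identification problem.
The run manifest records stage order, per-stage retained/discarded counts
(which telescope to the final marker count), thresholds and seeds.

## The simulator: what it emulates, and what it does not

The generator emulates the study design the workflow targets: unrelated
founders with B-allele frequencies uniform on (0.1, 0.5) — intermediate
frequencies guarantee informative markers; later generations from sampled
parent pairs with reuse (half-sib structure as in breeding germplasm);
evenly spaced markers (default 5 linkage groups × 200 markers × 100 cM);
Haldane meioses (Poisson crossover counts, uniform positions, no
interference — interference would only reduce the true close-DR
background). The default scenario, used throughout the tests, is 40
founders plus generations of 60 and 100 (200 individuals), 1 % random
miscalls, 2 % cluster-shifted markers (systematic AA→AB relabel), 2 wrong
parent records, 1 duplicate pair (copied column with independent 1 %
miscalls), 1 triploid and 2 bad-quality samples (10 % missingness, 5 %
miscalls, BAF noise sd 0.12 versus 0.02 for good samples). The triploid's
unreduced gamete is modelled as the parent's two homologs with tail-swap
crossovers, which preserves the per-locus allele multiset and therefore
reproduces the triploid-grandparent parentage caveat exactly. Every
injected error is registered with its locus, so recovery is scored
against truth.

What passing these tests does **not** show about real data: cluster
geometry is not modelled (calls are corrupted at the call level, not via
intensity-space clustering, so the two-dimensional phenomena a human sees
in cluster plots are only mimicked); linkage maps are error-free unless a
test perturbs them; founder phase in very small families (one or two
offspring) is fundamentally unidentifiable and real data will show the
same arbitrariness; and genotyping platforms with non-systematic locus
coverage (genotyping-by-sequencing) violate the low-missingness assumption
throughout.

## Numerical and scale choices

All randomness flows through explicit seeds; reruns are byte-identical.
Deterministic tie-breaks: map order (cM, bp, id); haplotype codes by first
appearance; border snapping toward lower cM; orientation ties left
unknown. Degenerate inputs (empty matrices, zero-length linkage groups,
single-anchor groups, markers with zero genotyped individuals) are handled
explicitly rather than by exception. The test suite runs the full default
scenario once (about 20 s on one core) and shares it across acceptance
checks; the elimination oracle uses 1000 random pedigrees of ≤8 members,
small enough for exhaustive enumeration; phasing/haploblock unit tests use
a 2 × 120-marker cohort. These sizes were chosen so the complete suite
exercises every stage at meaningful depth while staying fast enough to run
on every change.

## Known limitations

- Cause triage thresholds (3 individuals, 2 families, 70 % shared calls)
  are heuristics tuned to outbred cohorts of a few hundred individuals;
  very small cohorts should rely on the per-operation functions and manual
  review.
- The map-move evaluator tests candidate positions it is given; it does
  not search the genome for the best position of a misplaced marker.
- Haplotype-level elimination loses propagation power through individuals
  whose haplotypes are almost entirely unresolved (the wildcard cap).
- A small number of phase-artefact double recombinations survive in
  founders with few informative offspring; they are reported, not
  silently removed, and mirror the behaviour of interval-minimizing
  phasers on the same structures.
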