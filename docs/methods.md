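# Methods

This note documents the models and procedures implemented in `hlaseq`, the
parameters that matter, the numerical choices, and what the synthetic-data
tests do and do not demonstrate.

## Allele library and exon reconstruction

An allele is stored as an ordered map from exon index to nucleotide sequence
plus a documentation-status flag (`confirmed_common_well_documented` or
`other`). The per-locus exon template is the union of exon indices observed
across the locus's records. Peptide-binding exons (2–3 for Class I, 2 for
Class II) must be present on every record; anything else may be missing.

Missing exons are filled from a donor: among same-locus alleles whose
*original* (database-provided) exons include the needed one, the donor with
the highest sequence identity over the exons originally present in both
alleles is chosen. Identity is defined as `1 − d / max(|a|, |b|)` where `d`
is the global (Needleman–Wunsch) edit distance under unit costs — a single,
well-defined value, computed with `edlib`. Identity is computed over the
concatenation of shared exons rather than exon-by-exon: it uses all shared
evidence and is deterministic. Ties go first to well-documented donors, then
to the lexicographically smallest allele name. Donor sequences are always
taken from the input library, never from previously reconstructed exons, so
reconstruction is idempotent and never alters an original exon.

## Read compatibility

A read pair is compatible with a transcript when each mate aligns ungapped,
full length, on either strand, with at most `max_mismatches` substitutions,
and both mates hit the same transcript. Transcripts are exon concatenations,
so junction-spanning reads need no special handling. Gapped alignment and
base-quality weighting are deliberately out of scope: genotyping needs only
incidence, and the substitution-only model keeps an exhaustive oracle
feasible.

`max_mismatches` defaults to `max(2, ⌈0.02·L⌉)` per mate (2 for 50 bp
reads). The budget is sized to sequencing error — at a 0.5% per-base error
rate the probability of a 50 bp mate exceeding two substitutions is about
2·10⁻³ — and deliberately kept *below* typical inter-allele divergence.
This bound matters: a budget at or above the divergence between alleles of a
locus makes reads from one allele compatible with its relatives, wrong
selections tie with the true genotype, and typing degenerates into
tie-breaking. The parameter is exposed everywhere it is consumed.

Matrix construction uses an exact k-mer seed prefilter with
`k = ⌊L / (max_mismatches + 1)⌋` (capped at 31). By pigeonhole, any
qualifying match contains an exact run of at least that length, so the
prefilter provably never discards a pair the full scan would accept; tests
compare the prefiltered matrix against a scan with the prefilter disabled.
Pairs with identical compatibility rows are collapsed into one weighted row,
which leaves the genotyping objective unchanged.

## Genotyping ILP

All requested loci are solved jointly in one model over binary allele
selectors `y_a` and read-coverage variables `x_r` (continuous in [0, 1];
integrality is unnecessary because the objective pushes them to their
bounds):

- per locus: `1 ≤ Σ y_a ≤ 2`;
- per read pattern: `x_r ≤ Σ_{a compatible} y_a`;
- objective: maximize `Σ w_r x_r − λ Σ y_a`.

Reads compatible with alleles of several loci are counted once, globally.
`λ` (default 1.0 read-equivalent per selected allele) decides zygosity by
parsimony: a second allele must explain at least `λ` new reads to be called,
otherwise the locus is homozygous. A locus whose alleles have zero
compatible reads is reported as a no-call rather than an error. The model is
solved with HiGHS via `scipy.optimize.milp`.

Ties between equal-objective optima are broken deterministically toward the
lexicographically smallest sorted allele-name selection. At small scale
(up to 10⁵ per-locus selection combinations) alternate optima are enumerated
exhaustively and the smallest selected; beyond that a name-rank epsilon is
folded into the objective, scaled as `0.25 / (1 + Σ ranks)` so the total
perturbation stays below a quarter read-equivalent. `brute_force_genotype`
implements the identical objective and tie-break by exhaustive enumeration
and serves as the independent oracle.

Accuracy against truth is scored per sample and locus by maximum bipartite
matching between the two predicted and two truth alleles, with an edge when
the two names fall in the same G group (or share a field prefix when no
G-group table is supplied). Missing predictions score 0 of 2. The G-group
table follows the standard dialect: `locus*;members;groupG` lines; alleles
absent from the table collapse to their three-field truncation, which mirrors
singleton-group semantics and keeps the metric total.

## Expression quantification

The personalized transcriptome removes the reference's HLA transcript ids
and adds one sequence per distinct typed allele, mapped to its locus as gene
id. A homozygous genotype contributes one sequence recorded at copy number
2 — two identical sequences would make the mixture non-identifiable; tests
document that quantifying duplicated identical sequences and summing gives
the same locus-level TPM.

Abundance is the standard generative EM over the compatibility structure:
the E-step distributes each read pair among its compatible transcripts
proportionally to `θ_t / ℓ̃_t`, the M-step renormalizes. Effective length is
`ℓ̃ = max(1, ℓ − μ_frag + 1)` with mean fragment length μ_frag = 200 bp by
default. Convergence is `max |Δθ| < 1e-8` or 1000 iterations; the data
log-likelihood is recorded every iteration and asserted non-decreasing in
tests. TPM is `(c_t/ℓ̃_t) / Σ_u (c_u/ℓ̃_u) × 10⁶` and sums to 10⁶ whenever at
least one read is assigned. Reads compatible with nothing are dropped and
counted. No GC/positional bias correction or bootstrap variance is
implemented.

## Cohort statistics

Tumor–normal matching keys are the six classical Class I alleles (two per
locus, sorted) truncated to three fields — identity at the coding-nucleotide
level. Matching is one-to-one on identical keys; a key carried by two or
more tumors or normals identifies nobody and all its carriers are flagged
ambiguous.

Differential expression uses the equal-variance two-sample Student's t-test
(paired variant available) on `log2(TPM + 1)`; the log transform stabilizes
variance, and the pseudocount keeps zero expression finite. P-values are
Bonferroni-adjusted across the tested genes. Two flags are reported:
`significant_raw` (p < α, default α = 0.05) and `significant_strict`
(adjusted p < α *and* |mean log2 fold change| ≥ threshold). The fold-change
threshold defaults to 0.585 log2 units (1.5-fold), a conventional cutoff;
with the default threshold at 1.0 (2-fold) an effect of exactly one log2
unit would sit on the boundary and pass the filter only about half the time,
which makes the filter useless precisely at the effect sizes it is meant to
keep. Zero-variance genes with equal group means are reported with t = 0,
p = 1 and a `degenerate` flag; zero variance with unequal means yields
p = 0. Immune-cell fraction tables (values validated to [0, 1]) are compared
with the same machinery on the raw fractions, Bonferroni-corrected across
cell types.

## Synthetic data: what it emulates and what it does not

The generator fabricates, per locus, an ancestral transcript cut into a
Class-I-like template (8 exons, ≈1.1 kb) or Class-II-like template (6 exons,
≈0.8 kb), and derives alleles by substituting each base at half the target
pairwise divergence, resampling the rare zero-substitution draws so alleles
are distinct. The first two alleles of each locus share their
peptide-binding exons (with at least one substitution elsewhere), creating a
true multi-allele G group. Defaults emulate the intended study conditions:
2×50 bp paired-end reads, 30× coverage per allele, 0.5% substitution error,
2% pairwise divergence, Normal(200, 30) fragment lengths. Reads carry
substitution errors only — no indels, no quality-dependent error profile, no
positional bias, no intron retention — consistent with the ungapped
compatibility model. Matched cohorts are generated on the log2 scale (gene
baseline + Normal noise, planted effects added to tumors) and returned as
`2^x − 1` TPM so the tested fold change equals the planted effect exactly.

Passing the synthetic suite therefore shows that the algorithms are correct
under their own generative assumptions: the ILP finds provably optimal
selections, reconstruction restores near-identical sequences when a close
donor exists, EM recovers planted abundance ratios, and the cohort test has
the advertised power and type-I behavior. It does not demonstrate robustness
to real-data phenomena the generator omits: indels, intronic or intergenic
contamination, pseudogene cross-mapping, PCR and coverage bias, or allele
divergence patterns of the real HLA loci.

## Problem sizes used in the checks

The acceptance script and end-to-end tests run at deliberately desk-sized
scales chosen once: 100 random solver instances (≤3 loci, ≤8 alleles/locus,
≤200 weighted reads); 20 simulated individuals on a 3-locus × 20-allele
library at 30×; reconstruction on 30 alleles at 0.5% divergence (so that
≥99%-identical donors exist); abundance recovery at 1000× depth on a
two-allele mixture, where the ratio estimator's sampling standard deviation
is ≈0.05 — at the 2% divergence conditions only reads overlapping several of
the ~23 distinguishing sites discriminate the alleles, so the informative
read count is a small fraction of the total; and 100 cohort replicates per
arm (planted and null).

## Known limitations

- Novel alleles are not discovered: every call is a library member.
- Single-end and long-read data are unsupported; extraction requires
  paired-end alignments.
- No confidence scores or posterior probabilities accompany genotype calls.
- The quantifier implements plain EM without bias correction; absolute TPMs
  inherit its assumptions.
- Immune-cell deconvolution is consumed as an external table, never
  computed.
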