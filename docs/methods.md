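# Methods

This note records the models implemented in `mutspect`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real data.

## Mutation classes and spectrum matrices

A polarized biallelic SNP is classified by (ancestral base, 5' flank,
3' flank, derived base). Merging each class with its reverse complement —
so the ancestral base is always a pyrimidine — leaves 96 canonical classes
(6 substitution types × 16 flank pairs). Labels follow the `ACG>T`
convention: ancestral trinucleotide, then the derived middle base. Contexts
are read 5'→3' on the reference strand; since the partition is closed under
reverse complement, the strand-reading convention does not affect it.

Counting rules for the per-sample count matrix `C` (96 × n):

- the derived-allele-count stratum (f1 singletons, f2 doubletons, …) is
  computed jointly over **all** samples, ignoring population labels;
- a homozygous-derived genotype contributes 2 counts, a heterozygote 1;
- records are skipped when the ancestral-allele (`AA`) annotation is not a
  confident uppercase base, when it matches neither allele (triallelic
  history), or when the position has no two-sided flanking context;
- sites where every chromosome carries the derived allele are not
  segregating and are never counted.

Intensities `X` are `C` divided per sample by either the ATA>C count (the
most abundant class; that row becomes identically 1) or the per-sample
total (columns sum to 1). Ratios of intensities within a sample are
identical under both normalizations, which is the property the downstream
statistics rely on.

`group_z` compares per-individual signature proportions between two sample
sets with an unpooled (Welch) variance. The construction behind the
published Z values is not documented anywhere we could follow, so the
Welch form is this package's own choice; with equal group variances it
coincides with the pooled form.

## NMF signature extraction

`X ≈ W H` with `W ≥ 0` (96 × k signature weights) and `H ≥ 0` (k × n
loadings), fitted by the multiplicative updates for the Euclidean objective
‖X − WH‖²_F, which is non-increasing under the updates. Defaults:
`tol = 1e-6` relative objective change, `max_iter = 2000`. The W/H scale
split is a gauge; we fix it by normalizing each signature to sum 1 and
order factors by descending total loading so results are deterministic.

Initialization is random or from fastICA: each independent component's
sign is set so its entries sum positive, negative entries are zeroed, and
1e-9 is added so the multiplicative updates cannot absorb exact zeros. We
use the `exp` contrast with tolerance 1e-3 because the default log-cosh
contrast frequently oscillates without converging on sparse, gamma-like
signature data; if ICA still fails to converge the fit falls back to a
random start (logged). Consistent with the behavior reported for this
analysis, random starts reach a marginally closer fit than ICA starts;
ICA's value is cleaner factor structure, not lower residual. Random
initialization tends to spread the ubiquitous CpG mutations across every
factor; `subtract_cpg_floor` removes, for each NCG-context class, the
across-signature minimum weight (idempotent, non-CpG rows untouched).

Rank selection is reported, never automated: for each rank we rerun from
`n_starts` random starts (default 50, more available) and report the
consensus-matrix dispersion `mean(4(C_ij − ½)²)`, the best residual sum of
squares, and the silhouette of dominant-factor sample assignments under the
distance 1 − Pearson correlation of loading profiles. One extra start per
rank is warm-started from the previous rank's best factors (augmented with
a near-zero component), which makes best-of-starts RSS provably
non-increasing in rank rather than only stochastically so.

For plotting and catalog comparison, class weights can be rescaled by the
reference trinucleotide frequency of their context; the resulting scale is
not interpretable in absolute terms. Catalog matching reports Pearson
correlations against each catalog column, sorted descending. The PCA
alternative scales each class row to unit variance (constant rows dropped,
logged) before projecting samples.

## Genomic strata

Transcriptional strand: each position is labeled `+`, `-`, `both` or
`none` by the union of transcript intervals; `both`/`none` positions are
excluded from bias counting. Mutations are *not* collapsed with their
reverse complements here: a pyrimidine-class mutation whose C/T sits on
the + strand of a −-transcribed region lies on the untranscribed (coding)
strand. The per-sample statistic is log(untranscribed/transcribed), natural
log by default (configurable); when either count is zero, 0.5 is added to
both (Haldane correction, logged).

Methylation: the rate ratio (mutations at high-methylation sites / number
of high sites) ÷ (same for low sites) — a rate, not a raw-count, ratio,
since the site lists differ in size. A zero low-site rate is reported as an
infinite ratio with a flag rather than an error.

Decile tracks (background-selection B statistic, recombination rate in 1kb
bins): counts per decile per sample group, with the per-cell proportion of
a chosen class set; empty cells report proportion 0 rather than being
dropped. Fisher's exact test is the two-sided sum of hypergeometric point
probabilities (scipy's implementation, validated in tests against direct
enumeration). Summary tests on strand log-ratios use plain one-way ANOVA
and a Welch t-test.

## Coalescent simulation of repeat mutations

Standard-coalescent genealogies (pairwise coalescence rate 1 per coalescent
unit = 2·Ne generations), mutations as a Poisson process with rate θ/2 per
branch per unit length. θ defaults to 2; all reported spectra are
shape-only, so θ affects only Monte-Carlo resolution.

Exponential growth (N-fold starting at time s looking back, rate
g = log(N)/s) is applied by rescaling node times

    t' = (1/g)(e^{gt} − 1)            t ≤ s
    t' = (1/g)(e^{gs} − 1) + (t − s)  t > s

which is continuous, strictly increasing, and the identity as N → 1.
Recent branches stretch, genealogies become star-like, and singletons
inflate. The default growth condition is N = 100, s = 0.01 (≈ 9,000 years
for Ne = 15,000 and 30-year generations).

A repeat (recurrent) mutation is two independent, length-weighted mutation
placements on the same genealogy whose carrier sets are OR-ed; the union
size is the apparent allele count. This captures nested and non-nested
event pairs with the correct probabilities. Unions covering every leaf are
fixed, not segregating, and are excluded from spectra but tallied. The
absolute rate of repeat events is not modeled inside the spectra — single
and repeat spectra are normalized separately, and their mixture weights
enter only through the CpG model below.

The CpG-proportion model mixes the normalized single spectrum S and repeat
spectrum R assuming a fraction `frac_cpg` (default 0.15) of mutations are
CpGs of which `frac_repeat` (default 0.10) are repeat events:

    P_i = frac_cpg((1−frac_repeat) S_i + frac_repeat R_i)
          / [frac_cpg((1−frac_repeat) S_i + frac_repeat R_i) + (1−frac_cpg) S_i]

Two exact identities pin the algebra down: R ≡ S (or frac_repeat = 0)
gives P_i = frac_cpg everywhere, and a vanishing repeat spectrum (R ≡ 0)
gives the constant frac_cpg(1−frac_repeat)/(frac_cpg(1−frac_repeat) +
1−frac_cpg) = 0.135/0.985 at the defaults. Under growth, P_2 > P_1: the
doubleton CpG excess without a singleton excess that a pure mutation-rate
difference cannot produce.

Calibration targets used by the tests (all analytic): E[T_2] = 1;
E[total length] = 2·Σ_{i<n} 1/i; single-mutation SFS ∝ 1/i, hence singleton
fraction 1/H_{n−1} (≈ 0.2233 at n = 50). Pooled bin counts across trees
are not multinomial (branches within a tree are correlated), so agreement
is asserted with per-bin z-scores whose standard errors come from the
per-tree spread (ratio-estimator form), not with a naive chi-square.

## Damage-robust statistic for ancient samples

Ancient DNA deamination inflates every C>T class, so signature-1 intensity
cannot be compared naively between ancient and modern samples. The
corrected log-ratio

    M = log2[(X_TCC·X_ACC·X_TCT·X_CCC)/(X_TCA·X_ACA·X_TCA·X_CCA)]

uses only C>T classes, pairing each signature context (NC{C,T}) with a
control context (NCA); TCA>T appears twice to balance the four-vs-four
pairing. A uniform multiplicative inflation of all C>T counts therefore
cancels exactly (both products contain four C>T terms), as does any
per-sample normalization. M is reported normalized so a designated
reference panel (the African samples) has mean 0 and sd 1 (sample sd,
ddof = 1). If any of the eight classes has zero count, 0.5 is added to all
eight before forming intensities (logged).

Bootstrap uncertainty resamples the 96 class counts multinomially with the
observed total (Poisson-per-class available), recomputes M per replicate,
and reports the empirical 5% and 95% quantiles. Ancient samples are scored
on heterozygous sites restricted to positions that are singletons (one
heterozygote) in the modern panel.

## Rate arithmetic

With M total mutations of which N = pM are in a signature, increasing only
the signature count by ΔN gives the new proportion q = (N+ΔN)/(M+ΔN) and a
relative total-rate increase ΔN/M = (q−p)/(1−q) — strictly increasing in
q, decreasing in p. The repeat-mutation share implied by excess
cross-population sharing is share_sig − share_all by default (the `solve`
variant (share_sig−share_all)/(1−share_all) models repeat doubletons as
always cross-split). Coalescent units convert to years as s·2Ne·g_years.

## Synthetic data: what it emulates, and what it does not

The generator fabricates a reference chromosome (i.i.d. bases, or a
first-order Markov chain in which the C→G transition weight is multiplied
by `cpg_boost`), a multi-population diploid panel, annotation tracks, and
sample metadata with planted, recorded ground truth.

Each variant is attributed to a generating population (probability
proportional to sample count); its class is drawn with probability
proportional to (admissible context sites in the reference) × (the
population's class multiplier), and it is placed at an unused admissible
site, so reference context and class always agree. Carriers:

- `fixed_f` (default f = 2, the doubleton regime): one homozygote with
  probability `hom_prob` (default 0.1), otherwise two heterozygotes in the
  generating population — exercising the 2-vs-1 counting rule. A per-class
  cross-population fraction can place the second heterozygote in another
  population, emulating cross-population repeat mutations.
- `coalescent`: allele counts drawn from a simulated site frequency
  spectrum (constant size or a growth model) and spread uniformly over all
  haplotypes.

A configurable fraction of records carries a lowercase (low-confidence)
ancestral annotation to exercise the filtering rule. The default panel
used in examples and acceptance runs is two populations of 15 samples with
1.5× multipliers on the four signature-1 classes — chosen to be comfortably
detectable at desk scale while the study-scale effect (≈ 1.3× between the
extreme regional means) remains of the same order.

Deliberately absent: linkage disequilibrium, phasing, sequencing error,
base-quality structure, and any cell-line artifact beyond a metadata
label. Passing recovery tests therefore demonstrates the correctness of
the estimators under the stated sampling model — not robustness to the
correlated noise of real resequencing data. The `synthetic_catalog`
function generates a clearly-labelled synthetic signature catalog for
exercising catalog comparison; it is not derived from any real somatic
catalog.

## Problem sizes used by tests and acceptance runs

Calibration runs use 1e5 trees at n = 50 (constant size) and 2e4 trees for
growth comparisons; NMF recovery uses a planted 96×100 rank-3 matrix with
5% multiplicative noise; the end-to-end run uses a 400 kb reference,
2 × 15 samples and 40,000 doubletons. These sizes put every Monte-Carlo
standard error well below the planted effects being recovered.

## Known limitations

- The coalescent simulator is single-locus (no recombination or
  migration) by design; sequence-level placement is the synthetic
  generator's job.
- `rank_diagnostics` silhouette is undefined (NaN) when every sample is
  assigned to one factor.
- The repeat-mutation model draws both events on the same genealogy;
  mutation pairs spanning genealogy changes at recombination breakpoints
  are out of scope.
- Bootstrap quantiles for very sparse count vectors depend on the
  pseudocount policy; the number of affected replicates is logged.
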