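# Methods

## Model and procedure

The pipeline compares the co-expression structure of a fixed gene panel
between two sample groups, tumor (N_T samples) and normal (N_N samples),
from one study.

**Per-condition networks.** For every pair of genes the Spearman rank
correlation r_ij and a two-sided p-value are computed; p-values come from
the t-approximation on the rank correlation, t = r·√((n−2)/(1−r²)) with
n−2 degrees of freedom. Exact enumeration is not attempted: the
approximation is standard for n ≳ 10 and all supported cohorts are far
larger (the minimum enforced is n ≥ 4 per condition, the smallest n for
which the downstream Fisher variance 1/(n−3) exists). P-values are
Bonferroni-corrected with family size m(m−1)/2 — the tested pairs of one
condition of one study, the conservative literal reading — and the
thresholded matrix C keeps r_ij where the adjusted p-value is strictly
below τ.

**The change test.** Var(r) ∝ (1−ρ²)² makes raw correlation differences
incomparable across the correlation scale, so both coefficients are Fisher
transformed (z = atanh r, sampling variance ≈ 1/(N−3) independent of ρ for
bivariate-normal data) and compared with the Z statistic
Δz = (z_T − z_N)/√(1/(N_T−3) + 1/(N_N−3)), two-sided because both gains
and losses of co-expression are of interest. After a second Bonferroni
correction over the same family, the differential matrix D stores
Δr = r_T − r_N for pairs passing a two-part gate: the change is
significant (p̂^z < τ) *and* the pair was significantly correlated in at
least one condition (p̂^T < τ or p̂^N < τ). The gate prevents calling
"differential co-expression" on pairs that were never credibly
co-expressed in either group. All threshold comparisons are strict.

**Caveat — Spearman in a Pearson-derived test.** The 1/(N−3) variance is
exact for Pearson correlations of bivariate-normal data; for Fisher-
transformed *Spearman* coefficients the asymptotic variance is ≈
1.06/(N−3), so applying the test to rank correlations is mildly
anticonservative (nominal α = 0.01 behaves like ≈ 0.013). The calibration
checks in the test-suite and acceptance script therefore exercise the test
in the setting where its null distribution is exact (sample correlations of
bivariate-normal draws); the pipeline accepts the slight anticonservatism
on ranks as the method's own property, buffered in practice by the
Bonferroni correction's conservatism.

**Permutation null.** As an assumption-free complement, condition labels
are shuffled over the pooled samples (group sizes preserved), both Spearman
matrices and hence Δr and Δz are recomputed per permutation, and a pair is
flagged when its real |Δr| *and* |Δz| strictly exceed the corresponding
maxima over all permutations. Under exchangeability each pair exceeds with
probability ≤ 1/(n_perm+1); a simulation test verifies this. Whether
exceedance should use raw or adjusted statistics is not meaningful here —
the criterion compares raw magnitudes against their own permutation
distribution, implemented literally as "larger than in every permuted
dataset".

**Scores.** S⁰_i counts the nonzero entries of row i of D. S_i sums
−ln p̂^z over exactly those gated pairs — not over all pairs with
p̂^z < τ — because the gate is what defines a differentially co-expressed
pair, and the score tables pair S with S⁰. The natural logarithm is used
without Fisher's conventional factor 2, and Bonferroni-adjusted p-values
feed the sum (adjusted p̂ is used throughout the method; p-values of
exactly 0 are floored at the smallest positive double before the log, with
a warning). S^Cat/S^Comp count a gene's gated partners that are also known
catalysis-precedes / in-complex-with interaction partners; the tumor-gain
count uses |r_T| > |r_N| among gated pairs. Pathway scores sum member S⁰
and divide by pathway size; pathways with fewer than five member genes
(after intersection with the panel) are excluded. Hub thresholds (mean +
k·SD of S⁰) include zero-count genes in mean and SD — the inclusive
reading of "the study mean".

**DE versus DC.** A dedicated differential-expression fit is out of scope;
the built-in effect size is log₂((mean_T + c)/(mean_N + c)) with
pseudocount c = 1, and `de_dc_comparison` accepts an externally computed
log2-ratio column so a proper DE fit can be substituted. DC-not-DE genes
are those with S⁰ more than `sd_mult` SDs above the study mean but
|log₂ ratio| below `fc_cut`.

**Enrichment.** For a motif with m ≥ 2 targets in the panel, e
differential edges among the t = m(m−1)/2 target pairs are compared with a
Binomial(t, p) upper tail, p being the network-wide differential-edge
density *at the same edge-calling threshold* (default 10⁻¹⁰ on the
adjusted change p-value, plus the standard gate). Only target–target
edges count. scipy's survival function provides the numerically stable
tail; Bonferroni is over the motifs actually tested.

**PanCan.** Per-study networks are rebuilt at the stricter τ = 10⁻⁴, gene
universes are intersected and re-indexed, and a pair is recurrent when
differentially co-expressed in at least `min_studies` (default 3) studies.
The concatenated matrix D_C stacks the studies' D row-blocks; its columns
(genes) are the PCA observations, mean-centered but not scaled — scaling
would equalize the very study-size differences the analysis examines, and
centering is the minimal PCA prerequisite. The interaction-class
comparison applies Welch's t-test to the *ungated* Δz of class-member
versus other pairs (using all pairs keeps the comparison free of the
gate's selection effect; the population is configurable). Pairwise
"noisier co-expression" uses an OLS line fit per condition and the
median-centered (Brown–Forsythe) Levene test on the two residual sets —
robust to the heavy tails of expression residuals; var_T and var_N are
returned so the caller can check the direction.

## Synthetic data

The generator uses a Gaussian copula: latent normals with a block
correlation structure per condition, pushed through a strictly increasing
non-negative map (exponential by default, i.e. log-normal margins that
mimic the skew of RSEM values). Spearman statistics see only ranks, so
the planted structure survives the map exactly, with latent ρ mapping to
Spearman (6/π)·arcsin(ρ/2). Planted blocks must be disjoint, which makes
the latent correlation matrix block-diagonal and positive-definiteness
checkable block by block (equicorrelated modules need ρ > −1/(k−1); hub
modules use a one-factor construction, corr(hub, partner) = ρ and
corr(partner, partner) = ρ², which is always valid). Differential
expression is planted as a tumor-side latent shift of `shift`·ln 2,
multiplying log-normal values by 2^shift without touching ranks;
DC-not-DE genes get an equicorrelated normal-only block with margins
untouched, so their means match between conditions by construction.

Default sample sizes (103 tumor / 49 normal) mirror the smallest cohort in
the bundled manifest, so desk-scale results reflect realistic power at the
low end. Fixed study-condition scenarios live beside the generator:

- *decoupled recovery*: 20 genes, three decoupled pairs at ρ_N = 0.8
  (per-pair detection power ≈ 0.96 at these sizes and τ = 10⁻², so the
  ≥ 95% recovery check is measured over pairs pooled across replicates),
  two null pairs at ρ = 0.5;
- *regulon*: 40 genes, one 8-target module at ρ = 0.9 decoupling in tumor,
  five decoy motifs; ρ = 0.9 reflects the near-perfect normal-tissue
  co-expression reported for recurrently dysregulated pairs and is the
  strength regime where the fixed 10⁻¹⁰ edge threshold is reachable at
  these sample sizes;
- *PanCan*: seven 24-gene studies; two pairs decoupled (ρ_N = 0.9) in five
  studies, one in a single study.

What the generator does *not* model: count-level (negative-binomial)
noise, tumor purity and subtype mixtures, batch effects, and gene–gene
correlation outside the planted blocks. Passing tests therefore
demonstrate the statistical machinery on clean copula data, not robustness
to those real-data confounders.

## Numerical choices

- |r| is clamped to 1 − 10⁻¹⁵ before atanh, absorbing the transform's
  singularity when toy data contain perfect correlations.
- Constant (zero-variance) genes are kept in the matrices to preserve
  index alignment across conditions, with r = 0 and p = 1 forced on all
  their pairs.
- Adjusted p-values cap at 1; the capped value participates in the strict
  threshold comparisons unchanged.
- Expression TSVs are written at 17 significant digits and parsed with
  round-trip float precision, making write→read bit-exact.
- Enrichment results are sorted by p-value with a stable sort; ties keep
  GMT file order.

## Problem sizes

Simulation-based checks use 10,000 null pairs for calibration, 5,000
replicates for the variance-stabilization check, 200 replicates for
decoupled-pair recovery, 100 for regulon recovery and 60 for the
seven-study PanCan recovery — sizes at which the binomial uncertainty of
each measured fraction is a small multiple of a percentage point, keeping
the whole suite and the acceptance script in the seconds-to-minutes range
on one CPU.

## Known limitations

- Bonferroni with family m(m−1)/2 is deliberately conservative; no FDR
  alternative is offered.
- The Δz test on Spearman coefficients is mildly anticonservative (see
  caveat above).
- S is not a formal test statistic: the pair tests sharing a gene are
  dependent.
- The built-in log₂-ratio is a crude DE effect size; supply an external
  column for serious DE contrasts.
- PCA on D_C is descriptive; no significance is attached to components.
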