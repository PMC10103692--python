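# Methods

## Design and data model

A balanced line × tester trial crosses each of *l* lines with each of *t*
testers; the entry list (l + t + l·t genotypes) is grown in an RCBD with *r*
complete blocks, repeated under each environmental condition. The packaged
reference trial has l = 7, t = 3, r = 3, two irrigation regimes and ten
traits. Two table shapes are canonical: a long plot-level CSV (one row per
plot observation) and a wide genotype × trait means CSV — the two shapes in
which such trials are recorded and published, respectively. Missing or
duplicate cells are rejected outright rather than imputed: the balanced-data
formulas used throughout assume a complete layout, and an unbalanced trial
needs a different (mixed-model) analysis that is explicitly out of scope.
Typographic minus signs and multiplication signs in inputs are normalized to
ASCII on read.

## ANOVA

Sums of squares use the standard balanced identities
(SS_genotypes = r·Σ(ȳ_g − ȳ)², SS_reps = g·Σ(ȳ_k − ȳ)², error by
subtraction). The genotype SS is partitioned into parents, crosses, and a
1-df parents-vs-crosses contrast computed as
r·(n_p n_c/(n_p+n_c))·(ȳ_P − ȳ_C)²; the subtraction route is used as a
cross-check in tests. Cross variation splits into lines, testers and
line × tester marginals. **All F tests use the pooled RCBD error mean square
as denominator**, not the interaction mean square: this is the convention
under which a tester effect remains testable (and can be significant) even
when its mean square falls below the interaction's, which the reference
trial's water-deficit RWC column exhibits. The replications row is reported
but left unstarred by default. p-values below machine resolution are clamped
to zero; significance boundaries are inclusive and implemented by comparing
|effect| or F against the critical value directly, so a value placed exactly
on the boundary is starred deterministically. The LSD between two genotype
means is t(α/2, df_e)·√(2·MS_e/r).

## Combining ability

Effects are defined on the cross-mean matrix only — parents never enter
effect estimation (they feed only the heterosis and partition modules):
μ̂ is the grand mean of the l·t crosses, g_i and g_j the marginal deviations,
s_ij the residual. These estimates satisfy exactly the zero-sum constraints,
the reconstruction identity μ̂ + g_i + g_j + s_ij = x_ij, and the
energy identities r·t·Σg_i² = SS_lines, r·l·Σg_j² = SS_testers,
r·Σs_ij² = SS_LxT, all of which are enforced as tests. Standard errors are
the balanced line × tester forms SE(g_line) = √(MS_e/rt),
SE(g_tester) = √(MS_e/rl), SE(s) = √(MS_e(l−1)(t−1)/(rlt)); effects are
starred by two-sided t tests against zero. LSD rows (t·SE) are emitted
informationally: the printed LSD rows in the reference trial's GCA table do
not follow from any standard SE formula we tried, so the stars are the
authoritative significance output and no agreement with those rows is forced.

## Variance components and heritability

Method-of-moments only (no REML), matching how such trials are analyzed:
σ²SCA = (MS_LxT − MS_e)/r; per-set GCA variances
(MS_lines − MS_LxT)/(rt) and (MS_testers − MS_LxT)/(rl), pooled as their
unweighted mean. Negative moment estimates are retained as computed and
flagged — truncation would hide the diagnostic case MS_testers < MS_LxT that
actually occurs in the reference data. σ²E is taken as the error mean square
directly. Genetic variances use the inbreeding-coefficient form
σ²A = [4/(1+F)]·σ²GCA, σ²D = [2/(1+F)]²·σ²SCA with default F = 1
(self-pollinated, fully inbred parents), under which σ²A = 2σ²GCA and
σ²D = σ²SCA exactly. Heritabilities are percentages of σ²A+σ²D+σ²E.
Contributions of lines/testers/interaction are their shares of the cross SS
(MS × df). A `sigma2_gca_override` parameter lets a GCA variance obtained
elsewhere be carried through the downstream formulas; this is how the
reference trial's printed genetic-parameter table (whose pooled σ²GCA is not
derivable from its mean squares by any standard estimator) is reproduced.

## Heterosis

Heterobeltiosis = 100·(F1 − BP)/BP. BP is the max of the two parent means
for higher-is-better traits and the min for days-to-heading and plant
height — the only interpretation consistent with the signs published for the
reference trial. Significance compares |F1 − BP| with t(α/2, df_e)·√(2MS_e/r),
the two-entry-mean LSD; the variance multiplier is a parameter of
`heterosis_significance` in effect only through the default, since
alternative better-parent test variances exist in the literature. Mid-parent
and standard-check heterosis are out of scope.

## Multivariate

Trait columns are z-scored per condition with the sample (n−1) standard
deviation; standardization is per condition because the trial's two regimes
are clustered separately. Pearson correlations carry t-based two-sided
p-values on n−2 df. Clustering is agglomerative on Euclidean distances;
single/complete/average/weighted/ward go through scipy (ward is the
squared-distance, ward.D2-equivalent variant), and a "flexible" linkage
(Lance–Williams with β = −0.25, α = (1−β)/2, γ = 0) is implemented directly
as a naive O(n³) agglomerator — ample at trial sizes. The agglomerative
coefficient is mean(1 − h_first(i)/h_final); note a single outlier scores 0
for itself (its first merge is the last), so a tight-cluster-plus-outlier
configuration approaches (n−1)/n, not 1. The number of clusters is chosen
by majority vote of silhouette, Calinski–Harabasz and Davies–Bouldin on Ward
partitions (a small, standard index subset rather than a 30-index panel;
ties break toward smaller k). Cluster summaries are unweighted means of raw
trait values. Entanglement between two dendrograms is the sum of absolute
leaf-position differences divided by its maximum ⌊n²/2⌋ (attained by order
reversal): 0 = identical orderings, 1 = reversed. Heatmap support is the
reordered standardized matrix plus both dendrogram orders; no rendering.

## Simulator

Plot values follow y_ijk = μ + b_k + g_i + g_j + s_ij + e_ijk for crosses
and y_pk = μ_p + b_k + e_pk for parents, all effects normal. Drawn effect
vectors are re-centered exactly (SCA double-centered), so the zero-sum
invariants hold in finite samples and the moment estimators are unbiased for
the configured variances by construction. Parent means are drawn around μ
with variance σ²_gca_line + σ²_gca_tester + σ²_sca unless set explicitly.
Water deficit is an additive per-trait shift plus an optional error-variance
inflation — it emulates the mean displacement between regimes, not
genotype × environment interaction, so cross-condition stability analyses
are outside what passing tests demonstrate. The `rice_like_config` defaults
take per-trait means and deficit shifts from the packaged mean table and the
GCA/SCA/error variances from the packaged mean-square table; block variance
is set to half the error variance, a realistic figure for a well-managed
replicated trial. The seed is a required field and all randomness flows
through one `numpy` Generator; no global state.

What the simulator does *not* emulate: trait-trait correlation is optional
and off by default, errors are homoscedastic within a condition, and there
is no spatial field trend — so tests passing on synthetic data demonstrate
correctness of the estimators under the stated model, not robustness to
field artifacts.

## Problem sizes and numerics

Monte-Carlo checks use 200 simulated trials for variance-component
unbiasedness (assessed within three Monte-Carlo standard errors) and 100
seeds for SCA sign agreement, at the reference design size; each runs in a
few seconds. Algebraic identities are asserted at 1e−9 relative tolerance,
reconstruction at 1e−12. Degenerate inputs are defined, not special-cased
away: zero error MS yields infinite F (p = 0) and stars on any non-zero
effect; constant data yields all-zero SS with F reported as 0 and p = 1;
constant trait columns are a named error in standardization and correlation.

## Known limitations

No unbalanced or missing-data ANOVA, no reciprocal or Griffing diallel
methods, no REML, no mid-parent heterosis, no cubic clustering criterion,
and no graphics — tables and exportable matrices only.
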