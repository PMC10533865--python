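# Methods

This note records the statistical models the package implements, the
choices made where the published analysis conventions leave the design
open, and what the synthetic-data tests do and do not establish.

## Differential association engine

Counts for feature *g* in sample *j* are modeled as negative binomial with
mean μ_gj = q_g·s_j and variance μ + αμ². Size factors s_j are
median-of-ratios: the median over features (nonzero in every sample) of
count/geometric-mean; a single sample gets s = 1, and a table with no
feature nonzero everywhere raises an error rather than silently switching
to a pseudo-reference.

Dispersion is estimated by method of moments on normalized counts, with
sums of the moment residuals (s² − m) and weights m² accumulated within
each group. By default the sums are **pooled across features into one
shared α** (`dispersion_mode="pooled"`): with the 2–3 replicates typical
of fraction-resolved profiling, a per-feature second moment is essentially
noise, and plugging it into a Wald denominator is anticonservative — with
per-feature moments the measured null rejection at nominal 0.05 was ≈0.09,
versus ≈0.05 with the pooled estimate. `dispersion_mode="per_feature"` is
available for data with genuinely heterogeneous dispersion; its p-values
should then be read conservatively or re-calibrated. There is no
empirical-Bayes shrinkage, no LFC shrinkage, no independent filtering and
no outlier replacement: downstream thresholds are strict inequalities on
unshrunken estimates, so the estimator is kept transparent.

The test statistic is log₂FC/se with log₂FC = log₂((m₂+ε)/(m₁+ε)),
ε = 0.5 normalized counts, and a delta-method standard error from the NB
variance at the estimated means (means floored at ε so zero-count groups
stay finite); *p* is the two-sided normal tail, BH-adjusted across
features with defined *p*. Features with all-zero counts report log₂FC 0
and missing *p*/padj. Group relabeling flips the sign of log₂FC and leaves
*p* unchanged; in the Poisson limit (α→0, large means) the statistic
reduces to a two-sample z-test on log₂ normalized means. Isoform-level
analysis is the same engine run on a transcript-id count table.

Multiple-testing adjustment (BH step-up and Bonferroni) is implemented
directly from the definitions; missing p-values are excluded from m.

## Translational-status classification

For one condition pair, three contrasts are fit (input, monosome,
polysome). Input stability uses the same strict thresholds as the fraction
contrasts (|log₂FC| > 1 AND padj < 0.05 marks *instability*); no separate
input threshold is published, and features with missing input padj count
as stable. Stable features collect evidence from the fraction contrasts
(mono_up/mono_down/poly_up/poly_down at the same thresholds) and are
classified: evidence within {poly_up, mono_down} → derepressed, within
{mono_up, poly_down} → repressed, empty → unchanged, mixed → ambiguous.
Surfacing discordant signals as *ambiguous* keeps the derepressed/
repressed dichotomy auditable instead of silently resolving conflicts.

The baseline set for the trajectory table ("associated with polysomes in
the early phase") is defined as features with nonzero polysome counts in
every early-phase polysome sample — the weakest detection rule consistent
with that phrase; the published count behind the corresponding figure is
not reproducible without the original data, so no attempt is made to tune
this rule toward it. The trajectory table categorizes baseline features by
polysome evidence only (Poly up / Poly down / No) per later contrast; its
marginal sums equal the baseline size by construction.

## Single-nucleus utilities

Normalization is ln(1 + scale·count/total) with scale = 10,000; zero-depth
nuclei map to zeros. "Expressing" always means raw UMI count > 0, so
pct.1/pct.2 are invariant to normalization and library size. Marker
detection is a one-vs-rest two-sided Wilcoxon rank-sum on normalized
values (normal approximation with tie and continuity correction; exact
enumeration is used only as a test oracle at 4-vs-4), with
avg_log₂FC = log₂((mean_in + ε)/(mean_rest + ε)), ε = 1 in normalized
units — the published analyses do not define the fold-change arithmetic,
so this monotone, configurable choice is documented here. Emission filters:
pct.1 ≥ 0.10, avg_log₂FC ≥ 0.25, Bonferroni *p* < 0.05 (m = genes tested);
clusters with fewer than 3 nuclei are skipped with a warning.

The intersection filter (mean normalized expression > 0.1 AND ≥30% of
nuclei expressing) applies the mean threshold to **normalized** expression:
a raw-count mean cutoff would depend on sequencing depth. The
subplate-vs-neuronal comparison pools clusters on each side and applies
the 30% detection cutoff to the subplate pool only (which side carries the
cutoff is not published; the target-pool convention matches marker
detection and is configurable). Its fold-change gate is two-sided so that
down-regulated genes remain visible to the downstream sign filter.

## Permutation enrichment

Input sets are cluster markers with avg_log₂FC strictly above 0.5849
(2^0.5849 ≈ 1.5-fold). The background is detected ∩ scored genes; input
genes outside it are dropped with a warning and the target set is
restricted to it before counting (genes unscorable in the background
cannot contribute overlap under the null). Each of n_iter = 10,000
iterations draws |input| genes uniformly **without replacement** (gene
lists are sets); empirical *p* = count/n_iter exactly, so *p* = 0 is
representable, with a (count+1)/(n_iter+1) convention available for
log-scale plotting. The *enrichment rate* is observed/null-mean overlap —
the natural fold enrichment over the permutation null; the published axis
is not defined in the text, so this is an interpretation, flagged as such.
Because the null of a without-replacement overlap is exactly
hypergeometric, the closed-form tail serves as an independent oracle in
the tests — never as the implementation.

## RBP ranking, RIP targets, qPCR statistics

RBP candidates must (1) carry an RBP score entry, (2) be up-regulated
(avg_log₂FC > 0), (3) have ≥1 synaptic GO term, (4) have score > 0; they
are ranked by descending score with ties broken by descending avg_log₂FC
then symbol. The synaptic matcher is the case-insensitive substring
"synap" on term names — "synapt" alone would miss "synapse …" terms — and
an explicit term-name list can replace it.

RIP targets require log₂FC(RIP/IgG) strictly above the species threshold
(human 1.7, mouse 0.5) and padj strictly below 0.05; flags are
recomputable from the row's own fields. Cross-species intersection maps
mouse symbols to the human namespace by case-insensitive identity unless
an ortholog table is supplied. RIP-qPCR fold enrichment is 2^−ΔΔCt with
ΔCt taken within each (sample, antibody) stratum and the IgG stratum as
the negative control; technical replicates are averaged (arithmetic mean
of Ct) before any differencing, and non-detects drop the affected
stratum.

The polysome/monosome statistic is
ΔΔΔCt = [ΔCt(poly) − ΔCt(mono)] − mean over WT of the same quantity, so
the WT group mean is 0 by construction and any per-sample Ct offset
cancels. A transcript shifting toward polysomes yields negative ΔΔΔCt;
reporting layers multiply by a single constant (−1) to express the value
as a log₂ polysome/monosome ratio. The reference gene is a required
parameter with no default: the published panels are inconsistent about
whether β-actin or GAPDH anchored a given experiment. Group comparisons
gate on Shapiro–Wilk at *p* > 0.05 in both groups (the published gate
states no alpha; 0.05 is the study-wide level) → Welch *t*, otherwise
Mann–Whitney; groups with fewer than 3 values, or containing tied values,
go to Mann–Whitney (discrete data are not Gaussian, and Shapiro–Wilk has
little power to notice at these sizes).

## Synthetic data

`simulate_fraction_counts` draws NB counts with log-normal feature means
(default mean expression = library_size_mean/n_features = 100, σ = 1 on
the log scale), a shared dispersion (default 0.05), and log-normal
per-sample library factors (σ = 0.15). Planted derepressed features gain
effect_log2fc (default 2) on polysome means and lose it on monosome means
in the second condition — the antagonistic planting mirrors the
mass-shift reading of a translational change, where ribosomal occupancy
moves between fractions; repressed features are the mirror image, and
input-shifted features move their input means with a random sign.
`simulate_nucleus_matrix` draws Poisson UMIs (dropout emerges from low
rates, default baseline 0.2/gene/nucleus) with marker rates multiplied by
marker_fold inside their cluster. `simulate_annotations` plants RBP
scores, synaptic term names, and a risk set sampled with a configurable
enrichment weight on chosen marker genes. `simulate_ct_table` constructs
Ct values whose expected cKO ΔΔΔCt equals −(planted log₂ ratio) exactly,
with Gaussian noise per technical replicate (the noisy-recovery checks use
4 technical replicates, matching the ≥4-replicate qPCR convention); at
zero noise the inversion is exact to machine precision.
`simulate_rip_counts` reuses the NB machinery for a RIP-vs-IgG design.

All generators are pure functions of their parameters and seed. What they
deliberately do **not** model: batch effects, doublets, ambient RNA,
per-feature dispersion heterogeneity, amplification-efficiency drift, and
cell-composition confounding of bulk fractions. Recovery results on these
fixtures therefore demonstrate correctness of the statistical machinery
under its own assumptions, not robustness to those real-data artifacts.

Default problem sizes (2,000 features × 3 replicates for fraction counts;
5–6 clusters × 80–100 nuclei × 300–500 genes; 10,000 permutation
iterations) were chosen so every planted effect is comfortably detectable
at the published thresholds while a full pipeline run stays in seconds.

## Numerical details and edge cases

- All thresholds are strict inequalities, matching the published "> 1",
  "< 0.05", "> 0.5849", "> 1.7", "> 0.5" phrasings; boundary values are
  excluded everywhere and tested explicitly.
- Dispersion floor 1e−6; fold-change pseudo-count 0.5 normalized counts
  (engine) and 1 normalized unit (markers); all configurable via the YAML
  config, which mirrors every threshold with the published defaults.
- Gene symbols are case-sensitive internally; a single uppercasing
  utility is applied at cross-table joins (translatome ∩ snRNA-seq,
  mouse ∩ human).
- Empirical p-values are exact multiples of 1/n_iter; permutation draws
  are chunked row-permutations of the background indicator, reproducible
  from the seed.
- Logging records the seed, config hash, and row counts at each filtering
  step so a run's funnel can be reconstructed from its log.

## Known limitations

The engine intentionally does not reproduce a specific external DE
package: no shrinkage estimators, no GLMs with covariates, and only
two-group designs. Translational-efficiency ratios (polysome normalized
to input) are deliberately out of scope, as is everything upstream of
count tables (alignment, quantification) and clustering itself — cluster
labels arrive with the matrix. Published dataset-dependent totals (counts
of regulated transcripts, target-set sizes, cluster counts) depend on the
original deposited data and are not reproducible from synthetic fixtures;
the package instead verifies the statistical behaviour those totals rest
on.
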