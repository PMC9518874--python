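# Methods

This note documents the models behind each stage, the tunable parameters
that matter, what the synthetic data do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Rhythm detection

Both detectors share the fixed-period harmonic design
`y ~ a + b·cos(2πt/P) + c·sin(2πt/P)` with `P = 24 h` by default.
Abundances are log(x+1)-transformed before fitting; samples enter at their
absolute hours, so extra cycles and biological replicates contribute
additional observations of the same phase rather than being averaged.
Missing values are omitted per gene.

* **cosinor_F**: ordinary least squares; the rhythm p-value is the F-test
  of (b, c) = (0, 0) with (2, n−3) degrees of freedom. Exact under Gaussian
  log-scale noise, which is also the simulation's noise model — so
  calibration tests of this detector check implementation, not robustness.
* **robust_regression_perm**: the same design fitted by iteratively
  reweighted least squares with Tukey's bisquare (c = 4.685); the statistic
  is the relative reduction in robust residual scale (normalized MAD)
  versus an intercept-only fit, and the p-value comes from permutations of
  the time labels (default 1000; a seed is mandatory because the p-value is
  stochastic). This detector is the outlier-tolerant option for proteomics
  series; its p-values are granular at 1/(B+1).

Degenerate inputs: a constant series carries no rhythm information and is
assigned p = 1 with a warning; fewer than 4 usable samples yield a missing
p-value; fewer than 2 distinct time points within the period is an error.

**Probe combination.** Genes measured by several probes get one p-value via
the empirical Brown's method: each probe's samples are transformed by the
probe's own empirical CDF, `w = −2·ln(ECDF)`, and the empirical covariance
of `w` across probes rescales Fisher's chi-square null (scale
`c = var/2·mean`, degrees of freedom `f = 2·mean²/var`, with mean = 2k and
var = 4k + 2·Σ cov). When the estimated covariance would make the combined
test more aggressive than Fisher's (c < 1), it is capped at independence —
the standard guard against sampling noise in the covariance. With k = 1 the
input p is returned exactly; duplicated rows collapse toward a single test.

**Diagnostics.** A healthy p-value distribution in data containing rhythmic
genes is a uniform carpet plus a spike near zero. The diagnostic reports
histogram counts, the KS distance of the p > 0.5 region from
Uniform(0.5, 1), and a lowest-bin enrichment, flagging distributions
whose lowest bin is depleted (beyond binomial sampling error) or whose
upper tail is non-uniform.

**Classification.** Strict thresholds label p ≤ 0.01 rhythmic and p > 0.5
non-rhythmic; intermediate p-values are *ambiguous* and excluded from all
two-group comparisons, because calling them either way would dilute both
groups. Proteomics series, being noisier, default to a lighter rhythmic
cutoff (p ≤ 0.05). The alternative top-fraction mode ranks genes by p-value
and calls the lowest 15% rhythmic; ties break by stable gene-id order.

## Expression cost

`C_p = N · L_p · c̄_AA` with c̄_AA the mean cost over residues that have a
defined cost (ambiguity codes B/Z/X/U/J/O are excluded from the mean but
still count toward L_p, since they are real residues of unknown identity).
Two abundance conventions are reported: `meanN`, the arithmetic mean over
time points, and `maxN`, the average of the two largest *distinct*
observations — a maximum estimate robust to a single spiky measurement.
A constant series has no two distinct values; `maxN` then equals the
constant (the continuous limit of the rule). Note the distinct-value rule
means `maxN` can fall below `meanN` when the maximum value repeats; for
all-distinct series `maxN ≥ meanN` always holds.

Two built-in residue cost tables are shipped (aerobic-respiration
opportunity costs and chemostat-based estimates, both in high-energy
phosphate bonds per molecule); they are strongly linearly related
(Pearson r > 0.9 across simulated proteomes), so conclusions do not depend
on the choice. Class comparisons are Welch tests on natural-log values
(half-minimum pseudo-floor for the exact zeros proteomics produces);
c̄_AA is compared on its natural scale since it is already a bounded
per-residue average.

## Tissue analyses

Per tissue, gene-level mean expression is Z-scored across genes and divided
by the maximum Z, so the top gene sits exactly at 1. Values below the
cross-gene mean remain negative; only the upper range is mapped into
(0, 1]. Since δ is a within-gene difference of group means, the overall
location of the scale is immaterial.

`δ_i` = mean normalized expression over the tissues where gene *i* is
rhythmic minus the same over tissues where it is flat; genes lacking at
least one tissue in each group are excluded and counted. The run-level test
is a one-sample Student's t of the δ distribution against 0 (an all-zero
distribution short-circuits to t = 0, p = 1 rather than 0/0).

τ uses log2(x+1)-transformed mean expression (the +1 pseudocount keeps
sub-unit expression from producing negative logs; any residual negatives
are clamped to 0), scaled by the cross-tissue maximum:
`τ = Σ(1 − N̂)/(n−1)`. τ = 0 for uniform expression, 1 for single-tissue
expression, missing for genes silent everywhere. The τ-versus-breadth
report includes a partial Pearson correlation controlling for cross-tissue
mean expression (residual-on-residual), since expression level correlates
with both quantities; the covariate is exposed as an argument.

For tissue-specific genes (τ > 0.5) the per-gene Spearman/Pearson
correlation of expression with the rhythm p-value across tissues is
computed (≥ 4 informative tissues required); genes with negative
correlation (rhythmic where highly expressed) form set A, positive form
set B, and the two sets are handed to the selection stage.

## Single-cell noise

Genes pass an expression filter — log10(FPKM+1) > 1.5 in at least one cell
(log base 10 following the source method's convention; configurable) — and
get `F* = σ²/exp(P_d(log μ))` where P_d is the polynomial fit of log σ² on
log μ across genes. The degree is chosen automatically: the lowest d in
1..5 whose residuals satisfy |Kendall τ(F*, μ)| < 0.05 and |OLS slope| <
0.05, else the d minimizing |Kendall τ|. Because the fit is itself OLS in
log space, the degree-1 slope criterion is trivially met and the selection
is effectively driven by the rank correlation, which degree 1 fails only
when the log-log trend is genuinely curved over the observed range. F* is
invariant to rescaling all variances (the refit trend absorbs the factor);
it measures departure from the trend, not absolute noise.

With several retained cell types, F* is computed within each type and
averaged per gene weighted by cell count (the aggregation rule was an open
choice; pooled mode is also provided).

Class comparisons (Welch on log F*) follow five designs: rhythmic vs flat
transcripts (a) or proteins (b); transcripts compared within rhythmic (c)
or flat (d) proteins; proteins compared within genes with constant
transcripts (e). Design e is the clean test of a protein-level noise
effect, uncontaminated by the transcript-level signal.

## Selection

dN/dS is compared between rhythm classes on the log scale (genes with
dN/dS = 0 are excluded before the log and counted; multiple orthologue
entries per gene collapse by median). The controlled variant regresses
log(dN/dS) on log(expression) by OLS and compares the residuals — removing
the confound that rhythmic genes are highly expressed and highly expressed
genes are conserved. Residuals are invariant to rescaling expression by any
positive constant. Four category designs mirror the noise stage (a, b as
above; c: transcripts within rhythmic proteins; d: proteins within rhythmic
transcripts). The set-A/set-B comparison from the tissue stage uses a
Student's t-test (equal variances), as the sets are defined on the same
filtered population.

## Synthetic data

The generators emulate the statistical structure the analyses assume, not
any platform's artifacts:

* **Bulk time series**: log-normal baselines
  (`Normal(baseline_log_mean = 2, baseline_log_sd = 1)` on the natural-log
  scale); a `rhythmic_fraction = 0.2` of genes carry a cosine of amplitude
  `amplitude_rel = 0.6` with phase Uniform[0, 24) (peak times of real
  rhythmic genes are dispersed across the day; uniform is the
  maximum-entropy choice); residual noise sd 0.3, so the default planted
  amplitude is twice the noise sd; 12 time points every 2 h, 2 cycles.
  Replicates are independent noise realizations of the same deterministic
  curve. Rhythmic genes' baselines shift by `cost_coupling = 1` log unit —
  the planted "rhythmic genes are highly expressed" effect.
* **Multi-tissue**: a `tissue_specific_fraction = 0.3` of genes get a home
  tissue with baseline raised by `tissue_boost = 1.5`; with probability
  `tissue_coupling = 0.9` a tissue-specific rhythmic gene is rhythmic
  exactly in its home tissue, otherwise rhythm lands in a random tissue.
  The cost coupling is applied at the gene level here (not per tissue) so
  that δ isolates the tissue coupling. Setting `tissue_coupling = 0` gives
  the null in which δ is centred at 0.
* **Single cell**: gamma-Poisson counts with variance `μ + φμ²`,
  `φ = nb_dispersion = 0.5`; genes with rhythmic transcripts are the
  planted low-noise subset with dispersion `φ(1 − noise_coupling)`,
  `noise_coupling = 0.5`. Means are log-normal on an FPKM-like scale chosen
  so most genes pass the expression filter. φ → 0 recovers Poisson.
* **dN/dS**: `log dN/dS = α + β·log(expr) + γ·1[rhythmic] + ε` with
  α = −1.5, β = −0.2, γ = −0.3, ε ~ Normal(0, 0.3).
* **Proteins**: uniform-composition random sequences of length 80–600 for
  the cost stage.

Coupling magnitudes are not estimable from published summaries; the
defaults were chosen once for comfortable test power at the default sample
sizes and are documented here rather than tuned per test. What passing
tests show is that the pipeline recovers planted effects of these
magnitudes and stays calibrated under the corresponding nulls; they do not
show that real data contain such effects, nor do the generators reproduce
microarray saturation, UMI collisions, batch structure, or clock-hierarchy
(e.g. suprachiasmatic) regulation — a tissue blacklist is provided for
excluding such tissues in real runs.

All generators are bit-deterministic given the config seed; independent
streams are derived as `default_rng((seed, salt))` per output so adding an
output never perturbs another.

## Problem sizes and numerical choices

Default verification runs use 2 000 genes for detector calibration/power,
5 000 genes x 200 replicates for the dN/dS confound control, 600 genes x
300 cells for F*, and 250 genes x 5 tissues x 60 replicates for δ recovery
— sizes at which every Monte-Carlo band in the tests is comfortably
resolved while the full suite runs in well under a minute of compute per
stage. Tolerances: exact arithmetic (cost, τ, residual identities) is
checked to 1e-9 or better; Monte-Carlo quantities carry explicit bands
stated in each test. Tie-breaks: classification ties go to stable gene-id
order; degree-selection ties to the lowest degree. The ECDF in Brown's
method uses max-rank/n, making the transform exact at k = 1.

## Known limitations

* The robust permutation detector's p-values are granular (1/(B+1)) and it
  is far slower than the cosinor; it is intended for modest gene counts or
  targeted re-tests.
* F*'s back-transform (ratio form) is one of several monotone choices; all
  downstream comparisons are rank-based or log-scale, so conclusions are
  invariant to this choice, but absolute F* values are not comparable
  across choices.
* The Z normalization maps only the above-mean range into (0, 1]; δ is
  unaffected, but the normalized values themselves should not be read as
  proportions.
* No probe-to-gene mapping service is included: identifier maps are
  supplied as static TSV files.
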