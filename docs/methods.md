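# Methods

## The screening model

A cold-tolerance screen phenotypes g genotypes under two treatments
(control 22 °C, cold 4 °C) in a balanced complete-randomization design with
r replicates per genotype × treatment (optionally repeated over trials).
For one trait under one treatment the observation model is the one-way
random-effects layout

    y_ij = mu + g_i + e_ij,   g_i ~ (0, sigma2_g),   e_ij ~ (0, sigma2_e),

estimated by the classical expected-mean-squares identities on balanced
data: E[MSG] = r·sigma2_g + sigma2_e and E[MSE] = sigma2_e, so
sigma2_g = (MSG − MSE)/r, floored at zero with a warning when the contrast
is negative (standard practice; keeps H² in [0, 100]).

**Heritability basis.** H² is reported on the entry-mean basis,
sigma2_g / (sigma2_g + sigma2_e/r), because every downstream quantity (the
index, P, the ratios) operates on genotype means over replicates; a
plot-basis option (`basis="plot"`) divides by sigma2_g + sigma2_e instead.
With sigma2_g = 5, sigma2_e = 1, r = 3 the entry-mean closed form is
93.75%.

**Genetic advance.** GA = k · H² · sigma_p with
sigma_p = sqrt(sigma2_g + sigma2_e/r) and selection intensity k = 2.06
(top 5% of a normal distribution) by default; k is a plain argument.

**Coefficients of variation.** The "CVb" column is the genotypic CV,
100·sigma_g/mean; a phenotypic CV column (CVp) is emitted alongside since
conventions differ between reports.

**Trials.** By default replicates are averaged within each trial and the
trial means act as replicate units (no genotype × trial interaction is
modelled — the design treats seasonal runs as additive environments); a
`trials="pool"` flag treats every trial × replicate observation as a unit.

## Index matrices and the Smith–Hazel solve

G is assembled from pairwise analyses of cross-products (the bilinear
mirror of the ANOVA decomposition: cov_g = (MPG − MPE)/r, diagonal floored
at zero); P is the sample covariance matrix of genotype entry means. On
balanced data these satisfy P = G + E/r exactly, entry by entry — a
consistency identity the test suite asserts. G is a method-of-moments
estimate and is not forced positive semi-definite; only P enters a solve.

The index weights solve the linear system P b = G a directly
(`scipy.linalg.solve`, symmetric path), never via an explicit inverse;
the achieved residual max|Pb − Ga| is stored and must be below 1e-8.
P with condition number above 1e8 is refused, with the most collinear
trait pair named in the error. Economic weights a default to all ones:
the index literature folds a into G when no economic differentiation is
wanted, and the screen's three index traits are used raw.

**Trait orientation.** Index traits are used in their natural units
(leaf injury high = bad, qL/Fv/Fm high = good) without sign flips, and the
resulting CTI is interpreted as "low = tolerant": the injury term dominates
the score numerically, and keeping raw units lets externally published
coefficient vectors be applied verbatim via `--coeffs`. Users who want a
strictly monotone-bad index can negate beneficial traits in their own
weight vector.

**Categories.** The five classes T/MT/MS/S/SS are assigned by five
equal-width bins over [min CTI, max CTI] by default — deterministic and
scale-free; quantile bins and manual breakpoints are provided. Ties in
CTI are broken by genotype id so ranking is reproducible. If all scores
are identical every genotype is placed in the middle class with a warning.

## Ratios, correlations, PCA

Stress ratios are cold entry mean / control entry mean per genotype ×
trait (replicates averaged first). A ratio whose control mean is ≤ epsilon
(default 1e-9) is flagged missing and logged, not raised — with strongly
inflated traits such as NPQt a few control denominators can sit near zero.

Correlations are pairwise-complete Pearson r with two-sided p from the
exact t transform t = r·sqrt((n−2)/(1−r²)); stars follow the
0.001/0.01/0.05 convention per pair (mirroring how screening figures are
annotated), and a Holm-adjusted column is emitted in the long-format
output for readers who want family-wise control. Constant columns are
reported missing.

PCA standardizes columns by default (correlation-matrix PCA) because the
traits span four orders of magnitude (NPQt in the hundreds, qL in [0, 1]);
covariance-matrix PCA is behind `standardize=False`. Component signs are
fixed so each component's largest-magnitude loading is positive, making
loadings and scores deterministic across BLAS builds. Rows with any
missing value are dropped listwise before decomposition.

## The synthetic panel generator

The generator emulates the screen the analysis assumes:

    value = control_mean + cold_shift·[cold] + trial_effect
            + genotype_effect·(alpha under control, 1 under cold)
            + residual·(s under control, 1 under cold),

with one multivariate-normal genotype-effect draw per genotype from G_cov
(cold-response scale), i.i.d. residual draws from E_cov per replicate, and
per-trait clipping bounds. Genotype effects are attenuated under control
(alpha, default 0.2) because cold is what reveals varietal differences;
the calibrated soybean preset uses alpha = 0.05, the value implied by the
observed spread ratio of control vs cold qL (sd ≈ 0.006 vs ≈ 0.135).
Control residuals are shrunk by the same logic (`control_noise_scale`,
default 1.0, preset 0.05): measurement variability scales with the signal,
and near-ceiling fluorescence traits have almost no room to vary. Without
this, a residual covariance shared across treatments cannot reproduce both
the control and the cold ranges of a trait like NPQt, whose scale inflates
~40-fold under stress.

**Preset calibration.** Trait means and genotypic SDs are set from the
observed screening ranges (range ≈ 4.7 sd at n = 100); residual variances
follow from the ≈93% entry-mean heritability typical of such screens
(E_ii = r·G_ii·(1−h²)/h²). Genetic correlations encode the reported sign
structure (qL–Fv/Fm strongly positive; both negative with NPQt and leaf
injury; SPAD independent). The two leaf-injury off-diagonals are solved so
the generator *encodes* ratio correlations corr(qL_ratio, LI_ratio) = −0.22
and corr(FvFm_ratio, LI_ratio) = −0.30: a delta-method closed form
(`implied_ratio_correlation`) gives the first-order solution, then a
deterministic fixed-seed Monte-Carlo refinement adjusts for clipping and
ratio nonlinearity, which the delta method ignores. The calibrated
structure is cached per replicate count. Leaf injury is generated on a
continuous scale, clipped to [1, 8]; `round_li=True` rounds replicate
values to the ordinal scale.

**What the generator does not emulate:** genotype × trial interaction,
spatial field structure, non-Gaussian or heteroscedastic residuals within
a treatment, missing data, and the exact 40-fold NPQt scale collapse under
control (its simulated control range is wider than a real instrument
would show, and a small fraction of NPQt control denominators clip at
zero). Passing recovery tests therefore demonstrates correctness of the
estimators under the stated model, not robustness to field artefacts.

## Numerical and testing choices

- Covariance draws use an eigendecomposition factor (stable for PSD
  matrices with zero eigenvalues); configs with non-PSD matrices are
  rejected at construction (tolerance 1e-8 relative).
- All randomness flows through `numpy.random.default_rng(seed)` in a fixed
  draw order, so identical configs yield byte-identical panels.
- The ANOVA implementation is cross-checked against
  `scipy.stats.f_oneway` on random panels; the Pearson p-values against
  the explicit t transform; the linear solve against hand-solved diagonal
  systems and 1000 random SPD pairs (max residual < 1e-8).
- Statistical recovery tests use the study's design scale where stated
  (g = 100, r = 3 for heritability; g = 500 for covariance recovery;
  50 × 100-genotype panels for ratio correlations). The index-optimality
  property (the estimated index's correlation with aggregate genotypic
  worth beats ≥99% of random weight vectors) is checked on 300-genotype
  panels: at g = 100 the estimated coefficients' sampling noise produces
  ≈1.2% violations even though the achieved correlation is within 0.003
  of the in-sample optimum — the property under test is the asymptotic
  optimality of the index construction, not estimator variance at small g.
- Degenerate inputs: all-identical observations yield MSG = MSE = 0 and
  F = NaN with a warning; MSG ≤ MSE floors sigma2_g (and hence H², GA, CVb)
  to zero; duplicated index traits make P singular and the solve refuses.

## Known limitations

- Broad-sense heritability from a single-treatment one-way layout cannot
  separate genotype × environment variance from genetic variance; no
  REML/mixed-model path is provided.
- G's method-of-moments estimate can be indefinite in small samples; the
  solve only conditions on P, so a pathological G propagates into b.
- Equal-width categorization depends on the observed score range, so a
  single extreme genotype can compress the other classes; quantile binning
  is the remedy when class sizes matter.
- The ratio convention divides by control means; traits measured near zero
  under control produce unstable or missing ratios by construction.
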