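# Methods

This note records the models, conventions and design choices behind
`nephromorph`, in the order the pipeline runs.

## Synthetic tissue sections

Sections are discrete rasters (default 512×512 cells at 2 µm/cell,
i.e. a 1.05 mm² field) rather than vector geometry, so exhaustive label
counts are exact oracles for every stereological estimator.

**direct2d** places glomerular discs first — patent and sclerotic discs
have separate cell quotas, `round(fraction × cells)`, with the final
disc trimmed to its quota by keeping the cells closest to its centre —
and fills the remaining cells with a blocky random field (16-cell
blocks) over the four non-glomerular labels with renormalized
probabilities. Expected fractions therefore equal the requested ones
exactly, and glomerular fractions are exact per realization. Discs are
placed on a torus: with boundary clipping, the quota rule concentrates
glomerular area away from the edges and the grid-sampled interior is no
longer representative — a ~1% relative bias that a 2000-replicate
unbiasedness test resolves. A stationary field is the intended target,
so wraparound is the correct construction.

**sphere3d** realizes a 3D Poisson process of spheres (intensity
`glomerular_number_density` per mm³, lognormal diameters with the given
mean and CV, monodisperse when CV = 0) in a slab around the section
plane z = 0 and rasterizes the circular profiles. Only spheres whose
centre projects into the window are generated (an unbiased counting
frame), and each profile marks at least its centre cell, so the
expected profile count per area is exactly N_V·E[d]. Patency is a
Bernoulli label with probability 1 − sclerotic_fraction; the histologic
definition (a tuft counts as patent while most of its capillary lumens
remain open) is a human judgement we do not model. Profile areas are stored analytically
(πρ²) so tuft-area estimation is not limited by raster resolution.

## Stereology conventions

- Point grids: 5×5 sub-boxes of 40 µm side; the 25 evaluated points per
  grid are the bottom-left corners of the sub-boxes (equivalently, the
  grid's top and right boundary lines are excluded). Five grids are
  placed uniformly at random without overlap (rejection sampling); if
  fewer fit, the result is flagged tissue-insufficient rather than
  failing. A point takes the label of the raster cell containing it
  (half-open cells, lower-left inclusive). Counts are pooled across
  grids before fractions are computed.
- Mean tuft area A_G averages one uniformly chosen profile per
  glomerulus and requires at least 4 distinct glomeruli; cases below
  that are excluded (an error, matching morphometric practice).
- N_A counts **patent** glomeruli only, divided by the planimetric
  cortical area.
- The volumetric conversion uses D = √(4·A_G/π), the diameter of the
  circle whose area is the mean profile area. Written as `N_V = N_A/D`
  with `D = 4·A_G/π` the relation is dimensionally inconsistent; the
  square-root form is the only reading compatible with "assuming a
  spherical form of the tuft". This shortcut is knowingly biased for
  spheres: E[profile area] = πd²/6, so D underestimates d by √(2/3) and
  N_V overestimates truth by √(3/2) ≈ 1.2247. The package
  characterizes the bias by simulation instead of correcting it,
  because the estimator is used exactly as practised. The simulation
  uses ~40 profiles per section (2560 µm section, N_V = 50/mm³,
  comparable to the ~23 uniquely identified glomeruli per case in real
  morphometry) because E[1/√(mean area)] carries Jensen curvature of
  order +1–2% when only a handful of profiles are averaged — a
  finite-sample artefact, not the property under test.

## Synthetic cohort and trajectories

The generator's defaults emulate a 56-subject observational study of
primary proteinuric glomerulopathies. Categorical covariates use
largest-remainder apportionment (so the default cohort splits exactly
25 FSGS / 19 MCD / 12 MN; race 7/25/58/10% Asian/Black/White/Other,
30% female, 39% pediatric), and continuous marginals use stratified
quantile-matched sampling — baseline eGFR through a piecewise-linear
inverse CDF anchored at the quartiles 64.5 / 89.5 / 108.4 with tails at
15 and 150 mL/min/1.73 m² — so a 56-subject draw reproduces the target
descriptives closely while assignments remain random. Serum creatinine
is back-solved from the sampled eGFR through the 2009 CKD-EPI equation
(adults) or the bedside Schwartz equation 41.3·height/Scr (children,
age < 18; the bedside rather than full CKiD form is assumed), so the
eGFR equations round-trip on every generated subject.

Compartment fractions come from a Gaussian model whose correlation
target is the published six-compartment correlation matrix. That matrix
is singular to printed precision with an all-one-sign null eigenvector;
setting the compartment SDs proportional to that eigenvector (largest
SD 0.08, means 0.25/0.05/0.55/0.08/0.05/0.02) makes each row sum to a
constant exactly while attaining the target correlations — the simplex
constraint and the printed correlations are exactly compatible, which
the generator exploits. Values are clipped to (0,1) (rare) and rows
renormalized. A_G and N_A are negatively correlated lognormals
(glomerular hypertrophy accompanies glomerular loss); N_V is computed
from them by the Wicksell relation; pathologist-style IF/TA
descriptors are FIA/FATA plus N(0, 0.028) noise on the fraction scale,
×100.

Trajectories: eGFR_ij = 7.2 + baseline_egfr − 90·FATA
+ (−0.2007 − 1.5·FATA + 0.12·MCD)·t + e_ij, time in months. The level
term says measured eGFR tracks the screening value but carries an
additional atrophy-linked deficit beyond what a single screening
measurement captures (the constant recenters the population mean); the
slope terms make atrophy accelerate decline and an MCD diagnosis slow
it, with the base slope set so the population mean is −0.28/month
(−3.36/year) at the default covariate means. Noise is exchangeable
(ρ = 0.5, SD 8 mL/min/1.73 m²) by default; AR(1) and independence are
available. Visits start at t = 0 and recur at Uniform(4, 6)-month
intervals until 55.4 months or exponential dropout (rate 0.0170/month);
12.5% of subjects contribute only the baseline visit. The dropout rate
is derived from the target median follow-up of 30.4 months after
accounting for the ~2.5-month average gap between the dropout time and
the last scheduled visit.

What the generator does **not** emulate: treatment changes, assay
drift, informative dropout (dropout is independent of trajectory),
visit-time clustering by centre, and any real histologic texture.
Passing tests therefore demonstrate correctness of the estimators and
calibration of the pipeline under these stated conditions, not
performance on real biopsies.

## Correlations and principal components

Pearson correlations are computed on complete cases; significance flags
use a two-sided t test at α/15 (Bonferroni over the 15 pairwise tests
among six fractions). Constant columns raise a named error (detected by
`nunique` plus a relative SD threshold — an exactly constant pandas
column can report an SD of ~1e-18). PCA is the eigendecomposition of
the correlation matrix; eigenvalues are clipped at zero and matrices as
slightly indefinite as −1e-4 are accepted, because printed 3-decimal
correlation matrices routinely are. Signs follow the convention that
each component's FIA loading is nonnegative (falling back to the
largest-magnitude entry), which reproduces the published orientation of
PC1/PC3. "Dominant" loadings are those with |loading| ≥ 0.3, matching
truncated published listings; the full six-vectors are retained. Note
that a 3-decimal correlation matrix pins its eigenvectors only to about
±0.05, so published loadings computed from unrounded data can differ
from the printed matrix's own eigenvectors by that much.

## GEE engine

Identity-link Gaussian marginal model fitted by iteratively reweighted
estimating equations; independence and exchangeable working
correlations (exchangeable α by the moment estimator on Pearson
residuals, dispersion φ = Σr²/(N−p), Woodbury inverse per cluster).
Convergence is max|Δβ| < 1e-8 within 100 iterations; under
independence the solution is OLS in one step. Non-convergence flags the
result and warns rather than failing silently. Rank-deficient designs
raise an error naming the collinear columns (pivoted QR).

Inference is robust (sandwich) with Wald χ²(1) p-values. The default
covariance is the cluster-leverage bias-reduced sandwich (each
cluster's residual inflated by (I − H_i)⁻¹): with tens of clusters and
~20 parameters the plain sandwich understates variance enough that
nominal 95% intervals cover ~90–91%, while the bias-reduced form
restores 94–97% coverage in the package's own simulations. The plain
sandwich (`cov_type="robust"`) matches the statsmodels GEE oracle to
1e-10 and is used for such comparisons.

QIC = −2·Q(β̂; I) + 2·tr(Ω̂_I·V̂_R), with the Gaussian quasi-likelihood
evaluated under the independence model at the fitted means
(−2Q = SSR/φ̂) and Ω̂_I = XᵀX/φ̂. The trace penalty approaches the
parameter count for an adequate model. QIC is used comparatively;
its absolute scale depends on the dispersion convention.

R²_pred = 1 − PRESS/SSR. PRESS averages squared leave-one-**subject**-
out errors, predicting held-out visits from the marginal mean only (no
cluster-specific residual updating — GEE is a marginal model). SSR is
the averaged squared residual of the **time-only reference model** fit
to all data. Defining SSR against the candidate's own residuals would
force the ratio above 1 (a candidate's PRESS exceeds its own SSR), so
the reference-model reading is the only one under which the statistic
measures predictive gain; that is the convention implemented.
Note the synthetic study's R²_pred runs near 90%: the generator's
baseline-eGFR covariate is a strong, noiselessly recorded predictor of
level, which is the dominant share of the time-only model's error.

Quartile slope contrasts: subjects are binned at sample quantiles of a
stratifier (default FATA; values equal to a cut point fall in the lower
bin, lowest bin is the reference), and a GEE of
`egfr ~ stratum + time + stratum:time` is fitted; the interaction
coefficients are the slope differences against the lowest quartile,
tested by robust Wald.

Covariate coding throughout: race as Asian/Black/White indicators
(reference Other), diagnostic cohort as MCD/FSGS indicators (reference
membranous nephropathy), time in months continuous and always present;
baseline eGFR is a covariate while baseline visits stay in the outcome
vector (subjects with only a baseline visit still inform level
effects). The default working correlation is independence — the QIC
convention ignores longitudinal autocorrelation anyway — with
exchangeable available by configuration.

## Least-angle regression

The outcome is the per-subject OLS slope of eGFR on time ("average rate
of change"); subjects without two distinct visit times are dropped from
this stage only. Predictors (N_A, A_G, N_V, PC1–PC3) are standardized
to mean 0 and unit norm, the response centred. Classic LAR: enter the
predictor most correlated with the residual, move along the equiangular
direction of the active set until an inactive predictor ties, and
finish at the full OLS solution; ties break deterministically by column
order. Breakpoints are reported on both the standardized and original
scales. The implementation agrees with scikit-learn's `lars_path` on
entry order and every breakpoint to 1e-8.

## Numerical conventions and edge cases

- All randomness flows through `numpy.random.default_rng`; a seed fully
  determines sections, cohorts, trajectories and reports.
- Fractions from complete counts sum to 1 exactly (they share one
  denominator); fraction tables from the generator sum to 1 to 1e-9.
- Zero-point counts, zero cortical area, nonpositive A_G, zero
  reference SSR (detected with a relative 1e-10 threshold against
  exactly-fitting references) and empty strata raise typed errors.
- Test tolerances on Monte-Carlo quantities are 3-SE bands using the
  replicate SD of the quantity itself; descriptive checks of the
  56-subject study analogue average 20 replicate cohorts and add the
  generator's known small convolution biases (measurement noise widens
  the measured baseline IQR by ~2 units relative to the latent
  marginal) to the band.

## Problem sizes

The shipped tests and the acceptance script use: 200–2000 sections for
stereology Monte Carlo (512²–1280² cells), 20 000 subjects for
correlation-structure verification, 20-replicate descriptive averages,
200 replicates for coverage/recovery simulations and 100 for type-I
calibration. These sizes put Monte-Carlo SEs comfortably inside the
asserted bands while keeping a full run in tens of seconds.

## Known limitations

- The exchangeable AR(1) option indexes correlation by visit number,
  not elapsed time.
- sphere3d sections under-label glomeruli within a diameter of the
  lateral window edge (spheres centred outside the window are not
  generated); profile *counts* are unbiased by the centre-in-window
  rule, but edge cells are slightly depleted of glomerular label.
- The QIC dispersion convention (φ from the fitted model, N−p
  denominator) is one of several in circulation; comparisons should
  stay within one implementation.
- Pathologist descriptors IF/TA are modelled as noisy copies of
  FIA/FATA, not as an independent reading process with inter-rater
  structure.
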