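# nephromorph

Quantitative kidney-biopsy morphometry meets longitudinal kidney-function
modelling. `nephromorph` implements the full analysis chain used to ask
whether structural measurements on a baseline renal biopsy predict the
subsequent course of estimated glomerular filtration rate (eGFR) in
primary proteinuric glomerulopathies (minimal change disease, FSGS,
membranous nephropathy):

- **Stereology** — grid point counting of six fractional cortical areas
  (interstitium FIA, blood vessels FBVA, intact tubules FITA, atrophic
  tubules FATA, patent glomeruli FPGA, sclerotic glomeruli FSGA; 5×5
  grids, 25 points each, 125 points per section), planimetric mean tuft
  area A_G, areal density of patent glomeruli N_A, and the corpuscle
  conversion to volumetric density N_V = N_A / D with
  D = √(4·A_G/π).
- **Structural features** — Pearson correlation structure of the six
  fractions (Bonferroni-flagged over the 15 pairwise tests) and
  principal components of the correlation matrix, PC1 being the
  nephron-loss axis (≈ 0.50·FIA + 0.55·FATA − 0.60·FITA).
- **Predictor ranking** — least-angle regression (LAR) of the
  per-subject eGFR slope on the six morphometric predictors
  (N_A, A_G, N_V, PC1–PC3); entry order ranks importance and the path
  terminates at the full OLS solution.
- **Longitudinal models** — a from-scratch generalized estimating
  equations (GEE) engine for Gaussian outcomes with independence or
  exchangeable working correlation, cluster-leverage bias-reduced
  sandwich inference, QIC model scoring
  (−2·Q(β̂; I) + 2·tr(Ω̂_I·V̂_R)) and a leave-one-subject-out
  predictive R²,  R²_pred = 1 − PRESS/SSR, with SSR taken from the
  time-only reference model.
- **Synthetic data** — labeled cortical sections with known ground
  truth (either exact-fraction 2D rasters or plane sections of a 3D
  Poisson sphere process, so stereological identities hold), plus
  clinical cohorts and correlated longitudinal eGFR trajectories that
  emulate a 56-subject observational study (25 FSGS / 19 MCD / 12 MN,
  baseline eGFR median 89.5, visits every 4–6 months up to 55 months).

Every estimator is testable against ground truth without any external
data; statsmodels and scikit-learn serve only as independent oracles in
the test suite.

## Worked example

```python
import nephromorph as nm

ds = nm.simulate_study(seed=7)          # 56-subject synthetic study
s = nm.summarize_cohort(ds)
# subjects: 56  diagnoses: {'FSGS': 25, 'MCD': 19, 'MN': 12}
# baseline eGFR median 87.0 (IQR 61.6-110.8)
# follow-up median 31.0 mo, pooled slope -4.23/yr

spec = nm.ModelSpec.clinical(
    structural=("FIA", "FATA", "A_G_um2", "N_A_per_mm2"), name="model2"
)
fit = nm.fit_gee(ds, spec)
print(fit.summary())
```

The summary prints the robust coefficient table; with this seed the
dominant terms are exactly the ones a structure–function analysis
expects — the baseline-eGFR coefficient is 0.967 (p < 0.0001), the
follow-up-time slope −0.279/month (p < 0.0001), and the fractional
atrophic tubule area carries a large level deficit
(−111.9 mL/min/1.73 m² per unit FATA, p = 0.0002) while A_G and N_A
add nothing independent. Scoring the same model:

```python
q = nm.loo_press_r2(ds, spec)
# QIC 576.37   R2_pred 93.7%
```

i.e. relative to a time-only model, the 17-covariate model removes ~94%
of the averaged squared leave-one-subject-out prediction error. A
shell-level run of the same pipeline:

```console
nephromorph simulate --seed 7 --out cohort/
nephromorph features cohort/ --out features/
nephromorph fit cohort/ --out models/
nephromorph rank cohort/ --out lar.csv
nephromorph report cohort/ --out report.md
```

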