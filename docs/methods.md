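# Methods

## FvCB model and temperature normalisation

Net CO₂ assimilation of a C3 leaf is modelled as the minimum of three gross
rates minus respiration in the light:

    A = min(Ac, Aj, Ap) − Rd
    Ac = Vcmax (Ci − Γ*) / (Ci + Kc (1 + O/Ko))
    Aj = J (Ci − Γ*) / (4 Ci + 8 Γ*)
    Ap = 3 Tp

with all gas concentrations as mole fractions (Ci, Kc, Γ* in µmol mol⁻¹; Ko
and O in mmol mol⁻¹), an assumed infinite mesophyll conductance (so fitted
parameters are apparent), and no glycolate-export term in the TPU limb — the
simplest standard form.  The electron transport rate J is the smaller root of
the non-rectangular hyperbola θJ² − (αQ + Jmax)J + αQ Jmax = 0 with defaults
θ = 0.7 and α = 0.425 mol e⁻ mol⁻¹ photons; curves are measured at
saturating irradiance so the fit is insensitive to both, and missing
irradiance is treated as saturating (J = Jmax).

Every parameter P is stored at 25 °C and rescaled to the leaf temperature of
each observation by a peaked Arrhenius factor

    f(T) = exp(Ha (T − Tr)/(Tr R T)) · (1 + exp((Tr ΔS − Hd)/(Tr R))) / (1 + exp((T ΔS − Hd)/(T R)))

(temperatures in kelvin, Tr = 298.15 K), which reduces to the pure Arrhenius
exponential when Hd/ΔS are absent.  The numeric Ha/Hd/ΔS per parameter and
the Rubisco kinetics (Kc25 = 404.9 µmol mol⁻¹, Ko25 = 278.4 mmol mol⁻¹,
Γ*25 = 42.75 µmol mol⁻¹, O = 210 mmol mol⁻¹) ship in an editable YAML file
(`leafspec/data/temperature_responses.yaml`): peaked Kattge & Knorr (2007)
parameters for Vcmax/Jmax, Harley et al. (1992) for Tp, Bernacchi et al.
(2001) activation energies for Rdark and the kinetics.  They are
configuration, not code — swapping the file changes the temperature
parameterisation of the whole pipeline.

## A–Ci fitting

Each curve (≥ 6 observations; the standard protocol yields 15 CO₂ setpoints
at a constant 30–32 °C leaf temperature) is fit by Gaussian maximum
likelihood.  The limb assignments are not fixed a priori: they fall out of
the optimisation, so the likelihood surface has kinks where an observation
switches limbs.  The optimiser is bounded trust-region least squares
(minimising the residual sum of squares is equivalent to maximising the
Gaussian likelihood) with 5 multi-starts jittered multiplicatively (seeded)
around heuristic initial values: Vcmax from inverting the Rubisco limb at
low Ci, Jmax from inverting the electron-transport limb at the CO₂-saturated
end, Tp = plateau/3, Rd = 1 µmol m⁻² s⁻¹.  Bounds: Vcmax25 ∈ [1, 500],
Jmax25 ∈ [2, 800], Tp25 ∈ [0.5, 100], Rd25 ∈ [10⁻⁴, 15] µmol m⁻² s⁻¹.

Uncertainty is Wald-type for determinism and speed: the covariance is the
inverse finite-difference Hessian of the negative log-likelihood over the
rate parameters and σ at the optimum.  Two small-sample choices matter at
n ≈ 15 and are deliberate: the σ used for standard errors and bands is the
degrees-of-freedom corrected √(SSR/(n−p)) rather than the MLE √(SSR/n), and
interval critical values come from the t distribution with n−p degrees of
freedom.  With the MLE-σ/normal-quantile combination, simulated 95 %
intervals covered the truth only 82–86 % of the time; with the df/t form
they cover 93–94 %.  Log-likelihood and AIC are still computed from the MLE
σ.  Fits are flagged `reliable=False` when the Hessian is singular, a
parameter sits on a bound, or the residual noise collapses; the covariance
then falls back to a pseudo-inverse and the intervals should not be trusted.

Whether a curve supports the TPU limb is decided by fitting with and without
Ap and keeping the lower AIC (AIC = 2k − 2 logL, k counting σ); exact ties
go to the model without Ap.  A known property of this rule, visible in
simulation: with no generating Ap limitation, the extra one-sided parameter
still wins AIC in ~11 % of 15-point curves (the flat Ap ceiling can chop the
top one or two noisy points), so the false-inclusion rate of Tp25 is of that
order; a strongly expressed plateau is detected in ≥ 92 % of curves.

The respiration parameter co-estimated during curve fitting stays internal
to the fit.  The Rdark25 trait comes only from dark-adapted measurements:
60 one-hertz CO₂-efflux samples are averaged (se = sd/√n — an assumption,
since instrument-level error models are out of scope) and divided by the
Rdark Arrhenius factor at the measurement temperature.

Confidence and prediction bands for a fitted curve (as drawn by
`ACiResults.plot`) are parametric-bootstrap percentiles: parameter vectors
drawn from the multivariate normal implied by the covariance (diagonal
fallback with a warning when it is not positive definite), pushed through
the forward model; the prediction band adds Gaussian noise draws with the
fitted σ.  Bands are widened, where needed, to contain the point-estimate
curve, so the nesting point ⊆ confidence ⊆ prediction holds by construction.

## Spectra processing

Reflectance arrives as wide CSV with 3–4 replicate scans per leaf over
350–2500 nm.  Replicates are averaged per wavelength, then linearly
interpolated onto a 1 nm grid restricted to 500–2400 nm (1901 predictors),
trimming the noisy detector edges; both window and step are configuration.
Values are clipped to [0, 1.2] (small >1 artifacts from imperfect white
references are tolerated and flagged).  No smoothing and no replicate
outlier rejection are applied by default; averaging and regridding are both
linear, so their order does not matter.

## Ensemble PLSR

One model per trait.  Right-skewed capacity traits (Vcmax25, Jmax25) are
square-root transformed before regression; Tp25 and Rdark25 are not.  Single
fits are PLS1 by NIPALS (via scikit-learn) on centred predictors without
unit-variance scaling — reflectance columns share units, and scaling would
distort spectral shape.

**Component selection.**  The training set is split 70/30 at random 1000
times; every split's 70 % part is fit at each candidate component count and
scored by PRESS on its own 30 % part.  The chosen count is the smallest k
whose mean PRESS is within one standard error of the minimum, where the
standard error is sd/√1000 of PRESS at the minimising count (a plain-sd
variant is available; the sd/√n reading keeps the rule's bite at 1000
repetitions).  Per-iteration models reuse one NIPALS fit per split — the
components are nested, so the k-component regression vector is
W_k (P_kᵀW_k)⁻¹ q_k from the leading k columns.

**Ensemble.**  With the count fixed, 1000 sub-models are each fit on a fresh
random 70 % subset; each stores its regression vector and the RMSE on its
own 30 % holdout (transformed scale).  Per-iteration seeds derive from the
master seed through a counter-based SeedSequence scheme, making the whole
train/predict path bit-reproducible.  When replaying species/site splits the
component count selected on the random split is reused rather than
re-selected, so the three designs differ only in their partition.

**Prediction.**  Every sub-model predicts on the transformed scale and is
back-transformed (squared, after clipping negative square roots to zero)
*before* aggregation, so the ensemble spread propagates through the
nonlinearity.  The reported mean is the average of back-transformed
predictions; the 95 % confidence interval is the 2.5/97.5 percentile of the
1000 back-transformed predictions; the prediction interval adds, per
sub-model, one Gaussian draw with that sub-model's holdout sd before
back-transforming.  Intervals are widened if necessary so mean ∈ CI ⊆ PI.
Because each holdout sd already contains some ensemble-spread error, the
prediction interval mildly over-covers when model error dominates noise;
on synthetic data with iid noise its empirical coverage is 93–97 %.

**Interpretation.**  VIP for one fit is
VIP_j = √(p Σ_k SS_k (w_jk/‖w_k‖)² / Σ_k SS_k) with SS_k the response
variance captured by component k; squared VIPs average to one, and ensemble
VIP is the mean over sub-models.  Coefficient summaries report the
per-wavelength mean and 2.5/97.5 percentile band of the 1000 regression
vectors (transformed scale) with the VIP > 1 mask; the difference between
two ensembles is taken per paired sub-model index, with wavelengths flagged
significant where the percentile band excludes zero, plus the Pearson
correlation of the two mean coefficient vectors.

## Validation designs and metrics

- *random*: leaf-level simple random sample, ⌊0.8n⌋ training.
- *species*: species present in the newest campaign and absent from all
  earlier ones are "new"; 30 % of them (round half away from zero) are
  sampled and **all** their leaves validate, so validation species never
  occur in training.
- *site*: Panama observations train, Brazil observations validate;
  deterministic.  Traits with no Brazil data are refused with an error and
  sparse ones (< 15 validation leaves) warn.

Metrics on the validation set: RMSE; %RMSE = 100·RMSE / (trait max − min
over the *whole* dataset, before any split); and R² = 1 − SSres/SStot —
chosen over squared Pearson correlation because it penalises bias; it is not
clipped and can be negative.

## Synthetic data generator

The generator emulates the statistical structure the analysis relies on, not
leaf biophysics:

- **Traits**: hierarchical multivariate log-normal.  Species log-means are
  drawn around global means (Vcmax25 55, Jmax25 95, Tp25 6.5, Rdark25
  0.7 µmol m⁻² s⁻¹; log-sds 0.45/0.45/0.40/0.50) with 60 % of log-variance
  at the species level, then leaves around their species mean; the shared
  correlation matrix has Vcmax–Jmax 0.9, Vcmax–Tp 0.8, Vcmax–Rdark 0.6
  (remaining pairs 0.75/0.55/0.50; positive definite).  Tp25 is present for
  32 % of non-Brazil leaves, matching the fraction of curves whose fitting
  supports an Ap limb.  A Brazil-like site (15 % of species) is shifted low
  in capacity (−0.55 log units), has no Rdark25 and almost no Tp25, so the
  site split's code paths — including its refusals — are exercised.
- **Curves**: the 15-setpoint chamber CO₂ sequence (400 → 50 → 1800
  µmol mol⁻¹), Ci = 0.8 × setpoint (a fixed stomatal drawdown; the pipeline
  needs realistic Ci ranges, not stomatal realism), leaf temperature drawn
  from {30, 31, 32} °C, saturating irradiance, and additive Gaussian noise
  with sd 0.5 µmol m⁻² s⁻¹ — consistent with the few-percent relative
  uncertainties typical of curve fitting.  Dark-respiration series use 60
  samples with sd 0.45 µmol m⁻² s⁻¹ around the temperature-scaled rate.
- **Spectra**: a smooth green-vegetation baseline (green bump, red edge,
  NIR plateau, SWIR decline) minus Gaussian absorption features near 680,
  1450, 1940 and 2100 nm whose depths are linear in the standardised traits
  (each trait dominating one band but loading on several), plus spatially
  correlated noise (50 nm length-scale, sd 0.004) and white noise
  (sd 0.002), clipped to [0, 1].  Replicate scans add white jitter.

What passing tests on these data do **not** show: real spectra–trait links
are indirect (shared covariance with pigments, water, structure), spectra
have instrument-specific artifacts, and trait distributions have phylogenetic
structure beyond a two-level hierarchy.  The generator's linear trait→depth
map makes the recovery problem easier than nature's, so end-to-end R² here
(~0.9+) exceeds what field campaigns report (~0.6–0.9); the end-to-end check
is a regime test, not a performance claim.

## Problem sizes and numerical choices

Simulation-based checks use 200 curves (recovery, AIC selection), ensembles
of 200 sub-models and 200 PRESS iterations, and one full synthetic campaign
(~280 leaves, 1901-wavelength spectra) — sizes at which every Monte-Carlo
margin in the tests is stable while the whole suite runs in a few minutes.
Optimiser ties in model selection resolve to the simpler model; percentile
bands use linear-interpolation percentiles; degenerate inputs (constant
response, singular Hessians, empty holdouts, traits absent at a site) raise
or flag rather than silently proceeding.

## Known limitations

- Wald intervals understate the extra variance from limb reassignment near
  co-limitation; profile or bootstrap intervals would be heavier but better
  calibrated for leaves measured close to an Ac/Aj transition.
- AIC's ~11 % false Tp inclusion on 15-point curves (above) means
  population-level Tp25 availability is slightly overstated.
- The prediction-interval construction double-counts a little model error by
  design (each sub-model's holdout sd includes ensemble spread), trading
  sharpness for safety.
- Mesophyll conductance, C4 photosynthesis, stomatal models, light-response
  fitting and radiative-transfer realism are out of scope.
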