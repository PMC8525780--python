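# leafspec

Estimation of the four leaf-level parameters that drive modelled C3 net
photosynthesis — the maximum Rubisco carboxylation rate *V*<sub>cmax25</sub>,
the maximum electron transport rate *J*<sub>max25</sub>, the triose-phosphate
utilisation rate *T*<sub>p25</sub> and dark respiration
*R*<sub>dark25</sub>, all at the 25 °C reference — from two complementary
measurement streams:

1. **Gas exchange.** A–C<sub>i</sub> curves are fit by Gaussian maximum
   likelihood to the Farquhar–von Caemmerer–Berry (FvCB) model,
   `A = min(Ac, Aj, Ap) − Rd`, with every observation rescaled to its own
   leaf temperature through peaked Arrhenius functions, Wald uncertainty
   intervals, and AIC-based selection of whether the TPU limb (and hence a
   *T*<sub>p25</sub> estimate) is supported by a curve.  Dark-adapted 1 Hz
   CO₂-efflux series are averaged and temperature-normalised into
   *R*<sub>dark25</sub>.
2. **Reflectance spectroscopy.** Leaf reflectance (500–2400 nm, 1 nm grid)
   predicts those traits through ensemble partial least-squares regression:
   the component count is chosen by 1000× resampled PRESS with the
   one-standard-error rule, 1000 sub-models are fit on random 70% subsets,
   and predictions carry percentile confidence intervals (ensemble spread)
   and prediction intervals (spread + residual noise).  Models are
   interpreted through coefficient bands and VIP scores, and validated under
   three split designs of increasing difficulty: random leaves, held-out
   species, and a held-out site.

The target audience is plant ecophysiologists and remote-sensing/chemometrics
researchers building spectra–trait models, particularly for hyperdiverse
tropical canopies where measuring every species by gas exchange is
infeasible.  A synthetic-data generator reproduces the statistical structure
of such a campaign (hierarchical multi-species trait covariance, the
standard 15-setpoint CO₂ sequence at 30–32 °C, trait-linked absorption
features in the spectra) so the entire pipeline is testable without field
data.

## Worked example

Fit one (synthetic) A–C<sub>i</sub> curve, letting AIC decide whether the
TPU limb is warranted:

```python
import leafspec as ls
from leafspec.synthetic import gen_aci_curve

curve = gen_aci_curve(
    {"Vcmax25": 62.0, "Jmax25": 118.0, "Rdark25": 1.1, "Tp25": 7.0},
    noise_sd=0.5, Tleaf=31.0, seed=4, leaf_id="demo_leaf",
)
res = ls.ACiModel(curve).fit_select(seed=0)
print(res.summary())
```

```
FvCB A-Ci fit: leaf demo_leaf  (n = 15)
  Ap limb included: True   reliable: True
  logLik = -9.096   AIC = 28.191   sigma = 0.5182
  param       estimate        se  ci95 low  ci95 high
  Vcmax25       61.955     1.303    59.088     64.822
  Jmax25       126.541    19.441    83.752    169.331
  Tp25           7.008     0.102     6.785      7.232
  Rd25           1.133     0.204     0.683      1.583
  limitation states: {'Ac': 10, 'Ap': 4, 'Aj': 1}
```

The generating values (62, 118, 7.0, 1.1 µmol m⁻² s⁻¹) are recovered within
their 95 % intervals; *J*<sub>max25</sub> is the least certain because only
one observation is electron-transport limited once the plateau is
TPU-limited.  `res.plot()` draws the curve with the 95 % confidence and
prediction bands, and `res.intervals(grid)` returns them numerically.

Train and validate a spectra–trait ensemble on a full simulated campaign:

```python
from leafspec.synthetic import gen_traits, gen_spectra
from leafspec.workflow import assemble_dataset, evaluate_split, fit_curves
from leafspec.validation import reports_to_dataframe

traits = gen_traits(seed=42)                       # ~280 leaves, 50 species, 3 sites
curves = [gen_aci_curve(r, noise_sd=0.5, seed=100 + i) for i, r in traits.iterrows()]
fits_df, _ = fit_curves(curves, seed=0)            # refit traits from the curves
spectra = gen_spectra(traits, seed=43)
ds = assemble_dataset(fits_df, spectra, traits[["leaf_id", "species", "site", "campaign"]])

split = ls.make_random_split(ds, "Vcmax25", frac=0.8, seed=7)
report, ens, preds = evaluate_split(ds, "Vcmax25", split, n_iter=200, seed=7, max_ncomp=20)
print(ens.summary()); print(reports_to_dataframe([report]).to_string(index=False))
```

```
Ensemble PLSR: trait Vcmax25
  transformation: sqrt   components: 8
  sub-models: 200 (train_frac=0.7, seed=7)
  median sub-model holdout sd (transformed scale): 0.4496
  wavelengths with VIP > 1: 532 of 1901

  trait  split  n_obs  n_val  n_comp    rmse      range  pct_rmse       r2
Vcmax25 random    284     57       8 5.71188 157.946139  3.616347 0.964204
```

The PRESS/one-SE rule picked 8 latent components; on the 57 held-out leaves
the ensemble explains 96 % of the *V*<sub>cmax25</sub> variance with an RMSE
of 5.7 µmol m⁻² s⁻¹ (3.6 % of the whole-dataset trait range).  Each row of
`preds` carries the ensemble mean with its 95 % confidence and prediction
intervals.  `ens.coefficient_summary()` and
`leafspec.pls.coefficient_difference(ens_a, ens_b)` expose the per-wavelength
coefficient bands, VIP > 1 regions and between-trait coefficient contrasts
used for interpretation; `make_species_split` / `make_site_split` implement
the two harder validation designs (the site split refuses traits with no
observations at the held-out site).

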