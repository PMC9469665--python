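# phenolkin

Kinetic analysis of batch-culture phenol biodegradation: logistic biomass
growth, Haldane (Andrews) substrate-inhibition growth kinetics, and
modified-Gompertz degradation curves, estimated from replicated time-series
by SSR-minimising multistart nonlinear least squares.

Phenol is a common industrial pollutant that some soil bacteria — including
plant-growth-promoting strains such as *Curtobacterium flaccumfaciens* — can
use as a sole carbon source. Characterising how fast a strain grows on and
removes phenol, and at what concentration phenol starts inhibiting its own
degradation, comes down to three standard models fitted to batch data:

* **Logistic growth** for each OD600 curve,
  `dX/dt = μ_m X (1 − X/X_m)`, with closed form
  `X(t) = X_m / (1 + (X_m/X0 − 1) e^{−μ_m t})`;
* **Haldane substrate inhibition** for the specific growth rate versus
  initial phenol concentration,
  `μ(S) = μ_max S / (K_s + S + S²/K_i)`,
  a unimodal curve peaking at `S* = √(K_s K_i)`;
* **Modified Gompertz** for residual phenol,
  `S(t) = S0 (1 − exp(−exp((R_m e/S0)(λ − t) + 1)))`,
  parameterised by the maximum degradation rate `R_m` and lag time `λ`.

All fits minimise the sum of squared residuals with a bounded trust-region
least-squares solver inside a seeded multistart, so every result is exactly
reproducible. A forward simulator of the whole experiment (replicated
curves, multiplicative Gaussian measurement noise, per-curve sub-seeding)
makes every estimation stage testable against known ground truth.

The package is aimed at microbiologists and environmental engineers fitting
batch biodegradation data, and at anyone needing a tested reference
implementation of these three models and their analytic identities.

## Worked example

Simulate a six-concentration batch experiment (200–1200 mg/L phenol,
triplicates, 3 % measurement noise) and run the full analysis chain:

```bash
phenolkin simulate --out sim --seed 7 --noise-cv 0.03
phenolkin pipeline --growth sim/growth.csv --degradation sim/degradation.csv \
                   --rate sim/rate.csv --out report --seed 7
```

which prints (abridged):

```
Haldane substrate-inhibition fit
--------------------------------
 mu_max_per_h  K_s_mg_per_l  K_i_mg_per_l      ssr  ...  n_points rate_source
     2.174065       0.64839     299.35781 0.000909  ...         7    rate_csv

Modified Gompertz degradation fits
----------------------------------
condition  phenol_mg_per_l  R_m_mg_per_l_h  lambda_h         ssr
      200            200.0        5.299956 11.835666   42.812271
      400            400.0        6.774887 14.995404  145.161966
      700            700.0        8.969941 10.115362  929.629667
      ...
```

The Haldane fit recovers the generating `μ_max = 2.28 h⁻¹` and
`K_i = 291 mg/L` to within a few percent despite the 3 % noise (`K_s` is the
least identified of the three because the sampled concentrations all lie
above the rate peak); each Gompertz row recovers its generating
`(R_m, λ)` — e.g. 9.0 mg/L/h and 10.2 h at 700 mg/L. The report directory
holds the four tables as CSV (`logistic_fits.csv`, `haldane_fit.csv`,
`gompertz_fits.csv`, `removal_summary.csv`), a human-readable `summary.txt`,
and a `run_manifest.json` recording seed and settings. With
`--noise-cv 0` every table reproduces the generating parameters to better
than 0.1 %.

The same analysis is available as a library, statsmodels-style:

```python
from phenolkin import HaldaneModel, simulate_rate_points, default_truth

points = simulate_rate_points([50, 100, 200, 400, 700, 1000, 1200],
                              default_truth(), noise_cv=0.0, seed=1)
result = HaldaneModel(points).fit(n_restarts=20, seed=1)
print(result.summary())     # estimates, std errs, SSR, convergence
```

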