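# Methods

## Models

**Logistic growth.** Biomass in a batch reactor is modelled by
`dX/dt = μ_m X (1 − X/X_m)` with initial density `X0`, maximum specific
growth rate `μ_m` (h⁻¹) and carrying capacity `X_m` (OD600 units). The code
evaluates the integrated form in the overflow-safe parameterisation
`X(t) = X_m / (1 + (X_m/X0 − 1) e^{−μ_m t})`, algebraically identical to
`X0 e^{μ_m t} / (1 − (X0/X_m)(1 − e^{μ_m t}))`. Only growth branches are
admitted (`X0 < X_m` strictly); decaying logistic curves are rejected at the
parameter level because every curve analysed here is a growth curve.

**Haldane (Andrews) substrate inhibition.**
`μ(S) = μ_max S / (K_s + S + S²/K_i)` with all three parameters strictly
positive. The curve is unimodal with analytic peak `S* = √(K_s K_i)` and
peak value `μ* = μ_max / (1 + 2√(K_s/K_i))`; as `K_i → ∞` it degrades to the
Monod form `μ_max S / (K_s + S)`. Both identities are exercised in the test
suite (the Monod limit at `K_i = 10¹²` to 10⁻⁶ relative).

**Modified Gompertz degradation.** Residual substrate follows
`S(t) = S0 (1 − exp(−exp(a)))` with exponent argument
`a = (R_m e / S0)(λ − t) + 1`. This grouping — maximum depletion rate `R_m`
scaled by `e/S0` — is the standard modified-Gompertz exponent: it gives
`S(0) ≈ S0` whenever the lag is appreciable, `S(∞) = 0`, a maximum depletion
rate exactly `R_m` attained at the inflection time `t = λ + S0/(R_m e)`
where `S = S0 (1 − 1/e)`, and `λ` as the tangent intercept of the inflection
point. Compact renderings of this formula are often typeset ambiguously
(e.g. "R_m S0 e (λ−t) + 1"); any other grouping fails the boundary
conditions, so this one is used throughout. Euler's constant enters at full
floating precision. Negative fitted `λ` is accepted with a warning — noisy
short-lag data can produce it — but flagged as physically dubious.

Units: phenol concentrations are mg/L; "ppm" in dilute aqueous context is
treated as the same unit.

## Estimation

**Objective.** All fits minimise the unweighted sum of squared residuals
(SSR) between the replicate-mean series and the model curve. Replicates are
aggregated to the mean before fitting, matching the mean ± SD convention of
batch studies; pooled-residual fitting over all replicates is available via
`pooled=True`.

**Optimizer.** `scipy.optimize.least_squares` (trust-region reflective,
box-bounded, `xtol = ftol = gtol = 1e-12`) inside a seeded multistart. The
first start is a data-driven heuristic; the remaining starts (20 by default)
are drawn log-uniformly over the bounds (uniformly for parameters that may
be negative, i.e. `λ`) from a `numpy` generator seeded by the caller. The
start sequence is prefix-stable, so increasing the restart count with the
same seed can only improve the best SSR; exact ties keep the earliest
restart. Scalar objectives without a residual vector fall back to
Nelder–Mead. Everything is bit-deterministic given (data, bounds, restarts,
seed).

**Bounds.** `μ_max, μ_m ∈ (0, 10] h⁻¹`, `K_s ∈ (0, 10⁴] mg/L`,
`K_i ∈ (0, 10⁶] mg/L`, `X0, X_m ∈ (0, 10]` OD, `R_m ∈ (0, 100] mg/L·h`,
`λ ∈ [−50, 200] h` — generous relative to any plausible batch culture. A
fitted `K_i` within 1 % of its upper bound flags the result as weakly
identified (typical when the data contain no inhibition signal, i.e. are
effectively Monod, or sample only one side of the rate peak).

**Heuristic starts.** Logistic: `X0` = first mean, `X_m` = max mean, `μ_m`
from the log-phase slope (0.1 h⁻¹ if no log phase is detectable). Haldane:
`μ_max = 1.2·max μ`, `K_s` = concentration at half-maximum on the rising
limb (interpolated), `K_i = S_peak²/K_s`. Gompertz: `R_m` = steepest
finite-difference depletion rate, `λ` = last time the mean is still at
≥ 95 % of `S0`.

**Log-phase detection.** Among contiguous windows of ≥ 4 replicate-mean
points lying within 5–70 % of the series maximum, the window maximising the
R² of ln(mean) versus time is selected (ties → longest, then earliest); the
specific growth rate is the OLS slope of `ln(X/X0)` over that window, which
is invariant to biomass unit rescaling. The 5–70 % band and minimum window
length are heuristic conventions, exposed as configuration; there is no
universal definition of "the" log phase. A consequence worth knowing:
with 12-h sampling, fast growers (μ_m ≈ 0.3 h⁻¹ from a low inoculum) pass
through the admissible band between sampling times and no window exists —
the pipeline then records the condition as unextractable rather than
guessing. Hourly sampling resolves every default-truth condition.

**What is and is not fitted.** In the Gompertz fit `S0` is held at the known
initial concentration (only `R_m` and `λ` are estimated), because the
initial dose is an experimental setting, not an observable to infer. In the
logistic fit `X0` *is* estimated (started at the first observation), since
the effective in-medium starting density after inoculation is generally not
known precisely.

**Uncertainties.** Results carry asymptotic standard errors from the
Gauss–Newton covariance `s²(JᵀJ)⁻¹` at the optimum. These are linearisation
approximations and are reported as diagnostics only; no confidence intervals
or profile likelihoods are constructed.

## Synthetic experiment generator

The simulator emulates a six-concentration batch design: initial phenol at
200, 400, 700, 800, 1000 and 1200 mg/L; OD600 sampled every 12 h over
0–96 h; residual phenol every 6 h over 0–108 h (long enough to cover full
degradation of the mid-range cultures at ~103 h); triplicate cultures; and
multiplicative Gaussian noise with CV 3 % — the replicate scatter implied by
removal-table entries of the form "63 ± 1.89 %". Biomass is floored at
10⁻⁴ OD and substrate at 0, so no impossible negative measurement is ever
emitted. A single homoscedastic-relative CV is the simplest noise model
consistent with such tables; a per-condition CV table could replace it and
is left as configuration.

The canonical ground truth is one logistic pair `(μ_m, X_m)` and one
Gompertz pair `(R_m, λ)` per concentration plus one global Haldane triple
`(μ_max, K_s, K_i) = (2.28 h⁻¹, 4.3 mg/L, 291 mg/L)`, with `X0 = 0.05` OD
for every growth curve (a typical washed-inoculum density; configurable).
Note the fixture is deliberately taken at face value and is not internally
consistent as a single mechanistic system: the per-concentration logistic
`μ_m` values (0.05–0.30 h⁻¹) do not lie on the Haldane curve (≈ 1.3 h⁻¹ at
200 mg/L), and `λ` is not monotone in concentration. The growth, rate and
degradation stages are therefore validated independently, each against its
own generating parameters.

Randomness is split per curve by sub-seeding a generator from
(seed, data-kind, concentration), so adding or removing a condition never
perturbs the noise of the others, and every output is reproducible from the
one dataset seed.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: systematic (non-Gaussian, autocorrelated, or
heteroscedastic-beyond-relative) measurement error; abiotic phenol loss;
replicate-to-replicate biological variation in the kinetic parameters
themselves; pH/temperature dependence (condition screens are representable
only as extra labels); and metabolite dynamics. Parameter recovery on
synthetic data demonstrates that the estimation machinery is correct and
well-conditioned under the stated noise model, not that the models are
adequate for any particular organism.

## Pipeline

`run_full_pipeline` chains: tidy-CSV ingestion (strict schema validation
with line-numbered errors) → per-concentration logistic fits → log-phase
rate extraction → Haldane fit → per-concentration Gompertz fits →
percent-removal summary at a fixed time (default 48 h, linearly
interpolated when off-grid; overshoots from noise clamp to 0 % removal with
a warning) → four report CSVs, a text summary and a JSON run manifest. A
failure in one condition is recorded in the report's error map and the
remaining conditions proceed. Outputs are byte-identical across reruns with
the same config.

The Haldane stage accepts two sources of (S, μ) pairs: an independent rate
CSV when provided, otherwise the rates extracted from the growth curves.
The rate CSV path is preferred when specific growth rates were measured in
dedicated assays (and is what `phenolkin simulate` writes from the Haldane
truth); extraction keeps the chain self-contained when only OD curves
exist. Fewer than four surviving rate points skip the stage with a warning
rather than fitting an unidentifiable three-parameter model.

The percent-removal summary of simulated data reflects the Gompertz model
value (e.g. 48.4 % at 48 h for the 700 mg/L fixture curve), which is a
different quantity from any empirically observed removal percentage of a
particular strain — observed values fold in deviations from the fitted
model.

## Problem sizes and defaults

Noise-free recovery checks run the full 20-restart multistart (each fit
takes well under a second). The stochastic-robustness check uses 200
simulation seeds at 3 % CV with triplicates and 2 restarts per fit —
heuristic starts are reliable at this noise level, and the reduced restart
count keeps the 200-seed sweep to a few seconds while leaving medians far
from the 10 % criterion. The CLI interface is a thin layer over the library;
all analysis is available programmatically.
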