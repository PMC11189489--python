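# Methods

This note documents the models, estimators and design choices behind
`depotpk`, and what its synthetic-data validation does and does not
establish.

## Linker release model

β-eliminative linker cleavage is first order, so release is fully described
by `k_rel` (1/h) with `t½ = ln 2 / k_rel`. Cleavage is specific-base
catalyzed: the rate is proportional to hydroxide activity, hence
`k' = k · 10^(pH' − pH)`. Two corrections between tissues are exposed:

- an explicit **fold-factor** (default 1.5, the empirically observed slowing
  of cleavage in tumor vs subcutaneous tissue), the default path because the
  tumor interstitial pH offset is rarely known numerically; and
- the **ΔpH path**, for when it is (1.5-fold corresponds to ~0.17 pH units).

Temperature is metadata only — all reference half-lives are 37 °C values and
no Arrhenius model is attempted. The shipped registry (modulators
4-ClPhSO2 / PhSO2 / 4-MePhSO2 / MeSO2 with t½ = 9 / 27 / 40 / 160 h at
pH 7.4) holds published characterization values as named fixtures; a
YAML/JSON registry can replace it. A linker's `t_RG` (reverse-gelation time
of the carrier gel) is carried as a scalar and validated to exceed the
release half-life; no gel chemistry is modeled.

## Depot → tissue cascade

The local free-drug amount follows the Bateman solution of
`dA/dt = −k_rel A`, `dB/dt = k_rel A − k_loc B` with `A(0) = dose`,
`B(0) = 0`. The degenerate branch (`B = dose·k t e^(−kt)`) engages when the
rates agree within 1e−9 relative — far from any physiological separation but
close enough to keep the general branch free of catastrophic cancellation
(verified by a branch-continuity test). Cumulative clearance has its own
closed form, so `depot + free + cleared = dose` holds to machine precision.

Concentration output divides by a local distribution volume, default
0.15 mL — the mass of the ~12 mm biopsy plug used for tissue sampling, an
assumption rather than a measured volume. No systemic compartment is
modeled: the data this package treats are local tissue levels, and
everything leaving the local tissue (diffusion out plus elimination) is
lumped into "cleared". When the package's examples quote a free-drug
clearance for a small-molecule payload, they borrow the measured 1.5 h
tissue half-life of the fluorescent payload surrogate, since the payload's
own tissue clearance is not separately measured. Time-above-threshold is
computed by bracketing the unimodal closed form around the analytic peak and
refining with Brent root finding; a window still open at the horizon
(default 100 slow half-lives) is truncated and flagged.

## Synthetic biopsy cohorts

Each simulated sample draws a hidden recovery fraction
`E ~ lognormal(mean = r̄·(1 + s·t), CV)` shared by all of the sample's
channels, then independent multiplicative measurement noise per channel
(Gaussian CV, clipped at ±3 SD; clipping is symmetric so the noise
multiplier has exactly unit mean). Defaults: recovery mean 0.7 (the
separations themselves retain >98%, so losses are dominated by harvesting;
0.7 is a realistic harvest efficiency chosen once), recovery and signal CVs
10%, drift `s = 0`. Signals are arbitrary fluorescence units; only ratios
are meaningful. t = 0 samples are simulated as actually harvested samples,
since the normalization references measured t0 ratios.

Three named designs reflect the studies being emulated:

- intratumoral mouse: harvests at 0, 8, 24, 32, 48 h, 3 tumors/time;
- subcutaneous rat: 7 harvest times over 3 weeks (0, 2, 4, 7, 10, 14,
  21 d — one rat per time, times chosen once to span ~3 half-lives of a
  week-scale linker) × 4 depot sites;
- free-probe clearance: six temporal sites on one animal at 0–6 h
  (~4 half-lives of an ~1.5 h clearance).

The extract (free drug) channel follows the depot→tissue cascade evaluated
at unit dose, so pellet and extract pools are mutually consistent by
construction. Homogenization/centrifugation losses are not modeled as
separate mechanisms (they are lumped into `E`), and there is no spectral
bleed-through between channels.

## Ratio-metric estimator

The estimator is OLS of `y = ln[(payload/fl) / (payload/fl)_t0]` on t over
individual samples (not time-point means — preserves degrees of freedom at
n = 3/time; group-mean fitting can be emulated by passing aggregated
frames). The t0 reference is the arithmetic mean of the t0 ratios (chosen
for stability over a single reference sample; the reference only shifts the
intercept, not the slope). `k̂ = −slope`; R², the slope SE, and a 95% CI on
t½ via the delta method on `ln 2 / k` (floored at 0) are reported. A fitted
slope ≥ 0 yields a flagged no-release result with a `t½ = ∞` sentinel.
Records with non-positive marker signal or ratio are rejected with logged
warnings; fewer than three distinct surviving time points is an error.

The extract-pool fit drops points before the cascade-predicted peak time
(computed from the pellet fit's rate and the supplied tissue clearance),
because a mono-exponential is valid only on the terminal phase; it is not
t0-referenced (free drug starts at zero).

Known estimator property: with the 48 h intratumoral design at 10% CVs the
per-cohort slope uncertainty at t½ = 63 h is ~19% relative, so the mean of
`t½ = ln 2 / k̂` across replicate cohorts carries a small positive Jensen
bias (~+4%); the tests bound it below 5%. Estimates are unbiased in slope;
the bias is purely the reciprocal transform at finite information.

## Tumor growth, TG/TGI, additivity, survival

Volumes follow `V(t) = V₀ exp(g_i t − interaction·Σ_j kill_j·∫C_j)` with
`g_i` lognormal across animals (default CV 10%) and multiplicative
measurement noise (default CV 10%, clipped at ±3 SD). Defaults are
calibrated to the emulated studies: V₀ = 265 mm³ at treatment and
g = 0.105/day, which takes a control tumor to the 2000 mm³ humane endpoint
in ~19 days. Trajectories record the first measurement at or above the
threshold and then stop. RNG streams are split per animal from the group
seed, so enlarging a group never perturbs existing animals.

`TG = AUC(treated median curve) / AUC(vehicle median curve)` by trapezoid
over a day window; `TGI = 100(1 − TG)`. Choices, each exposed as an option:

- **Window**: treatment start to the last day every compared group retains
  ≥ 3 animals (survivor bias otherwise inflates treated AUCs once vehicle
  animals reach endpoint).
- **Curves**: group medians (matching median ± MAD presentation); per-animal
  variants can be formed by passing single-animal "groups".
- **Baseline**: by default each curve is shifted by its day-0 median before
  integration, so TG measures growth rather than carried-over starting
  volume. `baseline="none"` integrates raw medians.

The additivity index is `TG_calc / TG_obsd` with `TG_calc = TG_A·TG_B`;
index < 1 infra-additive, ≈ 1 additive, > 1 supra-additive. Because an
exact 1 is measure-zero under noise, indices within [0.8, 1.25] are
classified "additive" (configurable).

### The independent-action (Bliss) null calibration

Independent kills add in the exponent, so *pointwise* volume fractions
multiply exactly: `V_AB/V_veh = (V_A/V_veh)(V_B/V_veh)`. Ratios of AUCs do
not inherit this exactly when the kill accrues across the window: for kills
spread over weeks the AUC-based index deviates from 1 even noise-free (by
tens of percent at strong effect sizes, in a direction that depends on
baseline anchoring). The null-calibration experiment therefore validates the
index in the regime where the product rule is exact: each agent is delivered
as a short pulse (complete before the first on-treatment measurement), the
AUC window starts at that first on-treatment day, and integration is
unanchored. Under those conditions the noise-free index is exactly 1 at any
effect size, so the calibration runs at the studied single-agent strengths
(TG 0.38 and 0.33). The replicate study (500 cohorts, n = 6/group, 10%
volume CV, no inter-animal growth spread so measurement noise is the only
stochastic term) yields a mean index of ~1.00 with a ±0.004 CI; the small
residual (~+0.2%) is the Jensen curvature of a ratio of noisy AUCs. The
corollary — that week-scale depot exposures make the fractional-AUC index an
imperfect Bliss statistic even without any pharmacological interaction — is
a genuine limitation of AUC-based additivity indices worth keeping in mind
when indices near 1 are interpreted.

### Survival

Time-to-threshold (default 2000 mm³) is the log-linearly interpolated first
crossing (exact for exponential growth). Animals never reaching threshold
are extrapolated by fitting exponential growth to their terminal segment
above 1000 mm³ (≥ 2 points, positive slope required) — the "estimated
exponential growth" convention for summarizing controls — or censored at
last observation with a warning. Kaplan–Meier medians use the product-limit
convention "first time S(t) ≤ 0.5" (so four uncensored times 10/20/30/40
give a median of 20); a curve never reaching 0.5 is reported as the open
bound "> last time".

## What the synthetic validation does and does not show

Passing tests establish that the estimators recover the parameters of data
generated under the assay's own assumptions (shared recovery, multiplicative
noise, first-order kinetics, exponential growth), at the studied designs and
noise levels, and that the analysis conventions are internally consistent
(mass balance, Bliss null, closed-form survival). They do not establish
robustness to structure real tissue data may add — spectral bleed-through,
non-lognormal recovery, Gompertzian growth saturation, immune-mediated
effects, or toxicity-driven dropout — none of which are modeled.

## Problem sizes

Monte-Carlo checks use 200–500 replicate cohorts (chosen to put the standard
error of replicate means well below the tolerances being asserted) and the
acceptance pipeline simulates 500 four-arm cohorts; the whole suite runs in
well under a minute on one core.
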