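# depotpk

Tissue pharmacokinetics and anti-tumor efficacy analysis for long-acting
intratumoral (IT) drug depots.

Locally injected drugs normally leak out of tumors within hours. One way
around this is to tether the drug to hydrogel microspheres through a
self-cleaving β-eliminative linker: the particles sit where they are injected
and release native drug at a chemically programmed first-order rate, bathing
the tumor for days to weeks. `depotpk` implements the quantitative machinery
such a program needs, for scientists analyzing (or planning) depot
pharmacokinetics and efficacy studies:

- **Linker kinetics** (`depotpk.kinetics`) — conversions among half-life,
  rate constant and fraction remaining, `k = ln 2 / t½`; pH scaling of the
  base-catalyzed cleavage (`k' = k·10^(pH'−pH)`); the empirical ~1.5-fold
  tumor-vs-subcutaneous slowing; a registry of reference linkers
  (t½ = 9, 27, 40, 160 h at pH 7.4, 37 °C).
- **Depot → tissue exposure** (`depotpk.depot`) — the two-step first-order
  cascade in closed form (Bateman),
  `B(t) = D·k_rel/(k_loc−k_rel)·(e^(−k_rel t) − e^(−k_loc t))`,
  with peak exposure (C_max, t_max), time above a threshold concentration,
  and exact mass balance.
- **Synthetic biopsies** (`depotpk.biopsy`) — destructive-sampling cohorts of
  dual-labeled microspheres: a stable marker and a releasable payload share
  each sample's hidden recovery fraction, so their ratio is recovery-free.
- **Ratio-metric estimation** (`depotpk.ratiometric`) — the
  internal-standard half-life estimator: OLS on
  `ln[(payload/marker) / (payload/marker)_t0]` vs t, with R², slope SE and a
  delta-method CI on t½; a naive unnormalized estimator for bias comparison;
  two-pool (pellet/extract) concordance fits.
- **Efficacy analysis** (`depotpk.growth`) — exponential tumor growth with
  concentration-driven log-kill, `dV/dt = (g − k_kill·C(t))·V`; median ± MAD
  group curves; fractional tumor growth `TG = AUC_treated / AUC_vehicle` and
  `TGI = 100·(1 − TG)`; the Bliss-style additivity index
  `TG_calc / TG_obsd` with `TG_calc = TG_A·TG_B`; time-to-2000 mm³ survival
  with log-linear interpolation, exponential extrapolation above 1000 mm³,
  and Kaplan–Meier medians.

## Worked example

Each script in `examples/` exercises one capability. For instance:

```bash
$ python examples/04_two_pool_fit.py
true release t1/2: 6.5 d
pellet pool:  t1/2 = 6.40 d  (R^2 0.963)
extract pool: t1/2 = 6.35 d  (R^2 0.962, rise phase before 10.1 h excluded)
relative discrepancy: 0.7% (concordant pools support rate-limiting linker cleavage)
```

A simulated 3-week subcutaneous rat study (7 harvest times × 4 depot sites,
10% recovery and signal CVs) of a 6.5-day linker is fitted two independent
ways: the linker-bound payload still on recovered microspheres (pellet) and
the free drug in the tissue extract, each normalized to the stable marker.
Both recover the release half-life to within a few percent of truth and of
each other — free-drug levels in tissue are rate-limited by linker cleavage.

And the combination analysis:

```bash
$ python examples/05_tgi_combination_survival.py
independent-action cohort (n = 6/group):
  TG agent A: 0.373   TG agent B: 0.335
  TG_calc = 0.125  TG_obsd = 0.124
  additivity index = 1.01 -> additive
...
observed synergy example: TG_calc 0.13 / TG_obsd 0.04 -> index 3.1 (supra-additive)
```

When two agents act independently the observed combination TG matches the
product of the single-agent TGs (index ≈ 1); an observed TG far below that
product (index ≈ 3) is strong synergy.

A thin CLI mirrors the library for shell-driven runs
(`depotpk simulate-biopsy | fit-release | simulate-tgi | analyze-tgi |
analyze-combination | survival`); every run writes a `*.run.json` sidecar
with the resolved parameters and seed.

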