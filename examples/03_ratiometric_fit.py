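"""Ratio-metric half-life estimation on a synthetic biopsy cohort.

Simulates the intratumoral destructive-sampling design (harvests at 0, 8, 24,
32, 48 h; three tumors per time; 10% recovery and signal CVs) for a 63 h
linker, then recovers the half-life two ways.  With a recovery efficiency
that degrades over the study, the marker-normalized (ratio-metric) fit stays
on target while the naive log-signal fit is badly biased — the reason the
internal-standard normalization exists.
"""

from depotpk.biopsy import design_it_mouse, generate_release_cohort
from depotpk.kinetics import ReleaseModel
from depotpk.ratiometric import fit_release_halflife

release = ReleaseModel.from_half_life(63.0)

design = design_it_mouse(seed=0)
records = generate_release_cohort(design, release)
fit = fit_release_halflife(records, method="ratiometric")
print(f"stable assay, true t1/2 63 h: ratiometric fit "
      f"{fit.t_half_hat:.1f} h (R^2 {fit.r_squared:.3f}, "
      f"95% CI {fit.ci_95[0]:.0f}-{fit.ci_95[1]:.0f} h)")
print("  (a single 15-sample cohort carries ~20% slope uncertainty at this")
print("   half-life — note the CI brackets the truth; replicate-cohort means")
print("   converge to it)")

drifting = design_it_mouse(recovery_time_slope_per_h=-0.01, seed=0)
records = generate_release_cohort(drifting, release)
ratio = fit_release_halflife(records, method="ratiometric")
naive = fit_release_halflife(records, method="naive")
print("\nrecovery degrading 1%/h over the 48 h study:")
print(f"  ratiometric: {ratio.t_half_hat:.1f} h  (immune: the marker divides out)")
print(f"  naive:       {naive.t_half_hat:.1f} h  (drift masquerades as faster release)")
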