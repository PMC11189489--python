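"""Two-pool concordance: linker-bound (pellet) vs free (extract) payload.

Simulates the subcutaneous rat design (7 harvest times over 3 weeks, 4 depot
sites per time) for a 6.5-day linker.  The pellet pool decays with the
release rate directly; the free-drug extract pool, after its early rise, is
cleared so fast that it tracks the depot quasi-steadily and its terminal
slope estimates the same release half-life.  Agreement of the two
independent fits is an internal consistency check of the release model.
"""

from depotpk.biopsy import design_sc_rat, generate_release_cohort
from depotpk.kinetics import ReleaseModel
from depotpk.ratiometric import fit_two_pool

release = ReleaseModel.from_half_life(6.5 * 24.0)
records = generate_release_cohort(design_sc_rat(seed=0), release)
fits = fit_two_pool(records)

print(f"true release t1/2: 6.5 d")
print(f"pellet pool:  t1/2 = {fits.pellet.t_half_hat / 24:.2f} d  "
      f"(R^2 {fits.pellet.r_squared:.3f})")
print(f"extract pool: t1/2 = {fits.extract.t_half_hat / 24:.2f} d  "
      f"(R^2 {fits.extract.r_squared:.3f}, rise phase before "
      f"{fits.rise_cutoff_h:.1f} h excluded)")
print(f"relative discrepancy: {100 * fits.relative_discrepancy:.1f}% "
      f"(concordant pools support rate-limiting linker cleavage)")
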