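"""Ratio-metric estimator: exactness, recovery invariance, two-pool concordance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from depotpk.biopsy import (
    FREE_PAYLOAD_TISSUE_K,
    design_free_probe,
    design_it_mouse,
    design_sc_rat,
    generate_free_payload_cohort,
    generate_release_cohort,
    records_to_frame,
)
from depotpk.errors import DomainError, EstimationError
from depotpk.kinetics import LN2, ReleaseModel
from depotpk.ratiometric import (
    fit_release_halflife,
    fit_two_pool,
    log_ratio_vs_t0,
    normalize_to_marker,
)


class TestNormalize:
    def test_simple_ratio(self, noise_free_it_design, release_63h):
        records = generate_release_cohort(noise_free_it_design, release_63h)
        ratios = normalize_to_marker(records)
        assert ratios.loc[ratios.time_h == 0, "ratio"].iloc[0] == pytest.approx(1.0)

    def test_scaling_both_signals_cancels(self, it_design, release_63h):
        records = records_to_frame(generate_release_cohort(it_design, release_63h, seed=1))
        doubled = records.copy()
        doubled[["fl_signal", "payload_signal"]] *= 2.0
        assert np.allclose(
            normalize_to_marker(records)["ratio"], normalize_to_marker(doubled)["ratio"]
        )

    def test_bad_marker_rejected_all_bad_errors(self, it_design, release_63h):
        df = records_to_frame(generate_release_cohort(it_design, release_63h, seed=2))
        df.loc[0, "fl_signal"] = 0.0
        ratios = normalize_to_marker(df)
        assert len(ratios) == len(df) - 1
        df["fl_signal"] = -1.0
        with pytest.raises(EstimationError):
            normalize_to_marker(df)


class TestLogRatio:
    def test_reference_cases(self):
        t0 = [1.0, 1.2, 0.8]
        assert log_ratio_vs_t0([1.0], t0)[0] == pytest.approx(0.0)
        assert log_ratio_vs_t0([0.5], t0)[0] == pytest.approx(-math.log(2))

    def test_noise_free_transform_is_linear_decay(self, noise_free_it_design, release_63h):
        records = generate_release_cohort(noise_free_it_design, release_63h)
        ratios = normalize_to_marker(records)
        t0 = ratios.loc[ratios.time_h == 0, "ratio"]
        y = log_ratio_vs_t0(ratios["ratio"], t0)
        assert y == pytest.approx(-release_63h.k_rel * ratios["time_h"].to_numpy())

    def test_empty_reference_rejected(self):
        with pytest.raises(DomainError):
            log_ratio_vs_t0([1.0], [])


class TestFitReleaseHalflife:
    def test_noise_free_fit_is_exact(self, noise_free_it_design, release_63h):
        fit = fit_release_halflife(generate_release_cohort(noise_free_it_design, release_63h))
        assert fit.t_half_hat == pytest.approx(63.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.ci_95[0] <= fit.t_half_hat <= fit.ci_95[1]

    def test_stable_payload_flags_no_release(self, noise_free_it_design, release_63h):
        # a stably attached payload: constant payload/marker ratio at all times
        df = records_to_frame(generate_release_cohort(noise_free_it_design, release_63h))
        df["payload_signal"] = df["fl_signal"]
        fit = fit_release_halflife(df)
        assert fit.no_release and math.isinf(fit.t_half_hat)
        assert fit.k_hat == 0.0

    def test_too_few_time_points(self, release_63h):
        design = design_it_mouse(time_points_h=(0.0, 24.0), seed=0)
        records = generate_release_cohort(design, release_63h)
        with pytest.raises(EstimationError):
            fit_release_halflife(records)

    @given(scales=st.lists(st.floats(min_value=0.01, max_value=100.0), min_size=15, max_size=15))
    @settings(derandomize=True, max_examples=25)
    def test_recovery_invariance(self, scales):
        # multiplying each sample's pellet signals by an arbitrary positive
        # constant (a different recovery) leaves the ratio-metric fit unchanged
        design = design_it_mouse(seed=9)
        df = records_to_frame(
            generate_release_cohort(design, ReleaseModel.from_half_life(63.0), seed=9)
        )
        scaled = df.copy()
        factors = np.asarray(scales)
        scaled["fl_signal"] *= factors
        scaled["payload_signal"] *= factors
        base = fit_release_halflife(df)
        pert = fit_release_halflife(scaled)
        assert pert.k_hat == pytest.approx(base.k_hat, rel=1e-9)
        assert pert.r_squared == pytest.approx(base.r_squared, rel=1e-9)

    def test_estimator_consistency_in_noise(self, release_63h):
        # mean estimate converges to truth as noise vanishes
        errors = []
        for cv in (0.2, 0.05, 0.0125):
            estimates = []
            for rep in range(40):
                design = design_it_mouse(recovery_cv=cv, signal_cv=cv, seed=1000 + rep)
                fit = fit_release_halflife(generate_release_cohort(design, release_63h))
                estimates.append(fit.t_half_hat)
            errors.append(abs(np.mean(estimates) - 63.0))
        assert errors[-1] < 1.0  # near-exact at tiny noise
        assert errors[-1] < errors[0]

    def test_degrading_recovery_biases_naive_not_ratiometric(self):
        """A recovery efficiency that drifts over the study corrupts the naive
        log-signal fit but not the marker-normalized one — the reason the
        internal-standard normalization exists."""
        release = ReleaseModel.from_half_life(43.0)
        ratio_est, naive_est = [], []
        for rep in range(500):
            design = design_it_mouse(recovery_time_slope_per_h=-0.01, seed=20000 + rep)
            records = generate_release_cohort(design, release)
            ratio_est.append(fit_release_halflife(records, method="ratiometric").t_half_hat)
            naive_est.append(fit_release_halflife(records, method="naive").t_half_hat)
        ratio_bias = abs(np.mean(ratio_est) - 43.0) / 43.0
        naive_bias = abs(np.mean(naive_est) - 43.0) / 43.0
        assert ratio_bias < 0.05
        assert naive_bias > 0.20


class TestTwoPool:
    def test_noise_free_pools_agree_with_truth(self):
        # fast local clearance: the extract tracks the depot quasi-steadily
        release = ReleaseModel.from_half_life(6.5 * 24.0)
        design = design_sc_rat(recovery_cv=0.0, signal_cv=0.0, seed=0)
        records = generate_release_cohort(design, release)
        fits = fit_two_pool(records)
        assert fits.pellet.t_half_hat == pytest.approx(6.5 * 24.0, rel=1e-9)
        assert fits.extract.t_half_hat == pytest.approx(6.5 * 24.0, rel=0.02)

    def test_rat_design_concordance(self):
        """Pellet and extract half-life estimates agree within 15% of each
        other in at least 90% of replicate week-scale cohorts."""
        release = ReleaseModel.from_half_life(6.5 * 24.0)
        agree = 0
        n_reps = 200
        for rep in range(n_reps):
            design = design_sc_rat(seed=30000 + rep)
            fits = fit_two_pool(generate_release_cohort(design, release))
            agree += fits.relative_discrepancy < 0.15
        assert agree / n_reps >= 0.90

    def test_rise_phase_is_excluded(self):
        release = ReleaseModel.from_half_life(6.5 * 24.0)
        design = design_sc_rat(recovery_cv=0.0, signal_cv=0.0, seed=0)
        fits = fit_two_pool(generate_release_cohort(design, release))
        assert fits.rise_cutoff_h > 0
        assert fits.extract.n_points < fits.pellet.n_points


class TestFreePayloadClearance:
    def test_recovers_90min_half_life_on_six_site_design(self):
        """The 1.5 h free-payload tissue half-life is recovered within
        +-0.25 h in at least 80% of replicate six-site cohorts."""
        hits = 0
        n_reps = 500
        for rep in range(n_reps):
            design = design_free_probe(seed=40000 + rep)
            records = generate_free_payload_cohort(design, k_tissue=FREE_PAYLOAD_TISSUE_K)
            fit = fit_release_halflife(records, pool="extract")
            hits += abs(fit.t_half_hat - 1.5) <= 0.25
        assert hits / n_reps >= 0.80
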