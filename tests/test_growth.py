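"""Tumor growth simulation, TG/TGI, additivity index, threshold survival."""

import math

import numpy as np
import pandas as pd
import pytest

from depotpk.errors import AnalysisError, ConfigurationError, DomainError
from depotpk.growth import (
    ConstantExposure,
    GrowthSimParams,
    TumorTrajectory,
    additivity_index,
    auto_window,
    bliss_null_study,
    cohort_additivity_index,
    fractional_tg,
    group_median_mad,
    km_median,
    kill_for_target_fraction,
    pulse_exposure,
    simulate_combination_cohort,
    simulate_group,
    survival_times,
    trajectories_to_frame,
)


def exact_trajectory(animal="a1", group="vehicle", g=0.105, v0=265.0, days=None):
    days = np.arange(0.0, 22.0, 3.0) if days is None else np.asarray(days, float)
    return TumorTrajectory(animal, group, days, v0 * np.exp(g * days))


class TestSimulateGroup:
    def test_noise_free_control_is_exact_exponential(self):
        params = GrowthSimParams(n_animals=2, volume_cv=0.0, growth_rate_cv=0.0,
                                 threshold_mm3=1e12, group="vehicle", seed=0)
        for tr in simulate_group(params):
            expected = 265.0 * np.exp(0.105 * tr.days)
            assert tr.volumes == pytest.approx(expected, rel=1e-12)

    def test_kill_balancing_growth_gives_flat_volume(self):
        g = 0.105
        exposure = ConstantExposure(conc_uM=1.0)
        params = GrowthSimParams(
            exposure=exposure, kill_coefficient=g, n_animals=1,
            volume_cv=0.0, growth_rate_cv=0.0, seed=0,
        )
        tr = simulate_group(params)[0]
        assert tr.volumes == pytest.approx(np.full_like(tr.days, 265.0), rel=1e-12)

    def test_truncation_at_threshold(self):
        params = GrowthSimParams(n_animals=1, volume_cv=0.0, growth_rate_cv=0.0,
                                 days=tuple(range(0, 40, 3)), seed=0)
        tr = simulate_group(params)[0]
        crossing_day = math.log(2000.0 / 265.0) / 0.105  # 19.25 d
        assert tr.terminated_at == 21.0
        assert tr.days[-1] == 21.0 and tr.volumes[-1] >= 2000.0
        assert crossing_day < tr.terminated_at

    def test_seed_reproducibility_and_per_animal_streams(self):
        params = GrowthSimParams(n_animals=4, seed=5, group="g")
        a = simulate_group(params)
        b = simulate_group(params)
        for x, y in zip(a, b):
            assert np.array_equal(x.volumes, y.volumes)
        # adding an animal must not perturb the earlier streams
        more = simulate_group(GrowthSimParams(n_animals=5, seed=5, group="g"))
        assert np.array_equal(more[0].volumes, a[0].volumes)

    def test_interaction_scales_kill(self):
        exposure = ConstantExposure(conc_uM=1.0)
        base = dict(exposure=exposure, kill_coefficient=0.05, n_animals=1,
                    volume_cv=0.0, growth_rate_cv=0.0, threshold_mm3=1e12, seed=0)
        off = simulate_group(GrowthSimParams(interaction=0.0, **base))[0]
        on = simulate_group(GrowthSimParams(interaction=1.0, **base))[0]
        assert np.all(on.volumes <= off.volumes)
        assert off.volumes == pytest.approx(265.0 * np.exp(0.105 * off.days), rel=1e-12)


class TestMedianMad:
    def test_hand_case(self):
        trajs = [
            TumorTrajectory(f"a{i}", "g", np.array([0.0]), np.array([v]))
            for i, v in enumerate([100.0, 200.0, 300.0])
        ]
        out = group_median_mad(trajs)
        assert out.loc[0, "median_mm3"] == 200.0
        assert out.loc[0, "mad_mm3"] == 100.0

    def test_single_and_identical_animals_have_zero_mad(self):
        single = group_median_mad([exact_trajectory()])
        assert (single["mad_mm3"] == 0).all()
        twins = group_median_mad([exact_trajectory("a1"), exact_trajectory("a2")])
        assert (twins["mad_mm3"] == 0).all()


class TestFractionalTG:
    def test_self_comparison_is_unity(self):
        vehicle = [exact_trajectory(f"a{i}") for i in range(3)]
        res = fractional_tg(vehicle, vehicle)
        assert res.tg == 1.0 and res.tgi_percent == 0.0

    def test_flat_treated_under_anchoring_gives_full_inhibition(self):
        vehicle = [exact_trajectory()]
        days = np.arange(0.0, 22.0, 3.0)
        flat = [TumorTrajectory("t1", "rx", days, np.full(days.size, 265.0))]
        res = fractional_tg(flat, vehicle, baseline="anchor")
        assert res.tg == pytest.approx(0.0)
        assert res.tgi_percent == pytest.approx(100.0)

    def test_window_exceeding_curve_names_group(self):
        vehicle = [exact_trajectory()]
        short = [exact_trajectory(days=np.arange(0.0, 10.0, 3.0), group="rx")]
        with pytest.raises(AnalysisError, match="treated"):
            fractional_tg(short, vehicle, window=(0.0, 21.0))

    def test_dose_response_tg_monotone_in_kill(self):
        # stronger kill -> smaller TG in noise-free simulation
        vehicle = simulate_group(GrowthSimParams(
            group="vehicle", volume_cv=0.0, growth_rate_cv=0.0, seed=0))
        pulse = pulse_exposure()
        tgs = []
        for f in (0.8, 0.5, 0.2, 0.1):
            kill = kill_for_target_fraction(pulse, f)
            arm = simulate_group(GrowthSimParams(
                group="rx", exposure=pulse, kill_coefficient=kill,
                volume_cv=0.0, growth_rate_cv=0.0, seed=0))
            tgs.append(fractional_tg(arm, vehicle, window=(3.0, 18.0), baseline="none").tg)
        assert all(b < a for a, b in zip(tgs, tgs[1:]))


class TestAdditivityIndex:
    def test_worked_combination_example(self):
        # single-agent fractional growths 0.33 and 0.38, observed 0.04:
        # product ~0.12 and index ~3 -> strong synergy
        res = additivity_index(0.33, 0.38, 0.04)
        assert res.tg_calc == pytest.approx(0.33 * 0.38, rel=1e-12)
        assert res.tg_calc == pytest.approx(0.12, abs=0.01)
        assert res.index == pytest.approx(res.tg_calc / 0.04, rel=1e-12)
        assert res.index == pytest.approx(3.0, abs=0.15)
        assert res.classification == "supra-additive"

    def test_exact_product_is_additive(self):
        res = additivity_index(0.4, 0.5, 0.2)
        assert res.index == 1.0 and res.classification == "additive"

    def test_inactive_single_agents_with_active_combo(self):
        res = additivity_index(1.0, 1.0, 0.5)
        assert res.index == 2.0 and res.classification == "supra-additive"

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            additivity_index(0.3, 0.0, 0.1)


class TestBlissNull:
    def test_noise_free_independent_combination_multiplies_tg(self):
        groups = simulate_combination_cohort(seed=0, volume_cv=0.0)
        res = cohort_additivity_index(groups)
        assert res.tg_a == pytest.approx(0.38, rel=1e-9)
        assert res.tg_b == pytest.approx(0.33, rel=1e-9)
        assert res.tg_obsd == pytest.approx(0.38 * 0.33, rel=1e-9)
        assert res.index == pytest.approx(1.0, rel=1e-9)

    def test_synergistic_interaction_raises_index(self):
        groups = simulate_combination_cohort(seed=0, volume_cv=0.0, interaction=2.0)
        res = cohort_additivity_index(groups)
        assert res.index > 1.25
        assert res.classification == "supra-additive"

    def test_null_study_mean_near_one(self):
        study = bliss_null_study(n_cohorts=60, seed=1)
        assert study.mean_index == pytest.approx(1.0, abs=0.05)


class TestSurvival:
    def test_interpolated_crossing_matches_closed_form(self):
        g, v0 = 0.105, 265.0
        tr = exact_trajectory(g=g, v0=v0, days=np.arange(0.0, 22.0, 3.0))
        out = survival_times([tr])
        assert out.loc[0, "event"] == 1 and not out.loc[0, "extrapolated"]
        assert out.loc[0, "time_days"] == pytest.approx(math.log(2000.0 / v0) / g, abs=1e-9)

    def test_extrapolated_crossing_matches_closed_form(self):
        g, v0 = 0.105, 265.0
        days = np.arange(0.0, 16.0, 1.0)  # stops well below 2000 mm3
        tr = exact_trajectory(g=g, v0=v0, days=days)
        assert tr.volumes.max() < 2000.0
        out = survival_times([tr])
        assert out.loc[0, "event"] == 1 and out.loc[0, "extrapolated"]
        assert out.loc[0, "time_days"] == pytest.approx(math.log(2000.0 / v0) / g, abs=0.1)

    def test_already_over_threshold_at_day_zero(self):
        tr = TumorTrajectory("a", "g", np.array([0.0, 3.0]), np.array([2500.0, 3000.0]))
        out = survival_times([tr])
        assert out.loc[0, "time_days"] == 0.0 and out.loc[0, "event"] == 1

    def test_small_tumor_censored_with_warning(self):
        days = np.arange(0.0, 10.0, 1.0)
        tr = TumorTrajectory("a", "g", days, 100.0 * np.exp(0.05 * days))
        out = survival_times([tr])
        assert out.loc[0, "event"] == 0
        assert out.loc[0, "time_days"] == days[-1]

    def test_simulated_vehicle_cohorts_median_matches_closed_form(self):
        """Replicate noise-free vehicle cohorts: the KM median of the
        time-to-2000 mm3 equals the analytic crossing day."""
        closed = math.log(2000.0 / 265.0) / 0.105
        medians = []
        for rep in range(50):
            trajs = simulate_group(GrowthSimParams(
                group="vehicle", n_animals=5, volume_cv=0.0,
                growth_rate_cv=0.0, seed=rep))
            medians.append(km_median(survival_times(trajs)).median_days)
        assert np.mean(medians) == pytest.approx(closed, abs=0.05)


class TestKMMedian:
    @staticmethod
    def product_limit_median(times, events):
        """Independent oracle: explicit product-limit curve, first t with S <= 0.5."""
        s = 1.0
        for t in sorted(set(times)):
            at_risk = sum(1 for x in times if x >= t)
            deaths = sum(1 for x, e in zip(times, events) if x == t and e)
            s *= 1.0 - deaths / at_risk
            if s <= 0.5:
                return t
        return math.inf

    def test_odd_n_uncensored(self):
        df = pd.DataFrame({"time_days": [10.0, 20.0, 30.0], "event": [1, 1, 1]})
        assert km_median(df).median_days == 20.0

    def test_even_n_uncensored_matches_product_limit_oracle(self):
        times, events = [10.0, 20.0, 30.0, 40.0], [1, 1, 1, 1]
        oracle = self.product_limit_median(times, events)
        df = pd.DataFrame({"time_days": times, "event": events})
        assert km_median(df).median_days == oracle == 20.0

    def test_all_censored_reports_open_bound(self):
        df = pd.DataFrame({"time_days": [42.0] * 5, "event": [0] * 5})
        out = km_median(df)
        assert out.open_bound and str(out) == "> 42 days"

    def test_censoring_shifts_median_like_oracle(self):
        times = [5.0, 8.0, 12.0, 20.0, 25.0, 30.0]
        events = [1, 0, 1, 1, 0, 1]
        df = pd.DataFrame({"time_days": times, "event": events})
        assert km_median(df).median_days == self.product_limit_median(times, events)


class TestWindows:
    def test_auto_window_respects_attrition(self):
        days_full = np.arange(0.0, 22.0, 3.0)
        full = [TumorTrajectory(f"a{i}", "veh", days_full,
                                265.0 * np.exp(0.105 * days_full)) for i in range(3)]
        days_short = days_full[:-2]
        short = [TumorTrajectory(f"b{i}", "rx", days_short,
                                 100.0 * np.exp(0.05 * days_short)) for i in range(3)]
        window = auto_window({"veh": full, "rx": short})
        assert window == (0.0, days_short[-1])

    def test_group_with_too_few_animals_errors(self):
        lone = [exact_trajectory("a1", "rx")]
        with pytest.raises(AnalysisError, match="rx"):
            auto_window({"rx": lone})


def test_trajectories_frame_schema():
    df = trajectories_to_frame([exact_trajectory()])
    assert list(df.columns) == ["animal_id", "group", "day", "volume_mm3"]
    assert len(df) == 8
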