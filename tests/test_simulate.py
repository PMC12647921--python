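"""Simulator determinism, ramp geometry and the analytic ΔF oracle."""

import numpy as np
import pytest

from mnexcite.io import write_dataset
from mnexcite.pipeline import file_digest
from mnexcite.simulate import (
    DEFAULT_PROFILES,
    GroupProfile,
    PoolParams,
    UnitParams,
    analytic_deltaf,
    draw_pool,
    model_rate,
    simulate_cohort,
    simulate_trial,
    triangular_drive,
    unit_truth_table,
)


def flat_profile(dtheta: float) -> GroupProfile:
    return GroupProfile("flat", dtheta, {0.2: 1.0, 0.4: 1.0, 0.6: 1.0})


class TestTrialGeometry:
    def test_first_spike_at_threshold_crossing(self):
        # theta = 10 %MVT on an i20 ramp rising at 2 %MVT/s -> recruit at 5 s
        pool = UnitParams(np.array([10.0]), np.array([4.0]), np.array([0.5]))
        sim = simulate_trial(pool, PoolParams(isi_cv=0.0), 0.2, seed=0)
        assert sim.spike_times[0][0] == pytest.approx(5.0, abs=1e-9)

    def test_last_spike_just_before_derecruitment_crossing(self):
        # theta_eff = 6 -> the descent crosses 6 %MVT at t = 17 s; the final
        # spike precedes the crossing by less than one inter-spike interval
        pool = UnitParams(np.array([10.0]), np.array([4.0]), np.array([0.5]))
        sim = simulate_trial(pool, PoolParams(isi_cv=0.0), 0.2, seed=0)
        s = sim.spike_times[0]
        assert s[-1] <= 17.0 + 1e-9
        assert 17.0 - s[-1] < s[-1] - s[-2] + 1e-9

    def test_no_hysteresis_gives_symmetric_recruit_derecruit(self):
        params = PoolParams(isi_cv=0.0, delta_theta_cv=0.0, n_units=12)
        pool = draw_pool(params, flat_profile(0.0), 0.2, np.random.default_rng(1))
        truth = unit_truth_table(pool, 0.2)
        np.testing.assert_allclose(
            truth.recruit_torque_pct, truth.derecruit_torque_pct, atol=1e-12
        )
        sim = simulate_trial(pool, params, 0.2, seed=0)
        for s in sim.spike_times:
            if len(s) >= 2:  # symmetric ramp: active interval centred on 10 s,
                # up to one trailing ISI of spike discretization
                assert abs(20.0 - s[0] - s[-1]) < (s[-1] - s[-2]) + 1e-9

    def test_units_recruit_in_threshold_order(self):
        params = PoolParams(isi_cv=0.0, n_units=20)
        pool = draw_pool(params, DEFAULT_PROFILES["control"], 0.4, np.random.default_rng(2))
        sim = simulate_trial(pool, params, 0.4, seed=0)
        first = [s[0] for s in sim.spike_times if len(s)]
        assert np.all(np.diff(first) >= 0)

    def test_unrecruited_pool_gives_empty_spikes_not_error(self, caplog):
        pool = UnitParams(np.array([30.0]), np.array([2.0]), np.array([0.5]))
        with caplog.at_level("WARNING"):
            sim = simulate_trial(pool, PoolParams(isi_cv=0.0), 0.2, seed=0)
        assert len(sim.spike_times[0]) == 0
        assert any("no unit recruited" in r.message for r in caplog.records)

    def test_rates_track_rate_model(self):
        # noise-free instantaneous rates agree with the model rate mid-ISI
        pool = UnitParams(np.array([10.0]), np.array([4.0]), np.array([0.5]))
        params = PoolParams(isi_cv=0.0)
        sim = simulate_trial(pool, params, 0.2, seed=0)
        s = sim.spike_times[0]
        mid, rates = 0.5 * (s[1:] + s[:-1]), 1.0 / np.diff(s)
        model = model_rate(triangular_drive(mid, 0.2), 6.0, params.rate_min, 0.5,
                           params.rate_sat)
        keep = mid < 16.5  # exclude the boundary interval at derecruitment
        np.testing.assert_allclose(rates[keep], model[keep], rtol=0.01)


class TestAnalyticDeltaF:
    params = PoolParams()

    def test_matches_control_rate_difference(self):
        # gc * dtheta_t = 0.5 * 4 = 2.0 pps, verified against the rate model
        df = analytic_deltaf(5.0, 0.0, 0.5, 15.0, 4.0, 0.2, self.params)
        assert df == pytest.approx(2.0, abs=1e-12)
        rc = lambda d: float(model_rate(d, 5.0, self.params.rate_min, 0.5,
                                        self.params.rate_sat))
        assert df == pytest.approx(rc(15.0) - rc(11.0), abs=1e-12)

    def test_zero_hysteresis_gives_zero(self):
        assert analytic_deltaf(5.0, 0.0, 0.5, 15.0, 0.0, 0.2, self.params) == 0.0

    def test_saturated_control_gives_zero(self):
        # control saturated throughout the test window -> flat rate, 0 deltaF
        p = PoolParams(rate_sat=10.0)
        assert analytic_deltaf(2.0, 1.0, 2.0, 15.0, 4.0, 0.2, p) == pytest.approx(0.0)

    def test_control_not_covering_test_window_is_ineligible(self):
        # control derecruits above the test unit's derecruit drive -> None
        assert analytic_deltaf(10.0, 0.0, 0.5, 15.0, 8.0, 0.2, self.params) is None

    def test_monotone_in_injected_hysteresis(self):
        vals = [
            analytic_deltaf(5.0, 2.0, 0.5, 15.0, d, 0.2, self.params)
            for d in range(0, 7)
        ]
        assert np.all(np.diff(vals) > 0)


class TestCohort:
    def test_same_seed_is_byte_identical(self, tmp_path):
        kw = dict(group_sizes={"control": 2}, seed=7, intensities=(0.2,), n_trials=1)
        ds1, _ = simulate_cohort(**kw)
        ds2, _ = simulate_cohort(**kw)
        p1 = write_dataset(ds1, tmp_path / "a")
        p2 = write_dataset(ds2, tmp_path / "b")
        for k in p1:
            assert file_digest(p1[k]) == file_digest(p2[k])

    def test_different_seed_differs(self, tmp_path):
        ds1, _ = simulate_cohort({"control": 2}, seed=7, intensities=(0.2,), n_trials=1)
        ds2, _ = simulate_cohort({"control": 2}, seed=8, intensities=(0.2,), n_trials=1)
        assert not np.allclose(
            ds1.spike_trains[0].spike_times_s[:5], ds2.spike_trains[0].spike_times_s[:5]
        )

    def test_sarcopenic_truth_deltaf_flat_across_intensities(self):
        _, truth = simulate_cohort(
            {"sarcopenic": 4}, seed=3, intensities=(0.2, 0.4, 0.6), n_trials=1
        )
        elig = truth.pairs[truth.pairs.eligible]
        means = elig.groupby("intensity").analytic_deltaf_pps.mean()
        assert means.max() / means.min() < 1.10  # flat by construction

    def test_athlete_exceeds_control_truth_deltaf_at_i60(self):
        _, truth = simulate_cohort(
            {"control": 4, "athlete": 4}, seed=3, intensities=(0.6,), n_trials=1
        )
        elig = truth.pairs[truth.pairs.eligible]
        means = elig.groupby("group").analytic_deltaf_pps.mean()
        assert means["athlete"] > means["control"]

    def test_per_trial_unit_yield_is_plausible(self):
        ds, _ = simulate_cohort({"control": 3}, seed=5, intensities=(0.2, 0.6), n_trials=1)
        per_trial = {}
        for st in ds.spike_trains:
            per_trial.setdefault(st.trial_key, 0)
            per_trial[st.trial_key] += 1
        counts = list(per_trial.values())
        assert min(counts) >= 8 and max(counts) <= 32

    def test_sarcopenic_participants_meet_sdoc_screen(self):
        from mnexcite.stats import sdoc_classify

        ds, _ = simulate_cohort(
            {"sarcopenic": 4, "control": 4}, seed=9, intensities=(0.2,), n_trials=1
        )
        for p in ds.participants.values():
            expected = "sarcopenic" if p.group == "sarcopenic" else "not sarcopenic"
            assert sdoc_classify(p.sex, p.handgrip_kg, p.ugs_ms) == expected
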