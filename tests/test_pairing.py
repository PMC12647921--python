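"""ΔF pairing: eligibility criteria, pair ΔF, per-unit averaging, oracle checks."""

import numpy as np
import pytest

from mnexcite.io import AnalysisConfig, PairingConfig
from mnexcite.pairing import (
    PairResult,
    UnitRecord,
    eligible_pairs,
    pair_deltaf,
    unit_deltaf,
)
from mnexcite.simulate import analytic_deltaf, model_deltaf_at

from conftest import constant_curve, events, linear_curve


class TestPairDeltaF:
    def test_constant_control_gives_zero(self):
        ctrl = constant_curve(3.0, 18.0, 11.0)
        assert pair_deltaf(ctrl, events(6.0, 14.0)) == pytest.approx(0.0)

    def test_direct_subtraction(self):
        # control at 12 pps when the test recruits, 9 pps at derecruitment
        ctrl = linear_curve(2.0, 18.0, 14.0, 6.0)  # 0.5 pps/s decline
        ev = events(rec=6.0, derec=12.0)
        # rate(6) = 12, rate(12) = 9
        assert pair_deltaf(ctrl, ev) == pytest.approx(3.0, abs=1e-9)

    def test_undefined_outside_control_interval(self):
        ctrl = constant_curve(5.0, 10.0, 11.0)
        assert pair_deltaf(ctrl, events(6.0, 14.0)) is None

    def test_negative_values_retained(self):
        ctrl = linear_curve(2.0, 18.0, 6.0, 14.0)  # rising control
        assert pair_deltaf(ctrl, events(6.0, 12.0)) < 0


class TestEligibility:
    def control_and_test(self):
        ctrl = UnitRecord("c", linear_curve(3.0, 17.0, 8.0, 12.0),
                          events(3.0, 17.0, rt=6.0))
        test = UnitRecord("t", linear_curve(6.0, 14.0, 8.0, 12.0),
                          events(6.0, 14.0, rt=12.0))
        return ctrl, test

    def test_wellformed_pair_is_eligible(self):
        ctrl, test = self.control_and_test()
        pairs = eligible_pairs([ctrl, test])
        by = {(p.control_id, p.test_id): p for p in pairs}
        assert by[("c", "t")].eligible
        assert by[("c", "t")].delta_f_pps is not None

    def test_antisymmetry(self):
        ctrl, test = self.control_and_test()
        by = {(p.control_id, p.test_id): p for p in eligible_pairs([ctrl, test])}
        assert not by[("t", "c")].eligible
        assert "rank" in by[("t", "c")].failing()

    def test_control_recruited_after_test_flagged(self):
        ctrl = UnitRecord("c", linear_curve(7.0, 17.0, 8.0, 12.0),
                          events(7.0, 17.0, rt=14.0))
        test = UnitRecord("t", linear_curve(6.0, 14.0, 8.0, 12.0),
                          events(6.0, 14.0, rt=12.0))
        by = {(p.control_id, p.test_id): p for p in eligible_pairs([ctrl, test])}
        assert not by[("c", "t")].eligible
        assert {"rank", "separation"} & set(by[("c", "t")].failing())

    def test_control_derecruited_before_test_flagged(self):
        ctrl = UnitRecord("c", linear_curve(3.0, 12.0, 8.0, 12.0),
                          events(3.0, 12.0, rt=6.0))
        test = UnitRecord("t", linear_curve(6.0, 14.0, 8.0, 12.0),
                          events(6.0, 14.0, rt=12.0))
        by = {(p.control_id, p.test_id): p for p in eligible_pairs([ctrl, test])}
        assert "derecruit" in by[("c", "t")].failing()

    def test_low_modulation_flagged(self):
        ctrl = UnitRecord("c", constant_curve(3.0, 17.0, 10.0),
                          events(3.0, 17.0, rt=6.0))
        test = UnitRecord("t", linear_curve(6.0, 14.0, 8.0, 12.0),
                          events(6.0, 14.0, rt=12.0))
        by = {(p.control_id, p.test_id): p for p in eligible_pairs([ctrl, test])}
        assert "modulation" in by[("c", "t")].failing()

    def test_matches_brute_force_enumeration(self, noisefree_analysis):
        # independent re-application of the five criteria over all ordered pairs
        *_, ca = noisefree_analysis
        cfg = PairingConfig()
        recs = {r.unit_id: r for r in ca.records}
        expected = set()
        for c in ca.records:
            for t in ca.records:
                if c.unit_id == t.unit_id:
                    continue
                ce, te = c.events, t.events
                if not ce.recruitment_threshold_pct < te.recruitment_threshold_pct:
                    continue
                if not te.recruitment_time_s - ce.recruitment_time_s >= cfg.sep_min_s:
                    continue
                if not ce.derecruitment_time_s > te.derecruitment_time_s:
                    continue
                g = c.smoothed.grid_s
                seg = c.smoothed.rate_pps[
                    (g >= te.recruitment_time_s) & (g <= te.derecruitment_time_s)
                ]
                if len(seg) < 2 or np.ptp(seg) < cfg.mod_min_pps:
                    continue
                lo = max(c.smoothed.active_interval[0], t.smoothed.active_interval[0])
                hi = min(c.smoothed.active_interval[1], t.smoothed.active_interval[1])
                gg = np.linspace(lo, hi, max(int((hi - lo) * 100) + 1, 3))
                r = np.corrcoef(c.smoothed.rate_at(gg), t.smoothed.rate_at(gg))[0, 1]
                if not (np.isfinite(r) and r >= cfg.r_min):
                    continue
                expected.add((c.unit_id, t.unit_id))
        got = {(p.control_id, p.test_id) for p in ca.pairs if p.eligible}
        assert got == expected


class TestUnitDeltaF:
    def mk_pair(self, test_id, df):
        return PairResult(
            control_id="c", test_id=test_id,
            criteria={"rank": True}, separation_s=2.0,
            control_modulation_pps=3.0, rate_correlation=0.9, delta_f_pps=df,
        )

    def test_mean_over_controls(self):
        out = unit_deltaf([self.mk_pair("t", 2.0), self.mk_pair("t", 4.0)])
        assert out[0].delta_f_pps == pytest.approx(3.0)
        assert out[0].n_controls == 2

    def test_single_pair(self):
        out = unit_deltaf([self.mk_pair("t", 2.5)])
        assert out[0].delta_f_pps == pytest.approx(2.5)

    def test_no_eligible_pairs_gives_no_value(self):
        p = self.mk_pair("t", None)
        p.criteria = {"rank": False}
        assert unit_deltaf([p]) == []

    def test_matches_brute_force_recomputation(self, noisefree_analysis):
        *_, ca = noisefree_analysis
        got = {u.test_id: u for u in unit_deltaf(ca.pairs)}
        sums: dict[str, list[float]] = {}
        for p in ca.pairs:
            if p.eligible and p.delta_f_pps is not None:
                sums.setdefault(p.test_id, []).append(p.delta_f_pps)
        assert set(got) == set(sums)
        for t, vals in sums.items():
            assert got[t].delta_f_pps == pytest.approx(sum(vals) / len(vals))


class TestOracleAgreement:
    def test_noise_free_pairs_match_model_rate_oracle(self, noisefree_analysis):
        # oracle: control model rate at the test unit's observed events
        params, pool, sim, ds, ca = noisefree_analysis
        recs = {r.unit_id: r for r in ca.records}
        errs = []
        for p in ca.pairs:
            if not p.eligible:
                continue
            c = int(p.control_id[1:])
            te = recs[p.test_id].events
            truth = model_deltaf_at(
                pool.theta[c], pool.delta_theta[c], pool.gain[c],
                te.recruitment_time_s, te.derecruitment_time_s, 0.2, params,
            )
            errs.append(p.delta_f_pps - truth)
        assert len(errs) > 50
        assert np.max(np.abs(errs)) < 0.2

    def test_noise_free_mean_bias_vs_analytic_deltaf(self, noisefree_analysis):
        # against the exact crossing-based estimand the estimator carries a
        # small one-sided spike-discretization deflation; mean bias < 0.2 pps
        params, pool, sim, ds, ca = noisefree_analysis
        diffs = []
        for p in ca.pairs:
            if not p.eligible:
                continue
            c, t = int(p.control_id[1:]), int(p.test_id[1:])
            truth = analytic_deltaf(
                pool.theta[c], pool.delta_theta[c], pool.gain[c],
                pool.theta[t], pool.delta_theta[t], 0.2, params,
            )
            if truth is not None:
                diffs.append(p.delta_f_pps - truth)
        assert len(diffs) > 50
        assert abs(np.mean(diffs)) < 0.2

    def test_estimated_mean_monotone_in_hysteresis(self):
        # noise-free sweep of injected hysteresis -> strictly increasing mean
        from scipy.stats import spearmanr

        from mnexcite.pipeline import analyze_contraction
        from mnexcite.simulate import GroupProfile, PoolParams, draw_pool, simulate_trial

        from conftest import dataset_from_trial

        means = []
        for dtheta in range(0, 7):
            params = PoolParams(isi_cv=0.0, delta_theta_cv=0.0, n_units=15,
                                theta_min=8.0)
            profile = GroupProfile("sweep", float(dtheta), {0.2: 1.0})
            pool = draw_pool(params, profile, 0.2, np.random.default_rng(5))
            sim = simulate_trial(pool, params, 0.2, np.random.default_rng(6),
                                 participant_id="p1")
            ds = dataset_from_trial(sim)
            ca = analyze_contraction(ds, sim.trial.key, AnalysisConfig())
            vals = [u.delta_f_pps for u in unit_deltaf(ca.pairs)]
            means.append(np.mean(vals) if vals else 0.0)
        assert np.all(np.diff(means) > 0)
        assert spearmanr(range(7), means).statistic == pytest.approx(1.0)
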