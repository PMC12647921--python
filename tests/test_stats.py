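"""Robust mixed model, bootstrap contrasts, associations, SDOC, EMM arithmetic."""

import numpy as np
import pandas as pd
import pytest

from mnexcite.stats import (
    ConvergenceError,
    DesignInfo,
    RobustLinearMixedModel,
    emm_difference,
    fit_association_model,
    fit_bin_model,
    sdoc_classify,
    simulate_unit_table,
)


class TestRobustMixedModel:
    def test_constant_outcome_gives_zero_slopes(self):
        df = simulate_unit_table({"sarcopenic": 3, "control": 3}, seed=0)
        df["delta_f_pps"] = 4.2
        design = DesignInfo(("sarcopenic", "control"), (0.2, 0.4, 0.6))
        res = RobustLinearMixedModel.from_dataframe(df, "delta_f_pps", design).fit()
        assert res.params[0] == pytest.approx(4.2, abs=1e-8)
        np.testing.assert_allclose(res.params[1:], 0.0, atol=1e-8)

    def test_matches_statsmodels_mixedlm_when_gaussian(self):
        # cross-check: with an effectively infinite Huber constant the fit
        # reduces to a Gaussian random-intercept model
        import statsmodels.formula.api as smf

        df = simulate_unit_table(
            {"sarcopenic": 5, "control": 5},
            group_offsets={"control": {0.2: 0.8, 0.4: 0.8, 0.6: 0.8}},
            seed=2,
        )
        design = DesignInfo(("sarcopenic", "control"), (0.2, 0.4, 0.6))
        res = RobustLinearMixedModel.from_dataframe(
            df, "delta_f_pps", design, huber_c=1e6
        ).fit()
        df2 = df.assign(
            male=(df.sex == "male").astype(float),
            i40=np.isclose(df.intensity, 0.4).astype(float),
            i60=np.isclose(df.intensity, 0.6).astype(float),
            ctl=(df.group == "control").astype(float),
        )
        sm_res = smf.mixedlm(
            "delta_f_pps ~ ctl + i40 + i60 + ctl:i40 + ctl:i60 + male",
            df2, groups=df2.participant_id,
        ).fit(reml=True)
        want = [sm_res.params[k] for k in
                ["Intercept", "ctl", "i40", "i60", "ctl:i40", "ctl:i60", "male"]]
        got = [res.params[design.names.index(k)] for k in
               ["intercept", "group[control]", "intensity[i40]", "intensity[i60]",
                "group[control]:intensity[i40]", "group[control]:intensity[i60]",
                "sex[male]"]]
        np.testing.assert_allclose(got, want, atol=0.05)

    def test_outlier_resistance(self):
        # a gross outlier moves the robust fit far less than the scale of the
        # contamination
        df = simulate_unit_table({"control": 6}, seed=3)
        design = DesignInfo(("control",), (0.2, 0.4, 0.6))
        base = RobustLinearMixedModel.from_dataframe(df, "delta_f_pps", design).fit()
        df.loc[df.index[0], "delta_f_pps"] += 500.0
        poll = RobustLinearMixedModel.from_dataframe(df, "delta_f_pps", design).fit()
        assert abs(poll.params[0] - base.params[0]) < 0.1

    def test_singular_design_raises(self):
        df = simulate_unit_table({"control": 3}, seed=1)
        X = np.column_stack([np.ones(len(df)), np.ones(len(df))])
        with pytest.raises(ConvergenceError):
            RobustLinearMixedModel(df.delta_f_pps, X, df.participant_id)

    def test_one_participant_per_group_raises(self):
        df = simulate_unit_table({"sarcopenic": 1, "control": 1}, seed=1)
        with pytest.raises(ConvergenceError):
            fit_bin_model(df, bootstrap_B=50)


class TestBinModelContrasts:
    def test_known_shift_recovered(self):
        shift = {0.2: -1.0, 0.4: -1.0, 0.6: -1.0}
        df = simulate_unit_table(
            {"sarcopenic": 10, "control": 10}, units_per_participant=12,
            group_offsets={"sarcopenic": shift}, participant_sd=0.3, seed=4,
        )
        res = fit_bin_model(df, bootstrap_B=300, seed=0)
        for i, name in ((0.2, "i20"), (0.4, "i40"), (0.6, "i60")):
            c = res.contrast(f"control-sarcopenic@{name}")
            assert c.estimate == pytest.approx(1.0, abs=0.40)
            assert c.ci_low <= 1.0 <= c.ci_high

    def test_identical_groups_ci_covers_zero(self):
        df = simulate_unit_table({"sarcopenic": 6, "control": 6}, seed=8)
        res = fit_bin_model(df, bootstrap_B=300, seed=0)
        covering = [c for c in res.contrasts if "control-sarcopenic" in c.name]
        assert any(c.ci_low <= 0 <= c.ci_high for c in covering)

    def test_seeded_bootstrap_reproducible(self):
        df = simulate_unit_table({"sarcopenic": 4, "control": 4}, seed=5)
        r1 = fit_bin_model(df, bootstrap_B=100, seed=7)
        r2 = fit_bin_model(df, bootstrap_B=100, seed=7)
        for a, b in zip(r1.contrasts, r2.contrasts):
            assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_emms_consistent_with_contrasts(self):
        df = simulate_unit_table({"sarcopenic": 4, "control": 4}, seed=6)
        res = fit_bin_model(df, bootstrap_B=50, seed=0)
        c = res.contrast("control-sarcopenic@i40")
        assert c.estimate == pytest.approx(
            res.emm("control", 0.4) - res.emm("sarcopenic", 0.4), abs=1e-9
        )


class TestEmmDifference:
    @pytest.mark.parametrize(
        "a,b,diff,pct",
        [
            (5.14, 4.28, 0.86, 20),    # athlete vs control, high-threshold units
            (2.89, 5.14, -2.25, -44),
            (2.89, 4.28, -1.39, -32),
            (4.73, 4.13, 0.60, 15),
            (3.0, 3.0, 0.0, 0),
        ],
    )
    def test_reported_rounding(self, a, b, diff, pct):
        d = emm_difference(a, b).rounded()
        assert d == (pytest.approx(diff), pct)

    def test_zero_denominator_flagged(self):
        d = emm_difference(1.0, 0.0)
        assert d.percent is None


class TestAssociationModels:
    def build(self, beta, participant_sd, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for k in range(14):
            pid = f"p{k}"
            sex = "female" if k % 2 == 0 else "male"
            measure = rng.uniform(0.6, 2.2)
            intercept = rng.normal(0, participant_sd)
            for i in (0.2, 0.4, 0.6):
                for u in range(8):
                    y = 2.0 + beta * measure + intercept + rng.normal(0, 0.2)
                    rows.append((pid, "control", sex, i, measure, 70.0, y))
        return pd.DataFrame(rows, columns=[
            "participant_id", "group", "sex", "intensity", "ugs_ms",
            "body_mass_kg", "delta_f_pps",
        ])

    def test_pure_fixed_effect_gives_r2m_close_to_r2c(self):
        df = self.build(beta=2.0, participant_sd=0.0)
        res = fit_association_model(df, "ugs_ms")
        assert res.r2_marginal == pytest.approx(res.r2_conditional, abs=0.05)
        assert res.slopes.slope.mean() == pytest.approx(2.0, abs=0.3)

    def test_participant_driven_outcome_gives_low_r2m_high_r2c(self):
        df = self.build(beta=0.0, participant_sd=1.5)
        res = fit_association_model(df, "ugs_ms")
        assert res.r2_marginal < 0.25
        assert res.r2_conditional > 0.7

    def test_r2c_at_least_r2m(self):
        for seed in range(3):
            df = self.build(beta=1.0, participant_sd=0.8, seed=seed)
            res = fit_association_model(df, "ugs_ms")
            assert 0.0 <= res.r2_marginal <= res.r2_conditional <= 1.0

    def test_constant_predictor_raises(self):
        df = self.build(beta=1.0, participant_sd=0.5)
        df["ugs_ms"] = 1.0
        with pytest.raises(ConvergenceError):
            fit_association_model(df, "ugs_ms")

    def test_low_coverage_rejected(self):
        df = self.build(beta=1.0, participant_sd=0.5)
        df.loc[df.participant_id.isin([f"p{k}" for k in range(6)]), "ugs_ms"] = np.nan
        with pytest.raises(ValueError, match="participants"):
            fit_association_model(df, "ugs_ms")


class TestSdocClassifier:
    @pytest.mark.parametrize(
        "sex,grip,ugs,expected",
        [
            ("female", 18.0, 0.7, "sarcopenic"),
            ("male", 36.0, 0.7, "not sarcopenic"),     # above male grip cut-off
            ("female", 18.0, 0.9, "not sarcopenic"),   # both criteria required
            ("male", 35.0, 0.7, "sarcopenic"),
            ("female", 20.0, 0.7, "not sarcopenic"),   # cut-off is strict '<'
        ],
    )
    def test_truth_table(self, sex, grip, ugs, expected):
        assert sdoc_classify(sex, grip, ugs) == expected

    def test_missing_input_is_indeterminate(self):
        assert sdoc_classify("female", None, 0.7) is None
        assert sdoc_classify("male", 30.0, float("nan")) is None
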