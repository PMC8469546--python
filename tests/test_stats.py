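"""Permutation test, mixed models with Satterthwaite df, LRT, ANOVA."""
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from smrpipe.stats import (MODEL_SPECS, accuracy_anova,
                           feedback_pattern_permutation, fit_lme, lme_anova,
                           simulated_lrt)
from smrpipe.synthetic import MixedEffectsTruth, generate_erdd_table, \
    study_layout


def _day_patterns(rng, base, noise=0.02, rotated_days=(), rotated=None):
    """Six day-patterns around ``base``; selected days use ``rotated``."""
    out = []
    for day in range(1, 7):
        ref = rotated if day in rotated_days else base
        out.append(ref + noise * rng.standard_normal(len(ref)))
    return np.asarray(out)


class TestFeedbackPermutation:
    def test_identical_patterns_give_p_one(self):
        base = np.random.default_rng(0).standard_normal(30)
        res = feedback_pattern_permutation(np.tile(base, (6, 1)),
                                           n_permutations=999, seed=1)
        assert res.observed_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert np.allclose(res.null_sample, 0.0, atol=1e-12)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        P = _day_patterns(rng, rng.standard_normal(30), noise=0.3)
        a = feedback_pattern_permutation(P, n_permutations=999, seed=7)
        b = feedback_pattern_permutation(P, n_permutations=999, seed=7)
        assert a.p_value == b.p_value
        assert np.array_equal(a.null_sample, b.null_sample)

    def test_planted_feedback_day_change_detected(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(30)
        rotated = rng.standard_normal(30)
        P = _day_patterns(rng, base, rotated_days=(1, 6), rotated=rotated)
        res = feedback_pattern_permutation(P, n_permutations=999, seed=4)
        assert res.p_value <= 0.05
        assert res.observed_statistic < min(res.null_sample)

    def test_null_type_one_error_is_conservative(self):
        """Coarse calibration: ~1/15 of null repetitions reject at 0.05."""
        rng = np.random.default_rng(5)
        rejections = 0
        reps = 300
        for _ in range(reps):
            P = rng.standard_normal((6, 30))
            res = feedback_pattern_permutation(P, n_permutations=199,
                                               seed=int(rng.integers(2**31)))
            rejections += res.p_value <= 0.05
        rate = rejections / reps
        assert 0.01 <= rate <= 0.12

    def test_invalid_feedback_days(self):
        P = np.random.default_rng(6).standard_normal((6, 30))
        with pytest.raises(ValueError):
            feedback_pattern_permutation(P, feedback_days=(1, 9))


class TestMixedModels:
    def test_zero_noise_recovers_fixed_effects_exactly(self):
        truth = MixedEffectsTruth(
            intercept=-50.0, feedback_effect_by_subject={"s01": 13.0},
            subject_random_sd=0.0, residual_sd=0.0)
        fit = fit_lme(generate_erdd_table(truth, seed=0), "5")
        fe = fit.fe_params
        assert fe["Intercept"] == pytest.approx(-50.0, abs=1e-6)
        assert fe["isFeedbacked"] == pytest.approx(13.0, abs=1e-6)

    def test_model_catalogue_filters(self):
        tab = generate_erdd_table(MixedEffectsTruth(), seed=1)
        fit4 = fit_lme(tab, "4a")
        assert set(fit4.data["day"].unique()) == {2.0, 3.0, 4.0, 5.0}
        assert set(fit4.data["imageryType"]) <= {"FL", "FR", "SL", "SR"}
        fit6 = fit_lme(tab, "6")
        assert set(fit6.data["imageryType"]) <= {"TR", "TRv"}
        assert set(fit6.data["videoORfeed"]) == \
            {"feedback", "no_feedback", "video"}

    def test_per_subject_feedback_estimates(self):
        truth = MixedEffectsTruth(feedback_effect_by_subject={"s01": 13.0})
        fit = fit_lme(generate_erdd_table(truth, seed=2), "5")
        fx = fit.feedback_effects_by_subject()
        assert fx.loc["s01", "estimate"] == pytest.approx(13.0, abs=4.0)
        assert (fx.loc["s01", "ci_lower"] < 13.0 < fx.loc["s01", "ci_upper"])
        others = fx.drop("s01")
        assert np.all(np.abs(others["estimate"]) < 6.0)

    def test_satterthwaite_matches_lmertest_oracle(self, tmp_path):
        """Cross-check estimate/SE/df/p against R's lmerTest."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(7)
        rows = []
        for s, n in {"a": 8, "b": 12, "c": 6, "d": 10}.items():
            b = rng.normal(0, 2)
            for _ in range(n):
                x = int(rng.integers(0, 2))
                rows.append(dict(subject=s, day=float(rng.integers(2, 6)),
                                 imageryType="FR", isFeedbacked=x,
                                 ERDd=-50 + 3 * x + b + rng.normal(0, 4)))
        tab = pd.DataFrame(rows)
        csv = tmp_path / "d.csv"
        tab.to_csv(csv, index=False)
        fit = fit_lme(tab, ("ERDd ~ 1 + isFeedbacked", "~1"))
        ours = fit.fixed_effects_table().loc["isFeedbacked"]
        script = (
            "suppressMessages(library(lmerTest));"
            f"d <- read.csv('{csv}');"
            "m <- lmer(ERDd ~ 1 + isFeedbacked + (1|subject), data=d);"
            "s <- coef(summary(m))['isFeedbacked',];"
            "cat(s[['Estimate']], s[['Std. Error']], s[['df']],"
            "    s[['Pr(>|t|)']], sep=',')"
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True, timeout=300)
        est, se, df, p = map(float, out.stdout.strip().split(","))
        assert ours["estimate"] == pytest.approx(est, rel=1e-4)
        assert ours["se"] == pytest.approx(se, rel=1e-3)
        assert ours["df"] == pytest.approx(df, rel=1e-2)
        assert ours["p"] == pytest.approx(p, rel=1e-2, abs=1e-6)

    def test_balanced_fixed_design_matches_classical_anova(self):
        """Random-intercept variance pinned at 0: F and df go classical."""
        rng = np.random.default_rng(8)
        levels = np.repeat(["FR", "FL", "SR"], 12)
        groups = np.tile([f"s{i}" for i in range(1, 7)], 6)
        eps = rng.standard_normal(36)
        # remove group means so the REML subject variance sits at zero
        for g in np.unique(groups):
            eps[groups == g] -= eps[groups == g].mean()
        y = -50 + 5.0 * (levels == "FR") + eps
        tab = pd.DataFrame({
            "subject": groups, "day": 2.0, "imageryType": levels,
            "isFeedbacked": 0, "ERDd": y})
        fit = fit_lme(tab, ("ERDd ~ 1 + imageryType", "~1"))
        ours = lme_anova(fit)
        ols = smf.ols("ERDd ~ imageryType", data=tab).fit()
        classical = anova_lm(ols, typ=2)
        assert ours.loc["imageryType", "F"] == pytest.approx(
            float(classical.loc["imageryType", "F"]), abs=1e-6)
        assert ours.loc["imageryType", "df_den"] == pytest.approx(
            float(classical.loc["Residual", "df"]), abs=0.5)

    def test_invalid_formula_and_method(self):
        tab = generate_erdd_table(MixedEffectsTruth(), seed=3)
        with pytest.raises(ValueError):
            fit_lme(tab, "7")
        with pytest.raises(ValueError):
            fit_lme(tab, "5", method="MAP")
        with pytest.raises(ValueError, match="lacks columns"):
            fit_lme(tab.drop(columns=["ERDd"]), "5")


class TestSimulatedLRT:
    @staticmethod
    def _small_table(day_slope=0.0, seed=0):
        layout = study_layout(n_subjects=4)
        layout = layout[layout["imageryType"] == "FR"]
        truth = MixedEffectsTruth(day_slope=day_slope, subject_random_sd=8.0,
                                  residual_sd=9.0)
        return generate_erdd_table(truth, layout, seed=seed)

    def test_identical_models_give_zero_statistic(self):
        tab = self._small_table()
        res = simulated_lrt(tab, ("ERDd ~ 1", "~1"), ("ERDd ~ 1", "~1"),
                            n_sim=10, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0)

    def test_non_nested_rejected(self):
        tab = generate_erdd_table(MixedEffectsTruth(), seed=4)
        with pytest.raises(ValueError, match="not nested"):
            simulated_lrt(tab, "4b", "4a", n_sim=2, seed=0)

    def test_planted_day_effect_detected(self):
        """Strong day drift: bootstrap p < 0.05 in nearly all repetitions."""
        detected = 0
        for rep in range(8):
            tab = self._small_table(day_slope=4.0, seed=100 + rep)
            res = simulated_lrt(tab, ("ERDd ~ 1 + day", "~1"),
                                ("ERDd ~ 1", "~1"), n_sim=39,
                                seed=rep)
            detected += res.p_value < 0.05
        assert detected >= 7

    def test_p_confidence_interval_brackets(self):
        tab = self._small_table(day_slope=1.0, seed=5)
        res = simulated_lrt(tab, ("ERDd ~ 1 + day", "~1"),
                            ("ERDd ~ 1", "~1"), n_sim=49, seed=6)
        lo, hi = res.p_ci
        assert 0.0 <= lo <= res.p_value <= hi <= 1.0


class TestAccuracyAnova:
    @staticmethod
    def _acc_table(shift_s02=0.0, seed=0, schemes=("5x2",)):
        rng = np.random.default_rng(seed)
        rows = []
        for s in [f"s{i:02d}" for i in range(1, 8)]:
            for day in range(1, 7):
                for scheme in schemes:
                    acc = 0.9 + rng.normal(0, 0.02)
                    if s == "s02":
                        acc += shift_s02
                    rows.append(dict(subject=s, day=day,
                                     feedback=day in (1, 6),
                                     cv_scheme=scheme, accuracy=acc))
        return pd.DataFrame(rows)

    def test_constant_response_gives_zero_F(self):
        tab = self._acc_table()
        tab["accuracy"] = 0.9
        out = accuracy_anova(tab)
        assert np.allclose(out["F"], 0.0)

    def test_shifted_subject_detected(self):
        hits = 0
        for seed in range(10):
            out = accuracy_anova(self._acc_table(shift_s02=-0.2, seed=seed))
            hits += out.loc["subject", "p"] < 1e-3
        assert hits == 10

    def test_additive_degrees_of_freedom_match_design(self):
        """7 subjects x 6 days, additive: den df = 42 - 8 = 34."""
        out = accuracy_anova(self._acc_table(seed=1))
        assert out.loc["subject", "df_num"] == 6
        assert out.loc["feedback", "df_num"] == 1
        assert out.loc["subject", "df_den"] == 34
        # three-way layout: 84 rows, den df = 84 - 9 = 75
        tab3 = self._acc_table(seed=2, schemes=("5x2", "ts"))
        out3 = accuracy_anova(tab3, ("subject", "feedback", "cv_scheme"))
        assert out3.loc["cv_scheme", "df_den"] == 75

    def test_factor_validation(self):
        tab = self._acc_table()
        with pytest.raises(ValueError, match="missing factor"):
            accuracy_anova(tab, ("subject", "nope"))
        with pytest.raises(ValueError, match="2 levels"):
            accuracy_anova(tab, ("subject", "cv_scheme"))
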