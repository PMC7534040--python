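"""Mixed-effects inference: LMM, single-case tests, GLMM, correlations."""

import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import semcoh as sc
from semcoh.stats import _factorial_design, satterthwaite_df


@pytest.fixture(scope="module")
def lmm_data():
    return sc.gen_lmm_data(seed=5)


class TestLinearMixedModel:
    def test_matches_ols_without_random_effects(self, lmm_data):
        y = lmm_data["value"].to_numpy()
        ln = lmm_data["length"].to_numpy()
        X = np.column_stack([
            np.ones(len(y)),
            (lmm_data["group"] == "patient").astype(float),
            ln - ln.mean(),
        ])
        fit = sc.fit_lmm(y, X, {}, fixed_names=["intercept", "group", "len"])
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-6)
        df = satterthwaite_df(fit, np.array([0.0, 1.0, 0.0]))
        assert df == pytest.approx(len(y) - 3, rel=1e-6)

    def test_group_comparison_agrees_with_lmerTest(self, lmm_data, tmp_path):
        """Independent oracle: the same model fitted by lme4/lmerTest in R
        must reproduce estimate, SE, Satterthwaite df and p."""
        results, fit = sc.group_comparison(lmm_data)
        grp = next(r for r in results if r.term == "group")

        csv = tmp_path / "d.csv"
        lmm_data.to_csv(csv, index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(lmerTest))
            d <- read.csv("{csv}")
            d$grp <- as.numeric(d$group != "control")
            d$len_c <- d$length - mean(d$length)
            m <- lmer(value ~ grp + len_c + (1|participant) + (1|prompt)
                      + (0+grp|prompt), data=d, REML=TRUE)
            co <- summary(m)$coefficients["grp", ]
            cat(sprintf("%.8f %.8f %.6f %.8f\\n",
                co[1], co[2], co[3], co[5]))
        """)
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True,
            timeout=300,
        )
        assert out.returncode == 0, out.stderr
        est, se, df, p = map(float, out.stdout.split())
        assert grp.estimate == pytest.approx(est, rel=1e-4)
        assert grp.se == pytest.approx(se, rel=1e-3)
        assert grp.df == pytest.approx(df, rel=1e-2)
        assert grp.p == pytest.approx(p, rel=1e-2)

    def test_satterthwaite_df_in_bounds(self):
        for seed in (1, 2, 3):
            data = sc.gen_lmm_data(seed=seed)
            results, fit = sc.group_comparison(data)
            n, p = fit.n, len(fit.fixed_names)
            for r in results:
                assert 0 < r.df <= n - p + 1e-9

    def test_zero_variance_response_is_degenerate(self, lmm_data):
        flat = lmm_data.copy()
        flat["value"] = 0.3
        with pytest.raises(sc.FitError):
            sc.group_comparison(flat)

    def test_simplification_recorded_when_slope_absent(self):
        # generated without a by-prompt group slope: the full fit is
        # singular and the ladder must record the simplification
        data = sc.gen_lmm_data(sd_group_prompt=0.0, seed=23)
        _, fit = sc.group_comparison(data)
        assert fit.simplifications  # at least one rung descended


class TestSingleCase:
    def test_case_identical_to_control_not_significant(self, lmm_data):
        ctrl = lmm_data[lmm_data["group"] == "control"]
        case = ctrl[ctrl["participant"] == "C00"].copy()
        case["participant"] = "CASE"
        cc = sc.single_case_test(case, ctrl, measure="gc")
        assert not cc.significant
        assert cc.p > 0.3

    def test_strongly_shifted_case_detected(self, lmm_data):
        ctrl = lmm_data[lmm_data["group"] == "control"]
        case = ctrl[ctrl["participant"] == "C01"].copy()
        case["participant"] = "CASE"
        case["value"] = case["value"] - 0.5  # enormous deficit
        cc = sc.single_case_test(case, ctrl, measure="gc")
        assert cc.significant
        assert cc.estimate < 0

    def test_requires_multiple_controls(self, lmm_data):
        ctrl = lmm_data[lmm_data["participant"] == "C00"]
        case = ctrl.copy()
        case["participant"] = "CASE"
        with pytest.raises(ValueError):
            sc.single_case_test(case, ctrl)

    def test_crawford_howell_reference_value(self):
        # case 70 vs controls mean 100, sd 10, n 10:
        # t = -30 / (10 * sqrt(11/10)) = -2.8604, df 9
        controls = np.array([85.0, 90, 95, 100, 100, 100, 105, 105, 110, 110])
        t, df, p = sc.crawford_howell(70.0, controls)
        sd = controls.std(ddof=1)
        expected_t = (70 - controls.mean()) / (sd * np.sqrt(11 / 10))
        assert t == pytest.approx(expected_t)
        assert df == 9
        assert 0 < p < 0.05


class TestAccuracyGLMM:
    def test_recovers_planted_effects_against_glmer_scale(self):
        trials, _ = sc.gen_accuracy(
            effects={"intercept": 1.2, "group": 0.8, "demand": -0.9},
            n_participants=16, n_items=40, seed=3,
        )
        res = sc.accuracy_glmm(trials, random_slopes=False,
                               terms=["group", "demand"])
        by_term = {r.term: r for r in res}
        assert by_term["group"].estimate == pytest.approx(0.8, abs=0.6)
        assert by_term["demand"].estimate == pytest.approx(-0.9, abs=0.6)
        assert by_term["demand"].p < 0.05
        for r in res:
            assert 0 <= r.p <= 1
            assert r.se > 0

    def test_all_correct_raises_separation(self):
        trials, _ = sc.gen_accuracy(n_participants=4, n_items=8, seed=1)
        trials["correct"] = 1
        with pytest.raises(sc.SeparationError):
            sc.accuracy_glmm(trials)

    def test_pure_cell_names_the_cell(self):
        trials, _ = sc.gen_accuracy(n_participants=4, n_items=8, seed=1)
        mask = (
            (trials.group == "patient")
            & (trials.task == "task_a")
            & (trials.demand == "high")
        )
        trials.loc[mask, "correct"] = 0
        with pytest.raises(sc.SeparationError, match="task_a"):
            sc.accuracy_glmm(trials)

    def test_sum_coding_is_plus_minus_half(self):
        trials, _ = sc.gen_accuracy(n_participants=4, n_items=8, seed=2)
        X, names, codes = _factorial_design(
            trials, "group", "task", "demand")
        for col in (codes["group"], codes["task"], codes["demand"]):
            assert set(np.unique(col)) == {-0.5, 0.5}
        assert names[0] == "intercept"
        assert X.shape[1] == 8


class TestCorrelate:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert sc.correlate(x, x)[0] == pytest.approx(1.0)
        assert sc.correlate(x, -x)[0] == pytest.approx(-1.0)

    def test_toy_pairs_closed_form(self):
        r, p = sc.correlate([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)

    @given(
        a=st.floats(0.1, 5.0),
        b=st.floats(-10.0, 10.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_invariant_to_positive_affine_transform(self, a, b):
        x = np.array([0.2, 1.5, -0.7, 2.2, 0.9, -1.4])
        y = np.array([1.0, 2.1, -0.3, 1.8, 0.4, -0.9])
        r0, p0 = sc.correlate(x, y)
        r1, p1 = sc.correlate(a * x + b, y)
        assert r1 == pytest.approx(r0, abs=1e-9)
        assert p1 == pytest.approx(p0, abs=1e-9)

    def test_pairwise_complete_handling(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, 8.0, 10.0]
        r, _ = sc.correlate(x, y)
        assert r == pytest.approx(1.0)

    def test_errors(self):
        with pytest.raises(ValueError, match="3 complete"):
            sc.correlate([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValueError, match="zero-variance"):
            sc.correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
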