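"""Psychometric GLM algebra, outlier rule, ANOVA/post-hocs, GLMMs and cues."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from paradur.glmm import MixedGLMResult
from paradur.kinematics import MotionLaw
from paradur.observer import CohortSpec, simulate_cohort
from paradur.psychometrics import (
    LAW_ORDER,
    LOG3,
    GlmmFitMain,
    bic_select,
    bootstrap_differences,
    cue_reanalysis,
    detect_outliers,
    fit_all_subjects,
    fit_glmm_control,
    fit_glmm_main,
    fit_psychometric,
    glmm_pse_jnd,
    holm_adjust,
    pairwise_holm,
    rm_anova,
)

DESIGN_D = np.array([0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3])


def _binomial_trials(eta0, eta1, reps, seed, durations=DESIGN_D):
    rng = np.random.default_rng(seed)
    rows = []
    for D in durations:
        p = expit(eta0 + eta1 * D)
        y = rng.random(reps) < p
        for v in y:
            rows.append({"D_comp": D, "comparison_longer": bool(v)})
    return pd.DataFrame(rows)


class TestPsychometricGLM:
    def test_monte_carlo_recovery(self):
        """eta recovered within 2% from 1e4 replications per duration."""
        df = _binomial_trials(-15.0, 15.0, 10_000, seed=8)
        fit = fit_psychometric(df)
        assert fit.converged
        assert fit.eta0 == pytest.approx(-15.0, rel=0.02)
        assert fit.eta1 == pytest.approx(15.0, rel=0.02)

    def test_derived_quantities_algebra(self):
        df = _binomial_trials(-10.0, 10.0, 3000, seed=9)
        fit = fit_psychometric(df)
        assert fit.pse == pytest.approx(-fit.eta0 / fit.eta1, abs=1e-12)
        assert fit.jnd == pytest.approx(LOG3 / fit.eta1, abs=1e-12)
        assert fit.wf == pytest.approx(fit.jnd)  # T_ref = 1 s

    def test_shift_equivariance(self):
        """Shifting all durations by c shifts the PSE by c, JND unchanged."""
        df = _binomial_trials(-12.0, 12.0, 2000, seed=10)
        fit = fit_psychometric(df)
        shifted = df.copy()
        shifted["D_comp"] = shifted["D_comp"] + 0.25
        fit_s = fit_psychometric(shifted)
        assert fit_s.pse == pytest.approx(fit.pse + 0.25, abs=1e-6)
        assert fit_s.jnd == pytest.approx(fit.jnd, abs=1e-9)

    def test_degenerate_inputs_flagged(self):
        one_level = pd.DataFrame(
            {"D_comp": [1.0] * 10, "comparison_longer": [True] * 5 + [False] * 5}
        )
        assert not fit_psychometric(one_level).converged
        wrong_sign = _binomial_trials(12.0, -12.0, 500, seed=11)
        assert not fit_psychometric(wrong_sign).converged


class TestOutliers:
    def test_single_outlier_flagged(self):
        vals = [0.07, 0.08, 0.09, 0.10, 0.50]
        flags = detect_outliers(vals)
        # brute-force oracle: type-7 quartiles of the five values
        q1, q3 = np.percentile(vals, [25, 75])
        expected = (np.array(vals) > q3 + 1.5 * (q3 - q1)) | (
            np.array(vals) < q1 - 1.5 * (q3 - q1)
        )
        assert np.array_equal(flags, expected)
        assert flags.tolist() == [False, False, False, False, True]

    def test_all_equal_no_outliers(self):
        assert not detect_outliers([0.1] * 6).any()

    def test_requires_four_values(self):
        with pytest.raises(ValueError):
            detect_outliers([1.0, 2.0, 3.0])


class TestRMAnova:
    def test_degrees_of_freedom(self):
        rng = np.random.default_rng(0)
        res = rm_anova(rng.normal(size=(15, 3)))
        assert (res.df1, res.df2) == (2, 28)
        assert len(res.shapiro_p) == 3

    def test_identical_columns_no_effect(self):
        v = np.tile(np.arange(10.0)[:, None], (1, 3))
        res = rm_anova(v)
        assert res.F == pytest.approx(0.0, abs=1e-10)

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=(9, 4))
        res = rm_anova(v)
        n, k = v.shape
        grand = v.mean()
        ss_cond = n * np.sum((v.mean(axis=0) - grand) ** 2)
        ss_subj = k * np.sum((v.mean(axis=1) - grand) ** 2)
        ss_tot = np.sum((v - grand) ** 2)
        ss_err = ss_tot - ss_cond - ss_subj
        F = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
        assert res.F == pytest.approx(F, abs=1e-10)

    def test_incomplete_matrix_rejected(self):
        v = np.ones((5, 3))
        v[0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova(v)


class TestHolm:
    def test_hand_stepped_example(self):
        adj = holm_adjust([0.01, 0.04, 0.20])
        assert np.allclose(adj, [0.03, 0.08, 0.20])

    def test_identical_pairs_p_one(self):
        v = np.tile(np.arange(6.0)[:, None], (1, 3))
        table = pairwise_holm(v, ["a", "b", "c"])
        assert (table["p_holm"] == 1.0).all()

    def test_monotonicity(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=(12, 4))
        table = pairwise_holm(v)
        assert (table["p_holm"] >= table["p_raw"] - 1e-15).all()


def _dummy_main_fit(beta):
    res = MixedGLMResult(
        beta=np.asarray(beta, float), theta=np.zeros(3),
        cov_re=np.eye(2), loglike=0.0, bic=0.0, converged=True,
        n_obs=1, n_groups=1, k_params=9, message="", re_modes=np.zeros((1, 2)),
    )
    return GlmmFitMain(result=res, baseline=LAW_ORDER[0], law_order=LAW_ORDER)


class TestGlmmDerivedQuantities:
    def test_population_coefficient_arithmetic(self):
        """-intercept/slope and log(3)/slope on representative coefficients."""
        fit = _dummy_main_fit([-15.04, 14.94, 0, 0, 0, 0])
        pj = glmm_pse_jnd(fit)
        pse, jnd = pj[LAW_ORDER[0]]
        assert pse == pytest.approx(1.0067, abs=5e-4)
        assert jnd == pytest.approx(0.0735, abs=5e-4)

    def test_zero_effects_collapse_laws(self):
        pj = glmm_pse_jnd(_dummy_main_fit([-15.0, 15.0, 0, 0, 0, 0]))
        vals = list(pj.values())
        assert all(v == vals[0] for v in vals)

    def test_jnd_monotone_in_slope(self):
        j1 = glmm_pse_jnd(_dummy_main_fit([-15, 15, 0, 0, 0, 0]))[LAW_ORDER[0]][1]
        j2 = glmm_pse_jnd(_dummy_main_fit([-16, 16, 0, 0, 0, 0]))[LAW_ORDER[0]][1]
        assert j2 < j1

    def test_nonpositive_slope_flagged(self):
        pj = glmm_pse_jnd(_dummy_main_fit([-15, 15, 0, 0, 0, -20]))
        assert np.isnan(pj[LAW_ORDER[2]][1])


class TestMainGlmm:
    def test_baseline_choice_invariance(self, small_cohort_trials):
        """Per-law PSE/JND do not depend on which law is the dummy baseline."""
        fit_a = fit_glmm_main(small_cohort_trials, baseline=MotionLaw.CONST_TANGENTIAL)
        fit_b = fit_glmm_main(small_cohort_trials, baseline=MotionLaw.GRAVITATIONAL)
        pj_a, pj_b = glmm_pse_jnd(fit_a), glmm_pse_jnd(fit_b)
        for law in MotionLaw:
            assert pj_a[law][0] == pytest.approx(pj_b[law][0], abs=2e-3)
            assert pj_a[law][1] == pytest.approx(pj_b[law][1], abs=2e-3)

    def test_coefficient_table_layout(self, small_cohort_trials):
        fit = fit_glmm_main(small_cohort_trials)
        table = fit.coefficients()
        assert list(table["term"]) == ["intercept", "D", "M1", "M2", "D:M1", "D:M2"]


class TestBootstrap:
    def test_degenerate_single_replicate(self, small_cohort_trials):
        fit = fit_glmm_main(small_cohort_trials)
        out = bootstrap_differences(fit, B=1, seed=1)
        for pair in out["pairs"].values():
            ci = pair["jnd"]["ci"]
            assert ci[0] == pytest.approx(ci[1])

    def test_null_difference_covers_zero(self):
        """Identical generative laws: the bootstrap CI should include 0."""
        spec = CohortSpec(
            n_subjects=8,
            jnd_mean={law: 0.09 for law in MotionLaw},
            pse_mean={law: 1.0 for law in MotionLaw},
            bad_rt_rate=0.0, inattention_rate=0.0, seed=12,
        )
        trials = simulate_cohort(spec, replications=10, schedule_seed=120,
                                 response_seed=121)
        fit = fit_glmm_main(trials)
        out = bootstrap_differences(fit, B=40, seed=2)
        assert out["n_replicates"] >= 35
        covering = [
            not pair["jnd"]["excludes_zero"] for pair in out["pairs"].values()
        ]
        assert sum(covering) >= 2  # at least two of the three null pairs


class TestControlGlmm:
    def test_duration_only_cohort_flat_control_slope(self, small_cohort_trials):
        fit = fit_glmm_control(small_cohort_trials)
        assert fit.slope_experimental > 0.5
        assert abs(fit.slope_control) < 0.25 * fit.slope_experimental

    def test_missing_conditions_rejected(self, small_cohort_trials):
        only_exp = small_cohort_trials[small_cohort_trials["condition_id"].isin([3, 5])]
        with pytest.raises(ValueError):
            fit_glmm_control(only_exp)


class TestBicSelect:
    def test_no_law_effect_prefers_no_interaction(self):
        spec = CohortSpec(
            n_subjects=6,
            jnd_mean={law: 0.09 for law in MotionLaw},
            pse_mean={law: 1.0 for law in MotionLaw},
            jnd_sd={law: 0.0 for law in MotionLaw},
            pse_sd={law: 0.0 for law in MotionLaw},
            bad_rt_rate=0.0, inattention_rate=0.0, seed=13,
        )
        trials = simulate_cohort(spec, replications=8, schedule_seed=130,
                                 response_seed=131)
        chosen, fit, table = bic_select(trials)
        assert not chosen["interactions"]
        assert len(table) == 4 and np.isfinite(table["bic"]).all()

    def test_duplicate_candidates_tie_break_first(self, small_cohort_trials):
        cands = [
            {"random": "intercept", "interactions": True},
            {"random": "intercept", "interactions": True},
        ]
        chosen, fit, table = bic_select(small_cohort_trials, candidates=cands)
        assert table["bic"].iloc[0] == pytest.approx(table["bic"].iloc[1], abs=1e-6)
        assert chosen == cands[0]

    def test_needs_two_candidates(self, small_cohort_trials):
        with pytest.raises(ValueError):
            bic_select(small_cohort_trials, candidates=[{"random": "intercept",
                                                         "interactions": True}])


class TestCueReanalysis:
    def test_duration_cue_reproduces_psychometric_fit(self, small_cohort_trials):
        """With the cue = normalized duration, the refit is the duration fit."""
        base = fit_all_subjects(small_cohort_trials)
        cue = cue_reanalysis(small_cohort_trials, "duration")
        merged = base.merge(cue, on=["subject_id", "law"], suffixes=("", "_cue"))
        ok = merged[merged["converged"] & merged["converged_cue"]]
        # reference duration is 1 s, so normalization is the identity
        assert np.allclose(ok["jnd"], ok["jnd_cue"], atol=1e-9)

    def test_reference_cue_normalizes_to_one(self, obs):
        from paradur.psychometrics import _cue_value

        for cue in ("initial-tangential-velocity", "dilation-rate", "elevation-rate"):
            for law in MotionLaw:
                ref = _cue_value(4, law, cue, "start", obs, 9.8)
                assert ref is not None and ref != 0

    def test_noncausal_cue_has_larger_jnd(self, small_cohort_trials):
        """A duration-only cohort is better explained by duration than by the
        initial-speed cue, so the cue-scale JNDs come out larger."""
        base = fit_all_subjects(small_cohort_trials)
        cue = cue_reanalysis(small_cohort_trials, "initial-tangential-velocity")
        m_base = base[base["converged"]]["jnd"].median()
        m_cue = cue[cue["converged"]]["jnd"].median()
        assert m_cue > m_base

    def test_unknown_cue_rejected(self, small_cohort_trials):
        with pytest.raises(ValueError):
            cue_reanalysis(small_cohort_trials, "colour")
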