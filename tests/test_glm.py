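"""Choice GLM ladder: PCA features, design construction, fits, selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import behaviorcp as bcp
from behaviorcp.exceptions import InputError
from behaviorcp.glm import (
    DEFAULT_NESTING, MODEL_SPECS, DesignSpec, build_design_matrix,
    fit_choice_glm, fit_model, glm_row_mask, stepwise_select, trajectory_pca,
)


class TestTrajectoryPCA:
    def test_single_profile_explains_everything(self):
        profile = np.sin(np.linspace(0, 2 * np.pi, 40))
        X = np.outer([1.0, 2.0, -1.0, 0.5, 3.0], profile)
        feats = trajectory_pca(X)
        assert feats.explained_variance_fraction[0] > 0.999

    def test_planted_modes_variance_ratio(self):
        # two orthogonal modes with 4:1 variance and no noise -> (0.8, 0.2)
        rng = np.random.default_rng(0)
        t = np.linspace(0, 1, 60)
        m1 = np.sin(2 * np.pi * t)
        m2 = np.cos(2 * np.pi * t)
        X = (
            np.outer(rng.normal(0, 2.0, 500), m1)
            + np.outer(rng.normal(0, 1.0, 500), m2)
        )
        feats = trajectory_pca(X)
        assert np.allclose(feats.explained_variance_fraction, [0.8, 0.2], atol=0.03)

    def test_scores_uncorrelated(self):
        X = np.random.default_rng(1).normal(size=(200, 30))
        feats = trajectory_pca(X)
        r = np.corrcoef(feats.pc_scores.T)[0, 1]
        assert abs(r) < 1e-10


def _session_frame(n, premature_at=(), subject="A", session="s1"):
    stim = np.resize([0.6, 1.38, 1.62, 2.4], n)
    df = pd.DataFrame(
        {
            "subject": subject, "session": session, "trial": np.arange(1, n + 1),
            "stimulus_s": stim,
            "choice": np.where(np.arange(n) % 2 == 0, "long", "short"),
            "rewarded": False,
            "premature": np.isin(np.arange(1, n + 1), premature_at),
        }
    )
    df["prev_stimulus_s"] = df.stimulus_s.shift(1)
    df["prev_reward_code"] = 0
    df["prev_difficulty_s"] = (df.prev_stimulus_s - 1.5).abs()
    return df


class TestDesignMatrix:
    def test_exclusion_rules(self):
        trials = _session_frame(10, premature_at=(4,))
        mask = glm_row_mask(trials)
        kept = trials.trial[mask].tolist()
        assert kept == [2, 3, 6, 7, 8, 9, 10]

    def test_history_coding(self, small_session):
        trials, _ = small_session
        X, y = build_design_matrix(trials, None, MODEL_SPECS[3])
        assert set(X.columns) >= {"const", "interval", "prev_reward",
                                  "prev_difficulty", "prev_interval"}
        sub = trials.loc[X.index]
        assert X.prev_reward.isin([-1, 0, 1]).all()
        assert np.allclose(
            X.prev_difficulty, (X.prev_interval - 1.5).abs(), atol=1e-12
        )
        # example: previous stimulus 1.38 -> difficulty 0.12
        rows = X.loc[np.isclose(X.prev_interval, 1.38)]
        assert np.allclose(rows.prev_difficulty, 0.12)
        assert (y == (sub.choice == "long")).all()

    def test_no_retained_row_touches_premature(self, task):
        trials, trajs = bcp.simulate_dataset(task, n_sessions=2, n_trials=150, seed=5)
        mask = glm_row_mask(trials)
        assert not trials.premature[mask].any()
        prev_prem = trials.premature.shift(1, fill_value=False)
        same_sess = trials.session.eq(trials.session.shift(1)) & trials.subject.eq(
            trials.subject.shift(1)
        )
        assert not (prev_prem & same_sess)[mask].any()

    def test_traj_terms_require_features(self, small_session):
        trials, _ = small_session
        with pytest.raises(InputError):
            build_design_matrix(trials, None, MODEL_SPECS[2])


class TestFit:
    def test_intercept_only_closed_form(self):
        n = 400
        X = pd.DataFrame({"const": np.ones(n)})
        y = pd.Series([True, False] * (n // 2))
        res = fit_choice_glm(X, y)
        assert np.isclose(res.deviance, 2 * n * np.log(2), rtol=1e-6)
        assert res.prediction_success == 50.0

    def test_matches_direct_likelihood_maximization(self):
        # brute-force oracle: minimize the negative log-likelihood directly
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        logit = -0.3 + 1.2 * x
        y = rng.random(20) < 1 / (1 + np.exp(-logit))
        X = pd.DataFrame({"const": np.ones(20), "x": x})

        def nll(beta):
            z = X.to_numpy() @ beta
            return np.sum(np.log1p(np.exp(-z)) * y + np.log1p(np.exp(z)) * (~y))

        oracle = minimize(nll, np.zeros(2), method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-12}).x
        res = fit_choice_glm(X, y)
        assert np.allclose(res.params.to_numpy(), oracle, atol=1e-3)

    def test_information_criterion_identities(self, small_session):
        trials, trajs = small_session
        results, _, _ = bcp.run_model_ladder(trials, trajs)
        for r in results.values():
            assert np.isclose(r.aic, r.deviance + 2 * r.n_params)
            assert np.isclose(r.bic, r.deviance + r.n_params * np.log(r.n_trials))

    def test_noise_column_cannot_hurt_deviance(self, small_session):
        trials, _ = small_session
        X, y = build_design_matrix(trials, None, MODEL_SPECS[1])
        base = fit_choice_glm(X, y)
        X2 = X.copy()
        X2["noise"] = np.random.default_rng(3).normal(size=len(X))
        bigger = fit_choice_glm(X2, y)
        assert bigger.deviance <= base.deviance + 1e-6

    def test_nesting_monotonicity(self, task):
        trials, trajs = bcp.simulate_dataset(task, n_sessions=2, n_trials=200, seed=8)
        results, _, _ = bcp.run_model_ladder(trials, trajs)
        assert results[4].deviance <= results[2].deviance + 1e-6
        assert results[4].deviance <= results[3].deviance + 1e-6
        assert results[2].deviance <= results[1].deviance + 1e-6
        assert results[3].deviance <= results[1].deviance + 1e-6

    def test_history_effect_recovered(self, task):
        trials, trajs = bcp.simulate_dataset(task, n_sessions=4, n_trials=417, seed=10)
        result = fit_model(trials, None, MODEL_SPECS[3])
        assert result.params["prev_reward"] > 0


class TestStepwise:
    def test_recovers_subject_interval_interaction(self):
        # two subjects with different sensitivities: true model has S x I
        rng = np.random.default_rng(0)
        frames = []
        for subject, slope in (("A", 2.0), ("B", 6.0)):
            stim = rng.choice([0.6, 1.05, 1.38, 1.62, 1.95, 2.4], 2500)
            logit = slope * (stim - 1.5)
            choice = rng.random(2500) < 1 / (1 + np.exp(-logit))
            df = pd.DataFrame(
                {
                    "subject": subject, "session": "s1",
                    "trial": np.arange(1, 2501), "stimulus_s": stim,
                    "choice": np.where(choice, "long", "short"),
                    "rewarded": False, "premature": False,
                    "prev_stimulus_s": np.roll(stim, 1),
                    "prev_reward_code": 0,
                }
            )
            df["prev_difficulty_s"] = (df.prev_stimulus_s - 1.5).abs()
            frames.append(df)
        trials = pd.concat(frames, ignore_index=True)
        final = stepwise_select(MODEL_SPECS[1], trials, None)
        assert "subject:interval" in final.terms

    def test_removes_null_history_terms(self, task):
        params = bcp.GenerativeParams(
            history_reward_weight=0.0, traj_coupling_gain=0.0
        )
        trials, _ = bcp.simulate_dataset(
            task, params, n_sessions=4, n_trials=417, seed=12
        )
        final = stepwise_select(MODEL_SPECS[3], trials, None)
        dropped = set(MODEL_SPECS[3].terms) - set(final.terms)
        assert {"prev_reward", "prev_difficulty", "prev_interval"} & dropped

    def test_fixed_point_returns_unchanged(self):
        # strong single-predictor data: interval alone is BIC-minimal
        rng = np.random.default_rng(5)
        stim = rng.choice([0.6, 1.38, 1.62, 2.4], 800)
        choice = rng.random(800) < 1 / (1 + np.exp(-6 * (stim - 1.5)))
        trials = pd.DataFrame(
            {
                "subject": "A", "session": "s1", "trial": np.arange(1, 801),
                "stimulus_s": stim,
                "choice": np.where(choice, "long", "short"),
                "rewarded": False, "premature": False,
                "prev_stimulus_s": np.roll(stim, 1), "prev_reward_code": 0,
            }
        )
        trials["prev_difficulty_s"] = (trials.prev_stimulus_s - 1.5).abs()
        spec = DesignSpec(("interval",))
        assert stepwise_select(spec, trials, None).terms == ("interval",)


class TestCompare:
    def test_identical_models(self):
        X = pd.DataFrame({"const": np.ones(100), "x": np.arange(100.0)})
        y = pd.Series(np.arange(100) % 2 == 0)
        r = fit_choice_glm(X, y, spec=DesignSpec(("interval",)))
        _, lr = bcp.compare_models({1: r, 2: r}, nesting=[(1, 2)])
        assert lr.iloc[0].chi2 == 0.0 and lr.iloc[0].p == 1.0

    def test_chi2_tail_value(self):
        from behaviorcp.glm import GLMResult

        def fake(dev, k):
            return GLMResult(
                spec=DesignSpec(("interval",) if k == 2 else
                                ("interval", "traj_pc1", "traj_pc2")),
                params=pd.Series(dtype=float), deviance=dev,
                aic=dev + 2 * k, bic=dev + k * np.log(100),
                prediction_success=50.0, n_params=k, n_trials=100,
                converged=True,
            )

        _, lr = bcp.compare_models(
            {1: fake(100.0, 2), 2: fake(90.0, 4)}, nesting=[(1, 2)]
        )
        assert np.isclose(lr.iloc[0].chi2, 10.0)
        assert np.isclose(lr.iloc[0].p, 0.0067, atol=0.0005)

    def test_non_nested_pair_refused(self):
        from behaviorcp.glm import GLMResult

        a = GLMResult(DesignSpec(("traj_pc1",)), pd.Series(dtype=float),
                      10, 12, 14, 50, 1, 10, True)
        b = GLMResult(DesignSpec(("prev_reward",)), pd.Series(dtype=float),
                      8, 12, 14, 50, 2, 10, True)
        with pytest.raises(InputError):
            bcp.compare_models({1: a, 2: b}, nesting=[(1, 2)])

    def test_declared_nesting_holds_on_initial_specs(self):
        for small, big in DEFAULT_NESTING:
            assert MODEL_SPECS[small].is_nested_in(MODEL_SPECS[big])
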