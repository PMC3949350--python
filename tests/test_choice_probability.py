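"""Choice probability: auROC, shuffle nulls, weighted GMM, Bayes, binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import behaviorcp as bcp
from behaviorcp.choice_probability import (
    CPBinning, TrajectoryChoiceModel, choice_variance_table, cp_timecourse,
)
from behaviorcp.exceptions import InputError
from behaviorcp.trajectories import TrajectoryMatrix


def brute_force_auroc(pos, neg):
    """Oracle: exhaustive pair counting, ties worth one half."""
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    wins = sum((x > y) + 0.5 * (x == y) for x in pos for y in neg)
    return wins / (pos.size * neg.size)


class TestChoiceVariance:
    def test_worked_value(self):
        assert round(bcp.choice_variance(34, 56), 4) == 13.3571

    @pytest.mark.parametrize(
        "n_long,n_total,expected", [(0, 10, 0.0), (10, 10, 0.0), (2, 4, 1.0)]
    )
    def test_simple_values(self, n_long, n_total, expected):
        assert bcp.choice_variance(n_long, n_total) == expected

    def test_bounds(self):
        with pytest.raises(InputError):
            bcp.choice_variance(1, 0)
        with pytest.raises(InputError):
            bcp.choice_variance(5, 4)

    def test_cell_table_and_weights(self, small_session):
        trials, _ = small_session
        table = choice_variance_table(trials)
        assert (table.variance <= table.n / 4 + 1e-9).all()
        w = bcp.trial_weights(trials)
        assert w.shape == (len(trials),)
        assert (w[trials.premature.to_numpy()] == 0).all()

    def test_highest_variance_stimulus_is_near_boundary(self, task):
        trials, _ = bcp.simulate_session(task, bcp.GenerativeParams(), 2000, seed=1)
        sel = bcp.select_highest_variance_stimulus(trials)
        assert sel["Edgar"] in (1.38, 1.62)


class TestAuroc:
    def test_examples(self):
        assert bcp.instantaneous_cp([1.0, 2.0], [1.0, 2.0]) == 0.5
        assert bcp.instantaneous_cp([2.0, 3.0], [0.0, 1.0]) == 1.0
        assert bcp.instantaneous_cp([0.0, 2.0], [0.0, 1.0]) == 0.625

    def test_rectification_and_label_swap(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=15), rng.normal(1.0, 1.0, size=12)
        cp_ab = bcp.instantaneous_cp(a, b)
        cp_ba = bcp.instantaneous_cp(b, a)
        assert cp_ab == cp_ba
        assert 0.5 <= cp_ab <= 1.0

    def test_empty_class_signalled(self):
        with pytest.raises(InputError):
            bcp.instantaneous_cp([], [1.0])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(-5, 5), min_size=1, max_size=20),
        st.lists(st.integers(-5, 5), min_size=1, max_size=20),
    )
    def test_matches_brute_force_exactly(self, pos, neg):
        """Rank-sum identity equals exhaustive pair counting, ties and all."""
        assert bcp.auroc(pos, neg) == pytest.approx(
            brute_force_auroc(pos, neg), abs=1e-12
        )


def _toy_trajs(positions, frame_rate=120.0, t0=-0.5):
    taxis = t0 + np.arange(positions.shape[1]) / frame_rate
    return TrajectoryMatrix(positions, taxis, frame_rate)


class TestCPTimecourse:
    def test_deterministic_null_band(self):
        rng = np.random.default_rng(0)
        trajs = _toy_trajs(rng.normal(size=(30, 40)))
        y = rng.random(30) < 0.5
        s1 = cp_timecourse(trajs, y, n_shuffles=50, seed=7)
        s2 = cp_timecourse(trajs, y, n_shuffles=50, seed=7)
        assert np.array_equal(s1.null_upper, s2.null_upper)
        assert np.array_equal(s1.cp, s2.cp)

    def test_strong_coupling_low_noise_saturates(self, task):
        # choice ~ sign(z) almost surely (huge latent SD, no other noise),
        # and z is read out nearly perfectly from the trajectory
        params = bcp.GenerativeParams(
            traj_coupling_gain=300.0, traj_noise_sd=1.0,
            measurement_noise_sd=0.1, psycho_slope=0.0,
            history_reward_weight=0.0, latent_noise_sd=3.0,
        )
        trials, trajs = bcp.simulate_session(task, params, 80, seed=2)
        series = cp_timecourse(
            trajs, (trials.choice == "long").to_numpy(), seed=0
        )
        plateau = series.cp[series.time_axis >= 0.5]
        assert np.median(plateau) > 0.95
        assert series.significant[series.time_axis >= 0.5].mean() > 0.9

    def test_small_class_flagged_unusable(self):
        trajs = _toy_trajs(np.random.default_rng(1).normal(size=(5, 10)))
        series = cp_timecourse(trajs, np.array([True] * 4 + [False]), seed=0)
        assert not series.usable
        assert np.isnan(series.cp).all()

    def test_invariants(self):
        rng = np.random.default_rng(5)
        trajs = _toy_trajs(rng.normal(size=(40, 25)))
        y = rng.random(40) < 0.5
        s = cp_timecourse(trajs, y, seed=1)
        assert (s.cp >= 0.5).all() and (s.cp <= 1.0).all()
        assert np.array_equal(s.significant, s.cp > s.null_upper)


class TestWeightedGMM:
    def test_uniform_weights_single_component_is_mle(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (200, 3)), rng.normal(3, 1, (200, 3))])
        y = np.array(["short"] * 200 + ["long"] * 200)
        model = TrajectoryChoiceModel(n_components=1, pca_guard=False).fit(X, y)
        for c, mask in (("short", slice(0, 200)), ("long", slice(200, 400))):
            mix = model.mixtures_[c]
            assert np.allclose(mix["means"][0], X[mask].mean(axis=0), atol=1e-8)
            assert np.allclose(
                mix["covariances"][0],
                np.cov(X[mask].T, bias=True) + 1e-6 * np.eye(3),
                atol=1e-7,
            )

    def test_matches_sklearn_single_gaussian_posterior(self):
        """Independent oracle: unweighted 1-component class densities agree
        with sklearn GaussianMixture fits used in a Bayes rule."""
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 1, (150, 2)), rng.normal(2, 1.5, (150, 2))])
        y = np.array([False] * 150 + [True] * 150)
        model = TrajectoryChoiceModel(n_components=1, pca_guard=False).fit(X, y)
        grid = rng.normal(1, 2, size=(50, 2))
        ours = model.log_likelihood(grid)
        for j, mask in enumerate((~y, y)):
            gm = GaussianMixture(1, reg_covar=1e-6, random_state=0).fit(X[mask])
            assert np.allclose(ours[:, j], gm.score_samples(grid), atol=1e-6)

    def test_zero_weight_trials_have_no_influence(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(120, 4))
        y = np.array(["long", "short"] * 60)
        w = np.ones(120)
        w[::5] = 0.0
        m1 = TrajectoryChoiceModel(n_components=2, pca_guard=False).fit(
            X, y, sample_weight=w
        )
        m2 = TrajectoryChoiceModel(n_components=2, pca_guard=False).fit(
            X[w > 0], y[w > 0], sample_weight=w[w > 0]
        )
        for c in ("long", "short"):
            assert np.allclose(
                m1.mixtures_[c]["means"], m2.mixtures_[c]["means"], atol=1e-6
            )
        assert np.allclose(m1.priors_, m2.priors_, atol=1e-12)

    def test_well_separated_classes_heldout_accuracy(self):
        rng = np.random.default_rng(6)
        X_train = np.vstack([rng.normal(0, 1, (300, 2)), rng.normal(6, 1, (300, 2))])
        y_train = np.array(["short"] * 300 + ["long"] * 300)
        X_test = np.vstack([rng.normal(0, 1, (200, 2)), rng.normal(6, 1, (200, 2))])
        y_test = np.array(["short"] * 200 + ["long"] * 200)
        model = bcp.fit_trajectory_choice_model(X_train, y_train, seed=0)
        acc = (model.predict(X_test) == y_test).mean()
        assert acc > 0.95

    def test_pca_guard_triggers_in_high_dimensions(self, caplog):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(100, 50))
        y = np.array(["long", "short"] * 50)
        model = TrajectoryChoiceModel(n_components=2).fit(X, y)
        assert model.pca_ is not None
        assert model.pca_.n_components_ < 50


class TestPosterior:
    def _manual_model(self, ratio):
        """Two 1-D unit-variance Gaussian classes whose densities at x=0
        stand in the given likelihood ratio (long:short)."""
        model = TrajectoryChoiceModel(n_components=1)
        model.classes_ = np.array(["long", "short"])
        model.priors_ = np.array([0.5, 0.5])
        model.n_features_in_ = 1
        model.pca_ = None
        mu = np.sqrt(2 * np.log(ratio)) if ratio > 1 else 0.0
        model.mixtures_ = {
            "long": {"weights": np.array([1.0]), "means": np.array([[0.0]]),
                     "covariances": np.array([[[1.0]]])},
            "short": {"weights": np.array([1.0]), "means": np.array([[mu]]),
                      "covariances": np.array([[[1.0]]])},
        }
        return model

    def test_equal_likelihoods_give_half(self):
        model = self._manual_model(1.0)
        assert np.isclose(bcp.posterior_choice_probability(model, [[0.0]])[0], 0.5)

    def test_three_to_one_ratio(self):
        model = self._manual_model(3.0)
        assert np.isclose(
            bcp.posterior_choice_probability(model, [[0.0]])[0], 0.75
        )

    def test_posteriors_normalize_and_never_nan(self):
        model = self._manual_model(2.0)
        X = np.concatenate(
            [np.random.default_rng(0).normal(size=999), [1e4]]
        ).reshape(-1, 1)
        proba = model.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert np.isfinite(proba).all()

    def test_prior_free_likelihood_scale_invariance(self):
        """Multiplying both class likelihoods by a constant cancels in the
        Bayes posterior: shifting both log-likelihoods leaves it unchanged."""
        model = self._manual_model(3.0)
        X = np.random.default_rng(1).normal(size=(100, 1))
        log_like = model.log_likelihood(X)
        log_joint = log_like + np.log(model.priors_)
        from scipy.special import logsumexp

        p1 = np.exp(log_joint - logsumexp(log_joint, axis=1, keepdims=True))
        log_joint2 = (log_like + 123.4) + np.log(model.priors_)
        p2 = np.exp(log_joint2 - logsumexp(log_joint2, axis=1, keepdims=True))
        assert np.allclose(p1, p2)
        assert np.allclose(p1, model.predict_proba(X))


class TestBinning:
    def test_twelve_distinct_cps_six_bins_of_two(self):
        cps = np.linspace(0.1, 0.9, 12)
        binning = bcp.bin_trials_by_cp(cps, n_bins=6)
        assert np.array_equal(binning.counts, [2] * 6)

    def test_tied_cps_stable_equal_counts(self):
        binning = bcp.bin_trials_by_cp(np.full(13, 0.5), n_bins=6)
        assert binning.counts.max() - binning.counts.min() <= 1
        # stable tie-break: assignments non-decreasing in trial order
        assert (np.diff(binning.assignments) >= 0).all()

    def test_monotone_cps_monotone_bins(self):
        cps = np.linspace(0.1, 0.9, 30)
        binning = bcp.bin_trials_by_cp(cps, n_bins=6)
        assert (np.diff(binning.assignments) >= 0).all()

    def test_too_few_trials_rejected(self):
        with pytest.raises(InputError):
            bcp.bin_trials_by_cp([0.1, 0.2], n_bins=6)


class TestPerBinPsychometrics:
    def test_null_coupling_bins_indistinguishable(self, task):
        params = bcp.GenerativeParams(traj_coupling_gain=0.0)
        trials, trajs = bcp.simulate_session(task, params, 2400, seed=9)
        result = bcp.trajectory_cp_analysis(trials, trajs, seed=0)
        fits = result.bin_fits["Edgar"]
        bias = [f.bias_point_ for f in fits if f is not None]
        assert max(bias) - min(bias) < 0.2

    def test_binning_alignment_checked(self, small_session):
        trials, _ = small_session
        binning = CPBinning(np.zeros(5, int), 2, np.array([3, 2]), np.zeros(3))
        with pytest.raises(InputError):
            bcp.per_bin_psychometrics(trials, binning)
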