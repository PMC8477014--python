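"""Tabular classifiers, grid search, ensemble vote and backward elimination."""

import numpy as np
import pytest

from ethoclock.simulate import simulate_stream
from ethoclock.tabular import (
    EliminationProtocol,
    ModelSpec,
    backward_eliminate,
    default_grid,
    fit_classifier,
    grid_search,
    majority_vote,
    permutation_importance,
)
from ethoclock.windows import aggregate_samples
from .conftest import noise_injection_config


def _toy_separable(n=240, seed=0):
    rng = np.random.default_rng(seed)
    y = (np.arange(n) % 2).astype(np.int8)
    X = rng.standard_normal((n, 2)) * 0.1
    X[:, 0] += 3.0 * y
    return X, y


class TestFitClassifier:
    def test_defaults_are_tuned_values(self):
        assert ModelSpec.logistic().C == 0.1
        assert ModelSpec.logistic().solver == "newton-cg"
        f = ModelSpec.forest()
        assert (f.n_trees, f.max_features, f.min_leaf) == (80, "sqrt", 40)
        s = ModelSpec.svm()
        assert (s.kernel, s.gamma, s.svm_C) == ("rbf", 1.0, 10.0)

    @pytest.mark.parametrize("kind", ["logistic", "forest", "svm"])
    def test_separable_data_learned_and_deterministic(self, kind):
        X, y = _toy_separable()
        spec = ModelSpec(kind=kind, seed=3)
        m1 = fit_classifier(spec, X, y)
        m2 = fit_classifier(spec, X, y)
        assert np.mean(m1.predict(X) == y) == 1.0
        assert np.array_equal(m1.predict(X), m2.predict(X))
        scores = m1.score_night(X)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_single_class_labels_rejected(self):
        X, _ = _toy_separable()
        with pytest.raises(ValueError, match="single class"):
            fit_classifier(ModelSpec.logistic(), X, np.zeros(len(X)))

    def test_feature_count_checked_at_predict(self):
        X, y = _toy_separable()
        m = fit_classifier(ModelSpec.logistic(), X, y)
        with pytest.raises(ValueError, match="features"):
            m.predict(X[:, :1])


class TestGridSearch:
    def test_singleton_grid_returns_it(self):
        X, y = _toy_separable()
        spec = ModelSpec.logistic(C=7.0)
        assert grid_search([spec], X, y, k=4) is spec

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search([], np.zeros((4, 2)), np.array([0, 1, 0, 1]))

    def test_heavy_regularization_wins_on_collinear_noise(self):
        # weak replicated signal drowned in many noise columns: a lightly
        # regularized fit memorizes noise, a heavily regularized one wins CV
        rng = np.random.default_rng(7)
        n = 120
        z = rng.standard_normal(n)
        y = (z > 0).astype(np.int8)
        X = np.concatenate(
            [z[:, None] * 0.35 + rng.standard_normal((n, 100)),
             rng.standard_normal((n, 400))], axis=1,
        )
        grid = [ModelSpec.logistic(C=0.1), ModelSpec.logistic(C=1000.0)]

        def cv_acc(spec):
            from ethoclock.evaluate import block_kfold
            accs = []
            for tr, te in block_kfold(n, k=5, block_len=1, seed=12):
                m = fit_classifier(spec, X[tr], y[tr])
                accs.append(np.mean(m.predict(X[te]) == y[te]))
            return float(np.mean(accs))

        best = grid_search(grid, X, y, k=5, seed=12)
        direct = max(grid, key=cv_acc)
        assert best.C == direct.C == 0.1

    def test_repeat_with_same_seed_is_stable(self):
        X, y = _toy_separable()
        grid = default_grid("logistic")
        a = grid_search(grid, X, y, k=4, seed=5)
        b = grid_search(grid, X, y, k=4, seed=5)
        assert a is b


class TestMajorityVote:
    def test_two_of_three_carry_the_vote(self):
        a = np.array([0, 1, 1])
        b = np.array([0, 1, 0])
        c = np.array([1, 1, 0])
        assert majority_vote(a, b, c).tolist() == [0, 1, 0]

    def test_unanimous_identity(self):
        p = np.array([1, 0, 1, 1, 0])
        assert np.array_equal(majority_vote(p, p, p), p)

    def test_disjoint_error_thirds_yield_perfect_ensemble(self):
        y = np.zeros(9, dtype=int)
        a, b, c = y.copy(), y.copy(), y.copy()
        a[:3] = 1
        b[3:6] = 1
        c[6:] = 1
        assert np.array_equal(majority_vote(a, b, c), y)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            majority_vote(np.zeros(3), np.zeros(3), np.zeros(4))


@pytest.fixture(scope="module")
def noise_samples():
    cfg = noise_injection_config(seed=300)
    stream = simulate_stream(cfg)
    return cfg, aggregate_samples(stream, cfg.fps)


class TestBackwardElimination:
    def test_first_iteration_fits_every_behavior(self, noise_samples):
        cfg, samples = noise_samples
        proto = EliminationProtocol(window_len=20, stride=50, seed=0)
        trace = backward_eliminate(
            ModelSpec.logistic(), samples, cfg.schedule, proto, max_iterations=1
        )
        assert trace.fits_per_iteration == [cfg.catalog.size]

    def test_infinite_tolerance_runs_to_single_behavior(self, noise_samples):
        cfg, samples = noise_samples
        proto = EliminationProtocol(window_len=20, stride=50, seed=0)
        trace = backward_eliminate(
            ModelSpec.logistic(), samples, cfg.schedule, proto, tolerance=np.inf
        )
        assert len(trace.steps) == cfg.catalog.size - 1
        assert trace.fits_per_iteration == list(range(cfg.catalog.size, 1, -1))

    def test_retained_accuracy_never_below_stop_rule(self, noise_samples):
        cfg, samples = noise_samples
        proto = EliminationProtocol(window_len=20, stride=20, seed=1)
        tol = 0.005
        trace = backward_eliminate(
            ModelSpec.logistic(), samples, cfg.schedule, proto, tolerance=tol
        )
        final_best = max([trace.baseline_accuracy] + [a for _, a in trace.steps])
        assert trace.retained_accuracy >= final_best - tol


class TestPermutationImportance:
    def test_noise_behavior_scores_near_zero(self, noise_samples):
        from ethoclock.windows import build_windows, flatten_windows

        cfg, samples = noise_samples
        ws = build_windows(samples, cfg.schedule, window_len=20, stride=20)
        X, y = flatten_windows(ws), ws.labels
        model = fit_classifier(
            ModelSpec.forest(seed=2), X, y, catalog=ws.catalog, window_len=20
        )
        imp = permutation_importance(model, X, y, n_repeats=3, seed=2)
        noise_idx = ws.catalog.index("noise")
        assert imp[noise_idx] < 0.01
        assert imp.max() > 5 * max(imp[noise_idx], 1e-6)

    def test_same_seed_reproduces_scores(self, noise_samples):
        from ethoclock.windows import build_windows, flatten_windows

        cfg, samples = noise_samples
        ws = build_windows(samples, cfg.schedule, window_len=20, stride=40)
        X, y = flatten_windows(ws), ws.labels
        model = fit_classifier(
            ModelSpec.logistic(), X, y, catalog=ws.catalog, window_len=20
        )
        a = permutation_importance(model, X, y, n_repeats=2, seed=9)
        b = permutation_importance(model, X, y, n_repeats=2, seed=9)
        assert np.array_equal(a, b)

    def test_requires_feature_manifest(self):
        X, y = _toy_separable()
        m = fit_classifier(ModelSpec.logistic(), X, y)
        with pytest.raises(ValueError, match="manifest"):
            permutation_importance(m, X, y)
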