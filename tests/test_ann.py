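"""Evidence-framework network: forward pass, gradients, hyperparameter
updates against the closed-form linear oracle, committees and ARD."""

import numpy as np
import pytest

import sludgeqspr as sq
from sludgeqspr import ann


def bayes_ridge_oracle(X, y, alpha0, beta0, n_updates):
    """Closed-form evidence recursion for the linear model y = b + w.x with
    one prior precision per coefficient (the linear-mode grouping)."""
    Phi = np.column_stack([X, np.ones(len(y))])
    N, W = Phi.shape
    alphas = np.full(W, alpha0)
    beta = beta0
    w = None
    for it in range(n_updates + 1):
        A = beta * Phi.T @ Phi + np.diag(alphas)
        w = beta * np.linalg.solve(A, Phi.T @ y)
        if it == n_updates:
            break
        gamma = 1.0 - alphas * np.diag(np.linalg.inv(A))
        alphas = np.clip(gamma / np.maximum(w**2, 1e-300), 1e-8, 1e8)
        r = y - Phi @ w
        beta = float(np.clip((N - gamma.sum()) / (r @ r), 1e-8, 1e8))
    A = beta * Phi.T @ Phi + np.diag(alphas)
    gamma = 1.0 - alphas * np.diag(np.linalg.inv(A))
    r = y - Phi @ w
    E_D = 0.5 * float(r @ r)
    _, logdet = np.linalg.slogdet(A)
    ev = (
        -beta * E_D
        - 0.5 * float(alphas @ w**2)
        - 0.5 * logdet
        + 0.5 * float(np.sum(np.log(alphas)))
        + 0.5 * N * np.log(beta)
        - 0.5 * N * np.log(2 * np.pi)
    )
    return w, alphas, beta, gamma, ev


@pytest.fixture
def small_data(rng):
    X = rng.standard_normal((20, 3))
    y = X @ [1.0, -0.5, 0.2] + 0.1 * rng.standard_normal(20)
    return X, y


class TestForward:
    def test_zero_weights_give_output_bias(self, rng):
        arch = sq.NetworkArchitecture(n_inputs=4, n_hidden=3)
        w = np.zeros(arch.n_weights)
        w[-1] = 2.5
        np.testing.assert_allclose(
            ann.forward(arch, w, rng.standard_normal((10, 4))), 2.5
        )

    def test_tanh_limits(self):
        arch = sq.NetworkArchitecture(n_inputs=1, n_hidden=1)
        w = np.array([1.0, 0.0, 1.0, 0.0])  # W1=1, b1=0, w2=1, b2=0
        assert ann.forward(arch, w, [[0.0]])[0] == 0.0
        assert ann.forward(arch, w, [[50.0]])[0] == pytest.approx(1.0)

    def test_small_weight_linearization(self, rng):
        arch = sq.NetworkArchitecture(n_inputs=3, n_hidden=2)
        w = ann.init_weights(arch, rng)
        X = rng.standard_normal((10, 3))
        eps = 1e-3
        W1, b1, w2, b2 = arch.unpack(w * eps)
        linear = X @ (W1.T @ w2) + b1 @ w2 + b2  # first-order tanh expansion
        np.testing.assert_allclose(ann.forward(arch, w * eps, X), linear, atol=5 * eps**3)

    def test_dimension_mismatch(self, rng):
        arch = sq.NetworkArchitecture(n_inputs=3, n_hidden=2)
        with pytest.raises(ValueError):
            ann.forward(arch, np.zeros(arch.n_weights), rng.standard_normal((5, 4)))


class TestTotalError:
    def test_zero_weights_terms(self, small_data):
        X, y = small_data
        arch = sq.NetworkArchitecture(n_inputs=3, n_hidden=2)
        groups = ann.weight_groups(arch)
        hyper = sq.HyperParams(alphas=np.ones(len(groups)), beta=1.0)
        E, _ = ann.total_error(arch, np.zeros(arch.n_weights), X, y, hyper)
        assert E == pytest.approx(0.5 * float(y @ y))

    def test_gradient_matches_finite_differences(self, rng, small_data):
        X, y = small_data
        arch = sq.NetworkArchitecture(n_inputs=3, n_hidden=3)
        groups = ann.weight_groups(arch)
        hyper = sq.HyperParams(alphas=rng.uniform(0.05, 2.0, len(groups)), beta=1.7)
        w = ann.init_weights(arch, rng)
        _, g = ann.total_error(arch, w, X, y, hyper)
        step = 1e-6
        for i in range(w.size):
            e = np.zeros_like(w)
            e[i] = step
            num = (
                ann.total_error(arch, w + e, X, y, hyper)[0]
                - ann.total_error(arch, w - e, X, y, hyper)[0]
            ) / (2 * step)
            assert abs(g[i] - num) / (abs(num) + 1e-8) < 1e-5

    def test_alpha_scaling_is_linear(self, small_data, rng):
        X, y = small_data
        arch = sq.NetworkArchitecture(n_inputs=3, n_hidden=2)
        groups = ann.weight_groups(arch)
        w = ann.init_weights(arch, rng)
        alphas = np.ones(len(groups))
        E1, _ = ann.total_error(arch, w, X, y, sq.HyperParams(alphas=alphas, beta=1.0))
        E2, _ = ann.total_error(arch, w, X, y, sq.HyperParams(alphas=2 * alphas, beta=1.0))
        _, E_W = ann.data_and_prior_terms(arch, w, X, y)
        assert E2 - E1 == pytest.approx(float(E_W.sum()))


class TestTrainMap:
    def test_error_decreases_and_trace_monotone(self, small_data, rng):
        X, y = small_data
        arch = sq.NetworkArchitecture(n_inputs=3, n_hidden=2)
        hyper = sq.HyperParams(alphas=np.full(len(ann.weight_groups(arch)), 0.01), beta=5.0)
        w0 = ann.init_weights(arch, rng)
        w, trace = ann.train_map(arch, w0, X, y, hyper)
        assert trace[-1] <= trace[0]
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_stationary_start_returns_quickly(self, small_data):
        X, y = small_data
        arch = sq.NetworkArchitecture(n_inputs=3, n_hidden=1, linear_mode=True)
        hyper = sq.HyperParams(alphas=np.full(4, 1.0), beta=1.0)
        # exact quadratic minimum as the start
        Phi = np.column_stack([X, np.ones(len(y))])
        A = hyper.beta * Phi.T @ Phi + np.eye(4)
        w_star = hyper.beta * np.linalg.solve(A, Phi.T @ y)
        w, trace = ann.train_map(arch, w_star, X, y, hyper)
        assert len(trace) <= 2
        np.testing.assert_allclose(w, w_star, atol=1e-6)

    def test_fit_reaches_noise_floor(self, rng):
        X = rng.standard_normal((100, 2))
        y = X @ [1.0, -1.0] + 0.1 * rng.standard_normal(100)
        arch = sq.NetworkArchitecture(n_inputs=2, n_hidden=3)
        hyper = sq.HyperParams(alphas=np.full(len(ann.weight_groups(arch)), 1e-4), beta=100.0)
        w, _ = ann.train_map(arch, ann.init_weights(arch, rng), X, y, hyper, max_iter=500)
        mue = np.mean(np.abs(ann.forward(arch, w, X) - y))
        assert mue < 0.12


class TestEvidenceFramework:
    def test_linear_mode_matches_bayes_ridge(self, small_data):
        X, y = small_data
        arch = sq.NetworkArchitecture(n_inputs=3, n_hidden=1, linear_mode=True)
        beta0 = 1.0 / float(np.var(y))
        model = ann.train_one(X, y, arch, seed=0, outer_loops=8, alpha_init=0.01)
        w, alphas, beta, gamma, ev = bayes_ridge_oracle(X, y, 0.01, beta0, 8)
        np.testing.assert_allclose(model.w, w, atol=1e-5)
        np.testing.assert_allclose(model.hyper.alphas, alphas, rtol=1e-5, atol=1e-5)
        assert model.hyper.beta == pytest.approx(beta, rel=1e-5)
        np.testing.assert_allclose(model.gamma, gamma, atol=1e-5)
        assert model.log_evidence == pytest.approx(ev, abs=1e-5)

    def test_huge_alpha_drives_gamma_to_zero(self, small_data):
        X, y = small_data
        arch = sq.NetworkArchitecture(n_inputs=3, n_hidden=2)
        groups = ann.weight_groups(arch)
        alphas = np.full(len(groups), 1e8)
        hyper = sq.HyperParams(alphas=alphas, beta=1.0)
        w = np.zeros(arch.n_weights)
        _, gamma, _ = ann.reestimate_hyperparameters(arch, w, X, y, hyper)
        assert np.all(gamma < 1e-3)

    def test_gamma_bounds_throughout_training(self, small_data):
        X, y = small_data
        arch = sq.NetworkArchitecture(n_inputs=3, n_hidden=2)
        sizes = np.array([len(idx) for _, idx in ann.weight_groups(arch)])
        model = ann.train_one(X, y, arch, seed=3, outer_loops=6)
        assert model.trace, "outer iterations should be recorded"
        for entry in model.trace:
            assert np.all(entry["gamma"] >= 0) and np.all(entry["gamma"] <= sizes)
            assert np.all(entry["alphas"] > 0) and entry["beta"] > 0
            assert entry["gamma_total"] <= arch.n_weights

    def test_evidence_beta_term(self, small_data):
        X, y = small_data
        arch = sq.NetworkArchitecture(n_inputs=3, n_hidden=2)
        groups = ann.weight_groups(arch)
        w = ann.init_weights(arch, np.random.default_rng(0))
        h1 = sq.HyperParams(alphas=np.ones(len(groups)), beta=1.0)
        # at fixed fit and curvature, (N/2) log beta enters the evidence directly
        N = len(y)
        ev1 = ann.log_evidence(arch, w, X, y, h1)
        E_D, E_W = ann.data_and_prior_terms(arch, w, X, y)
        A1 = ann.gauss_newton_matrix(arch, w, X, h1)
        manual = (
            -E_D - float(E_W.sum())
            - 0.5 * np.linalg.slogdet(A1)[1]
            + 0.5 * N * np.log(1.0)
            - 0.5 * N * np.log(2 * np.pi)
        )
        assert ev1 == pytest.approx(manual, abs=1e-8)

    def test_outer_loops_zero_is_plain_map(self, small_data):
        X, y = small_data
        arch = sq.NetworkArchitecture(n_inputs=3, n_hidden=2)
        m0 = ann.train_one(X, y, arch, seed=5, outer_loops=0)
        groups = ann.weight_groups(arch)
        hyper = sq.HyperParams(
            alphas=np.full(len(groups), 0.01), beta=1.0 / float(np.var(y))
        )
        w_map, _ = ann.train_map(arch, ann.init_weights(arch, np.random.default_rng(5)), X, y, hyper)
        np.testing.assert_allclose(m0.w, w_map, atol=1e-10)
        np.testing.assert_allclose(m0.hyper.alphas, hyper.alphas)

    def test_same_seed_bit_identical(self, small_data):
        X, y = small_data
        arch = sq.NetworkArchitecture(n_inputs=3, n_hidden=2)
        m1 = ann.train_one(X, y, arch, seed=11, outer_loops=3)
        m2 = ann.train_one(X, y, arch, seed=11, outer_loops=3)
        assert np.array_equal(m1.w, m2.w)
        assert m1.log_evidence == m2.log_evidence


class TestCommittee:
    def test_selection_takes_top_evidence(self, rng):
        X = rng.standard_normal((60, 2))
        y = np.tanh(X[:, 0]) + 0.1 * rng.standard_normal(60)
        arch = sq.NetworkArchitecture(n_inputs=2, n_hidden=2)
        c = ann.train_committee(X, y - y.mean(), arch, 8, 3, seed=1, outer_loops=3)
        evidences = [m.log_evidence for m in c.members]
        selected = [evidences[i] for i in c.selected]
        unselected = [e for i, e in enumerate(evidences) if i not in c.selected]
        assert min(selected) >= max(unselected)

    def test_single_member_committee(self, rng):
        X = rng.standard_normal((40, 2))
        y = X[:, 0] + 0.1 * rng.standard_normal(40)
        arch = sq.NetworkArchitecture(n_inputs=2, n_hidden=2)
        c = ann.train_committee(X, y, arch, 1, 1, seed=0, outer_loops=2)
        np.testing.assert_allclose(c.predict(X), c.members[0].predict(X))

    def test_mean_equals_hand_loop_and_stays_in_spread(self, rng):
        X = rng.standard_normal((50, 2))
        y = X[:, 0] + 0.2 * rng.standard_normal(50)
        arch = sq.NetworkArchitecture(n_inputs=2, n_hidden=2)
        c = ann.train_committee(X, y, arch, 6, 4, seed=2, outer_loops=2)
        mean, lo, hi = ann.predict_committee(c, X, return_spread=True)
        hand = np.mean([c.members[i].predict(X) for i in c.selected], axis=0)
        np.testing.assert_allclose(mean, hand, atol=1e-12)
        assert np.all(mean >= lo - 1e-12) and np.all(mean <= hi + 1e-12)

    def test_prediction_invariant_to_member_order(self, rng):
        X = rng.standard_normal((30, 2))
        y = X[:, 0]
        arch = sq.NetworkArchitecture(n_inputs=2, n_hidden=2)
        c = ann.train_committee(X, y, arch, 5, 3, seed=4, outer_loops=1)
        perm = [2, 0, 1, 4, 3]
        shuffled = ann.Committee(
            members=[c.members[i] for i in perm],
            selected=[perm.index(i) for i in c.selected],
            k=c.k,
        )
        np.testing.assert_allclose(shuffled.predict(X), c.predict(X), atol=1e-12)


class TestArdRanking:
    def test_single_member_ascending_alpha(self):
        arch = sq.NetworkArchitecture(n_inputs=3, n_hidden=2)
        groups = ann.weight_groups(arch)
        alphas = np.ones(len(groups))
        alphas[:3] = [0.1, 10.0, 1.0]
        m = ann.BayesAnnModel(
            architecture=arch, w=np.zeros(arch.n_weights),
            hyper=sq.HyperParams(alphas=alphas, beta=1.0),
        )
        c = ann.Committee(members=[m], selected=[0], k=1)
        assert ann.ard_ranking(c, ["d1", "d2", "d3"]) == ["d1", "d3", "d2"]

    def test_reversed_members_tie_break_by_name(self):
        arch = sq.NetworkArchitecture(n_inputs=2, n_hidden=2)
        g = len(ann.weight_groups(arch))

        def member(a0, a1):
            alphas = np.ones(g)
            alphas[:2] = [a0, a1]
            return ann.BayesAnnModel(
                architecture=arch, w=np.zeros(arch.n_weights),
                hyper=sq.HyperParams(alphas=alphas, beta=1.0),
            )

        c = ann.Committee(members=[member(0.1, 1.0), member(1.0, 0.1)], selected=[0, 1], k=2)
        assert ann.ard_ranking(c, ["b_desc", "a_desc"]) == ["a_desc", "b_desc"]
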