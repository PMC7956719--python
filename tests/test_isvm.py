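import numpy as np
import pytest

from ecgauth.isvm import (ERROR, MARGIN, RESERVE, IncrementalSVM, SVMConfig,
                          batch_qp_oracle, decision, fit_initial, increment,
                          kkt_audit, rbf_kernel, smote_balance)

CFG = SVMConfig(C=7.0, sigma=2.0)


def _grid(lo=-4.0, hi=4.0, n=30):
    gx, gy = np.meshgrid(np.linspace(lo, hi, n), np.linspace(lo, hi, n))
    return np.column_stack([gx.ravel(), gy.ravel()])


class TestKernel:
    def test_zero_distance_is_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert rbf_kernel(x, x, 2.0) == pytest.approx(1.0)

    def test_distance_sigma_gives_inverse_e(self):
        assert rbf_kernel(np.zeros(2), np.array([2.0, 0.0]), 2.0) == pytest.approx(np.exp(-1))

    def test_gram_matrix_symmetric_psd(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        K = rbf_kernel(X, X, 1.5)
        assert np.allclose(K, K.T)
        assert np.min(np.linalg.eigvalsh(K)) > -1e-10

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            rbf_kernel(np.zeros(2), np.zeros(3), 1.0)


class TestFitInitial:
    def test_two_point_problem(self):
        X = np.array([[0.0, 0.0], [2.0, 0.0]])
        y = np.array([1.0, -1.0])
        m = fit_initial(X, y, CFG)
        f = m.decision_function(X)
        assert f[0] == pytest.approx(1.0, abs=1e-9)
        assert f[1] == pytest.approx(-1.0, abs=1e-9)
        assert np.all(m.sets == MARGIN)

    def test_matches_oracle_on_two_gaussians(self, two_gaussians):
        X, y = two_gaussians(40, seed=1)
        inc = fit_initial(X, y, CFG)
        orc = batch_qp_oracle(X, y, CFG)
        G = _grid()
        assert np.max(np.abs(inc.decision_function(G) - orc.decision_function(G))) <= 1e-4

    def test_xor_all_support_vectors(self):
        cfg = SVMConfig(C=10.0, sigma=1.0)
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        inc = fit_initial(X, y, cfg)
        orc = batch_qp_oracle(X, y, cfg)
        assert np.all(inc.alpha > 1e-8)
        assert np.allclose(np.sort(inc.alpha), np.sort(orc.alpha), atol=1e-4)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_initial(np.zeros((3, 2)), np.ones(3), CFG)


class TestIncrement:
    def test_reserve_fast_path_bit_identical(self, two_gaussians):
        X, y = two_gaussians(40, seed=2)
        m = fit_initial(X, y, CFG)
        alpha_before = m.alpha.copy()
        bias_before = m.bias
        # re-present a stored reserve vector: it is beyond the margin (y*f > 1)
        r0 = m.set_indices(RESERVE)[0]
        x_far, y_far = m.X[r0].copy(), m.y[r0]
        assert y_far * m.decision_function(x_far)[0] > 1.0
        m.increment(x_far, y_far)
        assert m.sets[m.n - 1] == RESERVE
        assert np.array_equal(m.alpha[:-1], alpha_before)
        assert m.bias == bias_before

    def test_order_independence(self, two_gaussians):
        X, y = two_gaussians(60, seed=3, spread=1.2)
        G = _grid()
        rng = np.random.default_rng(0)
        fs = []
        for _ in range(5):
            perm = rng.permutation(len(y))
            m = fit_initial(X[perm], y[perm], CFG)
            fs.append(m.decision_function(G))
        for f in fs[1:]:
            assert np.max(np.abs(f - fs[0])) <= 1e-4

    def test_duplicate_of_error_vector(self, two_gaussians):
        X, y = two_gaussians(50, seed=4, spread=2.0, sep=1.0)  # overlapping
        m = fit_initial(X, y, CFG)
        errs = m.set_indices(ERROR)
        assert errs.size > 0, "fixture should produce error vectors"
        xd, yd = m.X[errs[0]].copy(), m.y[errs[0]]
        m.increment(xd, yd)
        assert m.audit().ok
        Xd = np.vstack([X, xd])
        yD = np.concatenate([y, [yd]])
        orc = batch_qp_oracle(Xd, yD, CFG)
        G = _grid()
        assert np.max(np.abs(m.decision_function(G) - orc.decision_function(G))) <= 1e-4

    def test_nonfinite_sample_rejected(self, two_gaussians):
        X, y = two_gaussians(20, seed=5)
        m = fit_initial(X, y, CFG)
        with pytest.raises(ValueError):
            m.increment(np.array([np.nan, 0.0]), 1.0)


class TestDecision:
    @pytest.fixture()
    def overlapping_model(self, two_gaussians):
        X, y = two_gaussians(80, seed=6, spread=1.8, sep=1.5)
        return fit_initial(X, y, CFG)

    def test_margin_vectors_on_margin(self, overlapping_model):
        m = overlapping_model
        S = m.set_indices(MARGIN)
        f = m.decision_function(m.X[S])
        assert np.allclose(np.abs(f), 1.0, atol=CFG.kkt_tol * 10)

    def test_error_vectors_inside_margin(self, overlapping_model):
        m = overlapping_model
        E = m.set_indices(ERROR)
        assert E.size > 0
        assert np.all(m.y[E] * m.decision_function(m.X[E]) < 1.0 + CFG.kkt_tol)

    def test_reserve_vectors_beyond_margin(self, overlapping_model):
        m = overlapping_model
        R = m.set_indices(RESERVE)
        assert np.all(m.y[R] * m.decision_function(m.X[R]) > 1.0 - CFG.kkt_tol)

    def test_tie_at_zero_accepts(self, overlapping_model):
        f, label = decision(overlapping_model, overlapping_model.X[0])
        assert label == (1 if f >= 0 else -1)


class TestAudit:
    def test_clean_after_fit(self, two_gaussians):
        X, y = two_gaussians(50, seed=7)
        assert kkt_audit(fit_initial(X, y, CFG)).ok

    def test_constructed_violation_reported(self, two_gaussians):
        X, y = two_gaussians(50, seed=8, spread=1.5)
        m = fit_initial(X, y, CFG)
        # corrupt one set label without touching the solution: exactly that
        # sample must be reported (an error vector needs alpha = C, g <= 0)
        victim = int(m.set_indices(RESERVE)[0])
        m._sets[victim] = ERROR
        rep = m.audit()
        assert not rep.ok
        assert {v[0] for v in rep.violations} == {victim}

    def test_zeroed_margin_alpha_detected(self, two_gaussians):
        X, y = two_gaussians(50, seed=8, spread=1.5)
        m = fit_initial(X, y, CFG)
        S = m.set_indices(MARGIN)
        victim = int(S[np.argmax(m.alpha[S])])
        m._alpha[victim] = 0.0
        rep = m.audit()
        assert not rep.ok
        assert any(v[0] == victim for v in rep.violations)
        assert abs(rep.sum_alpha_y) > 1e-8  # class balance broken too

    def test_audit_after_sequential_increments(self, two_gaussians):
        X, y = two_gaussians(120, seed=9, spread=1.5)
        m = fit_initial(X[:20], y[:20], CFG)
        for xi, yi in zip(X[20:], y[20:]):
            m.increment(xi, yi)
            rep = m.audit()
            assert rep.ok, str(rep)
            assert abs(rep.sum_alpha_y) <= 1e-8


class TestSmote:
    def test_balances_to_majority_size(self):
        rng = np.random.default_rng(0)
        Xmin = rng.normal(size=(40, 5))
        Xmaj = rng.normal(size=(60, 5))
        out = smote_balance(Xmin, Xmaj, k=5, seed=1)
        assert out.shape == (60, 5)
        assert np.array_equal(out[:40], Xmin)

    def test_synthetics_on_minority_segments(self):
        rng = np.random.default_rng(1)
        Xmin = rng.normal(size=(10, 3))
        Xmaj = rng.normal(size=(25, 3))
        out = smote_balance(Xmin, Xmaj, k=3, seed=2)
        for s in out[10:]:
            # s = x + u (n - x) for some minority pair (x, n): collinearity check
            ok = False
            for i in range(10):
                for j in range(10):
                    d = Xmin[j] - Xmin[i]
                    if np.linalg.norm(d) < 1e-12:
                        continue
                    t = np.dot(s - Xmin[i], d) / np.dot(d, d)
                    if -1e-9 <= t <= 1 + 1e-9 and np.linalg.norm(s - (Xmin[i] + t * d)) < 1e-9:
                        ok = True
            assert ok

    def test_identical_minority_degenerate(self):
        Xmin = np.ones((5, 2))
        Xmaj = np.zeros((12, 2))
        out = smote_balance(Xmin, Xmaj, k=3, seed=3)
        assert np.allclose(out, 1.0)

    def test_too_small_minority_rejected(self):
        with pytest.raises(ValueError):
            smote_balance(np.ones((1, 2)), np.zeros((5, 2)))

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(2)
        Xmin, Xmaj = rng.normal(size=(6, 2)), rng.normal(size=(15, 2))
        a = smote_balance(Xmin, Xmaj, seed=9)
        b = smote_balance(Xmin, Xmaj, seed=9)
        assert np.array_equal(a, b)


class TestBatchOracle:
    def test_two_point_linear_closed_form(self):
        # separable pair at distance 2: alpha = 2/||x1-x2||^2 = 0.5, bias 0
        cfg = SVMConfig(C=7.0, sigma=1.0, kernel="linear")
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        y = np.array([1.0, -1.0])
        m = batch_qp_oracle(X, y, cfg)
        assert np.allclose(m.alpha, 0.5, atol=1e-6)
        assert m.bias == pytest.approx(0.0, abs=1e-6)
        assert m.decision_function(np.array([[3.0, 0.0]]))[0] == pytest.approx(3.0, abs=1e-5)

    def test_hard_margin_limit_no_training_errors(self, two_gaussians):
        X, y = two_gaussians(60, seed=10, sep=6.0, spread=0.5)
        m = batch_qp_oracle(X, y, SVMConfig(C=1e4, sigma=2.0))
        assert np.all(m.predict(X) == y)

    def test_oracle_state_is_valid(self, two_gaussians):
        X, y = two_gaussians(100, seed=11, spread=1.5)
        assert batch_qp_oracle(X, y, CFG).audit().ok

    def test_cap_enforced(self):
        with pytest.raises(ValueError):
            batch_qp_oracle(np.zeros((10, 2)), np.ones(10), CFG, max_n=5)


class TestStatePlumbing:
    def test_save_load_round_trip(self, tmp_path, two_gaussians):
        X, y = two_gaussians(40, seed=12)
        m = fit_initial(X, y, CFG)
        path = tmp_path / "model.npz"
        m.save(path)
        back = IncrementalSVM.load(path)
        G = _grid(n=10)
        assert np.array_equal(back.decision_function(G), m.decision_function(G))
        assert back.audit().ok

    def test_prune_reserve_keeps_decision(self, two_gaussians):
        X, y = two_gaussians(60, seed=13, sep=4.0)
        m = fit_initial(X, y, CFG)
        G = _grid(n=10)
        before = m.decision_function(G)
        removed = m.prune_reserve(threshold=1.3)
        assert removed > 0
        assert np.allclose(m.decision_function(G), before)
        assert m.audit().ok

    def test_increment_wrapper_returns_state(self, two_gaussians):
        X, y = two_gaussians(20, seed=14)
        m = fit_initial(X[:10], y[:10], CFG)
        assert increment(m, X[10], y[10]) is m
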