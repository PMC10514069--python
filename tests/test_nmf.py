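import numpy as np
import pytest

from cscpair.nmf import (
    CoupledNMF,
    FactorSet,
    NMFParams,
    assign_subgroups,
    compute_objective,
    initialize_factors,
    multiplicative_update,
    run_coupled_nmf,
    select_parameters,
)


def _random_instance(rng, shape=(20, 30), density=0.1):
    XL = rng.random(shape) * 5
    XR = rng.random(shape) * 5
    A = (rng.random((shape[0], shape[0])) < density).astype(float)
    return XL, XR, A


class TestInitialize:
    def test_deterministic_and_strictly_positive(self):
        a = initialize_factors((3, 4, 2, 5), 2, seed=11)
        b = initialize_factors((3, 4, 2, 5), 2, seed=11)
        for x, y in zip((a.WL, a.HL, a.WR, a.HR), (b.WL, b.HL, b.WR, b.HR)):
            np.testing.assert_array_equal(x, y)
            assert (x > 0).all()
        c = initialize_factors((3, 4, 2, 5), 2, seed=12)
        assert not np.array_equal(a.WL, c.WL)

    def test_shapes(self):
        f = initialize_factors((3, 4, 2, 5), 2, seed=0)
        assert f.WL.shape == (3, 2) and f.HL.shape == (2, 4)
        assert f.WR.shape == (2, 2) and f.HR.shape == (2, 5)

    def test_oversized_k_warns_not_errors(self):
        with pytest.warns(UserWarning):
            initialize_factors((2, 3, 2, 3), 5, seed=0)


class TestObjective:
    def test_perfect_reconstruction_is_zero(self, rng):
        W = rng.random((4, 2))
        H = rng.random((2, 6))
        X = W @ H
        f = FactorSet(W, H, W.copy(), H.copy())
        p = NMFParams(K=2, lambda1=1.0, lambda2=0.0, mu=0.0)
        total, terms = compute_objective((X, X, np.zeros((4, 4))), f, p)
        assert total == pytest.approx(0.0, abs=1e-12)
        assert terms["rec_l"] == pytest.approx(0.0, abs=1e-12)

    def test_scalar_coupling_trace(self):
        one = np.ones((1, 1))
        f = FactorSet(one, one, one, one)
        p = NMFParams(K=1, lambda1=0.0, lambda2=1.0, mu=0.0)
        total, terms = compute_objective((one, one, one), f, p)
        assert terms["coupling"] == 1.0
        assert total == pytest.approx(-1.0)

    def test_identity_coupling_trace(self):
        I = np.eye(2)
        f = FactorSet(I, np.ones((2, 2)), I, np.ones((2, 2)))
        p = NMFParams(K=2, lambda1=0.0, lambda2=1.0, mu=0.0)
        _, terms = compute_objective((np.ones((2, 2)), np.ones((2, 2)), I), f, p)
        assert terms["coupling"] == pytest.approx(2.0)


class TestMultiplicativeUpdate:
    def test_scalar_hand_evaluation(self):
        # X = 4, w = h = 1: w <- 4, then h <- (4*4)/(4*4*1) = 1; residual 0
        one = np.ones((1, 1))
        X = np.full((1, 1), 4.0)
        f = FactorSet(one, one, one, one)
        p = NMFParams(K=1, lambda1=1.0, lambda2=0.0, mu=0.0, eps=1e-300)
        out = multiplicative_update((X, X, one), f, p)
        assert out.WL[0, 0] == pytest.approx(4.0)
        assert out.HL[0, 0] == pytest.approx(1.0)
        total, _ = compute_objective((X, X, one), out, p)
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_reduces_to_textbook_nmf_when_uncoupled(self, rng):
        """With lambda2 = mu = 0 a round must match the classical
        Lee-Seung rules applied factor-by-factor (independent oracle)."""
        XL, XR, A = _random_instance(rng, (5, 5), 0.5)
        f = initialize_factors((5, 5, 5, 5), 2, seed=1)
        p = NMFParams(K=2, lambda1=1.0, lambda2=0.0, mu=0.0, eps=1e-300)
        out = multiplicative_update((XL, XR, A), f, p)
        WL = f.WL * (XL @ f.HL.T) / (f.WL @ f.HL @ f.HL.T)
        HL = f.HL * (WL.T @ XL) / (WL.T @ WL @ f.HL)
        np.testing.assert_allclose(out.WL, WL, rtol=1e-9)
        np.testing.assert_allclose(out.HL, HL, rtol=1e-9)

    def test_zero_data_with_ridge_shrinks_w(self):
        f = FactorSet(np.full((2, 1), 0.5), np.full((1, 2), 0.5),
                      np.full((2, 1), 0.5), np.full((1, 2), 0.5))
        p = NMFParams(K=1, lambda1=1.0, lambda2=0.0, mu=1.0)
        Z = np.zeros((2, 2))
        out = multiplicative_update((Z, Z, np.zeros((2, 2))), f, p)
        assert (out.WL < f.WL).all() and (out.WR < f.WR).all()

    def test_nonnegativity_preserved_100_rounds(self, rng):
        for seed in range(10):
            XL, XR, A = _random_instance(np.random.default_rng(seed), (8, 10), 0.2)
            f = initialize_factors((8, 10, 8, 10), 3, seed=seed)
            p = NMFParams(K=3, lambda1=0.7, lambda2=2.0, mu=0.3)
            for _ in range(100):
                f = multiplicative_update((XL, XR, A), f, p)
                for M in (f.WL, f.HL, f.WR, f.HR):
                    assert (M >= 0).all()
                    assert np.isfinite(M).all()


class TestSelectParameters:
    def _fixed_terms_factors(self):
        """Instance engineered so the four raw terms are easy to read off."""
        return None

    def test_hand_arithmetic(self, monkeypatch):
        import cscpair.nmf as nmf_mod

        def fake_objective(inputs, f, p):
            return 0.0, {"rec_l": 10.0, "rec_r": 5.0, "coupling": 2.0,
                         "regularization": 4.0}

        monkeypatch.setattr(nmf_mod, "compute_objective", fake_objective)
        f = initialize_factors((2, 2, 2, 2), 1, seed=0)
        assert select_parameters(None, f, (1, 1, 1)) == (2.0, 2.5, 1.25)
        assert select_parameters(None, f, (1, 1000, 1)) == (2.0, 2500.0, 1.25)

    def test_zero_trace_falls_back_to_zero(self, rng):
        XL = rng.random((3, 4))
        f = initialize_factors((3, 4, 3, 4), 2, seed=0)
        lam1, lam2, mu = select_parameters((XL, XL, np.zeros((3, 3))), f)
        assert lam2 == 0.0 and lam1 > 0 and mu > 0


class TestRunCoupledNMF:
    def test_recovers_noiseless_blocks(self, noiseless_fixture):
        inputs, truth = noiseless_fixture
        f, p, tr = run_coupled_nmf(inputs, K=2, seed=3)
        assert tr.rec_l[-1] < 1e-6 * max(tr.rec_l[0], 1e-30) + 1e-9

    def test_trace_identity_holds(self, recovery_fixture):
        inputs, _ = recovery_fixture
        f, p, tr = run_coupled_nmf(inputs, K=2, seed=5)
        for i in range(len(tr)):
            expected = (0.5 * tr.rec_l[i] + 0.5 * p.lambda1 * tr.rec_r[i]
                        - p.lambda2 * tr.coupling[i] + p.mu * tr.regularization[i])
            assert tr.total[i] == pytest.approx(expected, rel=1e-9)

    def test_same_seed_same_trace(self, recovery_fixture):
        inputs, _ = recovery_fixture
        _, _, t1 = run_coupled_nmf(inputs, K=2, seed=9)
        _, _, t2 = run_coupled_nmf(inputs, K=2, seed=9)
        assert t1.total == t2.total

    def test_k1_single_subgroup(self, recovery_fixture):
        inputs, _ = recovery_fixture
        f, _, _ = run_coupled_nmf(inputs, K=1, seed=0)
        assert set(assign_subgroups(f.HL)) == {0}

    def test_scale_consistency(self, noiseless_fixture):
        """Scaling both matrices by c > 0 and re-selecting parameters must
        not change the hard assignments."""
        from cscpair.io import CoupledInputs, ExpressionMatrix

        inputs, _ = noiseless_fixture
        e1 = CoupledNMF(n_components=2, random_state=4).fit(inputs)
        c = 3.7

        def scaled(m):
            return ExpressionMatrix(m.values * c, list(m.gene_ids),
                                    list(m.cell_ids), list(m.cell_types))

        e2 = CoupledNMF(n_components=2, random_state=4).fit(
            CoupledInputs(scaled(inputs.XL), scaled(inputs.XR), inputs.A))
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(e1.labels_, e2.labels_) == 1.0

    def test_estimator_api(self, recovery_fixture):
        inputs, _ = recovery_fixture
        est = CoupledNMF(n_components=2, random_state=0)
        params = est.get_params()
        assert params["n_components"] == 2
        est.set_params(max_iter=50).fit(inputs)
        assert est.labels_.size == inputs.n_senders + inputs.n_receivers
        assert (est.WL_ >= 0).all() and (est.HR_ >= 0).all()


class TestAssignSubgroups:
    def test_argmax_and_tie_break(self):
        H = np.array([[0.1, 0.5], [0.9, 0.5]])
        np.testing.assert_array_equal(assign_subgroups(H), [1, 0])

    def test_zero_column_warns_and_goes_to_zero(self):
        H = np.array([[0.0, 1.0], [0.0, 0.0]])
        with pytest.warns(UserWarning):
            labels = assign_subgroups(H)
        assert labels[0] == 0

    def test_row_permutation_permutes_labels(self, rng):
        import itertools

        H = rng.random((3, 4))
        base = assign_subgroups(H)
        for perm in itertools.permutations(range(3)):
            perm = np.asarray(perm)
            permuted = assign_subgroups(H[perm])
            np.testing.assert_array_equal(perm[permuted], base)


class TestEmpiricalContracts:
    def test_uncoupled_objective_monotone(self):
        """lambda2 = mu = 0: exact NMF monotonicity every round."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            XL, XR, A = _random_instance(rng)
            f = initialize_factors((20, 30, 20, 30), 3, seed=seed)
            p = NMFParams(K=3, lambda1=1.0, lambda2=0.0, mu=0.0)
            prev, _ = compute_objective((XL, XR, A), f, p)
            for _ in range(100):
                f = multiplicative_update((XL, XR, A), f, p)
                total, _ = compute_objective((XL, XR, A), f, p)
                assert total <= prev + 1e-9 * abs(prev)
                prev = total

    def test_coupled_final_below_initial_random_instances(self):
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            XL, XR, A = _random_instance(rng)
            est = CoupledNMF(n_components=3, random_state=seed).fit((XL, XR, A))
            assert est.trace_.total[-1] <= est.trace_.total[0]

    def test_coupled_mostly_monotone_on_structured_data(self, recovery_fixture):
        inputs, _ = recovery_fixture
        good = total = 0
        for seed in (0, 1, 2):
            est = CoupledNMF(n_components=2, random_state=seed).fit(inputs)
            t = np.asarray(est.trace_.total)
            d = np.diff(t)
            good += int(np.sum(d <= 1e-9 * np.abs(t[:-1])))
            total += d.size
            assert t[-1] <= t[0]
        assert good / total >= 0.95

    def test_l2_regularization_improves_run_stability(self, noisy_fixture):
        """Mean pairwise agreement across seeds must be strictly higher
        with the formula-selected mu than with mu disabled."""
        import itertools

        from sklearn.metrics import adjusted_rand_score

        inputs, _ = noisy_fixture
        stability = {}
        for tag, mult in (("on", (1.0, 1000.0, 1.0)), ("off", (1.0, 1000.0, 0.0))):
            labs = [
                CoupledNMF(n_components=2, multipliers=mult,
                           random_state=100 + s).fit(inputs).labels_
                for s in range(10)
            ]
            stability[tag] = np.mean([
                adjusted_rand_score(a, b)
                for a, b in itertools.combinations(labs, 2)
            ])
        assert stability["on"] > stability["off"]
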