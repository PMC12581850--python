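import numpy as np
import pytest

from jsnmf import (
    RunConfig,
    SyntheticSpec,
    ValidationError,
    fit,
    generate,
    jnmf_step,
    jsnmf_step,
    match_components,
    nndsvd_init,
    objective,
    reconstruction_metrics,
    relative_error,
    scale_blocks,
)
from jsnmf.factorization import gradients, ortho_matrix

from conftest import random_blocks, random_factors


def objective_scalar_oracle(W, H, blocks, R, alpha, beta, M):
    """Term-by-term summation with explicit loops; the independent oracle."""
    total = 0.0
    for X, Hi in zip(blocks, H):
        WH = W @ Hi
        for i in range(X.shape[0]):
            for j in range(X.shape[1]):
                total += (X[i, j] - WH[i, j]) ** 2
        G = Hi @ Hi.T
        for a in range(G.shape[0]):
            for b in range(G.shape[1]):
                total += 0.5 * beta * (G[a, b] - M[a, b]) ** 2
    if alpha:
        for i in range(W.shape[0]):
            for k in range(W.shape[1]):
                total += alpha * (W[i, k] - R[i, k]) ** 2
    return total


class TestNNDSVDInit:
    def test_deterministic_and_nonnegative(self, small_cohort):
        _, dataset, _ = small_cohort
        W1, H1 = nndsvd_init(dataset, 4)
        W2, H2 = nndsvd_init(dataset, 4)
        np.testing.assert_array_equal(W1, W2)
        for a, b in zip(H1, H2):
            np.testing.assert_array_equal(a, b)
        assert W1.min() > 0 and all(H.min() > 0 for H in H1)

    def test_rank_one_exact_recovery(self):
        w = np.array([0.5, 1.0, 2.0, 0.8])
        h = np.array([1.0, 0.4, 0.9, 2.0, 0.7])
        X = np.outer(w, h)
        W0, H0 = nndsvd_init([X[:, :2], X[:, 2:4], X[:, 4:]], 1)
        Xhat = W0 @ np.hstack(H0)
        rel = np.linalg.norm(X - Xhat, "fro") / np.linalg.norm(X, "fro")
        assert rel < 1e-8

    def test_matches_reference_nndsvd_up_to_floor(self, rng):
        from sklearn.decomposition._nmf import _initialize_nmf

        X = rng.uniform(0, 1, size=(12, 15))
        W, H = nndsvd_init([X[:, :5], X[:, 5:9], X[:, 9:]], 4)
        Wr, Hr = _initialize_nmf(X, 4, init="nndsvd")
        np.testing.assert_allclose(W, np.maximum(Wr, 1e-6), atol=1e-8)
        np.testing.assert_allclose(np.hstack(H), np.maximum(Hr, 1e-6), atol=1e-8)

    def test_K_above_rank_warns_and_floors(self, caplog):
        X = np.outer([1.0, 2.0, 3.0, 4.0], [1.0, 1.5, 0.5, 2.0])  # rank 1
        with caplog.at_level("WARNING"):
            W, H = nndsvd_init([X[:, :2], X[:, 2:3], X[:, 3:]], 3)
        assert "rank" in caplog.text
        assert np.all(W[:, 2] == 1e-6)


class TestObjective:
    def test_matches_scalar_loop_oracle(self, rng):
        blocks = random_blocks(rng, n=5, q=(3, 4, 2))
        W, H = random_factors(rng, n=5, K=2, q=(3, 4, 2))
        R = rng.uniform(0, 1, size=(5, 2))
        for tgt in ("identity", "ones"):
            M = ortho_matrix(2, tgt)
            got = objective(W, H, blocks, R, alpha=0.7, beta=1.3, ortho_target=tgt)
            want = objective_scalar_oracle(W, H, blocks, R, 0.7, 1.3, M)
            assert got == pytest.approx(want, rel=1e-10)

    def test_zero_at_exact_fit(self, rng):
        W, H = random_factors(rng)
        blocks = [W @ Hi for Hi in H]
        assert objective(W, H, blocks, None, 0.0, 0.0) == 0.0
        # prior satisfied: W == R removes the alpha term too
        assert objective(W, H, blocks, W, 5.0, 0.0) == 0.0


class TestSteps:
    def test_stationary_point_is_fixed(self, rng):
        W, H = random_factors(rng, n=6, K=2, q=(4, 5, 3))
        blocks = [W @ Hi for Hi in H]
        W2, H2 = jnmf_step(W, H, blocks)
        np.testing.assert_allclose(W2, W, rtol=1e-9)
        for a, b in zip(H2, H):
            np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_jnmf_objective_nonincreasing(self, rng):
        blocks = random_blocks(rng, n=8, q=(5, 6, 4))
        W, H = nndsvd_init(blocks, 3)
        prev = objective(W, H, blocks, None, 0.0, 0.0)
        for _ in range(50):
            W, H = jnmf_step(W, H, blocks)
            cur = objective(W, H, blocks, None, 0.0, 0.0)
            assert cur <= prev * (1 + 1e-12)
            prev = cur

    def test_zero_rows_absorb(self, rng):
        blocks = random_blocks(rng)
        W, H = random_factors(rng)
        W[2] = 0.0
        W2, _ = jnmf_step(W, H, blocks)
        assert np.all(W2[2] == 0.0)

    def test_reduction_to_jnmf_without_constraints(self, rng):
        blocks = random_blocks(rng)
        W, H = random_factors(rng)
        R = rng.uniform(0, 1, size=W.shape)
        W1, H1 = jnmf_step(W, H, blocks)
        W2, H2 = jsnmf_step(W, H, blocks, R, alpha=0.0, beta=0.0)
        np.testing.assert_array_equal(W1, W2)
        for a, b in zip(H1, H2):
            np.testing.assert_array_equal(a, b)

    def test_nonnegativity_preserved(self, rng):
        blocks = random_blocks(rng)
        W, H = random_factors(rng)
        R = rng.uniform(0, 1, size=W.shape)
        for _ in range(20):
            W, H = jsnmf_step(W, H, blocks, R, alpha=0.5, beta=0.5)
        assert W.min() >= 0 and all(Hi.min() >= 0 for Hi in H)


@pytest.mark.parametrize("seed", range(20))
def test_constrained_objective_monotone_random_instances(seed):
    """Monotone descent on randomized instances across variants and targets."""
    rng = np.random.default_rng(seed)
    blocks = [rng.uniform(0, 1, size=(20, q)) for q in (8, 10, 6)]
    alpha = float(rng.choice([0.0, 0.01, 0.1, 1.0, 10.0]))
    beta = float(rng.choice([0.0, 0.01, 0.1, 1.0, 10.0]))
    tgt = str(rng.choice(["identity", "ones"]))
    R = rng.uniform(0, 1, size=(20, 3))
    W, H = nndsvd_init(blocks, 3)
    prev = objective(W, H, blocks, R, alpha, beta, tgt)
    for _ in range(60):
        W, H = jsnmf_step(W, H, blocks, R, alpha, beta, tgt)
        cur = objective(W, H, blocks, R, alpha, beta, tgt)
        assert cur <= prev * (1 + 1e-9)
        prev = cur


class TestGradients:
    @pytest.mark.parametrize("tgt", ["identity", "ones"])
    def test_match_central_finite_differences(self, tgt, rng):
        blocks = random_blocks(rng, n=4, q=(3, 3, 3))
        W, H = random_factors(rng, n=4, K=2, q=(3, 3, 3))
        R = rng.uniform(0, 1, size=(4, 2))
        alpha, beta = 0.7, 1.1
        gW, gH = gradients(W, H, blocks, R, alpha, beta, tgt)
        h = 1e-6

        def obj(Wx, Hx):
            return objective(Wx, Hx, blocks, R, alpha, beta, tgt)

        for i in range(W.shape[0]):
            for k in range(W.shape[1]):
                Wp, Wm = W.copy(), W.copy()
                Wp[i, k] += h
                Wm[i, k] -= h
                fd = (obj(Wp, H) - obj(Wm, H)) / (2 * h)
                assert abs(fd - gW[i, k]) / max(1.0, abs(gW[i, k])) < 1e-5
        for b in range(3):
            for a in range(2):
                for j in range(3):
                    Hp = [Hi.copy() for Hi in H]
                    Hm = [Hi.copy() for Hi in H]
                    Hp[b][a, j] += h
                    Hm[b][a, j] -= h
                    fd = (obj(W, Hp) - obj(W, Hm)) / (2 * h)
                    assert abs(fd - gH[b][a, j]) / max(1.0, abs(gH[b][a, j])) < 1e-5


class TestRelativeError:
    def test_exact_fit_and_scale_invariance(self, rng):
        W, H = random_factors(rng)
        blocks = [W @ Hi for Hi in H]
        assert relative_error(blocks, W, H) == 0.0
        noisy_W = W * 1.1
        v1 = relative_error(blocks, noisy_W, H)
        v2 = relative_error([2 * X for X in blocks], 2 * noisy_W, H)
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_hand_computed_toy(self):
        X = np.array([[1.0, 1.0], [1.0, 1.0]])
        W = np.eye(2)
        H = np.array([[0.0, 1.0], [1.0, 1.0]])  # WH = [[0,1],[1,1]]
        # column means of |X-WH| = [0.5, 0]; grand mean of X = 1; average = 0.25
        assert relative_error([X], W, [H]) == pytest.approx(0.25)

    def test_zero_mean_block_rejected(self):
        with pytest.raises(ValidationError):
            relative_error([np.zeros((2, 2))], np.eye(2), [np.zeros((2, 2))])


class TestFit:
    def test_noiseless_planted_reaches_low_error(self):
        spec = SyntheticSpec(n=40, q=(20, 25, 30), K_true=3, module_size=6, sigma=0.0, seed=23)
        dataset, _ = generate(spec)
        cfg = RunConfig(K=3, max_iter=500, tol=1e-9, variant="jnmf")
        model, trace = fit(dataset, None, cfg)
        assert trace.relative_error[-1] < 0.05

    def test_deterministic_reruns(self, small_cohort, fast_config):
        _, dataset, _ = small_cohort
        from jsnmf import build_prior

        _, prior, _ = build_prior(dataset, fast_config)
        m1, t1 = fit(dataset, prior, fast_config)
        m2, t2 = fit(dataset, prior, fast_config)
        np.testing.assert_array_equal(m1.W, m2.W)
        assert t1.objective == t2.objective

    def test_zero_iterations_returns_initialization(self, small_cohort):
        _, dataset, _ = small_cohort
        cfg = RunConfig(K=3, max_iter=0)
        model, trace = fit(dataset, None, cfg, variant="jnmf")
        W0, H0 = nndsvd_init(scale_blocks(dataset.blocks), 3)
        np.testing.assert_array_equal(model.W, W0)
        assert len(trace) == 0

    def test_trace_objective_nonincreasing(self, small_cohort, fast_config):
        _, dataset, _ = small_cohort
        from jsnmf import build_prior

        _, prior, _ = build_prior(dataset, fast_config)
        _, trace = fit(dataset, prior, fast_config)
        obj = np.array(trace.objective)
        assert np.all(np.diff(obj) <= obj[:-1] * 1e-9 + 1e-15)
        assert len(trace.dW) == len(trace) and all(len(d) == len(trace) for d in trace.dH)

    def test_prior_required_for_similarity_variants(self, small_cohort, fast_config):
        _, dataset, _ = small_cohort
        with pytest.raises(ValidationError, match="prior"):
            fit(dataset, None, fast_config, variant="jsnmf")

    def test_sample_permutation_equivariance(self, rng):
        blocks = random_blocks(rng, n=10, q=(6, 7, 5))
        perm = rng.permutation(10)
        cfg = RunConfig(K=3, max_iter=40, scale_blocks=True, variant="jnmf")
        m1, t1 = fit(blocks, None, cfg)
        m2, t2 = fit([X[perm] for X in blocks], None, cfg)
        np.testing.assert_allclose(m2.W, m1.W[perm], atol=1e-8)
        for a, b in zip(m1.H, m2.H):
            np.testing.assert_allclose(a, b, atol=1e-8)
        assert t1.objective[-1] == pytest.approx(t2.objective[-1], rel=1e-9)
        assert t1.relative_error[-1] == pytest.approx(t2.relative_error[-1], rel=1e-9)


class TestReconstructionMetrics:
    def test_perfect_reconstruction(self, rng):
        W, H = random_factors(rng, n=6, K=2, q=(4, 5, 3))
        blocks = [W @ Hi for Hi in H]
        cfg = RunConfig(K=2, max_iter=0, scale_blocks=False)
        from jsnmf.factorization import FactorizationModel

        model = FactorizationModel(
            W=W, H=H, config=cfg, variant="jnmf",
            sample_ids=[f"s{i}" for i in range(6)],
            feature_ids=[[f"f{b}{j}" for j in range(q)] for b, q in enumerate((4, 5, 3))],
        )
        m = reconstruction_metrics(blocks, model, n_boot=50)
        assert m["euclidean_distance"] == pytest.approx(0.0, abs=1e-12)
        assert m["relative_error"] == pytest.approx(0.0, abs=1e-12)
        for pb in m["per_block"]:
            assert pb["mean_correlation"] == pytest.approx(1.0)

    def test_per_sample_pearson_matches_scalar_oracle(self, rng):
        from scipy.stats import pearsonr

        from jsnmf.factorization import FactorizationModel, per_sample_correlations

        W, H = random_factors(rng, n=6, K=2, q=(4, 5, 3))
        blocks = [W @ Hi + rng.normal(0, 0.1, size=(6, Hi.shape[1])) for Hi in H]
        cfg = RunConfig(K=2, scale_blocks=False)
        model = FactorizationModel(W=W, H=H, config=cfg, variant="jnmf",
                                   sample_ids=list("abcdef"), feature_ids=[[], [], []])
        r = per_sample_correlations(blocks, model)[0]
        for i in range(6):
            assert r[i] == pytest.approx(pearsonr(blocks[0][i], (W @ H[0])[i])[0])

    def test_noise_increases_euclidean_distance(self, rng):
        from jsnmf.factorization import FactorizationModel

        W, H = random_factors(rng, n=6, K=2, q=(4, 5, 3))
        clean = [W @ Hi for Hi in H]
        noisy = [X + rng.uniform(0.01, 0.1, X.shape) for X in clean]
        cfg = RunConfig(K=2, scale_blocks=False)
        model = FactorizationModel(W=W, H=H, config=cfg, variant="jnmf",
                                   sample_ids=list("abcdef"), feature_ids=[[], [], []])
        m0 = reconstruction_metrics(clean, model, n_boot=10)
        m1 = reconstruction_metrics(noisy, model, n_boot=10)
        assert m1["euclidean_distance"] > m0["euclidean_distance"]


def test_match_components_recovers_known_permutation(rng):
    W = rng.uniform(0, 1, size=(30, 4))
    perm = np.array([2, 0, 3, 1])
    noisy = W[:, perm] + rng.normal(0, 0.01, size=(30, 4))
    cols, meanr = match_components(noisy, W)
    # column `cols[a]` of `noisy` should be true column a
    np.testing.assert_array_equal(perm[cols], np.arange(4))
    assert meanr > 0.99
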