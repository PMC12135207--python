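"""Gaussian-mixture quantization, closed-form Gaussian W2 and the exact
transport LP, each checked against an independent oracle."""

from itertools import combinations

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from cytoqot import (CostMatrix, GmmSummary, QotConfig, ValidationError,
                     build_cost_matrix, cosine_cost, fit_gmm, gaussian_w2_sq,
                     mixture_distance, pairwise_distances, qot_distance,
                     qot_transport, solve_transport)
from cytoqot.io import harmonize

from conftest import make_sample


# --- independent oracles ---------------------------------------------------

def w2sq_1d_quantile(mu_a, sd_a, mu_b, sd_b):
    """1-D W2^2 via the quantile-coupling integral int_0^1 (F^-1 - G^-1)^2."""
    f = lambda u: (norm.ppf(u, mu_a, sd_a) - norm.ppf(u, mu_b, sd_b)) ** 2
    val, _ = quad(f, 1e-12, 1 - 1e-12, limit=200)
    return val


def transport_vertex_minimum(a, b, C):
    """Exhaustive minimization over the transportation polytope's vertices.

    Basic feasible solutions use at most H_a + H_b - 1 cells; every support
    subset of that size is solved by least squares and kept if feasible.
    """
    Ha, Hb = len(a), len(b)
    A = np.zeros((Ha + Hb, Ha * Hb))
    for p in range(Ha):
        A[p, p * Hb:(p + 1) * Hb] = 1.0
    for q in range(Hb):
        A[Ha + q, q::Hb] = 1.0
    rhs = np.concatenate([a, b])
    best = np.inf
    for cols in combinations(range(Ha * Hb), Ha + Hb - 1):
        sub = A[:, cols]
        sol, *_ = np.linalg.lstsq(sub, rhs, rcond=None)
        if (sol < -1e-10).any():
            continue
        x = np.zeros(Ha * Hb)
        x[list(cols)] = np.clip(sol, 0, None)
        if not np.allclose(A @ x, rhs, atol=1e-9):
            continue
        best = min(best, float(C.ravel() @ x))
    return best


def random_gmm(rng, H, m):
    w = rng.dirichlet(np.ones(H))
    means = rng.normal(0, 3, size=(H, m))
    covs = []
    for _ in range(H):
        L = rng.normal(0, 1, size=(m, m))
        covs.append(L @ L.T + 0.1 * np.eye(m))
    return GmmSummary(weights=w, means=means, covariances=np.array(covs))


# --- Gaussian W2 ------------------------------------------------------------

class TestGaussianW2:
    def test_identical_gaussians_zero(self, rng):
        m = rng.normal(size=3)
        L = rng.normal(size=(3, 3))
        cov = L @ L.T + np.eye(3)
        assert gaussian_w2_sq(m, cov, m, cov) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("a,b,expected", [
        ((0.0, 1.0), (3.0, 1.0), 9.0),   # equal variances: mean gap only
        ((0.0, 1.0), (0.0, 4.0), 1.0),   # (sigma_a - sigma_b)^2
        ((1.0, 2.0), (-1.0, 0.5), None),  # generic case, oracle only
    ])
    def test_1d_matches_quantile_integral(self, a, b, expected):
        got = gaussian_w2_sq([a[0]], [[a[1]]], [b[0]], [[b[1]]])
        oracle = w2sq_1d_quantile(a[0], np.sqrt(a[1]), b[0], np.sqrt(b[1]))
        assert got == pytest.approx(oracle, abs=1e-6)
        if expected is not None:
            assert got == pytest.approx(expected, abs=1e-9)

    def test_2d_diagonal_is_dimension_additive(self):
        got = gaussian_w2_sq([0, 0], np.diag([1.0, 1.0]),
                             [3, 0], np.diag([1.0, 4.0]))
        assert got == pytest.approx(9.0 + 1.0, abs=1e-9)

    def test_symmetry_and_mean_gap_lower_bound(self, rng):
        for _ in range(20):
            g1 = random_gmm(rng, 1, 4)
            g2 = random_gmm(rng, 1, 4)
            d12 = gaussian_w2_sq(g1.means[0], g1.covariances[0],
                                 g2.means[0], g2.covariances[0])
            d21 = gaussian_w2_sq(g2.means[0], g2.covariances[0],
                                 g1.means[0], g1.covariances[0])
            assert d12 == pytest.approx(d21, rel=1e-8, abs=1e-10)
            gap = np.sum((g1.means[0] - g2.means[0]) ** 2)
            assert d12 >= gap - 1e-8

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(ValidationError, match="PSD"):
            gaussian_w2_sq([0, 0], [[1, 0], [0, -1.0]], [0, 0], np.eye(2))

    def test_asymmetric_covariance_rejected(self):
        with pytest.raises(ValidationError, match="symmetric"):
            gaussian_w2_sq([0, 0], [[1, 0.5], [0.1, 1.0]], [0, 0], np.eye(2))


class TestCosineCost:
    @pytest.mark.parametrize("a,b,expected", [
        ((1, 0), (2, 0), 0.0),
        ((1, 0), (0, 1), 1.0),
        ((1, 0), (-1, 0), 2.0),
    ])
    def test_reference_angles(self, a, b, expected):
        assert cosine_cost(a, b) == pytest.approx(expected, abs=1e-12)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValidationError, match="zero-norm"):
            cosine_cost((0.0, 0.0), (1.0, 0.0))


class TestCostMatrix:
    def test_self_cost_zero_diagonal(self, rng):
        g = random_gmm(rng, 3, 2)
        C = build_cost_matrix(g, g)
        np.testing.assert_allclose(np.diag(C.values), 0.0, atol=1e-8)

    def test_matches_elementwise_recomputation(self, rng):
        ga, gb = random_gmm(rng, 2, 3), random_gmm(rng, 3, 3)
        for mode in ("gaussian_w2", "cosine"):
            C = build_cost_matrix(ga, gb, mode)
            assert C.values.shape == (2, 3)
            for p in range(2):
                for q in range(3):
                    if mode == "gaussian_w2":
                        want = gaussian_w2_sq(ga.means[p], ga.covariances[p],
                                              gb.means[q], gb.covariances[q])
                    else:
                        want = cosine_cost(ga.means[p], gb.means[q])
                    assert C.values[p, q] == pytest.approx(want, abs=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError, match="dimension"):
            build_cost_matrix(random_gmm(rng, 1, 2), random_gmm(rng, 1, 3))


# --- transport LP -----------------------------------------------------------

class TestSolveTransport:
    def test_1x1_fully_constrained(self):
        plan = solve_transport([1.0], [1.0], np.array([[7.0]]))
        np.testing.assert_allclose(plan.coupling, [[1.0]], atol=1e-12)
        assert plan.objective == pytest.approx(7.0)

    def test_zero_diagonal_gives_identity_coupling(self):
        C = np.array([[0.0, 5.0, 2.0], [1.0, 0.0, 3.0], [4.0, 9.0, 0.0]])
        w = np.ones(3) / 3
        plan = solve_transport(w, w, C)
        np.testing.assert_allclose(plan.coupling, np.eye(3) / 3, atol=1e-9)
        assert plan.objective == pytest.approx(0.0, abs=1e-12)

    def test_worked_2x2_example(self):
        plan = solve_transport([0.3, 0.7], [0.6, 0.4],
                               np.array([[1.0, 2.0], [3.0, 1.0]]))
        assert plan.objective == pytest.approx(1.6, abs=1e-9)
        np.testing.assert_allclose(plan.coupling,
                                   [[0.3, 0.0], [0.3, 0.4]], atol=1e-9)

    @pytest.mark.parametrize("shape", [(2, 2), (2, 3), (3, 3)])
    def test_matches_vertex_enumeration_on_rational_grids(self, shape, rng):
        Ha, Hb = shape
        grid = np.arange(1, 5)
        for _ in range(15):
            a = rng.choice(grid, Ha).astype(float)
            b = rng.choice(grid, Hb).astype(float)
            a, b = a / a.sum(), b / b.sum()
            C = rng.integers(0, 10, size=shape).astype(float)
            plan = solve_transport(a, b, C)
            oracle = transport_vertex_minimum(a, b, C)
            assert plan.objective == pytest.approx(oracle, abs=1e-9)
            np.testing.assert_allclose(plan.coupling.sum(axis=1), a, atol=1e-7)
            np.testing.assert_allclose(plan.coupling.sum(axis=0), b, atol=1e-7)

    def test_infeasible_marginals_rejected(self):
        with pytest.raises(ValidationError, match="sum"):
            solve_transport([0.5, 0.4], [0.5, 0.5], np.zeros((2, 2)))


# --- GMM quantization -------------------------------------------------------

class TestFitGmm:
    def test_single_gaussian_recovers_moments(self, rng):
        X = rng.normal(loc=[2.0, -1.0], scale=1.0, size=(500, 2))
        s = make_sample(rng, means=[(0, 0)], n_cells=1)  # placeholder shape
        g = fit_gmm(X, QotConfig(selection="fixed", n_components=1))
        assert g.weights == pytest.approx([1.0])
        se = 1.0 / np.sqrt(500)
        assert np.all(np.abs(g.means[0] - X.mean(axis=0)) < 3 * se)
        np.testing.assert_allclose(g.covariances[0], np.cov(X.T), atol=0.15)

    def test_bic_selects_two_for_two_blobs(self, rng):
        from sklearn.mixture import GaussianMixture
        s = make_sample(rng, means=[(0.0, 0.0), (10.0, 10.0)], n_cells=500)
        cfg = QotConfig(selection="bic", bic_range=(1, 5), bic_patience=None)
        g = fit_gmm(s, cfg)
        assert g.n_components == 2
        assert g.weights == pytest.approx([0.5, 0.5], abs=0.05)
        # independent BIC comparison on the same data
        bics = [GaussianMixture(H, reg_covar=1e-6, random_state=0)
                .fit(s.matrix).bic(s.matrix) for H in range(1, 6)]
        assert int(np.argmin(bics)) + 1 == 2

    def test_weights_simplex_and_sorted(self, rng):
        s = make_sample(rng, means=[(0, 0), (6, 0), (0, 6)], n_cells=150)
        g = fit_gmm(s, QotConfig(selection="fixed", n_components=3))
        assert g.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(g.weights) <= 1e-12)  # descending

    def test_too_many_components_rejected(self, rng):
        s = make_sample(rng, n_cells=3)
        with pytest.raises(ValidationError, match="exceeds"):
            fit_gmm(s, QotConfig(selection="fixed", n_components=5))

    def test_deterministic_and_permutation_invariant(self, rng):
        s = make_sample(rng, means=[(0, 0), (8, 8)], n_cells=200)
        cfg = QotConfig(selection="fixed", n_components=2, seed=7)
        g1, g2 = fit_gmm(s, cfg), fit_gmm(s, cfg)
        np.testing.assert_array_equal(g1.means, g2.means)
        perm = np.random.default_rng(1).permutation(s.n_cells)
        shuffled = CytoShuffle(s, perm)
        g3 = fit_gmm(shuffled, cfg)
        np.testing.assert_array_equal(g1.means, g3.means)
        np.testing.assert_array_equal(g1.covariances, g3.covariances)

    def test_json_roundtrip(self, rng):
        g = random_gmm(rng, 2, 3)
        back = GmmSummary.from_json(g.to_json())
        np.testing.assert_allclose(back.weights, g.weights)
        np.testing.assert_allclose(back.covariances, g.covariances)


def CytoShuffle(sample, perm):
    from dataclasses import replace
    return replace(sample, matrix=sample.matrix[perm])


# --- sample distances -------------------------------------------------------

H1 = QotConfig(selection="fixed", n_components=1)


class TestQotDistance:
    def test_self_distance_zero(self, two_blob_sample):
        cfg = QotConfig(selection="fixed", n_components=2)
        assert qot_distance(two_blob_sample, two_blob_sample, cfg) == \
            pytest.approx(0.0, abs=1e-7)

    def test_h1_reduces_to_gaussian_w2(self, rng):
        a = make_sample(rng, sample_id="a", means=[(0, 0)], n_cells=300)
        b = make_sample(rng, sample_id="b", means=[(4, 1)], n_cells=300)
        dist, plan, ga, gb = qot_transport(a, b, H1)
        direct = np.sqrt(gaussian_w2_sq(ga.means[0], ga.covariances[0],
                                        gb.means[0], gb.covariances[0]))
        assert dist == pytest.approx(direct, abs=1e-9)

    def test_symmetry(self, rng):
        a = make_sample(rng, sample_id="a", means=[(0, 0), (5, 5)])
        b = make_sample(rng, sample_id="b", means=[(1, 3)])
        cfg = QotConfig(selection="bic", bic_range=(1, 3))
        dab, dba = qot_distance(a, b, cfg), qot_distance(b, a, cfg)
        assert dab == pytest.approx(dba, rel=1e-8)

    def test_translation_covariance_h1(self, rng):
        a = make_sample(rng, sample_id="a", means=[(0, 0)], n_cells=300)
        b = make_sample(rng, sample_id="b", means=[(3, 1)], n_cells=300)
        _, plan, ga, gb = qot_transport(a, b, H1)
        v = np.array([2.0, -1.0])
        from dataclasses import replace
        b_shift = replace(b, matrix=b.matrix + v)
        d2 = qot_transport(a, b_shift, H1)[1].objective
        d1 = plan.objective
        gap = ga.means[0] - gb.means[0]
        expected_change = np.sum((gap - v) ** 2) - np.sum(gap ** 2)
        assert d2 - d1 == pytest.approx(expected_change, abs=1e-6)

    def test_constant_marker_leaves_distance_unchanged(self, rng):
        cfg = QotConfig(selection="fixed", n_components=2,
                        covariance_type="diag")
        mats = []
        for sid in ("a", "b"):
            s = make_sample(rng, sample_id=sid, means=[(0, 0, 0), (6, 6, 0)],
                            n_cells=200, n_markers=3)
            mat = s.matrix.copy()
            mat[:, 2] = 4.2  # constant, identical everywhere
            from dataclasses import replace
            mats.append(replace(s, matrix=mat))
        a, b = mats
        d_full = qot_distance(a, b, cfg)
        d_red = qot_distance(a.select_markers(("M01", "M02")),
                             b.select_markers(("M01", "M02")), cfg)
        assert d_full == pytest.approx(d_red, abs=1e-7)

    def test_metric_axioms_on_random_mixtures(self, rng):
        # nonnegativity, symmetry, identity, triangle inequality (MW2)
        for _ in range(50):
            H = rng.integers(1, 4)
            g1, g2, g3 = (random_gmm(rng, int(H), 3) for _ in range(3))
            d12 = mixture_distance(g1, g2)
            d13 = mixture_distance(g1, g3)
            d23 = mixture_distance(g2, g3)
            assert min(d12, d13, d23) >= 0
            assert mixture_distance(g2, g1) == pytest.approx(d12, abs=1e-7)
            assert mixture_distance(g1, g1) == pytest.approx(0.0, abs=1e-7)
            assert d13 <= d12 + d23 + 1e-7


class TestPairwiseDistances:
    def _study(self, rng, n=4):
        samples = []
        for i in range(n):
            samples.append(make_sample(
                rng, sample_id=f"s{i}", subject_id=f"sub{i}", timepoint="T1",
                means=[(2.0 * i, 0.0)], n_cells=120))
        return harmonize(samples)

    def test_two_samples_matches_single_pair(self, rng):
        study = self._study(rng, 2)
        dm = pairwise_distances(study, None, H1)
        direct = qot_distance(study.samples[0], study.samples[1], H1)
        assert dm.values[0, 1] == pytest.approx(direct, abs=1e-12)

    def test_duplicate_content_zero_distance(self, rng):
        from dataclasses import replace
        a = make_sample(rng, sample_id="a", subject_id="A", means=[(0, 0)])
        b = replace(a, sample_id="b", subject_id="B")
        study = harmonize([a, b])
        dm = pairwise_distances(study, None, H1)
        assert dm.values[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_matrix_matches_loop_recomputation(self, rng):
        study = self._study(rng, 4)
        dm = pairwise_distances(study, None, H1)
        for i in range(4):
            for j in range(i + 1, 4):
                want = qot_distance(study.samples[i], study.samples[j], H1)
                assert dm.values[i, j] == pytest.approx(want, abs=1e-12)
        assert np.all(np.diag(dm.values) == 0)

    def test_unknown_marker_rejected(self, rng):
        study = self._study(rng, 2)
        with pytest.raises(ValidationError, match="CD99"):
            pairwise_distances(study, ("CD99",), H1)

    def test_tsv_roundtrip(self, rng, tmp_path):
        dm = pairwise_distances(self._study(rng, 3), None, H1)
        dm.to_tsv(tmp_path / "d.tsv")
        from cytoqot import DistanceMatrix
        back = DistanceMatrix.from_tsv(tmp_path / "d.tsv")
        np.testing.assert_allclose(back.values, dm.values, atol=1e-12)
        assert back.subject_ids == dm.subject_ids
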