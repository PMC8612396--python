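"""Synthetic designs, overlap estimation, the overlap-controlled generator
and partition scoring."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import norm

from parsimix import (
    ConstraintSpec,
    MixtureParameters,
    adjusted_rand_index,
    check_constraints,
    generate_overlap_mixture,
    limit_model,
    make_design_A,
    make_design_B,
    pairwise_overlap,
    sample_mixture,
)


class TestDesignA:
    def test_lower_case_dimensions(self):
        X, labels, params = make_design_A(seed=0)
        assert X.shape == (90, 3)
        assert np.bincount(labels).tolist() == [50, 20, 20]

    def test_higher_variants(self):
        X, _, _ = make_design_A(higher_n=True, seed=0)
        assert X.shape == (180, 3)
        X, _, params = make_design_A(higher_p=True, seed=0)
        assert X.shape == (90, 4)
        assert params.covariances[0, 3, 3] == 100.0

    def test_printed_parameters(self):
        _, _, params = make_design_A(seed=0)
        assert np.allclose(params.means, [[0, 0, 0], [2, 6, 0], [6, 0, 0]])
        assert np.allclose(params.covariances[0], np.diag([2, 2, 100]))
        assert np.allclose(params.covariances[1], np.diag([3, 1, 100]))
        assert np.allclose(params.covariances[2], np.diag([1, 2, 100]))
        assert np.allclose(params.weights, [50 / 90, 20 / 90, 20 / 90])

    def test_empirical_moments(self):
        """Component means over many draws sit within 3 standard errors."""
        _, _, params = make_design_A(seed=0)
        n = 100_000
        X, labels = sample_mixture(params, sizes=[n, n, n], seed=1)
        for j in range(3):
            G = X[labels == j]
            se = np.sqrt(np.diag(params.covariances[j]) / n)
            assert np.all(np.abs(G.mean(axis=0) - params.means[j]) < 3 * se)


class TestDesignB:
    def test_dimensions_and_sizes(self):
        X, labels, params = make_design_B(seed=0)
        assert X.shape == (325, 3)  # 23+36+93+38+123+12
        assert np.bincount(labels).tolist() == [23, 36, 93, 38, 123, 12]

    def test_printed_means(self):
        _, _, params = make_design_B(seed=0)
        expected = [(-4.5, 3.6), (0.40, 3.6), (-4.4, -1), (9.2, -1), (0.4, -1), (9.2, 3.6)]
        assert np.allclose(params.means[:, :2], expected)
        assert np.allclose(params.means[:, 2], 0.0)

    def test_common_spherical_in_plane_scatter(self):
        _, _, params = make_design_B(seed=0)
        for C in params.covariances:
            assert np.allclose(C[:2, :2], params.covariances[0][:2, :2])
            assert C[0, 0] == C[1, 1]
            assert C[2, 2] == 100.0


class TestSampleMixture:
    def test_exact_sizes_and_seeded_reproducibility(self, rng, mixture_factory):
        params = mixture_factory(rng, 3, 2)
        X1, l1 = sample_mixture(params, sizes=[5, 7, 3], seed=11)
        X2, l2 = sample_mixture(params, sizes=[5, 7, 3], seed=11)
        assert np.array_equal(X1, X2) and np.array_equal(l1, l2)
        assert np.bincount(l1).tolist() == [5, 7, 3]

    def test_multinomial_total(self, rng, mixture_factory):
        params = mixture_factory(rng, 3, 2)
        X, labels = sample_mixture(params, n=57, seed=2)
        assert X.shape == (57, 2) and labels.size == 57

    def test_empirical_covariance(self, rng, mixture_factory):
        params = mixture_factory(rng, 2, 3)
        n = 100_000
        X, labels = sample_mixture(params, sizes=[n, 0], seed=3)
        emp = np.cov(X.T, bias=True)
        C = params.covariances[0]
        # elementwise within 3 standard errors (normal fourth-moment formula)
        se = np.sqrt((np.outer(np.diag(C), np.diag(C)) + C**2) / n)
        assert np.all(np.abs(emp - C) < 3 * se)


class TestOverlap:
    def test_vanishing_overlap_for_distant_components(self):
        params = MixtureParameters(
            weights=[0.5, 0.5],
            means=[[0.0, 0.0], [3000.0, 0.0]],
            covariances=np.stack([np.eye(2)] * 2),
        )
        assert pairwise_overlap(params, 20_000, seed=0).average <= 1e-4

    def test_one_dimensional_closed_form(self):
        """Two unit-variance components 2z apart: each directed probability is
        the standard-normal tail beyond z, so z = 1.959964 gives overlap 0.05."""
        z = 1.959964
        params = MixtureParameters(
            weights=[0.5, 0.5], means=[[0.0], [2 * z]], covariances=np.ones((2, 1, 1))
        )
        mc = 200_000
        summary = pairwise_overlap(params, mc, seed=4)
        expected = 2 * norm.sf(z)  # = 0.05
        se = math.sqrt(expected / 2 * (1 - expected / 2) / mc)
        assert abs(summary.average - expected) < 3 * 2 * se
        assert abs(summary.w[0, 1] - norm.sf(z)) < 3 * se

    def test_monotone_in_separation(self):
        prev = 1.1
        for gap in (0.5, 1.5, 3.0, 6.0):
            params = MixtureParameters(
                weights=[0.5, 0.5],
                means=[[0.0], [gap]],
                covariances=np.ones((2, 1, 1)),
            )
            avg = pairwise_overlap(params, 50_000, seed=5).average
            assert avg < prev
            prev = avg

    def test_summary_invariants(self, rng, mixture_factory):
        params = mixture_factory(rng, 3, 2)
        s = pairwise_overlap(params, 10_000, seed=6)
        assert np.all(np.diag(s.w) == 0)
        assert np.all((s.w >= 0) & (s.w <= 1))
        assert s.average == pytest.approx(s.w.sum() / 3)


class TestOverlapGenerator:
    @pytest.mark.parametrize("code", ["EEE", "VVI", "VVV"])
    def test_realized_overlap_and_pattern(self, code):
        params = generate_overlap_mixture(3, 6, model=code, target_overlap=0.05, seed=31)
        model = limit_model(code)
        spec = model.spec(substitute=100.0, substitute_shb=10.0)
        if math.isinf(model.limits[0]):
            spec = ConstraintSpec(100.0, spec.c_shw, spec.c_shb, spec.rotation)
        assert check_constraints(params, spec.effective(6), tol=1e-8).satisfied
        mc = 100_000
        realized = pairwise_overlap(params, mc, seed=77).average
        se = math.sqrt(0.05 * 0.95 / mc) * math.sqrt(6) / 3
        assert abs(realized - 0.05) <= 0.005 + 3 * se

    def test_equal_weights_honored(self):
        params = generate_overlap_mixture(3, 4, model="EEI", target_overlap=0.1, seed=2)
        assert np.allclose(params.weights, 1 / 3)

    def test_custom_target(self):
        params = generate_overlap_mixture(2, 3, model="VVV", target_overlap=0.2, seed=3)
        realized = pairwise_overlap(params, 100_000, seed=8).average
        assert abs(realized - 0.2) <= 0.012


def brute_force_ari(a, b):
    """Pair-counting Hubert–Arabie ARI over all unordered pairs."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = a.size
    both = same_a = same_b = 0
    pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        pairs += 1
        sa = a[i] == a[j]
        sb = b[i] == b[j]
        same_a += sa
        same_b += sb
        both += sa and sb
    expected = same_a * same_b / pairs
    max_index = 0.5 * (same_a + same_b)
    if max_index == expected:
        return 1.0
    return (both - expected) / (max_index - expected)


class TestARI:
    def test_identical_and_permuted(self):
        a = [0, 0, 1, 1, 2, 2]
        assert adjusted_rand_index(a, a) == 1.0
        assert adjusted_rand_index(a, [2, 2, 0, 0, 1, 1]) == 1.0

    def test_contingency_example(self):
        # contingency table [[2,1],[1,2]] on n=6
        a = [0, 0, 0, 1, 1, 1]
        b = [0, 0, 1, 0, 1, 1]
        assert adjusted_rand_index(a, b) == pytest.approx(brute_force_ari(a, b))

    def test_matches_brute_force_on_all_small_partitions(self):
        """Agreement with direct pair counting on random partitions, n <= 7."""
        rng = np.random.default_rng(12)
        for _ in range(200):
            n = int(rng.integers(2, 8))
            a = rng.integers(0, 3, size=n)
            b = rng.integers(0, 3, size=n)
            assert adjusted_rand_index(a, b) == pytest.approx(
                brute_force_ari(a, b), abs=1e-12
            )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([0, 1], [0, 1, 2])
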