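"""KDE bandwidths, PDF normalisation and KLS similarity properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from morphnet import (
    PDFEstimate,
    RegionSampleSet,
    build_network,
    estimate_pdf,
    kls_similarity,
    extract_region_samples,
    pairwise_grid,
    scott_bandwidth,
)
from morphnet.network import (
    DegenerateRegionError,
    DegenerateSampleError,
    GridCoverageError,
    GridMismatchError,
    ShapeMismatchError,
    _fit_kde,
)


def _grid_for(sample, points=256, pad=4.0):
    h = scott_bandwidth(sample)
    return np.linspace(sample.min() - pad * h, sample.max() + pad * h, points)


class TestBandwidthAndPDF:
    def test_scott_rule_value(self):
        """h = sigma_hat * n**(-1/5): unit-variance sample of 1000 values."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=1000)
        x = (x - x.mean()) / x.std(ddof=1)  # exact sigma_hat = 1
        pdf = estimate_pdf(x, _grid_for(x))
        assert pdf.bandwidth == pytest.approx(1000 ** (-0.2), rel=1e-10)
        assert pdf.bandwidth == pytest.approx(0.2512, abs=5e-5)
        assert pdf.bandwidth == pytest.approx(scott_bandwidth(x), rel=1e-10)

    @pytest.mark.parametrize("n", [10, 137, 1000])
    def test_unit_trapezoid_integral(self, n):
        rng = np.random.default_rng(n)
        x = rng.gamma(3.0, 2.0, n)
        pdf = estimate_pdf(x, _grid_for(x))
        assert np.trapezoid(pdf.density, pdf.grid) == pytest.approx(1.0, abs=1e-6)
        assert np.all(pdf.density >= 0)
        assert pdf.n_obs == n

    def test_kde_close_to_true_normal_density(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=5000)
        pdf = estimate_pdf(x, _grid_for(x))
        assert np.max(np.abs(pdf.density - norm.pdf(pdf.grid))) < 0.05

    def test_degenerate_and_coverage_errors(self):
        with pytest.raises(DegenerateSampleError):
            estimate_pdf(np.array([1.0, 1.0, 1.0]), np.linspace(0, 2, 64))
        x = np.random.default_rng(1).normal(size=50)
        with pytest.raises(GridCoverageError):
            estimate_pdf(x, np.linspace(x.min(), x.max(), 64))  # no padding
        with pytest.raises(DegenerateSampleError):
            _fit_kde(np.array([3.0]))


class TestKLS:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(2.0, 0.5, 400)
        pdf = estimate_pdf(x, _grid_for(x))
        assert kls_similarity(pdf, pdf) == 1.0

    def test_equal_uniform_densities(self):
        grid = np.linspace(0.0, 1.0, 128)
        p = PDFEstimate(grid, np.ones(128), bandwidth=0.1, n_obs=100)
        q = PDFEstimate(grid, np.ones(128), bandwidth=0.2, n_obs=50)
        assert kls_similarity(p, q) == 1.0

    def test_gaussian_pair_against_bruteforce_sum(self):
        """Discretised N(0,1) vs N(0.5,1): explicit-loop divergence oracle."""
        grid = np.linspace(-6.0, 6.5, 256)
        p_dens = norm.pdf(grid)
        q_dens = norm.pdf(grid, loc=0.5)
        # oracle: floor, renormalise, sum both directed divergences by loop
        pf = np.maximum(p_dens, 1e-10)
        qf = np.maximum(q_dens, 1e-10)
        pf, qf = pf / pf.sum(), qf / qf.sum()
        d = 0.0
        for i in range(grid.size):
            d += pf[i] * np.log(pf[i] / qf[i]) + qf[i] * np.log(qf[i] / pf[i])
        expected = np.exp(-d)
        p = PDFEstimate(grid, p_dens, 1.0, 1000)
        q = PDFEstimate(grid, q_dens, 1.0, 1000)
        assert kls_similarity(p, q) == pytest.approx(expected, rel=1e-12)
        # discretised symmetrised KL of equal-variance normals ~ (dmu/sigma)^2
        assert kls_similarity(p, q) == pytest.approx(np.exp(-0.25), abs=2e-3)

    def test_grid_mismatch_raises(self):
        g1 = np.linspace(0, 1, 64)
        g2 = np.linspace(0, 1.1, 64)
        p = PDFEstimate(g1, np.ones(64), 0.1, 10)
        q = PDFEstimate(g2, np.ones(64), 0.1, 10)
        with pytest.raises(GridMismatchError):
            kls_similarity(p, q)

    @given(
        mu1=st.floats(-2, 2), mu2=st.floats(-2, 2),
        s1=st.floats(0.3, 2.0), s2=st.floats(0.3, 2.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_symmetry_bounds_identity(self, mu1, mu2, s1, s2):
        """KLS is symmetric, lies in [0,1], and equals 1 on identical input."""
        grid = np.linspace(-10, 10, 256)
        p = PDFEstimate(grid, norm.pdf(grid, mu1, s1), s1, 100)
        q = PDFEstimate(grid, norm.pdf(grid, mu2, s2), s2, 100)
        k_pq = kls_similarity(p, q)
        assert k_pq == kls_similarity(q, p)
        assert 0.0 <= k_pq <= 1.0
        assert kls_similarity(p, p) == 1.0

    def test_monotone_decrease_with_mean_shift(self):
        grid = np.linspace(-8, 12, 512)
        base = PDFEstimate(grid, norm.pdf(grid), 1.0, 100)
        scores = []
        for shift in [0.0, 0.25, 0.5, 1.0, 2.0, 4.0]:
            q = PDFEstimate(grid, norm.pdf(grid, loc=shift), 1.0, 100)
            scores.append(kls_similarity(base, q))
        assert all(a > b for a, b in zip(scores, scores[1:]))


class TestBuildNetwork:
    def _sample_set(self, n_regions, seed, n=120):
        rng = np.random.default_rng(seed)
        return RegionSampleSet(
            {r: rng.normal(0.1 * r, 1.0, n) for r in range(1, n_regions + 1)}
        )

    def test_matches_operationwise_path(self):
        """build_network equals the explicit estimate_pdf + kls loop."""
        samples = self._sample_set(4, seed=5)
        net = build_network(samples, grid_points=128)
        for i in range(1, 5):
            for j in range(i + 1, 5):
                si, sj = samples[i], samples[j]
                grid = pairwise_grid(
                    si, scott_bandwidth(si), sj, scott_bandwidth(sj), 128
                )
                expected = kls_similarity(
                    estimate_pdf(si, grid), estimate_pdf(sj, grid)
                )
                assert net.values[i - 1, j - 1] == pytest.approx(expected, rel=1e-9)

    def test_shape_symmetry_diagonal(self):
        net = build_network(self._sample_set(6, seed=2), grid_points=96)
        v = net.values
        assert v.shape == (6, 6)
        assert np.array_equal(v, v.T)
        assert np.array_equal(np.diag(v), np.ones(6))
        assert np.all((v >= 0) & (v <= 1))

    def test_identical_regions_score_near_one(self):
        rng = np.random.default_rng(9)
        pooled = rng.normal(0.5, 0.1, 3000)
        samples = RegionSampleSet(
            {r: pooled[rng.integers(0, 3000, 500)] for r in range(1, 4)}
        )
        net = build_network(samples, grid_points=128)
        off = net.values[np.triu_indices(3, 1)]
        assert np.all(off > 0.95)

    def test_relabelling_conjugation_invariance(self):
        samples = self._sample_set(5, seed=13)
        net = build_network(samples, grid_points=96)
        perm = np.array([2, 0, 4, 1, 3])
        permuted = RegionSampleSet(
            {k + 1: samples[int(p) + 1] for k, p in enumerate(perm)}
        )
        net_p = build_network(permuted, grid_points=96)
        assert np.allclose(net_p.values, net.values[np.ix_(perm, perm)], atol=1e-12)

    def test_discretisation_stability(self):
        samples = self._sample_set(5, seed=21, n=300)
        v1 = build_network(samples, grid_points=256).values
        v2 = build_network(samples, grid_points=512).values
        assert np.max(np.abs(v1 - v2)) < 1e-3


class TestExtractRegionSamples:
    def test_values_and_counts(self):
        atlas = np.array([[[0, 1], [1, 2]], [[2, 2], [1, 0]]])
        gm = np.arange(8, dtype=float).reshape(2, 2, 2)
        rs = extract_region_samples(gm, atlas)
        assert rs.n_regions == 2
        assert sorted(rs[1]) == sorted(gm[atlas == 1])
        assert rs[2].size == 3

    def test_ninety_region_atlas(self):
        rng = np.random.default_rng(0)
        atlas = np.repeat(np.arange(1, 91), 4).reshape(6, 6, 10)
        gm = rng.random(atlas.shape)
        assert extract_region_samples(gm, atlas).n_regions == 90

    def test_error_paths(self):
        gm = np.zeros((2, 2, 2))
        with pytest.raises(ShapeMismatchError):
            extract_region_samples(gm, np.zeros((2, 2, 3), dtype=int))
        atlas = np.zeros((2, 2, 2), dtype=int)
        atlas[0, 0, 0] = 2  # region 1 has no voxels, region 2 only one
        gm = np.random.default_rng(1).random((2, 2, 2))
        with pytest.raises(DegenerateRegionError, match="region 1"):
            extract_region_samples(gm, atlas)
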