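"""Construction of individual gray-matter morphological similarity networks.

Each subject's network has one node per atlas region.  The edge between two
regions is a Kullback–Leibler-divergence-based similarity (KLS) between the
probability density functions (PDFs) of the regions' voxel-wise GM volume
values::

    KLS(p, q) = exp(-(KL(p || q) + KL(q || p)))

so that identical distributions score 1 and increasingly different
distributions decay towards 0.  PDFs are estimated by Gaussian kernel density
estimation with Scott's-rule bandwidth ``h = sigma_hat * n**(-1/5)`` and the
two directed divergences are evaluated by discrete summation on a shared
evaluation grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

#: Density floor applied before taking logarithms in the KL sum.  KL is
#: undefined on zeros; flooring keeps the symmetrised divergence finite and
#: deterministic.
DENSITY_FLOOR = 1e-10

#: Number of evaluation points of the shared pairwise grid.
DEFAULT_GRID_POINTS = 256

#: Grid padding beyond each sample's range, in units of that sample's
#: bandwidth.
GRID_PAD_BANDWIDTHS = 3.0


class NetworkError(ValueError):
    """Base class for network-construction errors."""


class ShapeMismatchError(NetworkError):
    """GM map and atlas are not on the same voxel grid."""


class DegenerateRegionError(NetworkError):
    """An atlas region holds fewer than two voxels."""


class DegenerateSampleError(NetworkError):
    """A voxel-value sample has fewer than two values or zero spread."""


class GridCoverageError(NetworkError):
    """The evaluation grid does not cover the sample range plus padding."""


class GridMismatchError(NetworkError):
    """Two PDF estimates were not evaluated on the identical grid."""


@dataclass
class RegionSampleSet:
    """Per-subject mapping ``region_id -> voxel GM-volume values``.

    Region ids are the consecutive integers ``1..n_regions``; every sample
    must hold at least two values with positive spread.
    """

    samples: dict[int, np.ndarray]
    atlas_name: str = "atlas"

    def __post_init__(self) -> None:
        ids = sorted(self.samples)
        if ids != list(range(1, len(ids) + 1)):
            raise NetworkError(
                f"region ids must be consecutive 1..R, got {ids[:5]}..."
            )
        clean = {}
        for rid, vals in self.samples.items():
            vals = np.asarray(vals, dtype=float).ravel()
            if vals.size < 2:
                raise DegenerateRegionError(
                    f"region {rid} has {vals.size} voxel value(s); need >= 2"
                )
            if np.ptp(vals) <= 0:
                raise DegenerateSampleError(f"region {rid} has zero spread")
            clean[rid] = vals
        self.samples = clean

    @property
    def n_regions(self) -> int:
        return len(self.samples)

    def __getitem__(self, region_id: int) -> np.ndarray:
        return self.samples[region_id]


@dataclass
class PDFEstimate:
    """A kernel density estimate evaluated on an explicit grid.

    ``density`` is renormalised to unit trapezoidal integral over ``grid``;
    ``bandwidth`` is the Scott's-rule Gaussian kernel width actually used.
    """

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n_obs: int


@dataclass
class SimilarityMatrix:
    """Symmetric R x R matrix of KLS scores for one subject.

    Diagonal entries are 1 (self-similarity) by convention and are excluded
    from thresholding, feature vectorisation and graph metrics downstream.
    """

    values: np.ndarray
    subject_id: str = ""
    region_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise NetworkError("similarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-9):
            raise NetworkError("similarity matrix must be symmetric")
        if self.region_ids is None:
            self.region_ids = np.arange(1, v.shape[0] + 1)
        else:
            self.region_ids = np.asarray(self.region_ids, dtype=int)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def extract_region_samples(
    gm_map: np.ndarray, atlas: np.ndarray, atlas_name: str = "atlas"
) -> RegionSampleSet:
    """Collect each region's GM values from a map/atlas pair.

    The sample for region ``r`` is exactly the ``gm_map`` values at voxels
    labelled ``r``; the background label 0 is excluded.
    """
    gm_map = np.asarray(gm_map, dtype=float)
    atlas = np.asarray(atlas)
    if gm_map.shape != atlas.shape:
        raise ShapeMismatchError(
            f"GM map shape {gm_map.shape} != atlas shape {atlas.shape}"
        )
    if not np.issubdtype(atlas.dtype, np.integer):
        if not np.all(atlas == np.round(atlas)):
            raise NetworkError("atlas labels must be integers")
        atlas = atlas.astype(int)
    n_regions = int(atlas.max())
    if n_regions < 1:
        raise NetworkError("atlas contains no positive labels")
    samples = {}
    for rid in range(1, n_regions + 1):
        vals = gm_map[atlas == rid]
        if vals.size < 2:
            raise DegenerateRegionError(
                f"region {rid} has {vals.size} voxel(s) in the atlas; need >= 2"
            )
        samples[rid] = vals
    return RegionSampleSet(samples, atlas_name=atlas_name)


def scott_bandwidth(sample: np.ndarray) -> float:
    """Scott's-rule bandwidth ``sigma_hat * n**(-1/5)`` (sigma with ddof=1)."""
    sample = np.asarray(sample, dtype=float)
    return float(np.std(sample, ddof=1) * sample.size ** (-1 / 5))


def _fit_kde(sample: np.ndarray) -> gaussian_kde:
    sample = np.asarray(sample, dtype=float).ravel()
    if sample.size < 2:
        raise DegenerateSampleError(f"need >= 2 observations, got {sample.size}")
    if np.ptp(sample) <= 0:
        raise DegenerateSampleError("sample has zero spread")
    # scipy's Scott factor is n**(-1/(d+4)) = n**(-1/5) in 1-D, applied to the
    # ddof=1 sample standard deviation -- exactly the rule used here.
    return gaussian_kde(sample, bw_method="scott")


def estimate_pdf(sample: np.ndarray, grid: np.ndarray) -> PDFEstimate:
    """Gaussian-kernel KDE of ``sample`` on ``grid``, unit trapezoid integral.

    ``grid`` must be strictly increasing and cover
    ``[min(sample) - 3h, max(sample) + 3h]`` with ``h`` the Scott bandwidth.
    """
    sample = np.asarray(sample, dtype=float).ravel()
    grid = np.asarray(grid, dtype=float).ravel()
    if grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise NetworkError("grid must be strictly increasing with >= 2 points")
    kde = _fit_kde(sample)
    h = float(np.sqrt(kde.covariance[0, 0]))
    lo = sample.min() - GRID_PAD_BANDWIDTHS * h
    hi = sample.max() + GRID_PAD_BANDWIDTHS * h
    tol = 1e-9 * max(1.0, abs(lo), abs(hi))
    if grid[0] > lo + tol or grid[-1] < hi - tol:
        raise GridCoverageError(
            f"grid [{grid[0]:g}, {grid[-1]:g}] does not cover "
            f"[{lo:g}, {hi:g}] (= sample range +/- {GRID_PAD_BANDWIDTHS}h)"
        )
    density = kde(grid)
    density = density / np.trapezoid(density, grid)
    return PDFEstimate(grid=grid, density=density, bandwidth=h, n_obs=sample.size)


def _discrete_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Symmetrised KL by discrete summation after flooring and renormalising."""
    p = np.maximum(np.asarray(p, dtype=float), DENSITY_FLOOR)
    q = np.maximum(np.asarray(q, dtype=float), DENSITY_FLOOR)
    p = p / p.sum()
    q = q / q.sum()
    log_ratio = np.log(p) - np.log(q)
    return float(np.sum(p * log_ratio) - np.sum(q * log_ratio))


def kls_similarity(p: PDFEstimate, q: PDFEstimate) -> float:
    """KL-based similarity ``exp(-(KL(p||q) + KL(q||p)))`` in [0, 1]."""
    if p.grid.shape != q.grid.shape or not np.array_equal(p.grid, q.grid):
        raise GridMismatchError("PDFs must be evaluated on the identical grid")
    d_sym = _discrete_divergence(p.density, q.density)
    return float(np.exp(-max(d_sym, 0.0)))


def pairwise_grid(
    sample_p: np.ndarray,
    bandwidth_p: float,
    sample_q: np.ndarray,
    bandwidth_q: float,
    grid_points: int = DEFAULT_GRID_POINTS,
) -> np.ndarray:
    """Shared evaluation grid spanning both samples' padded ranges."""
    lo = min(
        np.min(sample_p) - GRID_PAD_BANDWIDTHS * bandwidth_p,
        np.min(sample_q) - GRID_PAD_BANDWIDTHS * bandwidth_q,
    )
    hi = max(
        np.max(sample_p) + GRID_PAD_BANDWIDTHS * bandwidth_p,
        np.max(sample_q) + GRID_PAD_BANDWIDTHS * bandwidth_q,
    )
    return np.linspace(lo, hi, grid_points)


def build_network(
    samples: RegionSampleSet,
    grid_points: int = DEFAULT_GRID_POINTS,
    subject_id: str = "",
) -> SimilarityMatrix:
    """KLS similarity matrix over all region pairs of one subject.

    For every unordered pair the two region PDFs are evaluated on a shared
    grid (union of both padded ranges, ``grid_points`` equally spaced points)
    and converted to a KLS score.  The diagonal is set to 1.
    """
    n = samples.n_regions
    kdes = {}
    for rid in range(1, n + 1):
        try:
            kdes[rid] = _fit_kde(samples[rid])
        except DegenerateSampleError as exc:  # attach region identity
            raise DegenerateSampleError(f"region {rid}: {exc}") from exc
    bandwidths = {
        rid: float(np.sqrt(k.covariance[0, 0])) for rid, k in kdes.items()
    }
    values = np.eye(n)
    for i in range(1, n + 1):
        si = samples[i]
        for j in range(i + 1, n + 1):
            sj = samples[j]
            grid = pairwise_grid(
                si, bandwidths[i], sj, bandwidths[j], grid_points
            )
            # Normalisation by the trapezoid integral cancels in the floored,
            # sum-renormalised KL, so the raw KDE evaluations are equivalent
            # to full PDFEstimates here.
            d = _discrete_divergence(kdes[i](grid), kdes[j](grid))
            values[i - 1, j - 1] = values[j - 1, i - 1] = np.exp(-max(d, 0.0))
    return SimilarityMatrix(
        values=values, subject_id=subject_id or samples.atlas_name
    )
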