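"""Synthetic cohorts, toy atlases and toy graphs.

The study this pipeline targets compares regional GM-volume distribution
networks between a patient group and healthy controls (115 vs 87 subjects,
90 atlas regions).  No imaging data are deposited, so this module generates
cohorts with the statistical features the method needs:

* smooth spatial structure — region means follow a low-frequency gradient
  over homologous region pairs, so nearby region indices have similar PDFs
  (the analogue of spatial autocorrelation in VBM maps);
* a shared "global GM background" mixture component in every region, which
  keeps all pairwise similarities away from the degenerate extremes and
  supplies the long-range shortcuts real morphological networks show;
* heterogeneous region scales and per-subject jitter;
* an optional planted group effect: a location shift of the voxel-value
  distribution of a designated node subset in group B only, with per-node
  shift multipliers of varying sign and magnitude so that edges *within*
  the effect set also carry a group difference.

Identical :class:`CohortSpec` (same seed included) yields a bit-identical
cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .network import RegionSampleSet

__all__ = [
    "CohortSpec",
    "SubjectRecord",
    "make_toy_atlas",
    "generate_cohort",
    "toy_graph",
    "write_cohort_tsv",
    "read_cohort_tsv",
    "EFFECT_MULTIPLIERS",
]

#: Cyclic per-node multipliers of the planted location shift.  Varying sign
#: and magnitude guarantee that any two effect nodes end up with distinct
#: shifts, so edges among effect nodes differ between groups as well.
EFFECT_MULTIPLIERS = (1.0, -1.0, 0.6, -0.6, 1.4, -1.4, 0.8, -0.8, 1.2, -1.2)


class CohortSpecError(ValueError):
    """Invalid cohort specification."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a two-group synthetic cohort.

    Defaults mirror the target study design: 115 controls (group A) vs 87
    patients (group B), 90 regions, 200-800 voxels per region, and region
    value distributions on a GM-volume-like scale (means near 0.5,
    within-region spread ~0.1).
    """

    n_group_a: int = 115
    n_group_b: int = 87
    n_regions: int = 90
    voxels_per_region: tuple[int, int] = (200, 800)
    mean_level: float = 0.5
    gradient_amplitudes: tuple[float, float] = (0.05, 0.025)
    region_offset_sd: float = 0.03
    sigma_range: tuple[float, float] = (0.08, 0.14)
    subject_jitter_sd: float = 0.035
    background_weight: float = 0.6
    background_sd: float = 0.15
    effect_nodes: tuple[int, ...] = ()
    effect_size: float = 0.0
    effect_scale_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise CohortSpecError("both groups need >= 2 subjects")
        if self.n_regions < 2:
            raise CohortSpecError("need >= 2 regions")
        lo, hi = self.voxels_per_region
        if not (2 <= lo <= hi):
            raise CohortSpecError("voxels_per_region must satisfy 2 <= lo <= hi")
        if self.sigma_range[0] <= 0 or self.background_sd <= 0:
            raise CohortSpecError("distribution scales must be positive")
        if not 0 <= self.background_weight < 1:
            raise CohortSpecError("background_weight must lie in [0, 1)")
        if self.effect_size < 0:
            raise CohortSpecError("effect_size must be >= 0")
        if self.effect_scale_factor <= 0:
            raise CohortSpecError("effect_scale_factor must be > 0")
        nodes = tuple(sorted(set(int(r) for r in self.effect_nodes)))
        if nodes and not (1 <= nodes[0] and nodes[-1] <= self.n_regions):
            raise CohortSpecError(
                f"effect_nodes must lie in 1..{self.n_regions}"
            )
        object.__setattr__(self, "effect_nodes", nodes)


@dataclass
class SubjectRecord:
    """One synthetic participant: group label, regional samples, covariates."""

    subject_id: str
    group_label: str  # "A" (controls) or "B" (patients)
    region_samples: RegionSampleSet
    covariates: dict[str, float] = field(default_factory=dict)


def make_toy_atlas(
    n_regions: int, shape: tuple[int, int, int], seed: int = 0
) -> np.ndarray:
    """Partition a voxel grid into ``n_regions`` contiguous labelled regions.

    Voxels are ordered along a boustrophedon (snake) path through the grid,
    so consecutive voxels are face-adjacent, and the path is cut into
    ``n_regions`` runs of >= 2 voxels; label 0 never occurs (every voxel is
    assigned).  Region sizes vary slightly with the seed.
    """
    if n_regions < 2:
        raise ValueError("need >= 2 regions")
    shape = tuple(int(s) for s in shape)
    total = math.prod(shape)
    if total < 2 * n_regions:
        raise ValueError(
            f"shape {shape} has {total} voxels; need >= {2 * n_regions} "
            f"for {n_regions} regions of >= 2 voxels"
        )
    rng = np.random.default_rng(seed)
    sizes = np.full(n_regions, 2, dtype=int)
    extra = total - 2 * n_regions
    if extra:
        sizes += rng.multinomial(extra, np.full(n_regions, 1 / n_regions))
    # snake ordering: x reversed on odd rows, rows reversed on odd slices
    nx, ny, nz = shape
    order = np.empty(total, dtype=int)
    pos = 0
    row = 0  # global row counter keeps the path face-adjacent across slices
    for z in range(nz):
        ys = range(ny) if z % 2 == 0 else range(ny - 1, -1, -1)
        for y in ys:
            xs = range(nx) if row % 2 == 0 else range(nx - 1, -1, -1)
            row += 1
            for x in xs:
                order[pos] = (x * ny + y) * nz + z
                pos += 1
    labels = np.repeat(np.arange(1, n_regions + 1), sizes)
    flat = np.empty(total, dtype=np.int32)
    flat[order] = labels
    return flat.reshape(shape)


def _region_structure(spec: CohortSpec, rng: np.random.Generator):
    """Cohort-level region parameters: base means and scales."""
    n_pairs = (spec.n_regions + 1) // 2
    x = np.arange(n_pairs) / n_pairs
    a1, a2 = spec.gradient_amplitudes
    base = (
        spec.mean_level
        + a1 * np.sin(2 * np.pi * x)
        + a2 * np.sin(2 * np.pi * 3 * x + 1.0)
    )
    base = np.repeat(base, 2)[: spec.n_regions]
    base = base + rng.normal(0.0, spec.region_offset_sd, spec.n_regions)
    sigmas = rng.uniform(*spec.sigma_range, spec.n_regions)
    return base, sigmas


def _effect_shifts(spec: CohortSpec, sigmas: np.ndarray) -> np.ndarray:
    """Per-region location shift applied to group B (zero off the effect set)."""
    shifts = np.zeros(spec.n_regions)
    for k, rid in enumerate(spec.effect_nodes):
        mult = EFFECT_MULTIPLIERS[k % len(EFFECT_MULTIPLIERS)]
        shifts[rid - 1] = spec.effect_size * sigmas[rid - 1] * mult
    return shifts


def _draw_covariates(rng: np.random.Generator) -> dict[str, float]:
    """Covariates mimicking the study's demographics (age ~23+/-8, M:F ~4:1)."""
    age = float(np.clip(rng.normal(23.0, 8.0), 12.0, 55.0))
    onset = float(np.clip(rng.normal(13.0, 3.0), 5.0, age - 0.5))
    return {
        "age": age,
        "sex": float(rng.random() < 0.8),  # 1 = male
        "education": float(np.clip(rng.normal(12.0, 3.0), 3.0, 19.0)),
        "onset_age": onset,
        "duration": age - onset,
    }


def _subject_samples(
    spec: CohortSpec,
    base: np.ndarray,
    sigmas: np.ndarray,
    shifts: np.ndarray,
    is_patient: bool,
    rng: np.random.Generator,
    voxel_counts: np.ndarray | None,
) -> RegionSampleSet:
    mus = base + rng.normal(0.0, spec.subject_jitter_sd, spec.n_regions)
    lo, hi = spec.voxels_per_region
    samples = {}
    for r in range(spec.n_regions):
        n = int(voxel_counts[r]) if voxel_counts is not None else int(
            rng.integers(lo, hi + 1)
        )
        n_bg = rng.binomial(n, spec.background_weight)
        vals = np.concatenate(
            [
                rng.normal(mus[r], sigmas[r], n - n_bg),
                rng.normal(spec.mean_level, spec.background_sd, n_bg),
            ]
        )
        if is_patient and shifts[r] != 0.0:
            if spec.effect_scale_factor != 1.0:
                vals = vals.mean() + (vals - vals.mean()) * spec.effect_scale_factor
            vals = vals + shifts[r]
        samples[r + 1] = vals
    return RegionSampleSet(samples, atlas_name="synthetic")


def generate_cohort(
    spec: CohortSpec, atlas: np.ndarray | None = None
) -> list[SubjectRecord]:
    """Draw the full two-group cohort described by ``spec``.

    Group A subjects come first (``A001``...), then group B (``B001``...).
    With ``effect_size == 0`` the two groups are exchangeable draws from one
    generative process.  If ``atlas`` is given, each region's sample size
    equals that region's voxel count, so the cohort can be written as
    volumes on that atlas.
    """
    root = np.random.SeedSequence(spec.seed)
    struct_ss, cov_ss, subj_ss = root.spawn(3)
    base, sigmas = _region_structure(spec, np.random.default_rng(struct_ss))
    shifts = _effect_shifts(spec, sigmas)

    voxel_counts = None
    if atlas is not None:
        atlas = np.asarray(atlas)
        counts = np.bincount(atlas.ravel()[atlas.ravel() > 0])
        if int(atlas.max()) != spec.n_regions:
            raise CohortSpecError(
                f"atlas has {int(atlas.max())} regions, spec wants {spec.n_regions}"
            )
        voxel_counts = counts[1:]

    n_total = spec.n_group_a + spec.n_group_b
    cov_rng = np.random.default_rng(cov_ss)
    subject_seeds = subj_ss.spawn(n_total)
    cohort = []
    for idx in range(n_total):
        is_patient = idx >= spec.n_group_a
        group = "B" if is_patient else "A"
        number = idx - spec.n_group_a + 1 if is_patient else idx + 1
        rng = np.random.default_rng(subject_seeds[idx])
        cohort.append(
            SubjectRecord(
                subject_id=f"{group}{number:03d}",
                group_label=group,
                region_samples=_subject_samples(
                    spec, base, sigmas, shifts, is_patient, rng, voxel_counts
                ),
                covariates=_draw_covariates(cov_rng),
            )
        )
    return cohort


def toy_graph(kind: str, n: int) -> np.ndarray:
    """Small named weighted adjacency matrices for metric oracles.

    ``complete``, ``star`` (node 0 is the centre), ``ring``, ``path`` are
    unit-weight topologies; ``weighted_fixture`` is a deterministic complete
    graph with distinct weights ``1 / (1 + |i - j|)``.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    a = np.zeros((n, n))
    if kind == "complete":
        a = 1.0 - np.eye(n)
    elif kind == "star":
        a[0, 1:] = a[1:, 0] = 1.0
    elif kind == "ring":
        for i in range(n):
            a[i, (i + 1) % n] = a[(i + 1) % n, i] = 1.0
    elif kind == "path":
        for i in range(n - 1):
            a[i, i + 1] = a[i + 1, i] = 1.0
    elif kind == "weighted_fixture":
        i, j = np.indices((n, n))
        a = 1.0 / (1.0 + np.abs(i - j))
        np.fill_diagonal(a, 0.0)
    else:
        raise ValueError(f"unknown toy graph kind {kind!r}")
    return a


# ---------------------------------------------------------------------------
# cohort serialisation (tab-separated text)

def write_cohort_tsv(cohort: list[SubjectRecord], out_dir) -> None:
    """Write one ``<subject_id>.tsv`` (region_id, voxel_value) per subject
    plus a ``manifest.tsv`` with group labels and covariates."""
    import pandas as pd
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for subj in cohort:
        rec = {"subject_id": subj.subject_id, "group": subj.group_label}
        rec.update(subj.covariates)
        rows.append(rec)
        parts = [
            pd.DataFrame(
                {"region_id": rid, "voxel_value": vals}
            )
            for rid, vals in subj.region_samples.samples.items()
        ]
        pd.concat(parts, ignore_index=True).to_csv(
            out / f"{subj.subject_id}.tsv", sep="\t", index=False,
            float_format="%.10g",
        )
    pd.DataFrame(rows).to_csv(
        out / "manifest.tsv", sep="\t", index=False, float_format="%.10g"
    )


def read_cohort_tsv(in_dir) -> list[SubjectRecord]:
    """Read a cohort written by :func:`write_cohort_tsv`."""
    import pandas as pd
    from pathlib import Path

    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.tsv", sep="\t")
    cohort = []
    for _, row in manifest.iterrows():
        df = pd.read_csv(in_dir / f"{row.subject_id}.tsv", sep="\t")
        samples = {
            int(rid): grp["voxel_value"].to_numpy()
            for rid, grp in df.groupby("region_id")
        }
        covs = {
            k: float(row[k])
            for k in manifest.columns
            if k not in ("subject_id", "group")
        }
        cohort.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                group_label=str(row.group),
                region_samples=RegionSampleSet(samples, atlas_name="synthetic"),
                covariates=covs,
            )
        )
    return cohort


def cohort_to_volumes(
    cohort: list[SubjectRecord], atlas: np.ndarray
) -> list[np.ndarray]:
    """Render subjects as GM maps on ``atlas`` (sample sizes must match)."""
    maps = []
    for subj in cohort:
        gm = np.zeros(atlas.shape)
        for rid, vals in subj.region_samples.samples.items():
            mask = atlas == rid
            if mask.sum() != vals.size:
                raise CohortSpecError(
                    f"{subj.subject_id}: region {rid} sample size {vals.size} "
                    f"!= atlas voxel count {int(mask.sum())}"
                )
            gm[mask] = vals
        maps.append(gm)
    return maps
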