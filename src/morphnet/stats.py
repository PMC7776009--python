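"""Group-level statistics: permutation tests, BH-FDR, outliers, correlations.

Between-group differences in AUC metrics are assessed by label-permutation
tests (two-tailed by default, with the +1-corrected p-value estimator), nodal
measures are corrected by the Benjamini-Hochberg step-up FDR rule, clinical
associations use partial correlation with least-squares residualisation, and
extreme values are screened by the Q1 - 3*IQR / Q3 + 3*IQR fence rule with
linear-interpolation quantiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DEFAULT_N_PERM = 10_000

#: IQR fence multiplier of the outlier screen.
IQR_FENCE = 3.0


class StatsError(ValueError):
    pass


class CollinearityError(StatsError):
    pass


class DegeneracyError(StatsError):
    pass


@dataclass
class GroupComparison:
    """Observed group-mean difference and its permutation p-value."""

    observed_diff: float
    p_value: float
    n_perm: int
    metric: str = ""
    tail: str = "two"


@dataclass
class CorrelationResult:
    """Partial correlation coefficient with its two-tailed p-value."""

    r: float
    p_value: float
    n_used: int
    covariates: tuple[str, ...] = ()


def _permutation_diffs(
    pooled: np.ndarray, n_a: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean differences over random reallocations of the pooled values."""
    n = pooled.size
    total = pooled.sum()
    # each row of the argsorted random matrix is a uniform permutation
    idx = rng.random((n_perm, n)).argsort(axis=1)[:, :n_a]
    sums_a = pooled[idx].sum(axis=1)
    return sums_a / n_a - (total - sums_a) / (n - n_a)


def permutation_test(
    values_a,
    values_b,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    tail: str = "two",
    metric: str = "",
) -> GroupComparison:
    """Two-sample permutation test on group means.

    ``p = (1 + #{perm : |diff_perm| >= |diff_obs|}) / (n_perm + 1)`` for the
    default two-tailed alternative; ``tail`` may also be ``greater`` or
    ``less`` (one-tailed on the signed difference a - b).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("both groups need >= 2 values")
    observed = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("pooled values are constant; permutation test degenerate")
        return GroupComparison(observed, 1.0, n_perm, metric, tail)
    diffs = _permutation_diffs(pooled, a.size, n_perm, np.random.default_rng(seed))
    if tail == "two":
        hits = np.count_nonzero(np.abs(diffs) >= abs(observed))
    elif tail == "greater":
        hits = np.count_nonzero(diffs >= observed)
    elif tail == "less":
        hits = np.count_nonzero(diffs <= observed)
    else:
        raise StatsError(f"unknown tail {tail!r}")
    p = (1 + hits) / (n_perm + 1)
    return GroupComparison(observed, float(p), n_perm, metric, tail)


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up rule: (reject flags, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise StatsError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise StatsError("q must lie in (0, 1)")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def iqr_outliers(values) -> np.ndarray:
    """Keep flags under the Q1 - 3*IQR / Q3 + 3*IQR fence rule.

    Quantiles use linear interpolation; a value is dropped only when it lies
    strictly outside a fence, so constant data are never flagged.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise StatsError(f"need >= 4 values for the IQR rule, got {v.size}")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v >= q1 - IQR_FENCE * iqr) & (v <= q3 + IQR_FENCE * iqr)


def partial_correlation(x, y, covariates=None, names: tuple[str, ...] = ()):
    """Partial Pearson correlation of ``x`` and ``y`` given ``covariates``.

    Both variables are residualised on ``[1, covariates]`` by least squares;
    the two-tailed p-value comes from ``t = r * sqrt((n - 2 - k)/(1 - r^2))``.
    With no covariates this reduces to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise StatsError("x and y must have equal length")
    if covariates is None:
        z = np.empty((n, 0))
    else:
        z = np.asarray(covariates, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
        if z.shape[0] != n:
            raise StatsError("covariate rows must match x length")
    k = z.shape[1]
    if n < k + 4:
        raise StatsError(f"need >= k + 4 = {k + 4} observations, got {n}")
    design = np.column_stack([np.ones(n), z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("covariate matrix is rank-deficient")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise DegeneracyError("zero residual variance")
    r = float(np.corrcoef(rx, ry)[0, 1])
    dof = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1 - r**2))
        p = float(2 * sps.t.sf(abs(t), dof))
    return CorrelationResult(r=r, p_value=p, n_used=n, covariates=tuple(names))


def clinical_correlation(
    metric_values,
    clinical_values,
    covariates,
    covariate_names: tuple[str, ...] = (),
    screen_outliers: bool = True,
) -> CorrelationResult:
    """Partial correlation preceded by the joint IQR outlier screen.

    The fence rule is applied to the metric AUC and the clinical variable
    jointly; a subject failing either screen is removed before the
    correlation, mirroring the study's exclusion procedure.
    """
    x = np.asarray(metric_values, dtype=float)
    y = np.asarray(clinical_values, dtype=float)
    z = np.asarray(covariates, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    keep = np.ones(x.size, dtype=bool)
    if screen_outliers:
        keep = iqr_outliers(x) & iqr_outliers(y)
    return partial_correlation(
        x[keep], y[keep], z[keep], names=covariate_names
    )


# ---------------------------------------------------------------------------
# tidy cohort-level comparison tables

def compare_auc_tables(
    global_auc: pd.DataFrame,
    nodal_auc: pd.DataFrame,
    groups: pd.Series,
    n_perm: int = DEFAULT_N_PERM,
    q: float = 0.05,
    seed: int = 0,
    tail: str = "two",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Permutation comparisons of every AUC metric, nodal ones BH-corrected.

    ``global_auc``: rows = subjects, columns = global metrics.
    ``nodal_auc``: tidy frame (subject_id, metric, node, auc).
    ``groups``: subject_id -> "A"/"B".  Returns (global table, nodal table);
    the nodal table carries per-measure FDR flags.
    """
    seed_seq = np.random.SeedSequence(seed)
    g = groups.reindex(global_auc.index)
    mask_a = (g == "A").to_numpy()
    mask_b = (g == "B").to_numpy()

    rows = []
    child = seed_seq.spawn(len(global_auc.columns) + len(NODAL_ORDER))
    for i, metric in enumerate(global_auc.columns):
        vals = global_auc[metric].to_numpy()
        res = permutation_test(
            vals[mask_a], vals[mask_b], n_perm=n_perm,
            seed=int(child[i].generate_state(1)[0] % 2**31),
            tail=tail, metric=metric,
        )
        rows.append(
            {"metric": metric, "node": "global",
             "observed_diff": res.observed_diff, "p": res.p_value}
        )
    global_table = pd.DataFrame(rows)

    nodal_rows = []
    for m_idx, metric in enumerate(NODAL_ORDER):
        sub = nodal_auc[nodal_auc["metric"] == metric]
        if sub.empty:
            continue
        wide = sub.pivot(index="subject_id", columns="node", values="auc")
        wide = wide.reindex(global_auc.index)
        m_seed = np.random.SeedSequence(
            [seed, 1000 + m_idx]
        )
        node_seeds = m_seed.spawn(wide.shape[1])
        ps = []
        for n_idx, node in enumerate(wide.columns):
            vals = wide[node].to_numpy()
            res = permutation_test(
                vals[mask_a], vals[mask_b], n_perm=n_perm,
                seed=int(node_seeds[n_idx].generate_state(1)[0] % 2**31),
                tail=tail, metric=f"{metric}:{node}",
            )
            ps.append(res.p_value)
            nodal_rows.append(
                {"metric": metric, "node": int(node),
                 "observed_diff": res.observed_diff, "p": res.p_value}
            )
        reject, p_adj = bh_fdr(np.array(ps), q=q)
        for offset, (rej, pa) in enumerate(zip(reject, p_adj)):
            nodal_rows[-len(ps) + offset]["p_fdr"] = pa
            nodal_rows[-len(ps) + offset]["fdr_reject"] = bool(rej)
    nodal_table = pd.DataFrame(nodal_rows)
    return global_table, nodal_table


NODAL_ORDER = ("degree", "efficiency", "betweenness")


def significant_nodes(nodal_table: pd.DataFrame) -> list[int]:
    """Nodes FDR-significant in at least one nodal centrality measure."""
    if nodal_table.empty or "fdr_reject" not in nodal_table:
        return []
    sig = nodal_table[nodal_table["fdr_reject"]]
    return sorted(set(int(n) for n in sig["node"]))
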