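"""Single-subject classification from morphological network matrices.

A linear support-vector machine separates patients from controls using the
upper-triangle KLS entries of each subject's connectome (4005 features for
90 regions).  Hyperparameter C is selected by stratified nested
cross-validation (grid 1e-3..1e4 in decades, inner selection by balanced
accuracy), features are z-standardised with statistics fitted on the
training folds only, classes are inverse-frequency weighted, and reported
balanced accuracy / sensitivity / specificity are means over the outer
folds.  Statistical significance comes from label-permutation reruns of the
whole nested procedure, and region importance is ranked by summing each
region's incident mean-|weight| edge scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

DEFAULT_C_GRID = tuple(10.0**k for k in range(-3, 5))

#: The positive class (patients) for sensitivity/specificity.
POSITIVE_LABEL = 1


class ClassifyError(ValueError):
    pass


class SymmetryError(ClassifyError):
    pass


class StratificationError(ClassifyError):
    pass


@dataclass
class FeatureVector:
    subject_id: str
    values: np.ndarray
    pairs: list[tuple[int, int]]


@dataclass
class FoldResult:
    fold: int
    test_index: np.ndarray
    predictions: np.ndarray
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    chosen_c: float
    weights: np.ndarray


@dataclass
class CVResult:
    folds: list[FoldResult]
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    permutation_p: float | None = None

    @property
    def fold_weights(self) -> np.ndarray:
        return np.vstack([f.weights for f in self.folds])

    @property
    def chosen_c(self) -> list[float]:
        return [f.chosen_c for f in self.folds]


def pair_index_mapping(n_regions: int) -> list[tuple[int, int]]:
    """Row-major upper-triangle feature index -> (region i, region j), 1-based."""
    iu, ju = np.triu_indices(n_regions, 1)
    return [(int(i) + 1, int(j) + 1) for i, j in zip(iu, ju)]


def vectorize_connectome(matrix, subject_id: str = "") -> FeatureVector:
    """Upper-triangle (diagonal excluded) feature vector of a connectome."""
    values = np.asarray(getattr(matrix, "values", matrix), dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ClassifyError("connectome must be square")
    if not np.allclose(values, values.T, atol=1e-9):
        raise SymmetryError("connectome asymmetric beyond 1e-9")
    r = values.shape[0]
    iu, ju = np.triu_indices(r, 1)
    sid = subject_id or getattr(matrix, "subject_id", "")
    return FeatureVector(
        subject_id=sid, values=values[iu, ju], pairs=pair_index_mapping(r)
    )


def reconstruct_connectome(fv: FeatureVector) -> np.ndarray:
    """Inverse of :func:`vectorize_connectome` (unit diagonal)."""
    r = int((1 + np.sqrt(1 + 8 * fv.values.size)) / 2)
    m = np.eye(r)
    iu, ju = np.triu_indices(r, 1)
    m[iu, ju] = m[ju, iu] = fv.values
    return m


def stratified_folds(labels, k: int, seed: int = 0) -> np.ndarray:
    """Fold id per subject under stratified k-fold with seeded shuffling."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise StratificationError(
            f"smallest class has {counts.min()} members; cannot make {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.full(labels.size, -1, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(labels.size), labels)):
        assignment[test_idx] = fold
    return assignment


def _binary_labels(labels) -> np.ndarray:
    """Map labels to {0, 1} with 'B'/1 as the positive (patient) class."""
    labels = np.asarray(labels)
    if labels.dtype.kind in "iub":
        return labels.astype(int)
    return (labels == "B").astype(int)


def _fold_metrics(y_true, y_pred) -> tuple[float, float, float]:
    pos = y_true == POSITIVE_LABEL
    sens = float((y_pred[pos] == POSITIVE_LABEL).mean())
    spec = float((y_pred[~pos] != POSITIVE_LABEL).mean())
    return (sens + spec) / 2, sens, spec


def _make_pipeline(c: float) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="linear", C=c, class_weight="balanced")),
        ]
    )


def nested_cv_svm(
    features,
    labels,
    k_outer: int = 10,
    k_inner: int = 10,
    c_grid=DEFAULT_C_GRID,
    seed: int = 0,
) -> CVResult:
    """Nested stratified cross-validation of the linear SVM.

    The inner ``k_inner``-fold grid search selects C by balanced accuracy;
    the winning model is refit on the full outer-training set (scaler
    statistics included) and evaluated on the held-out fold, so test data
    never influence training.
    """
    x = np.asarray(features, dtype=float)
    y = _binary_labels(labels)
    if not len(c_grid):
        raise ClassifyError("C grid is empty")
    ss = np.random.SeedSequence(seed)
    outer_seed, inner_seed = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)
    )
    assignment = stratified_folds(y, k_outer, seed=outer_seed)
    folds = []
    for fold in range(k_outer):
        test_mask = assignment == fold
        x_tr, y_tr = x[~test_mask], y[~test_mask]
        if np.unique(y_tr).size < 2 or np.unique(y[test_mask]).size < 2:
            raise StratificationError(f"fold {fold} is single-class")
        inner_cv = StratifiedKFold(
            n_splits=k_inner, shuffle=True, random_state=inner_seed
        )
        search = GridSearchCV(
            _make_pipeline(1.0),
            param_grid={"svm__C": list(c_grid)},
            scoring="balanced_accuracy",
            cv=inner_cv,
        )
        search.fit(x_tr, y_tr)
        best = search.best_estimator_
        y_pred = best.predict(x[test_mask])
        bal, sens, spec = _fold_metrics(y[test_mask], y_pred)
        folds.append(
            FoldResult(
                fold=fold,
                test_index=np.nonzero(test_mask)[0],
                predictions=y_pred,
                balanced_accuracy=bal,
                sensitivity=sens,
                specificity=spec,
                chosen_c=float(search.best_params_["svm__C"]),
                weights=best.named_steps["svm"].coef_.ravel().copy(),
            )
        )
    return CVResult(
        folds=folds,
        balanced_accuracy=float(np.mean([f.balanced_accuracy for f in folds])),
        sensitivity=float(np.mean([f.sensitivity for f in folds])),
        specificity=float(np.mean([f.specificity for f in folds])),
    )


def label_permutation_significance(
    features,
    labels,
    n_perm: int = 1000,
    seed: int = 0,
    observed: CVResult | None = None,
    **cv_kwargs,
) -> tuple[float, CVResult]:
    """p-value of the observed balanced accuracy under label permutation.

    The whole nested CV is rerun on each permuted label vector;
    ``p = (1 + #{perm >= observed}) / (n_perm + 1)``.
    """
    y = _binary_labels(labels)
    cv_seed = cv_kwargs.pop("cv_seed", seed)
    if observed is None:
        observed = nested_cv_svm(features, y, seed=cv_seed, **cv_kwargs)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        res = nested_cv_svm(features, y_perm, seed=cv_seed, **cv_kwargs)
        if res.balanced_accuracy >= observed.balanced_accuracy:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    observed.permutation_p = float(p)
    return float(p), observed


def region_weight_ranking(
    fold_weights,
    pairs,
    top_n: int = 20,
    aggregate: str = "sum",
) -> pd.DataFrame:
    """Rank regions by their incident mean-|weight| edge scores.

    ``fold_weights``: (n_folds, n_features) per-fold SVM weight vectors;
    ``pairs``: feature index -> (region i, region j) mapping.  Edge score is
    the mean absolute weight across folds; a region's score sums (or, with
    ``aggregate='mean'``, averages) the scores of its incident edges.
    """
    w = np.atleast_2d(np.asarray(fold_weights, dtype=float))
    if w.shape[1] != len(pairs):
        raise ClassifyError(
            f"{w.shape[1]} weights but {len(pairs)} feature pairs"
        )
    edge_score = np.abs(w).mean(axis=0)
    regions = sorted({r for pair in pairs for r in pair})
    score = {r: 0.0 for r in regions}
    count = {r: 0 for r in regions}
    for (i, j), s in zip(pairs, edge_score):
        score[i] += s
        score[j] += s
        count[i] += 1
        count[j] += 1
    if aggregate == "mean":
        score = {r: score[r] / max(count[r], 1) for r in regions}
    elif aggregate != "sum":
        raise ClassifyError(f"unknown aggregate {aggregate!r}")
    if np.allclose(edge_score, 0):
        warnings.warn("all SVM weights are zero; ranking is input order")
    table = pd.DataFrame(
        {"region": regions, "score": [score[r] for r in regions]}
    )
    table = table.sort_values(
        ["score", "region"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table.head(top_n) if top_n else table
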