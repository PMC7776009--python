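"""Umbrella pipeline: simulate -> construct -> metrics -> compare -> NBS ->
classify -> correlate, with every stage seeded, logged and written to one
run directory alongside a machine-readable run manifest."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    label_permutation_significance,
    nested_cv_svm,
    region_weight_ranking,
    vectorize_connectome,
)
from .config import PipelineConfig
from .io import write_matrix, write_table
from .metrics import GLOBAL_METRICS, NODAL_METRICS, SparsityGrid, metric_auc_curve
from .nbs import nbs_test
from .stats import clinical_correlation, compare_auc_tables, significant_nodes
from .synthetic import CohortSpec, generate_cohort, write_cohort_tsv

logger = logging.getLogger("morphnet")


def _auc_frames(records_by_subject: dict[str, dict]) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Tidy per-threshold curves plus global/nodal AUC frames."""
    curve_rows, nodal_rows = [], []
    global_auc = {}
    for sid, records in records_by_subject.items():
        global_auc[sid] = {
            m: records[m].auc for m in GLOBAL_METRICS if m in records
        }
        for m in GLOBAL_METRICS:
            rec = records[m]
            for s, v in zip(rec.thresholds, rec.values):
                curve_rows.append(
                    {"subject_id": sid, "metric": m, "node": "global",
                     "threshold": s, "value": v}
                )
        for m in NODAL_METRICS:
            rec = records[m]
            for node in range(rec.values.shape[1]):
                nodal_rows.append(
                    {"subject_id": sid, "metric": m, "node": node + 1,
                     "auc": rec.auc[node]}
                )
    global_df = pd.DataFrame(global_auc).T
    global_df.index.name = "subject_id"
    return pd.DataFrame(curve_rows), global_df, pd.DataFrame(nodal_rows)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full analysis on a synthetic cohort.

    Returns a result bundle (cohort, matrices, AUC tables, comparison
    tables, NBS result, CV result) and writes every artifact under
    ``out_dir``.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- simulate ---------------------------------------------------------
    spec = CohortSpec(**{**config.cohort, "seed": config.stage_seed("simulate")})
    logger.info("simulate: %d + %d subjects, %d regions",
                spec.n_group_a, spec.n_group_b, spec.n_regions)
    cohort = generate_cohort(spec)
    cohort_dir = out / "cohort"
    write_cohort_tsv(cohort, cohort_dir)
    manifest = pd.DataFrame(
        [{"subject_id": s.subject_id, "group": s.group_label, **s.covariates}
         for s in cohort]
    )

    # --- construct --------------------------------------------------------
    from .network import build_network

    matrices_dir = out / "matrices"
    matrices_dir.mkdir(exist_ok=True)
    matrices = []
    for subj in cohort:
        m = build_network(
            subj.region_samples, grid_points=config.grid_points,
            subject_id=subj.subject_id,
        )
        matrices.append(m)
        write_matrix(m, matrices_dir / f"{subj.subject_id}.tsv")
    logger.info("construct: %d matrices of %d regions",
                len(matrices), matrices[0].n_regions)

    # --- metrics ----------------------------------------------------------
    grid = SparsityGrid.from_range(config.s_min, config.s_max, config.s_step)
    metrics_seed = np.random.SeedSequence(config.stage_seed("metrics"))
    subject_seeds = metrics_seed.spawn(len(matrices))
    records_by_subject = {}
    for m, sseq in zip(matrices, subject_seeds):
        records_by_subject[m.subject_id] = metric_auc_curve(
            m, grid, n_rand=config.n_rand,
            seed=int(sseq.generate_state(1)[0] % 2**31),
            degree_mode=config.degree_mode,
        )
    curves, global_auc, nodal_auc = _auc_frames(records_by_subject)
    write_table(curves, out / "metric_curves.tsv")
    write_table(global_auc.reset_index(), out / "global_auc.tsv")
    write_table(nodal_auc, out / "nodal_auc.tsv")

    # --- compare ----------------------------------------------------------
    groups = manifest.set_index("subject_id")["group"]
    global_cmp, nodal_cmp = compare_auc_tables(
        global_auc, nodal_auc, groups,
        n_perm=config.group_n_perm, q=config.q,
        seed=config.stage_seed("compare"), tail=config.tail,
    )
    write_table(global_cmp, out / "global_comparison.tsv")
    write_table(nodal_cmp, out / "nodal_comparison.tsv")
    nodes = significant_nodes(nodal_cmp)
    logger.info("compare: %d FDR-significant nodes", len(nodes))

    # --- nbs --------------------------------------------------------------
    nbs_result = None
    by_group = {"A": [], "B": []}
    for m, subj in zip(matrices, cohort):
        by_group[subj.group_label].append(m)
    if len(nodes) >= 2:
        nbs_result = nbs_test(
            by_group["A"], by_group["B"], nodes,
            t_threshold=config.t_threshold, n_perm=config.nbs_n_perm,
            seed=config.stage_seed("nbs"), tail=config.nbs_tail,
        )
        rows = [
            {"component_id": k + 1, "n_nodes": c.n_nodes,
             "n_edges": c.n_edges, "p": c.p_value,
             "edges": ";".join(f"{i}-{j}" for i, j in c.edges)}
            for k, c in enumerate(nbs_result.components)
        ]
        write_table(pd.DataFrame(
            rows, columns=["component_id", "n_nodes", "n_edges", "p", "edges"]
        ), out / "nbs_components.tsv")
    else:
        logger.info("nbs: skipped (fewer than 2 significant nodes)")
        write_table(pd.DataFrame(
            columns=["component_id", "n_nodes", "n_edges", "p", "edges"]
        ), out / "nbs_components.tsv")

    # --- classify ---------------------------------------------------------
    features = np.vstack([vectorize_connectome(m).values for m in matrices])
    pairs = vectorize_connectome(matrices[0]).pairs
    labels = manifest["group"].to_numpy()
    cv = nested_cv_svm(
        features, labels, k_outer=config.k_outer, k_inner=config.k_inner,
        c_grid=config.c_grid, seed=config.stage_seed("classify"),
    )
    if config.run_svm_permutation and config.svm_n_perm > 0:
        label_permutation_significance(
            features, labels, n_perm=config.svm_n_perm,
            seed=config.stage_seed("classify") + 1, observed=cv,
            k_outer=config.k_outer, k_inner=config.k_inner,
            c_grid=config.c_grid, cv_seed=config.stage_seed("classify"),
        )
    write_table(pd.DataFrame([{
        "balanced_accuracy": cv.balanced_accuracy,
        "sensitivity": cv.sensitivity,
        "specificity": cv.specificity,
        "permutation_p": cv.permutation_p,
    }]), out / "classification_summary.tsv")
    pred_rows = []
    for f in cv.folds:
        for idx, pred in zip(f.test_index, f.predictions):
            pred_rows.append({
                "subject_id": manifest["subject_id"].iloc[idx],
                "fold": f.fold, "true": int(labels[idx] == "B"),
                "predicted": int(pred), "chosen_c": f.chosen_c,
            })
    write_table(pd.DataFrame(pred_rows), out / "classification_folds.tsv")
    ranking = region_weight_ranking(cv.fold_weights, pairs, top_n=config.top_regions)
    write_table(ranking, out / "region_ranking.tsv")
    logger.info("classify: balanced accuracy %.3f", cv.balanced_accuracy)

    # --- correlate --------------------------------------------------------
    corr_rows = []
    sig_global = global_cmp[global_cmp["p"] < config.q]["metric"].tolist()
    patients = manifest[manifest["group"] == "B"]
    cov = patients[list(config.correlation_covariates)].to_numpy()
    for metric in sig_global:
        x = global_auc.loc[patients["subject_id"], metric].to_numpy()
        for clin in config.clinical_variables:
            y = patients[clin].to_numpy()
            try:
                res = clinical_correlation(
                    x, y, cov, covariate_names=config.correlation_covariates
                )
            except ValueError as exc:
                logger.warning("correlate %s~%s failed: %s", metric, clin, exc)
                continue
            corr_rows.append({
                "metric": metric, "clinical": clin, "r": res.r,
                "p": res.p_value, "n_used": res.n_used,
            })
    write_table(pd.DataFrame(
        corr_rows, columns=["metric", "clinical", "r", "p", "n_used"]
    ), out / "clinical_correlations.tsv")

    # --- run manifest -----------------------------------------------------
    run_manifest = {
        "package": "morphnet",
        "version": __version__,
        "config": config.to_dict(),
        "stage_seeds": {s: config.stage_seed(s) for s in
                        ("simulate", "construct", "metrics", "compare",
                         "nbs", "classify", "correlate")},
        "n_subjects": len(cohort),
        "n_regions": spec.n_regions,
    }
    (out / "run_manifest.json").write_text(
        json.dumps(run_manifest, indent=2, sort_keys=True)
    )
    return {
        "cohort": cohort,
        "manifest": manifest,
        "matrices": matrices,
        "global_auc": global_auc,
        "nodal_auc": nodal_auc,
        "global_comparison": global_cmp,
        "nodal_comparison": nodal_cmp,
        "significant_nodes": nodes,
        "nbs": nbs_result,
        "cv": cv,
        "region_ranking": ranking,
        "clinical_correlations": pd.DataFrame(corr_rows),
        "run_manifest": run_manifest,
    }
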