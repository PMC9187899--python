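"""Metrics, ROC/AUC, baseline comparators, and the end-to-end pipeline.

``run_pipeline`` wires the whole analysis together: simulate (or load) a
cohort, exclude incomplete records, split 7:3, fit the min-max normalizer
on the training split, up-sample the minority death class, discover and
profile phenotype clusters, score severity, compare per-cluster survival,
train the DCQMFF and CNN classifiers plus standard baselines, and emit a
JSON report.  Death is the positive class throughout.  A second,
independently seeded synthetic cohort plays the external-validation role.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import Lasso, LogisticRegression

from . import clinstats, dcqmff, phenotyping, preprocess, severity_scores
from .cnn_model import CNNConfig, fit_cnn, predict_cnn
from .features import FEATURES_11, FEATURES_35
from .synthetic_cohort import (
    CohortConfig,
    default_phenotype_specs,
    read_cohort,
    sample_cohort,
    write_cohort,
)

logger = logging.getLogger("sepsis_phenoscope.pipeline")


class UndefinedMetricError(ValueError):
    """A metric (AUC) is undefined on one-class input."""


def roc_points(scores, labels) -> np.ndarray:
    """(FPR, TPR) points swept over the unique score thresholds.

    Scores are "higher = more positive"; tied scores collapse into one
    point.  Returns an (m, 2) array from (0, 0) to (1, 1), monotone in
    both coordinates.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal lengths")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # keep only the last index of each tied-score run
    last = np.r_[s[1:] != s[:-1], True]
    pts = np.column_stack([fp[last] / n_neg, tp[last] / n_pos])
    return np.vstack([[0.0, 0.0], pts])


def auc(points: np.ndarray) -> float:
    """Trapezoid area under an ROC point list."""
    pts = np.asarray(points, dtype=float)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def roc_auc(scores, labels) -> float:
    return auc(roc_points(scores, labels))


def classification_metrics(pred_labels, labels) -> dict:
    """Accuracy, precision, recall, F1 with death (1) as positive class.

    Zero-denominator metrics are reported as 0.0 and flagged.
    """
    pred = np.asarray(pred_labels, dtype=int)
    true = np.asarray(labels, dtype=int)
    if pred.shape != true.shape:
        raise ValueError("length mismatch between predictions and labels")
    tp = int(((pred == 1) & (true == 1)).sum())
    fp = int(((pred == 1) & (true == 0)).sum())
    fn = int(((pred == 0) & (true == 1)).sum())
    tn = int(((pred == 0) & (true == 0)).sum())
    flags = []
    if tp + fp == 0:
        precision = 0.0
        flags.append("no_predicted_positives")
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall = 0.0
        flags.append("no_true_positives")
    else:
        recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return {
        "accuracy": (tp + tn) / pred.size,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "confusion": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
        "flags": flags,
    }


def evaluate_scores(scores, labels) -> dict:
    """Metrics at threshold 0.5 plus ROC AUC for probability scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    m = classification_metrics((scores > 0.5).astype(int), labels)
    m["auc"] = roc_auc(scores, labels)
    return m


def sofa_as_predictor(sofa, labels) -> dict:
    """The integer SOFA score used directly as a mortality classifier.

    ROC over score thresholds, plus metrics at the high-mortality flag
    (SOFA > 12).
    """
    sofa = np.asarray(sofa, dtype=float)
    if np.ptp(sofa) == 0:
        raise UndefinedMetricError("SOFA score is constant; ROC undefined")
    m = classification_metrics((sofa > 12).astype(int), labels)
    m["auc"] = roc_auc(sofa, labels)
    return m


def fit_baselines(
    x_train: np.ndarray,
    y_train: np.ndarray,
    eval_sets: dict[str, tuple[np.ndarray, np.ndarray]],
    seed: int = 0,
) -> dict:
    """Logistic regression, random forest, and lasso-regression baselines.

    Default hyperparameters, seeded.  The lasso fits a penalized linear
    regression to the 0/1 death labels and thresholds its continuous
    prediction at 0.5.
    """
    out: dict[str, dict] = {}
    models = {
        "logistic_regression": LogisticRegression(max_iter=2000, random_state=seed),
        "random_forest": RandomForestClassifier(random_state=seed),
        "lasso_regression": Lasso(alpha=0.001, random_state=seed),
    }
    for name, model in models.items():
        try:
            model.fit(x_train, y_train)
        except Exception as err:  # pragma: no cover - propagate with context
            raise RuntimeError(f"baseline {name!r} failed to fit") from err
        out[name] = {}
        for split, (x, y) in eval_sets.items():
            if isinstance(model, Lasso):
                scores = model.predict(x)
            else:
                scores = model.predict_proba(x)[:, 1]
            out[name][split] = evaluate_scores(scores, y)
    return out


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    seed: int = 0
    n_patients: int = 2902
    cohort_csv: str | None = None  # load instead of simulate
    outdir: str | Path = "pipeline_out"
    split_ratio: float = 0.7
    k_grid: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    k_override: int | None = None
    dcqmff_epochs: int = 300
    cnn_epochs: int = 60
    write_artifacts: bool = True


def _df_records(df: pd.DataFrame) -> list[dict]:
    return json.loads(df.to_json(orient="records"))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report dict (also written to
    ``<outdir>/report.json`` with artifacts when ``write_artifacts``)."""
    outdir = Path(config.outdir)
    if config.write_artifacts:
        outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "positive_class": "death (event within 28 days)",
    }

    # --- cohort -----------------------------------------------------------
    logger.info("stage: cohort")
    if config.cohort_csv is not None:
        cohort = read_cohort(config.cohort_csv)
        cohort_cfg = None
    else:
        cohort_cfg = CohortConfig(n_patients=config.n_patients, seed=config.seed)
        cohort = sample_cohort(cohort_cfg)
    complete, n_excluded = preprocess.exclude_incomplete(cohort)
    report["cohort"] = {
        "n_total": int(len(cohort)),
        "n_excluded_incomplete": n_excluded,
        "n_complete": int(len(complete)),
    }

    # --- split + normalize ------------------------------------------------
    logger.info("stage: split/normalize")
    split = preprocess.split_cohort(complete, ratio=config.split_ratio, seed=config.seed)
    norm = preprocess.fit_normalizer(split.train)
    train_n = preprocess.apply_normalizer(norm, split.train)
    test_n = preprocess.apply_normalizer(norm, split.test)
    report["split"] = {"n_train": len(split.train), "n_test": len(split.test)}

    # --- up-sample the minority death class (training only) ---------------
    logger.info("stage: upsample")
    ups_cfg = preprocess.UpsampleConfig(seed=config.seed)
    train_bal = preprocess.upsample_minority(train_n, ups_cfg)
    report["upsample"] = {
        "n_before": len(train_n),
        "n_after": len(train_bal),
        "deaths_after": int((1 - train_bal["survived_28d"]).sum()),
    }

    # --- phenotyping ------------------------------------------------------
    logger.info("stage: phenotyping")
    ksel = phenotyping.select_k(train_n, k_grid=config.k_grid, seed=config.seed)
    k_used = config.k_override or ksel.k_chosen
    model = phenotyping.fit_clusters(train_n, k_used, seed=config.seed)
    profile = phenotyping.profile_clusters(train_n, model, raw_table=split.train)
    emb = phenotyping.project_pca3(train_n)
    sizes = np.bincount(model.assignments, minlength=k_used)
    report["phenotyping"] = {
        "k_selection": {
            "k_grid": ksel.k_grid,
            "inertia": ksel.inertia,
            "silhouette": ksel.silhouette,
            "k_elbow": ksel.k_elbow,
            "k_silhouette": ksel.k_silhouette,
            "k_chosen": ksel.k_chosen,
        },
        "k_used": int(k_used),
        "cluster_sizes": sizes.tolist(),
        "top10_features": profile.top_k,
        "heterogeneity": _df_records(profile.table),
        "pca_explained_variance": emb.explained_variance_fractions.tolist(),
    }

    # --- severity + survival per cluster ----------------------------------
    logger.info("stage: severity/survival")
    scored = severity_scores.score_cohort(split.train)
    lab = model.assignments
    per_cluster = {}
    for g in range(k_used):
        sel = lab == g
        time = split.train.loc[sel, "time_days"].to_numpy(dtype=float)
        event = split.train.loc[sel, "event"].to_numpy(dtype=int)
        per_cluster[f"cluster_{g + 1}"] = {
            "n": int(sel.sum()),
            "survival_28d": float(split.train.loc[sel, "survived_28d"].mean()),
            "mean_sofa": float(scored.loc[sel, "sofa"].mean()),
            "mean_sic": float(scored.loc[sel, "sic"].mean()),
            "heparin_rate": float(split.train.loc[sel, "heparin"].mean()),
            "km_s28": clinstats.km_survival_at(time, event, 28.0) if event.sum() else 1.0,
        }
    surv_test = clinstats.survival_comparison(
        split.train["time_days"].to_numpy(dtype=float),
        split.train["event"].to_numpy(dtype=int),
        lab,
    )
    report["clusters"] = per_cluster
    report["cluster_survival_test"] = {
        "method": surv_test.method,
        "statistic": surv_test.statistic,
        "p_value": surv_test.p_value,
        "component_p": surv_test.extras["p_values"],
    }

    # --- validation cohort (external-validation stand-in) ------------------
    logger.info("stage: validation cohort")
    val_seed = (config.seed + 99991) % (2**31)
    val_cfg = CohortConfig(n_patients=config.n_patients, seed=val_seed)
    val_cohort, _ = preprocess.exclude_incomplete(sample_cohort(val_cfg))
    val_n = preprocess.apply_normalizer(norm, val_cohort)

    y_train = 1 - train_bal["survived_28d"].to_numpy(dtype=int)
    y_test = 1 - split.test["survived_28d"].to_numpy(dtype=int)
    y_val = 1 - val_cohort["survived_28d"].to_numpy(dtype=int)
    eval_sets_35 = {
        "train": (train_bal[list(FEATURES_35)].to_numpy(dtype=float), y_train),
        "test": (test_n[list(FEATURES_35)].to_numpy(dtype=float), y_test),
        "validation": (val_n[list(FEATURES_35)].to_numpy(dtype=float), y_val),
    }

    # --- DCQMFF -----------------------------------------------------------
    logger.info("stage: dcqmff")
    dc_cfg = dcqmff.DCQMFFConfig(epochs=config.dcqmff_epochs, seed=config.seed)
    dc_params, dc_trace = dcqmff.fit(train_bal, config=dc_cfg)
    report["dcqmff"] = {
        "final_loss": dc_trace[-1],
        **{
            split_name: evaluate_scores(
                dcqmff.predict(dc_params, tbl)["p_death"].to_numpy(), y
            )
            for split_name, (tbl, y) in {
                "train": (train_bal, y_train),
                "test": (test_n, y_test),
                "validation": (val_n, y_val),
            }.items()
        },
    }

    # --- CNN --------------------------------------------------------------
    logger.info("stage: cnn")
    cnn_cfg = CNNConfig(epochs=config.cnn_epochs, seed=config.seed)
    cnn, cnn_trace = fit_cnn(train_bal, config=cnn_cfg)
    report["cnn"] = {
        "final_loss": cnn_trace[-1],
        **{
            split_name: evaluate_scores(
                predict_cnn(cnn, tbl)["p_death"].to_numpy(), y
            )
            for split_name, (tbl, y) in {
                "train": (train_bal, y_train),
                "test": (test_n, y_test),
                "validation": (val_n, y_val),
            }.items()
        },
    }

    # --- SOFA as predictor + baselines -------------------------------------
    logger.info("stage: baselines")
    scored_test = severity_scores.score_cohort(split.test)
    report["sofa_score"] = sofa_as_predictor(
        scored_test["sofa"].to_numpy(), y_test
    )
    report["baselines"] = fit_baselines(
        eval_sets_35["train"][0], y_train, eval_sets_35, seed=config.seed
    )

    # --- artifacts ---------------------------------------------------------
    if config.write_artifacts:
        logger.info("stage: artifacts")
        if cohort_cfg is not None:
            write_cohort(cohort, outdir / "cohort.csv", cohort_cfg)
        norm.to_json(outdir / "normalizer.json")
        assigned = split.train.copy()
        assigned["cluster"] = model.assignments + 1
        assigned.to_csv(outdir / "train_clusters.csv", index=False)
        pd.DataFrame(emb.scores, columns=["pc1", "pc2", "pc3"]).to_csv(
            outdir / "embedding.csv", index=False
        )
        profile.table.to_csv(outdir / "heterogeneity.csv", index=False)
        profile.cluster_summaries.to_csv(outdir / "cluster_summaries.csv")
        for g in range(k_used):
            sel = lab == g
            t, s, r = clinstats.km_estimate(
                split.train.loc[sel, "time_days"].to_numpy(dtype=float),
                split.train.loc[sel, "event"].to_numpy(dtype=int),
            )
            pd.DataFrame({"time": t, "survival": s, "at_risk": r}).to_csv(
                outdir / f"km_cluster_{g + 1}.csv", index=False
            )
        dc_params.to_json(outdir / "dcqmff_params.json")
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
    return report
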