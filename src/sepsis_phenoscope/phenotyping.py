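"""Phenotype discovery: K selection, K-means fit, PCA embedding, and
per-feature heterogeneity profiling.

K is chosen by a compromise between the elbow of the inertia curve
(formalized as the K maximizing the second forward difference of inertia)
and the mean silhouette coefficient: when the two agree that K wins;
otherwise the candidate with the higher silhouette is chosen, ties going
to the smaller K.  Clustering runs on normalized features only — K-means
distances are meaningless across raw laboratory scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .clinstats import higher_p, jonckheere_terpstra, kruskal_wallis
from .features import FEATURES_35

_NORMALIZED_SPAN = (-0.5, 1.6)  # plausible range of shifted min-max output


@dataclass
class KSelectionReport:
    k_grid: list[int]
    inertia: list[float]
    silhouette: list[float]
    k_elbow: int
    k_silhouette: int
    k_chosen: int


@dataclass
class ClusterModel:
    K: int
    centroids: np.ndarray  # K x n_features, normalized space
    assignments: np.ndarray  # per-patient integer label
    inertia: float
    seed: int
    features: tuple[str, ...] = FEATURES_35


@dataclass
class Embedding3D:
    loadings: np.ndarray  # n_features x 3, orthonormal columns
    scores: np.ndarray  # n x 3
    explained_variance_fractions: np.ndarray  # length 3, non-increasing


@dataclass
class HeterogeneityReport:
    """Per-feature heterogeneity across clusters, most significant first."""

    table: pd.DataFrame  # feature, p_kw, p_jt, p_reported
    top_k: list[str]
    cluster_summaries: pd.DataFrame  # feature x cluster "median (q1-q3)"
    survival_test: object = None  # TestResult for per-cluster survival


def _feature_matrix(table: pd.DataFrame, features: tuple[str, ...]) -> np.ndarray:
    x = table[list(features)].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("complete cases required: feature matrix has NaNs")
    return x


def _check_normalized(x: np.ndarray) -> None:
    lo, hi = np.nanmin(x), np.nanmax(x)
    if lo < _NORMALIZED_SPAN[0] or hi > _NORMALIZED_SPAN[1]:
        raise ValueError(
            "features do not look normalized (values span "
            f"[{lo:.3g}, {hi:.3g}]); apply the min-max normalizer first"
        )


def select_k(
    table: pd.DataFrame,
    k_grid: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8),
    seed: int = 0,
    features: tuple[str, ...] = FEATURES_35,
    n_init: int = 10,
) -> KSelectionReport:
    """Scan K over the grid and pick the elbow/silhouette compromise."""
    k_grid = sorted(k_grid)
    if min(k_grid) < 2:
        raise ValueError("k_grid must contain only K >= 2")
    x = _feature_matrix(table, features)
    _check_normalized(x)
    if len(x) <= max(k_grid):
        raise ValueError("need more records than the largest K")
    inertia, silhouette = [], []
    for k in k_grid:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        lab = km.fit_predict(x)
        inertia.append(float(km.inertia_))
        silhouette.append(float(silhouette_score(x, lab)))
    # elbow: K maximizing the second forward difference of inertia
    # (needs interior points; grid edges cannot be elbows)
    d2 = [
        inertia[i - 1] - 2.0 * inertia[i] + inertia[i + 1]
        for i in range(1, len(k_grid) - 1)
    ]
    k_elbow = k_grid[1 + int(np.argmax(d2))] if d2 else k_grid[0]
    k_silhouette = k_grid[int(np.argmax(silhouette))]
    if k_elbow == k_silhouette:
        k_chosen = k_elbow
    else:
        s_e = silhouette[k_grid.index(k_elbow)]
        s_s = silhouette[k_grid.index(k_silhouette)]
        if s_e == s_s:
            k_chosen = min(k_elbow, k_silhouette)
        else:
            k_chosen = k_elbow if s_e > s_s else k_silhouette
    return KSelectionReport(
        k_grid=list(k_grid),
        inertia=inertia,
        silhouette=silhouette,
        k_elbow=k_elbow,
        k_silhouette=k_silhouette,
        k_chosen=k_chosen,
    )


def fit_clusters(
    table: pd.DataFrame,
    K: int,
    seed: int = 0,
    features: tuple[str, ...] = FEATURES_35,
    n_init: int = 10,
) -> ClusterModel:
    """K-means (k-means++ init, best inertia of ``n_init`` restarts)."""
    x = _feature_matrix(table, features)
    _check_normalized(x)
    if K > len(x):
        raise ValueError(f"K={K} exceeds n={len(x)}")
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed, max_iter=300, tol=1e-6)
    lab = km.fit_predict(x)
    if len(np.unique(lab)) < K:
        raise RuntimeError("K-means converged with an empty cluster")
    return ClusterModel(
        K=K,
        centroids=km.cluster_centers_,
        assignments=lab,
        inertia=float(km.inertia_),
        seed=seed,
        features=features,
    )


def project_pca3(
    table: pd.DataFrame, features: tuple[str, ...] = FEATURES_35
) -> Embedding3D:
    """Top-3 principal components of the centered feature matrix.

    Sign convention: within each component the largest-magnitude loading
    is made positive, so embeddings are reproducible across runs.
    """
    x = _feature_matrix(table, features)
    if len(x) < 4:
        raise ValueError("PCA-3D needs at least 4 records")
    rank = np.linalg.matrix_rank(x - x.mean(axis=0))
    if rank < 3:
        raise ValueError(f"feature matrix has rank {rank} < 3")
    pca = PCA(n_components=3, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.T.copy()  # features x 3
    for j in range(3):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    return Embedding3D(
        loadings=loadings,
        scores=scores,
        explained_variance_fractions=pca.explained_variance_ratio_.copy(),
    )


def profile_clusters(
    table: pd.DataFrame,
    model: ClusterModel,
    top_k: int = 10,
    jt_order: str = "index",
    raw_table: pd.DataFrame | None = None,
) -> HeterogeneityReport:
    """Rank features by heterogeneity across the fitted clusters.

    Each feature gets a Kruskal-Wallis p and a Jonckheere-Terpstra p
    (ordering = cluster index, or by cluster mortality when
    ``jt_order='severity'``); the reported p is the larger of the two.
    ``raw_table`` (same rows, original scale) feeds the median (IQR)
    summaries so they are readable in laboratory units; it defaults to
    ``table``.  If survival columns are present, a per-cluster survival
    comparison (log-rank vs Gehan-Breslow-Wilcoxon, higher p) is attached.
    """
    lab = np.asarray(model.assignments)
    ids = np.unique(lab)
    if ids.size < 2 or any((lab == g).sum() < 2 for g in ids):
        raise ValueError("need >= 2 clusters with >= 2 members each")
    if raw_table is None:
        raw_table = table
    if jt_order == "index":
        order = list(ids)
    elif jt_order == "severity":
        if "event" not in raw_table.columns:
            raise ValueError("severity ordering needs an 'event' column")
        mort = [raw_table.loc[lab == g, "event"].mean() for g in ids]
        order = [g for _, g in sorted(zip(mort, ids))]
    else:
        raise ValueError(f"unknown jt_order {jt_order!r}")

    rows = []
    summaries = {}
    for name in model.features:
        groups = [table.loc[lab == g, name].to_numpy(dtype=float) for g in ids]
        ordered = [table.loc[lab == g, name].to_numpy(dtype=float) for g in order]
        if np.ptp(np.concatenate(groups)) == 0:  # fully tied feature
            p_kw = p_jt = 1.0
        else:
            p_kw = kruskal_wallis(groups, exact=False).p_value
            p_jt = jonckheere_terpstra(ordered, exact=False).p_value
        rows.append({"feature": name, "p_kw": p_kw, "p_jt": p_jt,
                     "p_reported": max(p_kw, p_jt)})
        summaries[name] = {
            f"C{g + 1}": _fmt_median_iqr(raw_table.loc[lab == g, name])
            for g in ids
        }

    tab = pd.DataFrame(rows).sort_values(
        ["p_reported", "feature"], kind="stable"
    ).reset_index(drop=True)
    report = HeterogeneityReport(
        table=tab,
        top_k=tab["feature"].head(top_k).tolist(),
        cluster_summaries=pd.DataFrame(summaries).T,
    )
    if {"time_days", "event"}.issubset(raw_table.columns):
        from .clinstats import survival_comparison

        report.survival_test = survival_comparison(
            raw_table["time_days"].to_numpy(dtype=float),
            raw_table["event"].to_numpy(dtype=int),
            lab,
        )
    return report


def _fmt_median_iqr(col: pd.Series) -> str:
    v = col.to_numpy(dtype=float)
    return f"{np.median(v):.1f} ({np.quantile(v, 0.25):.1f}-{np.quantile(v, 0.75):.1f})"
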