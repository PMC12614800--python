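"""Response-archetype discovery: PCA + K-means with silhouette evaluation.

Feature vectors concatenate baselined, trial-resolved (or trial-averaged)
response snippets per cell. PCA retains the smallest component set reaching
80% explained variance; K-means (k-means++, 50 restarts) partitions the
scores, and the mean silhouette over k = 2..20 documents the segmentation
quality. Clusters are then merged via an explicit map and named by maximal
Pearson correlation with a library of archetype templates — the
reproducible stand-in for by-eye inspection and merging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .protocol import AlignedTensor

logger = logging.getLogger("fearcal")

DEFAULT_VARIANCE_THRESHOLD = 0.80
DEFAULT_K_RANGE = range(2, 21)
KMEANS_RESTARTS = 50
KMEANS_TOL = 1e-6
MIN_FLOW = 5


def feature_matrix(
    tensors: list[AlignedTensor] | AlignedTensor,
    trial_groups: list[list[int]] | None = None,
    window: float | None = None,
    cell_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Cells x features matrix of concatenated baselined response snippets.

    Each tensor contributes its post-onset bins up to ``window``: one block
    per trial, or one block per trial group averaged (0-based indices) —
    e.g. first/middle/last blocks of four extinction trials. ``cell_mask``
    restricts rows to (typically) the responsive cells.
    """
    if isinstance(tensors, AlignedTensor):
        tensors = [tensors]
    if not tensors:
        raise ValueError("no tensors given")
    n_cells = tensors[0].n_cells
    if any(t.n_cells != n_cells for t in tensors):
        raise ValueError("all tensors must share the same cell set")

    blocks = []
    for t in tensors:
        post = t.post(window)
        if trial_groups is None:
            blocks.extend(post[:, j, :] for j in range(post.shape[1]))
        else:
            blocks.extend(post[:, g, :].mean(axis=1) for g in trial_groups)
    X = np.concatenate(blocks, axis=1)
    if cell_mask is not None:
        X = X[np.asarray(cell_mask)]
    if X.shape[0] == 0:
        raise ValueError("empty cell set after masking")
    return X


def extinction_block_groups(n_trials: int = 12, block: int = 4) -> list[list[int]]:
    """First, middle and last blocks of ``block`` trials of one session."""
    mid = (n_trials - block) // 2
    return [list(range(block)),
            list(range(mid, mid + block)),
            list(range(n_trials - block, n_trials))]


@dataclass
class ClusterModel:
    """PCA basis + K-means partition of a response feature matrix."""

    k: int
    pca: PCA
    n_components: int
    explained_variance: float
    variance_threshold: float
    scores: np.ndarray             # (cells, n_components)
    raw_labels: np.ndarray         # (cells,) int
    centroids: np.ndarray          # (k, n_components)
    seed: int
    inertia: float
    silhouette_by_k: dict[int, float] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.raw_labels)


def _pca_scores(X: np.ndarray, variance_threshold: float, seed: int) -> tuple[PCA, np.ndarray, int]:
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("degenerate feature matrix: zero variance everywhere")
    pca = PCA(n_components=min(X.shape), random_state=seed)
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, variance_threshold) + 1)
    return pca, scores[:, :n_comp], n_comp


def silhouette_scan(
    X: np.ndarray,
    k_range: range = DEFAULT_K_RANGE,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
    seed: int = 0,
    n_init: int = 10,
) -> pd.DataFrame:
    """Mean silhouette (Euclidean, on retained PCA scores) for each k.

    Infeasible k (>= number of cells) are skipped with a warning. The
    returned frame carries a ``best_k`` attribute.
    """
    _, scores, _ = _pca_scores(X, variance_threshold, seed)
    rows = []
    for k in k_range:
        if k >= len(scores):
            logger.warning("silhouette scan: k=%d skipped (only %d cells)", k, len(scores))
            continue
        km = KMeans(n_clusters=k, n_init=n_init, tol=KMEANS_TOL, random_state=seed)
        labels = km.fit_predict(scores)
        rows.append({"k": k, "silhouette": float(silhouette_score(scores, labels))})
    out = pd.DataFrame(rows)
    out.attrs["best_k"] = int(out.loc[out["silhouette"].idxmax(), "k"]) if len(out) else None
    return out


def fit_cluster_model(
    X: np.ndarray,
    k: int,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
    seed: int = 0,
    n_init: int = KMEANS_RESTARTS,
) -> ClusterModel:
    """PCA to the variance threshold, then seeded k-means++ with restarts."""
    if not 2 <= k <= len(X):
        raise ValueError(f"k={k} must lie in [2, n_cells={len(X)}]")
    pca, scores, n_comp = _pca_scores(X, variance_threshold, seed)
    km = KMeans(n_clusters=k, n_init=n_init, tol=KMEANS_TOL, random_state=seed)
    labels = km.fit_predict(scores)
    return ClusterModel(
        k=k, pca=pca, n_components=n_comp,
        explained_variance=float(np.cumsum(pca.explained_variance_ratio_)[n_comp - 1]),
        variance_threshold=variance_threshold,
        scores=scores, raw_labels=labels, centroids=km.cluster_centers_,
        seed=seed, inertia=float(km.inertia_),
    )


@dataclass
class LabeledClustering:
    """Final (merged, semantically named) cluster assignments."""

    final_labels: np.ndarray       # (cells,) semantic names
    merged_labels: np.ndarray      # (cells,) int after merge map
    merge_map: dict[int, int]
    report: pd.DataFrame           # merged cluster, label, correlation, size


def merge_and_label(
    model: ClusterModel,
    X: np.ndarray,
    templates: dict[str, np.ndarray],
    merge_map: dict[int, int] | None = None,
) -> LabeledClustering:
    """Merge raw clusters per an explicit map and name them by template match.

    Every raw cluster must be covered by ``merge_map`` (identity when
    omitted). Each merged cluster is labelled with the template of maximal
    Pearson correlation against its mean feature vector; clusters mapped to
    the same template are thereby merged semantically, with counts adding.
    """
    raw_ids = np.unique(model.raw_labels)
    if merge_map is None:
        merge_map = {int(i): int(i) for i in raw_ids}
    unmapped = set(raw_ids.tolist()) - set(merge_map)
    if unmapped:
        raise ValueError(f"merge map leaves raw cluster(s) {sorted(unmapped)} unmapped")

    merged = np.array([merge_map[int(l)] for l in model.raw_labels])
    rows = []
    final = np.empty(len(merged), dtype=object)
    for mid in np.unique(merged):
        mask = merged == mid
        mean_vec = X[mask].mean(axis=0)
        corrs = {}
        for name, tmpl in templates.items():
            if len(tmpl) != X.shape[1]:
                raise ValueError(f"template {name!r} length {len(tmpl)} != {X.shape[1]} features")
            if np.ptp(tmpl) == 0 or np.ptp(mean_vec) == 0:
                corrs[name] = -np.inf
            else:
                corrs[name] = stats.pearsonr(mean_vec, tmpl)[0]
        label = max(corrs, key=corrs.get)
        final[mask] = label
        rows.append({"merged_cluster": int(mid), "label": label,
                     "correlation": float(corrs[label]), "n_cells": int(mask.sum())})
    return LabeledClustering(
        final_labels=final, merged_labels=merged, merge_map=dict(merge_map),
        report=pd.DataFrame(rows),
    )


@dataclass
class ClusterFlow:
    """Cross-labeling cell-count flow matrix (e.g. US clusters -> CS+ clusters)."""

    counts: pd.DataFrame         # source x target counts
    min_flow: int

    @property
    def display(self) -> pd.DataFrame:
        """Counts with sub-threshold flows masked to 0 (display rule)."""
        return self.counts.where(self.counts >= self.min_flow, 0)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def cluster_flow(
    labels_a: np.ndarray,
    labels_b: np.ndarray,
    min_flow: int = MIN_FLOW,
    common: np.ndarray | None = None,
) -> ClusterFlow:
    """Count matrix of cells moving between two labelings of the same cells.

    ``common`` optionally selects the shared cell subset. Flows below
    ``min_flow`` are masked in the display matrix only; counts conserve
    every cell.
    """
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if common is not None:
        a, b = a[common], b[common]
    if len(a) != len(b):
        raise ValueError("labelings must cover the same cells")
    if len(a) == 0:
        raise ValueError("empty common cell set")
    counts = pd.crosstab(pd.Series(a, name="source"), pd.Series(b, name="target"))
    return ClusterFlow(counts, min_flow)


def cluster_fractions_per_animal(labels: np.ndarray, animal_ids: np.ndarray) -> pd.DataFrame:
    """Per animal, the fraction of its cells in each final cluster.

    Rows sum to 1; animals with zero cells are excluded with a warning.
    Suitable input for a Friedman-type comparison of cluster prevalence.
    """
    labels, animal_ids = np.asarray(labels), np.asarray(animal_ids)
    if len(labels) != len(animal_ids):
        raise ValueError("labels and animal_ids must align")
    counts = pd.crosstab(pd.Series(animal_ids, name="animal"), pd.Series(labels, name="cluster"))
    empty = counts.sum(axis=1) == 0
    if empty.any():
        logger.warning("cluster fractions: %d animal(s) without cells excluded", int(empty.sum()))
        counts = counts[~empty]
    return counts.div(counts.sum(axis=1), axis=0)
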