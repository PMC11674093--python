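"""Unsupervised verification of a selected gene panel.

A good panel should separate the sample groups without seeing the labels:
samples are clustered (k-means or agglomerative/hierarchical) on the
standardized panel genes, clusters are aligned to classes by the matching
that maximizes agreement, and purity plus the adjusted Rand index are
reported together with the clusters x classes contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage as scipy_linkage, to_tree
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import adjusted_rand_score

from .data import ExpressionMatrix, LabelVector
from .ranking import standardize_genes

__all__ = ["ClusterVerification", "cluster", "align_and_score", "dendrogram_newick"]


@dataclass
class ClusterVerification:
    method: str
    assignments: dict[str, int]
    confusion: np.ndarray  # K x C counts
    cluster_ids: list[int]
    class_names: list[str]
    mapping: dict[int, str]  # cluster -> best-aligned class
    purity: float
    ari: float
    dendrogram: str | None = None  # newick, agglomerative only


def _relabel_first_appearance(raw: np.ndarray) -> np.ndarray:
    """Relabel cluster ids by order of first appearance in sample order."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, c in enumerate(raw):
        if c not in mapping:
            mapping[c] = len(mapping)
        out[i] = mapping[c]
    return out


def cluster(
    X_sel: ExpressionMatrix,
    K: int,
    method: str = "kmeans",
    linkage: str = "ward",
    seed: int = 0,
    standardize: bool = True,
) -> dict[str, int]:
    """Cluster samples on the panel genes; returns sample_id -> cluster id.

    k-means uses Euclidean distance with 10 restarts keeping the lowest
    within-cluster sum of squares; agglomerative clustering uses the chosen
    linkage on Euclidean distances, cut at K clusters.  Cluster ids are
    relabeled by first appearance in sample order, so they are stable and
    comparable across methods.
    """
    n = X_sel.n_samples
    if not (1 <= K <= n):
        raise ValueError(f"K must be in [1, {n}], got {K}")
    if method not in ("kmeans", "agglomerative"):
        raise ValueError(f"unknown clustering method {method!r}")
    if linkage not in ("ward", "average", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")

    values = standardize_genes(X_sel.values) if standardize else X_sel.values
    obs = values.T  # samples x genes
    if method == "kmeans":
        km = KMeans(n_clusters=K, n_init=10, random_state=seed)
        raw = km.fit_predict(obs)
    else:
        ac = AgglomerativeClustering(n_clusters=K, linkage=linkage)
        raw = ac.fit_predict(obs)
    labels = _relabel_first_appearance(raw)
    return dict(zip(X_sel.sample_ids, labels.tolist()))


def dendrogram_newick(
    X_sel: ExpressionMatrix, linkage_method: str = "ward", standardize: bool = True
) -> str:
    """Newick rendering of the full agglomerative merge tree."""
    values = standardize_genes(X_sel.values) if standardize else X_sel.values
    Z = scipy_linkage(values.T, method=linkage_method, metric="euclidean")
    root = to_tree(Z)

    def render(node) -> str:
        if node.is_leaf():
            return X_sel.sample_ids[node.id]
        left, right = node.get_left(), node.get_right()
        ld = node.dist - left.dist
        rd = node.dist - right.dist
        return f"({render(left)}:{ld:.6g},{render(right)}:{rd:.6g})"

    return render(root) + ";"


def align_and_score(
    assignments: dict[str, int],
    y: LabelVector,
    group_map: dict[str, str] | None = None,
    method: str = "kmeans",
    dendrogram: str | None = None,
) -> ClusterVerification:
    """Align clusters to classes and score purity and adjusted Rand index.

    ``group_map`` optionally collapses sub-labels before scoring (e.g.
    substages IA and IC both mapping to stage I), so stage-level agreement
    can be scored on substage-labelled data.  When the cluster count equals
    the class count the alignment is the cluster->class bijection maximizing
    the matched count (Hungarian assignment); otherwise each cluster maps to
    its majority class.  Purity = matched count / n under that mapping.
    """
    missing = [s for s in assignments if s not in set(y.sample_ids)]
    if missing or set(assignments) != set(y.sample_ids):
        raise ValueError("assignments must cover exactly the labeled samples")

    labels = y.labels
    if group_map:
        labels = [group_map.get(l, l) for l in labels]
        class_names: list[str] = []
        for l in labels:
            if l not in class_names:
                class_names.append(l)
    else:
        class_names = list(y.class_order)

    cluster_ids = sorted(set(assignments.values()))
    K, C = len(cluster_ids), len(class_names)
    cpos = {c: i for i, c in enumerate(cluster_ids)}
    lpos = {l: i for i, l in enumerate(class_names)}
    confusion = np.zeros((K, C), dtype=int)
    for s, l in zip(y.sample_ids, labels):
        confusion[cpos[assignments[s]], lpos[l]] += 1

    n = confusion.sum()
    if K == C:
        rows, cols = linear_sum_assignment(-confusion)
        mapping = {cluster_ids[r]: class_names[c] for r, c in zip(rows, cols)}
        matched = confusion[rows, cols].sum()
    else:
        mapping = {
            cluster_ids[r]: class_names[int(np.argmax(confusion[r]))] for r in range(K)
        }
        matched = confusion.max(axis=1).sum()

    true_codes = [lpos[l] for l in labels]
    pred_codes = [assignments[s] for s in y.sample_ids]
    ari = float(adjusted_rand_score(true_codes, pred_codes))

    return ClusterVerification(
        method=method,
        assignments=dict(assignments),
        confusion=confusion,
        cluster_ids=cluster_ids,
        class_names=class_names,
        mapping=mapping,
        purity=float(matched) / float(n),
        ari=ari,
        dendrogram=dendrogram,
    )
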