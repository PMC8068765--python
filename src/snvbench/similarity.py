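"""Pairwise agreement between pipelines and hierarchical clustering.

For one sample type, every (sample, variant) detection event observed in
any pipeline becomes a row of a 0/1 incidence matrix with one column per
pipeline.  Column pairs are compared with cosine, Jaccard or Pearson
similarity, and pipelines are clustered agglomeratively (average linkage,
UPGMA) on distance 1 - similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .vcf_io import CallSet, SAMPLE_TYPES, VariantKey

Metric = Literal["cosine", "jaccard", "pearson"]


@dataclass
class IncidenceMatrix:
    """0/1 detection indicators, one row per (sample, variant) event."""

    sample_type: str
    data: pd.DataFrame  # index: (sample_id, variant str), columns: pipeline ids

    @property
    def pipelines(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class SimilarityMatrix:
    metric: str
    values: pd.DataFrame  # symmetric, pipelines x pipelines

    @property
    def pipelines(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix
    leaf_order: list[str]
    newick: str

    def flat_clusters(self, n_clusters: int) -> dict[str, int]:
        """Cut the tree into ``n_clusters`` groups; pipeline -> cluster label."""
        labels = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return dict(zip(self._pipelines, (int(x) for x in labels)))

    _pipelines: list[str] = None  # set by cluster()


def build_incidence(callsets: Iterable[CallSet], sample_type: str) -> IncidenceMatrix:
    """Pool detection events of all samples of one type into one matrix.

    Rows are (sample, variant) pairs detected by at least one pipeline, so
    the same variant recurring in two samples contributes two rows.
    """
    if sample_type not in SAMPLE_TYPES:
        raise ValueError(f"unknown sample_type {sample_type!r}")
    selected = [cs for cs in callsets if cs.sample_type == sample_type]
    if not selected:
        raise ValueError(f"no call sets of sample_type {sample_type!r}")
    pipelines = sorted({cs.pipeline_id for cs in selected})
    samples = sorted({cs.sample_id for cs in selected})

    calls: dict[tuple[str, str], set[VariantKey]] = {
        (cs.sample_id, cs.pipeline_id): cs.keys() for cs in selected
    }
    rows = []
    index = []
    for sid in samples:
        universe: set[VariantKey] = set()
        for pid in pipelines:
            universe |= calls.get((sid, pid), set())
        for v in sorted(universe):
            rows.append(
                [1 if v in calls.get((sid, pid), ()) else 0 for pid in pipelines]
            )
            index.append((sid, f"{v.contig}:{v.position}:{v.ref}>{v.alt}"))
    data = pd.DataFrame(
        np.asarray(rows, dtype=np.int8).reshape(len(rows), len(pipelines)),
        columns=pipelines,
        index=pd.MultiIndex.from_tuples(index, names=["sample_id", "variant"])
        if index
        else None,
    )
    return IncidenceMatrix(sample_type=sample_type, data=data)


def similarity_matrix(m: IncidenceMatrix, metric: Metric = "cosine") -> SimilarityMatrix:
    """Pairwise column similarity of the incidence matrix.

    All-zero columns make cosine and Pearson undefined for their pairs
    (NaN off the diagonal); the diagonal is always 1.  Jaccard of two
    all-zero columns is likewise NaN (0/0).
    """
    X = m.data.to_numpy(dtype=np.float64)
    pipelines = m.pipelines
    n = len(pipelines)
    if n < 2:
        raise ValueError("need at least 2 pipelines")
    inter = X.T @ X  # co-detection counts
    sizes = X.sum(axis=0)

    if metric == "cosine":
        with np.errstate(invalid="ignore", divide="ignore"):
            norms = np.sqrt(sizes)
            S = inter / np.outer(norms, norms)
        S[np.outer(sizes == 0, np.ones(n, bool)) | np.outer(np.ones(n, bool), sizes == 0)] = np.nan
    elif metric == "jaccard":
        union = sizes[:, None] + sizes[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            S = np.where(union > 0, inter / np.where(union > 0, union, 1), np.nan)
    elif metric == "pearson":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            S = np.corrcoef(X, rowvar=False)
        const = X.std(axis=0) == 0
        S[const, :] = np.nan
        S[:, const] = np.nan
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(metric=metric, values=pd.DataFrame(S, index=pipelines, columns=pipelines))


def cluster(sm: SimilarityMatrix) -> ClusterResult:
    """Average-linkage agglomerative clustering on distance 1 - similarity.

    Refuses matrices with missing cells.  Deterministic: scipy breaks
    distance ties by merge index, which follows input column order.
    """
    S = sm.values.to_numpy(dtype=float)
    if np.isnan(S).any():
        bad = [
            (sm.pipelines[i], sm.pipelines[j])
            for i, j in zip(*np.where(np.isnan(S)))
            if i < j
        ]
        raise ValueError(
            f"similarity matrix has missing cells (e.g. {bad[:3]}); "
            "clustering requires a complete matrix"
        )
    D = 1.0 - S
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    # leaf order: tree traversal with children ordered by their smallest
    # original column index, so ties resolve to input order
    tree = hierarchy.to_tree(Z)

    def leaves(node) -> list[int]:
        if node.is_leaf():
            return [node.id]
        left, right = leaves(node.left), leaves(node.right)
        return left + right if min(left) <= min(right) else right + left

    order = [sm.pipelines[i] for i in leaves(tree)]
    result = ClusterResult(linkage=Z, leaf_order=order, newick=_newick(Z, sm.pipelines))
    result._pipelines = list(sm.pipelines)
    return result


def _newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage as a Newick string with ultrametric branch lengths."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_dist: float) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:{(parent_dist - 0.0) / 2:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        bl = (parent_dist - node.dist) / 2
        return f"({left},{right}):{bl:.6g}"

    if tree.is_leaf():  # single pipeline, degenerate
        return f"{labels[tree.id]};"
    inner = rec(tree, tree.dist)
    # strip the root's branch length
    return inner.rsplit(":", 1)[0] + ";"
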