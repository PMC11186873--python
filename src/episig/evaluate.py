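"""Unsupervised verification: Ward clustering, classical MDS, separation.

An episignature is "verified" by showing that cases and controls
separate without using the labels: Ward hierarchical clustering
(variance-minimising agglomeration on Euclidean distances, the ward.D2
convention) and classical (Torgerson) multidimensional scaling of the
pairwise Euclidean distances. Separation is quantified rather than
eyeballed: purity of the two-cluster cut and mean silhouette per label
group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_samples

from .errors import ValidationError


@dataclass
class LinkageTree:
    """Agglomerative merge sequence with leaf labels.

    ``linkage`` is a scipy linkage matrix: n-1 merges for n leaves,
    heights non-decreasing.
    """

    linkage: np.ndarray
    labels: List[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, n_clusters: int) -> pd.Series:
        assign = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(assign, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "merges": [
                {
                    "left": int(a),
                    "right": int(b),
                    "height": float(h),
                    "size": int(n),
                }
                for a, b, h, n in self.linkage
            ],
            "newick": self.to_newick(),
        }


def ward_cluster(values: pd.DataFrame) -> LinkageTree:
    """Ward's-method tree over samples (columns) on Euclidean distance.

    ``values`` is probes x samples (the usual orientation of a beta
    matrix restricted to selected probes).
    """
    if values.shape[1] < 2:
        raise ValidationError("clustering needs at least 2 samples")
    X = values.to_numpy(dtype=float).T
    if np.isnan(X).any():
        raise ValidationError("clustering input contains missing values")
    Z = hierarchy.linkage(X, method="ward")
    return LinkageTree(linkage=Z, labels=[str(c) for c in values.columns])


def classical_mds(distances: pd.DataFrame | np.ndarray, k: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centers the squared distances, eigendecomposes, and returns
    the top-``k`` coordinate columns (centered). Embedded pairwise
    distances reproduce the input exactly when the distances are
    realisable in ``k`` dimensions.
    """
    if isinstance(distances, pd.DataFrame):
        labels = [str(c) for c in distances.index]
        D = distances.to_numpy(dtype=float)
    else:
        D = np.asarray(distances, dtype=float)
        labels = [str(i) for i in range(D.shape[0])]
    if D.shape[0] != D.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8) or not np.allclose(np.diag(D), 0, atol=1e-8):
        raise ValidationError("distance matrix must be symmetric with zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if np.all(eigval[:k] <= 0):
        warnings.warn("degenerate geometry: no positive eigenvalues in MDS")
    coords = eigvec[:, :k] * np.sqrt(np.clip(eigval[:k], 0.0, None))
    out = pd.DataFrame(
        coords,
        index=pd.Index(labels, name="sample_id"),
        columns=[f"dim{i + 1}" for i in range(k)],
    )
    return out - out.mean(axis=0)


def mds_embed(values: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Classical MDS of the pairwise Euclidean distances between samples."""
    X = values.to_numpy(dtype=float).T
    D = squareform(pdist(X, metric="euclidean"))
    return classical_mds(pd.DataFrame(D, index=values.columns, columns=values.columns), k)


def separation_report(
    values: pd.DataFrame, labels: Sequence[str] | pd.Series
) -> Dict[str, object]:
    """Purity of the 2-cluster Ward cut and silhouette per label group.

    ``values`` is probes x samples; ``labels`` gives one group label per
    sample (column).
    """
    if isinstance(labels, pd.Series):
        labels = labels.loc[values.columns]
    labels = list(labels)
    if len(set(labels)) < 2:
        raise ValidationError("separation report needs at least 2 label groups")
    tree = ward_cluster(values)
    clusters = tree.cut(2)
    df = pd.DataFrame({"cluster": clusters.values, "label": labels}, index=values.columns)
    majority = df.groupby("cluster")["label"].agg(lambda s: s.value_counts().max())
    purity = float(majority.sum() / len(df))
    X = values.to_numpy(dtype=float).T
    sil = silhouette_samples(X, np.asarray(labels, dtype=object))
    sil_by_label = {
        lab: float(np.mean(sil[np.asarray(labels, dtype=object) == lab]))
        for lab in sorted(set(labels))
    }
    return {
        "purity_2cut": purity,
        "silhouette_by_label": sil_by_label,
        "cluster_sizes": df["cluster"].value_counts().to_dict(),
    }
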