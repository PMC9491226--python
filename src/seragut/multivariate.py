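"""Sample-level multivariate structure: PCA, PLS-DA with VIP, Ward.D2 trees.

PCA and the NIPALS PLS1 discriminant model operate on samples x features
matrices after centering or autoscaling; the Ward tree uses the Ward.D2
convention (heights on the Euclidean distance scale), matching R's
``hclust(method = "ward.D2")``.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .io_tables import FeatureMatrix

__all__ = [
    "PlsModel",
    "Dendrogram",
    "pca_scores",
    "plsda_fit",
    "vip_scores",
    "ward_d2_tree",
    "autoscale",
]


def _sample_matrix(data: FeatureMatrix | pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list, list]:
    """Return (samples x features array, sample ids, feature ids)."""
    if isinstance(data, FeatureMatrix):
        return data.values.to_numpy(float).T, data.sample_ids, data.feature_ids
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(float), list(data.index), list(data.columns)
    arr = np.asarray(data, float)
    return arr, list(range(arr.shape[0])), list(range(arr.shape[1]))


def autoscale(x: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Center columns and scale to unit variance; errors on constant columns."""
    sd = x.std(axis=0, ddof=ddof)
    if np.any(sd == 0):
        bad = list(np.where(sd == 0)[0])
        raise ValueError(f"constant features cannot be autoscaled (column indices {bad})")
    return (x - x.mean(axis=0)) / sd


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_scores(
    data: FeatureMatrix | pd.DataFrame | np.ndarray,
    scaling: str = "center",
    n_components: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of a samples x features matrix via SVD.

    Returns (scores, loadings, variance fractions).  The sign of each
    component is fixed so that its largest-magnitude loading is positive.
    """
    x, sample_ids, feature_ids = _sample_matrix(data)
    if scaling not in ("center", "autoscale"):
        raise ValueError(f"unknown scaling {scaling!r}")
    if n_components > min(x.shape[0] - 1, x.shape[1]):
        raise ValueError("n_components exceeds min(samples - 1, features)")
    if scaling == "autoscale":
        xs = autoscale(x)
    else:
        xs = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    total_var = (s**2).sum()
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components].T
    for a in range(n_components):
        j = np.argmax(np.abs(loadings[:, a]))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1
    frac = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    comp_names = [f"PC{a + 1}" for a in range(n_components)]
    return (
        pd.DataFrame(scores, index=sample_ids, columns=comp_names),
        pd.DataFrame(loadings, index=feature_ids, columns=comp_names),
        frac,
    )


# ---------------------------------------------------------------------------
# PLS-DA (NIPALS PLS1)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PlsModel:
    """A fitted two-class PLS1 discriminant model.

    ``scores`` T (samples x A), ``weights`` W and ``loadings`` P
    (features x A, each weight column unit-norm), response loadings ``q``
    and per-component explained response sum of squares
    ``ss = q_a^2 * (t_a' t_a)``.
    """

    n_components: int
    scores: np.ndarray
    weights: np.ndarray
    loadings: np.ndarray
    q: np.ndarray
    ss: np.ndarray
    class_coding: dict
    feature_ids: list
    sample_ids: list


def plsda_fit(
    data: FeatureMatrix | pd.DataFrame | np.ndarray,
    labels: Sequence,
    scaling: str = "autoscale",
    n_components: int = 2,
) -> PlsModel:
    """Fit NIPALS PLS1 on autoscaled X and centered -1/+1-coded labels.

    Both classes need at least 2 samples.  X and y are deflated per
    component; weight vectors are unit norm and score columns mutually
    orthogonal.
    """
    x, sample_ids, feature_ids = _sample_matrix(data)
    y_raw = np.asarray(labels)
    classes = sorted(pd.unique(y_raw).tolist())
    if len(classes) != 2:
        raise ValueError(f"PLS-DA needs exactly two classes, got {classes}")
    counts = {c: int((y_raw == c).sum()) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError(f"each class needs >= 2 samples, got {counts}")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if scaling != "autoscale":
        raise ValueError("only autoscale is supported for PLS-DA")
    coding = {classes[0]: -1.0, classes[1]: 1.0}
    y = np.array([coding[c] for c in y_raw], float)
    y = y - y.mean()
    xs = autoscale(x)

    n, p = xs.shape
    A = n_components
    T = np.zeros((n, A))
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    ss = np.zeros(A)
    for a in range(A):
        w = xs.T @ y
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError("degenerate response: zero covariance with all features")
        w /= norm
        t = xs @ w
        tt = float(t @ t)
        if tt == 0:
            raise ValueError("degenerate component with zero score variance")
        p_a = xs.T @ t / tt
        q_a = float(y @ t) / tt
        xs = xs - np.outer(t, p_a)
        y = y - q_a * t
        T[:, a], W[:, a], P[:, a], q[a] = t, w, p_a, q_a
        ss[a] = q_a**2 * tt
    return PlsModel(A, T, W, P, q, ss, coding, feature_ids, sample_ids)


def vip_scores(model: PlsModel) -> pd.Series:
    """Variable importance in projection for every feature.

    ``VIP_j = sqrt(p * sum_a ss_a w_ja^2 / sum_a ss_a)`` with unit-norm
    weight columns; the mean of squared VIPs over features is exactly 1.
    """
    total = model.ss.sum()
    if total == 0:
        raise ValueError("all components have zero explained response sum of squares")
    p = model.weights.shape[0]
    contrib = (model.weights**2) @ model.ss
    vip = np.sqrt(p * contrib / total)
    return pd.Series(vip, index=model.feature_ids, name="vip")


# ---------------------------------------------------------------------------
# Ward.D2 hierarchical clustering
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Dendrogram:
    """Agglomerative tree: scipy linkage matrix plus leaf identifiers."""

    merges: np.ndarray  # scipy linkage format
    leaf_ids: list

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self) -> str:
        """Nested-parentheses text rendering (heights as branch annotations)."""
        n = len(self.leaf_ids)
        nodes: dict[int, str] = {i: str(self.leaf_ids[i]) for i in range(n)}
        for k, (a, b, h, _size) in enumerate(self.merges):
            nodes[n + k] = f"({nodes[int(a)]},{nodes[int(b)]}):{h:.6g}"
        return nodes[n + len(self.merges) - 1] + ";"


def ward_d2_tree(
    data: FeatureMatrix | pd.DataFrame | np.ndarray,
    axis: str = "samples",
) -> Dendrogram:
    """Ward.D2 agglomerative clustering on Euclidean distances.

    ``axis`` selects whether samples or features are the clustered items.
    Heights are on the distance scale (Ward.D2 convention).
    """
    x, sample_ids, feature_ids = _sample_matrix(data)
    if axis == "samples":
        items, ids = x, sample_ids
    elif axis == "features":
        items, ids = x.T, feature_ids
    else:
        raise ValueError(f"unknown axis {axis!r}")
    if items.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if not np.all(np.isfinite(items)):
        raise ValueError("non-finite values in clustering input")
    merges = linkage(items, method="ward")
    return Dendrogram(merges, ids)
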