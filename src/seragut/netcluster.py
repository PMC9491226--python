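"""Signed weighted co-abundance networks and module detection.

The chain is the classic weighted-correlation-network recipe: a signed
adjacency ``a_ij = ((1 + cor_ij)/2)^beta`` with the soft threshold chosen by
the scale-free topology criterion (smallest beta whose signed model fit
R^2 >= 0.85), topological overlap similarity, average-linkage clustering of
the TOM dissimilarity, and a dynamic hybrid tree cut (deepSplit default 2,
minimum module size default 10) followed by an eigenfeature-correlation
(kME) assignment stage and eigenfeature-based module merging.  Modules are
named by a fixed color palette in decreasing size order; label 0 / grey means
unassigned.

The dynamic hybrid cut here is a re-implementation from the published
description: a dendrogram branch becomes a module when it is large enough,
internally tight (it completes — its highest internal merge lies — below a
deepSplit-dependent core-scatter bound) and well separated from its
surroundings (attachment gap above a deepSplit-dependent minimum); the root
is never one module.  Branch-for-branch parity with other
implementations is not a goal; recovery of planted block structure is.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy import stats as sps

from .io_tables import FeatureMatrix

__all__ = [
    "SoftThresholdScan",
    "NetworkModules",
    "MODULE_COLORS",
    "signed_adjacency",
    "pick_soft_threshold",
    "topological_overlap",
    "detect_modules",
    "module_eigenfeatures",
    "module_trait_association",
]

#: fixed palette; modules are colored in decreasing size order
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna",
    "yellowgreen", "lightsteelblue", "plum", "orangered", "mediumpurple",
)

# deepSplit -> (max core scatter, min gap), as fractions of the
# 5th-percentile-to-maximum dendrogram height range
_DEEP_SPLIT = {
    0: (0.64, 0.27),
    1: (0.73, 0.2025),
    2: (0.82, 0.135),
    3: (0.91, 0.0675),
    4: (0.95, 0.0375),
}


def _feature_array(data: FeatureMatrix | pd.DataFrame) -> tuple[np.ndarray, list]:
    if isinstance(data, FeatureMatrix):
        return data.values.to_numpy(float), data.feature_ids
    return data.to_numpy(float), list(data.index)


def _correlation(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=1, ddof=0)
    if np.any(sd == 0):
        bad = list(np.where(sd == 0)[0])
        raise ValueError(f"constant features have no defined correlation (row indices {bad})")
    return np.corrcoef(x)


def signed_adjacency(
    data: FeatureMatrix | pd.DataFrame,
    beta: int,
    log2_transform: bool = False,
) -> pd.DataFrame:
    """Signed adjacency ``((1 + cor)/2)^beta`` with zero diagonal.

    Pearson correlation across samples, optionally on log2(x + 1)
    intensities.  Negative correlations are suppressed toward zero, which is
    what makes the network signed.
    """
    x, ids = _feature_array(data)
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if log2_transform:
        x = np.log2(x + 1.0)
    r = _correlation(x)
    a = ((1.0 + r) / 2.0) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=ids, columns=ids)


@dataclasses.dataclass
class SoftThresholdScan:
    """Scale-free topology scan over a beta grid."""

    scan: pd.DataFrame  # columns: beta, signed_r2, slope, mean_connectivity
    chosen_beta: int | None
    r2_cut: float


def pick_soft_threshold(
    data: FeatureMatrix | pd.DataFrame,
    beta_grid: tuple[int, ...] = tuple(range(1, 31)),
    r2_cut: float = 0.85,
    n_bins: int = 10,
    log2_transform: bool = False,
    min_connectivity: float = 1.0,
) -> SoftThresholdScan:
    """Choose the smallest beta whose signed scale-free fit reaches ``r2_cut``.

    For each beta the connectivities ``k_i = sum_j a_ij`` are binned into
    ``n_bins`` equal-width bins and ``log10(frequency)`` is regressed on
    ``log10(mean k)`` over non-empty bins; the fit is reported as
    ``R^2 * (-sign(slope))`` so that only topologies with the expected
    decreasing tail can qualify.  Betas with fewer than 3 usable bins are
    marked unevaluable (NaN) and never chosen; so are betas whose mean
    connectivity falls below ``min_connectivity`` — at that point the network
    is essentially edgeless and the near-zero connectivities of uncorrelated
    features masquerade as a power-law tail.
    """
    x, ids = _feature_array(data)
    if len(ids) < 30:
        raise ValueError("need at least 30 features for a meaningful scale-free fit")
    if log2_transform:
        x = np.log2(x + 1.0)
    r = _correlation(x)
    base = (1.0 + r) / 2.0
    np.fill_diagonal(base, 0.0)
    rows = []
    chosen = None
    for beta in beta_grid:
        a = base**beta
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        edges = np.linspace(k.min(), k.max(), n_bins + 1)
        which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
        freq, mean_k = [], []
        for b in range(n_bins):
            mask = which == b
            if mask.sum() > 0 and k[mask].mean() > 0:
                freq.append(mask.sum() / len(k))
                mean_k.append(k[mask].mean())
        if len(freq) < 3 or k.mean() < min_connectivity:
            rows.append({"beta": beta, "signed_r2": np.nan, "slope": np.nan,
                         "mean_connectivity": float(k.mean())})
            continue
        lx, ly = np.log10(mean_k), np.log10(freq)
        slope, _, rval, _, _ = sps.linregress(lx, ly)
        signed_r2 = float(rval**2 * (-np.sign(slope)))
        rows.append({"beta": beta, "signed_r2": signed_r2, "slope": float(slope),
                     "mean_connectivity": float(k.mean())})
        if chosen is None and signed_r2 >= r2_cut:
            chosen = int(beta)
    return SoftThresholdScan(pd.DataFrame(rows), chosen, r2_cut)


def topological_overlap(adjacency: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Topological overlap similarity of a symmetric adjacency in [0, 1].

    ``w_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    unit diagonal.
    """
    if isinstance(adjacency, pd.DataFrame):
        ids = list(adjacency.index)
        a = adjacency.to_numpy(float)
    else:
        a = np.asarray(adjacency, float)
        ids = list(range(a.shape[0]))
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    w = (shared + a) / denom
    np.fill_diagonal(w, 1.0)
    return pd.DataFrame(w, index=ids, columns=ids)


@dataclasses.dataclass
class NetworkModules:
    """Feature -> module assignment with eigenfeatures.

    Label 0 (grey) means unassigned; positive labels are ordered by
    decreasing module size and mapped onto the fixed color palette.
    """

    assignment: pd.Series  # feature id -> int label
    module_colors: dict[int, str]
    eigenfeatures: pd.DataFrame  # module (ME<color>) x samples
    var_explained: dict[int, float]
    kme: pd.Series | None = None
    scan: SoftThresholdScan | None = None

    def members(self, label: int) -> list[str]:
        return list(self.assignment.index[self.assignment == label])

    @property
    def labels(self) -> list[int]:
        return sorted(set(self.assignment) - {0})


# ---------------------------------------------------------------------------
# dynamic hybrid branch selection
# ---------------------------------------------------------------------------

def _dynamic_branches(merges: np.ndarray, n_leaves: int, deep_split: int, min_size: int) -> np.ndarray:
    """Select dendrogram branches as modules; return leaf labels (0 = none)."""
    if deep_split not in _DEEP_SPLIT:
        raise ValueError("deep_split must be in 0..4")
    mcs, mg = _DEEP_SPLIT[deep_split]
    heights = merges[:, 2]
    hmax = float(heights.max())
    h5 = float(np.percentile(heights, 5))
    span = max(hmax - h5, 0.0)
    max_scatter = h5 + mcs * span
    min_gap = mg * span

    n_nodes = n_leaves + len(merges)
    size = np.ones(n_nodes)
    parent_height = np.full(n_nodes, np.inf)
    children = {}
    for k, (a, b, h, _s) in enumerate(merges):
        a, b = int(a), int(b)
        node = n_leaves + k
        children[node] = (a, b)
        size[node] = size[a] + size[b]
        parent_height[a] = h
        parent_height[b] = h

    def qualifies(node: int) -> bool:
        if size[node] < min_size or node < n_leaves:
            return False
        own_height = merges[node - n_leaves, 2]
        if not np.isfinite(parent_height[node]):
            return False  # the root (the whole tree) is never one module
        # tightness: the branch must be complete (its last internal merge)
        # below the deepSplit-dependent scatter bound
        gap = parent_height[node] - own_height
        return own_height <= max_scatter and gap >= min_gap

    labels = np.zeros(n_leaves, dtype=int)
    next_label = 1

    def collect(node: int, label: int) -> None:
        stack = [node]
        while stack:
            nd = stack.pop()
            if nd < n_leaves:
                labels[nd] = label
            else:
                stack.extend(children[nd])

    # root-down: a qualifying branch becomes a module and is not split further
    stack = [n_nodes - 1]
    while stack:
        node = stack.pop()
        if node < n_leaves:
            continue
        if qualifies(node):
            collect(node, next_label)
            next_label += 1
        else:
            stack.extend(children[node])
    return labels


def module_eigenfeatures(
    data: FeatureMatrix | pd.DataFrame,
    assignment: pd.Series,
) -> tuple[pd.DataFrame, dict[int, float], pd.DataFrame]:
    """First principal component of each module's standardized members.

    Each member feature is z-scored across samples; the eigenfeature is the
    leading right singular vector (a per-sample profile) scaled to zero mean
    and unit variance and sign-oriented so the mean member correlation is
    positive.  Returns (eigenfeature matrix [module x sample], variance
    explained per module, per-feature kME table).  Constant member features
    are dropped from the PC with a log note.
    """
    x, ids = _feature_array(data)
    if isinstance(data, FeatureMatrix):
        samples = data.sample_ids
    else:
        samples = list(data.columns)
    assignment = assignment.reindex(ids).fillna(0).astype(int)
    eig_rows, var_expl = {}, {}
    for label in sorted(set(assignment) - {0}):
        members = [i for i, f in enumerate(ids) if assignment[f] == label]
        if len(members) < 2:
            raise ValueError(f"module {label} has fewer than 2 members")
        sub = x[members]
        sd = sub.std(axis=1, ddof=0)
        keep = sd > 0
        if not keep.all():
            members = [m for m, k in zip(members, keep) if k]
            sub, sd = sub[keep], sd[keep]
        if sub.shape[0] == 0:
            raise ValueError(f"module {label}: all member features constant")
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        e = vt[0]
        e = (e - e.mean()) / e.std(ddof=0)
        mean_cor = np.mean([np.corrcoef(z[i], e)[0, 1] for i in range(z.shape[0])])
        if mean_cor < 0:
            e = -e
        eig_rows[label] = e
        var_expl[label] = float(s[0] ** 2 / (s**2).sum())
    eig = pd.DataFrame(eig_rows, index=samples).T
    # kME: correlation of every feature with every eigenfeature
    sd_all = x.std(axis=1, ddof=0)
    kme = pd.DataFrame(np.nan, index=ids, columns=list(eig.index))
    ok = sd_all > 0
    if len(eig):
        zx = np.zeros_like(x)
        zx[ok] = (x[ok] - x[ok].mean(axis=1, keepdims=True)) / sd_all[ok, None]
        em = eig.to_numpy()
        ez = (em - em.mean(axis=1, keepdims=True)) / em.std(axis=1, ddof=0)[:, None]
        kme.loc[np.array(ids)[ok]] = (zx[ok] @ ez.T) / x.shape[1]
    return eig, var_expl, kme


def detect_modules(
    data: FeatureMatrix | pd.DataFrame,
    beta: int,
    deep_split: int = 2,
    min_size: int = 10,
    kme_assign_threshold: float = 0.3,
    merge_height: float = 0.25,
    log2_transform: bool = False,
) -> NetworkModules:
    """Detect co-abundance modules by the dynamic hybrid cut of the TOM tree.

    Pipeline: signed adjacency -> TOM dissimilarity -> average-linkage tree
    -> dynamic branch selection (see module docstring) -> size filter ->
    eigenfeature merge (modules whose eigenfeatures are within
    ``merge_height`` on the 1 - cor scale are merged) -> kME assignment of
    leftover features (highest |kME| >= ``kme_assign_threshold``) ->
    relabeling by decreasing size with palette colors.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    x, ids = _feature_array(data)
    adj = signed_adjacency(data, beta, log2_transform=log2_transform)
    tom = topological_overlap(adj)
    diss = 1.0 - tom.to_numpy()
    np.fill_diagonal(diss, 0.0)
    merges = linkage(squareform(diss, checks=False), method="average")
    labels = _dynamic_branches(merges, len(ids), deep_split, min_size)
    assignment = pd.Series(labels, index=ids)
    vals = data.values if isinstance(data, FeatureMatrix) else data
    work = np.log2(vals + 1.0) if log2_transform else vals

    if (assignment > 0).any():
        # merge close modules on the eigenfeature 1 - cor scale
        while True:
            eig, _, _ = module_eigenfeatures(work, assignment)
            if len(eig) < 2:
                break
            cor = np.corrcoef(eig.to_numpy())
            np.fill_diagonal(cor, -np.inf)
            i, j = np.unravel_index(np.argmax(cor), cor.shape)
            if 1.0 - cor[i, j] >= merge_height:
                break
            la, lb = list(eig.index)[i], list(eig.index)[j]
            assignment[assignment == lb] = la

        # kME assignment of unassigned features
        eig, _, kme = module_eigenfeatures(work, assignment)
        grey = assignment.index[assignment == 0]
        for f in grey:
            row = kme.loc[f]
            if row.isna().all():
                continue
            best = row.abs().idxmax()
            if abs(row[best]) >= kme_assign_threshold:
                assignment[f] = int(best)

    # relabel by decreasing size, assign colors
    counts = assignment[assignment > 0].value_counts()
    relabel = {old: new + 1 for new, old in enumerate(counts.index)}
    assignment = assignment.map(lambda v: relabel.get(v, 0)).astype(int)
    colors = {0: "grey"}
    for new_label in sorted(relabel.values()):
        colors[new_label] = MODULE_COLORS[(new_label - 1) % len(MODULE_COLORS)]
    if (assignment > 0).any():
        eig, var_expl, kme = module_eigenfeatures(work, assignment)
        eig.index = [f"ME{colors[l]}" for l in eig.index]
        kme_best = pd.Series(
            [kme.loc[f, assignment[f]] if assignment[f] > 0 else np.nan for f in assignment.index],
            index=assignment.index,
        )
    else:
        sample_cols = data.sample_ids if isinstance(data, FeatureMatrix) else list(data.columns)
        eig = pd.DataFrame(index=pd.Index([], dtype=object), columns=sample_cols)
        var_expl = {}
        kme_best = pd.Series(np.nan, index=assignment.index)
    return NetworkModules(assignment, colors, eig, var_expl, kme=kme_best)


def module_trait_association(
    eigenfeatures: pd.DataFrame,
    trait: pd.Series | np.ndarray,
    covariate: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Spearman (and covariate-adjusted partial Spearman) per eigenfeature.

    The partial coefficient is the partial Pearson correlation on ranks,
    ``r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))``, with a
    t-approximation p on n - 3 df.  Degenerate denominators are flagged NA
    with a reason.
    """
    trait = np.asarray(trait, float)
    n = len(trait)
    if eigenfeatures.shape[1] != n:
        raise ValueError("trait length does not match eigenfeature samples")
    cov = None if covariate is None else np.asarray(covariate, float)
    if cov is not None and n < 5:
        raise ValueError("partial correlation needs n >= 5")
    rt = sps.rankdata(trait)
    rc = sps.rankdata(cov) if cov is not None else None
    rows = []
    for me in eigenfeatures.index:
        e = eigenfeatures.loc[me].to_numpy(float)
        r, p = sps.spearmanr(e, trait)
        row = {"module": me, "spearman_r": float(r), "spearman_p": float(p),
               "partial_r": np.nan, "partial_p": np.nan, "partial_note": ""}
        if cov is not None:
            re_ = sps.rankdata(e)
            r_xy = np.corrcoef(re_, rt)[0, 1]
            r_xz = np.corrcoef(re_, rc)[0, 1]
            r_yz = np.corrcoef(rt, rc)[0, 1]
            denom_sq = (1 - r_xz**2) * (1 - r_yz**2)
            if denom_sq <= 1e-12:
                row["partial_note"] = "covariate perfectly rank-correlated with trait or eigenfeature"
            else:
                pr = (r_xy - r_xz * r_yz) / np.sqrt(denom_sq)
                pr = float(np.clip(pr, -1.0, 1.0))
                df = n - 3
                if abs(pr) >= 1.0:
                    pp = 0.0
                else:
                    tstat = pr * np.sqrt(df / (1 - pr**2))
                    pp = float(2 * sps.t.sf(abs(tstat), df))
                row["partial_r"], row["partial_p"] = pr, pp
        rows.append(row)
    return pd.DataFrame(rows).set_index("module")
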