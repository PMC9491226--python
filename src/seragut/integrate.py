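"""Cross-domain integration of the metabolome and the gut metagenome.

Three levels of integration:

1. **Ordination congruence** — symmetric Procrustes superimposition of the
   two-dimensional PCA shapes of the two omics (residual ``M^2``; reflections
   allowed) with a PROTEST row-permutation test of significance.
2. **Differential-feature correlation** — all-pairs Spearman correlations
   between screened differential taxa and metabolites, BH-FDR adjusted.
3. **Background-adjusted module-cluster map** — for KEGG modules selected by
   a member-versus-background Wilcoxon test of per-KO trait correlations and
   metabolite clusters selected by (BMI-adjusted) eigenfeature-trait
   correlation, the association strength is the median in-module KO-cluster
   Spearman coefficient minus the median over all KOs (SCCbg.adj), with a
   member-versus-non-member Wilcoxon p and BH-FDR marks.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_tables import FeatureMatrix, KoModuleMap
from .stats import bh_fdr, wilcoxon_rank_sum

__all__ = [
    "ProcrustesFit",
    "procrustes_m2",
    "protest",
    "correlate_differential",
    "ko_phenotype_module_test",
    "crossdomain_map",
]


@dataclasses.dataclass
class ProcrustesFit:
    """Symmetric Procrustes superimposition result.

    ``m2`` is the residual sum of squares after optimal translation,
    rotation (reflections allowed) and scaling of unit-norm centered
    configurations; 0 means identical shapes.
    """

    m2: float
    rotation: np.ndarray
    scale: float
    translation: np.ndarray
    protest_p: float | None = None
    n_perm: int = 0
    note: str = ""


def _standardize_configuration(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    mu = x.mean(axis=0)
    xc = x - mu
    norm = np.sqrt((xc**2).sum())
    if norm == 0:
        raise ValueError("zero-variance configuration")
    return xc / norm, mu, norm


def procrustes_m2(x: np.ndarray | pd.DataFrame, y: np.ndarray | pd.DataFrame) -> ProcrustesFit:
    """Symmetric Procrustes: center, scale to unit sum of squares, rotate.

    With ``X' Y = U S V^T`` of the standardized configurations, the optimal
    rotation (full orthogonal group, reflections allowed) gives
    ``m2 = 1 - (trace S)^2``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("configurations must have the same number of rows")
    if x.shape[0] < x.shape[1] or y.shape[0] < y.shape[1]:
        raise ValueError("fewer rows (samples) than columns (axes)")
    xs, xmu, xnorm = _standardize_configuration(x)
    ys, ymu, ynorm = _standardize_configuration(y)
    if xs.shape[1] != ys.shape[1]:
        k = max(xs.shape[1], ys.shape[1])
        xs = np.pad(xs, ((0, 0), (0, k - xs.shape[1])))
        ys = np.pad(ys, ((0, 0), (0, k - ys.shape[1])))
    u, s, vt = np.linalg.svd(xs.T @ ys)
    rotation = u @ vt  # x @ rotation maps X onto Y (reflections allowed)
    trace = float(s.sum())
    m2 = max(0.0, 1.0 - trace**2)
    scale = trace * ynorm / xnorm
    translation = ymu - scale * (xmu @ rotation) if xmu.shape == ymu.shape else ymu
    return ProcrustesFit(m2=m2, rotation=rotation, scale=scale, translation=translation)


def protest(
    x: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> ProcrustesFit:
    """Permutation test of Procrustes concordance.

    Rows of ``Y`` are permuted ``n_perm`` times;
    ``p = (1 + #{m2_perm <= m2_obs}) / (1 + n_perm)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    fit = procrustes_m2(x, y)
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if procrustes_m2(x, y[perm]).m2 <= fit.m2:
            count += 1
    fit.protest_p = (1 + count) / (1 + n_perm)
    fit.n_perm = n_perm
    if n < 5:
        fit.note = "fewer than 5 rows: permutation p is unreliable"
    return fit


def _spearman_with_exact_p(va: np.ndarray, vb: np.ndarray, exact_max_n: int = 8) -> tuple[float, float, str]:
    """Spearman r with an exact permutation p for small n.

    For ``n <= exact_max_n`` the two-sided p is the fraction of the n!
    permutations of one rank vector with ``|r_perm| >= |r_obs|``; beyond
    that, the usual t-approximation.
    """
    import itertools

    n = len(va)
    r = float(sps.spearmanr(va, vb).statistic)
    if n > exact_max_n:
        return r, float(sps.spearmanr(va, vb).pvalue), "t approximation"
    ra = sps.rankdata(va)
    rb = sps.rankdata(vb)
    ra = (ra - ra.mean()) / ra.std(ddof=0)
    rb = (rb - rb.mean()) / rb.std(ddof=0)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r_perm = float(np.mean(ra[list(perm)] * rb))
        total += 1
        if abs(r_perm) >= abs(r) - 1e-12:
            count += 1
    return r, count / total, "exact permutation"


def correlate_differential(
    features_a: FeatureMatrix,
    features_b: FeatureMatrix,
    exact_max_n: int = 8,
) -> pd.DataFrame:
    """All-pairs Spearman correlation between two differential feature sets.

    Both matrices must share samples (intersection taken, order aligned).
    For ``<= exact_max_n`` shared samples p-values are exact by rank-
    permutation enumeration.  Constant vectors yield NA with a reason;
    BH-FDR across defined pairs.
    """
    shared = [s for s in features_a.sample_ids if s in set(features_b.sample_ids)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    a = features_a.values[shared]
    b = features_b.values[shared]
    rows = []
    for fa in a.index:
        va = a.loc[fa].to_numpy(float)
        for fb in b.index:
            vb = b.loc[fb].to_numpy(float)
            if np.all(va == va[0]) or np.all(vb == vb[0]):
                rows.append({"feature_a": fa, "feature_b": fb, "spearman_r": np.nan,
                             "p_value": np.nan, "note": "constant vector"})
                continue
            r, p, note = _spearman_with_exact_p(va, vb, exact_max_n=exact_max_n)
            rows.append({"feature_a": fa, "feature_b": fb, "spearman_r": r,
                         "p_value": p, "note": note})
    out = pd.DataFrame(rows)
    ok = out["p_value"].notna()
    out["q_value"] = np.nan
    if ok.any():
        out.loc[ok, "q_value"] = bh_fdr(out.loc[ok, "p_value"].to_numpy())
    return out


def _ko_trait_correlations(ko: FeatureMatrix, trait: np.ndarray) -> pd.Series:
    x = ko.values.to_numpy(float)
    r = np.full(x.shape[0], np.nan)
    rt = sps.rankdata(trait)
    rt = (rt - rt.mean()) / rt.std(ddof=0)
    for i in range(x.shape[0]):
        if np.all(x[i] == x[i, 0]):
            continue
        ri = sps.rankdata(x[i])
        ri = (ri - ri.mean()) / ri.std(ddof=0)
        r[i] = float(np.mean(ri * rt))
    return pd.Series(r, index=ko.feature_ids)


def ko_phenotype_module_test(
    ko: FeatureMatrix,
    trait: pd.Series | np.ndarray,
    module_map: KoModuleMap,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon member-vs-background test of KO-trait correlations per module.

    Each KO's Spearman correlation with the trait is computed; a module is
    selected when the rank-sum test of member versus non-member correlations
    has p < ``alpha``.  Direction is the sign of the difference in median
    correlation.  Modules with fewer than 2 KOs present (or fewer than 2
    outside) are skipped/raise respectively.
    """
    trait = np.asarray(trait, float)
    if len(trait) != len(ko.sample_ids):
        raise ValueError("trait length does not match KO samples")
    r_all = _ko_trait_correlations(ko, trait)
    rows = []
    ko_set = set(ko.feature_ids)
    for mid in module_map:
        members = sorted(module_map[mid] & ko_set)
        if len(members) < 2:
            rows.append({"module": mid, "n_members": len(members), "direction": 0,
                         "p_value": np.nan, "selected": False, "note": "fewer than 2 member KOs"})
            continue
        non_members = sorted(ko_set - set(members))
        if len(non_members) < 2:
            raise ValueError(f"module {mid!r} covers (nearly) all KOs: empty background")
        rm = r_all[members].dropna().to_numpy()
        rb = r_all[non_members].dropna().to_numpy()
        res = wilcoxon_rank_sum(rm, rb, exact_max_n=0)
        direction = int(np.sign(np.median(rm) - np.median(rb)))
        rows.append({"module": mid, "n_members": len(members), "direction": direction,
                     "p_value": res.p_value, "selected": bool(res.p_value < alpha), "note": ""})
    return pd.DataFrame(rows).set_index("module")


def _fdr_mark(q: float, levels: tuple[float, float, float]) -> str:
    if q < levels[2]:
        return "q<0.01"
    if q < levels[1]:
        return "q<0.05"
    if q < levels[0]:
        return "q<0.1"
    return "none"


def crossdomain_map(
    ko: FeatureMatrix,
    eigenfeatures: pd.DataFrame,
    module_map: KoModuleMap,
    trait: pd.Series | np.ndarray,
    covariate: pd.Series | np.ndarray | None = None,
    alpha: float = 0.05,
    fdr_levels: tuple[float, float, float] = (0.1, 0.05, 0.01),
    require_partial: bool = True,
) -> dict:
    """Background-adjusted KEGG-module x metabolite-cluster association map.

    Selection: KEGG modules by :func:`ko_phenotype_module_test` on the trait;
    metabolite clusters by eigenfeature-trait Spearman p < ``alpha`` and
    (when a covariate is given and ``require_partial``) covariate-adjusted
    partial p < ``alpha``.  For every selected (module, cluster) pair the
    per-KO Spearman correlations with the cluster eigenfeature give

    * ``scc_bg_adj`` = median(member correlations) - median(all-KO
      correlations) — the background-adjusted effect,
    * a member-vs-non-member Wilcoxon p, BH-FDR adjusted across the
      populated cells, with significance marks at the ``fdr_levels``.

    Returns a dict with keys ``map`` (long-format DataFrame),
    ``module_selection``, ``cluster_selection`` and ``status``.
    """
    from .netcluster import module_trait_association

    module_sel = ko_phenotype_module_test(ko, trait, module_map, alpha=alpha)
    cluster_assoc = module_trait_association(eigenfeatures, trait, covariate)
    sel = cluster_assoc["spearman_p"] < alpha
    if covariate is not None and require_partial:
        sel &= cluster_assoc["partial_p"] < alpha
    cluster_assoc["selected"] = sel

    selected_modules = [m for m in module_sel.index if module_sel.loc[m, "selected"]]
    selected_clusters = [c for c in cluster_assoc.index if cluster_assoc.loc[c, "selected"]]
    if not selected_modules or not selected_clusters:
        return {
            "map": pd.DataFrame(
                columns=["kegg_module", "metabolite_cluster", "scc_bg_adj",
                         "wilcoxon_p", "fdr_q", "mark"]
            ),
            "module_selection": module_sel,
            "cluster_selection": cluster_assoc,
            "status": "no selected modules and/or clusters",
        }

    ko_set = set(ko.feature_ids)
    rows = []
    for cid in selected_clusters:
        e = eigenfeatures.loc[cid].to_numpy(float)
        r_all = _ko_trait_correlations(ko, e)
        med_all = float(np.nanmedian(r_all))
        for mid in selected_modules:
            members = sorted(module_map[mid] & ko_set)
            rm = r_all[members].dropna().to_numpy()
            rb = r_all[sorted(ko_set - set(members))].dropna().to_numpy()
            res = wilcoxon_rank_sum(rm, rb, exact_max_n=0)
            rows.append({
                "kegg_module": mid,
                "metabolite_cluster": cid,
                "scc_bg_adj": float(np.median(rm)) - med_all,
                "wilcoxon_p": res.p_value,
            })
    cmap = pd.DataFrame(rows)
    cmap["fdr_q"] = bh_fdr(cmap["wilcoxon_p"].to_numpy())
    cmap["mark"] = [_fdr_mark(q, fdr_levels) for q in cmap["fdr_q"]]
    return {
        "map": cmap,
        "module_selection": module_sel,
        "cluster_selection": cluster_assoc,
        "status": "ok",
    }
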