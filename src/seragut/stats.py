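"""Univariate tests, the composite metabolite screen, FDR and ORA.

The exact small-sample paths (Fisher 2x2, Wilcoxon rank-sum and signed-rank)
are implemented by enumeration of the null distribution; large samples fall
back to the standard normal approximations with tie and continuity
corrections.  The composite differential-metabolite screen combines a PLS-DA
VIP score, a log2 fold change on the normalized intensity scale and a
(paired) t-test p-value; a feature passes only if all three criteria hold
(default VIP > 1, |log2FC| >= 0.25, p < 0.05).
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io_tables import FeatureMatrix
from .multivariate import plsda_fit, vip_scores

__all__ = [
    "TestResult",
    "welch_t",
    "welch_t_summary",
    "paired_t",
    "fisher_exact_2x2",
    "chi_square_2x2",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "kruskal_wallis",
    "bh_fdr",
    "screen_differential",
    "ora_hypergeometric",
]


@dataclasses.dataclass
class TestResult:
    statistic: float
    p_value: float
    df: float | None = None
    degenerate: bool = False
    note: str = ""


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------

def welch_t_summary(n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float) -> TestResult:
    """Welch's unequal-variance t-test from group summaries."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if v1 + v2 == 0:
        if mean1 == mean2:
            return TestResult(0.0, 1.0, df=float(n1 + n2 - 2), degenerate=True)
        return TestResult(math.inf, 0.0, df=float(n1 + n2 - 2), degenerate=True,
                          note="zero variance with unequal means")
    t = (mean1 - mean2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(t, float(p), df=float(df))


def welch_t(x=None, y=None, **summary) -> TestResult:
    """Welch t-test from raw vectors, or delegate to the summary form.

    ``welch_t(x, y)`` computes group summaries internally (sample SD, n-1
    denominator); ``welch_t(n1=..., mean1=..., sd1=..., n2=..., mean2=...,
    sd2=...)`` is equivalent to :func:`welch_t_summary`.
    """
    if y is None:
        return welch_t_summary(**summary)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return welch_t_summary(
        len(x), float(x.mean()), float(x.std(ddof=1)),
        len(y), float(y.mean()), float(y.std(ddof=1)),
    )


def paired_t(pre: Sequence, post: Sequence) -> TestResult:
    """Paired t-test: one-sample t on the differences, df = n - 1."""
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape:
        raise ValueError("paired vectors must have equal length")
    d = pre - post
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0:
        if mean == 0:
            return TestResult(0.0, 1.0, df=float(n - 1), degenerate=True)
        return TestResult(math.inf, 0.0, df=float(n - 1), degenerate=True,
                          note="all differences equal and nonzero")
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return TestResult(float(t), float(p), df=float(n - 1))


# ---------------------------------------------------------------------------
# exact categorical / rank tests
# ---------------------------------------------------------------------------

def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with the observed margins
    whose probability is at most that of the observed table (relative
    tolerance 1e-7 for ties).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0
    rv = sps.hypergeom(n, r1, c1)
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-7)].sum()))


def chi_square_2x2(a: int, b: int, c: int, d: int, correction: bool = False) -> float:
    """Pearson chi-square p for a 2x2 table (provided for comparison)."""
    chi2, p, _, _ = sps.chi2_contingency([[a, b], [c, d]], correction=correction)
    return float(p)


def _rank(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values)


def wilcoxon_rank_sum(x: Sequence, y: Sequence, exact_max_n: int = 16) -> TestResult:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test.

    Exact enumeration of all rank splits when ``len(x) + len(y) <=
    exact_max_n`` and there are no ties; otherwise the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    n1, n2 = len(x), len(y)
    if n1 + n2 <= exact_max_n and not has_ties:
        ranks = _rank(pooled)
        w_obs = ranks[:n1].sum()
        all_ranks = np.arange(1, n1 + n2 + 1)
        sums = np.array([sum(c) for c in itertools.combinations(all_ranks, n1)], float)
        lower = float((sums <= w_obs).mean())
        upper = float((sums >= w_obs).mean())
        p = min(1.0, 2.0 * min(lower, upper))
        return TestResult(float(w_obs), p, note="exact")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=True)
    return TestResult(float(res.statistic), float(res.pvalue), note="normal approximation")


def wilcoxon_signed_rank(pre: Sequence, post: Sequence, exact_max_n: int = 12) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test; zero differences dropped.

    Exact enumeration of the 2^n sign assignments for n <= ``exact_max_n``
    remaining pairs, otherwise the normal approximation with continuity
    correction.
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape:
        raise ValueError("paired vectors must have equal length")
    d = pre - post
    n_zero = int((d == 0).sum())
    d = d[d != 0]
    n = len(d)
    note = f"dropped {n_zero} zero differences" if n_zero else ""
    if n == 0:
        return TestResult(0.0, 1.0, degenerate=True, note=note or "all differences zero")
    ranks = _rank(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        sums = np.array(
            [ranks[list(signs)].sum() for k in range(n + 1) for signs in itertools.combinations(range(n), k)]
        )
        lower = float((sums <= w_plus).mean())
        upper = float((sums >= w_plus).mean())
        p = min(1.0, 2.0 * min(lower, upper))
        return TestResult(w_plus, p, note=(note + "; exact").strip("; "))
    mean = n * (n + 1) / 4.0
    # variance with tie correction over midranks
    _, counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (counts**3 - counts).sum() / 48.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(w_plus, float(min(1.0, p)), note=(note + "; normal approximation").strip("; "))


def kruskal_wallis(groups: Sequence[Sequence]) -> TestResult:
    """Kruskal-Wallis H with tie correction; p from chi-squared (k-1 df)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, df=float(len(groups) - 1), degenerate=True)
    h, p = sps.kruskal(*arrays)
    return TestResult(float(h), float(p), df=float(len(groups) - 1))


# ---------------------------------------------------------------------------
# multiple testing / enrichment
# ---------------------------------------------------------------------------

def bh_fdr(p_values: Sequence) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (order preserving)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora_hypergeometric(
    selected: set,
    annotation_sets: dict,
    universe: set,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per annotation set.

    ``p = P(X >= overlap)`` under ``Hypergeom(|universe|, |set|, |selected|)``
    after intersecting each set with the universe; BH q-values appended.
    """
    if not universe:
        raise ValueError("empty universe")
    if not set(selected) <= set(universe):
        raise ValueError("selected features must be a subset of the universe")
    rows = []
    m = len(universe)
    n_sel = len(selected)
    for set_id, members in annotation_sets.items():
        members = set(members) & set(universe)
        overlap = len(members & set(selected))
        if n_sel == 0 or not members:
            p = 1.0
        else:
            p = float(sps.hypergeom.sf(overlap - 1, m, len(members), n_sel))
        rows.append({"set_id": set_id, "set_size": len(members), "overlap": overlap, "p_value": p})
    out = pd.DataFrame(rows).set_index("set_id")
    out["q_value"] = bh_fdr(out["p_value"].to_numpy()) if len(out) else []
    return out


# ---------------------------------------------------------------------------
# the composite screen
# ---------------------------------------------------------------------------

def screen_differential(
    fm: FeatureMatrix,
    labels: Sequence,
    paired: bool = False,
    subjects: Sequence | None = None,
    vip_threshold: float = 1.0,
    lfc_threshold: float = 0.25,
    alpha: float = 0.05,
    n_components: int = 2,
) -> pd.DataFrame:
    """Composite differential screen: VIP > t1 AND |log2FC| >= t2 AND p < t3.

    ``labels`` is a two-class vector aligned with the matrix samples.  The
    log2 fold change is the ratio of arithmetic group means of the normalized
    intensities (class A = first label in sorted order, over class B);
    p-values come from Welch's t (unpaired) or the paired t on
    subject-matched samples (``subjects`` required when ``paired``).
    Features with a non-positive group mean are excluded and flagged.
    """
    labels = np.asarray(labels)
    classes = sorted(pd.unique(labels).tolist())
    if len(classes) != 2:
        raise ValueError(f"screen needs exactly two classes, got {classes}")
    model = plsda_fit(fm, labels, n_components=n_components)
    vip = vip_scores(model)

    x = fm.values.to_numpy(float)
    mask_a = labels == classes[0]
    mask_b = labels == classes[1]
    rows = []
    for i, fid in enumerate(fm.feature_ids):
        xa, xb = x[i, mask_a], x[i, mask_b]
        ma, mb = xa.mean(), xb.mean()
        if ma <= 0 or mb <= 0:
            rows.append(
                {"feature_id": fid, "vip": float(vip[fid]), "log2fc": np.nan,
                 "p_value": np.nan, "passes": False, "direction": "na", "excluded": True}
            )
            continue
        log2fc = math.log2(ma / mb)
        if paired:
            if subjects is None:
                raise ValueError("paired screen requires subject ids")
            subj = np.asarray(subjects)
            order_a = np.argsort(subj[mask_a])
            order_b = np.argsort(subj[mask_b])
            if not np.array_equal(np.sort(subj[mask_a]), np.sort(subj[mask_b])):
                raise ValueError("paired screen requires matching subjects in both classes")
            res = paired_t(xa[order_a], xb[order_b])
        else:
            res = welch_t(xa, xb)
        passes = (
            float(vip[fid]) > vip_threshold
            and abs(log2fc) >= lfc_threshold
            and res.p_value < alpha
        )
        rows.append(
            {
                "feature_id": fid,
                "vip": float(vip[fid]),
                "log2fc": log2fc,
                "p_value": res.p_value,
                "passes": bool(passes),
                "direction": f"up_in_{classes[0]}" if log2fc > 0 else f"up_in_{classes[1]}",
                "excluded": False,
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")
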