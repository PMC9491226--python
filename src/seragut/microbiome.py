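"""Alpha diversity and the LDA-effect-size (LEfSe) discriminant-taxa screen.

The LEfSe screen is the two-class form of the procedure: a Kruskal-Wallis
pre-filter (default p < 0.05) on per-million-scaled features, then a
bootstrapped two-class Fisher linear discriminant whose per-feature effect
sizes are averaged over subsamples and reported on a signed log10 scale.
A feature is called discriminant when ``|lda_score| >= 2`` (the conventional
cutoff) and its stage-1 p-value passes.  The subclass (one-against-all)
stage of the original procedure is omitted: two-group designs have no
subclasses.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .io_tables import FeatureMatrix, RANK_ORDER
from .stats import kruskal_wallis

__all__ = ["alpha_diversity", "lefse", "concat_rank_matrices", "expand_clades"]


def expand_clades(species: FeatureMatrix) -> dict[str, FeatureMatrix]:
    """Sum a species-level clade table up to every higher taxonomy rank.

    Feature ids must be full pipe-delimited clade strings; the result maps
    each rank to a matrix keyed by the truncated clade string, with
    abundances summed over descendants.
    """
    out: dict[str, FeatureMatrix] = {}
    n_ranks = {r: i + 1 for i, r in enumerate(RANK_ORDER)}
    for rank, depth in n_ranks.items():
        grouped: dict[str, np.ndarray] = {}
        for fid in species.feature_ids:
            parts = str(fid).split("|")
            if len(parts) < depth:
                continue
            key = "|".join(parts[:depth])
            row = species.values.loc[fid].to_numpy(float)
            grouped[key] = grouped.get(key, 0) + row
        if not grouped:
            continue
        df = pd.DataFrame(grouped, index=species.sample_ids).T
        meta = pd.DataFrame(
            {"taxonomy_rank": rank, "display_name": [k.split("|")[-1][3:] for k in df.index]},
            index=df.index,
        )
        out[rank] = FeatureMatrix(df, meta)
    return out


def alpha_diversity(abundances: Sequence, index: str = "shannon") -> float:
    """Within-sample diversity of one relative-abundance vector.

    ``shannon`` = -sum p ln p, ``simpson`` = 1 - sum p^2 (Gini-Simpson),
    ``observed`` = count of entries > 0.  For shannon/simpson the vector is
    renormalized to sum 1 over its nonzero entries.
    """
    p = np.asarray(abundances, float)
    if np.any(p < 0):
        raise ValueError("abundances must be non-negative")
    if p.sum() == 0:
        raise ValueError("all-zero abundance vector")
    if index == "observed":
        return float((p > 0).sum())
    p = p[p > 0]
    p = p / p.sum()
    if index == "shannon":
        return float(-(p * np.log(p)).sum())
    if index == "simpson":
        return float(1.0 - (p**2).sum())
    raise ValueError(f"unknown diversity index {index!r}")


def concat_rank_matrices(rank_matrices: dict[str, FeatureMatrix]) -> FeatureMatrix:
    """Stack per-rank taxon matrices into one clade x sample matrix.

    Used to run the discriminant screen across all taxonomy ranks at once
    (each clade is a feature), the way multi-rank biomarker reports are made.
    """
    frames, metas = [], []
    for rank in RANK_ORDER:
        if rank in rank_matrices:
            frames.append(rank_matrices[rank].values)
            metas.append(rank_matrices[rank].feature_meta)
    if not frames:
        raise ValueError("no rank matrices supplied")
    return FeatureMatrix(pd.concat(frames), pd.concat(metas))


@dataclasses.dataclass
class LefseRecord:
    feature_id: str
    kw_p: float
    lda_score: float
    enriched_class: str
    passes: bool


def lefse(
    fm: FeatureMatrix,
    classes: Sequence,
    kw_alpha: float = 0.05,
    n_boot: int = 30,
    boot_fraction: float = 2.0 / 3.0,
    lda_threshold: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-class LEfSe screen; returns one record per stage-1 survivor.

    Samples are scaled to a per-sample total of 1e6 internally, so the screen
    is invariant to a global rescaling of the raw counts.  For each of
    ``n_boot`` subsamples (fraction ``boot_fraction`` per class, without
    replacement) a ridge-regularized Fisher discriminant is fitted on the
    retained features; the per-feature effect is the average of the weighted
    discriminant contribution and the raw class-mean difference, averaged
    over bootstraps, and reported as ``sign(m1 - m2) * log10(1 + effect)``.
    """
    classes = np.asarray(classes)
    labels = sorted(pd.unique(classes).tolist())
    if len(labels) != 2:
        raise ValueError(f"need exactly two classes, got {labels}")
    idx_a = np.where(classes == labels[0])[0]
    idx_b = np.where(classes == labels[1])[0]
    if min(len(idx_a), len(idx_b)) < 3:
        raise ValueError("each class needs >= 3 samples")
    rng = np.random.default_rng(seed)

    x = fm.values.to_numpy(float)
    totals = x.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("sample with zero total abundance")
    x = x / totals * 1e6  # per-million scaling

    # stage 1: Kruskal-Wallis per feature
    kw_p = np.array(
        [kruskal_wallis([x[i, idx_a], x[i, idx_b]]).p_value for i in range(x.shape[0])]
    )
    retained = np.where(kw_p < kw_alpha)[0]
    if retained.size == 0:
        return pd.DataFrame(
            columns=["kw_p", "lda_score", "enriched_class", "passes"]
        ).rename_axis("feature_id")

    xr = x[retained]
    p = xr.shape[0]
    n_a = max(2, int(round(boot_fraction * len(idx_a))))
    n_b = max(2, int(round(boot_fraction * len(idx_b))))
    effects = np.zeros(p)
    n_used = 0
    for _ in range(n_boot):
        sa = rng.choice(idx_a, size=n_a, replace=False)
        sb = rng.choice(idx_b, size=n_b, replace=False)
        m1 = xr[:, sa].mean(axis=1)
        m2 = xr[:, sb].mean(axis=1)
        centered_a = xr[:, sa] - m1[:, None]
        centered_b = xr[:, sb] - m2[:, None]
        sw = (centered_a @ centered_a.T + centered_b @ centered_b.T) / max(n_a + n_b - 2, 1)
        lam = 1e-6 * np.trace(sw) / p
        try:
            w = np.linalg.solve(sw + lam * np.eye(p), m1 - m2)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("singular within-class covariance even after ridge") from exc
        norm = np.linalg.norm(w)
        if norm == 0:
            continue
        w = w / norm
        effect_size = abs(float(w @ (m1 - m2)))
        effects += (np.abs(w) * effect_size + np.abs(m1 - m2)) / 2.0
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable bootstrap iterations")
    effects /= n_used

    m1_full = x[retained][:, idx_a].mean(axis=1)
    m2_full = x[retained][:, idx_b].mean(axis=1)
    sign = np.sign(m1_full - m2_full)
    scores = sign * np.log10(1.0 + effects)
    rows = []
    for j, i in enumerate(retained):
        enriched = labels[0] if sign[j] >= 0 else labels[1]
        rows.append(
            {
                "feature_id": fm.feature_ids[i],
                "kw_p": float(kw_p[i]),
                "lda_score": float(scores[j]),
                "enriched_class": enriched,
                "passes": bool(kw_p[i] < kw_alpha and abs(scores[j]) >= lda_threshold),
            }
        )
    out = pd.DataFrame(rows).set_index("feature_id")
    return out.reindex(out["lda_score"].abs().sort_values(ascending=False).index)
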