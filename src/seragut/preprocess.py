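"""Metabolomics feature-table preprocessing.

The fixed stage order is

1. probabilistic quotient normalization (PQN) — per-sample dilution
   correction against a reference spectrum (median over QC injections by
   default),
2. QC-based robust LOESS signal correction (QC-RSC) — per-feature,
   per-batch drift curves fitted on the QC injections over run order,
3. QC coefficient-of-variation filter (default: drop features with
   CV > 30% across QC injections),
4. annotation filter — keep only features carrying an annotation class.

Each stage returns the corrected/filtered matrix plus a
:class:`PreprocessReport` recording dilution factors, dropped features and
per-stage feature counts.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io_tables import FeatureMatrix

__all__ = [
    "PreprocessReport",
    "pqn_normalize",
    "qc_rsc_correct",
    "qc_cv_filter",
    "annotation_filter",
    "run_preprocessing",
]


@dataclasses.dataclass
class PreprocessReport:
    """Bookkeeping for one or more preprocessing stages."""

    dilution_factors: pd.Series | None = None
    dropped_cv: dict[str, float] = dataclasses.field(default_factory=dict)
    dropped_unannotated: list[str] = dataclasses.field(default_factory=list)
    rsc_fallback_features: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    stages: list[dict] = dataclasses.field(default_factory=list)

    def record_stage(self, name: str, n_in: int, n_out: int) -> None:
        self.stages.append({"stage": name, "features_in": n_in, "features_out": n_out})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)


def _qc_columns(fm: FeatureMatrix, info: pd.DataFrame) -> list[str]:
    qc = [sid for sid in fm.sample_ids if sid in info.index and bool(info.loc[sid, "is_qc"])]
    return qc


# ---------------------------------------------------------------------------
# 1. PQN
# ---------------------------------------------------------------------------

def pqn_normalize(
    fm: FeatureMatrix,
    info: pd.DataFrame | None = None,
    reference_policy: str = "qc_median",
    report: PreprocessReport | None = None,
) -> tuple[FeatureMatrix, PreprocessReport]:
    """Probabilistic quotient normalization.

    The reference spectrum is the per-feature median over the reference
    samples (QC injections for ``qc_median``, all samples for ``all_median``).
    Each sample is divided by the median of its feature-wise quotients
    against the reference, computed over features with a positive reference
    value.  Factors are recorded in the report.
    """
    if reference_policy not in ("qc_median", "all_median"):
        raise ValueError(f"unknown reference policy {reference_policy!r}")
    if report is None:
        report = PreprocessReport()
    values = fm.values
    if reference_policy == "qc_median":
        if info is None:
            raise ValueError("qc_median reference requires sample info")
        ref_cols = _qc_columns(fm, info)
        if not ref_cols:
            raise ValueError("no QC samples available for the qc_median reference")
    else:
        ref_cols = list(values.columns)
    reference = values[ref_cols].median(axis=1)
    usable = reference > 0
    if not usable.any():
        raise ValueError("reference spectrum is zero everywhere")
    factors = {}
    out = values.copy()
    ref = reference[usable]
    for sid in values.columns:
        quotients = values.loc[usable.index[usable], sid] / ref
        quotients = quotients[np.isfinite(quotients)]
        if quotients.empty:
            raise ValueError(f"sample {sid!r} has no usable quotients against the reference")
        f = float(quotients.median())
        if f <= 0:
            raise ValueError(f"sample {sid!r} has non-positive dilution factor {f}")
        factors[sid] = f
        out[sid] = values[sid] / f
    report.dilution_factors = pd.Series(factors)
    report.record_stage("pqn", fm.shape[0], fm.shape[0])
    return fm.with_values(out), report


# ---------------------------------------------------------------------------
# 2. QC-RSC
# ---------------------------------------------------------------------------

def qc_rsc_correct(
    fm: FeatureMatrix,
    info: pd.DataFrame,
    span: float = 0.75,
    robust_iters: int = 2,
    report: PreprocessReport | None = None,
) -> tuple[FeatureMatrix, PreprocessReport]:
    """QC-based robust LOESS signal correction.

    Per feature and batch, a robust locally weighted degree-1 regression
    (tricube weights, Tukey-bisquare reweighting for ``robust_iters``
    iterations) of QC intensity on injection order is fitted, evaluated at
    every injection order by linear interpolation between the QC fits
    (clamped to the nearest QC fit outside the QC range), and the raw values
    are divided by the curve and rescaled to the batch QC median.  A feature
    whose fitted curve is non-positive anywhere falls back to median-only
    correction (identity) and is logged.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if report is None:
        report = PreprocessReport()
    values = fm.values
    out = values.copy().astype(float)
    cols_in_info = [c for c in values.columns if c in info.index]
    if len(cols_in_info) != len(values.columns):
        missing = set(values.columns) - set(cols_in_info)
        raise ValueError(f"samples missing from metadata: {sorted(missing)[:3]}")
    for batch, binfo in info.loc[cols_in_info].groupby("batch"):
        cols = [c for c in values.columns if c in binfo.index]
        order = binfo.loc[cols, "injection_order"].to_numpy(float)
        is_qc = binfo.loc[cols, "is_qc"].to_numpy(bool)
        if is_qc.sum() < 4:
            raise ValueError(f"batch {batch!r} has {int(is_qc.sum())} QC injections; need >= 4")
        qc_order = order[is_qc]
        sort_idx = np.argsort(qc_order)
        qc_order_sorted = qc_order[sort_idx]
        sub = values[cols].to_numpy(float)
        for i, fid in enumerate(values.index):
            qc_y = sub[i, is_qc][sort_idx]
            med = float(np.median(qc_y))
            fitted_qc = lowess(
                qc_y, qc_order_sorted, frac=span, it=robust_iters, return_sorted=False
            )
            if not np.all(np.isfinite(fitted_qc)) or np.any(fitted_qc <= 0) or med <= 0:
                report.rsc_fallback_features.append((fid, str(batch)))
                continue
            curve = np.interp(order, qc_order_sorted, fitted_qc)
            out.loc[fid, cols] = sub[i] / curve * med
    report.record_stage("qc_rsc", fm.shape[0], fm.shape[0])
    return fm.with_values(out), report


# ---------------------------------------------------------------------------
# 3. QC-CV filter
# ---------------------------------------------------------------------------

def qc_cv_filter(
    fm: FeatureMatrix,
    info: pd.DataFrame,
    threshold: float = 0.30,
    report: PreprocessReport | None = None,
) -> tuple[FeatureMatrix, PreprocessReport]:
    """Drop features whose QC coefficient of variation exceeds ``threshold``.

    CV = sample (n-1) standard deviation / mean over QC injections; a feature
    with zero QC mean is treated as CV = +inf and removed.
    """
    if report is None:
        report = PreprocessReport()
    qc_cols = _qc_columns(fm, info)
    if len(qc_cols) < 2:
        raise ValueError("QC-CV filter needs at least 2 QC samples")
    qc = fm.values[qc_cols]
    mean = qc.mean(axis=1)
    sd = qc.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.inf)
    cv = pd.Series(cv, index=fm.values.index)
    keep = cv <= threshold
    for fid in cv.index[~keep]:
        report.dropped_cv[fid] = float(cv[fid])
    out = fm.subset_features(list(cv.index[keep]))
    report.record_stage("qc_cv_filter", fm.shape[0], out.shape[0])
    return out, report


# ---------------------------------------------------------------------------
# 4. annotation filter
# ---------------------------------------------------------------------------

def annotation_filter(
    fm: FeatureMatrix,
    report: PreprocessReport | None = None,
) -> tuple[FeatureMatrix, PreprocessReport]:
    """Keep only features with a non-empty annotation class.

    The report's stage entry records survivor counts split by ion mode.
    """
    if report is None:
        report = PreprocessReport()
    ann = fm.feature_meta["annotation_class"].fillna("").astype(str)
    keep = ann != ""
    report.dropped_unannotated = list(fm.values.index[~keep])
    out = fm.subset_features(list(fm.values.index[keep]))
    counts = out.feature_meta["ion_mode"].value_counts().to_dict()
    report.record_stage("annotation_filter", fm.shape[0], out.shape[0])
    report.stages[-1]["survivors_pos"] = int(counts.get("pos", 0))
    report.stages[-1]["survivors_neg"] = int(counts.get("neg", 0))
    return out, report


# ---------------------------------------------------------------------------
# the full chain
# ---------------------------------------------------------------------------

def run_preprocessing(
    fm: FeatureMatrix,
    info: pd.DataFrame,
    cv_threshold: float = 0.30,
    span: float = 0.75,
    robust_iters: int = 2,
    reference_policy: str = "qc_median",
) -> tuple[FeatureMatrix, PreprocessReport]:
    """PQN -> QC-RSC -> CV filter -> annotation filter, with one shared report."""
    report = PreprocessReport()
    fm, report = pqn_normalize(fm, info, reference_policy=reference_policy, report=report)
    fm, report = qc_rsc_correct(fm, info, span=span, robust_iters=robust_iters, report=report)
    fm, report = qc_cv_filter(fm, info, threshold=cv_threshold, report=report)
    fm, report = annotation_filter(fm, report=report)
    return fm, report
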