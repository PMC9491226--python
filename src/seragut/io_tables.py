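"""Readers and writers for all tabular inputs and results.

Every table in the pipeline is a tab-separated UTF-8 file.  The three
in-memory containers defined here — :class:`FeatureMatrix`,
:class:`SampleInfo` (a validated :class:`pandas.DataFrame`) and
:class:`KoModuleMap` — are the currency of every downstream stage, so all
parsing conventions live in this module and nowhere else.

Supported dialects:

* plain feature tables (features x samples or transposed),
* MetaPhlAn2-style merged taxonomy tables (pipe-delimited clade strings with
  ``k__/p__/c__/o__/f__/g__/s__`` rank prefixes, relative abundances),
* HUMAnN2-style KO / pathway tables (stratified ``X|g__...`` rows dropped
  with a logged count),
* a ``module_id <TAB> module_name <TAB> K00001,K00002,...`` KEGG-module map,
* the per-sample clinical/technical metadata table.

Missing values are not allowed in feature tables; zeros encode absence.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "KoModuleMap",
    "ParseReport",
    "RANK_ORDER",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_metaphlan_table",
    "read_humann_table",
    "read_sample_info",
    "write_sample_info",
    "read_ko_module_map",
    "write_ko_module_map",
    "make_sample_info",
]

#: taxonomy ranks in MetaPhlAn prefix order
RANK_ORDER = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_PREFIX_TO_RANK = dict(zip("kpcofgs", RANK_ORDER))
_CLADE_RE = re.compile(r"^[kpcofgs]__.*$")
_KO_RE = re.compile(r"^K\d+$")

SAMPLE_INFO_COLUMNS = [
    "sample_id",
    "subject_id",
    "timepoint",
    "group",
    "pasi_before",
    "pasi_after",
    "bmi",
    "weight_kg",
    "injection_order",
    "batch",
]


@dataclasses.dataclass
class ParseReport:
    """Warnings and bookkeeping collected while reading a table."""

    warnings: list[str] = dataclasses.field(default_factory=list)
    dropped_stratified: int = 0

    def warn(self, message: str) -> None:
        self.warnings.append(message)


class FeatureMatrix:
    """A non-negative features x samples abundance/intensity table.

    Parameters
    ----------
    values
        DataFrame with feature ids as index and sample ids as columns.
    feature_meta
        Optional per-feature metadata aligned to ``values.index``; recognised
        columns are ``ion_mode`` (``pos``/``neg``/``na``), ``annotation_class``
        and ``taxonomy_rank`` (empty string when not applicable).
    """

    def __init__(self, values: pd.DataFrame, feature_meta: pd.DataFrame | None = None):
        values = values.astype(float)
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        if values.columns.duplicated().any():
            dup = values.columns[values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if np.isnan(values.to_numpy()).any():
            raise ValueError("feature table contains missing values; zeros encode absence")
        if (values.to_numpy() < 0).any():
            r, c = np.argwhere(values.to_numpy() < 0)[0]
            raise ValueError(
                f"negative value at feature {values.index[r]!r}, sample {values.columns[c]!r}"
            )
        if feature_meta is None:
            feature_meta = pd.DataFrame(
                {"ion_mode": "na", "annotation_class": "", "taxonomy_rank": ""},
                index=values.index,
            )
        else:
            feature_meta = feature_meta.reindex(values.index)
            for col, default in (
                ("ion_mode", "na"),
                ("annotation_class", ""),
                ("taxonomy_rank", ""),
            ):
                if col not in feature_meta:
                    feature_meta[col] = default
            feature_meta = feature_meta.fillna({"ion_mode": "na", "annotation_class": "", "taxonomy_rank": ""})
        self.values = values
        self.feature_meta = feature_meta

    # -- basic accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_features(self, feature_ids: Iterable[str]) -> "FeatureMatrix":
        ids = list(feature_ids)
        return FeatureMatrix(self.values.loc[ids], self.feature_meta.loc[ids])

    def subset_samples(self, sample_ids: Iterable[str]) -> "FeatureMatrix":
        ids = list(sample_ids)
        return FeatureMatrix(self.values[ids], self.feature_meta)

    def with_values(self, values: pd.DataFrame) -> "FeatureMatrix":
        """New matrix with the same metadata (restricted to the new index)."""
        return FeatureMatrix(values, self.feature_meta.reindex(values.index))

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.values.copy(), self.feature_meta.copy())

    def __repr__(self) -> str:  # pragma: no cover
        return f"FeatureMatrix({self.shape[0]} features x {self.shape[1]} samples)"


@dataclasses.dataclass
class KoModuleMap:
    """KEGG-module -> KO membership map (a KO may belong to several modules)."""

    modules: dict[str, set[str]]
    names: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for mid, kos in self.modules.items():
            if not kos:
                raise ValueError(f"module {mid!r} has an empty KO set")
            for ko in kos:
                if not _KO_RE.match(ko):
                    raise ValueError(f"module {mid!r}: malformed KO id {ko!r}")

    def __iter__(self):
        return iter(self.modules)

    def __getitem__(self, module_id: str) -> set[str]:
        return self.modules[module_id]

    def __len__(self) -> int:
        return len(self.modules)


# ---------------------------------------------------------------------------
# feature matrices
# ---------------------------------------------------------------------------

def _read_numeric_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    df.index = df.index.astype(str)
    out = {}
    for col in df.columns:
        try:
            # astype(float) parses via strtod, so repr-serialized floats
            # round-trip bit exactly (pd.to_numeric's fast parser does not)
            out[col] = df[col].astype(float)
        except (ValueError, TypeError):
            for row, cell in df[col].items():
                try:
                    float(cell)
                except (ValueError, TypeError):
                    raise ValueError(
                        f"non-numeric cell at row {row!r}, column {col!r}: {cell!r}"
                    ) from None
            raise
    return pd.DataFrame(out, index=df.index)


def read_feature_matrix(
    path: str | Path,
    orientation: str = "features_in_rows",
    feature_meta: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Read a plain TSV feature table in either orientation.

    Always returns a features x samples matrix; duplicate identifiers and
    negative or non-numeric cells are rejected with the offending position.
    """
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_numeric_table(path)
    if orientation == "samples_in_rows":
        df = df.T
    return FeatureMatrix(df, feature_meta)


def write_feature_matrix(fm: FeatureMatrix, path: str | Path, meta_path: str | Path | None = None) -> None:
    """Write a feature matrix (and optionally its metadata) as TSV.

    Floats are serialized with ``repr`` so a write/read round trip is
    bit-exact.
    """
    df = fm.values
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(map(str, df.columns)) + "\n")
        arr = df.to_numpy()
        for i, fid in enumerate(df.index):
            fh.write(str(fid) + "\t" + "\t".join(repr(float(v)) for v in arr[i]) + "\n")
    if meta_path is not None:
        fm.feature_meta.to_csv(meta_path, sep="\t", index_label="feature_id")


def read_metaphlan_table(path: str | Path) -> tuple[dict[str, FeatureMatrix], ParseReport]:
    """Read a MetaPhlAn2 merged abundance table into one matrix per rank.

    Rows are pipe-delimited clade strings; the rank of a row is inferred from
    the prefix of its terminal clade.  Full clade strings are kept as feature
    ids (terminal names can collide across lineages); the terminal name goes
    into ``feature_meta['display_name']``.  Per-sample rank sums exceeding 100
    (relative tolerance 1e-6) are recorded as warnings in the parse report.
    """
    df = _read_numeric_table(path)
    report = ParseReport()
    by_rank: dict[str, list[str]] = {r: [] for r in RANK_ORDER}
    for clade in df.index:
        parts = str(clade).split("|")
        for part in parts:
            if not _CLADE_RE.match(part):
                raise ValueError(f"malformed clade prefix in {clade!r}: {part!r}")
        rank = _PREFIX_TO_RANK[parts[-1][0]]
        by_rank[rank].append(clade)
    out: dict[str, FeatureMatrix] = {}
    for rank, clades in by_rank.items():
        if not clades:
            continue
        sub = df.loc[clades]
        sums = sub.sum(axis=0)
        for sid, total in sums.items():
            if total > 100 * (1 + 1e-6):
                report.warn(f"rank {rank}: sample {sid} abundances sum to {total:.6f} > 100")
        meta = pd.DataFrame(
            {
                "taxonomy_rank": rank,
                "display_name": [c.split("|")[-1][3:] for c in clades],
            },
            index=sub.index,
        )
        out[rank] = FeatureMatrix(sub, meta)
    return out, report


def read_humann_table(path: str | Path) -> tuple[FeatureMatrix, ParseReport]:
    """Read a HUMAnN2-style KO/pathway table, dropping stratified rows.

    Rows whose id contains ``|`` (per-taxon stratification) are removed; the
    count is recorded in the parse report.
    """
    df = _read_numeric_table(path)
    report = ParseReport()
    stratified = [i for i in df.index if "|" in str(i)]
    report.dropped_stratified = len(stratified)
    if stratified:
        report.warn(f"dropped {len(stratified)} stratified rows")
        df = df.drop(index=stratified)
    return FeatureMatrix(df), report


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def make_sample_info(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a raw metadata frame and attach derived columns.

    Adds ``is_qc`` (timepoint == 'qc') and ``dpasi`` (fractional PASI
    reduction, shared by the pre and post rows of a subject).  Raises on
    duplicated sample ids, a subject with two samples at the same timepoint,
    missing BMI on a study sample, or duplicated injection order in a batch.
    """
    df = df.copy()
    missing = [c for c in SAMPLE_INFO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample info missing required columns: {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id: {dup!r}")
    df["timepoint"] = df["timepoint"].astype(str)
    bad_tp = set(df["timepoint"]) - {"pre", "post", "qc"}
    if bad_tp:
        raise ValueError(f"unknown timepoint values: {sorted(bad_tp)}")
    df["is_qc"] = df["timepoint"] == "qc"
    df.loc[df["is_qc"], "group"] = "na"
    study = df[~df["is_qc"]]
    if study[["bmi"]].isna().any().any():
        bad = study.loc[study["bmi"].isna(), "sample_id"].iloc[0]
        raise ValueError(f"missing bmi for study sample {bad!r}")
    for (subj, tp), n in study.groupby(["subject_id", "timepoint"]).size().items():
        if n > 1:
            raise ValueError(f"subject {subj!r} has {n} {tp!r} samples")
    for batch, sub in df.groupby("batch"):
        if sub["injection_order"].duplicated().any():
            raise ValueError(f"duplicate injection order in batch {batch!r}")
    # dPASI = fractional reduction, computed per subject and attached to both
    # the pre and post rows.
    dpasi = pd.Series(np.nan, index=df.index)
    for subj, sub in study.groupby("subject_id"):
        before = sub["pasi_before"].dropna()
        after = sub["pasi_after"].dropna()
        if len(before) and len(after) and float(before.iloc[0]) > 0:
            d = (float(before.iloc[0]) - float(after.iloc[0])) / float(before.iloc[0])
            dpasi[sub.index] = d
    df["dpasi"] = dpasi
    return df.set_index("sample_id", drop=False)


def read_sample_info(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV (see :func:`make_sample_info`)."""
    df = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "subject_id": str, "batch": str}, comment="#"
    )
    return make_sample_info(df)


def write_sample_info(info: pd.DataFrame, path: str | Path) -> None:
    info.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# KEGG-module map
# ---------------------------------------------------------------------------

def read_ko_module_map(path: str | Path) -> KoModuleMap:
    """Read ``module_id<TAB>module_name<TAB>K00001,K00002`` lines."""
    modules: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"line {lineno}: expected 3 tab-separated fields")
            mid, name, kos = parts
            ko_set = {k.strip() for k in kos.split(",") if k.strip()}
            if not ko_set:
                raise ValueError(f"module {mid!r} (line {lineno}) has an empty KO list")
            modules[mid] = ko_set
            names[mid] = name
    return KoModuleMap(modules, names)


def write_ko_module_map(km: KoModuleMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for mid in km.modules:
            kos = ",".join(sorted(km.modules[mid]))
            fh.write(f"{mid}\t{km.names.get(mid, mid)}\t{kos}\n")
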