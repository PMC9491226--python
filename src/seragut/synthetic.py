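"""Synthetic cohort, metabolome and microbiome generator with planted truth.

The generator emulates a small paired treatment-response study: 15 psoriasis
patients (8 good responders, 6 poor responders, 1 moderate) sampled before and
after 16 weeks of therapy, with

* an untargeted LC-MS serum feature table (log-normal intensities,
  block-correlated metabolite clusters driven by latent factors, per-sample
  dilution, smooth injection-order drift, multiplicative batch effects and
  interleaved pooled-QC injections),
* MetaPhlAn2/HUMAnN2-style gut profiles (Dirichlet species compositions under
  the five dominant phyla, KO gene families organized into KEGG-like modules
  driven by latent factors),
* latent factors linking one metabolite cluster and one KO module to the
  clinical improvement score (dPASI) and another cluster to BMI.

Every planted effect is recorded in a :class:`SyntheticTruth` so downstream
screens can be tested for recovery and false-positive control.  All functions
are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .io_tables import FeatureMatrix, KoModuleMap, make_sample_info

__all__ = [
    "SyntheticTruth",
    "generate_cohort",
    "generate_metabolome",
    "generate_microbiome",
    "simulate_scenario",
    "DOMINANT_PHYLA",
]

#: the five phyla that dominate the gut communities being emulated
DOMINANT_PHYLA = (
    "Bacteroidetes",
    "Firmicutes",
    "Proteobacteria",
    "Fusobacteria",
    "Actinobacteria",
)
_PHYLUM_WEIGHTS = (0.40, 0.35, 0.12, 0.07, 0.06)

_ANNOTATION_CLASSES = (
    "Lipids",
    "Benzenoids",
    "Organic acids",
    "Organoheterocyclic compounds",
    "Organic oxygen compounds",
    "Phenylpropanoids",
    "Fatty acyls",
    "Nucleosides",
)

# response bands: fractional PASI improvement sampled uniformly per group
_IMPROVEMENT_BANDS = {"GR": (0.76, 0.99), "PR": (0.05, 0.49), "moderate": (0.50, 0.74)}

# BMI distributions mimicking the study's group summaries
_BMI_PARAMS = {"GR": (21.45, 3.48), "PR": (26.77, 3.58), "moderate": (22.0, 3.5)}


@dataclasses.dataclass
class SyntheticTruth:
    """Record of every planted effect, for recovery testing."""

    planted_cluster_members: dict[str, list[str]] = dataclasses.field(default_factory=dict)
    planted_differential_features: dict[str, float] = dataclasses.field(default_factory=dict)
    planted_ko_modules: dict[str, list[str]] = dataclasses.field(default_factory=dict)
    planted_links: list[tuple[str, str, int]] = dataclasses.field(default_factory=list)
    planted_discriminative_taxa: dict[str, str] = dataclasses.field(default_factory=dict)
    latent_factors: pd.DataFrame | None = None
    cluster_factor: dict[str, str] = dataclasses.field(default_factory=dict)
    module_factor: dict[str, str] = dataclasses.field(default_factory=dict)
    drift_curves: pd.DataFrame | None = None
    dilution_factors: pd.Series | None = None
    batch_multipliers: pd.DataFrame | None = None
    base_metabolome: pd.DataFrame | None = None

    def validate(self, min_cluster_size: int = 10) -> None:
        for cid, members in self.planted_cluster_members.items():
            if len(members) < min_cluster_size:
                raise ValueError(f"planted cluster {cid} has {len(members)} < {min_cluster_size} members")
        for mid, cid, _sign in self.planted_links:
            if mid not in self.planted_ko_modules:
                raise ValueError(f"planted link references unknown KO module {mid!r}")
            if cid not in self.planted_cluster_members:
                raise ValueError(f"planted link references unknown cluster {cid!r}")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lower: float, size: int) -> np.ndarray:
    out = np.empty(size)
    for i in range(size):
        x = rng.normal(mean, sd)
        while x <= lower:
            x = rng.normal(mean, sd)
        out[i] = x
    return out


def _zscore(v: np.ndarray) -> np.ndarray:
    s = v.std(ddof=0)
    if s == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / s


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def generate_cohort(
    n_gr: int = 8,
    n_pr: int = 6,
    n_moderate: int = 1,
    seed: int = 0,
    n_factors: int = 5,
    factor_noise: float = 0.45,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a paired pre/post cohort with group-consistent clinical data.

    BMI is drawn from group-specific truncated normals (PR mean above GR, as
    in the overweight-poor-responder pattern being emulated), PASI improvement
    uniformly within each response band (GR >= 0.76, PR < 0.50, moderate in
    between), so every subject's dPASI is consistent with its group label by
    construction.

    Also creates per-sample latent factors: ``F1`` tracks dPASI, ``F2`` tracks
    BMI, the rest are free.  These factors are shared by the metabolome and
    microbiome generators, which is how cross-domain links are planted.
    """
    if n_gr + n_pr + n_moderate == 0:
        raise ValueError("cohort is empty: all group counts are zero")
    rng = np.random.default_rng(seed)
    groups = ["GR"] * n_gr + ["PR"] * n_pr + ["moderate"] * n_moderate
    n = len(groups)
    subjects = [f"S{i + 1:02d}" for i in range(n)]

    bmi = np.concatenate(
        [
            _truncated_normal(rng, *_BMI_PARAMS["GR"], 15.0, n_gr),
            _truncated_normal(rng, *_BMI_PARAMS["PR"], 15.0, n_pr),
            _truncated_normal(rng, *_BMI_PARAMS["moderate"], 15.0, n_moderate),
        ]
    )
    height_m = _truncated_normal(rng, 1.66, 0.06, 1.40, n)
    weight = bmi * height_m**2
    pasi_before = _truncated_normal(rng, 13.3, 4.0, 3.0, n)
    improvement = np.array([rng.uniform(*_IMPROVEMENT_BANDS[g]) for g in groups])
    pasi_after = pasi_before * (1.0 - improvement)

    rows = []
    for i, subj in enumerate(subjects):
        for tp in ("pre", "post"):
            rows.append(
                {
                    "sample_id": f"{subj}_{tp}",
                    "subject_id": subj,
                    "timepoint": tp,
                    "group": groups[i],
                    "pasi_before": pasi_before[i],
                    "pasi_after": pasi_after[i],
                    "bmi": bmi[i],
                    "weight_kg": weight[i],
                    "injection_order": len(rows) + 1,
                    "batch": "B1",
                }
            )
    info = make_sample_info(pd.DataFrame(rows))

    # latent factors: per-subject bases plus a small per-sample jitter
    dpasi = improvement
    f_subj = np.column_stack(
        [
            _zscore(dpasi) + factor_noise * rng.normal(size=n),
            _zscore(bmi) + factor_noise * rng.normal(size=n),
        ]
        + [rng.normal(size=n) for _ in range(max(0, n_factors - 2))]
    )
    factor_names = [f"F{k + 1}" for k in range(f_subj.shape[1])]
    sample_ids = list(info.index)
    fac = np.zeros((len(sample_ids), f_subj.shape[1]))
    for j, sid in enumerate(sample_ids):
        i = subjects.index(info.loc[sid, "subject_id"])
        fac[j] = f_subj[i] + 0.15 * rng.normal(size=f_subj.shape[1])
    factors = pd.DataFrame(fac, index=sample_ids, columns=factor_names)
    # standardize each factor across samples so loadings mean what they say
    factors = (factors - factors.mean()) / factors.std(ddof=0)

    truth = SyntheticTruth(latent_factors=factors)
    return info, truth


# ---------------------------------------------------------------------------
# metabolome
# ---------------------------------------------------------------------------

def generate_metabolome(
    cohort: pd.DataFrame,
    truth: SyntheticTruth | None = None,
    n_features: int = 300,
    n_clusters: int = 5,
    cluster_size: int = 20,
    n_qc: int = 10,
    drift_amplitude: float = 0.3,
    seed: int = 0,
    within_r: float = 0.8,
    n_differential: int = 20,
    effect_log2: float = 1.0,
    dilution_sd: float = 0.15,
    n_batches: int = 2,
    batch_sd: float = 0.1,
    frac_unannotated: float = 0.10,
    strict: bool = True,
) -> tuple[FeatureMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate an LC-MS-like feature table with planted structure.

    Returns the feature matrix (study + QC injections), the sample metadata
    augmented with QC rows, injection order and batch, and the truth record.

    The multiplicative model per feature ``f`` and injection ``s`` is
    ``value = base * dilution_s * drift_f(order_s) * batch_mult_{b(s),f}``
    where ``base`` is log-normal with block correlation inside planted
    clusters and QC injections carry the pooled mean profile (dilution 1, no
    analytic noise).  Drift is an affine transform of a per-feature cubic in
    injection order, scaled so max/min = 1 + ``drift_amplitude``.
    """
    if n_clusters * cluster_size > n_features:
        raise ValueError("n_clusters * cluster_size exceeds n_features")
    if n_qc < 3:
        raise ValueError("need at least 3 QC injections")
    if strict and n_clusters > 0 and cluster_size < 10:
        raise ValueError(
            "cluster_size < 10 violates the minimum co-abundance module size "
            "convention (pass strict=False to override)"
        )
    rng = np.random.default_rng(seed)
    if truth is None:
        truth = SyntheticTruth()
    study = cohort[cohort["timepoint"] != "qc"]
    study_ids = list(study.index)
    n_study = len(study_ids)

    if truth.latent_factors is None or truth.latent_factors.shape[1] < n_clusters:
        extra = pd.DataFrame(
            rng.normal(size=(n_study, n_clusters)),
            index=study_ids,
            columns=[f"F{k + 1}" for k in range(n_clusters)],
        )
        base_fac = truth.latent_factors
        if base_fac is not None:
            extra.iloc[:, : base_fac.shape[1]] = base_fac.loc[study_ids].to_numpy()
        truth.latent_factors = (extra - extra.mean()) / extra.std(ddof=0)
    factors = truth.latent_factors.loc[study_ids]

    feature_ids = [f"M{i + 1:04d}" for i in range(n_features)]
    # cluster membership: contiguous blocks at the front of the feature list
    cluster_of = {}
    for k in range(n_clusters):
        cid = f"C{k + 1}"
        members = feature_ids[k * cluster_size : (k + 1) * cluster_size]
        truth.planted_cluster_members[cid] = members
        truth.cluster_factor[cid] = factors.columns[k]
        for f in members:
            cluster_of[f] = k
    background = feature_ids[n_clusters * cluster_size :]

    # feature metadata: cluster members always annotated, a slice of the
    # background left without an annotation class (exercises the filter)
    n_unann = int(round(frac_unannotated * len(background)))
    unannotated = set(background[:n_unann])
    ion_mode = np.where(rng.random(n_features) < 0.78, "pos", "neg")
    meta = pd.DataFrame(
        {
            "ion_mode": ion_mode,
            "annotation_class": [
                "" if f in unannotated else _ANNOTATION_CLASSES[i % len(_ANNOTATION_CLASSES)]
                for i, f in enumerate(feature_ids)
            ],
            "taxonomy_rank": "",
        },
        index=feature_ids,
    )

    # planted differential features (baseline GR vs PR), alternating sign
    candidates = [f for f in background if f not in unannotated]
    diff_feats = candidates[: min(n_differential, len(candidates))]
    for i, f in enumerate(diff_feats):
        truth.planted_differential_features[f] = effect_log2 * (1 if i % 2 == 0 else -1)

    # log-scale construction
    mu = rng.normal(11.5, 1.0, size=n_features)
    s = rng.uniform(0.25, 0.40, size=n_features)
    z = rng.normal(size=(n_features, n_study))
    fac_arr = factors.to_numpy().T  # factors x samples
    for i, f in enumerate(feature_ids):
        if f in cluster_of:
            k = cluster_of[f]
            z[i] = math.sqrt(within_r) * fac_arr[k] + math.sqrt(1 - within_r) * z[i]
    x = mu[:, None] + s[:, None] * z
    is_pre = (study["timepoint"] == "pre").to_numpy()
    grp = study["group"].to_numpy()
    for f, eff in truth.planted_differential_features.items():
        i = feature_ids.index(f)
        shift = eff * math.log(2) / 2.0
        x[i, is_pre & (grp == "GR")] += shift
        x[i, is_pre & (grp == "PR")] -= shift
    base_study = np.exp(x)
    pooled = base_study.mean(axis=1)

    # injection sequence: QCs interleaved every ceil(n_study / n_qc) positions
    order_perm = rng.permutation(n_study)
    every = math.ceil(n_study / n_qc)
    seq: list[str] = []
    qc_ids = [f"QC{q + 1:02d}" for q in range(n_qc)]
    qi = 0
    for i, idx in enumerate(order_perm):
        if i % every == 0 and qi < n_qc:
            seq.append(qc_ids[qi])
            qi += 1
        seq.append(study_ids[idx])
    while qi < n_qc:
        seq.append(qc_ids[qi])
        qi += 1
    n_inj = len(seq)
    order = {sid: i + 1 for i, sid in enumerate(seq)}
    batch_bounds = np.array_split(np.arange(n_inj), n_batches)
    batch_of = {}
    for b, idxs in enumerate(batch_bounds):
        for i in idxs:
            batch_of[seq[i]] = f"B{b + 1}"

    # per-feature drift: affine transform of a cubic in scaled injection order
    t = (np.arange(n_inj)) / max(n_inj - 1, 1)
    coef = rng.normal(size=(n_features, 3))
    raw = coef[:, [0]] * t + coef[:, [1]] * t**2 + coef[:, [2]] * t**3
    lo, hi = raw.min(axis=1, keepdims=True), raw.max(axis=1, keepdims=True)
    span = np.where(hi > lo, hi - lo, 1.0)
    u = (raw - lo) / span
    drift = 1.0 + drift_amplitude * u  # features x injection position

    dilution = pd.Series(1.0, index=seq, dtype=float)
    dilution[study_ids] = np.exp(rng.normal(0.0, dilution_sd, size=n_study))
    batch_mult = pd.DataFrame(
        np.exp(rng.normal(0.0, batch_sd, size=(n_features, n_batches))),
        index=feature_ids,
        columns=[f"B{b + 1}" for b in range(n_batches)],
    )

    values = np.empty((n_features, n_inj))
    for j, sid in enumerate(seq):
        if sid.startswith("QC"):
            base_col = pooled
        else:
            base_col = base_study[:, study_ids.index(sid)]
        pos = order[sid] - 1
        values[:, j] = (
            base_col * dilution[sid] * drift[:, pos] * batch_mult[batch_of[sid]].to_numpy()
        )
    fm = FeatureMatrix(pd.DataFrame(values, index=feature_ids, columns=seq), meta)

    # sample metadata with QC rows, injection order and batches attached
    info = cohort.copy()
    qc_rows = pd.DataFrame(
        {
            "sample_id": qc_ids,
            "subject_id": "QC",
            "timepoint": "qc",
            "group": "na",
            "pasi_before": np.nan,
            "pasi_after": np.nan,
            "bmi": np.nan,
            "weight_kg": np.nan,
            "injection_order": [order[q] for q in qc_ids],
            "batch": [batch_of[q] for q in qc_ids],
        }
    )
    info = info.drop(columns=["is_qc", "dpasi"], errors="ignore").reset_index(drop=True)
    info["injection_order"] = [order[sid] for sid in info["sample_id"]]
    info["batch"] = [batch_of[sid] for sid in info["sample_id"]]
    info = make_sample_info(pd.concat([info, qc_rows], ignore_index=True))

    truth.drift_curves = pd.DataFrame(
        drift[:, [order[sid] - 1 for sid in seq]], index=feature_ids, columns=seq
    )
    truth.dilution_factors = dilution
    truth.batch_multipliers = batch_mult
    base_all = np.column_stack(
        [pooled if sid.startswith("QC") else base_study[:, study_ids.index(sid)] for sid in seq]
    )
    truth.base_metabolome = pd.DataFrame(base_all, index=feature_ids, columns=seq)
    truth.validate(min_cluster_size=10 if strict else 2)
    return fm, info, truth


# ---------------------------------------------------------------------------
# microbiome
# ---------------------------------------------------------------------------

def _clade_string(phylum: str, family_idx: int, species_idx: int) -> str:
    p = phylum
    return (
        f"k__Bacteria|p__{p}|c__{p}_c1|o__{p}_o1"
        f"|f__{p}_f{family_idx}|g__{p}_g{family_idx}|s__{p}_s{species_idx}"
    )


def generate_microbiome(
    cohort: pd.DataFrame,
    truth: SyntheticTruth | None = None,
    n_species: int = 60,
    n_kos: int = 200,
    n_modules: int = 8,
    seed: int = 0,
    n_discriminative: int = 3,
    discrimination_fold: float = 10.0,
    module_size: int = 8,
    ko_noise_sd: float = 0.5,
    link_sign: int = 1,
) -> tuple[FeatureMatrix, FeatureMatrix, KoModuleMap, SyntheticTruth]:
    """Generate species compositions and a KO table with planted modules.

    Species relative abundances come from a Dirichlet model whose
    concentrations are boosted ``discrimination_fold``-fold in PR samples for
    the designated discriminative taxa; compositions sum to 100 per sample.
    KO abundances are driven by per-module latent factors; the first module
    shares the latent factor of the first planted metabolite cluster (sign
    ``link_sign``), which plants the cross-domain link.
    """
    if n_species < 5:
        raise ValueError("n_species < 5 cannot cover the five dominant phyla")
    if n_modules > n_kos / 5:
        raise ValueError("n_modules exceeds n_kos / 5")
    rng = np.random.default_rng(seed)
    if truth is None:
        truth = SyntheticTruth()
    study = cohort[cohort["timepoint"] != "qc"]
    study_ids = list(study.index)
    n_study = len(study_ids)

    # species skeleton under the five dominant phyla
    counts = np.maximum(1, np.round(np.array(_PHYLUM_WEIGHTS) * n_species).astype(int))
    while counts.sum() > n_species:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n_species:
        counts[np.argmax(_PHYLUM_WEIGHTS)] += 1
    clades, phylum_of = [], []
    for p_idx, phylum in enumerate(DOMINANT_PHYLA):
        for j in range(counts[p_idx]):
            clades.append(_clade_string(phylum, j // 3 + 1, j + 1))
            phylum_of.append(phylum)
    alpha = np.array(
        [w * math.exp(rng.normal(0, 1.0)) for w, _ in zip(np.repeat(_PHYLUM_WEIGHTS, counts), clades)]
    )
    alpha = alpha / alpha.sum() * 50.0  # moderate between-sample variability

    disc_idx = rng.choice(n_species, size=n_discriminative, replace=False)
    for i in disc_idx:
        truth.planted_discriminative_taxa[clades[i]] = "PR"

    comp = np.empty((n_species, n_study))
    grp = study["group"].to_numpy()
    for j in range(n_study):
        a = alpha.copy()
        if grp[j] == "PR":
            a[disc_idx] *= discrimination_fold
        comp[:, j] = rng.dirichlet(a) * 100.0
    taxa_meta = pd.DataFrame(
        {"taxonomy_rank": "species", "display_name": [c.split("|")[-1][3:] for c in clades]},
        index=clades,
    )
    taxa = FeatureMatrix(pd.DataFrame(comp, index=clades, columns=study_ids), taxa_meta)

    # KO modules: disjoint blocks at the front of the KO list
    ko_ids = [f"K{i + 1:05d}" for i in range(n_kos)]
    if truth.latent_factors is None:
        lf = pd.DataFrame(
            rng.normal(size=(n_study, n_modules)),
            index=study_ids,
            columns=[f"F{k + 1}" for k in range(n_modules)],
        )
        truth.latent_factors = (lf - lf.mean()) / lf.std(ddof=0)
    factors = truth.latent_factors.loc[study_ids]

    module_map: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    mod_factor = {}
    extra_fac = {}
    for m in range(n_modules):
        mid = f"KM{m + 1:04d}"
        members = ko_ids[m * module_size : (m + 1) * module_size]
        module_map[mid] = set(members)
        names[mid] = f"synthetic module {m + 1}"
        truth.planted_ko_modules[mid] = members
        if m == 0:
            # shares the factor of planted metabolite cluster C1 (linked)
            fvals = link_sign * factors.iloc[:, 0].to_numpy()
            truth.module_factor[mid] = factors.columns[0]
        elif m == 1 and factors.shape[1] > 1:
            fvals = factors.iloc[:, 1].to_numpy()
            truth.module_factor[mid] = factors.columns[1]
        else:
            fvals = rng.normal(size=n_study)
            extra_fac[mid] = fvals
            truth.module_factor[mid] = f"free_{mid}"
        mod_factor[mid] = fvals
    if truth.planted_cluster_members:
        truth.planted_links.append(("KM0001", next(iter(truth.planted_cluster_members)), link_sign))

    mu = rng.normal(0.0, 1.0, size=n_kos)
    xs = mu[:, None] + ko_noise_sd * rng.normal(size=(n_kos, n_study))
    for m, (mid, members) in enumerate(truth.planted_ko_modules.items()):
        loadings = rng.uniform(0.6, 1.0, size=len(members))
        for li, ko in enumerate(members):
            i = ko_ids.index(ko)
            xs[i] += loadings[li] * mod_factor[mid]
    ko = FeatureMatrix(pd.DataFrame(np.exp(xs), index=ko_ids, columns=study_ids))

    km = KoModuleMap(module_map, names)
    truth.validate()
    return taxa, ko, km, truth


# ---------------------------------------------------------------------------
# whole scenario
# ---------------------------------------------------------------------------

def simulate_scenario(
    seed: int = 0,
    n_gr: int = 8,
    n_pr: int = 6,
    n_moderate: int = 1,
    n_features: int = 300,
    n_clusters: int = 5,
    cluster_size: int = 20,
    n_qc: int = 10,
    drift_amplitude: float = 0.3,
    n_species: int = 60,
    n_kos: int = 200,
    n_modules: int = 8,
    **metabolome_kwargs,
) -> dict:
    """Generate a complete linked study (cohort + metabolome + microbiome).

    Returns a dict with keys ``info``, ``metabolome``, ``taxa``, ``ko``,
    ``ko_modules`` and ``truth``.  Child seeds are derived deterministically
    from ``seed``.
    """
    info, truth = generate_cohort(n_gr, n_pr, n_moderate, seed=seed, n_factors=max(5, n_clusters))
    fm, info, truth = generate_metabolome(
        info,
        truth,
        n_features=n_features,
        n_clusters=n_clusters,
        cluster_size=cluster_size,
        n_qc=n_qc,
        drift_amplitude=drift_amplitude,
        seed=seed + 1,
        **metabolome_kwargs,
    )
    taxa, ko, km, truth = generate_microbiome(
        info,
        truth,
        n_species=n_species,
        n_kos=n_kos,
        n_modules=n_modules,
        seed=seed + 2,
    )
    return {
        "info": info,
        "metabolome": fm,
        "taxa": taxa,
        "ko": ko,
        "ko_modules": km,
        "truth": truth,
    }
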