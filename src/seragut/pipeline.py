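"""Configuration-driven orchestration of the full analysis chain.

A single config (dict or YAML file) specifies either input table paths or a
synthetic scenario block (exactly one of the two), per-stage parameters and
an output directory.  Stages run in the fixed order

``simulate/load -> preprocess -> screen -> diversity -> lefse -> modules ->
integrate``

and every output TSV carries a header comment with the package version, the
seed and a hash of the resolved parameters, so runs are auditable and
bit-reproducible.  Stages can be rerun selectively; earlier intermediates
are then read back from the output directory.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import comb

from . import __version__
from .io_tables import (
    FeatureMatrix,
    read_feature_matrix,
    read_humann_table,
    read_ko_module_map,
    read_sample_info,
    write_feature_matrix,
    write_sample_info,
)
from .integrate import crossdomain_map, protest
from .microbiome import alpha_diversity, concat_rank_matrices, expand_clades, lefse
from .multivariate import pca_scores, ward_d2_tree
from .netcluster import detect_modules, module_trait_association, pick_soft_threshold
from .preprocess import run_preprocessing
from .stats import screen_differential
from .synthetic import simulate_scenario

__all__ = ["run_pipeline", "load_config", "default_config", "adjusted_rand_index", "ALL_STAGES"]

ALL_STAGES = ("simulate", "preprocess", "screen", "diversity", "lefse", "modules", "integrate")


def default_config(seed: int = 0, out_dir: str = "seragut_out") -> dict:
    """The default synthetic scenario configuration."""
    return {
        "out_dir": out_dir,
        "seed": seed,
        "scenario": {
            "n_gr": 8, "n_pr": 6, "n_moderate": 1,
            "n_features": 300, "n_clusters": 5, "cluster_size": 20,
            "n_qc": 10, "drift_amplitude": 0.3,
            "n_species": 60, "n_kos": 200, "n_modules": 8,
        },
        "preprocess": {"cv_threshold": 0.30, "span": 0.75, "robust_iters": 2},
        "screen": {"vip": 1.0, "lfc": 0.25, "alpha": 0.05, "n_components": 2},
        "lefse": {"kw_alpha": 0.05, "n_boot": 30, "lda_threshold": 2.0},
        "modules": {
            "deep_split": 2, "min_size": 10, "kme_assign_threshold": 0.3,
            "merge_height": 0.25, "r2_cut": 0.85, "log2_transform": True,
        },
        "integrate": {"alpha": 0.05, "n_perm": 999, "require_partial": True},
    }


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _validate_config(config: dict) -> dict:
    cfg = default_config()
    for key, val in config.items():
        if isinstance(val, dict) and key in cfg and isinstance(cfg[key], dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    has_scenario = "scenario" in config and config["scenario"] is not None
    has_inputs = "inputs" in config and config["inputs"] is not None
    if has_scenario and has_inputs:
        raise ValueError("config must specify exactly one of 'inputs' and 'scenario'")
    if has_inputs:
        cfg.pop("scenario", None)
    return cfg


def _param_hash(cfg: dict) -> str:
    # out_dir does not affect any computed value, so identical analyses
    # written to different directories hash (and therefore diff) identically
    hashed = {k: v for k, v in cfg.items() if k != "out_dir"}
    return hashlib.md5(json.dumps(hashed, sort_keys=True, default=str).encode()).hexdigest()[:10]


def _header(cfg: dict) -> str:
    return f"# seragut {__version__} seed={cfg.get('seed')} params={_param_hash(cfg)}\n"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: dict, index_label: str = "id") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index_label=index_label)


def _write_matrix(fm: FeatureMatrix, path: Path, cfg: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(cfg))
    with open(path, "a", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(map(str, fm.values.columns)) + "\n")
        arr = fm.values.to_numpy()
        for i, fid in enumerate(fm.values.index):
            fh.write(str(fid) + "\t" + "\t".join(repr(float(v)) for v in arr[i]) + "\n")


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index between two flat partitions."""
    a = pd.Series(list(labels_a)).astype("category").cat.codes.to_numpy()
    b = pd.Series(list(labels_b)).astype("category").cat.codes.to_numpy()
    if len(a) != len(b):
        raise ValueError("partitions must label the same items")
    contingency = pd.crosstab(a, b).to_numpy()
    sum_comb = comb(contingency, 2).sum()
    sum_a = comb(contingency.sum(axis=1), 2).sum()
    sum_b = comb(contingency.sum(axis=0), 2).sum()
    n = comb(len(a), 2)
    expected = sum_a * sum_b / n if n else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: dict | str | Path, stages: tuple[str, ...] | None = None) -> dict:
    """Run (a subset of) the analysis stages; returns the result bundle.

    ``config`` is a dict or a YAML path.  When ``stages`` is given, earlier
    intermediates are read from the output directory instead of recomputed.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = _validate_config(config)
    stages = tuple(stages) if stages else ALL_STAGES
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    results: dict = {"config": cfg}

    with open(out / "resolved_config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)

    # ---- stage: simulate (or load real inputs) ---------------------------
    truth = None
    if "simulate" in stages:
        if "scenario" in cfg:
            sim = simulate_scenario(seed=seed, **cfg["scenario"])
            info, raw, taxa, ko, km, truth = (
                sim["info"], sim["metabolome"], sim["taxa"], sim["ko"],
                sim["ko_modules"], sim["truth"],
            )
            _write_matrix(raw, out / "metabolome_raw.tsv", cfg)
            raw.feature_meta.to_csv(out / "metabolome_meta.tsv", sep="\t", index_label="feature_id")
            write_sample_info(info, out / "sample_info.tsv")
            _write_matrix(taxa, out / "taxa_species.tsv", cfg)
            _write_matrix(ko, out / "ko_abundance.tsv", cfg)
            with open(out / "ko_modules.tsv", "w", encoding="utf-8") as fh:
                for mid in km.modules:
                    fh.write(f"{mid}\t{km.names.get(mid, mid)}\t{','.join(sorted(km.modules[mid]))}\n")
            truth_json = {
                "planted_cluster_members": truth.planted_cluster_members,
                "planted_differential_features": truth.planted_differential_features,
                "planted_ko_modules": truth.planted_ko_modules,
                "planted_links": truth.planted_links,
                "planted_discriminative_taxa": truth.planted_discriminative_taxa,
            }
            with open(out / "truth.json", "w", encoding="utf-8") as fh:
                json.dump(truth_json, fh, indent=1)
        else:
            paths = cfg["inputs"]
            for key in ("metabolome", "sample_info", "taxa", "ko", "ko_modules"):
                if key not in paths or not Path(paths[key]).exists():
                    raise FileNotFoundError(f"missing input path for {key!r}")
            raw = read_feature_matrix(paths["metabolome"])
            if "metabolome_meta" in paths:
                meta = pd.read_csv(paths["metabolome_meta"], sep="\t", index_col=0)
                raw = FeatureMatrix(raw.values, meta)
            info = read_sample_info(paths["sample_info"])
            taxa = read_feature_matrix(paths["taxa"])
            ko, _ = read_humann_table(paths["ko"])
            km = read_ko_module_map(paths["ko_modules"])
    else:
        meta = pd.read_csv(out / "metabolome_meta.tsv", sep="\t", index_col=0)
        raw = FeatureMatrix(read_feature_matrix(out / "metabolome_raw.tsv").values, meta)
        info = read_sample_info(out / "sample_info.tsv")
        taxa = read_feature_matrix(out / "taxa_species.tsv")
        ko = read_feature_matrix(out / "ko_abundance.tsv")
        km = read_ko_module_map(out / "ko_modules.tsv")
        if (out / "truth.json").exists():
            with open(out / "truth.json", encoding="utf-8") as fh:
                truth_json = json.load(fh)
                truth = truth_json
    results.update({"info": info, "taxa": taxa, "ko": ko, "ko_modules": km, "truth": truth})

    study = info[~info["is_qc"]]
    pre = study[study["timepoint"] == "pre"]
    pre_gp = pre[pre["group"].isin(["GR", "PR"])]

    # ---- stage: preprocess ----------------------------------------------
    if "preprocess" in stages:
        processed, report = run_preprocessing(raw, info, **cfg["preprocess"])
        _write_matrix(processed, out / "metabolome_processed.tsv", cfg)
        processed.feature_meta.to_csv(
            out / "metabolome_processed_meta.tsv", sep="\t", index_label="feature_id"
        )
        _write_tsv(report.to_frame(), out / "preprocess_report.tsv", cfg, index_label="row")
        results["preprocess_report"] = report
    elif {"screen", "modules", "integrate"} & set(stages):
        meta = pd.read_csv(out / "metabolome_processed_meta.tsv", sep="\t", index_col=0)
        processed = FeatureMatrix(
            read_feature_matrix(out / "metabolome_processed.tsv").values, meta
        )
    else:
        processed = None
    results["metabolome"] = processed

    met_pre = processed.subset_samples(list(pre_gp.index)) if processed is not None else None

    # ---- stage: screen (multivariate + differential metabolites) ---------
    if "screen" in stages:
        scores, loadings, frac = pca_scores(
            processed.subset_samples(list(study.index)), scaling="autoscale", n_components=2
        )
        _write_tsv(scores, out / "pca_scores.tsv", cfg, index_label="sample_id")
        tree = ward_d2_tree(met_pre, axis="samples")
        (out / "dendrogram_pre_samples.newick").write_text(tree.to_newick() + "\n")
        sc = cfg["screen"]
        screen = screen_differential(
            met_pre,
            pre_gp["group"].to_numpy(),
            vip_threshold=sc["vip"], lfc_threshold=sc["lfc"], alpha=sc["alpha"],
            n_components=sc["n_components"],
        )
        _write_tsv(screen, out / "screen_baseline_gr_vs_pr.tsv", cfg, index_label="feature_id")
        results["screen"] = screen
    elif (out / "screen_baseline_gr_vs_pr.tsv").exists():
        # nothing downstream consumes the screen; read it back only for the
        # completeness of the returned bundle
        screen = pd.read_csv(out / "screen_baseline_gr_vs_pr.tsv", sep="\t",
                             index_col=0, comment="#")
        results["screen"] = screen

    # ---- stage: diversity -------------------------------------------------
    taxa_study = taxa.subset_samples([s for s in taxa.sample_ids if s in study.index])
    if "diversity" in stages:
        rows = []
        for sid in taxa_study.sample_ids:
            v = taxa_study.values[sid].to_numpy(float)
            rows.append({
                "sample_id": sid,
                "group": study.loc[sid, "group"],
                "timepoint": study.loc[sid, "timepoint"],
                "shannon": alpha_diversity(v, "shannon"),
                "simpson": alpha_diversity(v, "simpson"),
                "observed": alpha_diversity(v, "observed"),
            })
        diversity = pd.DataFrame(rows).set_index("sample_id")
        _write_tsv(diversity, out / "alpha_diversity.tsv", cfg, index_label="sample_id")
        results["diversity"] = diversity

    # ---- stage: lefse ------------------------------------------------------
    if "lefse" in stages:
        ranks = expand_clades(taxa_study)
        allranks = concat_rank_matrices(ranks)
        pre_taxa = allranks.subset_samples(
            [s for s in allranks.sample_ids if s in pre_gp.index]
        )
        lf = cfg["lefse"]
        lefse_res = lefse(
            pre_taxa,
            pre_gp.loc[pre_taxa.sample_ids, "group"].to_numpy(),
            kw_alpha=lf["kw_alpha"], n_boot=lf["n_boot"],
            lda_threshold=lf["lda_threshold"], seed=seed,
        )
        _write_tsv(lefse_res, out / "lefse_baseline.tsv", cfg, index_label="feature_id")
        results["lefse"] = lefse_res

    # ---- stage: modules ----------------------------------------------------
    mod = cfg["modules"]
    if "modules" in stages:
        # module structure is a property of the metabolome itself, so the
        # co-expression network uses every study sample; the trait/covariate
        # association below is restricted to baseline samples
        met_study = processed.subset_samples(list(study.index))
        scan = pick_soft_threshold(
            met_study, r2_cut=mod["r2_cut"], log2_transform=mod["log2_transform"]
        )
        beta = scan.chosen_beta if scan.chosen_beta is not None else 9
        modules = detect_modules(
            met_study, beta=beta, deep_split=mod["deep_split"], min_size=mod["min_size"],
            kme_assign_threshold=mod["kme_assign_threshold"],
            merge_height=mod["merge_height"], log2_transform=mod["log2_transform"],
        )
        modules.scan = scan
        _write_tsv(scan.scan.set_index("beta"), out / "soft_threshold_scan.tsv", cfg,
                   index_label="beta")
        assign = pd.DataFrame({
            "label": modules.assignment,
            "color": [modules.module_colors[l] for l in modules.assignment],
            "kme": modules.kme,
        })
        _write_tsv(assign, out / "module_assignment.tsv", cfg, index_label="feature_id")
        _write_tsv(modules.eigenfeatures, out / "module_eigenfeatures.tsv", cfg,
                   index_label="module")
        trait = pre["dpasi"].to_numpy(float)
        covariate = pre["bmi"].to_numpy(float)
        eigen_pre_cols = modules.eigenfeatures[list(pre.index)]
        assoc = module_trait_association(eigen_pre_cols, trait, covariate)
        _write_tsv(assoc, out / "module_trait_association.tsv", cfg, index_label="module")
        results["modules"] = modules
        results["module_trait"] = assoc
        results["chosen_beta"] = scan.chosen_beta
        eigen = modules.eigenfeatures
    elif "integrate" in stages:
        eigen = pd.read_csv(out / "module_eigenfeatures.tsv", sep="\t", index_col=0, comment="#")
        assoc = pd.read_csv(out / "module_trait_association.tsv", sep="\t", index_col=0,
                            comment="#")
        results["module_trait"] = assoc
    else:
        eigen = None

    # ---- stage: integrate --------------------------------------------------
    if "integrate" in stages:
        ig = cfg["integrate"]
        pre_ids = [s for s in pre.index if s in set(ko.sample_ids)]
        ko_pre = ko.subset_samples(pre_ids)
        met_pre_all = processed.subset_samples(pre_ids)
        sc_met, _, _ = pca_scores(met_pre_all, scaling="autoscale", n_components=2)
        ko_log = FeatureMatrix(np.log2(ko_pre.values + 1.0))
        sc_ko, _, _ = pca_scores(ko_log, scaling="autoscale", n_components=2)
        fit = protest(sc_ko.to_numpy(), sc_met.to_numpy(), n_perm=ig["n_perm"], seed=seed)
        pro = pd.DataFrame([{
            "m2": fit.m2, "protest_p": fit.protest_p, "n_perm": fit.n_perm,
            "scale": fit.scale, "note": fit.note,
        }])
        _write_tsv(pro.set_index(pd.Index(["ko_vs_metabolome"], name="comparison")),
                   out / "procrustes.tsv", cfg, index_label="comparison")
        eigen_pre = eigen[pre_ids] if all(c in eigen.columns for c in pre_ids) else eigen
        trait = pre.loc[pre_ids, "dpasi"].to_numpy(float)
        covariate = pre.loc[pre_ids, "bmi"].to_numpy(float)
        cd = crossdomain_map(
            ko_pre, eigen_pre, km, trait, covariate,
            alpha=ig["alpha"], require_partial=ig["require_partial"],
        )
        _write_tsv(cd["map"], out / "crossdomain_map.tsv", cfg, index_label="row")
        _write_tsv(cd["module_selection"], out / "ko_module_selection.tsv", cfg,
                   index_label="module")
        _write_tsv(cd["cluster_selection"], out / "cluster_selection.tsv", cfg,
                   index_label="module")
        results["procrustes"] = fit
        results["crossdomain"] = cd

    # ---- recovery report against planted truth ----------------------------
    if truth is not None and "modules" in stages and "integrate" in stages:
        results["recovery"] = _recovery_report(results, out, cfg)
    return results


def _recovery_report(results: dict, out: Path, cfg: dict) -> dict:
    """Compare detected structure with the planted truth (synthetic runs)."""
    truth = results["truth"]
    if not isinstance(truth, dict):
        truth = {
            "planted_cluster_members": truth.planted_cluster_members,
            "planted_links": truth.planted_links,
        }
    modules = results.get("modules")
    report: dict = {}
    if modules is not None and truth.get("planted_cluster_members"):
        planted = truth["planted_cluster_members"]
        member_of = {}
        for cid, members in planted.items():
            for f in members:
                member_of[f] = cid
        feats = [f for f in modules.assignment.index if f in member_of]
        if feats:
            report["module_ari"] = adjusted_rand_index(
                [member_of[f] for f in feats],
                [modules.assignment[f] for f in feats],
            )
        report["n_modules_detected"] = len(modules.labels)
        report["chosen_beta"] = results.get("chosen_beta")
    cd = results.get("crossdomain")
    if cd is not None and truth.get("planted_links"):
        cmap = cd["map"]
        link_rows = []
        for mid, cid, sign in truth["planted_links"]:
            # map the planted cluster id onto the detected module that holds
            # the majority of its members
            det = None
            if results.get("modules") is not None:
                members = truth["planted_cluster_members"].get(cid, [])
                labels = [results["modules"].assignment.get(f, 0) for f in members]
                labels = [l for l in labels if l > 0]
                if labels:
                    lab = pd.Series(labels).mode()[0]
                    det = f"ME{results['modules'].module_colors[lab]}"
            hit = cmap[(cmap["kegg_module"] == mid) & (cmap["metabolite_cluster"] == det)]
            link_rows.append({
                "kegg_module": mid, "planted_cluster": cid, "detected_cluster": det,
                "planted_sign": sign,
                "recovered": bool(len(hit)) and bool((hit["mark"] != "none").any()),
                "scc_bg_adj": float(hit["scc_bg_adj"].iloc[0]) if len(hit) else np.nan,
            })
        report["links"] = link_rows
    with open(out / "recovery_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report
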