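"""Microbiome screens and cross-domain integration.

Runs the LEfSe-style discriminant-taxa screen at baseline, compares the
metabolome and KO-profile ordinations with Procrustes/PROTEST, and builds
the background-adjusted KEGG-module x metabolite-cluster association map.
"""

import numpy as np

from seragut import (
    crossdomain_map,
    detect_modules,
    lefse,
    pca_scores,
    protest,
    run_preprocessing,
)
from seragut.io_tables import FeatureMatrix
from seragut.synthetic import simulate_scenario

sim = simulate_scenario(seed=1)
info, taxa, ko, km, truth = (
    sim["info"], sim["taxa"], sim["ko"], sim["ko_modules"], sim["truth"]
)
baseline = info[(~info["is_qc"]) & (info["timepoint"] == "pre")
                & info["group"].isin(["GR", "PR"])]

# --- discriminant taxa at baseline -----------------------------------------
from seragut.microbiome import concat_rank_matrices, expand_clades

allranks = concat_rank_matrices(expand_clades(taxa))
taxa_pre = allranks.subset_samples(list(baseline.index))
res = lefse(taxa_pre, list(baseline["group"]), seed=1)
survivors = res[res["passes"]]
print(f"LEfSe survivors (|LDA| >= 2): {len(survivors)} clades")
print(survivors.round(3).head(8).to_string())
planted_found = [c for c in truth.planted_discriminative_taxa
                 if c in res.index and res.loc[c, "passes"]]
print(f"planted discriminative taxa recovered: "
      f"{len(planted_found)}/{len(truth.planted_discriminative_taxa)}")

# --- ordination congruence ---------------------------------------------------
processed, _ = run_preprocessing(sim["metabolome"], info)
pre_all = info[(~info["is_qc"]) & (info["timepoint"] == "pre")]
met_scores, _, _ = pca_scores(processed.subset_samples(list(pre_all.index)),
                              scaling="autoscale", n_components=2)
ko_pre = ko.subset_samples(list(pre_all.index))
ko_log = FeatureMatrix(np.log2(ko_pre.values + 1.0))
ko_scores, _, _ = pca_scores(ko_log, scaling="autoscale", n_components=2)
fit = protest(ko_scores.to_numpy(), met_scores.to_numpy(), n_perm=999, seed=1)
print(f"\nProcrustes M2 = {fit.m2:.3f}, PROTEST p = {fit.protest_p:.3f}")

# --- cross-domain map --------------------------------------------------------
study = info[~info["is_qc"]]
modules = detect_modules(processed.subset_samples(list(study.index)),
                         beta=9, log2_transform=True)
cd = crossdomain_map(
    ko_pre,
    modules.eigenfeatures[list(pre_all.index)],
    km,
    pre_all["dpasi"].to_numpy(float),
    pre_all["bmi"].to_numpy(float),
)
print(f"\ncross-domain map status: {cd['status']}")
print(cd["map"].round(4).to_string())
print("planted link:", truth.planted_links)
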