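"""Detect co-abundance metabolite modules and associate them with dPASI.

Fits a signed weighted correlation network on the study samples, cuts the
topological-overlap dendrogram into modules, and tests each module
eigenfeature against the clinical improvement score (dPASI) with BMI as a
covariate on the baseline samples.
"""

from seragut import (
    detect_modules,
    module_trait_association,
    pick_soft_threshold,
    run_preprocessing,
)
from seragut.synthetic import simulate_scenario

sim = simulate_scenario(seed=1)
processed, _ = run_preprocessing(sim["metabolome"], sim["info"])
info = sim["info"]
study = info[~info["is_qc"]]
met = processed.subset_samples(list(study.index))

scan = pick_soft_threshold(met, log2_transform=True)
print(scan.scan.head(10).round(3).to_string())
beta = scan.chosen_beta if scan.chosen_beta is not None else 9
print(f"chosen beta: {scan.chosen_beta} (using {beta})")

modules = detect_modules(met, beta=beta, log2_transform=True)
sizes = modules.assignment[modules.assignment > 0].value_counts()
print(f"\n{len(modules.labels)} modules; sizes:")
for label, n in sizes.items():
    print(f"  {modules.module_colors[label]:>10}: {n} features")

baseline = study[study["timepoint"] == "pre"]
assoc = module_trait_association(
    modules.eigenfeatures[list(baseline.index)],
    baseline["dpasi"].to_numpy(float),
    baseline["bmi"].to_numpy(float),
)
print("\nmodule-dPASI association (BMI-adjusted):")
print(assoc.round(4).to_string())
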