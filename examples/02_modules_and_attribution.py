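"""Module discovery, scoring, and cell-type attribution.

Plants two latent co-expression programs — gene sets whose Poisson rates
rise together across smooth spatial fields, independent of cell type —
then runs the full pipeline: conditional correlation, Leiden module
detection on the thresholded matrix, inverse-sqrt-weighted module
scores, and cell-type attribution.
"""

import numpy as np

import nichecor as nc

cfg = nc.SimulationConfig(
    n_cells=8000,
    seed=1,
    planted_modules=[
        nc.PlantedModule("progA"),
        nc.PlantedModule("progB", affected_cell_types=("TypeB",)),
    ],
)
ds, truth = nc.simulate_dataset(cfg)
ds = nc.filter_min_counts(ds, 1)

run_cfg = nc.RunConfig(seed=1, numeric_covariates=["total_counts", "negprobes"])
result = nc.run_analysis(ds, run_cfg)

print(f"{len(result.modules)} modules detected "
      f"(edge threshold {run_cfg.edge_threshold}, min size {run_cfg.min_module_size})")
for mod in result.modules:
    print(f"  {mod.name}: {len(mod.genes)} genes, "
          f"mean within-module conditional correlation {mod.avg_cor:.2f}")

metrics = nc.evaluate_recovery(result.modules, truth)
print(f"\nrecovery vs planted truth: pairwise F1 {metrics['f1']:.2f}, "
      f"adjusted Rand {metrics['ari']:.2f}")

print("\ncell-type attribution A(c) per module (max over the module's genes")
print("of the correlation between the module's environment score and the")
print("type-restricted neighborhood expression of that gene):")
cell_types = sorted(set(ds.cell_type))
for mod in result.modules:
    scores = {ct: result.attrib.celltype_score(mod.name, ct) for ct in cell_types}
    line = ", ".join(f"{ct}: {v:.2f}" for ct, v in scores.items())
    print(f"  {mod.name}: {line}")
print("\nThe program modulated only inside TypeB cells attributes sharply to")
print("TypeB; the shared program attributes to whichever cell types populate")
print("the regions where its latent field happens to be high.")
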