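"""Benchmark-design generators: SE genes, depth sweeps, cell-cell signaling.

Generates (1) a spatial-expression benchmark with 100 SE genes among 1000,
(2) a sequencing-depth experimental-design sweep, and (3) a small
cell-cell-communication dataset with ligand boosting between adjacent cell
types, printing the ground-truth calibration of each.
"""

import numpy as np

from srtgen import (CCCDesign, SEDesign, ccc_benchmark, clustering_scenarios,
                    make_reference_fixture, se_benchmark, synthetic_lr_pairs)

template, _ = make_reference_fixture(1, 673, layout="random", n_domains=5,
                                     pattern="layered", seed=31)

# --- spatial-expression benchmark -------------------------------------------
design = SEDesign(n_genes=1000, n_se=100, baseline_mu=0.4, phi=0.35,
                  target_domain="domain_3", folds=(5.0, 0.2), seed=1)
data, truth = se_benchmark(template, design)
inside = data.domains == "domain_3"
up = truth.index[truth.direction == "up"]
ratio = data.counts[up][:, inside].mean() / data.counts[up][:, ~inside].mean()
print(f"SE benchmark: {truth.is_se.sum()} SE genes "
      f"({(truth.direction == 'up').sum()} up, "
      f"{(truth.direction == 'down').sum()} down)")
print(f"realized in/out mean ratio of up-regulated genes: {ratio:.2f} "
      "(designed: 5.0)")

# --- experimental-design sweep ----------------------------------------------
ref, _ = make_reference_fixture(50, 300, layout="grid", n_domains=3,
                                param_sampler="starmap_like", seed=8)
total = float(ref.counts.sum())
outs = clustering_scenarios(ref, depths=[0.5 * total, total, 2 * total],
                            scenario="I", seed=2)
print("\nDepth sweep (scenario I), total counts per run:")
for o in outs:
    print(f"  target {o.config['scenario']['target_total']:.0f} -> "
          f"realized {o.data.counts.sum()}")

# --- cell-cell communication -------------------------------------------------
ccc = ccc_benchmark(template, CCCDesign(
    n_locations=2000, n_genes=200, cells_per_type=600, scenario=1,
    lr_pairs=synthetic_lr_pairs(60, 200, seed=3), fold=5.0, seed=5))
per_region = {str(r): int((ccc.regions == r).sum())
              for r in np.unique(ccc.regions)}
print(f"\nCCC benchmark: regions of equal size {per_region}")
print(f"boosted (ligand, cell) entries: {ccc.boosted.sum()}")
print("truth table head:")
print(ccc.truth.head(3).to_string(index=False))
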