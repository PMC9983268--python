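# srtgen

Spatial-pattern-preserving simulation of spatially resolved transcriptomics
(SRT) count data.

## The problem

Developing and benchmarking SRT analysis methods — spatial clustering for
tissue-domain detection, spatially-expressed (SE) gene identification,
cell-cell-communication inference — requires synthetic datasets with a known
ground truth that still *look like* real SRT data. Generic single-cell
RNA-seq simulators can reproduce count distributions, but they ignore the
spatial coordinates entirely and therefore destroy the spatial expression
patterns that SRT methods are built to detect. `srtgen` simulates
gene × location count matrices that preserve both:

* **count structure** — per-gene expression mean, variance, coefficient of
  variation, and zero proportion, plus per-location zero proportion and
  library size; and
* **spatial structure** — each gene's spatial expression pattern, as
  measured for example by Moran's I.

## The method

**Reference-based simulation** proceeds in three steps:

1. **Locations.** Use the reference's measured locations directly, or
   estimate the tissue outskirt with a concave hull and generate a
   user-specified number of new locations inside it — on a square lattice
   (Visium-like arrays) or as a uniform random point process (imaging-based
   platforms). Domain labels are carried to new locations by k-nearest-
   neighbor majority vote (k = 3 by default).
2. **Count models.** For each gene, fit Poisson, zero-inflated Poisson
   (ZIP), negative binomial (NB), and zero-inflated negative binomial
   (ZINB) models by maximum likelihood and keep the fit with the lowest
   AIC = 2k − 2ℓ. The NB uses the mean/overdispersion parameterization
   Var(X) = μ + φμ²; zero-inflated families mix a point mass π₀ at zero
   with the count component. Fresh counts are then sampled from the
   selected model.
3. **Rank assignment.** Per gene, the i-th largest simulated count is
   placed at the location with the i-th largest reference expression (ties
   broken by a seeded permutation). This preserves the gene's spatial
   pattern exactly in rank while the counts themselves are new draws.

Fitting and assignment run either tissue-wide or independently within each
annotated domain; means can be rescaled for sequencing-depth designs, and a
region's spatial pattern can be extrapolated onto another region through an
affine map between the two regions' hull frames.

**Reference-free simulation** builds tissues from named primitives (circle,
square, annulus) or arbitrary polygons, labels domains geometrically, and
draws counts from user-specified models with per-domain mean fold-changes.

The package also ships the three **benchmark-design generators** (SE
null/alternative designs, sequencing-depth/location-number experimental
design grids, and ligand-receptor cell-cell-communication datasets with
spatial adjacency signal) and the **fidelity metrics** (six metric
distributions, two-sample Kolmogorov–Smirnov comparisons, per-gene Moran's
I) used to validate synthetic data against their reference.

## A worked example

```python
from srtgen import (RefSimConfig, fidelity_report, make_reference_fixture,
                    simulate_tissue)

ref, truth = make_reference_fixture(
    n_genes=200, n_locations=400, layout="grid", n_domains=4,
    pattern="layered", n_spatial_genes=20, spatial_fold=8.0, seed=1)
out = simulate_tissue(ref, RefSimConfig(mode="tissue", seed=2))
report = fidelity_report(ref, out.data)
print(report.ks_table)
```

prints (see `examples/01_reference_based_simulation.py`):

```
       metric     D        p
         mean 0.025 1.000000
     variance 0.035 0.999350
           cv 0.035 0.999350
    zero_prop 0.045 0.981954
loc_zero_prop 0.070 0.268233
 library_size 0.050 0.680263
```

Every KS p-value is above 0.05: none of the six count metrics differs
detectably between the synthetic and the reference data. The same run
reports a per-gene Moran's I concordance (Pearson r between reference and
synthetic I values) of 0.990 — the spatial patterns survive the simulation.
The `examples/` directory holds one short script per capability
(reference-based simulation, model selection, reference-free designs,
benchmark generators).

A thin CLI mirrors the library: `srtgen fit|simulate|free|design-se|
design-ccc|design-clustering|metrics|fixture`, each writing outputs plus a
provenance JSON capturing the configuration and seed.

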