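# Methods

This note documents the statistical models, numerical choices, and design
decisions behind `srtgen`, and states what the synthetic-data generator does
and does not emulate.

## Count models

Each gene's counts across locations are modelled independently by one of
four families:

| family  | parameters      | pmf |
|---------|-----------------|-----|
| Poisson | μ               | Pois(x; μ) |
| NB      | μ, φ            | NB(x; μ, φ), Var = μ + φμ² |
| ZIP     | μ, π₀           | π₀·1[x=0] + (1−π₀)·Pois(x; μ) |
| ZINB    | μ, φ, π₀        | π₀·1[x=0] + (1−π₀)·NB(x; μ, φ) |

The NB is parameterized by its mean μ and overdispersion φ (= 1/size of the
size-parameterized NB), so φ → 0 recovers the Poisson. π₀ is the
structural-zero probability; the marginal mean of a zero-inflated family is
(1 − π₀)μ. Family selection is by lowest AIC = 2k − 2ℓ with k = 1 (Poisson),
2 (ZIP, NB), 3 (ZINB); AIC ties within 1e-9 resolve toward parsimony in the
order Poisson, NB, ZIP, ZINB (NB before ZIP at equal k because
overdispersion, not zero inflation, is the more common mechanism in UMI
counts). An all-zero gene short-circuits to Poisson with μ = 0.

### Fitting

* Poisson: closed form, μ̂ = x̄.
* NB: μ̂ = x̄ (the NB mean score is free of φ), and φ is found by a coarse
  log-grid plus bounded Brent refinement of the profile likelihood.
* ZIP / ZINB: π₀ has a closed-form conditional MLE given the
  count-component parameters. Setting the π₀ score to zero gives
  π̂₀ = (p₀ᵒᵇˢ − f₀) / (1 − f₀) clipped to [0, 1), where p₀ᵒᵇˢ is the
  observed zero fraction and f₀ the count component's zero probability.
  ZIP therefore reduces to a 1-D profile optimization in μ (grid + Brent)
  and ZINB to a 2-D Nelder–Mead in (log μ, log φ), started from the nested
  NB solution, the nested ZIP solution (φ at its floor), and a moment
  estimate. Keeping the nested solutions among the candidates guarantees
  the likelihood nesting inequalities ℓ(ZINB) ≥ ℓ(NB) ≥ ℓ(Poisson) and
  ℓ(ZINB) ≥ ℓ(ZIP) ≥ ℓ(Poisson) to optimizer tolerance.
* Genes with no observed zeros have a flat likelihood in π₀; the fit pins
  π₀ = 0 and the ZI families collapse onto their base families.

### Numerics

Counts are compressed to (value, weight) pairs before fitting, which makes
a likelihood evaluation O(#unique values) — sparse SRT genes have very few.
The NB log-pmf is computed with the integer product form
Σ_{j<x} log(r + j), r = 1/φ, instead of a `gammaln` difference; this stays
fully accurate for r up to ~1e12, so φ can be floored at 1e-12 and the NB
boundary is numerically indistinguishable from the Poisson (the floored-NB
vs Poisson log-likelihood gap at n = 5000, μ ≈ 3 is ~1e-7, comfortably
inside the 1e-6 nesting slack). For counts above 65536 the product form is
replaced by the `gammaln` difference, whose rounding is negligible at those
magnitudes. π₀ is capped at 1 − 1e-12. NB sampling uses the gamma–Poisson
mixture, which is robust for arbitrarily small φ.

## Rank-preserving assignment

For one gene, the sorted simulated counts are placed at locations ordered
by decreasing reference expression; tied reference blocks are permuted with
a seeded RNG to avoid coordinate-dependent bias. The output is always a
permutation of the simulated multiset (library size per gene is conserved
through assignment). With tie-free reference *and* tie-free simulated
counts the Spearman correlation between reference and synthetic expression
is exactly 1; when the simulated draw contains ties, average-rank Spearman
is marginally below 1 by construction even though rank order is preserved
exactly — the implementation-independent invariant is that synthetic counts
are monotone along decreasing reference expression, and the tests assert
exactly that.

## Geometry

* **Concave hull**: shapely's `concave_hull` with
  ratio = concavity/(1 + concavity); concavity ∈ (0, ∞), default 1.0
  (ratio 0.5). Larger concavity → larger enclosed area, converging to the
  convex hull; all input points lie inside or on the polygon. The
  parameter's scale is this package's own; it is not calibrated to any
  other implementation's knob.
* **Grid locations**: lattice pitch solved by bisection until the interior
  point count is within ±10% of the target, ties resolved toward more
  points. **Random locations**: rejection sampling from the bounding box,
  exactly n points, i.i.d. uniform over the polygon.
* **Label transfer**: Boyer–Moore majority vote over the k (default 3)
  Euclidean nearest reference neighbors; when no strict majority exists
  (e.g. three distinct labels at k = 3) the single nearest neighbor's label
  is used — deterministic and local. kNN distance ties break toward the
  lowest reference index.
* **Affine region mapping**: the two polygons are each summarized by an
  anchor frame — area centroid, principal axes of the polygon's second
  moments (signs fixed to avoid reflection), and projected half-extents —
  and the transform carries one frame onto the other. Frame alignment
  avoids vertex-to-vertex correspondences, which are ill-defined between
  hulls with different vertex counts. A least-squares point-pair fit is
  also provided.
* The annulus primitive is represented as a single simple "keyhole"
  polygon (outer and inner rings joined by an infinitesimal slit, relative
  width 1e-9), keeping the one-simple-polygon contract while excluding the
  hole from containment and sampling.

## Reference-based simulation

Tissue-based runs fit/sample/rank genome-wide; domain-specific runs do all
three independently within each annotated domain (each domain needs ≥ 2
locations). When new locations are requested, model fitting still uses the
original reference counts; a pseudo-reference — for each gene and new
location, one count sampled uniformly with replacement from the location's
k nearest reference neighbors — is used only to rank the new locations. In
domain mode, labels are transferred first and the pseudo-reference is
imputed per domain from that domain's reference locations only, preventing
cross-domain leakage. Region redesign projects the source region's
locations (carrying their counts) through the affine map into the target
region and then runs exactly the new-location mechanics with the projected
locations as reference; counts outside the target region are untouched,
and the simulated counts come from models fitted on the source region.

**Depth scaling** multiplies every fitted μ by the factor before sampling
(φ, π₀ unchanged), keeping each selected family closed under scaling;
binomial thinning of sampled counts is available as an alternative
(`thinning=True`) for factors ≤ 1 but is not the default mechanism. When
the location count changes, reference-location fits are reused rather than
refitted.

## Reference-free simulation

Counts are drawn i.i.d. per location with the domain fold applied to the
count-component mean only (not to π₀, matching a *mean* fold-change).
Because draws are i.i.d. within a domain, allocation is exchangeable and
genes show domain-specific but no intra-domain spatial structure — by
design, reference-free genes do not carry general spatial patterns.
Geometric domain labeling assigns each location the label of the largest
(outermost) containing sub-polygon; uncovered locations get "background".

## Benchmark designs

* **SE designs**: NB counts; non-SE genes share the tissue baseline
  (μ = baseline, φ fixed); SE genes take μ·fold inside the target domain.
  Canonical regimes: baseline μ 0.03 with φ 0.3 and folds 5/10 (up) and
  1/5/1/10 (down) for the sparse array regime; baseline μ 0.4 with φ 0.35
  and folds 3/4, 1/3/1/4 for the moderate single-cell regime; 1000 genes,
  100 SE (50 per direction per setting), or 0 SE under the null.
* **Clustering scenarios**: scenario I rescales the per-gene means so the
  expected total tracks each target depth at fixed locations; scenario II
  fixes the total and sweeps the location count (per-location depth scales
  inversely); scenario III crosses the two grids at fixed per-location
  depth (the canonical grid is 6 location counts × 5 depths = 30 runs).
  Each cell is a full domain-specific simulation.
* **CCC designs**: 5000 cells uniform in the tissue shape, partitioned into
  four equal-count strips along the first principal axis of the point
  cloud (equal-count strips realize "equal-sized regions" exactly); cell
  types drawn per region from the rotated composition vectors
  (0.70/0.10/0.10/0.10, 0.45/0.45/0.05/0.05, 0.60/0.30/0.05/0.05,
  0.35/0.30/0.30/0.05; region r ranks types r, r+1, r+2, r+3 mod 4). The
  expression pool is 5000 genes × 8000 cells (2000 per type), NB-shared
  (homogeneous) or NB per type (heterogeneous); pool cells are sampled onto
  positions without replacement unless a type's demand exceeds its pool.
  930 L-R pairs are each assigned uniformly to one of the 16 ordered type
  pairs (self-pairs included). For every (L, R, A, B), each A cell whose 4
  nearest cells include a B cell has its **ligand** count multiplied by the
  fold (1 = null, 5 or 10) and rounded to integer; receptor expression in B
  cells is deliberately left untouched. A gene serving as ligand in
  several pairs can be boosted more than once in a cell that qualifies for
  each. The heterogeneous mode's default type parameters are a synthetic
  stand-in (log-normal spread around the homogeneous baseline); explicit
  per-type parameters can be supplied.

## Fidelity metrics

Gene-wise mean, sample variance (n − 1 denominator), cv = sd/mean (missing
when mean = 0 and dropped from KS comparisons), zero proportion;
location-wise zero proportion and library size; two-sample asymptotic KS
per metric; per-gene Moran's I
I = (n/S₀) Σᵢⱼ wᵢⱼ(xᵢ−x̄)(xⱼ−x̄) / Σᵢ(xᵢ−x̄)², zero diagonal, computed on
raw counts. The default weights are binary kNN with k = 5, symmetrized by
max(W, Wᵀ) and not row-standardized — robust across lattice and random
layouts; inverse-distance weights are available. Moran's I of a constant
gene is undefined and reported missing. No significance test is attached
to Moran's I; it is used descriptively.

## Synthetic reference fixtures

`make_reference_fixture` emulates two data regimes: sparse array spots
(log-normal gene means with median 0.03, NB dispersion around 0.3) and
moderate single-cell counts (median 0.4, dispersion 0.35), with layered
domains as contiguous equal-count bands and an adjustable number of
"layered" genes whose mean is elevated (default 8-fold) in one domain.
What it does **not** emulate: gene–gene correlation (the framework fits one
gene at a time, so simulated genes are independent), platform-specific
artifacts (spot swapping, segmentation errors, histology covariates), and
continuous within-domain gradients. Tests passing on fixtures therefore
demonstrate correctness of the machinery, not that every property of a
specific real tissue is reproduced.

## Problem sizes and seeds

A single user seed is expanded into independent substreams keyed by
(stage, gene/domain index) via `numpy` SeedSequence, so outputs are
bit-reproducible and adding genes or stages does not perturb existing
draws. The test suite exercises the distribution-preservation guarantee at
1000 genes × 2000 locations over 10 seeds and the MLE-vs-grid-oracle check
at n = 5000 with 20 replicates per family; other tests use smaller
fixtures (hundreds of genes/locations) chosen to keep the full suite
comfortably fast while leaving Monte-Carlo margins near their asymptotic
values.

## Known limitations

* No gene–gene or cell–cell count dependence; copula-style joint structure
  is out of scope.
* Single simple polygons only (no multi-polygon tissues or true holes —
  the annulus keyhole is the one sanctioned workaround).
* Covariate-dependent (regression) count models are not supported.
* The Spearman-exactly-1 pattern guarantee applies to tie-free pairs; tied
  draws preserve rank order exactly but score marginally below 1 under
  average-rank Spearman.
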