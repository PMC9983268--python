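"""Benchmark-design generators with recorded ground truth.

Three families of method-evaluation datasets:

* Spatial-expression (SE) benchmarks — negative binomial counts on an
  annotated tissue template; a null design of 1000 genes with no spatial
  signal, and alternative designs where 100 SE genes (50 up, 50 down per
  strength setting) carry a domain-specific mean fold-change against the
  tissue baseline. Defaults mirror a sparse Visium-like cortex regime
  (baseline mean 0.03, dispersion 0.3, folds 5/10 and 1/5/1/10) and a
  moderate STARmap-like regime (0.4, 0.35, folds 3/4 and 1/3/1/4).

* Spatial-clustering experimental-design grids — domain-specific
  simulations swept over total sequencing depth (scenario I), number of
  locations at fixed total depth (scenario II), or the cross-product at
  fixed per-location depth (scenario III: 6 location counts x 5 depths in
  the canonical grid).

* Cell-cell-communication (CCC) benchmarks — 5000 single cells placed
  uniformly in a tissue shape, partitioned into four equal-count regions
  with rotated cell-type compositions; a 5000-gene x 8000-cell expression
  pool (homogeneous or cell-type-specific NB); 930 ligand-receptor pairs
  assigned uniformly at random to the 16 ordered cell-type pairs; and the
  ligand gene boosted by a fixed fold in every A cell whose four nearest
  cells include a B cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import spawn_rng
from .count_models import sample_family
from .data_core import SRTData, SimOutput
from .geometry import ShapeProfile, _knn_indices, estimate_shape, \
    generate_random_locations
from .simulate_ref import RefSimConfig, simulate_domains

__all__ = [
    "SEDesign",
    "CCCDesign",
    "CCC_SCENARIOS",
    "se_benchmark",
    "clustering_scenarios",
    "ccc_benchmark",
    "CCCResult",
    "assign_lr_pairs",
    "synthetic_lr_pairs",
    "apply_adjacency_boost",
]


# ---------------------------------------------------------------------------
# spatial-expression benchmarks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SEDesign:
    """Design of one SE benchmark setting.

    ``folds`` lists the mean fold-changes applied inside ``target_domain``;
    the ``n_se`` SE genes are split evenly across the folds in the given
    order (e.g. ``(5.0, 0.2)`` gives 50 up-regulated and 50 down-regulated
    genes of the canonical 100). ``n_se = 0`` is the null design.
    """

    n_genes: int = 1000
    n_se: int = 100
    baseline_mu: float = 0.03
    phi: float = 0.3
    target_domain: str = ""
    folds: tuple[float, ...] = (5.0, 0.2)
    seed: int = 0

    def __post_init__(self):
        if self.n_se > self.n_genes:
            raise ValueError("n_se cannot exceed n_genes")
        if any(f <= 0 for f in self.folds):
            raise ValueError("folds must be positive")


def se_benchmark(domain_template: SRTData, design: SEDesign
                 ) -> tuple[SRTData, pd.DataFrame]:
    """Generate an SE benchmark dataset plus its truth table.

    Non-SE genes are NB(baseline_mu, phi) allocated randomly across all
    locations; SE genes have NB mean baseline_mu outside the target domain
    and fold x baseline_mu inside it. The truth table records per gene the
    SE indicator, fold, direction and target domain.
    """
    if domain_template.domains is None:
        raise ValueError("the template must carry domain labels")
    if design.n_se > 0 and design.target_domain not in set(domain_template.domains):
        raise ValueError(f"unknown domain {design.target_domain!r}")
    n_loc = domain_template.n_locations
    inside = domain_template.domains == design.target_domain
    seed = design.seed

    counts = np.zeros((design.n_genes, n_loc), dtype=np.int64)
    rows = []
    n_folds = max(len(design.folds), 1)
    per_fold = design.n_se // n_folds if design.n_se else 0
    for g in range(design.n_genes):
        rng = spawn_rng(seed, "se", g)
        is_se = g < design.n_se
        if is_se:
            fold = design.folds[min(g // max(per_fold, 1), n_folds - 1)]
            counts[g, ~inside] = sample_family(
                "nb", design.baseline_mu, design.phi, None, int((~inside).sum()), rng)
            counts[g, inside] = sample_family(
                "nb", design.baseline_mu * fold, design.phi, None,
                int(inside.sum()), rng)
        else:
            fold = 1.0
            counts[g] = sample_family("nb", design.baseline_mu, design.phi,
                                      None, n_loc, rng)
        rows.append({"gene_id": f"gene_{g + 1:04d}", "is_se": is_se,
                     "fold": fold,
                     "direction": "up" if fold > 1 else ("down" if fold < 1 else "none"),
                     "domain": design.target_domain if is_se else ""})
    data = SRTData(counts, domain_template.coords.copy(),
                   domains=domain_template.domains.copy())
    return data, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clustering experimental-design scenarios
# ---------------------------------------------------------------------------

def clustering_scenarios(ref: SRTData, depths, n_locations_list=None,
                         scenario: str = "I", layout: str = "random",
                         seed: int = 0, k_neighbors: int = 3) -> list[SimOutput]:
    """Domain-specific simulation sweeps over depth and location number.

    * Scenario I: reference locations, depth_factor = target_total /
      reference_total for each target in ``depths``.
    * Scenario II: fixed total depth (the first entry of ``depths``, or the
      reference total when ``depths`` is empty/None), sweeping
      ``n_locations_list``; the per-gene means are rescaled by
      n_ref / n_new so the expected total stays constant.
    * Scenario III: the full cross-product of depths x location counts at
      fixed per-location depth — for each (d, n) pair the factor is
      d / reference_total, independent of n, so average depth per location
      tracks d while the location count varies.
    """
    if ref.domains is None:
        raise ValueError("clustering scenarios run domain-specific simulations; "
                         "the reference needs domain labels")
    ref_total = float(ref.counts.sum())
    n_ref = ref.n_locations
    outs: list[SimOutput] = []

    def run(factor, n_new, tag):
        new_loc = None if n_new is None else (int(n_new), layout)
        cfg = RefSimConfig(mode="domain", new_locations=new_loc,
                           depth_factor=float(factor), seed=seed,
                           k_neighbors=k_neighbors)
        out = simulate_domains(ref, cfg)
        out.config["scenario"] = tag
        outs.append(out)

    if scenario == "I":
        if not depths:
            raise ValueError("scenario I needs a list of target total depths")
        for d in depths:
            if d <= 0:
                raise ValueError("depths must be positive")
            run(d / ref_total, None, {"scenario": "I", "target_total": d})
    elif scenario == "II":
        if not n_locations_list:
            raise ValueError("scenario II needs a list of location counts")
        total = depths[0] if depths else ref_total
        for n_new in n_locations_list:
            if n_new <= 0:
                raise ValueError("location counts must be positive")
            run((total / ref_total) * (n_ref / n_new), n_new,
                {"scenario": "II", "target_total": total, "n_locations": n_new})
    elif scenario == "III":
        if not depths or not n_locations_list:
            raise ValueError("scenario III needs depths and location counts")
        for d in depths:
            for n_new in n_locations_list:
                run(d / ref_total, n_new,
                    {"scenario": "III", "per_location_depth": d / n_ref,
                     "n_locations": n_new})
    else:
        raise ValueError(f"unknown scenario {scenario!r}; expected I, II or III")
    return outs


# ---------------------------------------------------------------------------
# cell-cell-communication benchmarks
# ---------------------------------------------------------------------------

# region composition vectors: proportions of the (rotated) four cell types
CCC_SCENARIOS: dict[int, tuple[float, ...]] = {
    1: (0.70, 0.10, 0.10, 0.10),
    2: (0.45, 0.45, 0.05, 0.05),
    3: (0.60, 0.30, 0.05, 0.05),
    4: (0.35, 0.30, 0.30, 0.05),
}


@dataclass(frozen=True)
class CCCDesign:
    """Design of one cell-cell-communication benchmark replicate."""

    n_locations: int = 5000
    scenario: int = 1
    n_genes: int = 5000
    cells_per_type: int = 2000
    expression_mode: str = "homogeneous"       # or 'heterogeneous'
    lr_pairs: pd.DataFrame | None = None       # columns: ligand, receptor
    fold: float = 5.0                          # 1 = null
    n_adjacent: int = 4
    pool_mu: float = 0.5                       # homogeneous NB mean
    pool_phi: float = 0.35                     # NB dispersion
    type_params: pd.DataFrame | None = None    # heterogeneous per-type mu/phi
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in CCC_SCENARIOS:
            raise ValueError(f"scenario must be one of {sorted(CCC_SCENARIOS)}")
        if self.fold < 1:
            raise ValueError("fold must be >= 1 (1 is the null)")
        if self.expression_mode not in ("homogeneous", "heterogeneous"):
            raise ValueError("expression_mode must be homogeneous or heterogeneous")


@dataclass
class CCCResult:
    """A CCC benchmark dataset with its ground truth and provenance."""

    data: SRTData                      # domains hold the cell-type labels
    regions: np.ndarray                # per-cell region label (region_1..4)
    truth: pd.DataFrame                # ligand, receptor, type_a, type_b, interacting
    boosted: np.ndarray                # boolean genes x cells boost mask
    config: dict


def synthetic_lr_pairs(n_pairs: int = 930, n_genes: int = 691,
                       seed: int = 0) -> pd.DataFrame:
    """A synthetic ligand-receptor pair list over a shared gene pool.

    Stands in for a curated database pair list: ``n_pairs`` distinct
    (ligand, receptor) pairs drawn from ``n_genes`` gene symbols, mirroring
    the 930 pairs over 691 unique genes used in the communication
    benchmarks.
    """
    if n_pairs > n_genes * (n_genes - 1):
        raise ValueError(
            f"cannot draw {n_pairs} distinct ordered pairs from {n_genes} genes")
    rng = spawn_rng(seed, "lr_pairs")
    genes = np.array([f"gene_{i + 1:04d}" for i in range(n_genes)])
    seen, rows = set(), []
    while len(rows) < n_pairs:
        l, r = rng.choice(n_genes, size=2, replace=False)
        if (l, r) not in seen:
            seen.add((l, r))
            rows.append({"ligand": genes[l], "receptor": genes[r]})
    return pd.DataFrame(rows)


def assign_lr_pairs(lr_pairs: pd.DataFrame, n_types: int = 4,
                    seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Assign each L-R pair uniformly at random to an ordered type pair.

    With ``n_types = 4`` there are 16 ordered (A, B) combinations including
    self-pairs; each L-R pair is assigned independently and uniformly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else spawn_rng(seed, "assign_lr")
    out = lr_pairs.copy().reset_index(drop=True)
    combos = rng.integers(0, n_types * n_types, size=len(out))
    out["type_a"] = [f"type_{c // n_types + 1}" for c in combos]
    out["type_b"] = [f"type_{c % n_types + 1}" for c in combos]
    return out


def apply_adjacency_boost(counts: np.ndarray, coords: np.ndarray,
                          cell_types: np.ndarray, gene_ids: np.ndarray,
                          assignments: pd.DataFrame, fold: float,
                          n_adjacent: int = 4
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Boost ligand expression in A cells spatially adjacent to B cells.

    For every assigned (L, R, A, B): each cell of type A whose
    ``n_adjacent`` nearest cells include at least one B cell has its L-gene
    count multiplied by ``fold`` and rounded to the nearest integer.
    ``fold = 1`` returns the matrix unchanged. Returns (new_counts, boosted
    mask).
    """
    counts = np.asarray(counts)
    boosted = np.zeros_like(counts, dtype=bool)
    if fold == 1.0:
        return counts.copy(), boosted
    out = counts.copy()
    nbr = _knn_indices(coords, coords, n_adjacent + 1)  # includes self
    nbr = np.array([[j for j in row if j != i][:n_adjacent]
                    for i, row in enumerate(nbr)])
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    types = np.asarray(cell_types)
    for row in assignments.itertuples(index=False):
        gi = gene_pos.get(row.ligand)
        if gi is None:
            continue
        a_cells = np.flatnonzero(types == row.type_a)
        if a_cells.size == 0:
            continue
        adjacent_b = (types[nbr[a_cells]] == row.type_b).any(axis=1)
        hit = a_cells[adjacent_b]
        out[gi, hit] = np.rint(out[gi, hit] * fold).astype(np.int64)
        boosted[gi, hit] = True
    return out, boosted


def _partition_regions(coords: np.ndarray, n_regions: int = 4) -> np.ndarray:
    """Four equal-count strips along the first principal axis of the cloud."""
    c = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    proj = c @ vt[0]
    order = np.argsort(proj, kind="stable")
    region = np.empty(coords.shape[0], dtype=int)
    for r, chunk in enumerate(np.array_split(order, n_regions)):
        region[chunk] = r
    return region


def ccc_benchmark(shape_source, design: CCCDesign) -> CCCResult:
    """Generate a single-cell-resolution CCC benchmark dataset.

    See the module docstring for the construction. ``shape_source`` is an
    SRTData (its locations define the tissue shape via the concave hull) or
    a ShapeProfile.
    """
    seed = design.seed
    if isinstance(shape_source, SRTData):
        shape = estimate_shape(shape_source.coords)
    elif isinstance(shape_source, ShapeProfile):
        shape = shape_source
    else:
        raise TypeError("shape_source must be an SRTData or a ShapeProfile")

    coords = generate_random_locations(shape, design.n_locations,
                                       spawn_rng(seed, "ccc", "locations"))
    region_idx = _partition_regions(coords, 4)

    # cell-type labels per cell: multinomial with the region's composition;
    # region r ranks the types in rotated order (r, r+1, r+2, r+3) mod 4
    comp = np.asarray(CCC_SCENARIOS[design.scenario])
    rng_types = spawn_rng(seed, "ccc", "types")
    type_idx = np.empty(design.n_locations, dtype=int)
    for r in range(4):
        mask = region_idx == r
        probs = np.empty(4)
        for i in range(4):
            probs[(r + i) % 4] = comp[i]
        type_idx[mask] = rng_types.choice(4, size=int(mask.sum()), p=probs)
    type_labels = np.array([f"type_{t + 1}" for t in range(4)])
    cell_types = type_labels[type_idx]

    # expression pool: n_genes x (4 * cells_per_type)
    gene_ids = np.array([f"gene_{i + 1:04d}" for i in range(design.n_genes)])
    pool_n = 4 * design.cells_per_type
    rng_pool = spawn_rng(seed, "ccc", "pool")
    pool = np.empty((design.n_genes, pool_n), dtype=np.int64)
    if design.expression_mode == "homogeneous":
        for g in range(design.n_genes):
            pool[g] = sample_family("nb", design.pool_mu, design.pool_phi,
                                    None, pool_n, rng_pool)
        pool_types = np.repeat(np.arange(4), design.cells_per_type)
        pool_types = rng_pool.permutation(pool_types)   # random type assignment
    else:
        tp = design.type_params
        if tp is None:
            # synthetic stand-in for reference cell-type parameters: type-
            # specific NB means spread around the homogeneous baseline
            rng_tp = spawn_rng(seed, "ccc", "type_params")
            tp = pd.DataFrame({
                "type": type_labels,
                "mu": design.pool_mu * rng_tp.lognormal(0.0, 0.5, size=4),
                "phi": np.full(4, design.pool_phi)})
        tp = tp.set_index("type")
        pool_types = np.repeat(np.arange(4), design.cells_per_type)
        for t in range(4):
            cols = pool_types == t
            mu_t = float(tp.loc[type_labels[t], "mu"])
            phi_t = float(tp.loc[type_labels[t], "phi"])
            for g in range(design.n_genes):
                pool[g, cols] = sample_family("nb", mu_t, phi_t, None,
                                              int(cols.sum()), rng_pool)

    # place pool cells of the demanded types onto positions
    rng_place = spawn_rng(seed, "ccc", "place")
    counts = np.empty((design.n_genes, design.n_locations), dtype=np.int64)
    for t in range(4):
        need = np.flatnonzero(type_idx == t)
        avail = np.flatnonzero(pool_types == t)
        if need.size == 0:
            continue
        if avail.size == 0:
            raise ValueError(f"no pool cells of type {type_labels[t]}")
        replace = need.size > avail.size      # only oversample when demanded
        take = rng_place.choice(avail, size=need.size, replace=replace)
        counts[:, need] = pool[:, take]

    lr = design.lr_pairs if design.lr_pairs is not None \
        else synthetic_lr_pairs(seed=seed)
    assignments = assign_lr_pairs(lr, 4, spawn_rng(seed, "ccc", "assign_lr"))
    counts, boosted = apply_adjacency_boost(
        counts, coords, cell_types, gene_ids, assignments,
        design.fold, design.n_adjacent)

    truth = assignments.copy()
    truth["interacting"] = design.fold > 1
    data = SRTData(counts, coords, gene_ids, None, cell_types)
    region_labels = np.array([f"region_{r + 1}" for r in region_idx])
    return CCCResult(data, region_labels, truth, boosted,
                     {"scenario": design.scenario, "fold": design.fold,
                      "expression_mode": design.expression_mode,
                      "n_adjacent": design.n_adjacent, "seed": seed})
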