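"""Reference-based simulation engine.

Given a reference SRT dataset, the engine (1) reuses the measured locations
or synthesizes new ones inside the estimated tissue shape, (2) fits each
gene's count distribution by AIC-selected maximum likelihood and draws fresh
counts from it, and (3) assigns the drawn counts to locations by matching
rank order against the gene's reference expression, which preserves the
gene's spatial expression pattern while the counts themselves are new draws
from the fitted model.

Fitting and assignment run either over the whole tissue (``mode='tissue'``)
or independently within each annotated domain (``mode='domain'``), the
latter producing sharper domain contrasts. When new locations are requested,
model fitting still uses the original reference counts; a kNN-sampled
pseudo-reference at the new locations is used only for the ranking step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ._rng import spawn_rng
from .count_models import CountModelFit, sample_counts, select_model
from .data_core import SRTData, SimOutput
from .geometry import (DEFAULT_CONCAVITY, _knn_indices, apply_affine,
                       estimate_shape, fit_affine, generate_grid_locations,
                       generate_random_locations, transfer_domain_labels)

__all__ = [
    "RefSimConfig",
    "rank_assign",
    "simulate_tissue",
    "simulate_domains",
    "simulate",
    "impute_reference_at_new_locations",
    "redesign_region",
    "scale_depth",
]


@dataclass(frozen=True)
class RefSimConfig:
    """Configuration of a reference-based simulation run.

    ``new_locations``: optional (count, layout) pair, layout in
    {'grid', 'random'}; when omitted the reference's own locations are
    reused. ``depth_factor`` rescales every fitted mean before sampling
    (sequencing-depth adjustment); with ``thinning=True`` the counts are
    instead binomially thinned after sampling (only meaningful for
    depth_factor <= 1).
    """

    mode: str = "tissue"                       # 'tissue' or 'domain'
    new_locations: tuple[int, str] | None = None
    k_neighbors: int = 3
    depth_factor: float = 1.0
    concavity: float = DEFAULT_CONCAVITY
    thinning: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("tissue", "domain"):
            raise ValueError("mode must be 'tissue' or 'domain'")
        if self.depth_factor <= 0:
            raise ValueError("depth_factor must be > 0")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")

    def as_dict(self) -> dict:
        return {"mode": self.mode, "new_locations": self.new_locations,
                "k_neighbors": self.k_neighbors,
                "depth_factor": self.depth_factor,
                "concavity": self.concavity, "thinning": self.thinning,
                "seed": self.seed}


def rank_assign(sim_counts, ref_expr, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Place simulated counts at locations by reference rank order.

    The i-th largest simulated count goes to the location with the i-th
    largest reference expression; ties in the reference are broken by a
    seeded uniform permutation of the tied block. The output is always a
    permutation of ``sim_counts``.
    """
    sim = np.asarray(sim_counts)
    ref = np.asarray(ref_expr, dtype=float)
    if sim.shape[0] != ref.shape[0]:
        raise ValueError(
            f"length mismatch: {sim.shape[0]} counts vs {ref.shape[0]} "
            "reference values")
    rng = seed if isinstance(seed, np.random.Generator) else spawn_rng(seed, "rank_assign")
    # location order from highest to lowest reference expression;
    # lexsort's last key is primary, the random key shuffles tied blocks
    order = np.lexsort((rng.random(ref.shape[0]), -ref))
    out = np.empty_like(sim)
    out[order] = np.sort(sim)[::-1]
    return out


def scale_depth(fits, depth_factor: float):
    """Multiply every fitted mean by ``depth_factor`` (phi, pi0 unchanged).

    Accepts a single :class:`CountModelFit`, a gene -> fit mapping, or a
    nested domain -> {gene -> fit} mapping, and returns the same structure.
    Expected total count scales linearly with the factor.
    """
    if depth_factor <= 0:
        raise ValueError(f"depth_factor must be > 0, got {depth_factor}")
    if isinstance(fits, CountModelFit):
        return fits.scaled(depth_factor)
    return {k: scale_depth(v, depth_factor) for k, v in fits.items()}


def _thin(counts: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    return rng.binomial(counts, min(p, 1.0))


def impute_reference_at_new_locations(ref: SRTData, new_coords, k: int = 3,
                                      seed: int | np.random.Generator = 0,
                                      location_subset=None) -> np.ndarray:
    """Pseudo-reference expression at new locations by kNN sampling.

    For every gene and new location, one count is sampled uniformly (with
    replacement) from the counts of the location's k nearest reference
    neighbors. The result is used only to rank new locations during count
    assignment; model fitting always uses the original reference counts.
    ``location_subset`` optionally restricts the reference to a subset of
    location indices (used for per-domain imputation).
    """
    coords = ref.coords
    counts = ref.counts
    if location_subset is not None:
        idx = np.asarray(location_subset)
        coords, counts = coords[idx], counts[:, idx]
    if coords.shape[0] == 0:
        raise ValueError("empty reference")
    k = min(k, coords.shape[0])
    new_coords = np.asarray(new_coords, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else spawn_rng(seed, "impute")
    nbr = _knn_indices(coords, new_coords, k)            # (n_new, k)
    # independent neighbor choice per (gene, location)
    pick = rng.integers(0, k, size=(counts.shape[0], new_coords.shape[0]))
    chosen = nbr[np.arange(new_coords.shape[0])[None, :], pick]
    return counts[np.arange(counts.shape[0])[:, None], chosen]


def _synthesize_locations(ref: SRTData, config: RefSimConfig, rng):
    n_new, layout = config.new_locations
    shape = estimate_shape(ref.coords, config.concavity)
    if layout == "grid":
        return generate_grid_locations(shape, n_new)
    if layout == "random":
        return generate_random_locations(shape, n_new, rng)
    raise ValueError(f"unknown layout {layout!r}; expected grid or random")


def _simulate_block(ref_counts: np.ndarray, rank_ref: np.ndarray,
                    n_out: int, config: RefSimConfig, seed_path: tuple,
                    fits_out: dict, gene_ids) -> np.ndarray:
    """Fit/sample/rank every gene of one block (whole tissue or one domain)."""
    seed = config.seed
    out = np.zeros((ref_counts.shape[0], n_out), dtype=np.int64)
    for g in range(ref_counts.shape[0]):
        fit = select_model(ref_counts[g])
        fits_out[str(gene_ids[g])] = fit
        sampling_fit = fit if (config.depth_factor == 1.0 or config.thinning) \
            else fit.scaled(config.depth_factor)
        counts = sample_counts(sampling_fit, n_out,
                               spawn_rng(seed, *seed_path, "sample", g))
        if config.thinning and config.depth_factor != 1.0:
            counts = _thin(counts, config.depth_factor,
                           spawn_rng(seed, *seed_path, "thin", g))
        out[g] = rank_assign(counts, rank_ref[g],
                             spawn_rng(seed, *seed_path, "rank", g))
    return out


def simulate_tissue(ref: SRTData, config: RefSimConfig) -> SimOutput:
    """Tissue-based reference simulation (fit, sample and rank genome-wide)."""
    if config.mode != "tissue":
        raise ValueError("config.mode must be 'tissue'")
    seed = config.seed
    if config.new_locations is None:
        coords = ref.coords.copy()
        loc_ids = ref.location_ids.copy()
        domains = None if ref.domains is None else ref.domains.copy()
        rank_ref = ref.counts
        n_out = ref.n_locations
    else:
        coords = _synthesize_locations(ref, config, spawn_rng(seed, "locations"))
        n_out = coords.shape[0]
        loc_ids = None
        domains = None
        if ref.domains is not None:
            domains = transfer_domain_labels(ref.coords, ref.domains, coords,
                                             config.k_neighbors)
        rank_ref = impute_reference_at_new_locations(
            ref, coords, config.k_neighbors, spawn_rng(seed, "impute"))

    fits: dict[str, CountModelFit] = {}
    counts = _simulate_block(ref.counts, rank_ref, n_out, config,
                             ("tissue",), fits, ref.gene_ids)
    data = SRTData(counts, coords, ref.gene_ids.copy(), loc_ids, domains)
    return SimOutput(data, fits, config.as_dict(), seed)


def simulate_domains(ref: SRTData, config: RefSimConfig) -> SimOutput:
    """Domain-specific simulation: fit/sample/rank independently per domain.

    With new locations, domain labels are first transferred to the new
    coordinates by kNN majority vote, and the ranking pseudo-reference for
    each domain is imputed using only that domain's reference locations (no
    cross-domain leakage).
    """
    if config.mode != "domain":
        raise ValueError("config.mode must be 'domain'")
    if ref.domains is None:
        raise ValueError("domain-specific simulation requires reference domains")
    seed = config.seed
    dom_labels = np.unique(ref.domains)
    for d in dom_labels:
        if np.sum(ref.domains == d) < 2:
            raise ValueError(f"domain {d!r} has fewer than 2 locations")

    if config.new_locations is None:
        coords = ref.coords.copy()
        loc_ids = ref.location_ids.copy()
        out_domains = ref.domains.copy()
        n_out = ref.n_locations
    else:
        coords = _synthesize_locations(ref, config, spawn_rng(seed, "locations"))
        n_out = coords.shape[0]
        loc_ids = None
        out_domains = transfer_domain_labels(ref.coords, ref.domains, coords,
                                             config.k_neighbors)

    counts = np.zeros((ref.n_genes, n_out), dtype=np.int64)
    fits: dict[str, dict[str, CountModelFit]] = {}
    for d in dom_labels:
        ref_mask = ref.domains == d
        out_mask = out_domains == d
        if not out_mask.any():
            fits[str(d)] = {}
            continue
        ref_block = ref.counts[:, ref_mask]
        if config.new_locations is None:
            rank_ref = ref_block
        else:
            rank_ref = impute_reference_at_new_locations(
                ref, coords[out_mask], config.k_neighbors,
                spawn_rng(seed, "impute", d),
                location_subset=np.flatnonzero(ref_mask))
        dom_fits: dict[str, CountModelFit] = {}
        counts[:, out_mask] = _simulate_block(
            ref_block, rank_ref, int(out_mask.sum()), config,
            ("domain", d), dom_fits, ref.gene_ids)
        fits[str(d)] = dom_fits
    data = SRTData(counts, coords, ref.gene_ids.copy(), loc_ids, out_domains)
    return SimOutput(data, fits, config.as_dict(), seed)


def simulate(ref: SRTData, config: RefSimConfig) -> SimOutput:
    """Dispatch to tissue-based or domain-specific simulation per config."""
    if config.mode == "domain":
        return simulate_domains(ref, config)
    return simulate_tissue(ref, config)


def redesign_region(ref: SRTData, source_region_locations,
                    target_region_locations, k: int = 3, seed: int = 0,
                    concavity: float = DEFAULT_CONCAVITY) -> SimOutput:
    """Extrapolate one region's spatial expression pattern onto another.

    The source region's shape is affinely mapped onto the target region's
    shape; source locations are projected through that map and carry their
    reference counts with them, serving as the new reference for the target.
    Counts for the target region are then simulated from models fitted on
    the source region's counts and rank-assigned against a kNN-sampled
    pseudo-reference at the target locations. Counts outside the target
    region are left untouched.
    """
    src_idx = np.asarray(source_region_locations)
    tgt_idx = np.asarray(target_region_locations)
    if src_idx.dtype == bool:
        src_idx = np.flatnonzero(src_idx)
    if tgt_idx.dtype == bool:
        tgt_idx = np.flatnonzero(tgt_idx)
    if src_idx.size < 3 or tgt_idx.size < 3:
        raise ValueError("both regions need at least 3 locations")

    src_shape = estimate_shape(ref.coords[src_idx], concavity)
    tgt_shape = estimate_shape(ref.coords[tgt_idx], concavity)
    transform = fit_affine(src_shape, tgt_shape)
    projected = apply_affine(transform, ref.coords[src_idx])

    # pseudo-reference: per gene/target location, sample among k nearest
    # projected source locations (which carry the source counts)
    k_eff = min(k, projected.shape[0])
    nbr = _knn_indices(projected, ref.coords[tgt_idx], k_eff)
    rng = spawn_rng(seed, "redesign", "impute")
    pick = rng.integers(0, k_eff, size=(ref.n_genes, tgt_idx.size))
    chosen = nbr[np.arange(tgt_idx.size)[None, :], pick]
    src_counts = ref.counts[:, src_idx]
    pseudo = src_counts[np.arange(ref.n_genes)[:, None], chosen]

    counts = ref.counts.copy()
    fits: dict[str, CountModelFit] = {}
    for g in range(ref.n_genes):
        fit = select_model(src_counts[g])
        fits[str(ref.gene_ids[g])] = fit
        sim = sample_counts(fit, tgt_idx.size, spawn_rng(seed, "redesign", "sample", g))
        counts[g, tgt_idx] = rank_assign(sim, pseudo[g],
                                         spawn_rng(seed, "redesign", "rank", g))
    data = SRTData(counts, ref.coords.copy(), ref.gene_ids.copy(),
                   ref.location_ids.copy(),
                   None if ref.domains is None else ref.domains.copy())
    return SimOutput(data, fits,
                     {"kind": "redesign", "k": k, "concavity": concavity,
                      "n_source": int(src_idx.size), "n_target": int(tgt_idx.size)},
                     seed)
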