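"""Reference-free simulation: user-designed shapes, domains and count models.

Without any reference dataset, the user supplies a tissue shape (a named
primitive or an arbitrary polygon), a location layout, per-location domain
labels (directly or as sub-polygons), a baseline count model per gene, and a
per-domain mean fold-change. Counts are drawn i.i.d. per location with the
domain's fold applied to the count-component mean only (phi and pi0 are
unchanged), so genes display domain-specific expression patterns but no
spatial structure inside a domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import spawn_rng
from .count_models import CountModelFit, sample_family
from .data_core import SRTData, SimOutput
from .geometry import ShapeProfile, generate_grid_locations, generate_random_locations

__all__ = ["FreeDesign", "make_shape", "simulate_free"]

_CIRCLE_VERTICES = 128


def _circle(center, r, n_vertices=_CIRCLE_VERTICES) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    return np.column_stack([center[0] + r * np.cos(theta),
                            center[1] + r * np.sin(theta)])


def make_shape(spec) -> ShapeProfile:
    """Build a ShapeProfile from a primitive spec, vertex array, or CSV path.

    Primitive specs are tuples/lists:

    * ``("circle", (cx, cy), r[, n_vertices])`` — regular polygon, at least
      64 vertices (128 by default).
    * ``("square", (cx, cy), side)``
    * ``("annulus", (cx, cy), r_in, r_out)`` — a ring; represented as a
      simple "keyhole" polygon whose outer and inner circles are joined by
      an infinitesimally thin slit so the ring remains a single simple
      polygon (area within ~1e-9 of the true annulus).

    A (m, 2) array of vertices or a CSV path with columns x,y is accepted
    verbatim.
    """
    if isinstance(spec, ShapeProfile):
        return spec
    if isinstance(spec, (str,)) or hasattr(spec, "read"):
        return ShapeProfile.from_csv(spec)
    if isinstance(spec, np.ndarray):
        return ShapeProfile(spec)
    kind = spec[0]
    if kind == "circle":
        _, center, r, *rest = spec
        n_vert = rest[0] if rest else _CIRCLE_VERTICES
        if r <= 0:
            raise ValueError("circle radius must be > 0")
        if n_vert < 64:
            raise ValueError("circles are discretized at >= 64 vertices")
        return ShapeProfile(_circle(center, r, n_vert))
    if kind == "square":
        _, center, side = spec
        if side <= 0:
            raise ValueError("square side must be > 0")
        h = side / 2.0
        cx, cy = center
        return ShapeProfile(np.array([[cx - h, cy - h], [cx + h, cy - h],
                                      [cx + h, cy + h], [cx - h, cy + h]]))
    if kind == "annulus":
        _, center, r_in, r_out = spec
        if not (0 < r_in < r_out):
            raise ValueError("annulus requires 0 < r_in < r_out")
        eps = 1e-9 * r_out                       # slit half-width
        outer = _circle(center, r_out)
        inner = _circle(center, r_in)[::-1]      # opposite orientation
        # open a slit along +x: start both rings just above/below the axis
        return ShapeProfile(np.vstack([
            [center[0] + r_out, center[1] + eps], outer[1:],
            [center[0] + r_out, center[1] - eps],
            [center[0] + r_in, center[1] - eps], inner[:-1],
            [center[0] + r_in, center[1] + eps],
        ]))
    raise ValueError(f"unknown shape primitive {kind!r}")


@dataclass
class FreeDesign:
    """Full specification of a reference-free simulation.

    ``model`` is either a dict of shared baseline parameters
    ``{"family", "mu", "phi", "pi0"}`` applied to ``n_genes`` genes, or a
    DataFrame with one row per gene (columns family, mu, phi, pi0).
    ``domains`` may be an explicit per-location label array, a list of
    ``(label, shape-spec)`` sub-polygons (locations labeled by containment,
    the largest containing polygon — the outermost — winning ties, with
    unmatched locations labeled ``"background"``), or None for a single
    tissue-wide domain. ``fold`` maps domain label -> mean fold-change
    (> 0) applied inside the domain versus the tissue baseline.
    """

    shape: object
    n_locations: int
    layout: str = "random"
    n_genes: int = 100
    model: Mapping | pd.DataFrame = field(
        default_factory=lambda: {"family": "nb", "mu": 1.0, "phi": 0.3, "pi0": 0.0})
    domains: object = None
    fold: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def gene_table(self) -> pd.DataFrame:
        if isinstance(self.model, pd.DataFrame):
            df = self.model.copy()
            for col, default in (("phi", 0.0), ("pi0", 0.0)):
                if col not in df:
                    df[col] = default
            if "gene_id" not in df:
                df["gene_id"] = [f"gene_{i + 1:04d}" for i in range(len(df))]
            return df
        m = dict(self.model)
        return pd.DataFrame({
            "gene_id": [f"gene_{i + 1:04d}" for i in range(self.n_genes)],
            "family": m.get("family", "nb"),
            "mu": float(m.get("mu", 1.0)),
            "phi": float(m.get("phi", 0.0)),
            "pi0": float(m.get("pi0", 0.0))})


def _label_by_geometry(coords: np.ndarray, domain_shapes) -> np.ndarray:
    shapes = [(str(lab), make_shape(spec)) for lab, spec in domain_shapes]
    labels = np.full(coords.shape[0], "background", dtype=object)
    best_area = np.full(coords.shape[0], -np.inf)
    for lab, shp in shapes:
        inside = shp.contains(coords)
        area = shp.area
        take = inside & (area > best_area)
        labels[take] = lab
        best_area[take] = area
    return labels.astype(str)


def simulate_free(design: FreeDesign) -> SimOutput:
    """Run a reference-free simulation from a :class:`FreeDesign`.

    Counts are drawn independently per location; within a domain every
    location shares the same distribution (mean = fold x baseline mu), so
    the allocation of counts to locations is exchangeable within the domain.
    """
    if design.n_locations < 1:
        raise ValueError("n_locations must be >= 1")
    shape = make_shape(design.shape)
    seed = design.seed
    if design.layout == "grid":
        coords = generate_grid_locations(shape, design.n_locations)
    elif design.layout == "random":
        coords = generate_random_locations(shape, design.n_locations,
                                           spawn_rng(seed, "free", "locations"))
    else:
        raise ValueError(f"unknown layout {design.layout!r}")
    n_loc = coords.shape[0]

    if design.domains is None:
        domains = np.full(n_loc, "tissue")
    elif isinstance(design.domains, (list, tuple)) and len(design.domains) \
            and isinstance(design.domains[0], (list, tuple)):
        domains = _label_by_geometry(coords, design.domains)
    else:
        domains = np.asarray(design.domains).astype(str)
        if len(domains) != n_loc:
            raise ValueError(
                f"domain labels ({len(domains)}) must match generated "
                f"locations ({n_loc})")

    present = set(np.unique(domains))
    unknown = set(map(str, design.fold)) - present
    if unknown:
        raise ValueError(f"fold map references absent domains: {sorted(unknown)}")
    folds = {d: float(design.fold.get(d, 1.0)) for d in present}
    if any(f <= 0 for f in folds.values()):
        raise ValueError("all fold values must be > 0")

    genes = design.gene_table()
    counts = np.zeros((len(genes), n_loc), dtype=np.int64)
    fits: dict[str, CountModelFit] = {}
    dom_masks = {d: domains == d for d in present}
    for g, row in enumerate(genes.itertuples(index=False)):
        rng = spawn_rng(seed, "free", "counts", g)
        for d in sorted(present):
            mask = dom_masks[d]
            mu_d = row.mu * folds[d]
            counts[g, mask] = sample_family(row.family, mu_d, row.phi,
                                            row.pi0, int(mask.sum()), rng)
        fits[row.gene_id] = CountModelFit(
            family=str(row.family).lower(), mu=float(row.mu),
            phi=float(row.phi) if row.phi else None,
            pi0=float(row.pi0) if row.pi0 else None)
    data = SRTData(counts, coords, genes["gene_id"].to_numpy(), None, domains)
    config = {"kind": "reference_free", "n_locations": design.n_locations,
              "layout": design.layout, "fold": folds, "seed": seed}
    return SimOutput(data, fits, config, seed)
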