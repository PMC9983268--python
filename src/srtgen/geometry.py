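"""Tissue geometry: concave-hull shape estimation, location generation,
domain-label transfer, and affine region mapping.

The tissue (or a region of it) is summarized by a :class:`ShapeProfile`, a
simple polygon enclosing the measured locations. New location layouts are
generated inside it either on a square lattice (Visium-like arrays) or by a
uniform random point process (imaging-based platforms such as MERFISH or
seqFISH+). Domain labels are carried onto new locations by k-nearest-neighbor
majority vote (k = 3 by default), and spatial patterns can be extrapolated
from one region to another through an affine map between the two regions'
shape frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from ._rng import spawn_rng

__all__ = [
    "ShapeProfile",
    "AffineTransform",
    "estimate_shape",
    "generate_grid_locations",
    "generate_random_locations",
    "transfer_domain_labels",
    "fit_affine",
    "fit_affine_points",
    "apply_affine",
]

DEFAULT_CONCAVITY = 1.0


@dataclass(frozen=True)
class ShapeProfile:
    """Ordered polygon vertices delimiting a tissue or region outskirt."""

    vertices: np.ndarray                 # (m, 2), open ring (no repeat vertex)
    concavity: float = DEFAULT_CONCAVITY

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        object.__setattr__(self, "vertices", v)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("a shape needs >= 3 (x, y) vertices")
        poly = Polygon(v)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("vertices must form a simple polygon with positive area")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return self.polygon.area

    def contains(self, points: np.ndarray, boundary: bool = True) -> np.ndarray:
        """Boolean containment mask; ``boundary`` counts boundary points in."""
        pts = np.asarray(points, dtype=float)
        poly = self.polygon
        if boundary:
            return shapely.covers(poly, shapely.points(pts))
        return shapely.contains_xy(poly, pts[:, 0], pts[:, 1])

    def to_csv(self, path) -> None:
        np.savetxt(path, self.vertices, delimiter=",", header="x,y", comments="")

    @classmethod
    def from_csv(cls, path, concavity: float = DEFAULT_CONCAVITY) -> "ShapeProfile":
        verts = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(verts, concavity)


@dataclass(frozen=True)
class AffineTransform:
    """y = linear @ x + offset, with an invertible 2x2 linear part."""

    linear: np.ndarray
    offset: np.ndarray

    def __post_init__(self):
        lin = np.asarray(self.linear, dtype=float).reshape(2, 2)
        off = np.asarray(self.offset, dtype=float).reshape(2)
        if abs(np.linalg.det(lin)) < 1e-12:
            raise ValueError("linear part must be invertible")
        object.__setattr__(self, "linear", lin)
        object.__setattr__(self, "offset", off)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.linear.T + self.offset

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.linear)
        return AffineTransform(inv, -inv @ self.offset)


def estimate_shape(points, concavity: float = DEFAULT_CONCAVITY) -> ShapeProfile:
    """Concave hull of a point cloud as a simple polygon.

    ``concavity`` in (0, inf) controls how tightly the hull hugs the points;
    it maps to shapely's concave-hull ratio ``concavity / (1 + concavity)``,
    so the hull converges to the convex hull as concavity grows and the
    enclosed area is non-decreasing in the parameter. All input points lie
    inside or on the returned polygon.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 distinct points to estimate a shape")
    if concavity <= 0:
        raise ValueError("concavity must be > 0")
    mp = shapely.multipoints(pts)
    ratio = concavity / (1.0 + concavity)
    hull = shapely.concave_hull(mp, ratio=ratio, allow_holes=False)
    if hull.geom_type != "Polygon" or hull.area <= 0:
        hull = shapely.convex_hull(mp)
    if hull.geom_type != "Polygon" or hull.area <= 0:
        raise ValueError("points are collinear; no polygon exists")
    verts = np.asarray(hull.exterior.coords)[:-1]
    return ShapeProfile(verts, concavity)


def generate_grid_locations(shape: ShapeProfile, n_target: int) -> np.ndarray:
    """Square-lattice locations strictly inside the polygon.

    The lattice pitch is solved by bisection until the interior point count
    is within +-10% of ``n_target`` (ties resolved toward more points).
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    poly = shape.polygon
    area = poly.area
    if area <= 0:
        raise ValueError("polygon has zero area")
    minx, miny, maxx, maxy = poly.bounds

    def lattice(h: float) -> np.ndarray:
        xs = np.arange(minx + h / 2.0, maxx, h)
        ys = np.arange(miny + h / 2.0, maxy, h)
        if xs.size == 0 or ys.size == 0:
            return np.empty((0, 2))
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        inside = shapely.contains_xy(poly, pts[:, 0], pts[:, 1])
        return pts[inside]

    lo_n, hi_n = int(math.floor(0.9 * n_target)), int(math.ceil(1.1 * n_target))
    h = math.sqrt(area / n_target)
    pts = lattice(h)
    # bracket: smaller pitch -> more points
    h_small, h_big = h, h
    while lattice(h_small).shape[0] < n_target and h_small > 1e-9 * h:
        h_small /= 2.0
    while lattice(h_big).shape[0] > n_target and h_big < 1e3 * h:
        h_big *= 2.0
    best = None
    for _ in range(60):
        mid = 0.5 * (h_small + h_big)
        pts = lattice(mid)
        n = pts.shape[0]
        if lo_n <= n <= hi_n:
            if (best is None
                    or abs(n - n_target) < abs(best.shape[0] - n_target)
                    or (abs(n - n_target) == abs(best.shape[0] - n_target)
                        and n > best.shape[0])):     # ties -> more points
                best = pts
        if n == n_target:
            return pts
        if n > n_target:
            h_small = mid
        else:
            h_big = mid
        if (h_big - h_small) < 1e-12 * max(h_big, 1.0):
            break
    if best is not None:
        return best
    # fall back to the closer bracket end
    a, b = lattice(h_small), lattice(h_big)
    return a if abs(a.shape[0] - n_target) <= abs(b.shape[0] - n_target) else b


def generate_random_locations(shape: ShapeProfile, n: int,
                              seed: int | np.random.Generator = 0) -> np.ndarray:
    """Exactly ``n`` i.i.d. uniform points inside the polygon (rejection)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    poly = shape.polygon
    if poly.area <= 0:
        raise ValueError("polygon has zero area")
    rng = seed if isinstance(seed, np.random.Generator) else spawn_rng(seed, "random_locations")
    minx, miny, maxx, maxy = poly.bounds
    frac = poly.area / ((maxx - minx) * (maxy - miny))
    out = np.empty((0, 2))
    while out.shape[0] < n:
        m = max(int((n - out.shape[0]) / max(frac, 1e-3) * 1.2), 32)
        cand = np.column_stack([rng.uniform(minx, maxx, m),
                                rng.uniform(miny, maxy, m)])
        keep = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        out = np.vstack([out, cand[keep]])
    return out[:n]


def _knn_indices(ref_coords: np.ndarray, query: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k Euclidean nearest reference points for each query.

    Exact distance ties are broken toward the lowest reference index by
    nudging distances with an index-proportional epsilon before ranking.
    """
    ref = np.asarray(ref_coords, dtype=float)
    qry = np.asarray(query, dtype=float)
    tree = cKDTree(ref)
    kk = min(k + 8, ref.shape[0])          # headroom for tie groups
    dist, idx = tree.query(qry, k=kk)
    if kk == 1:
        dist, idx = dist[:, None], idx[:, None]
    # stable ordering: (distance rounded to 1e-12 relative, index)
    scale = max(float(dist.max()), 1.0)
    key = np.round(dist / scale, 12) + idx * 1e-15
    order = np.argsort(key, axis=1, kind="stable")
    return np.take_along_axis(idx, order, axis=1)[:, :k]


def transfer_domain_labels(ref_coords, ref_labels, new_coords, k: int = 3) -> np.ndarray:
    """Assign each new location the majority domain label of its k nearest
    reference locations (Boyer-Moore style majority vote).

    When no strict majority (> k/2) exists among the k neighbors, the label
    of the single nearest neighbor is used.
    """
    ref_coords = np.asarray(ref_coords, dtype=float)
    ref_labels = np.asarray(ref_labels)
    if ref_coords.shape[0] == 0:
        raise ValueError("empty reference set")
    if len(ref_labels) != ref_coords.shape[0]:
        raise ValueError("one label per reference location required")
    if k < 1 or k > ref_coords.shape[0]:
        raise ValueError(f"k must be in [1, {ref_coords.shape[0]}]")
    nbr = _knn_indices(ref_coords, np.asarray(new_coords, dtype=float), k)
    out = np.empty(nbr.shape[0], dtype=ref_labels.dtype)
    for i in range(nbr.shape[0]):
        labels = ref_labels[nbr[i]]
        # Boyer-Moore majority candidate
        cand, votes = None, 0
        for lab in labels:
            if votes == 0:
                cand, votes = lab, 1
            elif lab == cand:
                votes += 1
            else:
                votes -= 1
        if cand is not None and np.sum(labels == cand) * 2 > k:
            out[i] = cand
        else:
            out[i] = labels[0]          # nearest neighbor fallback
    return out


def _shape_frame(shape: ShapeProfile) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(centroid, rotation, half-extents) anchor frame of a polygon.

    The rotation columns are the principal axes of the polygon area (second
    moments), ordered by decreasing spread, with signs normalized so the
    frame is right-handed and reflection-free; extents are the half-ranges
    of the vertices projected onto the axes.
    """
    poly = shape.polygon
    c = np.array([poly.centroid.x, poly.centroid.y])
    # second moments of area via the shoelace decomposition
    v = np.vstack([shape.vertices, shape.vertices[0]]) - c
    x, y = v[:-1, 0], v[:-1, 1]
    x1, y1 = v[1:, 0], v[1:, 1]
    cross = x * y1 - x1 * y
    a = cross.sum() / 2.0
    ixx = np.sum(cross * (y * y + y * y1 + y1 * y1)) / 12.0
    iyy = np.sum(cross * (x * x + x * x1 + x1 * x1)) / 12.0
    ixy = np.sum(cross * (x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y)) / 24.0
    cov = np.array([[iyy, ixy], [ixy, ixx]]) / a
    w, vecs = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    vecs = vecs[:, order]
    # deterministic signs: dominant component of each axis positive
    for j in range(2):
        kmax = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[kmax, j] < 0:
            vecs[:, j] = -vecs[:, j]
    if np.linalg.det(vecs) < 0:          # no reflection
        vecs[:, 1] = -vecs[:, 1]
    proj = (shape.vertices - c) @ vecs
    ext = (proj.max(axis=0) - proj.min(axis=0)) / 2.0
    return c, vecs, ext


def fit_affine(src: ShapeProfile, dst: ShapeProfile) -> AffineTransform:
    """Affine map carrying the source shape's anchor frame onto the target's.

    The anchor frame is centroid + principal axes + projected half-extents;
    frame alignment avoids needing vertex-to-vertex correspondences between
    hulls with different vertex counts. Applying the transform to the source
    frame reproduces the target frame to numerical tolerance.
    """
    c_s, r_s, e_s = _shape_frame(src)
    c_d, r_d, e_d = _shape_frame(dst)
    if np.any(e_s < 1e-12) or np.any(e_d < 1e-12):
        raise ValueError("degenerate (zero-extent) shape")
    scale = np.diag(e_d / e_s)
    linear = r_d @ scale @ r_s.T
    offset = c_d - linear @ c_s
    return AffineTransform(linear, offset)


def fit_affine_points(src_points, dst_points) -> AffineTransform:
    """Least-squares affine map from matched point pairs (exact for 3 pairs)."""
    src = np.asarray(src_points, dtype=float)
    dst = np.asarray(dst_points, dtype=float)
    if src.shape != dst.shape or src.shape[0] < 3:
        raise ValueError("need >= 3 matched point pairs of equal shape")
    design = np.column_stack([src, np.ones(src.shape[0])])
    sol, *_ = np.linalg.lstsq(design, dst, rcond=None)
    return AffineTransform(sol[:2].T, sol[2])


def apply_affine(t: AffineTransform, points) -> np.ndarray:
    """Apply y = linear @ x + offset to each point."""
    return t.apply(points)
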