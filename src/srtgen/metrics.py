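"""Fidelity metrics comparing synthetic against reference SRT data.

Four gene-wise metrics (mean, variance, coefficient of variation, zero
proportion across locations) and two location-wise metrics (zero proportion
across genes, library size) summarize the count structure; two-sample
Kolmogorov-Smirnov tests compare each metric's distribution between the
reference and the synthetic data, and per-gene Moran's I quantifies how well
spatial autocorrelation is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .count_models import model_preference_summary
from .data_core import SRTData
from .geometry import _knn_indices

__all__ = [
    "GENE_METRICS",
    "LOCATION_METRICS",
    "MetricsReport",
    "gene_metrics",
    "location_metrics",
    "ks_compare",
    "spatial_weights",
    "morans_i",
    "morans_i_matrix",
    "fidelity_report",
]

GENE_METRICS = ("mean", "variance", "cv", "zero_prop")
LOCATION_METRICS = ("loc_zero_prop", "library_size")


def gene_metrics(data: SRTData) -> pd.DataFrame:
    """Per-gene mean, sample variance (n-1), cv = sd/mean, zero proportion.

    cv is reported missing (NaN) for genes with zero mean and such genes
    are dropped from downstream KS comparisons.
    """
    if data.n_locations < 2:
        raise ValueError("gene metrics need at least 2 locations")
    x = data.counts.astype(float)
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, np.sqrt(var) / mean, np.nan)
    zero_prop = (x == 0).mean(axis=1)
    return pd.DataFrame({"mean": mean, "variance": var, "cv": cv,
                         "zero_prop": zero_prop}, index=data.gene_ids)


def location_metrics(data: SRTData) -> pd.DataFrame:
    """Per-location zero proportion (over genes) and library size."""
    if data.n_genes < 1:
        raise ValueError("location metrics need at least 1 gene")
    zero_prop = (data.counts == 0).mean(axis=0)
    libsize = data.counts.sum(axis=0)
    return pd.DataFrame({"loc_zero_prop": zero_prop, "library_size": libsize},
                        index=data.location_ids)


def ks_compare(ref_values, syn_values) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value.

    Missing values are dropped from each vector independently; identical
    inputs give D = 0, p = 1.
    """
    a = np.asarray(ref_values, dtype=float)
    b = np.asarray(syn_values, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("empty vector after missing-value removal")
    if a.size == b.size and np.array_equal(np.sort(a), np.sort(b)):
        return 0.0, 1.0
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def spatial_weights(coords, weights: str = "knn", k: int = 5) -> sparse.csr_matrix:
    """Spatial weight matrix with zero diagonal.

    ``'knn'``: binary k-nearest-neighbor adjacency, symmetrized by taking
    max(W, W.T) and not row-standardized (the package default, robust on
    both lattice and random layouts). ``'inverse_distance'``: dense 1/d
    weights.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if weights == "knn":
        kk = min(k, n - 1)
        nbr = _knn_indices(coords, coords, kk + 1)     # includes self
        rows, cols = [], []
        for i in range(n):
            js = [j for j in nbr[i] if j != i][:kk]
            rows.extend([i] * len(js))
            cols.extend(js)
        w = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        return w.maximum(w.T)
    if weights == "inverse_distance":
        d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        with np.errstate(divide="ignore"):
            w = 1.0 / d
        np.fill_diagonal(w, 0.0)
        return sparse.csr_matrix(w)
    raise ValueError(f"unknown weights {weights!r}; expected knn or inverse_distance")


def morans_i(values, coords=None, weights="knn", k: int = 5, W=None) -> float:
    """Moran's I spatial autocorrelation of one variable.

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2
    with S0 the total weight and zero diagonal. Returns NaN for a constant
    vector (the statistic is undefined). A precomputed weight matrix can be
    passed as ``W`` (sparse or dense) to bypass the coordinate-based builder.
    """
    x = np.asarray(values, dtype=float)
    if W is None:
        if coords is None:
            raise ValueError("either coords or W is required")
        if len(x) < 3:
            raise ValueError("Moran's I needs at least 3 locations")
        W = spatial_weights(coords, weights, k)
    W = sparse.csr_matrix(W)
    d = x - x.mean()
    denom = float(d @ d)
    if denom == 0.0:
        return float("nan")
    s0 = float(W.sum())
    num = float(d @ (W @ d))
    return (len(x) / s0) * num / denom


def morans_i_matrix(counts, coords=None, weights="knn", k: int = 5, W=None) -> np.ndarray:
    """Vectorized per-gene Moran's I for a genes x locations matrix."""
    X = np.asarray(counts, dtype=float)
    if W is None:
        W = spatial_weights(coords, weights, k)
    W = sparse.csr_matrix(W)
    D = X - X.mean(axis=1, keepdims=True)
    denom = (D * D).sum(axis=1)
    num = (D * (W @ D.T).T).sum(axis=1)
    s0 = float(W.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (X.shape[1] / s0) * num / denom
    out[denom == 0.0] = np.nan
    return out


@dataclass
class MetricsReport:
    """Assembled fidelity comparison between a reference and a synthetic set."""

    ref_gene: pd.DataFrame
    syn_gene: pd.DataFrame
    ref_location: pd.DataFrame
    syn_location: pd.DataFrame
    ks_table: pd.DataFrame                       # metric, D, p
    morans: pd.DataFrame | None = None           # gene_id, ref_i, syn_i
    model_preference: pd.DataFrame | None = None
    weight_spec: dict = field(default_factory=dict)

    def save(self, out_prefix) -> None:
        from pathlib import Path
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.ks_table.to_csv(f"{prefix}.ks.tsv", sep="\t", index=False)
        self.ref_gene.join(self.syn_gene, lsuffix="_ref", rsuffix="_syn") \
            .to_csv(f"{prefix}.gene_metrics.tsv", sep="\t")
        self.ref_location.join(self.syn_location, lsuffix="_ref", rsuffix="_syn") \
            .to_csv(f"{prefix}.location_metrics.tsv", sep="\t")
        if self.morans is not None:
            self.morans.to_csv(f"{prefix}.morans.tsv", sep="\t", index=False)
        if self.model_preference is not None:
            self.model_preference.to_csv(f"{prefix}.model_preference.tsv", sep="\t")


def fidelity_report(ref: SRTData, syn: SRTData, weights: str = "knn",
                    k: int = 5, compute_morans: bool | None = None,
                    compute_model_preference: bool = False) -> MetricsReport:
    """Compare a synthetic dataset against its reference.

    Computes the six metric distributions on both datasets, a two-sample KS
    test per metric, and — when the two datasets share identical locations
    (or ``compute_morans=True`` is forced) — paired per-gene Moran's I.
    ``compute_model_preference`` additionally profiles the AIC-preferred
    count family on both datasets (can be slow on large gene sets).
    """
    if set(ref.gene_ids) != set(syn.gene_ids):
        missing = set(ref.gene_ids) ^ set(syn.gene_ids)
        raise ValueError(f"gene sets differ between reference and synthetic: "
                         f"{sorted(missing)[:10]}{'...' if len(missing) > 10 else ''}")
    rg, sg = gene_metrics(ref), gene_metrics(syn)
    rl, sl = location_metrics(ref), location_metrics(syn)
    rows = []
    for m in GENE_METRICS:
        d, p = ks_compare(rg[m], sg[m])
        rows.append({"metric": m, "D": d, "p": p})
    for m in LOCATION_METRICS:
        d, p = ks_compare(rl[m], sl[m])
        rows.append({"metric": m, "D": d, "p": p})
    ks_table = pd.DataFrame(rows)

    if compute_morans is None:
        compute_morans = (ref.n_locations == syn.n_locations
                          and np.allclose(ref.coords, syn.coords))
    morans = None
    if compute_morans:
        W = spatial_weights(ref.coords, weights, k)
        morans = pd.DataFrame({
            "gene_id": ref.gene_ids,
            "ref_i": morans_i_matrix(ref.counts, W=W),
            "syn_i": morans_i_matrix(
                syn.counts[_gene_aligner(ref, syn)], W=W),
        })

    pref = None
    if compute_model_preference:
        pref = pd.DataFrame({"reference": model_preference_summary(ref),
                             "synthetic": model_preference_summary(syn)})
    return MetricsReport(rg, sg, rl, sl, ks_table, morans, pref,
                         {"weights": weights, "k": k})


def _gene_aligner(ref: SRTData, syn: SRTData) -> np.ndarray:
    pos = {g: i for i, g in enumerate(syn.gene_ids)}
    return np.array([pos[g] for g in ref.gene_ids])
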