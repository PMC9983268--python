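"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's internals: likelihoods go through
scipy.stats pmfs, maxima are located by iterative dense grid refinement,
and Moran's I is an explicit double loop over the formula.
"""

import numpy as np
from scipy import stats


def zi_loglik(counts, base_logpmf_fn, pi0):
    lp = base_logpmf_fn(counts)
    if pi0 <= 0:
        return float(lp.sum())
    out = np.log1p(-pi0) + lp
    zero = counts == 0
    out[zero] = np.logaddexp(np.log(pi0), np.log1p(-pi0) + lp[zero])
    return float(out.sum())


def family_loglik(counts, family, mu, phi=0.0, pi0=0.0):
    counts = np.asarray(counts)
    if family in ("poisson", "zip"):
        base = lambda x: stats.poisson.logpmf(x, mu)
    else:
        r = 1.0 / phi
        base = lambda x: stats.nbinom.logpmf(x, r, r / (r + mu))
    return zi_loglik(counts, base, pi0 if family in ("zip", "zinb") else 0.0)


def _refine(f, bounds, n_grid=13, n_rounds=5):
    """Iterative dense grid maximization over a box; returns (argmax, max)."""
    bounds = [list(b) for b in bounds]
    best_x, best_v = None, -np.inf
    for _ in range(n_rounds):
        axes = [np.linspace(lo, hi, n_grid) for lo, hi in bounds]
        grids = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([g.ravel() for g in grids])
        vals = np.array([f(p) for p in pts])
        i = int(np.argmax(vals))
        if vals[i] > best_v:
            best_v, best_x = vals[i], pts[i]
        # shrink the box around the current argmax
        for d, (lo, hi) in enumerate(bounds):
            step = (hi - lo) / (n_grid - 1)
            bounds[d] = [best_x[d] - step, best_x[d] + step]
    return best_x, best_v


def grid_mle(counts, family):
    """Grid-search MLE of (mu, phi, pi0) for one family (log/logit scales)."""
    counts = np.asarray(counts)
    mean = counts.mean()
    if family == "poisson":
        return {"mu": mean, "phi": 0.0, "pi0": 0.0,
                "loglik": family_loglik(counts, "poisson", mean)}
    lm = np.log(max(mean, 1e-3))
    if family == "nb":
        f = lambda p: family_loglik(counts, "nb", np.exp(p[0]), np.exp(p[1]))
        x, v = _refine(f, [[lm - 1.5, lm + 2.5], [np.log(1e-4), np.log(50.0)]])
        return {"mu": np.exp(x[0]), "phi": np.exp(x[1]), "pi0": 0.0, "loglik": v}
    if family == "zip":
        f = lambda p: family_loglik(counts, "zip", np.exp(p[0]), 0.0,
                                    1.0 / (1.0 + np.exp(-p[1])))
        x, v = _refine(f, [[lm - 1.0, lm + 3.0], [-8.0, 8.0]])
        return {"mu": np.exp(x[0]), "phi": 0.0,
                "pi0": 1.0 / (1.0 + np.exp(-x[1])), "loglik": v}
    f = lambda p: family_loglik(counts, "zinb", np.exp(p[0]), np.exp(p[1]),
                                1.0 / (1.0 + np.exp(-p[2])))
    x, v = _refine(f, [[lm - 1.0, lm + 3.0], [np.log(1e-4), np.log(50.0)],
                       [-8.0, 8.0]], n_grid=11, n_rounds=6)
    return {"mu": np.exp(x[0]), "phi": np.exp(x[1]),
            "pi0": 1.0 / (1.0 + np.exp(-x[2])), "loglik": v}


def morans_i_bruteforce(values, W):
    """Moran's I by explicit double loop over the defining formula."""
    x = np.asarray(values, dtype=float)
    W = np.asarray(W.todense()) if hasattr(W, "todense") else np.asarray(W)
    n = len(x)
    xbar = x.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * (x[i] - xbar) * (x[j] - xbar)
            s0 += W[i, j]
    den = float(((x - xbar) ** 2).sum())
    return (n / s0) * num / den
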