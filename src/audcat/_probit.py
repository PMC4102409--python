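"""Shared cumulative-Gaussian (probit) maximum-likelihood machinery.

Both psychometric analyses — 2AFC discrimination and category choice — fit
P(response) = Phi((d - mu) / sigma) to raw binary trials.  The fit is a
bounded quasi-Newton optimization with jittered restarts; bootstrap refits
warm-start from the point estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr

_EPS = 1e-12


@dataclass
class ProbitFit:
    mu: float
    sigma: float
    loglik: float
    converged: bool


def _nll(params, d, y):
    mu, sigma = params
    p = ndtr((d - mu) / sigma)
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return -float(np.sum(np.where(y, np.log(p), np.log1p(-p))))


def fit_probit(
    d: np.ndarray,
    y: np.ndarray,
    mu_bounds: tuple[float, float],
    sigma_bounds: tuple[float, float] = (1e-4, 2.0),
    n_restarts: int = 5,
    seed: int = 0,
    x0: tuple[float, float] | None = None,
) -> ProbitFit:
    """MLE of Phi((d - mu)/sigma) on raw binary trials.

    Starts from a method-of-moments guess (plus ``n_restarts - 1`` jittered
    copies) unless ``x0`` is given, in which case a single warm start is used
    (the bootstrap path).
    """
    d = np.asarray(d, dtype=float)
    y = np.asarray(y, dtype=bool)
    if d.shape != y.shape:
        raise ValueError("d and y must have matching shapes")
    if y.all() or not y.any():
        raise ValueError(
            "degenerate data: all responses identical; collect more trials spanning the transition"
        )
    bounds = [mu_bounds, sigma_bounds]

    if x0 is not None:
        starts = [np.asarray(x0, dtype=float)]
    else:
        rng = np.random.default_rng(seed)
        mu0 = float(np.clip(np.median(d), *mu_bounds))
        sigma0 = float(np.clip(np.std(d) or 0.1, *sigma_bounds))
        starts = [np.array([mu0, sigma0])]
        for _ in range(n_restarts - 1):
            jitter_mu = mu0 + 0.5 * sigma0 * rng.standard_normal()
            jitter_sigma = sigma0 * np.exp(0.5 * rng.standard_normal())
            starts.append(
                np.array(
                    [
                        np.clip(jitter_mu, *mu_bounds),
                        np.clip(jitter_sigma, *sigma_bounds),
                    ]
                )
            )

    best = None
    for start in starts:
        res = minimize(_nll, start, args=(d, y), method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    return ProbitFit(
        mu=float(best.x[0]),
        sigma=float(best.x[1]),
        loglik=-float(best.fun),
        converged=bool(best.success),
    )
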