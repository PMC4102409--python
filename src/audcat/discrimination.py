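"""Frequency-discrimination thresholds from 2AFC data.

The psychometric function is the probability of reporting the comparison
tone as higher, as a function of the log-frequency offset between comparison
and standard.  A cumulative Gaussian is fit by maximum likelihood to the raw
trials; the single-interval threshold follows from the difference model of
two equal-variance measurements, sigma_d = sigma_fit / sqrt(2).  A subject's
sensory-noise level sigma_s is the mean sigma_d across the eight standards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._probit import fit_probit

__all__ = [
    "DiscriminationFit",
    "SubjectThreshold",
    "delta_octaves",
    "bin_discrimination",
    "fit_discrimination_psychometric",
    "fit_all_standards",
    "subject_threshold",
]

SQRT2 = math.sqrt(2.0)


@dataclass
class DiscriminationFit:
    """Cumulative-Gaussian fit for one standard frequency."""

    standard_hz: float
    mu_fit: float  # bias, octaves
    sigma_fit: float  # psychometric width, octaves
    sigma_d: float  # single-interval threshold = sigma_fit / sqrt(2)
    n_trials: int
    ci: tuple[float, float] | None = None  # bootstrap 95% CI on sigma_d
    boot_sigma_d: np.ndarray | None = None
    converged: bool = True


@dataclass
class SubjectThreshold:
    """Per-subject sensory uncertainty: mean sigma_d across standards."""

    subject: str
    sigma_s: float
    per_standard: list
    ci: tuple[float, float] | None = None


def delta_octaves(trials: pd.DataFrame) -> np.ndarray:
    """Signed comparison-minus-standard offset in octaves."""
    return np.log2(
        trials["comparison_hz"].to_numpy(dtype=float)
        / trials["standard_hz"].to_numpy(dtype=float)
    )


def bin_discrimination(trials: pd.DataFrame, n_bins: int = 5) -> pd.DataFrame:
    """Bin "comparison judged higher" proportions per standard.

    Bins are equidistant in log units spanning the observed offset range of
    each standard.  Binning serves display and confidence intervals only;
    the MLE fit always uses raw trials.
    """
    if len(trials) == 0:
        raise ValueError("no discrimination trials to bin")
    rows = []
    for standard, group in trials.groupby("standard_hz"):
        d = np.log2(group["comparison_hz"].to_numpy(dtype=float) / float(standard))
        y = group["judged_comparison_higher"].to_numpy(dtype=bool)
        edges = np.linspace(d.min(), d.max(), n_bins + 1)
        idx = np.clip(np.digitize(d, edges[1:-1]), 0, n_bins - 1)
        for b in range(n_bins):
            sel = idx == b
            if not sel.any():
                continue
            rows.append(
                {
                    "standard_hz": float(standard),
                    "delta_mid": 0.5 * (edges[b] + edges[b + 1]),
                    "n_higher": int(y[sel].sum()),
                    "n_total": int(sel.sum()),
                }
            )
    return pd.DataFrame(rows)


def fit_discrimination_psychometric(
    trials: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> DiscriminationFit:
    """MLE cumulative-Gaussian fit for the trials of one standard.

    The bias term mu is left free (it is not constrained to zero).  The
    bootstrap resamples trials nonparametrically and refits from the point
    estimate; the CI is the percentile interval on sigma_d.
    """
    standards = trials["standard_hz"].unique()
    if len(standards) != 1:
        raise ValueError("fit_discrimination_psychometric expects trials of a single standard")
    d = delta_octaves(trials)
    y = trials["judged_comparison_higher"].to_numpy(dtype=bool)
    if len(np.unique(d)) < 3:
        raise ValueError("need responses at >= 3 distinct offsets to fit")
    half_range = max(1.0, float(np.max(np.abs(d))))
    fit = fit_probit(d, y, mu_bounds=(-half_range, half_range), seed=seed)

    boot = None
    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed + 1)
        boot = np.empty(n_boot)
        n = len(d)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if yb.all() or not yb.any():
                boot[b] = np.nan
                continue
            bfit = fit_probit(
                d[idx],
                yb,
                mu_bounds=(-half_range, half_range),
                x0=(fit.mu, fit.sigma),
            )
            boot[b] = bfit.sigma / SQRT2
        good = boot[~np.isnan(boot)]
        ci = (float(np.percentile(good, 2.5)), float(np.percentile(good, 97.5)))

    return DiscriminationFit(
        standard_hz=float(standards[0]),
        mu_fit=fit.mu,
        sigma_fit=fit.sigma,
        sigma_d=fit.sigma / SQRT2,
        n_trials=len(trials),
        ci=ci,
        boot_sigma_d=boot,
        converged=fit.converged,
    )


def fit_all_standards(
    trials: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> list[DiscriminationFit]:
    """One fit per standard frequency, collapsed across sessions/blocks."""
    fits = []
    for k, (standard, group) in enumerate(sorted(trials.groupby("standard_hz"))):
        fits.append(fit_discrimination_psychometric(group, n_boot=n_boot, seed=seed + 7 * k))
    return fits


def subject_threshold(fits: list[DiscriminationFit], subject: str = "S1") -> SubjectThreshold:
    """Average the per-standard thresholds into the subject's sigma_s.

    If every fit carries bootstrap draws of equal count, the CI of the mean
    is formed by averaging matched draws across standards (resampling within
    standard, as the per-standard bootstrap already did).
    """
    if not fits:
        raise ValueError("need at least one per-standard fit")
    sigma_s = float(np.mean([f.sigma_d for f in fits]))
    ci = None
    boots = [f.boot_sigma_d for f in fits]
    if all(b is not None for b in boots) and len({len(b) for b in boots}) == 1:
        stacked = np.vstack(boots)
        means = np.nanmean(stacked, axis=0)
        ci = (float(np.percentile(means, 2.5)), float(np.percentile(means, 97.5)))
    return SubjectThreshold(subject=subject, sigma_s=sigma_s, per_standard=list(fits), ci=ci)


def fits_to_frame(fits: list[DiscriminationFit], subject: str = "S1") -> pd.DataFrame:
    """Tidy per-standard threshold table for CSV output."""
    return pd.DataFrame(
        {
            "subject": subject,
            "standard_hz": [f.standard_hz for f in fits],
            "mu_fit": [f.mu_fit for f in fits],
            "sigma_fit": [f.sigma_fit for f in fits],
            "sigma_d": [f.sigma_d for f in fits],
            "n_trials": [f.n_trials for f in fits],
            "ci_lo": [f.ci[0] if f.ci else np.nan for f in fits],
            "ci_hi": [f.ci[1] if f.ci else np.nan for f in fits],
        }
    )
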