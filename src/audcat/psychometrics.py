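"""Descriptive analysis of categorization behavior.

Choice data are summarized as 9-bin psychometric curves (probability of
choosing the low category A versus tone frequency) and fit with a
*decreasing* cumulative Gaussian, P(A | x) = 1 - Phi((x - mu)/sigma) on the
log-frequency scale, by maximum likelihood on raw trials.  The point of
subjective equality (PSE) is the frequency at the fitted mu.  Binning uses
the unique equidistant log partition anchored at the category edges: three
bins tile the A-exclusive region, three the overlap, three the B-exclusive
region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._probit import fit_probit
from .core_model import FrequencyScale
from .io import responded_only

__all__ = [
    "PsychometricFit",
    "bin_categorization",
    "fit_choice_psychometric",
    "per_session_fits",
    "fits_to_frame",
]


@dataclass
class PsychometricFit:
    """Cumulative-Gaussian summary of choice behavior in one condition."""

    condition: float
    pse_hz: float
    sigma: float  # octaves
    n_trials: int
    ci_pse: tuple[float, float] | None = None
    ci_sigma: tuple[float, float] | None = None
    session: int | None = None
    extrapolated: bool = False
    converged: bool = True


def bin_categorization(
    trials: pd.DataFrame, scale: FrequencyScale | None = None, n_bins: int = 9
) -> pd.DataFrame:
    """Per-bin counts of A choices over equidistant log-frequency bins.

    Membership is half-open [lo, hi) with the last bin closed; with the
    default 9 bins over the full range, bins 1-3 tile the A-exclusive
    region, 4-6 the overlap and 7-9 the B-exclusive region.  Only responded
    trials are counted.
    """
    scale = scale or FrequencyScale()
    trials = responded_only(trials)
    x = scale.to_log(trials["frequency_hz"].to_numpy(dtype=float))
    chose_a = (trials["choice"] == "A").to_numpy()
    edges = np.linspace(scale.x_min, scale.x_max, n_bins + 1)
    idx = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rows = []
    for b in range(n_bins):
        sel = idx == b
        rows.append(
            {
                "bin_index": b + 1,
                "f_center_hz": float(scale.to_hz(centers[b])),
                "f_lo_hz": float(scale.to_hz(edges[b])),
                "f_hi_hz": float(scale.to_hz(edges[b + 1])),
                "n_a": int(chose_a[sel].sum()),
                "n_total": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def fit_choice_psychometric(
    trials: pd.DataFrame,
    scale: FrequencyScale | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    session: int | None = None,
) -> PsychometricFit:
    """MLE decreasing cumulative Gaussian for one condition's raw trials.

    P(A) falls with frequency (A is the low category), so the fit regresses
    the indicator of a *B* choice on log frequency.  The PSE is reported in
    Hz and flagged ``extrapolated`` if it falls outside the stimulus range.
    """
    scale = scale or FrequencyScale()
    trials = responded_only(trials)
    conditions = trials["condition"].unique()
    if len(conditions) != 1:
        raise ValueError("fit_choice_psychometric expects trials of a single condition")
    x = scale.to_log(trials["frequency_hz"].to_numpy(dtype=float))
    y_b = (trials["choice"] == "B").to_numpy()
    mu_bounds = (scale.x_min - 2.0, scale.x_max + 2.0)
    fit = fit_probit(x, y_b, mu_bounds=mu_bounds, seed=seed)

    ci_pse = ci_sigma = None
    if n_boot > 0:
        rng = np.random.default_rng(seed + 1)
        mus = np.empty(n_boot)
        sigmas = np.empty(n_boot)
        n = len(x)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            yb = y_b[idx]
            if yb.all() or not yb.any():
                mus[b] = sigmas[b] = np.nan
                continue
            bf = fit_probit(x[idx], yb, mu_bounds=mu_bounds, x0=(fit.mu, fit.sigma))
            mus[b], sigmas[b] = bf.mu, bf.sigma
        good = ~np.isnan(mus)
        pse_draws = scale.to_hz(mus[good])
        ci_pse = (float(np.percentile(pse_draws, 2.5)), float(np.percentile(pse_draws, 97.5)))
        ci_sigma = (
            float(np.percentile(sigmas[good], 2.5)),
            float(np.percentile(sigmas[good], 97.5)),
        )

    pse_hz = float(scale.to_hz(fit.mu))
    return PsychometricFit(
        condition=float(conditions[0]),
        pse_hz=pse_hz,
        sigma=fit.sigma,
        n_trials=len(trials),
        ci_pse=ci_pse,
        ci_sigma=ci_sigma,
        session=session,
        extrapolated=not (scale.f_min_hz <= pse_hz <= scale.f_max_hz),
        converged=fit.converged,
    )


def per_session_fits(
    trials: pd.DataFrame,
    scale: FrequencyScale | None = None,
    n_boot: int = 0,
    seed: int = 0,
) -> list[PsychometricFit]:
    """Independent fits per (session, condition) — the learning-curve table.

    Sessions whose data are degenerate (all one response) are skipped with a
    warning rather than aborting the table.
    """
    if "session" not in trials.columns:
        raise ValueError("per_session_fits requires a 'session' column")
    fits = []
    for k, ((session, condition), group) in enumerate(
        sorted(trials.groupby(["session", "condition"]))
    ):
        try:
            fits.append(
                fit_choice_psychometric(
                    group, scale=scale, n_boot=n_boot, seed=seed + 13 * k, session=int(session)
                )
            )
        except ValueError as exc:
            warnings.warn(
                f"skipping session {session}, condition {condition}: {exc}", stacklevel=2
            )
    return fits


def fits_to_frame(fits: list[PsychometricFit], subject: str = "S1") -> pd.DataFrame:
    """Tidy fits table (one row per fit) for CSV output."""
    return pd.DataFrame(
        {
            "subject": subject,
            "session": [f.session if f.session is not None else -1 for f in fits],
            "condition": [f.condition for f in fits],
            "pse_hz": [f.pse_hz for f in fits],
            "sigma": [f.sigma for f in fits],
            "n_trials": [f.n_trials for f in fits],
            "ci_pse_lo": [f.ci_pse[0] if f.ci_pse else np.nan for f in fits],
            "ci_pse_hi": [f.ci_pse[1] if f.ci_pse else np.nan for f in fits],
            "ci_sigma_lo": [f.ci_sigma[0] if f.ci_sigma else np.nan for f in fits],
            "ci_sigma_hi": [f.ci_sigma[1] if f.ci_sigma else np.nan for f in fits],
            "extrapolated": [f.extrapolated for f in fits],
        }
    )
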