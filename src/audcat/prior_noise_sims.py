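"""Trial-by-trial noise on the categorical priors under an optimal (MAP) rule.

Two simulations probe whether a MAP observer with *non-stationary* priors can
mimic probability matching:

* **mean noise** — each iteration independently perturbs the two category
  centers by Normal(0, sigma_mu) and recomputes the MAP psychometric curve;
  averaging over iterations flattens the slope;
* **prior noise** — each iteration perturbs the block prior,
  pi' = clip(pi + Normal(0, sigma_pi), 0, 1), producing plateaus in the
  averaged curve (at any noise level when pi = 0.5).

A companion analysis computes running estimates of pi over windows of
consecutive trials: their binomial variability over short histories is the
natural scale for the prior noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_model import (
    MAP,
    FrequencyScale,
    ObserverModel,
    SubjectiveCategory,
    map_choice_a_prob_general,
    objective_categories,
)
from .synthetic_data import ExperimentDesign, child_rng, generate_trial_sequence

__all__ = [
    "NoiseSimConfig",
    "HistoryConfig",
    "default_probe_grid",
    "simulate_mean_noise",
    "simulate_prior_noise",
    "running_prior_estimates",
]

MEAN_NOISE_LEVELS = tuple(np.geomspace(0.01, 1.28, 8))  # octaves
PRIOR_NOISE_LEVELS = tuple(np.geomspace(0.01, 0.64, 8))  # probability units


def default_probe_grid(scale: FrequencyScale | None = None, n: int = 101) -> np.ndarray:
    scale = scale or FrequencyScale()
    return np.geomspace(scale.f_min_hz, scale.f_max_hz, n)


@dataclass
class NoiseSimConfig:
    """Configuration of one family of categorical-prior-noise simulations."""

    noise_kind: str  # "mean" | "prior"
    base_model: ObserverModel
    levels: tuple = ()
    n_iter: int = 600
    probe_grid_hz: np.ndarray | None = None
    common_shift: bool = False  # mean noise: shift both categories together
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_kind not in ("mean", "prior"):
            raise ValueError("noise_kind must be 'mean' or 'prior'")
        if self.base_model.rule != MAP:
            raise ValueError("categorical-prior noise simulations assume a MAP base model")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not self.levels:
            self.levels = MEAN_NOISE_LEVELS if self.noise_kind == "mean" else PRIOR_NOISE_LEVELS
        if any(s < 0 for s in self.levels):
            raise ValueError("noise SDs must be non-negative")
        if self.probe_grid_hz is None:
            self.probe_grid_hz = default_probe_grid(self.base_model.scale)


def _net_curves(config: NoiseSimConfig, perturb) -> pd.DataFrame:
    """Average MAP psychometric curves over perturbed models.

    ``perturb(level, condition, rng) -> (model, condition_key)`` builds the
    per-iteration model.  Returns a tidy frame of the mean curve and its SD
    envelope per (level, condition).
    """
    grid = np.asarray(config.probe_grid_hz, dtype=float)
    frames = []
    for level in config.levels:
        for condition in sorted(config.base_model.priors):
            rng = child_rng(config.seed, config.noise_kind, f"{level:.6g}", f"{condition:g}")
            acc = np.zeros((config.n_iter, grid.size))
            for it in range(config.n_iter):
                model, cond_key = perturb(float(level), float(condition), rng)
                acc[it] = map_choice_a_prob_general(grid, cond_key, model)
            frames.append(
                pd.DataFrame(
                    {
                        "kind": config.noise_kind,
                        "noise_sd": float(level),
                        "condition": float(condition),
                        "f_hz": grid,
                        "psi_mean": acc.mean(axis=0),
                        "psi_sd": acc.std(axis=0),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def simulate_mean_noise(config: NoiseSimConfig) -> pd.DataFrame:
    """Net psychometric curves under Gaussian jitter of the category means.

    Each iteration displaces each category's box center by Normal(0,
    sigma_mu) — independently for the two categories unless
    ``common_shift`` — and evaluates the exact MAP curve; curves are then
    averaged.  With sigma_mu = 0 the net curve equals the unperturbed one.
    """
    if config.noise_kind != "mean":
        raise ValueError("config.noise_kind must be 'mean'")
    base = config.base_model

    def perturb(level, condition, rng):
        if config.common_shift:
            d_a = d_b = level * rng.standard_normal()
        else:
            d_a, d_b = level * rng.standard_normal(2)
        cat_a = SubjectiveCategory(
            "A", base.category_a.mu + d_a, base.category_a.width, base.category_a.smooth_sd
        )
        cat_b = SubjectiveCategory(
            "B", base.category_b.mu + d_b, base.category_b.width, base.category_b.smooth_sd
        )
        return replace(base, category_a=cat_a, category_b=cat_b), condition

    return _net_curves(config, perturb)


def simulate_prior_noise(config: NoiseSimConfig) -> pd.DataFrame:
    """Net psychometric curves under Gaussian jitter of the prior probability.

    Samples pi' = pi + Normal(0, sigma_pi) are clipped (not resampled) to
    [0, 1]; clipped extremes make the whole curve 0 or 1, which is what
    creates the interior plateaus once averaged.
    """
    if config.noise_kind != "prior":
        raise ValueError("config.noise_kind must be 'prior'")
    base = config.base_model

    def perturb(level, condition, rng):
        pi_true = base.prior_of(condition).pi_a
        pi_noisy = float(np.clip(pi_true + level * rng.standard_normal(), 0.0, 1.0))
        model = replace(base, priors={**{k: v.pi_a for k, v in base.priors.items()},
                                      condition: pi_noisy})
        return model, condition

    return _net_curves(config, perturb)


# ---------------------------------------------------------------------------
# running estimates of the prior over trial history
# ---------------------------------------------------------------------------


@dataclass
class HistoryConfig:
    """Windowed category-fraction analysis of generated trial sequences."""

    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    bin_lengths: tuple = (2, 4, 8, 16, 32)
    n_sequences: int = 20  # independent block sequences per condition
    sliding: bool = False

    def __post_init__(self) -> None:
        if any(length < 1 for length in self.bin_lengths):
            raise ValueError("bin lengths must be >= 1")


def running_prior_estimates(config: HistoryConfig) -> pd.DataFrame:
    """Mean and SD of window category-A fractions per (condition, bin length).

    Windows are non-overlapping consecutive blocks by default (a sliding
    window is available).  For Bernoulli(pi) sequences the window SD follows
    the binomial sqrt(pi (1 - pi) / L) scaling, which is the comparison
    scale for the prior-noise levels that produce plateaus.
    """
    design = replace(config.design, n_sessions=config.n_sequences)
    trials = generate_trial_sequence(design)
    rows = []
    for condition, g in sorted(trials.groupby("condition")):
        for length in config.bin_lengths:
            fractions = []
            for _, block in g.groupby("session"):
                is_a = (block["true_category"] == "A").to_numpy(dtype=float)
                if length > is_a.size:
                    warnings.warn(
                        f"window of {length} exceeds block length {is_a.size}; skipped",
                        stacklevel=2,
                    )
                    continue
                if config.sliding:
                    kernel = np.ones(length) / length
                    fractions.append(np.convolve(is_a, kernel, mode="valid"))
                else:
                    n_win = is_a.size // length
                    fractions.append(
                        is_a[: n_win * length].reshape(n_win, length).mean(axis=1)
                    )
            if not fractions:
                continue
            fractions = np.concatenate(fractions)
            rows.append(
                {
                    "condition": float(condition),
                    "bin_length": int(length),
                    "mean_fraction": float(fractions.mean()),
                    "sd_fraction": float(fractions.std(ddof=1)),
                    "n_windows": int(fractions.size),
                }
            )
    return pd.DataFrame(rows)
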