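"""Synthetic behavioral data with the statistical structure of the experiment.

Emulates both tasks end to end so every analysis stage can be exercised
without any recorded subject data:

* categorization sessions — each session holds one block per prior condition
  (0.25 / 0.5 / 0.75 by default, order shuffled per session); within a block
  the category is Bernoulli(pi) and the tone frequency uniform in log units
  on that category's support;
* observer responses — simulated from any :class:`~audcat.core_model.ObserverModel`
  (noisy measurement, posterior, MAP or MATCH decision), with an optional
  lapse fraction recorded as ``choice = "none"`` to exercise the
  responded-trials-only filter;
* 2AFC frequency discrimination — 2-up-1-down adaptive staircases at the
  eight standard frequencies, with the comparison placed above or below the
  standard at random and responses drawn from the difference model
  (correct with probability Phi(|dx| / (sigma_d * sqrt(2)))).

Randomness flows from a single root seed through deterministic child streams
per (subject, session, block), so regenerating any piece is reproducible and
independent of the others.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .core_model import (
    MAP,
    FrequencyScale,
    ObserverModel,
    _map_criteria_vec,
    category_likelihood,
    category_support,
    decide,
)

__all__ = [
    "DEFAULT_STANDARDS_HZ",
    "ExperimentDesign",
    "StaircaseConfig",
    "generate_trial_sequence",
    "simulate_observer",
    "simulate_staircase",
    "generate_discrimination_data",
]

DEFAULT_STANDARDS_HZ = (794.0, 1260.0, 2297.0, 2639.0, 3031.0, 3482.0, 4462.0, 4976.0)

CATEGORIZATION_COLUMNS = [
    "subject",
    "session",
    "condition",
    "trial_index",
    "true_category",
    "frequency_hz",
    "choice",
]
DISCRIMINATION_COLUMNS = [
    "subject",
    "standard_hz",
    "comparison_hz",
    "standard_first",
    "judged_comparison_higher",
    "correct",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """Session/block layout of the categorization and discrimination tasks.

    Defaults give 3 sessions x 234 trials/block = 702 trials per prior
    condition, inside the experiment's 600-1000 per-condition range.
    """

    scale: FrequencyScale = field(default_factory=FrequencyScale)
    conditions: tuple = (0.25, 0.5, 0.75)
    n_sessions: int = 3
    trials_per_block: int = 234
    standards_hz: tuple = DEFAULT_STANDARDS_HZ
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_block < 1:
            raise ValueError("trials_per_block must be >= 1")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        for c in self.conditions:
            if not 0.0 < c < 1.0:
                raise ValueError("conditions must lie strictly inside (0, 1)")
        for s in self.standards_hz:
            if not self.scale.f_min_hz <= s <= self.scale.f_max_hz:
                raise ValueError("standards must lie within the stimulus range")


def _key_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) % (2**32)
    return zlib.crc32(str(key).encode())


def child_rng(root_seed: int, *keys) -> np.random.Generator:
    """Deterministic child stream derived from the root seed and a key path."""
    entropy = [int(root_seed) % (2**32)] + [_key_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# categorization trials
# ---------------------------------------------------------------------------


def generate_trial_sequence(design: ExperimentDesign, subject: str = "S1") -> pd.DataFrame:
    """Stimulus sequence for all sessions of one subject (choices unset).

    Per block: the true category is Bernoulli(pi) trial by trial, and the
    frequency is uniform in log units on that category's support.  Block
    order within a session is shuffled (the design does not fix it).
    """
    scale = design.scale
    supports = {
        lab: tuple(scale.to_log(e) for e in category_support(scale, lab)) for lab in ("A", "B")
    }
    rows = []
    for session in range(1, design.n_sessions + 1):
        order_rng = child_rng(design.seed, subject, session, "order")
        order = list(order_rng.permutation(np.asarray(design.conditions, dtype=float)))
        for block_pos, pi_a in enumerate(order):
            rng = child_rng(design.seed, subject, session, block_pos)
            n = design.trials_per_block
            is_a = rng.random(n) < pi_a
            u = rng.random(n)
            x = np.where(
                is_a,
                supports["A"][0] + u * (supports["A"][1] - supports["A"][0]),
                supports["B"][0] + u * (supports["B"][1] - supports["B"][0]),
            )
            rows.append(
                pd.DataFrame(
                    {
                        "subject": subject,
                        "session": session,
                        "condition": float(pi_a),
                        "trial_index": np.arange(n),
                        "true_category": np.where(is_a, "A", "B"),
                        "frequency_hz": scale.to_hz(x),
                        "choice": "",
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def simulate_observer(
    trials: pd.DataFrame,
    model: ObserverModel,
    rng: np.random.Generator,
    lapse_rate: float = 0.0,
) -> pd.DataFrame:
    """Fill in choices by simulating the observer trial by trial.

    Each trial draws a measurement m ~ Normal(x(f), sigma_s), computes the
    posterior under the trial's block condition and applies the decision
    rule.  A ``lapse_rate`` fraction of trials is marked ``choice = "none"``
    (no response), exercising downstream exclusion; lapses are injected after
    the decision so the rng stream for choices is unchanged at rate 0.
    """
    if not 0.0 <= lapse_rate < 1.0:
        raise ValueError("lapse_rate must lie in [0, 1)")
    out = trials.copy()
    x = model.scale.to_log(out["frequency_hz"].to_numpy(dtype=float))
    m = x + model.sigma_s * rng.standard_normal(len(out))
    conditions = out["condition"].to_numpy(dtype=float)
    if model.rule == MAP:
        # criterion form of the MAP rule: robust where the posterior sits at
        # 0.5 to machine precision across the overlap (sharp boxes, tiny noise)
        unique = np.unique(conditions)
        crits = _map_criteria_vec(
            np.array([model.prior_of(c).pi_a for c in unique]),
            model.category_a,
            model.category_b,
            model.sigma_s,
        )
        crit_per_trial = crits[np.searchsorted(unique, conditions)]
        choice = np.where(m < crit_per_trial, "A", "B")
    else:
        la = category_likelihood(m, model.category_a, model.sigma_s)
        lb = category_likelihood(m, model.category_b, model.sigma_s)
        pi = np.array([model.prior_of(c).pi_a for c in conditions])
        num = pi * la
        den = num + (1.0 - pi) * lb
        post = np.full(len(out), np.nan)
        good = den > 0.0
        np.divide(num, den, out=post, where=good)
        post[~good] = pi[~good]
        choice = decide(post, model.rule, rng)
    if lapse_rate > 0.0:
        lapse = rng.random(len(out)) < lapse_rate
        choice = np.where(lapse, "none", choice)
    out["choice"] = choice
    return out


# ---------------------------------------------------------------------------
# discrimination staircases
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StaircaseConfig:
    """2-up-1-down schedule (Levitt-style; the exact steps are a convention).

    The comparison offset |dx| (octaves) starts at ``initial_delta``, moves
    multiplicatively (down after two consecutive correct responses, up after
    each error), with factor ``factor_early`` until ``reversal_switch``
    reversals have occurred and ``factor_late`` afterwards, clamped to
    [floor, ceiling].
    """

    n_trials: int = 40
    initial_delta: float = 0.5
    floor: float = 0.005
    ceiling: float = 2.0
    factor_early: float = 0.5
    factor_late: float = 0.75
    reversal_switch: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.floor <= self.initial_delta <= self.ceiling:
            raise ValueError("require 0 < floor <= initial_delta <= ceiling")
        for f in (self.factor_early, self.factor_late):
            if not 0 < f < 1:
                raise ValueError("step factors must lie in (0, 1)")


def simulate_staircase(
    sigma_d_true: float,
    standard_hz: float,
    config: StaircaseConfig | None = None,
    rng: np.random.Generator | None = None,
    subject: str = "S1",
) -> pd.DataFrame:
    """One adaptive track of 2AFC trials at a single standard frequency.

    The simulated subject judges which interval was higher from two noisy
    measurements (SD ``sigma_d_true`` each), so the probability of a correct
    response is Phi(|dx| / (sigma_d_true * sqrt(2))); the 2-up-1-down rule
    then converges near the 70.7%-correct offset.
    """
    if not sigma_d_true > 0:
        raise ValueError("sigma_d_true must be positive")
    config = config or StaircaseConfig()
    rng = rng if rng is not None else np.random.default_rng(0)

    delta = config.initial_delta
    n_correct_streak = 0
    n_reversals = 0
    last_move = None  # "down" | "up"
    sd_diff = sigma_d_true * math.sqrt(2.0)
    rows = []
    for _ in range(config.n_trials):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        dx = sign * delta
        comparison_hz = standard_hz * 2.0**dx
        standard_first = bool(rng.random() < 0.5)
        p_higher = ndtr(dx / sd_diff)
        judged_higher = bool(rng.random() < p_higher)
        correct = judged_higher == (dx > 0)
        rows.append(
            {
                "subject": subject,
                "standard_hz": standard_hz,
                "comparison_hz": comparison_hz,
                "standard_first": standard_first,
                "judged_comparison_higher": judged_higher,
                "correct": correct,
            }
        )
        factor = config.factor_early if n_reversals < config.reversal_switch else config.factor_late
        if correct:
            n_correct_streak += 1
            if n_correct_streak == 2:
                n_correct_streak = 0
                delta = max(delta * factor, config.floor)
                if last_move == "up":
                    n_reversals += 1
                last_move = "down"
        else:
            n_correct_streak = 0
            delta = min(delta / factor, config.ceiling)
            if last_move == "down":
                n_reversals += 1
            last_move = "up"
    return pd.DataFrame(rows)


def generate_discrimination_data(
    design: ExperimentDesign,
    sigma_d_true: float,
    subject: str = "S1",
    n_blocks: int = 4,
    config: StaircaseConfig | None = None,
) -> pd.DataFrame:
    """Full discrimination dataset: one staircase per standard per block.

    With the default 40-trial tracks and 4 blocks this yields 160 trials per
    standard (the experiment collected 2-4 sessions of two 30/40-trial
    blocks, collapsed across sessions for analysis).
    """
    frames = []
    for block in range(n_blocks):
        for standard in design.standards_hz:
            rng = child_rng(design.seed, subject, "discrim", block, int(standard * 1000))
            frames.append(
                simulate_staircase(sigma_d_true, standard, config=config, rng=rng, subject=subject)
            )
    return pd.concat(frames, ignore_index=True)
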