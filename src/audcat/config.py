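"""Structured run configuration for the command-line pipeline.

A single YAML mapping drives all stages; CLI flags override individual keys.
Every output CSV records the root seed and a hash of the resolved config, so
a rerun from the same file is byte-identical.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .core_model import FrequencyScale, MATCH
from .synthetic_data import DEFAULT_STANDARDS_HZ, ExperimentDesign

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # experiment design
    f_min_hz: float = 500.0
    f_max_hz: float = 5550.0
    conditions: tuple = (0.25, 0.5, 0.75)
    n_sessions: int = 3
    trials_per_block: int = 234
    standards_hz: tuple = DEFAULT_STANDARDS_HZ
    # generative observer (simulate stage)
    rule: str = MATCH
    prior_family: str = "subjective"
    sigma_cat: float = 0.1
    sigma_s: float = 0.02
    sigma_d_true: float = 0.02
    lapse_rate: float = 0.0
    n_subjects: int = 1
    discrimination_blocks: int = 4
    # analysis switches
    n_boot: int = 200
    n_starts: int = 20
    fit_rules: tuple = ("match", "map")
    fit_variants: tuple = ("prediction", "subjective7", "subjective8")
    # noise simulations
    noise_kind: str = "prior"
    noise_levels: tuple = ()
    noise_iterations: int = 600
    history_bin_lengths: tuple = (2, 4, 8, 16, 32)
    # plumbing
    seed: int = 0
    out_dir: str = "audcat_out"

    @property
    def scale(self) -> FrequencyScale:
        return FrequencyScale(self.f_min_hz, self.f_max_hz)

    @property
    def design(self) -> ExperimentDesign:
        return ExperimentDesign(
            scale=self.scale,
            conditions=tuple(self.conditions),
            n_sessions=self.n_sessions,
            trials_per_block=self.trials_per_block,
            standards_hz=tuple(self.standards_hz),
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path=None, **overrides) -> RunConfig:
    """Load a YAML config, applying keyword overrides (CLI flags win)."""
    data: dict = {}
    if path is not None:
        with open(Path(path), "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("conditions", "standards_hz", "fit_rules", "fit_variants",
                "noise_levels", "history_bin_lengths"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return RunConfig(**data)
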