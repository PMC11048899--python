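"""Configuration objects for the cohort generator, staging filters and the
cross-validation harness.  All are plain dataclasses that round-trip through
YAML so that every run is reproducible from a config file plus a seed."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .variables import STATISTICS, VARIABLE_CODES, VARIABLES


@dataclass(frozen=True)
class PlantedEffect:
    """A planted association between one extended statistic and the outcome.

    ``effect_size`` is the increment of the log-odds of progression per one
    standard deviation of the extended statistic (standardised log-odds).
    """

    variable: str
    statistic: str
    effect_size: float

    def __post_init__(self) -> None:
        if self.variable not in VARIABLE_CODES:
            raise ValueError(
                f"unknown variable {self.variable!r} in effect spec; "
                f"expected one of {VARIABLE_CODES}"
            )
        if self.statistic not in STATISTICS:
            raise ValueError(
                f"unknown statistic {self.statistic!r}; expected one of {STATISTICS}"
            )


def _default_means() -> dict[str, float]:
    return {v.code: v.mean for v in VARIABLES}


def _default_sds() -> dict[str, float]:
    return {v.code: v.sd for v in VARIABLES}


def _default_egfr_params() -> dict[str, float]:
    # Pre-window exams sit in the normal range; the staging exam falls in the
    # experimental (stage 3a) band for progressors and the control (3b) band
    # otherwise.  Values in mL/min/1.73 m^2.
    return {
        "normal_loc": 75.0,
        "normal_scale": 8.0,
        "normal_floor": 60.0,
        "experimental_lo": 45.0,
        "experimental_hi": 60.0,
        "control_lo": 30.0,
        "control_hi": 45.0,
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic longitudinal screening cohort.

    Defaults mirror the motivating screening cohort: 335 eligible subjects
    with three examinations each and 33 progressors (class ratio ~0.0985).
    """

    n_subjects: int = 335
    exams_per_subject: int | Sequence[int] = 3
    class_ratio: float = 33 / 335
    effect_spec: tuple[PlantedEffect, ...] = ()
    baseline_means: Mapping[str, float] = field(default_factory=_default_means)
    baseline_sds: Mapping[str, float] = field(default_factory=_default_sds)
    baseline_corr: float = 0.0
    egfr_params: Mapping[str, float] = field(default_factory=_default_egfr_params)
    noise_scale: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not (0.0 < self.class_ratio < 1.0):
            raise ValueError(f"class_ratio must lie in (0, 1), got {self.class_ratio}")
        if isinstance(self.exams_per_subject, int):
            if not (1 <= self.exams_per_subject <= 14):
                raise ValueError("exams_per_subject must lie in 1..14")
        else:
            object.__setattr__(self, "exams_per_subject", tuple(self.exams_per_subject))
            if len(self.exams_per_subject) != self.n_subjects:
                raise ValueError("per-subject exam counts must have length n_subjects")
            if any(not (1 <= k <= 14) for k in self.exams_per_subject):
                raise ValueError("every exam count must lie in 1..14")
        if not (0.0 <= self.baseline_corr < 1.0):
            raise ValueError("baseline_corr must lie in [0, 1)")
        effects = tuple(
            e if isinstance(e, PlantedEffect) else PlantedEffect(*e)
            for e in self.effect_spec
        )
        object.__setattr__(self, "effect_spec", effects)


@dataclass(frozen=True)
class StageThresholds:
    """eGFR thresholds driving cohort filtering and group assignment.

    Bands are half-open ``[lo, hi)`` in mL/min/1.73 m^2; the dialysis-range
    exclusion is strict (``egfr < egfr_exclusion`` removes the subject).
    """

    egfr_exclusion: float = 15.0
    experimental_band: tuple[float, float] = (45.0, 60.0)
    control_band: tuple[float, float] = (30.0, 45.0)
    normal_floor: float = 60.0

    def __post_init__(self) -> None:
        e_lo, e_hi = self.experimental_band
        c_lo, c_hi = self.control_band
        if not (e_lo < e_hi and c_lo < c_hi):
            raise ValueError("stage bands must be non-empty intervals")
        if e_lo < c_hi and c_lo < e_hi:  # [lo, hi) interval overlap
            raise ValueError("experimental and control bands must not overlap")
        if self.egfr_exclusion >= min(e_lo, c_lo):
            raise ValueError("exclusion threshold must sit below both stage bands")


@dataclass(frozen=True)
class CVConfig:
    """Nested cross-validation settings.

    The outer loop estimates performance and harvests importances; the inner
    loop (``inner_folds``-fold over the outer-training portion) tunes
    hyperparameters.  Oversampling is applied to training partitions only.
    """

    outer_folds: int = 10
    inner_folds: int = 9
    oversampler: str = "random"
    oversample_ratio: float = 1.0
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("outer_folds and inner_folds must both be >= 2")
        if self.oversampler not in ("random", "smote", "none"):
            raise ValueError("oversampler must be 'random', 'smote' or 'none'")
        if self.oversample_ratio <= 0:
            raise ValueError("oversample_ratio must be positive")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(config, path: str | Path) -> None:
    """Serialise any of the config dataclasses to YAML."""
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))


_CONFIG_TYPES = {
    "generator": GeneratorConfig,
    "thresholds": StageThresholds,
    "cv": CVConfig,
}


def load_config(path: str | Path, kind: str):
    """Load a config dataclass from YAML; ``kind`` selects the type."""
    cls = _CONFIG_TYPES[kind]
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if kind == "generator" and "effect_spec" in raw:
        raw["effect_spec"] = tuple(
            PlantedEffect(**e) if isinstance(e, dict) else PlantedEffect(*e)
            for e in raw["effect_spec"]
        )
    if kind == "thresholds":
        for key in ("experimental_band", "control_band"):
            if key in raw:
                raw[key] = tuple(raw[key])
    return cls(**raw)
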