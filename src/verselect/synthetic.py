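"""Synthetic longitudinal screening cohorts.

The restricted screening database behind the motivating study cannot be
shipped, so this module generates cohorts with the statistical structure the
analysis assumes:

* per-subject multivariate-normal baselines over the 19 measurements, with
  optional exchangeable correlation;
* later exams evolve as a random walk (exam ``t+1`` = exam ``t`` + noise),
  so trend and variability statistics carry subject-level information;
* a binary progression outcome drawn from a logistic model over planted
  extended statistics, with class counts fixed by deterministic rounding;
* eGFR trajectories that place progressors in the experimental (stage 3a)
  band and non-progressors in the control (stage 3b) band at the staging
  exam, after a run of normal-range (>= 60) values.

Outcome assignment uses a conditional-logistic draw: subject ``i`` is a
progressor iff ``eta_i + G_i`` ranks among the top ``n_pos`` scores, where
``G_i`` is iid standard-logistic noise.  Marginally this gives
``P(Y=1 | eta) = sigmoid(eta - t)`` for a data-determined threshold ``t``,
so planted log-odds slopes are recoverable by ordinary logistic regression
while small cohorts still hit their class counts exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GeneratorConfig
from .variables import VARIABLE_CODES, VARIABLES

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["subject_id", "exam", *VARIABLE_CODES, "egfr"]

#: floor for physiologically positive measurements, as a fraction of the
#: variable's baseline mean
_TRUNCATION_FRACTION = 1e-3


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort: the raw record table plus per-subject ground truth.

    ``records`` is the long-format record table (one row per subject per
    exam); ``truth`` holds the planted group label and outcome per subject,
    which downstream stages must be able to recover.
    """

    records: pd.DataFrame
    truth: pd.DataFrame
    manifest: dict


def _subject_ids(n: int) -> np.ndarray:
    width = max(4, len(str(n)))
    return np.array([f"S{i + 1:0{width}d}" for i in range(n)])


def _extended_stat(v1: np.ndarray, v2: np.ndarray, statistic: str) -> np.ndarray:
    if statistic == "C":
        return v2
    if statistic == "M":
        return (v1 + v2) / 2.0
    if statistic == "S":
        return np.abs(v2 - v1) / np.sqrt(2.0)
    if statistic == "D":
        return v2 - v1
    raise ValueError(f"unknown statistic {statistic!r}")


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a longitudinal screening cohort under ``config``.

    Returns a :class:`SyntheticCohort`; identical config (including seed)
    yields a bit-identical record table.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    if isinstance(config.exams_per_subject, int):
        counts = np.full(n, config.exams_per_subject, dtype=int)
    else:
        counts = np.asarray(config.exams_per_subject, dtype=int)
    max_k = int(counts.max())

    means = np.array([config.baseline_means[c] for c in VARIABLE_CODES])
    sds = np.array([config.baseline_sds[c] for c in VARIABLE_CODES])
    if np.any(sds <= 0):
        raise ValueError("baseline SDs must be strictly positive")

    # Baseline (exam 1): exchangeable-correlation multivariate normal.
    rho = config.baseline_corr
    shared = rng.standard_normal(n)
    idio = rng.standard_normal((n, len(VARIABLE_CODES)))
    z = np.sqrt(rho) * shared[:, None] + np.sqrt(1.0 - rho) * idio
    values = np.empty((max_k, n, len(VARIABLE_CODES)))
    values[0] = means + sds * z
    # Later exams: random walk with within-subject noise.
    for t in range(1, max_k):
        step = config.noise_scale * sds * rng.standard_normal((n, len(VARIABLE_CODES)))
        values[t] = values[t - 1] + step

    # Physiological measurements are strictly positive; truncate stray draws.
    floor = _TRUNCATION_FRACTION * means
    n_truncated = int(np.sum(values < floor))
    if n_truncated:
        logger.warning("truncated %d negative/near-zero draws at the floor", n_truncated)
    values = np.maximum(values, floor)

    eligible = counts >= 3
    n_elig = int(eligible.sum())
    if n_elig == 0 and config.effect_spec:
        raise ValueError("no subject has >= 3 exams; cannot assign outcomes")

    # Linear predictor over the planted extended statistics of the staging
    # window (predictor exams = the two before the last).
    eta = np.zeros(n_elig)
    if n_elig:
        idx = np.where(eligible)[0]
        t1 = counts[idx] - 3  # 0-based exam indices of the window
        t2 = counts[idx] - 2
        for effect in config.effect_spec:
            j = VARIABLE_CODES.index(effect.variable)
            v1 = values[t1, idx, j]
            v2 = values[t2, idx, j]
            stat = _extended_stat(v1, v2, effect.statistic)
            sd = stat.std()
            if sd == 0:
                raise ValueError(
                    f"planted statistic {effect.variable}({effect.statistic}) is "
                    "constant across subjects; cannot standardise"
                )
            eta += effect.effect_size * (stat - stat.mean()) / sd

    # Conditional-logistic outcome draw with exact class counts.
    n_pos = int(round(config.class_ratio * n_elig))
    n_pos = min(max(n_pos, 1), n_elig - 1) if n_elig >= 2 else 0
    y = np.zeros(n_elig, dtype=int)
    if n_elig >= 2:
        score = eta + rng.logistic(size=n_elig)
        y[np.argsort(score)[::-1][:n_pos]] = 1

    # eGFR trajectories: normal-range exams before the staging exam, then a
    # band placement determined by the outcome.
    p = config.egfr_params
    egfr = np.empty((max_k, n))
    draws = p["normal_loc"] + p["normal_scale"] * rng.standard_normal((max_k, n))
    # reflect below-floor draws so every pre-staging value is >= the floor
    egfr[:] = p["normal_floor"] + np.abs(draws - p["normal_floor"])
    stage_u = rng.uniform(size=n)
    if n_elig:
        idx = np.where(eligible)[0]
        last = counts[idx] - 1
        lo = np.where(y == 1, p["experimental_lo"], p["control_lo"])
        hi = np.where(y == 1, p["experimental_hi"], p["control_hi"])
        egfr[last, idx] = lo + stage_u[idx] * (hi - lo)

    sids = _subject_ids(n)
    rows = []
    for i in range(n):
        k = counts[i]
        block = pd.DataFrame(values[:k, i, :], columns=list(VARIABLE_CODES))
        block.insert(0, "exam", np.arange(1, k + 1))
        block.insert(0, "subject_id", sids[i])
        block["egfr"] = egfr[:k, i]
        rows.append(block)
    records = pd.concat(rows, ignore_index=True)[RECORD_COLUMNS]

    truth = pd.DataFrame({"subject_id": sids, "n_exams": counts})
    group = np.full(n, "ineligible", dtype=object)
    y_full = np.full(n, -1, dtype=int)
    if n_elig:
        idx = np.where(eligible)[0]
        group[idx] = np.where(y == 1, "experimental", "control")
        y_full[idx] = y
    truth["group"] = group
    truth["y"] = y_full

    manifest = {
        "seed": config.seed,
        "n_subjects": n,
        "n_eligible": n_elig,
        "n_positive": int((y_full == 1).sum()),
        "n_records": int(len(records)),
        "n_truncated_draws": n_truncated,
        "effect_spec": [
            {"variable": e.variable, "statistic": e.statistic, "effect_size": e.effect_size}
            for e in config.effect_spec
        ],
    }
    return SyntheticCohort(records=records, truth=truth, manifest=manifest)


_DEGENERATE_KINDS = ("too_few", "too_many", "dialysis")


def generate_degenerate_subjects(
    kinds: tuple[str, ...] = _DEGENERATE_KINDS, seed: int = 0
) -> pd.DataFrame:
    """Emit one subject per requested filter-violating pattern.

    ``too_few`` has 2 exams, ``too_many`` has 13, ``dialysis`` has a single
    eGFR reading of 14.9 (just under the dialysis-range exclusion of 15).
    Used as fixtures for the cohort filters.
    """
    rng = np.random.default_rng(seed)
    means = np.array([v.mean for v in VARIABLES])
    rows = []
    for kind in kinds:
        if kind not in _DEGENERATE_KINDS:
            raise ValueError(f"unknown degenerate kind {kind!r}")
        n_exams = {"too_few": 2, "too_many": 13, "dialysis": 3}[kind]
        egfr = np.full(n_exams, 75.0)
        if kind == "dialysis":
            egfr[1] = 14.9
        for t in range(n_exams):
            meas = means * (1.0 + 0.05 * rng.standard_normal(len(means)))
            rows.append([f"D_{kind}", t + 1, *meas, egfr[t]])
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write a record table as CSV with the canonical column order."""
    records[RECORD_COLUMNS].to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    records = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"record table at {path} is missing columns {sorted(missing)}")
    return records[RECORD_COLUMNS]


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2))
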