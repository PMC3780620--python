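"""Experimental designs and synthetic trial-stream generation.

Three within-subject designs are emulated.  Each block pairs a "baseline"
count distribution with one of two "alternative" distributions, every
distribution being a truncated, rounded Gaussian over circle counts:

* experiment 1 — baseline N(65, 10^2); alternatives N(55, 10^2) ("high")
  and N(35, 10^2) ("low"): the mean separation is manipulated.
* experiment 2 — baseline N(65, 20^2); alternatives N(35, 20^2)
  ("high_var") and N(35, 10^2) ("low_var"): the variance is manipulated.
* experiment 3 — baseline N(50, 10^2); alternatives N(60, 10^2) ("low")
  and N(80, 10^2) ("high"): the alternatives sit above the baseline.

A session is 8 blocks per condition (16 total), randomly interleaved, each
block holding 10 baseline and 10 alternative trials in random order.  Counts
are truncated to [10, 100] and rounded to the nearest integer; within a block
each trial type is tagged with a distinct color drawn from the 3 available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ConditionSpec",
    "ExperimentDesign",
    "TrialRecord",
    "make_design",
    "draw_count",
    "generate_session",
    "trials_to_frame",
    "frame_to_trials",
    "write_trials_csv",
    "read_trials_csv",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = [
    "subject_id", "experiment", "block_index", "condition_label",
    "trial_index_in_block", "trial_type", "color", "true_count",
    "response", "valid",
]


@dataclass(frozen=True)
class ConditionSpec:
    """One block condition: the baseline and alternative count distributions."""

    label: str
    baseline_mean: float
    baseline_sd: float
    alt_mean: float
    alt_sd: float

    def __post_init__(self):
        if self.baseline_sd <= 0 or self.alt_sd <= 0:
            raise ValueError("standard deviations must be > 0")


@dataclass(frozen=True)
class ExperimentDesign:
    """Full design of one experiment (conditions + block structure)."""

    experiment: str
    conditions: tuple
    n_blocks_per_condition: int = 8
    trials_per_block: int = 20
    n_baseline_per_block: int = 10
    truncation: tuple = (10, 100)
    n_colors_total: int = 3

    def __post_init__(self):
        if self.n_baseline_per_block > self.trials_per_block:
            raise ValueError("n_baseline_per_block exceeds trials_per_block")
        lo, hi = self.truncation
        if not lo < hi:
            raise ValueError("truncation bounds must satisfy low < high")
        for c in self.conditions:
            for m in (c.baseline_mean, c.alt_mean):
                if not lo <= m <= hi:
                    raise ValueError(f"condition mean {m} outside truncation bounds")

    @property
    def n_blocks(self) -> int:
        return self.n_blocks_per_condition * len(self.conditions)


@dataclass
class TrialRecord:
    """One trial: stimulus (color, true count) and the subject's response."""

    subject_id: str
    experiment: str
    block_index: int
    condition_label: str
    trial_index_in_block: int
    trial_type: str  # "baseline" | "alternative"
    color: int
    true_count: int
    response: Optional[int] = None
    valid: bool = True

    def __post_init__(self):
        if self.response is None and self.valid:
            # responses are filled later by a responder; a missing response on
            # a *valid* trial is allowed only pre-simulation
            pass
        if self.response is not None and not self.valid:
            raise ValueError("invalid trial cannot carry a response")


_DESIGNS = {
    "exp1": (
        ConditionSpec("high", 65, 10, 55, 10),
        ConditionSpec("low", 65, 10, 35, 10),
    ),
    "exp2": (
        ConditionSpec("high_var", 65, 20, 35, 20),
        ConditionSpec("low_var", 65, 20, 35, 10),
    ),
    "exp3": (
        ConditionSpec("low", 50, 10, 60, 10),
        ConditionSpec("high", 50, 10, 80, 10),
    ),
}


def make_design(experiment_id: str, overrides: dict | None = None) -> ExperimentDesign:
    """Return the built-in design for ``exp1``, ``exp2`` or ``exp3``.

    ``overrides`` may replace any :class:`ExperimentDesign` field; the
    ``conditions`` entry, if present, is a list of dicts with
    :class:`ConditionSpec` fields (e.g. from a YAML config).
    """
    try:
        conditions = _DESIGNS[experiment_id]
    except KeyError:
        raise ValueError(
            f"unknown experiment_id {experiment_id!r}; expected one of "
            f"{sorted(_DESIGNS)}") from None
    kwargs: dict = {"experiment": experiment_id, "conditions": conditions}
    if overrides:
        unknown = set(overrides) - set(ExperimentDesign.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown design override keys {sorted(unknown)}")
        kwargs.update(overrides)
        if "conditions" in overrides:
            kwargs["conditions"] = tuple(
                c if isinstance(c, ConditionSpec) else ConditionSpec(**c)
                for c in overrides["conditions"])
        if "truncation" in overrides:
            kwargs["truncation"] = tuple(overrides["truncation"])
    return ExperimentDesign(**kwargs)


def draw_count(mean: float, sd: float, truncation=(10, 100), rng=None, size=None,
               mode: str = "clamp"):
    """Draw integer circle counts from a truncated, rounded Gaussian.

    ``mode="clamp"`` (default) rounds the Gaussian draw and clips it to the
    bounds; ``mode="resample"`` redraws until the rounded value lands inside
    the bounds.
    """
    if sd <= 0:
        raise ValueError("sd must be > 0")
    rng = np.random.default_rng(rng)
    lo, hi = truncation
    if mode == "clamp":
        g = rng.normal(mean, sd, size=size)
        out = np.clip(np.rint(g), lo, hi).astype(int)
    elif mode == "resample":
        n = 1 if size is None else int(np.prod(size))
        vals = np.empty(n, dtype=int)
        filled = 0
        while filled < n:
            g = np.rint(rng.normal(mean, sd, size=n - filled))
            ok = g[(g >= lo) & (g <= hi)]
            vals[filled:filled + ok.size] = ok.astype(int)
            filled += ok.size
        out = vals.reshape(size) if size is not None else vals
    else:
        raise ValueError(f"unknown truncation mode {mode!r}")
    if size is None:
        return int(np.asarray(out).reshape(-1)[0])
    return out


def generate_session(design: ExperimentDesign, subject_id: str, rng=None,
                     truncation_mode: str = "clamp") -> list:
    """Generate one subject's full trial stream (responses left missing).

    Block order interleaves the conditions by uniform random permutation; trial
    types within a block are randomly interleaved; each block draws two
    distinct colors (one per trial type) from the available colors.
    """
    rng = np.random.default_rng(rng)
    labels = [c.label for c in design.conditions for _ in range(design.n_blocks_per_condition)]
    block_labels = [labels[i] for i in rng.permutation(len(labels))]
    by_label = {c.label: c for c in design.conditions}
    trials: list[TrialRecord] = []
    for b, label in enumerate(block_labels):
        cond = by_label[label]
        n_alt = design.trials_per_block - design.n_baseline_per_block
        types = np.array(["baseline"] * design.n_baseline_per_block
                         + ["alternative"] * n_alt)
        types = types[rng.permutation(len(types))]
        colors = 1 + rng.choice(design.n_colors_total, size=2, replace=False)
        color_of = {"baseline": int(colors[0]), "alternative": int(colors[1])}
        for i, tt in enumerate(types):
            if tt == "baseline":
                m, s = cond.baseline_mean, cond.baseline_sd
            else:
                m, s = cond.alt_mean, cond.alt_sd
            x = draw_count(m, s, design.truncation, rng, mode=truncation_mode)
            trials.append(TrialRecord(
                subject_id=subject_id, experiment=design.experiment,
                block_index=b, condition_label=label,
                trial_index_in_block=i, trial_type=str(tt),
                color=color_of[str(tt)], true_count=x,
                response=None, valid=True))
    return trials


# ---------------------------------------------------------------------------
# tabular round-trips

def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    df = pd.DataFrame([{
        "subject_id": t.subject_id, "experiment": t.experiment,
        "block_index": t.block_index, "condition_label": t.condition_label,
        "trial_index_in_block": t.trial_index_in_block,
        "trial_type": t.trial_type, "color": t.color,
        "true_count": t.true_count,
        "response": np.nan if t.response is None else t.response,
        "valid": t.valid,
    } for t in trials], columns=TRIAL_COLUMNS)
    return df


def frame_to_trials(df: pd.DataFrame) -> list:
    out = []
    for row in df.itertuples(index=False):
        resp = None if pd.isna(row.response) else int(row.response)
        out.append(TrialRecord(
            subject_id=str(row.subject_id), experiment=str(row.experiment),
            block_index=int(row.block_index),
            condition_label=str(row.condition_label),
            trial_index_in_block=int(row.trial_index_in_block),
            trial_type=str(row.trial_type), color=int(row.color),
            true_count=int(row.true_count), response=resp,
            valid=bool(row.valid)))
    return out


def write_trials_csv(df: pd.DataFrame, path) -> None:
    """Write the standard trial table (missing responses as empty fields)."""
    out = df.copy()
    out["response"] = out["response"].map(
        lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=False)


def read_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    df["response"] = pd.to_numeric(df["response"], errors="coerce")
    df["valid"] = df["valid"].astype(bool)
    return df[TRIAL_COLUMNS]
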