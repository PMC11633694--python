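"""Primary task metrics of the object-location memory task and the long-format
outcome tables consumed by the mixed model.

The four primary metrics per session x condition:

* proportion correct — fraction of trials where the studied item was
  identified among the two probe fractals;
* identification time — ms from probe onset to touching the chosen fractal
  (over correctly identified trials by default, configurable);
* localization time — ms spent dragging the chosen fractal to its remembered
  location;
* absolute error — Euclidean distance (px) from the studied location to the
  response location.

Times are canonically milliseconds throughout; converters to/from seconds are
provided because bedside reports often quote seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    Assignment,
    EmptyDataError,
    MappingError,
    OMTTrial,
    OUTCOME_NAMES,
    SESSION_OF_WEEK,
)


def seconds_to_ms(seconds: float) -> float:
    return float(seconds) * 1000.0


def ms_to_seconds(ms: float) -> float:
    return float(ms) / 1000.0


def absolute_error(target_xy: Sequence[float], response_xy: Sequence[float]) -> float:
    """Euclidean distance (px) between the studied and the reported location."""
    dx = float(response_xy[0]) - float(target_xy[0])
    dy = float(response_xy[1]) - float(target_xy[1])
    if not (math.isfinite(dx) and math.isfinite(dy)):
        raise ValueError("coordinates must be finite")
    return math.hypot(dx, dy)


@dataclass(frozen=True)
class PrimaryMetrics:
    """Session-level summary of the four primary metrics over n trials."""

    proportion_correct: float
    mean_identification_time_ms: float
    mean_localization_time_ms: float
    mean_absolute_error_px: float
    n: int
    n_correct: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion_correct <= 1.0:
            raise ValueError("proportion_correct outside [0, 1]")


def primary_metrics(
    trials: Iterable[OMTTrial],
    condition: Optional[int] = None,
    times_correct_only: bool = True,
    use_median: bool = False,
) -> PrimaryMetrics:
    """Summarise ``trials`` (optionally one condition) into the four metrics.

    ``times_correct_only`` restricts the two timing means to correctly
    identified trials (the time "to identify the correct object"); proportion
    correct and absolute error always use all filtered trials. Means by
    default; ``use_median`` switches both timing and error summaries to
    medians.
    """
    kept = [t for t in trials if condition is None or t.condition == condition]
    if not kept:
        raise EmptyDataError(
            f"no trials left after filtering (condition={condition!r})"
        )
    correct = [t for t in kept if t.identified_correct]
    timed = correct if times_correct_only else kept
    center = np.median if use_median else np.mean
    id_t = float(center([t.identification_time_ms for t in timed])) if timed else float("nan")
    loc_t = float(center([t.localization_time_ms for t in timed])) if timed else float("nan")
    err = float(center([absolute_error(t.target_xy, t.response_xy) for t in kept]))
    return PrimaryMetrics(
        proportion_correct=len(correct) / len(kept),
        mean_identification_time_ms=id_t,
        mean_localization_time_ms=loc_t,
        mean_absolute_error_px=err,
        n=len(kept),
        n_correct=len(correct),
    )


def metrics_by_session(
    trials: Iterable[OMTTrial], condition: Optional[int] = None, **kwargs
) -> pd.DataFrame:
    """Per subject x week table of the four metrics (one row each)."""
    trials = list(trials)
    rows = []
    keys = sorted({(t.subject_id, t.session_week) for t in trials})
    for sid, week in keys:
        subset = [t for t in trials if t.subject_id == sid and t.session_week == week]
        try:
            m = primary_metrics(subset, condition=condition, **kwargs)
        except EmptyDataError:
            continue
        rows.append(
            {
                "subject_id": sid,
                "session_week": week,
                "condition": condition if condition is not None else 0,
                "proportion_correct": m.proportion_correct,
                "mean_identification_time_ms": m.mean_identification_time_ms,
                "mean_localization_time_ms": m.mean_localization_time_ms,
                "mean_absolute_error_px": m.mean_absolute_error_px,
                "n": m.n,
                "n_correct": m.n_correct,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class LongOutcomeTable:
    """Trial-level rows (subject, session, drug, week, trial, value) for one
    outcome, the input format of the random-intercept mixed model."""

    outcome_name: str
    frame: pd.DataFrame  # columns: subject_id, session, drug, week, trial_index, value

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    @property
    def n_subjects(self) -> int:
        return self.frame["subject_id"].nunique()


def build_long_table(
    trials: Iterable[OMTTrial],
    assignments: Iterable[Assignment],
    outcome_name: str,
    weeks: Optional[Sequence[int]] = None,
    condition: Optional[int] = None,
) -> LongOutcomeTable:
    """Assemble the trial-by-trial long table for ``outcome_name``.

    Session derives from the week (0/8 -> 1, 12/20 -> 2) and the drug label
    from the subject's crossover assignment at that session. Per-trial
    correctness is encoded 0/1 so that proportion correct can be modelled at
    trial level.
    """
    if outcome_name not in OUTCOME_NAMES:
        raise ValueError(f"outcome_name must be one of {OUTCOME_NAMES}")
    amap = {a.subject_id: a for a in assignments}
    rows = []
    for t in trials:
        if weeks is not None and t.session_week not in weeks:
            continue
        if condition is not None and t.condition != condition:
            continue
        if t.subject_id not in amap:
            raise MappingError(f"trial subject {t.subject_id!r} has no assignment")
        session = SESSION_OF_WEEK[t.session_week]
        drug = amap[t.subject_id].drug_by_session[session]
        if outcome_name == "proportion_correct":
            value = float(t.identified_correct)
        elif outcome_name == "absolute_error":
            value = absolute_error(t.target_xy, t.response_xy)
        elif outcome_name == "identification_time":
            value = t.identification_time_ms
        else:
            value = t.localization_time_ms
        rows.append((t.subject_id, session, drug, t.session_week, t.trial_index, value))
    frame = pd.DataFrame(
        rows, columns=["subject_id", "session", "drug", "week", "trial_index", "value"]
    )
    return LongOutcomeTable(outcome_name=outcome_name, frame=frame)
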