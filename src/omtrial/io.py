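"""CSV serialization of trial datasets, run configuration and logging.

Dialect: comma-separated, UTF-8, '.' decimal, one header row. Writing is
deterministic — fixed column order, rows sorted by (subject, week, index) and
floats at fixed 6-decimal precision — so repeated writes of the same dataset
are byte-identical. ``read_dataset(write_dataset(X))`` reproduces X exactly
when float fields carry at most 6 decimals (the synthetic generator rounds to
that precision), and to 1e-6 otherwise.
"""

from __future__ import annotations

import logging
import sys
import uuid
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd
import yaml

from .datamodel import (
    AdverseEventRecord,
    Assignment,
    Dataset,
    Demographics,
    OMTTrial,
    QuestionnaireRecord,
    SchemaError,
    ScreenGeometry,
    DataValidationError,
)

FLOAT_FMT = "%.6f"

TRIAL_COLUMNS = [
    "subject_id",
    "session_week",
    "trial_index",
    "condition",
    "target_x",
    "target_y",
    "nontarget_x",
    "nontarget_y",
    "identified_correct",
    "response_x",
    "response_y",
    "identification_time_ms",
    "localization_time_ms",
]
QUESTIONNAIRE_COLUMNS = ["subject_id", "instrument", "respondent", "week", "score"]
AE_COLUMNS = ["subject_id", "arm", "term", "n_instances"]
DEMOGRAPHICS_COLUMNS = ["subject_id", "age_years", "sex", "baseline_mmse"]
ASSIGNMENT_COLUMNS = ["subject_id", "sequence"]

DEFAULT_FILENAMES = {
    "trials": "trials.csv",
    "questionnaires": "questionnaires.csv",
    "adverse_events": "adverse_events.csv",
    "demographics": "demographics.csv",
    "assignments": "assignments.csv",
}

PathMap = Mapping[str, Union[str, Path]]


def default_path_map(directory: Union[str, Path]) -> dict[str, Path]:
    d = Path(directory)
    return {kind: d / name for kind, name in DEFAULT_FILENAMES.items()}


# ---------------------------------------------------------------------------
# Records <-> DataFrames
# ---------------------------------------------------------------------------


def trials_to_frame(trials: list[OMTTrial]) -> pd.DataFrame:
    rows = []
    for t in trials:
        nx, ny = (t.nontarget_xy[0] if t.nontarget_xy else (float("nan"),) * 2)
        rows.append(
            (
                t.subject_id,
                t.session_week,
                t.trial_index,
                t.condition,
                t.target_xy[0],
                t.target_xy[1],
                nx,
                ny,
                int(t.identified_correct),
                t.response_xy[0],
                t.response_xy[1],
                t.identification_time_ms,
                t.localization_time_ms,
            )
        )
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return df.sort_values(
        ["subject_id", "session_week", "trial_index"], kind="mergesort"
    ).reset_index(drop=True)


def frame_to_trials(df: pd.DataFrame, source: str = "trials") -> list[OMTTrial]:
    _require_columns(df, TRIAL_COLUMNS, source)
    out: list[OMTTrial] = []
    for i, row in enumerate(df.itertuples(index=False)):
        nontarget = ()
        if pd.notna(row.nontarget_x) and pd.notna(row.nontarget_y):
            nontarget = ((float(row.nontarget_x), float(row.nontarget_y)),)
        out.append(
            OMTTrial(
                subject_id=str(row.subject_id),
                session_week=int(row.session_week),
                trial_index=int(row.trial_index),
                condition=int(row.condition),
                target_xy=(float(row.target_x), float(row.target_y)),
                nontarget_xy=nontarget,
                identified_correct=bool(int(row.identified_correct)),
                response_xy=(float(row.response_x), float(row.response_y)),
                identification_time_ms=float(row.identification_time_ms),
                localization_time_ms=float(row.localization_time_ms),
            )
        )
    return out


def questionnaires_to_frame(records: list[QuestionnaireRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(q.subject_id, q.instrument, q.respondent, q.week, q.score) for q in records],
        columns=QUESTIONNAIRE_COLUMNS,
    )
    return df.sort_values(
        ["subject_id", "instrument", "respondent", "week"], kind="mergesort"
    ).reset_index(drop=True)


def ae_to_frame(records: list[AdverseEventRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(a.subject_id, a.arm, a.term, a.n_instances) for a in records],
        columns=AE_COLUMNS,
    )
    return df.sort_values(["subject_id", "arm", "term"], kind="mergesort").reset_index(
        drop=True
    )


def demographics_to_frame(records: list[Demographics]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(d.subject_id, d.age_years, d.sex, d.baseline_mmse) for d in records],
        columns=DEMOGRAPHICS_COLUMNS,
    )
    return df.sort_values(["subject_id"], kind="mergesort").reset_index(drop=True)


def assignments_to_frame(records: list[Assignment]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(a.subject_id, a.sequence) for a in records], columns=ASSIGNMENT_COLUMNS
    )
    return df.sort_values(["subject_id"], kind="mergesort").reset_index(drop=True)


def _require_columns(df: pd.DataFrame, columns: list[str], source: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing column(s) {missing}")


# ---------------------------------------------------------------------------
# Dataset I/O
# ---------------------------------------------------------------------------


def write_dataset(dataset: Dataset, path_map: PathMap) -> dict[str, Path]:
    """Write every record kind of ``dataset`` to the paths in ``path_map``.

    Unknown keys in ``path_map`` are ignored; omitted kinds are not written.
    """
    frames = {
        "trials": trials_to_frame(dataset.trials),
        "questionnaires": questionnaires_to_frame(dataset.questionnaires),
        "adverse_events": ae_to_frame(dataset.adverse_events),
        "demographics": demographics_to_frame(dataset.demographics),
        "assignments": assignments_to_frame(dataset.assignments),
    }
    written: dict[str, Path] = {}
    for kind, frame in frames.items():
        if kind not in path_map:
            continue
        path = Path(path_map[kind])
        path.parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")
        written[kind] = path
    return written


def read_dataset(
    path_map: PathMap, screen: Optional[ScreenGeometry] = None
) -> Dataset:
    """Read the CSV files named in ``path_map`` into typed, checked records.

    Raises :class:`SchemaError` for a missing column and
    :class:`DataValidationError` (naming file and row) for the first record
    violating a hard invariant. Schedule completeness is *not* enforced here;
    use :func:`omtrial.datamodel.validate_dataset` for the full report.
    """
    ds = Dataset()
    if "trials" in path_map:
        df = pd.read_csv(path_map["trials"])
        ds.trials = frame_to_trials(df, source=str(path_map["trials"]))
        for i, t in enumerate(ds.trials):
            probs = t.problems(screen)
            if probs:
                raise DataValidationError(
                    f"{path_map['trials']} row {i}: {'; '.join(probs)}"
                )
    if "questionnaires" in path_map:
        df = pd.read_csv(path_map["questionnaires"])
        _require_columns(df, QUESTIONNAIRE_COLUMNS, str(path_map["questionnaires"]))
        ds.questionnaires = [
            QuestionnaireRecord(
                str(r.subject_id), str(r.instrument), str(r.respondent),
                int(r.week), float(r.score),
            )
            for r in df.itertuples(index=False)
        ]
        for i, q in enumerate(ds.questionnaires):
            probs = q.problems()
            if probs:
                raise DataValidationError(
                    f"{path_map['questionnaires']} row {i}: {'; '.join(probs)}"
                )
    if "adverse_events" in path_map:
        df = pd.read_csv(path_map["adverse_events"])
        _require_columns(df, AE_COLUMNS, str(path_map["adverse_events"]))
        ds.adverse_events = [
            AdverseEventRecord(str(r.subject_id), str(r.arm), str(r.term), int(r.n_instances))
            for r in df.itertuples(index=False)
        ]
        for i, a in enumerate(ds.adverse_events):
            probs = a.problems()
            if probs:
                raise DataValidationError(
                    f"{path_map['adverse_events']} row {i}: {'; '.join(probs)}"
                )
    if "demographics" in path_map:
        df = pd.read_csv(path_map["demographics"])
        _require_columns(df, DEMOGRAPHICS_COLUMNS, str(path_map["demographics"]))
        ds.demographics = [
            Demographics(str(r.subject_id), float(r.age_years), str(r.sex), int(r.baseline_mmse))
            for r in df.itertuples(index=False)
        ]
    if "assignments" in path_map:
        df = pd.read_csv(path_map["assignments"])
        _require_columns(df, ASSIGNMENT_COLUMNS, str(path_map["assignments"]))
        ds.assignments = [
            Assignment(str(r.subject_id), str(r.sequence))
            for r in df.itertuples(index=False)
        ]
    return ds


# ---------------------------------------------------------------------------
# Run configuration + logging
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """YAML-backed run options shared by the CLI commands."""

    screen: ScreenGeometry = field(default_factory=ScreenGeometry)
    seed: int = 0
    options: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        scr = raw.get("screen", {})
        screen = ScreenGeometry(
            width_px=float(scr.get("width_px", 1024.0)),
            height_px=float(scr.get("height_px", 768.0)),
            margin_px=float(scr.get("margin_px", 100.0)),
        )
        return cls(screen=screen, seed=int(raw.get("seed", 0)),
                   options=dict(raw.get("options", {})))

    def to_yaml(self, path: Union[str, Path]) -> None:
        payload = {
            "screen": {
                "width_px": self.screen.width_px,
                "height_px": self.screen.height_px,
                "margin_px": self.screen.margin_px,
            },
            "seed": self.seed,
            "options": self.options,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def get_logger(run_id: Optional[str] = None) -> logging.Logger:
    """Logger to stderr tagged with a run id (random if not given)."""
    run_id = run_id or uuid.uuid4().hex[:8]
    logger = logging.getLogger(f"omtrial.{run_id}")
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter(f"%(asctime)s omtrial[{run_id}] %(levelname)s: %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger
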