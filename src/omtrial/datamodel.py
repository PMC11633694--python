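"""Shared data model for a placebo-controlled crossover cohort performing the
"What was where?" object-location memory task (OMT).

The trial structure encoded here: participants are randomized 1:1 (restricted
block) to receive active drug or placebo first, then cross over. Assessments
fall at weeks 0, 8, 12 and 20; weeks 0/8 form session (arm) 1 and weeks 12/20
form session 2, with week 0 and week 12 acting as the within-arm baselines.
Each OMT session presents 20 trials mixing one-item and two-item displays on a
touch screen; the participant identifies the studied fractal and drags it back
to its studied location.

Coordinates are 0-based screen pixels, origin top-left, y increasing downward.
Durations are milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

XY = Tuple[float, float]

#: Scheduled assessment weeks.
WEEKS: Tuple[int, ...] = (0, 8, 12, 20)

#: Week -> crossover session (arm) index.
SESSION_OF_WEEK: Mapping[int, int] = {0: 1, 8: 1, 12: 2, 20: 2}

#: Weeks at which the participant has completed 4 weeks on drug/placebo.
END_OF_ARM_WEEKS: Tuple[int, ...] = (8, 20)

LEV_FIRST = "LEV_FIRST"
PBO_FIRST = "PBO_FIRST"
SEQUENCES = (LEV_FIRST, PBO_FIRST)

#: Sequence -> {session: drug label} with drug coded 0=placebo, 1=active.
DRUG_BY_SEQUENCE: Mapping[str, Mapping[int, int]] = {
    LEV_FIRST: {1: 1, 2: 0},
    PBO_FIRST: {1: 0, 2: 1},
}

#: Allowed (instrument, respondent) pairs for questionnaire records.
INSTRUMENT_RESPONDENTS = frozenset(
    {
        ("MMSE", "patient"),
        ("BADLS", "caregiver"),
        ("DSRS", "caregiver"),
        ("NPI", "caregiver"),
        ("EQ5D", "patient"),
        ("EQ5D", "caregiver"),
        ("EQ5D", "proxy"),
        ("QoL", "patient"),
        ("QoL", "caregiver"),
    }
)

OUTCOME_NAMES = (
    "proportion_correct",
    "absolute_error",
    "identification_time",
    "localization_time",
)


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class OmtrialError(Exception):
    """Base class for all package errors."""


class ConfigError(OmtrialError):
    """Invalid run or cohort configuration."""


class SchemaError(OmtrialError):
    """A CSV file does not match the documented dialect (e.g. missing column)."""


class DataValidationError(OmtrialError):
    """A record violates a type invariant."""


class GeometryError(OmtrialError):
    """Screen geometry infeasible for the requested operation."""


class ParameterError(OmtrialError):
    """Invalid model parameters."""


class SmallSampleError(OmtrialError):
    """Fewer observations than the operation's documented floor."""


class MappingError(OmtrialError):
    """A record refers to a subject with no assignment (or similar orphan)."""


class EmptyDataError(OmtrialError):
    """A filter left no trials; raised instead of returning silent zeros."""


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenGeometry:
    """Touch-screen geometry in pixels.

    ``margin_px`` is the item-free band at the edges: stimuli are placed on the
    margin-inset rectangle, while responses (and the uniform guessing
    component) live on the full screen of area ``area``.
    """

    width_px: float = 1024.0
    height_px: float = 768.0
    margin_px: float = 100.0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise GeometryError("screen dimensions must be positive")
        if self.margin_px < 0:
            raise GeometryError("margin_px must be non-negative")
        if self.width_px <= 2 * self.margin_px or self.height_px <= 2 * self.margin_px:
            raise GeometryError(
                "margin too large: usable area "
                f"({self.width_px}-2*{self.margin_px}) x "
                f"({self.height_px}-2*{self.margin_px}) must be positive"
            )

    @property
    def area(self) -> float:
        """Full screen area in px^2 (support of the uniform guess component)."""
        return self.width_px * self.height_px

    @property
    def usable_width(self) -> float:
        return self.width_px - 2 * self.margin_px

    @property
    def usable_height(self) -> float:
        return self.height_px - 2 * self.margin_px

    def contains(self, xy: Sequence[float]) -> bool:
        x, y = float(xy[0]), float(xy[1])
        return 0.0 <= x <= self.width_px and 0.0 <= y <= self.height_px

    def item_bounds(self) -> Tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the margin-inset item rectangle."""
        return (
            self.margin_px,
            self.width_px - self.margin_px,
            self.margin_px,
            self.height_px - self.margin_px,
        )


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass
class OMTTrial:
    """One task trial.

    ``condition`` is the number of items in the memory array (1 or 2);
    two-item trials carry exactly one non-target location.
    """

    subject_id: str
    session_week: int
    trial_index: int
    condition: int
    target_xy: XY
    nontarget_xy: Tuple[XY, ...]
    identified_correct: bool
    response_xy: XY
    identification_time_ms: float
    localization_time_ms: float

    def __post_init__(self) -> None:
        self.target_xy = (float(self.target_xy[0]), float(self.target_xy[1]))
        self.nontarget_xy = tuple(
            (float(p[0]), float(p[1])) for p in self.nontarget_xy
        )
        self.response_xy = (float(self.response_xy[0]), float(self.response_xy[1]))
        self.identified_correct = bool(self.identified_correct)

    def problems(self, screen: Optional[ScreenGeometry] = None) -> list[str]:
        """Invariant violations for this record (empty list if valid)."""
        out: list[str] = []
        if self.session_week not in WEEKS:
            out.append(f"session_week {self.session_week} not in {WEEKS}")
        if self.condition not in (1, 2):
            out.append(f"condition {self.condition} not in (1, 2)")
        if self.condition == 1 and self.nontarget_xy:
            out.append("condition=1 trial carries a nontarget coordinate")
        if self.condition == 2 and len(self.nontarget_xy) != 1:
            out.append("condition=2 trial must carry exactly one nontarget")
        if self.identification_time_ms <= 0:
            out.append("identification_time_ms must be > 0")
        if self.localization_time_ms <= 0:
            out.append("localization_time_ms must be > 0")
        if screen is not None:
            for name, xy in (
                ("target_xy", self.target_xy),
                ("response_xy", self.response_xy),
                *((f"nontarget_xy[{i}]", p) for i, p in enumerate(self.nontarget_xy)),
            ):
                if not screen.contains(xy):
                    out.append(f"{name} {xy} outside screen bounds")
        return out


@dataclass(frozen=True)
class Assignment:
    """Randomization assignment of one subject to a crossover sequence."""

    subject_id: str
    sequence: str

    def __post_init__(self) -> None:
        if self.sequence not in SEQUENCES:
            raise DataValidationError(
                f"unknown sequence {self.sequence!r}; expected one of {SEQUENCES}"
            )

    @property
    def drug_by_session(self) -> Mapping[int, int]:
        """Session -> drug label; the two sessions carry opposite labels."""
        return DRUG_BY_SEQUENCE[self.sequence]

    def drug_at_week(self, week: int) -> int:
        return self.drug_by_session[SESSION_OF_WEEK[week]]


@dataclass(frozen=True)
class QuestionnaireRecord:
    subject_id: str
    instrument: str
    respondent: str
    week: int
    score: float

    def problems(self) -> list[str]:
        out: list[str] = []
        if (self.instrument, self.respondent) not in INSTRUMENT_RESPONDENTS:
            out.append(
                f"unknown instrument/respondent pair "
                f"({self.instrument}, {self.respondent})"
            )
        if self.week not in WEEKS:
            out.append(f"week {self.week} not in {WEEKS}")
        return out


@dataclass(frozen=True)
class AdverseEventRecord:
    subject_id: str
    arm: str  # "active" | "placebo"
    term: str
    n_instances: int

    def problems(self) -> list[str]:
        out: list[str] = []
        if self.arm not in ("active", "placebo"):
            out.append(f"arm {self.arm!r} not in ('active', 'placebo')")
        if self.n_instances < 0:
            out.append("n_instances must be >= 0")
        return out


@dataclass(frozen=True)
class Demographics:
    subject_id: str
    age_years: float
    sex: str  # "M" | "F"
    baseline_mmse: int

    def problems(self) -> list[str]:
        out: list[str] = []
        if self.age_years <= 0:
            out.append("age_years must be positive")
        if self.sex not in ("M", "F"):
            out.append(f"sex {self.sex!r} not in ('M', 'F')")
        if not 0 <= self.baseline_mmse <= 30:
            out.append(f"baseline_mmse {self.baseline_mmse} outside 0..30")
        return out


# ---------------------------------------------------------------------------
# Dataset container and validation
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """A full trial dataset: every record kind, in memory."""

    trials: list[OMTTrial] = field(default_factory=list)
    questionnaires: list[QuestionnaireRecord] = field(default_factory=list)
    adverse_events: list[AdverseEventRecord] = field(default_factory=list)
    demographics: list[Demographics] = field(default_factory=list)
    assignments: list[Assignment] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {
            "trials": len(self.trials),
            "questionnaires": len(self.questionnaires),
            "adverse_events": len(self.adverse_events),
            "demographics": len(self.demographics),
            "assignments": len(self.assignments),
        }

    @property
    def subject_ids(self) -> list[str]:
        return sorted({a.subject_id for a in self.assignments})

    def assignment_for(self, subject_id: str) -> Assignment:
        for a in self.assignments:
            if a.subject_id == subject_id:
                return a
        raise MappingError(f"subject {subject_id!r} has no assignment")


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_dataset`; never raises, always reports."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors

    def summary(self) -> str:
        lines = [f"{k}: {v}" for k, v in sorted(self.counts.items())]
        lines.append(f"errors: {len(self.errors)}; warnings: {len(self.warnings)}")
        return "\n".join(lines)


def validate_dataset(
    dataset: Dataset,
    screen: Optional[ScreenGeometry] = None,
    weeks: Iterable[int] = WEEKS,
) -> ValidationReport:
    """Check every record invariant and the per-subject assessment schedule.

    Validation is total: any input produces a report, with every rejected
    record identified by kind and index. Completeness against the week
    0/8/12/20 schedule is reported as warnings (mirroring real trials, where
    missed visits are data features, not file corruption).
    """
    report = ValidationReport(counts=dataset.counts())
    weeks = tuple(weeks)
    assigned = {a.subject_id for a in dataset.assignments}

    for i, t in enumerate(dataset.trials):
        for p in t.problems(screen):
            report.errors.append(f"trials[{i}] ({t.subject_id}, wk{t.session_week}): {p}")
        if assigned and t.subject_id not in assigned:
            report.errors.append(f"trials[{i}]: subject {t.subject_id!r} has no assignment")

    seen_q: set[tuple] = set()
    for i, q in enumerate(dataset.questionnaires):
        for p in q.problems():
            report.errors.append(f"questionnaires[{i}] ({q.subject_id}): {p}")
        key = (q.subject_id, q.instrument, q.respondent, q.week)
        if key in seen_q:
            report.errors.append(f"questionnaires[{i}]: duplicate record {key}")
        seen_q.add(key)

    for i, a in enumerate(dataset.adverse_events):
        for p in a.problems():
            report.errors.append(f"adverse_events[{i}] ({a.subject_id}): {p}")

    for i, d in enumerate(dataset.demographics):
        for p in d.problems():
            report.errors.append(f"demographics[{i}] ({d.subject_id}): {p}")

    # Per-subject completeness against the assessment schedule.
    trial_weeks: dict[str, set[int]] = {}
    for t in dataset.trials:
        trial_weeks.setdefault(t.subject_id, set()).add(t.session_week)
    for sid in sorted(assigned or trial_weeks.keys()):
        missing = [w for w in weeks if w not in trial_weeks.get(sid, set())]
        if missing and trial_weeks.get(sid):
            report.warnings.append(
                f"subject {sid}: no OMT trials at week(s) {missing}"
            )
        elif sid not in trial_weeks:
            report.warnings.append(f"subject {sid}: no OMT trials at all")
    q_weeks: dict[tuple, set[int]] = {}
    for q in dataset.questionnaires:
        q_weeks.setdefault((q.subject_id, q.instrument, q.respondent), set()).add(q.week)
    for key, have in sorted(q_weeks.items()):
        missing = [w for w in weeks if w not in have]
        if missing:
            report.warnings.append(
                f"questionnaire {key}: missing week(s) {missing}"
            )
    return report
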