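"""Synthetic crossover cohorts with known ground truth.

Everything downstream — metrics, mixture fitting, the permutation null and
the trial statistics — is validated against data generated here, because the
real trial deposits no raw data. The generator emulates the study structure:
two crossover sequences (active-first n=5, placebo-first n=3 by default),
assessments at weeks 0/8/12/20, 20 task trials per assessment mixing one- and
two-item displays, mixture-distributed localization responses, log-normal
response times, questionnaire scores per instrument/respondent, and
per-arm Poisson adverse-event counts.

Drug effects are applied at the end-of-arm assessments (weeks 8 and 20) of
sessions whose assigned label is active; the within-arm baselines (weeks 0
and 12) precede titration or follow washout and are generated drug-free.
Identification-time shifts follow the linear predictor
``session_shift*s + drug_shift*d + interaction_shift*s*d`` with session coded
1/2 and drug 0/1, matching the mixed model's coding, and are additive on the
whole response-time distribution (hence on its median).

Every latent quantity used is recorded in the ground-truth ledger
(per-subject parameters plus per-trial mixture component labels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datamodel import (
    AdverseEventRecord,
    Assignment,
    ConfigError,
    Dataset,
    Demographics,
    END_OF_ARM_WEEKS,
    GeometryError,
    LEV_FIRST,
    OMTTrial,
    ParameterError,
    PBO_FIRST,
    QuestionnaireRecord,
    SESSION_OF_WEEK,
    ScreenGeometry,
    WEEKS,
)
from .io import default_path_map, write_dataset, FLOAT_FMT
from .mixture import MixtureParams

REJECTION_CAP = 10_000

#: Adverse-event vocabulary with sampling weights (most frequent first).
AE_TERMS: Tuple[Tuple[str, float], ...] = (
    ("headache", 11.0),
    ("fatigue", 3.0),
    ("dizziness", 3.0),
    ("somnolence", 3.0),
    ("irritability", 3.0),
    ("word finding difficulty", 2.0),
    ("nausea", 2.0),
    ("low mood", 2.0),
)


def _round6(x: float) -> float:
    return round(float(x), 6)


@dataclass(frozen=True)
class InstrumentSpec:
    """Population model of one questionnaire series.

    ``drug_effect`` is the additive score shift at end-of-arm assessments of
    active sessions (0 under the null)."""

    instrument: str
    respondent: str
    mean: float
    between_sd: float
    noise_sd: float
    drug_effect: float = 0.0


DEFAULT_INSTRUMENTS: Tuple[InstrumentSpec, ...] = (
    InstrumentSpec("MMSE", "patient", 17.7, 4.5, 1.5),
    InstrumentSpec("BADLS", "caregiver", 22.0, 8.0, 2.5),
    InstrumentSpec("DSRS", "caregiver", 21.0, 9.0, 2.0),
    InstrumentSpec("NPI", "caregiver", 12.0, 8.0, 3.0),
    InstrumentSpec("EQ5D", "patient", 0.70, 0.15, 0.05),
    InstrumentSpec("EQ5D", "caregiver", 0.80, 0.12, 0.05),
    InstrumentSpec("EQ5D", "proxy", 0.65, 0.15, 0.05),
    InstrumentSpec("QoL", "patient", 35.0, 6.0, 2.0),
    InstrumentSpec("QoL", "caregiver", 36.0, 6.0, 2.0),
)


@dataclass(frozen=True)
class DrugEffects:
    """Additive drug effects on the latent scales (all zero = null trial)."""

    logit_p_target: float = 0.0
    logit_p_misbind: float = 0.0
    log_sigma: float = 0.0
    logit_p_ident: float = 0.0
    identification_time_ms: float = 0.0  # beta_2: additive on the time median
    session_x_time_ms: float = 0.0       # beta_3: session x drug interaction
    localization_time_ms: float = 0.0


@dataclass
class CohortConfig:
    """Study conditions of the simulated cohort.

    Defaults reproduce the trial's structure: 8 subjects allocated 5:3
    (active-first : placebo-first), 20 trials per session split 10/10 between
    one- and two-item displays on a 1024x768 screen with a 100 px item
    margin, and zero drug effects (the null)."""

    n_subjects: int = 8
    allocation: dict = field(
        default_factory=lambda: {LEV_FIRST: 5, PBO_FIRST: 3}
    )
    n_trials_per_session: int = 20
    n_one_item: int = 10
    n_two_item: int = 10
    screen: ScreenGeometry = field(default_factory=ScreenGeometry)
    min_item_separation_px: float = 150.0
    # population mixture (two-item condition)
    p_target_mean: float = 0.60
    p_misbind_mean: float = 0.20
    mixture_logit_sd: float = 0.40
    sigma_mean_px: float = 50.0
    log_sigma_sd: float = 0.20
    # identification accuracy
    p_ident_mean: float = 0.75
    p_ident_logit_sd: float = 0.50
    # response times (log-normal)
    id_time_median_ms: float = 6000.0
    id_time_log_sd: float = 0.40
    id_time_between_log_sd: float = 0.25
    loc_time_median_ms: float = 4000.0
    loc_time_log_sd: float = 0.40
    loc_time_between_log_sd: float = 0.25
    session_time_shift_ms: float = 0.0  # beta_1: fixed session effect
    drug_effects: DrugEffects = field(default_factory=DrugEffects)
    # secondary outcomes
    instruments: Tuple[InstrumentSpec, ...] = DEFAULT_INSTRUMENTS
    ae_rate_active: float = 2.2
    ae_rate_placebo: float = 2.2
    # demographics
    age_mean: float = 68.4
    age_sd: float = 9.2
    p_female: float = 0.625
    # behaviour switches
    misbinding_requires_correct_id: bool = True
    missing_session_mask: Tuple[Tuple[str, int], ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if sum(self.allocation.values()) != self.n_subjects:
            raise ConfigError(
                f"allocation {self.allocation} does not sum to n_subjects="
                f"{self.n_subjects}"
            )
        if any(k not in (LEV_FIRST, PBO_FIRST) for k in self.allocation):
            raise ConfigError(f"unknown sequence key in allocation {self.allocation}")
        if self.n_trials_per_session <= 0:
            raise ConfigError("n_trials_per_session must be > 0")
        if self.n_one_item + self.n_two_item != self.n_trials_per_session:
            raise ConfigError("n_one_item + n_two_item must equal n_trials_per_session")
        usable = min(self.screen.usable_width, self.screen.usable_height)
        if self.min_item_separation_px >= math.hypot(
            self.screen.usable_width, self.screen.usable_height
        ):
            raise ConfigError(
                f"min_item_separation_px={self.min_item_separation_px} exceeds the "
                f"usable screen diagonal"
            )
        if usable <= 0:
            raise ConfigError("screen has no usable area")


@dataclass
class SubjectProfile:
    """Ground-truth latent parameters of one simulated subject."""

    subject_id: str
    sequence: str
    baseline_mixture: MixtureParams
    drug_effect: DrugEffects
    p_ident: float
    id_time_median_ms: float
    id_time_log_sd: float
    loc_time_median_ms: float
    loc_time_log_sd: float
    session_time_shift_ms: float
    questionnaire_baselines: dict
    ae_rate_active: float
    ae_rate_placebo: float
    age_years: float
    sex: str


@dataclass
class CohortData:
    """Generated dataset plus its ground truth."""

    dataset: Dataset
    profiles: list[SubjectProfile]
    ground_truth: pd.DataFrame
    trial_truth: pd.DataFrame
    config: CohortConfig

    def write(self, directory: Union[str, Path]) -> None:
        directory = Path(directory)
        write_dataset(self.dataset, default_path_map(directory))
        self.ground_truth.to_csv(
            directory / "ground_truth.csv", index=False, float_format=FLOAT_FMT,
            lineterminator="\n",
        )
        self.trial_truth.to_csv(
            directory / "trial_truth.csv", index=False, float_format=FLOAT_FMT,
            lineterminator="\n",
        )


# ---------------------------------------------------------------------------
# Sampling primitives
# ---------------------------------------------------------------------------


def sample_item_locations(
    n_items: int,
    screen: ScreenGeometry,
    min_sep: float,
    rng: np.random.Generator,
) -> list[Tuple[float, float]]:
    """Uniform item locations on the margin-inset rectangle, redrawn until the
    pairwise distance reaches ``min_sep`` (rejection cap 10,000 draws)."""
    if n_items not in (1, 2):
        raise ParameterError("n_items must be 1 or 2")
    xmin, xmax, ymin, ymax = screen.item_bounds()
    for _ in range(REJECTION_CAP):
        pts = np.column_stack(
            [rng.uniform(xmin, xmax, size=n_items), rng.uniform(ymin, ymax, size=n_items)]
        )
        if n_items == 1 or np.hypot(*(pts[0] - pts[1])) >= min_sep:
            return [(_round6(x), _round6(y)) for x, y in pts]
    raise GeometryError(
        f"could not place {n_items} items min_sep={min_sep} within "
        f"{REJECTION_CAP} draws; min_sep too large for this screen"
    )


def _truncated_normal_point(
    center: Sequence[float], sigma: float, screen: ScreenGeometry,
    rng: np.random.Generator,
) -> Tuple[float, float]:
    """Normal draw truncated to the screen by redraw (not clipping)."""
    cx, cy = float(center[0]), float(center[1])
    for _ in range(REJECTION_CAP):
        x = rng.normal(cx, sigma)
        y = rng.normal(cy, sigma)
        if screen.contains((x, y)):
            return (x, y)
    raise GeometryError("truncated normal redraw cap exceeded (center off-screen?)")


def sample_response(
    params: MixtureParams,
    target_xy: Sequence[float],
    nontarget_xy: Optional[Sequence[Sequence[float]]],
    screen: ScreenGeometry,
    rng: np.random.Generator,
    p_ident: float = 1.0,
    misbinding_requires_correct_id: bool = True,
) -> Tuple[bool, Tuple[float, float], str]:
    """Draw one trial's (identified_correct, response location, component).

    Identification is Bernoulli(p_ident). The response component is drawn
    with probabilities (p_target, p_misbind, p_guess); target and non-target
    components are isotropic normals (SD sigma) truncated to the screen by
    redraw, guesses uniform over the full screen. With
    ``misbinding_requires_correct_id`` (default), incorrectly identified
    trials redistribute the swap mass over target and guess components.
    """
    nontargets = list(nontarget_xy or [])
    if params.p_misbind > 0 and not nontargets:
        raise ParameterError("p_misbind > 0 requires a nontarget location")
    correct = bool(rng.random() < p_ident)
    w = np.array([params.p_target, params.p_misbind, params.p_guess])
    if not nontargets or (misbinding_requires_correct_id and not correct):
        w = np.array([params.p_target, 0.0, params.p_guess])
        if w.sum() <= 0:
            raise ParameterError("degenerate weights after removing swap component")
    w = w / w.sum()
    comp = ("target", "nontarget", "guess")[int(rng.choice(3, p=w))]
    if comp == "target":
        xy = _truncated_normal_point(target_xy, params.sigma_px, screen, rng)
    elif comp == "nontarget":
        xy = _truncated_normal_point(nontargets[0], params.sigma_px, screen, rng)
    else:
        xy = (rng.uniform(0.0, screen.width_px), rng.uniform(0.0, screen.height_px))
    return correct, (_round6(xy[0]), _round6(xy[1])), comp


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _clip_simplex(p_t: float, p_n: float, cap: float = 0.98) -> Tuple[float, float, float]:
    """Project (p_target, p_misbind) so the triple stays on the simplex with a
    strictly positive guess weight."""
    s = p_t + p_n
    if s > cap:
        p_t, p_n = p_t * cap / s, p_n * cap / s
    return p_t, p_n, 1.0 - p_t - p_n


def _subject_profile(
    sid: str, sequence: str, cfg: CohortConfig, rng: np.random.Generator
) -> SubjectProfile:
    a_t = logit(cfg.p_target_mean) + rng.normal(0.0, cfg.mixture_logit_sd)
    a_n = logit(cfg.p_misbind_mean) + rng.normal(0.0, cfg.mixture_logit_sd)
    p_t, p_n, p_u = _clip_simplex(float(expit(a_t)), float(expit(a_n)))
    sigma = cfg.sigma_mean_px * math.exp(rng.normal(0.0, cfg.log_sigma_sd))
    baselines = {
        (s.instrument, s.respondent): s.mean + rng.normal(0.0, s.between_sd)
        for s in cfg.instruments
    }
    return SubjectProfile(
        subject_id=sid,
        sequence=sequence,
        baseline_mixture=MixtureParams(p_t, p_n, p_u, sigma),
        drug_effect=cfg.drug_effects,
        p_ident=float(expit(logit(cfg.p_ident_mean) + rng.normal(0.0, cfg.p_ident_logit_sd))),
        id_time_median_ms=cfg.id_time_median_ms
        * math.exp(rng.normal(0.0, cfg.id_time_between_log_sd)),
        id_time_log_sd=cfg.id_time_log_sd,
        loc_time_median_ms=cfg.loc_time_median_ms
        * math.exp(rng.normal(0.0, cfg.loc_time_between_log_sd)),
        loc_time_log_sd=cfg.loc_time_log_sd,
        session_time_shift_ms=cfg.session_time_shift_ms,
        questionnaire_baselines=baselines,
        ae_rate_active=cfg.ae_rate_active,
        ae_rate_placebo=cfg.ae_rate_placebo,
        age_years=max(50.5, cfg.age_mean + rng.normal(0.0, cfg.age_sd)),
        sex="F" if rng.random() < cfg.p_female else "M",
    )


def _effective_mixture(profile: SubjectProfile, on_drug: bool) -> MixtureParams:
    base = profile.baseline_mixture
    if not on_drug:
        return base
    eff = profile.drug_effect
    a_t = logit(base.p_target) + eff.logit_p_target
    a_n = logit(base.p_misbind) + eff.logit_p_misbind
    p_t, p_n, p_u = _clip_simplex(float(expit(a_t)), float(expit(a_n)))
    return MixtureParams(p_t, p_n, p_u, base.sigma_px * math.exp(eff.log_sigma))


def _one_item_params(mix: MixtureParams) -> MixtureParams:
    """One-item displays admit no swap: renormalize (target, guess)."""
    s = mix.p_target + mix.p_guess
    return MixtureParams(mix.p_target / s, 0.0, mix.p_guess / s, mix.sigma_px)


def _effective_p_ident(profile: SubjectProfile, on_drug: bool) -> float:
    if not on_drug:
        return profile.p_ident
    return float(expit(logit(profile.p_ident) + profile.drug_effect.logit_p_ident))


def generate_cohort(config: CohortConfig, include_trials: bool = True) -> CohortData:
    """Generate a full crossover cohort, deterministic given ``config.seed``.

    One RNG stream per subject is spawned from the master seed, so cohorts
    are reproducible under subject-parallel generation. ``include_trials``
    can be switched off when only questionnaires/adverse events are needed
    (e.g. large secondary-outcome simulations).
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)
    alloc_rng = np.random.default_rng(master.spawn(1)[0])
    sequences = [LEV_FIRST] * config.allocation.get(LEV_FIRST, 0) + [
        PBO_FIRST
    ] * config.allocation.get(PBO_FIRST, 0)
    sequences = list(alloc_rng.permutation(sequences))
    width = max(2, len(str(config.n_subjects)))
    subject_ids = [f"S{i + 1:0{width}d}" for i in range(config.n_subjects)]
    subject_seeds = master.spawn(config.n_subjects)

    ds = Dataset()
    profiles: list[SubjectProfile] = []
    truth_rows = []
    trial_truth_rows = []
    missing = set(config.missing_session_mask)

    for sid, seq, sseed in zip(subject_ids, sequences, subject_seeds):
        rng = np.random.default_rng(sseed)
        profile = _subject_profile(sid, seq, config, rng)
        profiles.append(profile)
        assignment = Assignment(sid, seq)
        ds.assignments.append(assignment)

        # --- task trials -------------------------------------------------
        if include_trials:
            for week in WEEKS:
                if (sid, week) in missing:
                    continue
                session = SESSION_OF_WEEK[week]
                d = assignment.drug_by_session[session]
                end_of_arm = week in END_OF_ARM_WEEKS
                on_drug = bool(d == 1 and end_of_arm)
                mix = _effective_mixture(profile, on_drug)
                p_ident = _effective_p_ident(profile, on_drug)
                time_shift = 0.0
                if end_of_arm:
                    time_shift = (
                        profile.session_time_shift_ms * session
                        + profile.drug_effect.identification_time_ms * d
                        + profile.drug_effect.session_x_time_ms * session * d
                    )
                loc_shift = profile.drug_effect.localization_time_ms * d if end_of_arm else 0.0
                conditions = rng.permutation(
                    [1] * config.n_one_item + [2] * config.n_two_item
                )
                for idx, cond in enumerate(conditions):
                    pts = sample_item_locations(
                        int(cond), config.screen, config.min_item_separation_px, rng
                    )
                    target, nontargets = pts[0], pts[1:]
                    trial_mix = mix if cond == 2 else _one_item_params(mix)
                    correct, resp, comp = sample_response(
                        trial_mix, target, nontargets, config.screen, rng,
                        p_ident=p_ident,
                        misbinding_requires_correct_id=config.misbinding_requires_correct_id,
                    )
                    id_t = profile.id_time_median_ms * math.exp(
                        rng.normal(0.0, profile.id_time_log_sd)
                    ) + time_shift
                    loc_t = profile.loc_time_median_ms * math.exp(
                        rng.normal(0.0, profile.loc_time_log_sd)
                    ) + loc_shift
                    ds.trials.append(
                        OMTTrial(
                            subject_id=sid,
                            session_week=week,
                            trial_index=idx,
                            condition=int(cond),
                            target_xy=target,
                            nontarget_xy=tuple(nontargets),
                            identified_correct=correct,
                            response_xy=resp,
                            identification_time_ms=_round6(max(id_t, 1.0)),
                            localization_time_ms=_round6(max(loc_t, 1.0)),
                        )
                    )
                    trial_truth_rows.append(
                        {
                            "subject_id": sid,
                            "session_week": week,
                            "trial_index": idx,
                            "condition": int(cond),
                            "component": comp,
                            "on_drug": int(on_drug),
                            "p_target": trial_mix.p_target,
                            "p_misbind": trial_mix.p_misbind,
                            "p_guess": trial_mix.p_guess,
                            "sigma_px": trial_mix.sigma_px,
                            "p_ident": p_ident,
                        }
                    )

        # --- questionnaires ----------------------------------------------
        for spec in config.instruments:
            base = profile.questionnaire_baselines[(spec.instrument, spec.respondent)]
            for week in WEEKS:
                session = SESSION_OF_WEEK[week]
                d = assignment.drug_by_session[session]
                shift = spec.drug_effect * d if week in END_OF_ARM_WEEKS else 0.0
                score = base + rng.normal(0.0, spec.noise_sd) + shift
                ds.questionnaires.append(
                    QuestionnaireRecord(
                        sid, spec.instrument, spec.respondent, week, _round6(score)
                    )
                )

        # --- adverse events ----------------------------------------------
        terms = [t for t, _ in AE_TERMS]
        weights = np.array([w for _, w in AE_TERMS])
        weights = weights / weights.sum()
        for arm, rate in (("active", profile.ae_rate_active),
                          ("placebo", profile.ae_rate_placebo)):
            total = int(rng.poisson(rate))
            if total > 0:
                counts = rng.multinomial(total, weights)
                for term, c in zip(terms, counts):
                    if c > 0:
                        ds.adverse_events.append(
                            AdverseEventRecord(sid, arm, term, int(c))
                        )

        # --- demographics -------------------------------------------------
        mmse_baseline = next(
            q.score
            for q in ds.questionnaires
            if q.subject_id == sid and q.instrument == "MMSE" and q.week == 0
        )
        ds.demographics.append(
            Demographics(
                sid,
                _round6(profile.age_years),
                profile.sex,
                int(np.clip(round(mmse_baseline), 0, 30)),
            )
        )

        row = {
            "subject_id": sid,
            "sequence": seq,
            "p_target": profile.baseline_mixture.p_target,
            "p_misbind": profile.baseline_mixture.p_misbind,
            "p_guess": profile.baseline_mixture.p_guess,
            "sigma_px": profile.baseline_mixture.sigma_px,
            "p_ident": profile.p_ident,
            "id_time_median_ms": profile.id_time_median_ms,
            "id_time_log_sd": profile.id_time_log_sd,
            "loc_time_median_ms": profile.loc_time_median_ms,
            "loc_time_log_sd": profile.loc_time_log_sd,
            "session_time_shift_ms": profile.session_time_shift_ms,
            "drug_logit_p_target": profile.drug_effect.logit_p_target,
            "drug_logit_p_misbind": profile.drug_effect.logit_p_misbind,
            "drug_log_sigma": profile.drug_effect.log_sigma,
            "drug_logit_p_ident": profile.drug_effect.logit_p_ident,
            "drug_identification_time_ms": profile.drug_effect.identification_time_ms,
            "drug_session_x_time_ms": profile.drug_effect.session_x_time_ms,
            "drug_localization_time_ms": profile.drug_effect.localization_time_ms,
            "ae_rate_active": profile.ae_rate_active,
            "ae_rate_placebo": profile.ae_rate_placebo,
            "age_years": profile.age_years,
            "sex": profile.sex,
        }
        for (instr, resp), v in sorted(profile.questionnaire_baselines.items()):
            row[f"q_{instr}_{resp}"] = v
        truth_rows.append(row)

    return CohortData(
        dataset=ds,
        profiles=profiles,
        ground_truth=pd.DataFrame(truth_rows),
        trial_truth=pd.DataFrame(trial_truth_rows),
        config=config,
    )


def null_config(**overrides) -> CohortConfig:
    """Study-sized cohort with all drug effects zero (the simulation null)."""
    return replace(CohortConfig(), **overrides) if overrides else CohortConfig()
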