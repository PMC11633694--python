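"""The trial's statistical plan.

Change scores compare the end of each crossover arm to that arm's own
baseline (week 8 - week 0; week 20 - week 12). Questionnaire measures are
compared between arms with a paired t-test or Wilcoxon signed-rank test,
gated on Shapiro-Wilk normality of the paired differences. Baseline group
comparisons use a two-sample t / Mann-Whitney U (continuous, same gate) or
chi-square (categorical). The computerized task metrics are analysed at trial
level with a within-subject random-intercept linear mixed model

    value ~ 1 + session * drug + (1 | subject)

fitted by maximum likelihood (REML switch available), with Wald t = beta/SE
referenced against the standard normal by default. Multiplicity is corrected
with Bonferroni (Holm available) over an explicit family. Adverse events are
summarised per arm and compared with a paired t-test on per-subject counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from scipy.special import ndtr
from statsmodels.stats.multitest import multipletests

from .datamodel import (
    AdverseEventRecord,
    Assignment,
    Dataset,
    EmptyDataError,
    OUTCOME_NAMES,
    ParameterError,
    QuestionnaireRecord,
    ScreenGeometry,
    SmallSampleError,
)
from .metrics import LongOutcomeTable, build_long_table
from . import mixture as mixmod

LMM_TERMS = ("intercept", "session", "drug", "session_x_drug")


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChangeScore:
    subject_id: str
    instrument: str
    respondent: str
    session: int
    arm_drug: int  # 0 placebo / 1 active during that session
    delta: float   # end-of-arm score minus that arm's baseline


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    n: int
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    normality_p: Optional[float] = None
    note: Optional[str] = None


@dataclass(frozen=True)
class WaldTerm:
    coefficient: float
    standard_error: float
    t_value: float
    p_value: float


@dataclass
class LMMResult:
    terms: dict[str, WaldTerm]
    sigma2_subject: float
    sigma2_residual: float
    n_obs: int
    n_subjects: int
    converged: bool
    method: str  # "ML" | "REML"
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": name,
                    "coefficient": t.coefficient,
                    "standard_error": t.standard_error,
                    "t_value": t.t_value,
                    "p_value": t.p_value,
                }
                for name, t in self.terms.items()
            ]
        )


@dataclass(frozen=True)
class PlannedRecruitment:
    powered_n: int
    attrition_rate: float
    planned_n: int


@dataclass
class GateResult:
    normal: bool
    p_value: Optional[float]
    note: Optional[str] = None


@dataclass
class AESummary:
    arm_totals: dict[str, int]
    term_totals: dict[str, int]
    grand_total: int
    per_subject: pd.DataFrame  # columns: subject_id, active, placebo
    test: TestResult
    excluded: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Small worked-example arithmetic
# ---------------------------------------------------------------------------


def wald_summary(coefficient: float, standard_error: float,
                 df: Optional[float] = None) -> Tuple[float, float]:
    """Wald t = coefficient/SE and its two-sided p.

    Normal reference by default; pass ``df`` for a Student-t reference.
    """
    if standard_error <= 0:
        raise ParameterError("standard_error must be > 0")
    t = coefficient / standard_error
    if df is None:
        p = 2.0 * (1.0 - float(ndtr(abs(t))))
    else:
        p = 2.0 * float(st.t.sf(abs(t), df))
    return float(t), min(p, 1.0)


def pooled_mean(
    group_means: Sequence[float],
    group_ns: Sequence[int],
    group_sds: Optional[Sequence[float]] = None,
) -> Union[float, Tuple[float, float]]:
    """Size-weighted pooled mean; with ``group_sds`` also the pooled SD via
    the within + between variance decomposition."""
    if len(group_means) != len(group_ns) or (
        group_sds is not None and len(group_sds) != len(group_means)
    ):
        raise ParameterError("group_means/group_ns/group_sds lengths must match")
    if any(n < 1 for n in group_ns):
        raise ParameterError("all group sizes must be >= 1")
    ns = np.asarray(group_ns, float)
    ms = np.asarray(group_means, float)
    total = ns.sum()
    mean = float((ns * ms).sum() / total)
    if group_sds is None:
        return mean
    sds = np.asarray(group_sds, float)
    ss_within = ((ns - 1) * sds**2).sum()
    ss_between = (ns * (ms - mean) ** 2).sum()
    sd = float(math.sqrt((ss_within + ss_between) / (total - 1)))
    return mean, sd


def planned_recruitment(powered_n: int, attrition_rate: float) -> PlannedRecruitment:
    """Recruitment target inflating the powered sample for attrition."""
    if not 0.0 <= attrition_rate < 1.0:
        raise ParameterError("attrition_rate must be in [0, 1)")
    planned = math.ceil(powered_n / (1.0 - attrition_rate))
    return PlannedRecruitment(powered_n, attrition_rate, planned)


def adjust_multiplicity(
    p_values: Sequence[float], method: str = "bonferroni", alpha: float = 0.05
) -> Tuple[np.ndarray, np.ndarray]:
    """Adjusted p-values and alpha-level significance flags.

    Bonferroni by default (adj = min(1, m*p)); ``method='holm'`` for the
    step-down variant.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ParameterError("p_values must be non-empty")
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p_values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method=method)
    return adjusted, reject


# ---------------------------------------------------------------------------
# Change scores and paired comparisons
# ---------------------------------------------------------------------------


def change_scores(
    questionnaires: Iterable[QuestionnaireRecord],
    assignments: Iterable[Assignment],
) -> Tuple[list[ChangeScore], list[str]]:
    """End-of-arm minus within-arm-baseline deltas, one per
    subject x instrument x respondent x session; missing weeks are listed as
    exclusions, never silently dropped."""
    amap = {a.subject_id: a for a in assignments}
    scores: dict[tuple, float] = {}
    for q in questionnaires:
        scores[(q.subject_id, q.instrument, q.respondent, q.week)] = q.score
    keys = sorted({(k[0], k[1], k[2]) for k in scores})
    out: list[ChangeScore] = []
    excluded: list[str] = []
    for sid, instr, resp in keys:
        if sid not in amap:
            excluded.append(f"{sid}/{instr}/{resp}: no assignment")
            continue
        for session, (w_base, w_end) in ((1, (0, 8)), (2, (12, 20))):
            base = scores.get((sid, instr, resp, w_base))
            end = scores.get((sid, instr, resp, w_end))
            if base is None or end is None:
                excluded.append(
                    f"{sid}/{instr}/{resp}: missing week "
                    f"{w_base if base is None else w_end}"
                )
                continue
            out.append(
                ChangeScore(
                    subject_id=sid,
                    instrument=instr,
                    respondent=resp,
                    session=session,
                    arm_drug=amap[sid].drug_by_session[session],
                    delta=end - base,
                )
            )
    return out, excluded


def normality_gate(
    paired_differences: Sequence[float], alpha: float = 0.05
) -> GateResult:
    """Shapiro-Wilk gate: normal iff p >= alpha. Constant differences are
    routed to the non-normal (rank) branch with a note."""
    d = np.asarray(paired_differences, float)
    if d.size < 3:
        raise SmallSampleError("normality gate needs n >= 3 differences")
    if np.allclose(d, d[0]):
        return GateResult(normal=False, p_value=None, note="constant differences")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat_p = st.shapiro(d).pvalue
    return GateResult(normal=bool(stat_p >= alpha), p_value=float(stat_p))


def _paired_t_ci(diffs: np.ndarray, conf: float = 0.95) -> Tuple[float, float]:
    n = diffs.size
    m = diffs.mean()
    se = diffs.std(ddof=1) / math.sqrt(n)
    half = st.t.ppf(0.5 + conf / 2, n - 1) * se
    return float(m - half), float(m + half)


def compare_change_between_arms(
    active_deltas: Sequence[float],
    placebo_deltas: Sequence[float],
    alpha: float = 0.05,
) -> TestResult:
    """Within-subject comparison of active vs placebo change scores.

    Inputs are paired by subject. Paired t (with 95% CI) if the differences
    pass the normality gate, Wilcoxon signed-rank otherwise. All-zero
    differences return the degenerate null result (p = 1) with a note.
    """
    a = np.asarray(active_deltas, float)
    p = np.asarray(placebo_deltas, float)
    if a.size != p.size:
        raise ParameterError("active/placebo deltas must be paired (equal length)")
    if a.size < 3:
        raise SmallSampleError("paired comparison needs >= 3 subjects")
    diffs = a - p
    if np.allclose(diffs, 0.0):
        return TestResult(
            method="wilcoxon_signed_rank", statistic=0.0, p_value=1.0,
            n=a.size, note="degenerate: all paired differences are zero",
        )
    gate = normality_gate(diffs, alpha=alpha)
    if gate.normal:
        res = st.ttest_rel(a, p)
        lo, hi = _paired_t_ci(diffs)
        return TestResult(
            method="paired_t", statistic=float(res.statistic),
            p_value=float(res.pvalue), n=a.size, ci_low=lo, ci_high=hi,
            normality_p=gate.p_value,
        )
    res = st.wilcoxon(a, p)
    return TestResult(
        method="wilcoxon_signed_rank", statistic=float(res.statistic),
        p_value=float(res.pvalue), n=a.size, normality_p=gate.p_value,
        note=gate.note,
    )


def compare_baseline_groups(
    values: Union[Sequence[float], np.ndarray, pd.DataFrame],
    group_labels: Optional[Sequence] = None,
    categorical: bool = False,
    alpha: float = 0.05,
) -> TestResult:
    """Two-group baseline comparison.

    Continuous: Welch two-sample t if both groups pass the normality gate,
    Mann-Whitney U otherwise. Categorical: Pearson chi-square (no continuity
    correction) on the contingency table; pass either a prebuilt 2-D table or
    (values, group_labels) pairs.
    """
    if categorical:
        if group_labels is not None:
            table = pd.crosstab(pd.Series(values), pd.Series(group_labels)).to_numpy()
        else:
            table = np.asarray(values, float)
        if table.ndim != 2 or (table.sum(axis=0) == 0).any():
            raise ParameterError("contingency table needs two non-empty groups")
        if np.allclose(table[:, :1], table):  # identical columns -> stat 0
            return TestResult(
                method="chi_square", statistic=0.0, p_value=1.0,
                n=int(table.sum()), note="identical group distributions",
            )
        chi2, p, _, _ = st.chi2_contingency(table, correction=False)
        return TestResult(
            method="chi_square", statistic=float(chi2), p_value=float(p),
            n=int(table.sum()),
        )
    if group_labels is None:
        raise ParameterError("continuous comparison needs group_labels")
    v = np.asarray(values, float)
    labels = np.asarray(group_labels)
    groups = [v[labels == g] for g in pd.unique(labels)]
    if len(groups) != 2 or any(len(g) == 0 for g in groups):
        raise ParameterError("exactly two non-empty groups required")
    g1, g2 = groups

    def _norm_ok(g: np.ndarray) -> Tuple[bool, Optional[float]]:
        if len(g) < 3 or np.allclose(g, g[0]):
            return False, None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pv = st.shapiro(g).pvalue
        return bool(pv >= alpha), float(pv)

    ok1, p1 = _norm_ok(g1)
    ok2, p2 = _norm_ok(g2)
    if ok1 and ok2:
        res = st.ttest_ind(g1, g2, equal_var=False)
        return TestResult(
            method="two_sample_t", statistic=float(res.statistic),
            p_value=float(res.pvalue), n=len(v),
            normality_p=min(p1, p2),
        )
    res = st.mannwhitneyu(g1, g2, alternative="two-sided")
    return TestResult(
        method="mann_whitney_u", statistic=float(res.statistic),
        p_value=float(res.pvalue), n=len(v),
        normality_p=None if p1 is None or p2 is None else min(p1, p2),
    )


# ---------------------------------------------------------------------------
# Random-intercept LMM
# ---------------------------------------------------------------------------


def _satterthwaite_dfs(
    X: np.ndarray, groups: np.ndarray, tau2: float, sigma2: float
) -> np.ndarray:
    """Satterthwaite approximate denominator df per fixed-effect term for the
    random-intercept model V = sigma2*I + tau2*11' (per group).

    df_i = 2*C_ii^2 / (g_i' A g_i) with C = (X'V^-1 X)^-1, g_i the gradient
    of C_ii in (tau2, sigma2), and A the inverse ML Fisher information of the
    variance components. Within-subject contrasts get large df (their
    variance barely depends on tau2); contrasts with between-subject content
    get df near the number of subjects.
    """
    uniq, inv = np.unique(groups, return_inverse=True)
    p = X.shape[1]
    # per-group sufficient statistics
    xtx = np.zeros((len(uniq), p, p))
    xt1 = np.zeros((len(uniq), p))
    m = np.zeros(len(uniq))
    for g in range(len(uniq)):
        Xg = X[inv == g]
        xtx[g] = Xg.T @ Xg
        xt1[g] = Xg.sum(axis=0)
        m[g] = len(Xg)

    def info_matrix(t2: float, s2: float) -> np.ndarray:
        denom = s2 + m * t2
        i_tt = 0.5 * np.sum((m / denom) ** 2)
        i_ts = 0.5 * np.sum(m / denom**2)
        i_ss = 0.5 * np.sum((m - 1) / s2**2 + 1.0 / denom**2)
        return np.array([[i_tt, i_ts], [i_ts, i_ss]])

    def cov_beta(t2: float, s2: float) -> np.ndarray:
        c = t2 / (s2 + m * t2)
        M = np.einsum("gij->ij", xtx) / s2 - np.einsum(
            "g,gi,gj->ij", c / s2, xt1, xt1
        )
        return np.linalg.inv(M)

    C = cov_beta(tau2, sigma2)
    h_t = max(1e-6 * sigma2, 1e-3 * tau2)
    h_s = 1e-3 * sigma2
    # forward difference at the tau2 >= 0 boundary, central otherwise
    if tau2 - h_t >= 0:
        dC_dt = (cov_beta(tau2 + h_t, sigma2) - cov_beta(tau2 - h_t, sigma2)) / (2 * h_t)
    else:
        dC_dt = (cov_beta(tau2 + h_t, sigma2) - C) / h_t
    dC_ds = (cov_beta(tau2, sigma2 + h_s) - cov_beta(tau2, sigma2 - h_s)) / (2 * h_s)
    A = np.linalg.inv(info_matrix(tau2, sigma2))
    dfs = np.empty(p)
    for i in range(p):
        g = np.array([dC_dt[i, i], dC_ds[i, i]])
        denom = float(g @ A @ g)
        dfs[i] = 2.0 * C[i, i] ** 2 / denom if denom > 0 else np.inf
    return np.clip(dfs, 1.0, 1e7)


def _cr2_se_df(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, groups: np.ndarray,
    tau2: float, sigma2: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Bell-McCaffrey CR2 cluster-robust SEs and Satterthwaite df per term.

    The random-intercept working model V_g = sigma2*I + tau2*11' whitens each
    cluster; in whitened space the GLS fit is OLS, where the canonical CR2
    adjustment A_g = (I - H_gg)^{-1/2} applies. The meat uses empirical
    whitened residuals, so subject-level heteroskedasticity (e.g. slower
    subjects being noisier) is absorbed rather than assumed away — with 8
    clusters the usual model-based Wald SEs are anti-conservative exactly for
    that reason. df follows the Satterthwaite approximation of the variance
    estimator's quadratic form under the working model.
    """
    uniq, inv = np.unique(groups, return_inverse=True)
    n, p = X.shape
    Xt = np.empty_like(X, dtype=float)
    yt = np.empty_like(y, dtype=float)
    blocks: list[np.ndarray] = []
    for g in range(len(uniq)):
        idx = np.flatnonzero(inv == g)
        m = len(idx)
        # V^{-1/2} = (1/sigma) (I - (theta/m) 11'),
        # theta = 1 - sigma/sqrt(sigma^2 + m tau^2)
        theta = 1.0 - math.sqrt(sigma2) / math.sqrt(sigma2 + m * tau2)
        Xg = X[idx]
        Xt[idx] = (Xg - theta * Xg.mean(axis=0)) / math.sqrt(sigma2)
        yt[idx] = (y[idx] - theta * y[idx].mean()) / math.sqrt(sigma2)
        blocks.append(idx)
    B = np.linalg.inv(Xt.T @ Xt)
    beta_gls = B @ (Xt.T @ yt)
    resid = yt - Xt @ beta_gls
    # per-cluster CR2 pieces and the Satterthwaite helper vectors
    meat = np.zeros((p, p))
    # w_cols[g] = A_g' Xt_g B  (m_g x p); used both for the meat and the df
    w_parts: list[np.ndarray] = []
    for idx in blocks:
        Xg = Xt[idx]
        Hgg = Xg @ B @ Xg.T
        evals, evecs = np.linalg.eigh(np.eye(len(idx)) - Hgg)
        inv_sqrt = np.where(evals > 1e-10, 1.0 / np.sqrt(np.clip(evals, 1e-10, None)), 0.0)
        Ag = (evecs * inv_sqrt) @ evecs.T
        XgA = Xg.T @ Ag  # p x m_g
        u = XgA @ resid[idx]
        meat += np.outer(u, u)
        w_parts.append((Ag @ Xg @ B))  # m_g x p
    V = B @ meat @ B
    se = np.sqrt(np.diag(V))
    # Satterthwaite df per coordinate under the (whitened-iid) working model:
    # V_ii = eps' G eps with G = sum_g q_g q_g', q_g = (I-H)'_{.,g} w_g
    XtB = Xt @ B  # n x p
    dfs = np.empty(p)
    for i in range(p):
        Q = np.zeros((len(blocks), n))
        for g, idx in enumerate(blocks):
            w = w_parts[g][:, i]  # m_g
            q = np.zeros(n)
            q[idx] = w
            q -= XtB @ (Xt[idx].T @ w)
            Q[g] = q
        gram = Q @ Q.T
        tr = float(np.trace(gram))
        tr2 = float(np.sum(gram**2))
        dfs[i] = tr**2 / tr2 if tr2 > 0 else np.inf
    return se, np.clip(dfs, 1.0, 1e7)


def fit_random_intercept_lmm(
    long_table: LongOutcomeTable,
    reml: bool = True,
    df_method: Union[str, int, None] = "satterthwaite",
) -> LMMResult:
    """Fit ``value ~ 1 + session*drug + (1|subject)`` at trial level.

    REML by default: with a handful of subjects the ML variance components
    are biased low and Wald inference becomes anti-conservative even with
    approximate df; ``reml=False`` switches to ML when likelihoods must be
    comparable across fixed-effect structures. Wald t = beta/SE.
    ``df_method`` picks the reference distribution for p-values:
    ``"satterthwaite"`` (default) approximates per-term denominator df — with
    as few subjects as this trial, the session-by-drug contrast carries
    between-subject information with roughly n_subjects - 2 df, and a normal
    reference is anti-conservative; ``"normal"`` uses the standard-normal
    reference (the convention behind the printed coefficient/SE/t/p tables);
    an integer fixes the t df. Binary 0/1 outcome rows are fitted as a linear
    probability model. A singular fit (zero subject variance) is returned,
    flagged, rather than raised.
    """
    frame = long_table.frame
    if frame["subject_id"].nunique() < 2:
        raise SmallSampleError("LMM needs >= 2 subjects")
    if frame["session"].nunique() < 2:
        raise SmallSampleError("LMM needs both sessions represented")
    y = frame["value"].to_numpy(float)
    s = frame["session"].to_numpy(float)
    d = frame["drug"].to_numpy(float)
    X = np.column_stack([np.ones_like(s), s, d, s * d])
    groups = frame["subject_id"].to_numpy()
    # standardize the outcome for optimizer conditioning (exact rescaling:
    # coefficients and variance components are mapped back below)
    loc = float(y.mean())
    scale = float(y.std())
    if scale <= 0:
        scale = 1.0
    y_std = (y - loc) / scale
    caught: list[str] = []
    fitted = None
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        model = sm.MixedLM(y_std, X, groups=groups)
        for method in (None, "powell", "cg"):
            try:
                fitted = model.fit(
                    reml=reml, maxiter=500,
                    **({} if method is None else {"method": method}),
                )
            except np.linalg.LinAlgError:
                continue
            if np.all(np.isfinite(np.asarray(fitted.bse_fe, float))):
                break
        caught = [str(w.message) for w in wlist]
    if fitted is None:
        raise RuntimeError("mixed-model optimizer failed for every method")
    coefs = np.asarray(fitted.fe_params, float) * scale
    coefs[0] += loc
    ses = np.asarray(fitted.bse_fe, float) * scale
    tau2 = float(np.asarray(fitted.cov_re)[0, 0]) * scale**2
    sigma2_resid = float(fitted.scale) * scale**2
    if df_method == "cr2":
        ses, dfs = _cr2_se_df(X, y, coefs, groups, tau2, sigma2_resid)
    elif df_method == "satterthwaite":
        dfs = _satterthwaite_dfs(X, groups, tau2, sigma2_resid)
    elif df_method == "normal" or df_method is None:
        dfs = [None] * len(LMM_TERMS)
    else:
        dfs = [float(df_method)] * len(LMM_TERMS)
    terms = {}
    for name, c, se, df_i in zip(LMM_TERMS, coefs, ses, dfs):
        df_arg = None if df_i is None or not np.isfinite(df_i) else df_i
        t, p = wald_summary(float(c), float(se), df=df_arg)
        terms[name] = WaldTerm(float(c), float(se), t, p)
    sigma2_subject = tau2
    result = LMMResult(
        terms=terms,
        sigma2_subject=sigma2_subject,
        sigma2_residual=sigma2_resid,
        n_obs=len(y),
        n_subjects=int(pd.Series(groups).nunique()),
        converged=bool(fitted.converged),
        method="REML" if reml else "ML",
        warnings=caught,
    )
    if sigma2_subject <= 1e-12:
        result.warnings.append("singular fit: subject variance estimated at 0")
    return result


# ---------------------------------------------------------------------------
# Adverse events
# ---------------------------------------------------------------------------


def adverse_event_summary(
    ae_records: Iterable[AdverseEventRecord],
    subjects: Optional[Sequence[str]] = None,
) -> AESummary:
    """Totals by arm and term plus a paired t-test on per-subject
    (active - placebo) instance counts with 95% CI.

    ``subjects`` is the crossover roster; subjects on it with no reports
    count 0 in both arms (everyone is exposed to both arms). Without a
    roster, subjects seen in the records are used.
    """
    records = list(ae_records)
    arm_totals = {"active": 0, "placebo": 0}
    term_totals: dict[str, int] = {}
    per: dict[str, dict[str, int]] = {}
    for r in records:
        arm_totals[r.arm] = arm_totals.get(r.arm, 0) + r.n_instances
        term_totals[r.term] = term_totals.get(r.term, 0) + r.n_instances
        per.setdefault(r.subject_id, {"active": 0, "placebo": 0})
        per[r.subject_id][r.arm] += r.n_instances
    roster = list(subjects) if subjects is not None else sorted(per)
    excluded = [sid for sid in per if subjects is not None and sid not in roster]
    rows = [
        {
            "subject_id": sid,
            "active": per.get(sid, {}).get("active", 0),
            "placebo": per.get(sid, {}).get("placebo", 0),
        }
        for sid in roster
    ]
    table = pd.DataFrame(rows, columns=["subject_id", "active", "placebo"])
    a = table["active"].to_numpy(float)
    p = table["placebo"].to_numpy(float)
    diffs = a - p
    if len(diffs) == 0:
        raise EmptyDataError("no subjects to compare adverse events over")
    if np.allclose(diffs, 0.0):
        test = TestResult(
            method="paired_t", statistic=0.0, p_value=1.0, n=len(diffs),
            ci_low=0.0, ci_high=0.0,
            note="degenerate: identical per-subject counts in both arms",
        )
    elif len(diffs) < 2:
        test = TestResult(
            method="paired_t", statistic=float("nan"), p_value=1.0, n=len(diffs),
            note="degenerate: fewer than 2 subjects, no paired test possible",
        )
    else:
        res = st.ttest_rel(a, p)
        lo, hi = _paired_t_ci(diffs)
        test = TestResult(
            method="paired_t", statistic=float(res.statistic),
            p_value=float(res.pvalue), n=len(diffs), ci_low=lo, ci_high=hi,
        )
    return AESummary(
        arm_totals=arm_totals,
        term_totals=term_totals,
        grand_total=sum(arm_totals.values()),
        per_subject=table,
        test=test,
        excluded=[f"{sid}: not on roster" for sid in excluded],
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


@dataclass
class TrialReport:
    """All analysis outputs for one dataset."""

    lmm: dict[str, LMMResult]
    questionnaire_tests: dict[tuple, TestResult]
    ae_summary: Optional[AESummary]
    baseline_tests: dict[str, TestResult]
    multiplicity: Optional[pd.DataFrame]
    mixture_fits: Optional[pd.DataFrame] = None
    change_score_exclusions: list[str] = field(default_factory=list)

    def lmm_frame(self) -> pd.DataFrame:
        rows = []
        for outcome, res in self.lmm.items():
            f = res.to_frame()
            f.insert(0, "outcome", outcome)
            rows.append(f)
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


def analyze_trial(
    dataset: Dataset,
    screen: Optional[ScreenGeometry] = None,
    alpha: float = 0.05,
    lmm_weeks: Sequence[int] = (8, 20),
    lmm_condition: Optional[int] = 1,
    outcomes: Sequence[str] = OUTCOME_NAMES,
    fit_mixtures: bool = False,
    multiplicity_method: str = "bonferroni",
    lmm_df_method: Union[str, int, None] = "cr2",
) -> TrialReport:
    """Run the full statistical plan on one dataset.

    The mixed model uses the end-of-arm assessments (one week per session)
    and, by default, the one-item condition (the trial's tabulated frame);
    pass ``lmm_condition=None`` to pool conditions or 2 for two-item trials.
    ``fit_mixtures`` adds per subject x session two-item mixture
    decompositions (no permutation null here; that is a separate, costlier
    call). The multiplicity family is every fitted outcome x the three
    non-intercept fixed-effect terms.
    """
    screen = screen or ScreenGeometry()
    # --- mixed models on the task metrics --------------------------------
    lmm_results: dict[str, LMMResult] = {}
    for outcome in outcomes:
        table = build_long_table(
            dataset.trials, dataset.assignments, outcome,
            weeks=lmm_weeks, condition=lmm_condition,
        )
        if table.n_obs == 0:
            continue
        lmm_results[outcome] = fit_random_intercept_lmm(table, df_method=lmm_df_method)

    # --- questionnaires ----------------------------------------------------
    changes, excluded = change_scores(dataset.questionnaires, dataset.assignments)
    frame = pd.DataFrame([c.__dict__ for c in changes])
    q_tests: dict[tuple, TestResult] = {}
    if not frame.empty:
        for (instr, resp), sub in frame.groupby(["instrument", "respondent"]):
            wide = sub.pivot_table(
                index="subject_id", columns="arm_drug", values="delta"
            )
            if not {0, 1}.issubset(wide.columns):
                continue
            wide = wide.dropna()
            if len(wide) < 3:
                continue
            q_tests[(instr, resp)] = compare_change_between_arms(
                wide[1].to_numpy(), wide[0].to_numpy(), alpha=alpha
            )

    # --- adverse events ----------------------------------------------------
    ae = None
    if dataset.adverse_events:
        ae = adverse_event_summary(
            dataset.adverse_events, subjects=dataset.subject_ids or None
        )

    # --- baseline comparisons ----------------------------------------------
    baseline: dict[str, TestResult] = {}
    if dataset.demographics and dataset.assignments:
        demo = pd.DataFrame([d.__dict__ for d in dataset.demographics])
        amap = {a.subject_id: a.sequence for a in dataset.assignments}
        demo["sequence"] = demo["subject_id"].map(amap)
        demo = demo.dropna(subset=["sequence"])
        if demo["sequence"].nunique() == 2:
            baseline["age"] = compare_baseline_groups(
                demo["age_years"], demo["sequence"], alpha=alpha
            )
            baseline["baseline_mmse"] = compare_baseline_groups(
                demo["baseline_mmse"].astype(float), demo["sequence"], alpha=alpha
            )
            baseline["sex"] = compare_baseline_groups(
                demo["sex"], demo["sequence"], categorical=True, alpha=alpha
            )

    # --- mixture decomposition (two-item condition) -------------------------
    mix_frame = None
    if fit_mixtures:
        rows = []
        for sid in dataset.subject_ids:
            for week in sorted({t.session_week for t in dataset.trials}):
                sel = mixmod.select_mixture_trials(
                    [t for t in dataset.trials
                     if t.subject_id == sid and t.session_week == week]
                )
                try:
                    f = mixmod.fit_em(sel, screen)
                except SmallSampleError:
                    continue
                rows.append(
                    {
                        "subject_id": sid, "week": week,
                        "p_target": f.params.p_target,
                        "p_misbind": f.params.p_misbind,
                        "p_guess": f.params.p_guess,
                        "sigma_px": f.params.sigma_px,
                        "log_likelihood": f.log_likelihood,
                        "converged": f.converged,
                        "n_trials": f.n_trials,
                    }
                )
        mix_frame = pd.DataFrame(rows)

    # --- multiplicity -------------------------------------------------------
    mult = None
    if lmm_results:
        fam = [
            (outcome, term, res.terms[term].p_value)
            for outcome, res in lmm_results.items()
            for term in ("session", "drug", "session_x_drug")
        ]
        adjusted, flags = adjust_multiplicity(
            [p for _, _, p in fam], method=multiplicity_method, alpha=alpha
        )
        mult = pd.DataFrame(
            {
                "outcome": [o for o, _, _ in fam],
                "term": [t for _, t, _ in fam],
                "p_value": [p for _, _, p in fam],
                "p_adjusted": adjusted,
                "significant": flags,
            }
        )

    return TrialReport(
        lmm=lmm_results,
        questionnaire_tests=q_tests,
        ae_summary=ae,
        baseline_tests=baseline,
        multiplicity=mult,
        mixture_fits=mix_frame,
        change_score_exclusions=excluded,
    )
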