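"""Spatial mixture decomposition of two-item localization responses.

Responses on the screen are modelled as a three-component mixture:

    f(r) = p_T * g(r; x_T, sigma) + p_N * g(r; x_N, sigma) + p_U / A

where g is an isotropic bivariate normal truncated to the screen rectangle
and renormalized there, x_T / x_N are the target and non-target (swap)
locations, A is the screen area and (p_T, p_N, p_U) sit on the probability
simplex. p_T is target detection, p_N misbinding (swap responses around the
other studied item), p_U uniform guessing, and the shared sigma is the
imprecision of localization. This transplants the classical analogue-report
mixture model of visual working memory from 1-D circular feature space to the
2-D screen.

Fitting is by expectation-maximization with responsibilities over the three
components. Because the truncated-normal normalizer depends on sigma, the
M-step uses the closed-form untruncated sigma update and accepts it only if it
improves the expected complete-data log-likelihood, falling back to a bounded
1-D search (generalized EM), so the observed-data log-likelihood is
non-decreasing at every iteration.

Since the swap component is only identified relative to the *observed pairing*
of targets and non-targets, chance-level misbinding is calibrated with a
permutation null: non-target locations are shuffled across trials (targets and
responses fixed), the mixture refitted, and the observed p_N compared with the
permutation distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp, ndtr

from .datamodel import (
    DataValidationError,
    OMTTrial,
    ParameterError,
    ScreenGeometry,
    SmallSampleError,
)

SIGMA_FLOOR_PX = 1.0
MIN_FIT_TRIALS = 10


@dataclass(frozen=True)
class MixtureParams:
    """Mixture weights (target / misbind / guess) and shared imprecision."""

    p_target: float
    p_misbind: float
    p_guess: float
    sigma_px: float

    def __post_init__(self) -> None:
        for name in ("p_target", "p_misbind", "p_guess"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if abs(self.p_target + self.p_misbind + self.p_guess - 1.0) > 1e-9:
            raise ParameterError("mixture weights must sum to 1 (tol 1e-9)")
        if self.sigma_px <= 0:
            raise ParameterError("sigma_px must be positive")

    def as_tuple(self) -> Tuple[float, float, float, float]:
        return (self.p_target, self.p_misbind, self.p_guess, self.sigma_px)


@dataclass
class MixtureFit:
    params: MixtureParams
    log_likelihood: float
    n_iterations: int
    converged: bool
    n_trials: int
    standard_errors: Optional[dict] = None
    ll_history: list[float] = field(default_factory=list)


@dataclass
class PermutationNull:
    """Observed misbinding against its shuffle null.

    ``p_value`` uses the add-one permutation estimator
    (1 + #{null >= observed}) / (n_permutations + 1), which is exact under
    exchangeability. ``corrected_p_misbind`` is the chance-corrected weight
    max(0, observed - mean(null)).
    """

    observed_p_misbind: float
    null_p_misbind: list[float]
    n_permutations: int
    p_value: float
    corrected_p_misbind: float


# ---------------------------------------------------------------------------
# Arrays from trials
# ---------------------------------------------------------------------------


def trials_to_arrays(
    trials: Iterable[OMTTrial], correct_only: bool = False
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(responses, targets, nontargets) arrays; nontarget rows are NaN for
    one-item trials. ``correct_only`` keeps correctly identified trials only
    (the default frame in which misbinding is defined)."""
    X, T, N = [], [], []
    for t in trials:
        if correct_only and not t.identified_correct:
            continue
        X.append(t.response_xy)
        T.append(t.target_xy)
        N.append(t.nontarget_xy[0] if t.nontarget_xy else (np.nan, np.nan))
    return np.asarray(X, float), np.asarray(T, float), np.asarray(N, float)


def select_mixture_trials(
    trials: Iterable[OMTTrial], condition: int = 2, correct_only: bool = True
) -> list[OMTTrial]:
    """Default trial frame for mixture fitting: two-item, correct-ID trials."""
    return [
        t
        for t in trials
        if t.condition == condition and (t.identified_correct or not correct_only)
    ]


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------


def _log_trunc_normal(
    X: np.ndarray, C: np.ndarray, sigma: float, screen: ScreenGeometry
) -> np.ndarray:
    """Log density (per px^2) of the isotropic normal centred at C, truncated
    and renormalized on the screen rectangle. X, C: (n, 2)."""
    z2 = np.sum(((X - C) / sigma) ** 2, axis=-1)
    logphi = -0.5 * z2 - math.log(2.0 * math.pi) - 2.0 * math.log(sigma)
    zx = ndtr((screen.width_px - C[..., 0]) / sigma) - ndtr(-C[..., 0] / sigma)
    zy = ndtr((screen.height_px - C[..., 1]) / sigma) - ndtr(-C[..., 1] / sigma)
    return logphi - np.log(zx * zy)


def mixture_density(
    params: MixtureParams,
    response_xy: Sequence[float],
    target_xy: Sequence[float],
    nontarget_xy: Optional[Sequence[Sequence[float]]] = None,
    screen: ScreenGeometry = ScreenGeometry(),
) -> float:
    """Mixture density (per px^2) of one response; integrates to 1 on the
    screen."""
    if not screen.contains(response_xy):
        raise DataValidationError(f"response {tuple(response_xy)} outside screen")
    nontargets = list(nontarget_xy or [])
    if params.p_misbind > 0 and not nontargets:
        raise ParameterError("p_misbind > 0 requires a nontarget location")
    X = np.asarray([response_xy], float)
    dens = params.p_guess / screen.area
    if params.p_target > 0:
        dens += params.p_target * float(
            np.exp(_log_trunc_normal(X, np.asarray([target_xy], float),
                                     params.sigma_px, screen))[0]
        )
    if params.p_misbind > 0:
        dens += params.p_misbind * float(
            np.exp(_log_trunc_normal(X, np.asarray([nontargets[0]], float),
                                     params.sigma_px, screen))[0]
        )
    return dens


def _component_logdens(
    X: np.ndarray,
    T: np.ndarray,
    N: np.ndarray,
    sigma: float,
    screen: ScreenGeometry,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-trial log densities of (target, nontarget, uniform) components.
    Trials without a nontarget get -inf for the swap component."""
    lt = _log_trunc_normal(X, T, sigma, screen)
    ln = np.full(len(X), -np.inf)
    has_n = ~np.isnan(N[:, 0])
    if has_n.any():
        ln[has_n] = _log_trunc_normal(X[has_n], N[has_n], sigma, screen)
    lu = np.full(len(X), -math.log(screen.area))
    return lt, ln, lu


def log_likelihood(
    params: MixtureParams,
    trials,
    screen: ScreenGeometry = ScreenGeometry(),
) -> float:
    """Sum of per-trial log mixture densities. ``trials`` is a list of
    :class:`OMTTrial` or an (X, T, N) array triple."""
    X, T, N = trials if isinstance(trials, tuple) else trials_to_arrays(trials)
    if len(X) == 0:
        raise SmallSampleError("log_likelihood needs at least one trial")
    lt, ln, lu = _component_logdens(X, T, N, params.sigma_px, screen)
    with np.errstate(divide="ignore"):
        stack = np.stack(
            [
                np.log(params.p_target) + lt,
                np.log(params.p_misbind) + ln,
                np.log(params.p_guess) + lu,
            ]
        )
    ll_i = logsumexp(stack, axis=0)
    if not np.all(np.isfinite(ll_i)):
        return -np.inf
    return float(ll_i.sum())


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------


def _e_step(X, T, N, weights, sigma, screen):
    """Return (per-trial ll, responsibilities (n, 3))."""
    lt, ln, lu = _component_logdens(X, T, N, sigma, screen)
    with np.errstate(divide="ignore"):
        logw = np.log(np.asarray(weights))
    stack = np.stack([logw[0] + lt, logw[1] + ln, logw[2] + lu], axis=1)
    ll_i = logsumexp(stack, axis=1)
    gamma = np.exp(stack - ll_i[:, None])
    return float(ll_i.sum()), gamma


def _q_sigma(sigma, X, T, N, gamma, screen):
    """Expected complete-data log-likelihood terms that depend on sigma."""
    lt, ln, _ = _component_logdens(X, T, N, sigma, screen)
    gn = gamma[:, 1]
    # gamma for the swap component is 0 where there is no nontarget; treat
    # 0 * (-inf) as 0.
    swap = np.where(gn > 0, gn * np.where(np.isfinite(ln), ln, 0.0), 0.0)
    return float(np.sum(gamma[:, 0] * lt) + np.sum(swap))


def _m_step(X, T, N, gamma, sigma_old, screen, sigma_floor, allow_misbind):
    n = len(X)
    w = gamma.mean(axis=0)
    if not allow_misbind:
        w[1] = 0.0
    w = np.clip(w, 0.0, None)
    w = w / w.sum()

    # sigma update: untruncated closed form, kept only if Q improves.
    d2t = np.sum((X - T) ** 2, axis=1)
    has_n = ~np.isnan(N[:, 0])
    d2n = np.zeros(n)
    d2n[has_n] = np.sum((X[has_n] - N[has_n]) ** 2, axis=1)
    denom = gamma[:, 0].sum() + gamma[:, 1].sum()
    sigma_max = math.hypot(screen.width_px, screen.height_px)
    candidates = [sigma_old]
    if denom > 1e-12:
        s2 = (np.sum(gamma[:, 0] * d2t) + np.sum(gamma[:, 1] * d2n)) / (2.0 * denom)
        candidates.append(min(max(math.sqrt(max(s2, 0.0)), sigma_floor), sigma_max))
    qvals = [_q_sigma(s, X, T, N, gamma, screen) for s in candidates]
    best = int(np.argmax(qvals))
    # Closed form ignores truncation; if it fails to improve Q, refine by a
    # bounded search so the generalized-EM ascent property holds.
    if best == 0 and len(candidates) > 1:
        res = minimize_scalar(
            lambda s: -_q_sigma(s, X, T, N, gamma, screen),
            bounds=(sigma_floor, sigma_max),
            method="bounded",
            options={"xatol": 1e-4},
        )
        if -res.fun > qvals[0]:
            return w, float(res.x)
        return w, sigma_old
    return w, float(candidates[best])


def _nearest_center_responsibilities(X, T, N, uniform_floor=0.1):
    """Initial responsibilities: nearest of target/nontarget gets the
    non-uniform mass; ties split equally; 10% floor on the uniform column."""
    n = len(X)
    gamma = np.zeros((n, 3))
    gamma[:, 2] = uniform_floor
    d2t = np.sum((X - T) ** 2, axis=1)
    has_n = ~np.isnan(N[:, 0])
    d2n = np.full(n, np.inf)
    d2n[has_n] = np.sum((X[has_n] - N[has_n]) ** 2, axis=1)
    rest = 1.0 - uniform_floor
    tie = np.isclose(d2t, d2n) & has_n
    t_near = (d2t < d2n) | ~has_n
    gamma[t_near & ~tie, 0] = rest
    gamma[~t_near & ~tie, 1] = rest
    gamma[tie, 0] = rest / 2
    gamma[tie, 1] = rest / 2
    return gamma


def _run_em(X, T, N, screen, gamma0, tol, max_iter, sigma_floor, allow_misbind,
            init_params=None):
    history: list[float] = []
    if init_params is not None:
        weights = np.array(
            [init_params.p_target, init_params.p_misbind, init_params.p_guess]
        )
        sigma = init_params.sigma_px
    else:
        weights, sigma = _m_step(
            X, T, N, gamma0, sigma_old=max(sigma_floor, 40.0),
            screen=screen, sigma_floor=sigma_floor, allow_misbind=allow_misbind,
        )
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, gamma = _e_step(X, T, N, weights, sigma, screen)
        history.append(ll)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * (abs(prev_ll) + 1e-10):
            converged = True
            break
        prev_ll = ll
        weights, sigma = _m_step(
            X, T, N, gamma, sigma_old=sigma, screen=screen,
            sigma_floor=sigma_floor, allow_misbind=allow_misbind,
        )
    final_ll, _ = _e_step(X, T, N, weights, sigma, screen)
    history.append(final_ll)
    params = MixtureParams(
        p_target=float(weights[0]),
        p_misbind=float(weights[1]),
        p_guess=float(weights[2]),
        sigma_px=float(max(sigma, sigma_floor)),
    )
    return params, final_ll, it, converged, history


def fit_em(
    trials,
    screen: ScreenGeometry = ScreenGeometry(),
    init: Optional[MixtureParams] = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 5,
    min_trials: int = MIN_FIT_TRIALS,
    sigma_floor: float = SIGMA_FLOOR_PX,
    seed: int = 0,
) -> MixtureFit:
    """Maximum-likelihood mixture fit by (generalized) EM.

    ``trials`` is a list of :class:`OMTTrial` or an (X, T, N) array triple.
    Trials without a non-target are fitted with the swap component disabled
    for them; if *no* trial has a non-target the model reduces to
    target + uniform and p_misbind is exactly 0. The best of ``n_restarts``
    jittered initializations is returned; restart 0 uses deterministic
    nearest-center responsibilities with a 10% uniform floor. When ``init``
    is given it seeds restart 0 directly (warm start).
    """
    X, T, N = trials if isinstance(trials, tuple) else trials_to_arrays(trials)
    if len(X) < min_trials:
        raise SmallSampleError(
            f"mixture fit needs >= {min_trials} trials, got {len(X)}"
        )
    allow_misbind = bool((~np.isnan(N[:, 0])).any())
    rng = np.random.default_rng(seed)
    gamma0 = _nearest_center_responsibilities(X, T, N)
    best = None
    for r in range(max(1, n_restarts)):
        if r == 0:
            g = gamma0
            ip = init
        else:
            jitter = rng.normal(0.0, 0.5, size=gamma0.shape)
            g = gamma0 * np.exp(jitter)
            g = g / g.sum(axis=1, keepdims=True)
            ip = None
        params, ll, it, conv, hist = _run_em(
            X, T, N, screen, g, tol, max_iter, sigma_floor, allow_misbind,
            init_params=ip,
        )
        if best is None or ll > best[1]:
            best = (params, ll, it, conv, hist)
    params, ll, it, conv, hist = best
    return MixtureFit(
        params=params,
        log_likelihood=ll,
        n_iterations=it,
        converged=conv,
        n_trials=len(X),
        ll_history=hist,
    )


# ---------------------------------------------------------------------------
# Permutation null and bootstrap
# ---------------------------------------------------------------------------


def permutation_misbinding_null(
    trials,
    screen: ScreenGeometry = ScreenGeometry(),
    n_permutations: int = 99,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 2,
) -> PermutationNull:
    """Calibrate misbinding against chance by shuffling non-target locations.

    For each permutation the non-target column is permuted across trials
    (targets and responses fixed), the mixture refitted (warm-started at the
    observed fit), and that fit's p_misbind recorded. Deterministic given
    ``seed``. Requires every trial to carry a non-target.
    """
    if n_permutations < 19:
        raise ParameterError(
            "n_permutations must be >= 19 to resolve p < 0.05"
        )
    X, T, N = trials if isinstance(trials, tuple) else trials_to_arrays(trials)
    if np.isnan(N[:, 0]).any():
        raise ParameterError("permutation null requires two-item trials only")
    observed = fit_em(
        (X, T, N), screen, tol=tol, max_iter=max_iter,
        n_restarts=n_restarts, seed=seed,
    )
    rng = np.random.default_rng(seed)
    null: list[float] = []
    for _ in range(n_permutations):
        perm = rng.permutation(len(X))
        fit_p = fit_em(
            (X, T, N[perm]), screen, init=observed.params, tol=tol,
            max_iter=max_iter, n_restarts=1, seed=seed,
        )
        null.append(fit_p.params.p_misbind)
    obs = observed.params.p_misbind
    n_ge = sum(1 for v in null if v >= obs)
    return PermutationNull(
        observed_p_misbind=obs,
        null_p_misbind=null,
        n_permutations=n_permutations,
        p_value=(1 + n_ge) / (n_permutations + 1),
        corrected_p_misbind=max(0.0, obs - float(np.mean(null))),
    )


def bootstrap_se(
    trials,
    screen: ScreenGeometry = ScreenGeometry(),
    n_boot: int = 200,
    seed: int = 0,
    **fit_kwargs,
) -> Optional[dict]:
    """Nonparametric trial-resampling standard errors of the four parameters.

    Returns ``None`` (absent SEs, not zeros) when ``n_boot`` is 0.
    """
    if n_boot == 0:
        return None
    X, T, N = trials if isinstance(trials, tuple) else trials_to_arrays(trials)
    fit_kwargs.setdefault("n_restarts", 1)
    base = fit_em((X, T, N), screen, **fit_kwargs)
    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, 4))
    for b in range(n_boot):
        idx = rng.integers(0, len(X), size=len(X))
        fit_b = fit_em(
            (X[idx], T[idx], N[idx]), screen, init=base.params, **fit_kwargs
        )
        draws[b] = fit_b.params.as_tuple()
    ses = draws.std(axis=0, ddof=1)
    return {
        "p_target": float(ses[0]),
        "p_misbind": float(ses[1]),
        "p_guess": float(ses[2]),
        "sigma_px": float(ses[3]),
    }
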