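"""Rank-abundance distribution (RAD) models, likelihood fitting, AIC selection.

Five species-abundance distribution (SAD) models give expected abundance as a
function of rank r = 1..S for a community of S species and N individuals:

broken stick (0 parameters)
    a_r = (N/S) * sum_{k=r}^{S} 1/k — the null model of random resource splits.
niche preemption (1 parameter, alpha in (0,1))
    a_r = N * alpha * (1-alpha)^(r-1) / (1 - (1-alpha)^S) — geometric series;
    each species preempts fraction alpha of the remaining resource.
lognormal (2 parameters, mu and sigma on the log scale)
    a_r = exp(mu + sigma * Phi^-1(1 - (r - 0.5)/S)) using the standard
    plotting-position quantile convention.
zipf (2 parameters, p1 in (0,1), gamma < 0)
    a_r = N * p1 * r^gamma — pure power law.
Zipf-Mandelbrot (3 parameters, c > 0, beta > -1, gamma < 0)
    a_r = N * c * (r + beta)^gamma — power law with rank offset.

Fitting maximizes the Poisson log-likelihood of the observed descending
counts against the model's expected abundances, with a deterministic
multistart; models are compared by AIC = -2*loglik + 2k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit, ndtri

__all__ = [
    "MODEL_ORDER",
    "RADFit",
    "ModelSelection",
    "expected_rad",
    "fit_rad",
    "select_sad",
    "sorted_counts",
]

#: Candidate order, also the fixed tie-break order in model selection.
MODEL_ORDER = ("brokenstick", "preemption", "lognormal", "zipf", "mandelbrot")

#: Free-parameter count per model.
MODEL_K = {"brokenstick": 0, "preemption": 1, "lognormal": 2, "zipf": 2, "mandelbrot": 3}

_OBJ_TOL = 1e-8


@dataclass(frozen=True)
class RADFit:
    """A fitted rank-abundance model."""

    model: str
    params: Mapping[str, float]
    k: int
    fitted: tuple[float, ...]
    loglik: float
    aic: float

    def expected(self, S: int, N: float) -> np.ndarray:
        """Expected abundances for this model/params at another (S, N)."""
        return expected_rad(self.model, self.params, S, N)


@dataclass(frozen=True)
class ModelSelection:
    """All candidate fits plus the AIC-best model."""

    fits: Mapping[str, RADFit]
    best: str
    delta_aic: Mapping[str, float]


def expected_rad(
    model: str, params: Mapping[str, float], S: int, N: float
) -> np.ndarray:
    """Expected abundance at ranks 1..S under ``model`` with ``params``."""
    if S < 1:
        raise ValueError(f"S must be >= 1, got {S}")
    if N <= 0:
        raise ValueError(f"N must be positive, got {N}")
    r = np.arange(1, S + 1, dtype=float)
    if model == "brokenstick":
        # (N/S) * sum_{k=r}^{S} 1/k via reversed cumulative sum of 1/k
        inv = 1.0 / np.arange(1, S + 1, dtype=float)
        tail = np.cumsum(inv[::-1])[::-1]
        return (N / S) * tail
    if model == "preemption":
        alpha = float(params["alpha"])
        if not 0.0 < alpha < 1.0:
            raise ValueError(f"preemption requires 0 < alpha < 1, got {alpha}")
        return N * alpha * (1 - alpha) ** (r - 1) / (1 - (1 - alpha) ** S)
    if model == "lognormal":
        mu, sigma = float(params["mu"]), float(params["sigma"])
        if sigma < 0:
            raise ValueError(f"lognormal requires sigma >= 0, got {sigma}")
        q = ndtri(1.0 - (r - 0.5) / S)
        return np.exp(mu + sigma * q)
    if model == "zipf":
        p1, gamma = float(params["p1"]), float(params["gamma"])
        if not 0.0 < p1 <= 1.0:
            raise ValueError(f"zipf requires 0 < p1 <= 1, got {p1}")
        if gamma >= 0:
            raise ValueError(f"zipf requires gamma < 0, got {gamma}")
        return N * p1 * r**gamma
    if model == "mandelbrot":
        c, beta, gamma = (
            float(params["c"]),
            float(params["beta"]),
            float(params["gamma"]),
        )
        if c <= 0:
            raise ValueError(f"mandelbrot requires c > 0, got {c}")
        if beta <= -1:
            raise ValueError(f"mandelbrot requires beta > -1, got {beta}")
        if gamma >= 0:
            raise ValueError(f"mandelbrot requires gamma < 0, got {gamma}")
        return N * c * (r + beta) ** gamma
    raise ValueError(f"unknown model {model!r}; choose from {MODEL_ORDER}")


def sorted_counts(counts: Mapping[str, int] | Sequence[int]) -> np.ndarray:
    """Counts sorted into rank order (descending; species-name tie-break)."""
    if isinstance(counts, Mapping):
        items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        values = [v for _, v in items]
    else:
        values = sorted(counts, reverse=True)
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no counts to fit")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    return arr


def _poisson_loglik(obs: np.ndarray, exp_: np.ndarray, *, with_const: bool) -> float:
    exp_ = np.clip(exp_, 1e-300, None)
    ll = float(np.sum(obs * np.log(exp_) - exp_))
    if with_const:
        ll -= float(np.sum(gammaln(obs + 1.0)))
    return ll


# --- parameter transforms: unconstrained optimizer space <-> natural space ---

def _to_natural(model: str, theta: np.ndarray) -> dict[str, float]:
    if model == "preemption":
        return {"alpha": float(expit(theta[0]))}
    if model == "lognormal":
        return {"mu": float(theta[0]), "sigma": float(np.exp(theta[1]))}
    if model == "zipf":
        return {"p1": float(expit(theta[0])), "gamma": float(-np.exp(theta[1]))}
    if model == "mandelbrot":
        return {
            "c": float(np.exp(theta[0])),
            "beta": float(np.exp(theta[1]) - 1.0),
            "gamma": float(-np.exp(theta[2])),
        }
    return {}


def _clip_logit(p: float) -> float:
    return float(logit(min(max(p, 1e-4), 1 - 1e-4)))


def _starts(model: str, obs: np.ndarray) -> list[np.ndarray]:
    """Deterministic multistart points derived from simple moment fits."""
    S = obs.size
    N = float(obs.sum())
    pos = np.clip(obs, 0.5, None)  # guard zeros for log-based starts
    r = np.arange(1, S + 1, dtype=float)
    logv = np.log(pos)

    if model == "preemption":
        slope = np.polyfit(r, logv, 1)[0] if S > 1 else -0.5
        a0 = min(max(1.0 - math.exp(slope), 0.01), 0.99)
        return [np.array([_clip_logit(a)]) for a in (a0, 0.3, 0.7)]
    if model == "lognormal":
        mu0, sd0 = float(logv.mean()), float(max(logv.std(), 0.1))
        return [
            np.array([mu0, math.log(sd0)]),
            np.array([mu0, math.log(max(2 * sd0, 0.5))]),
            np.array([mu0, math.log(0.5)]),
        ]
    if model == "zipf":
        g0 = np.polyfit(np.log(r), logv, 1)[0] if S > 1 else -1.0
        g0 = min(g0, -0.05)
        p0 = min(max(obs[0] / N, 1e-3), 1 - 1e-3)
        return [
            np.array([_clip_logit(p0), math.log(-g0)]),
            np.array([_clip_logit(p0), math.log(1.0)]),
            np.array([_clip_logit(0.3), math.log(0.5)]),
        ]
    if model == "mandelbrot":
        g0 = np.polyfit(np.log(r), logv, 1)[0] if S > 1 else -1.0
        g0 = min(g0, -0.05)
        c0 = min(max(obs[0] / N, 1e-3), 10.0)
        return [
            np.array([math.log(c0), math.log(1e-6 + 1.0) - 1.0, math.log(-g0)]),
            np.array([math.log(c0), math.log(2.0), math.log(-g0)]),
            np.array([math.log(c0), math.log(6.0), math.log(1.0)]),
        ]
    raise ValueError(f"model {model!r} has no free parameters to start")


def fit_rad(
    counts: Mapping[str, int] | Sequence[int], model: str
) -> RADFit:
    """Fit one SAD model to pooled integer counts by Poisson ML.

    Counts are ranked internally (descending, species-name tie-break). The
    optimizer maximizes the Poisson log-likelihood over a deterministic
    multistart; the reported ``loglik`` includes the factorial constant so
    AIC values are comparable across models.
    """
    obs = sorted_counts(counts)
    S = obs.size
    N = float(obs.sum())
    if N <= 0:
        raise ValueError("total count must be positive")
    k = MODEL_K.get(model)
    if k is None:
        raise ValueError(f"unknown model {model!r}; choose from {MODEL_ORDER}")
    if S < k + 1:
        raise ValueError(
            f"model {model!r} needs at least {k + 1} species, got {S}"
        )

    if model == "brokenstick":
        fitted = expected_rad(model, {}, S, N)
        ll = _poisson_loglik(obs, fitted, with_const=True)
        return RADFit(model, {}, 0, tuple(fitted), ll, -2 * ll + 0)

    def neg_ll(theta: np.ndarray) -> float:
        params = _to_natural(model, theta)
        try:
            exp_ = expected_rad(model, params, S, N)
        except (ValueError, OverflowError, FloatingPointError):
            return 1e12
        if not np.all(np.isfinite(exp_)):
            return 1e12
        return -_poisson_loglik(obs, exp_, with_const=False)

    best = None
    for x0 in _starts(model, obs):
        res = minimize(
            neg_ll,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": _OBJ_TOL, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError(
            f"{model} fit failed to converge; best objective "
            f"{None if best is None else best.fun}"
        )
    params = _to_natural(model, best.x)
    fitted = expected_rad(model, params, S, N)
    ll = _poisson_loglik(obs, fitted, with_const=True)
    return RADFit(model, params, k, tuple(fitted), ll, -2 * ll + 2 * k)


def select_sad(
    counts: Mapping[str, int] | Sequence[int],
    *,
    models: Sequence[str] | None = None,
    strict_four: bool = False,
) -> ModelSelection:
    """Fit all eligible SAD models and pick the AIC minimum.

    Eligibility requires S >= k + 1 observed species for a k-parameter model.
    AIC ties (delta < 1e-6) are broken by fewer parameters, then by the fixed
    candidate order. ``strict_four`` drops the plain zipf model from the
    candidate set (it is the beta -> 0 limit of Zipf-Mandelbrot).
    """
    obs = sorted_counts(counts)
    S = obs.size
    candidates = list(models) if models is not None else list(MODEL_ORDER)
    if strict_four and "zipf" in candidates:
        candidates.remove("zipf")
    eligible = [m for m in candidates if S >= MODEL_K[m] + 1]
    if len(eligible) < 2:
        raise ValueError(
            f"need at least 2 eligible models, got {eligible} for S={S}"
        )
    fits = {m: fit_rad(obs, m) for m in eligible}
    min_aic = min(f.aic for f in fits.values())
    delta = {m: f.aic - min_aic for m, f in fits.items()}
    tied = [m for m in eligible if delta[m] < 1e-6]
    tied.sort(key=lambda m: (MODEL_K[m], MODEL_ORDER.index(m)))
    return ModelSelection(fits=fits, best=tied[0], delta_aic=delta)
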