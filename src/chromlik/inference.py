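"""Maximum-likelihood estimation, likelihood-ratio tests and profiles.

Optimization runs on natural-log rates, which makes every positivity
constraint a simple box bound and puts rates spanning several orders of
magnitude on comparable scales.  The default path is bounded quasi-Newton
(L-BFGS-B with finite-difference gradients) with a Nelder-Mead polish when
the quasi-Newton run terminates abnormally, plus optional jittered restarts
for multimodal surfaces.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import scipy.optimize
import scipy.stats

from .errors import InvalidArgumentError, NestingError
from .likelihood import RootPrior, ZeroLikelihoodWarning, negloglik
from .models import RateMatrix
from .statespace import StateSpace
from .treeio import Phylogeny, TipObservations

__all__ = ["FitResult", "LRTResult", "ProfileCurve", "fit_mle", "lrt",
           "profile_likelihood", "DEFAULT_BOUNDS", "DEFAULT_INIT"]

#: Natural-scale box for every rate; wide enough for rates from 1e-6 to ~1.
DEFAULT_BOUNDS: tuple[float, float] = (1e-10, 100.0)
#: Natural-scale default starting value for every rate.
DEFAULT_INIT: float = 0.01
#: Objective value substituted for a zero-likelihood evaluation so the
#: optimizer can retreat from the region instead of dying on +inf.
_BIG = 1e10


@dataclass
class FitResult:
    """MLEs (natural scale) with the minimized negative log-likelihood."""

    model: str
    mle: dict[str, float]
    nll: float
    converged: bool
    free_names: tuple[str, ...]
    fixed: dict[str, float] = field(default_factory=dict)
    n_iter: int = 0
    n_eval: int = 0
    restarts_used: int = 0
    message: str = ""

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def log_mle(self) -> np.ndarray:
        """Free MLEs on the optimizer's log scale, in free-name order."""
        return np.log([self.mle[name] for name in self.free_names])

    def params(self) -> dict[str, float]:
        """All parameters, free and fixed, by name."""
        return {**self.mle, **self.fixed}

    def to_dict(self) -> dict:
        return {
            "model": self.model, "mle": self.mle, "fixed": self.fixed,
            "nll": self.nll, "converged": self.converged,
            "free_names": list(self.free_names), "n_iter": self.n_iter,
            "n_eval": self.n_eval, "restarts_used": self.restarts_used,
            "message": self.message,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


@dataclass
class LRTResult:
    """Likelihood-ratio test of a reduced model nested in a full model."""

    D: float
    df: int
    p_value: float
    alpha: float
    reject: bool

    def to_dict(self) -> dict:
        return {"D": self.D, "df": self.df, "p_value": self.p_value,
                "alpha": self.alpha, "reject": self.reject}


@dataclass
class ProfileCurve:
    """Profile likelihood of one focal parameter over a fixed grid."""

    focal: str
    grid: np.ndarray
    nll: np.ndarray
    min_nll: float
    confidence: float
    lower: float | None
    upper: float | None
    open_lower: bool
    open_upper: bool

    def to_dict(self) -> dict:
        return {
            "focal": self.focal, "grid": list(map(float, self.grid)),
            "nll": list(map(float, self.nll)), "min_nll": self.min_nll,
            "confidence": self.confidence, "lower": self.lower,
            "upper": self.upper, "open_lower": self.open_lower,
            "open_upper": self.open_upper,
        }


# ---------------------------------------------------------------------------
# MLE
# ---------------------------------------------------------------------------

def _resolve_init(init, free_names: Sequence[str]) -> np.ndarray:
    """Free-parameter starting point on the log scale."""
    if init is None:
        return np.full(len(free_names), np.log(DEFAULT_INIT))
    if isinstance(init, Mapping):
        return np.log([float(init.get(name, DEFAULT_INIT)) for name in free_names])
    arr = np.asarray(init, dtype=float)
    if arr.shape != (len(free_names),):
        raise InvalidArgumentError(
            f"init has shape {arr.shape}, expected ({len(free_names)},) "
            "log-scale values for the free parameters")
    return arr


def fit_mle(tree: Phylogeny, data: TipObservations,
            builder: Callable[[np.ndarray, StateSpace], RateMatrix],
            space: StateSpace, param_names: Sequence[str], *,
            init=None, bounds: tuple[float, float] | None = None,
            fixed: Mapping[str, float] | None = None,
            root: RootPrior | None = None, model_name: str = "custom",
            options: Mapping | None = None, seed: int = 0) -> FitResult:
    """Minimize the negative log-likelihood over free log-rates.

    Parameters
    ----------
    param_names
        Full parameter order expected by ``builder``.
    init
        Either ``None`` (every free rate starts at 0.01), a mapping of
        natural-scale values by name, or a log-scale vector over the free
        parameters.
    bounds
        Natural-scale ``(low, high)`` applied to every rate.
    fixed
        Name -> natural-scale value assignments excluded from optimization.
    options
        ``restarts`` (extra jittered starts, default 3; jitter sd 0.5 on the
        log scale, seeded), ``maxiter``, ``ftol``, ``gtol``, and ``method``
        (branch propagation route; the ``"fast"`` path by default, whose
        absolute error is far below the stopping tolerances).
    """
    opts = dict(options or {})
    restarts = int(opts.get("restarts", 3))
    maxiter = int(opts.get("maxiter", 500))
    ftol = float(opts.get("ftol", 1e-8))
    gtol = float(opts.get("gtol", 1e-6))
    method = str(opts.get("method", "fast"))

    param_names = tuple(param_names)
    fixed = dict(fixed or {})
    unknown = set(fixed) - set(param_names)
    if unknown:
        raise InvalidArgumentError(
            f"fixed parameter(s) {sorted(unknown)} not in {param_names}")
    free_names = tuple(n for n in param_names if n not in fixed)
    if not free_names:
        raise InvalidArgumentError("no free parameters to optimize")
    free_idx = [param_names.index(n) for n in free_names]

    lo, hi = bounds if bounds is not None else DEFAULT_BOUNDS
    if not (0 < lo < hi):
        raise InvalidArgumentError(f"bounds must satisfy 0 < low < high, got {bounds}")
    log_lo, log_hi = np.log(lo), np.log(hi)

    full_log = np.empty(len(param_names))
    for name, value in fixed.items():
        if value <= 0:
            raise InvalidArgumentError(
                f"fixed value for {name} must be > 0 (rates are log-scaled)")
        full_log[param_names.index(name)] = np.log(value)

    n_eval = 0

    def objective(x_free: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        full_log[free_idx] = x_free
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ZeroLikelihoodWarning)
            value = negloglik(tree, data, builder, full_log, space, root,
                              method=method).value
        return value if np.isfinite(value) else _BIG

    x0 = np.clip(_resolve_init(init, free_names), log_lo, log_hi)
    if objective(x0) >= _BIG:
        raise InvalidArgumentError(
            "objective is not finite at the starting point; jitter the init "
            "or supply one closer to plausible rates")

    box = [(log_lo, log_hi)] * len(free_names)
    rng = np.random.default_rng(seed)

    def minimize_from(x_start: np.ndarray):
        res = scipy.optimize.minimize(
            objective, x_start, method="L-BFGS-B", bounds=box,
            options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol})
        if not res.success:
            polish = scipy.optimize.minimize(
                objective, res.x, method="Nelder-Mead", bounds=box,
                options={"maxiter": maxiter, "fatol": 10 * ftol,
                         "xatol": 1e-6})
            if polish.fun <= res.fun:
                res = polish
        return res

    best = minimize_from(x0)
    restarts_used = 0
    for _ in range(max(restarts, 0)):
        trial = minimize_from(np.clip(x0 + rng.normal(0.0, 0.5, len(x0)),
                                      log_lo, log_hi))
        restarts_used += 1
        if trial.fun < best.fun - 1e-9 or (trial.success and not best.success):
            best = trial

    converged = bool(best.success and best.fun < _BIG)
    if not converged:
        warnings.warn(
            f"optimizer did not converge for model {model_name!r}: "
            f"{best.message}", UserWarning, stacklevel=2)
    mle = {name: float(np.exp(v)) for name, v in zip(free_names, best.x)}
    return FitResult(
        model=model_name, mle=mle, nll=float(best.fun), converged=converged,
        free_names=free_names, fixed={k: float(v) for k, v in fixed.items()},
        n_iter=int(getattr(best, "nit", 0)), n_eval=n_eval,
        restarts_used=restarts_used, message=str(best.message))


# ---------------------------------------------------------------------------
# Likelihood-ratio test
# ---------------------------------------------------------------------------

def lrt(full: FitResult, reduced: FitResult, alpha: float = 0.05) -> LRTResult:
    """Chi-squared likelihood-ratio test of ``reduced`` nested in ``full``.

    ``D = 2 (nll_reduced - nll_full)`` is referred to a chi-squared
    distribution with df equal to the difference in free parameter counts.
    A slightly negative D (>= -1e-6) is clipped to 0 as float noise; a
    larger negative value signals an optimizer failure on the full model and
    raises :class:`NestingError`.
    """
    if not 0 < alpha < 1:
        raise InvalidArgumentError(f"alpha must be in (0, 1), got {alpha}")
    df = full.n_free - reduced.n_free
    if df <= 0:
        raise InvalidArgumentError(
            f"full model must have more free parameters than reduced "
            f"({full.n_free} vs {reduced.n_free})")
    D = 2.0 * (reduced.nll - full.nll)
    if D < -1e-6:
        raise NestingError(
            f"D = {D:.6g} < 0: the reduced fit beats the full fit, so either "
            "the models are not nested or the full optimization failed")
    D = max(D, 0.0)
    p = float(scipy.stats.chi2.sf(D, df))
    return LRTResult(D=D, df=df, p_value=p, alpha=alpha, reject=bool(p < alpha))


# ---------------------------------------------------------------------------
# Profile likelihood
# ---------------------------------------------------------------------------

def _interp_crossing(x0, y0, x1, y1, level):
    if y1 == y0:
        return x1
    return x0 + (level - y0) * (x1 - x0) / (y1 - y0)


def profile_likelihood(tree: Phylogeny, data: TipObservations,
                       builder: Callable[[np.ndarray, StateSpace], RateMatrix],
                       space: StateSpace, param_names: Sequence[str],
                       focal: str, grid: Sequence[float], *,
                       fixed: Mapping[str, float] | None = None,
                       root: RootPrior | None = None,
                       confidence: float = 0.95,
                       global_fit: FitResult | None = None,
                       model_name: str = "custom",
                       options: Mapping | None = None, seed: int = 0
                       ) -> ProfileCurve:
    """Profile the likelihood of ``focal`` over ``grid``.

    At each grid value the nuisances are re-optimized, warm-started from the
    global MLE.  The likelihood interval at the requested confidence level
    is read off where the profile crosses ``min_nll + chi2(1).ppf(conf)/2``
    (1.92 log-units at 95%), linearly interpolated between grid points;
    endpoints the grid fails to bracket are flagged open rather than raised.
    """
    grid = np.asarray(sorted(float(g) for g in grid))
    if grid.min() <= 0:
        raise InvalidArgumentError("profile grid values must be > 0")
    if focal not in param_names:
        raise InvalidArgumentError(f"unknown focal parameter {focal!r}")
    fixed = dict(fixed or {})
    if focal in fixed:
        raise InvalidArgumentError(f"focal parameter {focal!r} is fixed")

    if global_fit is None:
        global_fit = fit_mle(tree, data, builder, space, param_names,
                             fixed=fixed, root=root, model_name=model_name,
                             options=options, seed=seed)
    warm = global_fit.params()
    nuisance_names = [n for n in global_fit.free_names if n != focal]

    profile = np.empty(len(grid))
    for k, value in enumerate(grid):
        point = fit_mle(
            tree, data, builder, space, param_names,
            init={n: warm[n] for n in nuisance_names},
            fixed={**fixed, focal: value}, root=root, model_name=model_name,
            options={"restarts": 0, **(dict(options or {}))}, seed=seed)
        profile[k] = point.nll

    min_nll = min(float(global_fit.nll), float(profile.min()))
    level = min_nll + scipy.stats.chi2.ppf(confidence, 1) / 2.0

    lower = upper = None
    open_lower = open_upper = True
    below = profile <= level
    if below.any():
        first, last = int(np.argmax(below)), len(grid) - 1 - int(np.argmax(below[::-1]))
        if first > 0:
            lower = _interp_crossing(grid[first - 1], profile[first - 1],
                                     grid[first], profile[first], level)
            open_lower = False
        if last < len(grid) - 1:
            upper = _interp_crossing(grid[last], profile[last],
                                     grid[last + 1], profile[last + 1], level)
            open_upper = False
    return ProfileCurve(
        focal=focal, grid=grid, nll=profile, min_nll=min_nll,
        confidence=confidence, lower=lower, upper=upper,
        open_lower=open_lower, open_upper=open_upper)
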