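"""Objective functions, simplex fitting and estimation-error metrics.

Fits minimise the residual sum of squares between data and model output,
where the model output is produced by the numerical simulator at the same
discretisation as the data (closed-form recovery formulae are available as
an explicit alternative backend).  Optimisation is Nelder–Mead in
log10-parameter space, which preserves positivity without constraints and
leaves interior optima untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import minimize

from . import analytic
from .core import PARAM_NAMES, PhysicalParams
from .simulate import (ExperimentDesign, RecoveryCurve, SimulationError,
                       SpatialField, build_grid, simulate_frap,
                       simulate_recovery)

__all__ = [
    "FitProblem",
    "FitResult",
    "BatchMetrics",
    "objective_recovery",
    "objective_spatial",
    "fit",
    "estimation_error",
    "batch_metrics",
]

Dataset = Union[RecoveryCurve, SpatialField]

_ANALYTIC_MODELS = {
    "rapid_equilibration": analytic.recovery_rapid_equilibration,
    "reaction_limited": lambda p, r_n, t: analytic.recovery_reaction_limited(p, t),
    "first_order": analytic.recovery_first_order,
    "effective_diffusion": analytic.recovery_effective_diffusion,
}

_LOG_FLOOR = 1e-12  # stands in for exactly-zero parameters in log space


@dataclass(frozen=True)
class FitProblem:
    """Datasets, parameter partition and options of one inverse problem.

    ``datasets`` pairs each recovery curve or spatial field with the
    experiment design that produced it (bleach radius, frames, grid), so
    several bleach radii can be fitted simultaneously.  ``free`` lists the
    parameters being estimated; the rest are pinned at ``fixed`` values.
    ``model`` selects the forward model inside the objective: the numerical
    simulator by default, or one of the closed-form curves
    (rapid_equilibration, reaction_limited, first_order,
    effective_diffusion) as an explicit fast backend.
    """

    datasets: Sequence[Tuple[Dataset, ExperimentDesign]]
    free: Tuple[str, ...] = PARAM_NAMES
    fixed: Dict[str, float] = field(default_factory=dict)
    bounds: Optional[Dict[str, Tuple[float, float]]] = None
    use_sigmas: bool = False
    model: str = "simulator"

    def __post_init__(self) -> None:
        if len(self.datasets) < 1:
            raise ValueError("need at least one dataset")
        names = set(self.free) | set(self.fixed)
        if names != set(PARAM_NAMES) or len(self.free) + len(self.fixed) != 4:
            raise ValueError(
                "free + fixed must partition {D_u, D_v, k_on, k_off}; got "
                f"free={self.free}, fixed={sorted(self.fixed)}")
        if self.bounds is not None:
            for name, (lo, hi) in self.bounds.items():
                if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo < hi):
                    raise ValueError(f"bad bounds for {name}: {(lo, hi)}")
        if self.model != "simulator" and self.model not in _ANALYTIC_MODELS:
            raise ValueError(f"unknown model {self.model!r}")

    def assemble(self, free_values: np.ndarray) -> PhysicalParams:
        """Combine free values (ordered as ``self.free``) with the fixed."""
        d = dict(self.fixed)
        d.update(zip(self.free, free_values))
        return PhysicalParams(**{k: float(d[k]) for k in PARAM_NAMES})


@dataclass(frozen=True)
class FitResult:
    """Outcome of one optimisation run."""

    theta_hat: PhysicalParams
    objective: float
    n_evals: int
    converged: bool
    at_bound: Dict[str, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "theta_hat": self.theta_hat.to_dict(),
            "objective": self.objective,
            "n_evals": self.n_evals,
            "converged": self.converged,
            "at_bound": dict(self.at_bound),
        }


@dataclass(frozen=True)
class BatchMetrics:
    """Aggregated proportional-error metrics over a batch of fits.

    ``mu`` is the mean proportional estimation error per parameter and
    ``f`` the fraction of instances with error below the chosen threshold.
    """

    mu: Dict[str, float]
    f: Dict[str, float]
    threshold: float
    n_run: int


def _model_curve(theta: PhysicalParams, design: ExperimentDesign,
                 model: str) -> np.ndarray:
    if model == "simulator":
        return simulate_recovery(theta, design).values
    return np.asarray(_ANALYTIC_MODELS[model](theta, design.r_n,
                                              design.times))


def objective_recovery(theta: PhysicalParams, problem: FitProblem) -> float:
    """Σ_k Σ_i (F_data − F_model)², optionally weighted by 1/(2σ_i²)."""
    phi = 0.0
    for data, design in problem.datasets:
        if not isinstance(data, RecoveryCurve):
            raise TypeError("objective_recovery expects RecoveryCurve data")
        model = _model_curve(theta, design, problem.model)
        res2 = (data.values - model) ** 2
        if problem.use_sigmas and data.sigmas is not None:
            res2 = res2 / (2.0 * np.asarray(data.sigmas) ** 2)
        phi += float(res2.sum())
    return phi


def objective_spatial(theta: PhysicalParams, problem: FitProblem) -> float:
    """Σ_k Σ_i Σ_j (w_data(r_j, t_i) − w_model(r_j, t_i))²."""
    if problem.model != "simulator":
        raise ValueError("spatial objective requires the simulator model")
    phi = 0.0
    for data, design in problem.datasets:
        if not isinstance(data, SpatialField):
            raise TypeError("objective_spatial expects SpatialField data")
        grid = build_grid(design)
        if data.grid.n != grid.n or not np.isclose(data.grid.dr, grid.dr):
            raise ValueError("data grid does not match the design grid")
        fld = simulate_frap(theta, design)
        phi += float(((data.w - fld.w) ** 2).sum())
    return phi


def _objective(theta: PhysicalParams, problem: FitProblem) -> float:
    phi = 0.0
    for ds in problem.datasets:
        sub = FitProblem(datasets=[ds], free=problem.free,
                         fixed=problem.fixed, use_sigmas=problem.use_sigmas,
                         model=problem.model)
        if isinstance(ds[0], RecoveryCurve):
            phi += objective_recovery(theta, sub)
        else:
            phi += objective_spatial(theta, sub)
    return phi


def _nelder_mead(f, x0: np.ndarray, bounds, maxfev: int, xatol: float,
                 fatol: float):
    """Nelder–Mead with an explicit initial simplex of +0.05 decades.

    scipy's default simplex scales with the coordinate values, which is
    degenerate near log10 θ ≈ 0; a fixed absolute perturbation is the
    appropriate choice in log space.
    """
    n = len(x0)
    simplex = np.tile(x0, (n + 1, 1))
    for i in range(n):
        simplex[i + 1, i] += 0.05
        if bounds is not None:
            simplex[i + 1, i] = min(simplex[i + 1, i], bounds[i][1])
    return minimize(f, x0, method="Nelder-Mead", bounds=bounds,
                    options={"maxfev": maxfev, "xatol": xatol,
                             "fatol": fatol, "initial_simplex": simplex,
                             "adaptive": n > 2})


def fit(problem: FitProblem, guess: PhysicalParams, maxfev: int = 2000,
        xatol: float = 1e-6, fatol: float = 1e-10,
        n_restarts: int = 2, rng=None) -> FitResult:
    """Minimise the fit objective from ``guess`` over the free parameters.

    Runs Nelder–Mead in log10 space (positivity-preserving); when
    ``problem.bounds`` is present the bounds are enforced in log space by
    the optimiser's clipping rule, and parameters finishing within a
    relative distance of 10⁻³ of a bound are flagged in ``at_bound``.  On
    non-convergence the search restarts (up to ``n_restarts`` times) from
    a perturbed best point; the best result found is always returned.
    """
    free = problem.free
    g = np.array([max(getattr(guess, name), _LOG_FLOOR) for name in free])
    x0 = np.log10(g)
    log_bounds = None
    if problem.bounds is not None:
        log_bounds = [tuple(np.log10(problem.bounds[name]))
                      if name in problem.bounds else (-12.0, 12.0)
                      for name in free]
        x0 = np.array([np.clip(x, lo, hi)
                       for x, (lo, hi) in zip(x0, log_bounds)])

    n_evals = 0

    def f(x):
        nonlocal n_evals
        n_evals += 1
        try:
            return _objective(problem.assemble(10.0 ** x), problem)
        except SimulationError:
            return 1e30

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    res = _nelder_mead(f, x0, log_bounds, maxfev, xatol, fatol)
    best = res
    attempts = 0
    while not best.success and attempts < n_restarts:
        attempts += 1
        x_start = best.x + rng.uniform(-0.1, 0.1, size=len(x0))
        if log_bounds is not None:
            x_start = np.array([np.clip(x, lo, hi)
                                for x, (lo, hi) in zip(x_start, log_bounds)])
        res = _nelder_mead(f, x_start, log_bounds, maxfev, xatol, fatol)
        if res.fun < best.fun:
            best = res

    theta_hat = problem.assemble(10.0 ** best.x)
    at_bound: Dict[str, bool] = {}
    if problem.bounds is not None:
        for name, x, (lo, hi) in zip(free, best.x, log_bounds):
            val = 10.0 ** x
            blo, bhi = 10.0 ** lo, 10.0 ** hi
            at_bound[name] = bool(abs(val - blo) <= 1e-3 * blo
                                  or abs(val - bhi) <= 1e-3 * bhi)
    return FitResult(theta_hat=theta_hat, objective=float(best.fun),
                     n_evals=n_evals, converged=bool(best.success),
                     at_bound=at_bound)


def estimation_error(theta_hat: PhysicalParams,
                     truth: PhysicalParams) -> Dict[str, float]:
    """Proportional estimation error |θ̂ − θ|/θ per parameter.

    Parameters whose true value is zero (possible for D_v, since the
    sampling protocol allows δ = 0) have no proportional error; they are
    reported as NaN with a warning and excluded from aggregates.
    """
    out = {}
    for name in PARAM_NAMES:
        t = getattr(truth, name)
        h = getattr(theta_hat, name)
        if t == 0:
            warnings.warn(f"true {name} is zero; proportional error "
                          "undefined, reporting NaN")
            out[name] = float("nan")
        else:
            out[name] = abs(h - t) / t
    return out


def batch_metrics(errors: List[Dict[str, float]],
                  threshold: float = 0.01) -> BatchMetrics:
    """Mean error μ_l and success fraction f_l(μ) over a batch.

    NaN entries (failed instances or undefined errors) count against
    f_l — they are never below the threshold — and are excluded from the
    mean.
    """
    if not errors:
        raise ValueError("empty error list")
    names = sorted({k for e in errors for k in e})
    mu, f = {}, {}
    for name in names:
        vals = np.array([e.get(name, np.nan) for e in errors], dtype=float)
        finite = vals[np.isfinite(vals)]
        mu[name] = float(finite.mean()) if len(finite) else float("nan")
        f[name] = float(np.sum(vals < threshold)) / len(vals)
    return BatchMetrics(mu=mu, f=f, threshold=threshold, n_run=len(errors))
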