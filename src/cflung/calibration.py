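"""Calibration of the disease model against an observed average-FVC
trajectory, and one-at-a-time sensitivity analysis.

The objective is the mean squared percent error (MSPE) between the
replicate-mean simulated percent functional volume and the observed mean
percent-predicted FVC on the age grid 18-50 (33 ages):

    PE(t)   = 100 * (model(t) - observed(t)) / observed(t)
    MSPE    = mean_t PE(t)^2

Minimization uses the derivative-free Nelder-Mead simplex on
log-transformed parameters, with common random numbers across objective
evaluations so the stochastic objective behaves quasi-deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .geometry import AirwayTree
from .model import FvcTrajectory, SimParams, simulate

__all__ = [
    "FitSpec",
    "FitResult",
    "SensitivityRow",
    "DEFAULT_FREE_PARAMETERS",
    "DEFAULT_AGES",
    "mean_and_se",
    "percent_error",
    "mspe",
    "model_trajectory_by_age",
    "fit",
    "sensitivity",
]

DEFAULT_FREE_PARAMETERS = ("P_c", "v_c", "T_s", "v_s")
DEFAULT_AGES = tuple(range(18, 51))


def mean_and_se(trajectories) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and dispersion of a replicate set.

    The dispersion is the root-mean-square deviation from the pointwise
    mean with divisor equal to the number of replicates (not ``n - 1``).
    Accepts an :class:`FvcTrajectory` or a 2-D array (replicates x time).
    """
    if isinstance(trajectories, FvcTrajectory):
        values = trajectories.values
    else:
        values = np.asarray(trajectories, dtype=float)
        if values.ndim != 2:
            raise ValueError("expected a 2-D replicates-by-time array")
    mean = values.mean(axis=0)
    dev = values - mean
    se = np.sqrt(np.mean(dev * dev, axis=0))
    return mean, se


def percent_error(model: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Per-age percent error ``100 * (model - observed) / observed``."""
    model = np.asarray(model, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if model.shape != observed.shape:
        raise ValueError(
            f"model and observed grids differ: {model.shape} vs {observed.shape}"
        )
    if np.any(observed == 0):
        raise ValueError("observed trajectory contains zeros; percent error undefined")
    return 100.0 * (model - observed) / observed


def mspe(model: np.ndarray, observed: np.ndarray) -> float:
    """Mean of squared percent errors over the (matched) age grid."""
    pe = percent_error(model, observed)
    return float(np.mean(pe * pe))


def model_trajectory_by_age(traj: FvcTrajectory,
                            ages: Sequence[int] = DEFAULT_AGES) -> np.ndarray:
    """Replicate-mean percent functional volume sampled at integer ages."""
    return traj.at_ages(ages)


@dataclass(frozen=True)
class FitSpec:
    """Controls for :func:`fit`.

    ``n_replicates`` simulations are averaged per objective evaluation,
    always with the same replicate seeds (common random numbers).
    """

    free_parameters: tuple[str, ...] = DEFAULT_FREE_PARAMETERS
    n_replicates: int = 20
    max_iterations: int = 200
    xatol: float = 1e-3
    fatol: float = 1e-3
    initial_step: float = 0.02  # relative simplex displacement per parameter
    seed: int = 12345
    ages: tuple[int, ...] = DEFAULT_AGES


@dataclass
class FitResult:
    params: SimParams
    mspe: float
    n_iterations: int
    n_evaluations: int
    converged: bool
    trace: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "params": {k: getattr(self.params, k)
                       for k in ("P_c", "v_c", "T_s", "v_s", "S_star", "alpha")},
            "mspe": self.mspe,
            "n_iterations": self.n_iterations,
            "n_evaluations": self.n_evaluations,
            "converged": self.converged,
            "trace": self.trace,
        }


@dataclass(frozen=True)
class SensitivityRow:
    parameter: str
    value: float
    unit: str
    perturbation: float
    mspe_variation_pct: float
    absolute_change: bool = False


_UNITS = {"P_c": "mm^-2/month", "v_c": "mm^3/month",
          "T_s": "month", "v_s": "scars/month"}


def _evaluate(params: SimParams, tree: AirwayTree, observed: np.ndarray,
              spec: FitSpec) -> float:
    traj = simulate(params.with_(seed=spec.seed), tree, spec.n_replicates)
    model = model_trajectory_by_age(traj, spec.ages)
    return mspe(model, observed)


def _check_observed(observed, ages) -> np.ndarray:
    if isinstance(observed, pd.DataFrame):
        frame = observed.set_index(observed["age_years"].astype(int))
        missing = [a for a in ages if a not in frame.index]
        if missing:
            raise ValueError(f"observed trajectory lacks ages {missing}")
        values = frame.loc[list(ages), "mean_fvc_pct"].to_numpy(dtype=float)
    else:
        values = np.asarray(observed, dtype=float)
        if values.shape != (len(ages),):
            raise ValueError(
                f"observed trajectory must cover ages {ages[0]}..{ages[-1]}"
            )
    if np.any(~np.isfinite(values)) or np.any(values == 0):
        raise ValueError("observed trajectory has missing or zero entries")
    return values


def fit(observed, initial_params: SimParams, tree: AirwayTree,
        spec: FitSpec = FitSpec()) -> FitResult:
    """Nelder-Mead minimization of the MSPE over the free parameters.

    ``observed`` is either a frame with columns ``age_years``/``mean_fvc_pct``
    covering the fit ages, or an array on that grid.  Parameters are
    optimized on the log scale (all are positive rates/delays spanning
    orders of magnitude) and reported on the natural scale.  A non-finite
    objective value is returned to the simplex as a large penalty rather
    than raising.
    """
    observed_vals = _check_observed(observed, spec.ages)
    free = tuple(spec.free_parameters)
    for name in free:
        if getattr(initial_params, name) <= 0:
            raise ValueError(f"initial {name} must be positive for log-scale fit")
    x0 = np.log([getattr(initial_params, name) for name in free])
    trace: list[dict] = []

    def objective(x: np.ndarray) -> float:
        values = dict(zip(free, np.exp(x)))
        try:
            params = initial_params.with_(**values)
            value = _evaluate(params, tree, observed_vals, spec)
        except (ValueError, FloatingPointError):
            value = np.inf
        if not np.isfinite(value):
            value = 1e12
        trace.append({"params": values, "mspe": value})
        return value

    simplex = np.vstack([x0] + [x0 + spec.initial_step * e
                                for e in np.eye(len(free))])
    res = optimize.minimize(
        objective, x0, method="Nelder-Mead",
        options={
            "maxiter": spec.max_iterations,
            "xatol": spec.xatol,
            "fatol": spec.fatol,
            "initial_simplex": simplex,
            "adaptive": False,
        },
    )
    best = initial_params.with_(**dict(zip(free, np.exp(res.x))))
    return FitResult(
        params=best,
        mspe=float(res.fun),
        n_iterations=int(res.nit),
        n_evaluations=int(res.nfev),
        converged=bool(res.success),
        trace=trace,
    )


def sensitivity(params: SimParams, observed, tree: AirwayTree,
                perturbation: float = 0.01,
                parameters: Sequence[str] = DEFAULT_FREE_PARAMETERS,
                spec: FitSpec = FitSpec()) -> list[SensitivityRow]:
    """One-at-a-time sensitivity: percent change of MSPE for a +1% change
    in each parameter, all others held at their baseline values.

    Objective evaluations share replicate seeds (common random numbers).
    If the baseline MSPE is zero, the absolute MSPE change is reported
    instead and flagged.
    """
    if perturbation < 0:
        raise ValueError("perturbation must be non-negative")
    observed_vals = _check_observed(observed, spec.ages)
    base = _evaluate(params, tree, observed_vals, spec)
    rows = []
    for name in parameters:
        value = getattr(params, name)
        perturbed = _evaluate(params.with_(**{name: value * (1 + perturbation)}),
                              tree, observed_vals, spec)
        if base > 0:
            rows.append(SensitivityRow(name, value, _UNITS.get(name, ""),
                                       perturbation,
                                       100.0 * (perturbed - base) / base))
        else:
            rows.append(SensitivityRow(name, value, _UNITS.get(name, ""),
                                       perturbation, perturbed - base,
                                       absolute_change=True))
    return rows
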