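"""Competing kinetic models for enzyme temperature optima.

Two macroscopic models can both produce a curved Arrhenius plot and a rate
maximum below the melting temperature:

* the **two-state dead-end model**: the Michaelis complex ES is in a
  temperature-dependent equilibrium (``Keq``) with an unreactive state
  ES', so ``kcat = k3 / (1 + Keq)``.  A large positive ``dHeq`` balanced
  by a large positive ``dSeq`` switches the population near a crossover
  temperature and shuts the enzyme down above it.

* the **activation heat-capacity model**: a constant negative ``dCp``
  between transition state and ground state makes ``dH(T)`` and ``dS(T)``
  temperature dependent, curving the Arrhenius plot even for a one-state
  mechanism.

Both are evaluated, differentiated into apparent activation parameters,
and fitted here by weighted nonlinear least squares with a multistart
strategy; within a measured temperature window the two fitted curves are
typically indistinguishable, and only their extrapolations (or independent
structural evidence) discriminate them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .thermokinetics import (
    DEFAULT_CONSTANTS,
    ActivationParameters,
    BarrierSeries,
    Constants,
    RateSeries,
    barrier_to_rate,
    barriers_from_rates,
)


@dataclass(frozen=True)
class TwoStateParams:
    """Parameters of the dead-end model: chemical step (dH3, dS3) and
    ES<->ES' equilibrium (dHeq, dSeq).  Units kcal/mol and kcal/mol/K."""

    dH3: float
    dS3: float
    dHeq: float
    dSeq: float

    def flipped(self) -> "TwoStateParams":
        """The sign-degenerate twin obtained by negating dHeq and dSeq.

        The twin fits rate data exactly as well (1+Keq and 1+1/Keq differ
        by a factor Keq that is absorbed into the chemical step), but it
        implies a large negative activation enthalpy and the wrong sign of
        the equilibrium thermodynamics.
        """
        return TwoStateParams(
            dH3=self.dH3 - self.dHeq,
            dS3=self.dS3 - self.dSeq,
            dHeq=-self.dHeq,
            dSeq=-self.dSeq,
        )


@dataclass(frozen=True)
class HeatCapacityParams:
    """Activation heat-capacity model: dH0/dS0 at T0 plus constant dCp."""

    dH0: float
    dS0: float
    dCp: float
    T0: float = 298.0

    def __post_init__(self) -> None:
        if self.T0 <= 0:
            raise ValueError("reference temperature must be positive")


@dataclass(frozen=True)
class ApparentParameters:
    """Apparent activation parameters of the two-state model at one T."""

    T: float
    dHapp: float
    dSapp: float
    dCpapp: float


def _check_T(T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive")
    return T


def two_state_ln_keq(T, p: TwoStateParams, R: float = DEFAULT_CONSTANTS.R):
    """ln Keq = -(dHeq - T*dSeq)/(R*T); the log-domain workhorse."""
    T = _check_T(T)
    out = -(p.dHeq - T * p.dSeq) / (R * T)
    return out if out.shape else float(out)


def two_state_keq(T, p: TwoStateParams, R: float = DEFAULT_CONSTANTS.R):
    """Equilibrium constant of ES <-> ES' at temperature T."""
    out = np.exp(two_state_ln_keq(T, p, R))
    return out if np.shape(out) else float(out)


def two_state_barrier(T, p: TwoStateParams, R: float = DEFAULT_CONSTANTS.R):
    """Apparent activation free energy dG3 + R*T*ln(1+Keq) (log-safe)."""
    T = _check_T(T)
    ln_keq = -(p.dHeq - T * p.dSeq) / (R * T)
    out = p.dH3 - T * p.dS3 + R * T * np.logaddexp(0.0, ln_keq)
    return out if out.shape else float(out)


def two_state_kcat(T, p: TwoStateParams, constants: Constants = DEFAULT_CONSTANTS):
    """kcat = k3/(1+Keq), evaluated via the apparent barrier."""
    return barrier_to_rate(two_state_barrier(T, p, constants.R), T, constants)


def es_prime_fraction(T, p: TwoStateParams, R: float = DEFAULT_CONSTANTS.R):
    """Fractional population Phi = Keq/(1+Keq) of the dead-end state."""
    ln_keq = two_state_ln_keq(T, p, R)
    out = 1.0 / (1.0 + np.exp(-np.asarray(ln_keq)))
    return out if out.shape else float(out)


def apparent_parameters(
    T: float, p: TwoStateParams, R: float = DEFAULT_CONSTANTS.R
) -> ApparentParameters:
    """Apparent dH, dS and dCp of the two-state model at temperature T.

    dHapp = dH3 - Phi*dHeq and dSapp = dS3 - Phi*dSeq, with
    Phi = Keq/(1+Keq).  The apparent heat capacity is the exact
    temperature derivative of dHapp: dCpapp = -dHeq^2 * Phi*(1-Phi)/(R*T^2),
    nonpositive everywhere and peaked (in magnitude) where the population
    switches.
    """
    Tf = float(_check_T(T))
    phi = es_prime_fraction(Tf, p, R)
    dHapp = p.dH3 - phi * p.dHeq
    dSapp = p.dS3 - phi * p.dSeq
    dCpapp = -(p.dHeq**2) * phi * (1.0 - phi) / (R * Tf**2)
    return ApparentParameters(T=Tf, dHapp=dHapp, dSapp=dSapp, dCpapp=dCpapp)


def apparent_cp_curve(
    p: TwoStateParams, Tgrid, R: float = DEFAULT_CONSTANTS.R
) -> list[ApparentParameters]:
    """Apparent activation parameters over a temperature grid."""
    return [apparent_parameters(float(T), p, R) for T in np.asarray(Tgrid, float)]


def heat_capacity_barrier(T, p: HeatCapacityParams):
    """(dH(T), dS(T), dG(T)) of the heat-capacity model.

    dH(T) = dH0 + dCp*(T-T0); dS(T) = dS0 + dCp*ln(T/T0); dG = dH - T*dS.
    """
    T = _check_T(T)
    dH = p.dH0 + p.dCp * (T - p.T0)
    dS = p.dS0 + p.dCp * np.log(T / p.T0)
    dG = dH - T * dS
    if T.shape:
        return dH, dS, dG
    return float(dH), float(dS), float(dG)


def heat_capacity_enthalpy(T, p: HeatCapacityParams):
    """dH(T) alone; defined for T >= 0 (no log term)."""
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise ValueError("temperature must be nonnegative")
    out = p.dH0 + p.dCp * (T - p.T0)
    return out if out.shape else float(out)


def heat_capacity_kcat(T, p: HeatCapacityParams, constants: Constants = DEFAULT_CONSTANTS):
    """Eyring rate with the temperature-dependent dG(T) of the dCp model."""
    _, _, dG = heat_capacity_barrier(T, p)
    return barrier_to_rate(dG, T, constants)


ModelParams = Union[TwoStateParams, HeatCapacityParams, ActivationParameters]


def model_barrier(T, params: ModelParams, R: float = DEFAULT_CONSTANTS.R):
    """Dispatch dG(T) for any of the three supported barrier models."""
    if isinstance(params, TwoStateParams):
        return two_state_barrier(T, params, R)
    if isinstance(params, HeatCapacityParams):
        return heat_capacity_barrier(T, params)[2]
    if isinstance(params, ActivationParameters):
        return params.barrier(T)
    raise TypeError(f"unsupported parameter type {type(params).__name__}")


def model_rate(T, params: ModelParams, constants: Constants = DEFAULT_CONSTANTS):
    """Eyring rate of any supported model at temperature T."""
    return barrier_to_rate(model_barrier(T, params, constants.R), T, constants)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """Outcome of a weighted nonlinear least-squares model fit."""

    params: ModelParams
    covariance: np.ndarray
    residuals: np.ndarray
    wrss: float
    objective: str
    accepted: bool
    rejection_reason: Optional[str]
    identifiable: bool
    condition_number: float
    n_starts: int


def _to_barriers(data, constants: Constants) -> BarrierSeries:
    if isinstance(data, BarrierSeries):
        return data
    if isinstance(data, RateSeries):
        return barriers_from_rates(data, constants)
    raise TypeError("data must be a BarrierSeries or RateSeries")


def _fit_weights(series: BarrierSeries, objective: str, R: float):
    # Uncertainty of dG/T is sem/T; of ln k it is sem/(R*T).
    if series.has_sem:
        sem = np.where(series.sem > 0, series.sem, series.sem[series.sem > 0].min())
    else:
        sem = np.ones_like(series.T)
    if objective == "gibbs_over_T":
        return 1.0 / (sem / series.T)
    if objective == "log_rate":
        return 1.0 / (sem / (R * series.T))
    raise ValueError(f"unknown objective {objective!r}")


def _observed(series: BarrierSeries, objective: str, constants: Constants):
    if objective == "gibbs_over_T":
        return series.dG / series.T
    return np.log(barrier_to_rate(series.dG, series.T, constants))


def _predicted(T, params: ModelParams, objective: str, constants: Constants):
    dG = model_barrier(T, params, constants.R)
    if objective == "gibbs_over_T":
        return dG / T
    return np.log(barrier_to_rate(dG, T, constants))


def _linear_subfit_two_state(series, w, dHeq, dSeq, R):
    """Exact WLS solve for (dH3, dS3) given the equilibrium parameters.

    In dG/T space the two-state model is dH3*(1/T) - dS3 + R*softplus(lnKeq),
    linear in the chemical-step parameters.
    """
    T = series.T
    ln_keq = -(dHeq - T * dSeq) / (R * T)
    offset = R * np.logaddexp(0.0, ln_keq)
    y = series.dG / T - offset
    x = 1.0 / T
    A = np.column_stack([x, -np.ones_like(x)])
    sw = np.sqrt(w) if w is not None else np.ones_like(x)
    sol, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
    return float(sol[0]), float(sol[1])


def _linear_subfit_heat_capacity(series, w, dCp, T0):
    """Exact WLS solve for (dH0, dS0) given dCp (model linear in them)."""
    T = series.T
    y = series.dG / T - dCp * (T - T0) / T + dCp * np.log(T / T0)
    A = np.column_stack([1.0 / T, -np.ones_like(T)])
    sw = np.sqrt(w) if w is not None else np.ones_like(T)
    sol, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
    return float(sol[0]), float(sol[1])


_TWO_STATE_BOUNDS = ([-100.0, -1.0, 0.0, 0.0], [100.0, 1.0, 200.0, 1.0])
_HEAT_CAP_BOUNDS = ([-200.0, -2.0, -20.0], [200.0, 2.0, 0.0])


def reject_sign_degenerate(
    params: TwoStateParams,
    T_range: tuple[float, float] = (278.0, 313.0),
    R: float = DEFAULT_CONSTANTS.R,
) -> tuple[bool, Optional[str]]:
    """Physical-branch screen for fitted two-state parameters.

    Rejects the sign-degenerate twin (negative dHeq/dSeq), the degenerate
    no-transition case, and solutions whose chemical step has a large
    negative activation enthalpy (dH3 < -R*T over the data range).
    """
    if params.dHeq < 0 or params.dSeq < 0:
        return False, "wrong sign of dHeq and dSeq"
    if params.dHeq == 0:
        return False, "degenerate equilibrium (dHeq = 0): no population transition"
    if params.dH3 < -R * max(T_range):
        return False, "negative activation enthalpy for the chemical step"
    return True, None


def fit_model(
    data,
    which: str,
    init: Optional[ModelParams] = None,
    bounds=None,
    objective: str = "gibbs_over_T",
    constants: Constants = DEFAULT_CONSTANTS,
    T0: float = 298.0,
    weighted: bool = True,
) -> FitResult:
    """Fit the two-state or heat-capacity model to barrier or rate data.

    Weighted nonlinear least squares on ``dG/T`` (default, mirroring the
    Arrhenius-space presentation) or on ``ln k``; exact data gives the
    same optimum either way.  A multistart over equilibrium-parameter
    guesses — with the two linear parameters solved exactly per start —
    guards against local minima; among converged starts the best solution
    on the physical branch is returned.
    """
    series = _to_barriers(data, constants)
    n = len(series)
    n_par = 4 if which == "two_state" else 3
    min_n = 5 if which == "two_state" else 4
    if n < min_n:
        raise ValueError(f"{which} fit requires at least {min_n} points")
    w = _fit_weights(series, objective, constants.R) if weighted else np.ones(n)
    y = _observed(series, objective, constants)
    T = series.T

    def residuals(theta):
        p = _unpack(theta)
        return (_predicted(T, p, objective, constants) - y) * w

    if which == "two_state":
        def _unpack(theta):
            return TwoStateParams(*theta)

        starts = []
        if init is not None:
            starts.append([init.dH3, init.dS3, init.dHeq, init.dSeq])
        for dHeq in (10.0, 20.0, 30.0, 40.0):
            for Tc in T:  # entropy seeded from a Keq=1 crossing at each grid T
                dSeq = dHeq / Tc
                dH3, dS3 = _linear_subfit_two_state(series, w**2, dHeq, dSeq, constants.R)
                starts.append([dH3, dS3, dHeq, dSeq])
        lo, hi = bounds if bounds is not None else _TWO_STATE_BOUNDS
    elif which == "heat_capacity":
        def _unpack(theta):
            return HeatCapacityParams(theta[0], theta[1], theta[2], T0)

        starts = []
        if init is not None:
            starts.append([init.dH0, init.dS0, init.dCp])
        for dCp in (0.0, -0.25, -0.5, -1.0, -2.0, -4.0):
            dH0, dS0 = _linear_subfit_heat_capacity(series, w**2, dCp, T0)
            starts.append([dH0, dS0, dCp])
        lo, hi = bounds if bounds is not None else _HEAT_CAP_BOUNDS
    else:
        raise ValueError(f"unknown model {which!r}")

    best = None
    best_any = None
    for x0 in starts:
        x0c = np.clip(x0, lo, hi)
        try:
            sol = least_squares(residuals, x0c, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if not sol.success and not np.isfinite(sol.cost):
            continue
        p = _unpack(sol.x)
        if which == "two_state":
            ok, reason = reject_sign_degenerate(p, (T.min(), T.max()), constants.R)
        else:
            ok, reason = True, None
        entry = (sol.cost, sol, p, ok, reason)
        if best_any is None or sol.cost < best_any[0]:
            best_any = entry
        if ok and (best is None or sol.cost < best[0]):
            best = entry
    chosen = best if best is not None else best_any
    if chosen is None:
        raise RuntimeError("model fit failed to converge from any start")
    cost, sol, p, ok, reason = chosen

    J = sol.jac
    dof = max(n - n_par, 1)
    s2 = 2.0 * sol.cost / dof
    JTJ = J.T @ J
    cond = float(np.linalg.cond(JTJ)) if np.all(np.isfinite(JTJ)) else math.inf
    cov = s2 * np.linalg.pinv(JTJ)
    identifiable = bool(np.isfinite(cond) and cond < 1e10)

    return FitResult(
        params=p,
        covariance=cov,
        residuals=sol.fun / np.where(w == 0, 1.0, w),
        wrss=float(2.0 * sol.cost),
        objective=objective,
        accepted=ok,
        rejection_reason=reason,
        identifiable=identifiable,
        condition_number=cond,
        n_starts=len(starts),
    )


def optimum_temperature(
    params: ModelParams,
    Trange: tuple[float, float] = (270.0, 320.0),
    constants: Constants = DEFAULT_CONSTANTS,
    grid_step: float = 0.5,
) -> Optional[float]:
    """Locate the interior rate maximum of a model on a temperature range.

    A coarse grid bracket followed by bounded scalar minimization of
    ``-ln k``; returns None when the rate is monotone on the range (the
    argmax sits at a boundary).
    """
    lo, hi = Trange
    if not (0 < lo < hi):
        raise ValueError("invalid temperature range")
    grid = np.arange(lo, hi + grid_step, grid_step)
    grid = grid[grid <= hi]
    lnk = np.log(model_rate(grid, params, constants))
    i = int(np.argmax(lnk))
    if i == 0 or i == grid.size - 1:
        return None
    bracket = (grid[i - 1], grid[i + 1])
    res = minimize_scalar(
        lambda T: -np.log(model_rate(float(T), params, constants)),
        bounds=bracket,
        method="bounded",
        options={"xatol": 1e-4},
    )
    Topt = float(res.x)
    if Topt - lo < 1e-3 or hi - Topt < 1e-3:
        return None
    return Topt


def heat_capacity_optimum(p: HeatCapacityParams, R: float = DEFAULT_CONSTANTS.R) -> Optional[float]:
    """Closed-form optimum of the dCp model: the root of dH(T) = -R*T."""
    denom = p.dCp + R
    if denom == 0:
        return None
    T = (p.dCp * p.T0 - p.dH0) / denom
    return float(T) if T > 0 else None
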