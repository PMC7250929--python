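"""Transition-state-theory conversions and Arrhenius decomposition.

Rates and activation free energies are interconverted through the Eyring
form ``k = C * T * exp(-dG / (R * T))`` with energies in kcal/mol and
temperatures in kelvin.  Activation enthalpies and entropies are obtained
from (optionally sem-weighted) linear regression of ``dG/T`` against
``1/T``: the slope is ``dH`` and the intercept ``-dS``.  A piecewise
variant searches exhaustively for a single breakpoint, the signature of a
population transition in the underlying kinetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.9872e-3

#: Boltzmann constant over Planck constant, s^-1 K^-1 (2018 SI values).
KB_OVER_H = 1.380649e-23 / 6.62607015e-34


@dataclass(frozen=True)
class Constants:
    """Physical constants and rate-reporting conventions.

    In ``relative`` mode (the default) rates are reported as ratios to the
    Eyring rate at ``(Tref, dG_ref)``; the prefactor ``C`` cancels.  In
    ``absolute`` mode rates are ``C * T * exp(-dG/(R*T))`` in s^-1 with
    ``C = kB/h`` unless overridden.
    """

    R: float = R_KCAL
    prefactor_mode: str = "relative"
    C: float = KB_OVER_H
    Tref: float = 298.15
    dG_ref: float = 0.0

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("gas constant must be positive")
        if self.prefactor_mode not in ("relative", "absolute"):
            raise ValueError(f"unknown prefactor mode {self.prefactor_mode!r}")

    @property
    def reference_rate(self) -> float:
        """Eyring rate (with C=1) at the reference point."""
        return self.Tref * math.exp(-self.dG_ref / (self.R * self.Tref))


DEFAULT_CONSTANTS = Constants()


@dataclass(frozen=True)
class ActivationParameters:
    """Temperature-independent activation enthalpy/entropy pair.

    ``dH`` in kcal/mol, ``dS`` in kcal/mol/K; ``Tref`` is only used when
    displaying the T*dS product.
    """

    dH: float
    dS: float
    Tref: float = 298.15

    def barrier(self, T):
        """Activation free energy dG = dH - T*dS at temperature ``T``."""
        return self.dH - np.asarray(T, dtype=float) * self.dS

    def t_dS(self, T: Optional[float] = None) -> float:
        """The T*dS term (kcal/mol) at ``T`` (default ``Tref``)."""
        T = self.Tref if T is None else T
        return T * self.dS


def _as_sorted_arrays(T, value, sem):
    T = np.asarray(T, dtype=float)
    value = np.asarray(value, dtype=float)
    if sem is None:
        sem = np.zeros_like(T)
    sem = np.asarray(sem, dtype=float)
    if not (T.shape == value.shape == sem.shape):
        raise ValueError("temperature, value and sem must have equal length")
    return T, value, sem


@dataclass(frozen=True)
class BarrierSeries:
    """Activation free energies dG (kcal/mol) with s.e.m., on a T grid (K)."""

    T: np.ndarray
    dG: np.ndarray
    sem: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        T, dG, sem = _as_sorted_arrays(self.T, self.dG, self.sem)
        if T.size and np.any(T <= 0):
            raise ValueError("temperatures must be positive (kelvin)")
        if np.any(np.diff(T) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any(sem < 0):
            raise ValueError("sem must be nonnegative")
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "dG", dG)
        object.__setattr__(self, "sem", sem)

    def __len__(self) -> int:
        return int(self.T.size)

    @classmethod
    def from_entries(cls, entries: Sequence) -> "BarrierSeries":
        """Build from an iterable of (T, dG[, sem]) tuples."""
        rows = [tuple(e) for e in entries]
        T = [r[0] for r in rows]
        dG = [r[1] for r in rows]
        sem = [r[2] if len(r) > 2 else 0.0 for r in rows]
        return cls(np.array(T, float), np.array(dG, float), np.array(sem, float))

    @property
    def has_sem(self) -> bool:
        return bool(np.any(self.sem > 0))


@dataclass(frozen=True)
class RateSeries:
    """Rate constants over temperature; relative or absolute per Constants."""

    T: np.ndarray
    k: np.ndarray
    sem: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        T, k, sem = _as_sorted_arrays(self.T, self.k, self.sem)
        if T.size and np.any(T <= 0):
            raise ValueError("temperatures must be positive (kelvin)")
        if np.any(np.diff(T) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any(k <= 0):
            raise ValueError("rates must be positive")
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "sem", sem)

    def __len__(self) -> int:
        return int(self.T.size)


def barrier_to_rate(dG, T, constants: Constants = DEFAULT_CONSTANTS):
    """Eyring rate for barrier ``dG`` (kcal/mol) at ``T`` (K).

    Relative mode normalizes by the rate at the reference point of
    ``constants``; absolute mode multiplies by the TST prefactor ``C``.
    """
    T = np.asarray(T, dtype=float)
    dG = np.asarray(dG, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive")
    raw = T * np.exp(-dG / (constants.R * T))
    if constants.prefactor_mode == "relative":
        out = raw / constants.reference_rate
    else:
        out = constants.C * raw
    return out if out.shape else float(out)


def rate_to_barrier(k, T, constants: Constants = DEFAULT_CONSTANTS):
    """Exact inverse of :func:`barrier_to_rate`."""
    T = np.asarray(T, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive")
    if np.any(k <= 0):
        raise ValueError("rate must be positive for barrier inversion")
    if constants.prefactor_mode == "relative":
        raw = k * constants.reference_rate
    else:
        raw = k / constants.C
    out = -constants.R * T * np.log(raw / T)
    return out if out.shape else float(out)


@dataclass(frozen=True)
class ArrheniusFit:
    """Result of a (weighted) linear fit of dG/T against 1/T."""

    params: ActivationParameters
    r_squared: float
    wrss: float
    dH_se: float = float("nan")
    dS_se: float = float("nan")
    weighted: bool = False
    n_points: int = 0


def _wls_line(x, y, w):
    """Weighted least-squares line fit; returns slope, intercept, wrss, r2, ses."""
    W = np.sum(w)
    xm = np.sum(w * x) / W
    ym = np.sum(w * y) / W
    sxx = np.sum(w * (x - xm) ** 2)
    if sxx <= 0:
        raise ValueError("all temperatures equal; cannot fit a line")
    sxy = np.sum(w * (x - xm) * (y - ym))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    wrss = float(np.sum(w * resid**2))
    sst = float(np.sum(w * (y - ym) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - wrss / sst
    n = x.size
    if n > 2 and wrss > 0:
        s2 = wrss / (n - 2)
        slope_se = math.sqrt(s2 / sxx)
        inter_se = math.sqrt(s2 * (1.0 / W + xm**2 / sxx))
    else:
        slope_se = inter_se = 0.0
    return slope, intercept, wrss, r2, slope_se, inter_se


def _weights(series: BarrierSeries, weighted: Optional[bool]):
    if weighted is None:
        weighted = series.has_sem
    if weighted and series.has_sem:
        # y = dG/T, so the y-uncertainty is sem/T.
        sem_y = series.sem / series.T
        floor = max(sem_y[sem_y > 0].min() if np.any(sem_y > 0) else 1.0, 1e-12)
        sem_y = np.where(sem_y > 0, sem_y, floor)
        return 1.0 / sem_y**2, True
    return np.ones_like(series.T), False


def fit_arrhenius(series: BarrierSeries, weighted: Optional[bool] = None) -> ArrheniusFit:
    """Linear Arrhenius decomposition of a barrier series.

    Regresses ``dG/T`` on ``1/T``; slope is ``dH`` and intercept ``-dS``.
    Weights default to ``1/sem^2`` (propagated to dG/T) when s.e.m. values
    are present, and to uniform otherwise.
    """
    if len(series) < 3:
        raise ValueError("Arrhenius fit requires at least 3 points")
    w, used_w = _weights(series, weighted)
    x = 1.0 / series.T
    y = series.dG / series.T
    slope, intercept, wrss, r2, slope_se, inter_se = _wls_line(x, y, w)
    params = ActivationParameters(dH=slope, dS=-intercept)
    return ArrheniusFit(
        params=params,
        r_squared=r2,
        wrss=wrss,
        dH_se=slope_se,
        dS_se=inter_se,
        weighted=used_w,
        n_points=len(series),
    )


@dataclass(frozen=True)
class PiecewiseArrheniusFit:
    """Two-segment Arrhenius fit with an exhaustively searched breakpoint.

    ``breakpoint`` is None when the single line is preferred; otherwise it
    is the data temperature shared by the two segments.  ``selection_score``
    is the ratio of single-line to two-segment weighted RSS (larger means
    the break is better supported).
    """

    low: ArrheniusFit
    high: ArrheniusFit
    single: ArrheniusFit
    breakpoint: Optional[float]
    selection_score: float
    accepted: bool


def fit_piecewise_arrhenius(
    series: BarrierSeries,
    weighted: Optional[bool] = None,
    improvement_factor: float = 4.0,
    min_segment_points: int = 3,
) -> PiecewiseArrheniusFit:
    """Exhaustive one-breakpoint Arrhenius fit.

    Every interior data temperature leaving at least ``min_segment_points``
    on each side (the breakpoint itself is shared) is tried; the candidate
    minimizing the summed weighted RSS wins.  The broken model is accepted
    only when the single-line weighted RSS exceeds ``improvement_factor``
    times the two-segment one.
    """
    n = len(series)
    if n < 2 * min_segment_points:
        raise ValueError(
            f"piecewise fit needs at least {2 * min_segment_points} points, got {n}"
        )
    single = fit_arrhenius(series, weighted)
    best = None
    for i in range(min_segment_points - 1, n - min_segment_points + 1):
        lo = BarrierSeries(series.T[: i + 1], series.dG[: i + 1], series.sem[: i + 1])
        hi = BarrierSeries(series.T[i:], series.dG[i:], series.sem[i:])
        f_lo = fit_arrhenius(lo, weighted)
        f_hi = fit_arrhenius(hi, weighted)
        wrss = f_lo.wrss + f_hi.wrss
        if best is None or wrss < best[0]:
            best = (wrss, float(series.T[i]), f_lo, f_hi)
    wrss_two, T_break, f_lo, f_hi = best
    if wrss_two <= 0:
        score = math.inf if single.wrss > 0 else 0.0
    else:
        score = single.wrss / wrss_two
    accepted = score > improvement_factor and single.wrss > 1e-18
    return PiecewiseArrheniusFit(
        low=f_lo,
        high=f_hi,
        single=single,
        breakpoint=T_break if accepted else None,
        selection_score=score,
        accepted=accepted,
    )


def rates_from_barriers(
    series: BarrierSeries, constants: Constants = DEFAULT_CONSTANTS
) -> RateSeries:
    """Convert a barrier series to a rate series (sem propagated to rates)."""
    k = barrier_to_rate(series.dG, series.T, constants)
    sem = None
    if series.has_sem:
        sem = np.asarray(k) * series.sem / (constants.R * series.T)
    return RateSeries(series.T, np.asarray(k), sem)


def barriers_from_rates(
    series: RateSeries, constants: Constants = DEFAULT_CONSTANTS
) -> BarrierSeries:
    """Convert a rate series back to barriers (sem propagated)."""
    dG = rate_to_barrier(series.k, series.T, constants)
    sem = None
    if series.sem is not None and np.any(series.sem > 0):
        sem = constants.R * series.T * series.sem / series.k
    return BarrierSeries(series.T, np.asarray(dG), sem)
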