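"""Two-state gating of a catalytically essential enzyme-substrate contact.

The dead-end state of the kinetic model is given a structural reading: a
hydrogen-bonded aspartate-substrate contact that ruptures with a large
enthalpy cost and large entropy gain.  The gate is modeled
thermodynamically — a discrete bound/unbound equilibrium obeying van 't
Hoff, each state emitting a Gaussian contact-distance distribution — and
composes with chemical-step barriers into full rate-vs-temperature curves.
A harmonic distance restraint can be applied; it reweights the distance
density by the Boltzmann factor of the penalty, forcing the contact closed
and abolishing the high-temperature rate decay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .thermokinetics import (
    DEFAULT_CONSTANTS,
    BarrierSeries,
    Constants,
    RateSeries,
    barrier_to_rate,
)


@dataclass(frozen=True)
class GatingModel:
    """Thermodynamics of the contact plus distance-emission statistics.

    ``dHgate``/``dSgate`` govern the bound <-> unbound equilibrium
    (kcal/mol and kcal/mol/K); the distance statistics (A) are synthetic
    plumbing consistent with an intact vs broken H bond, not fitted to any
    measured density.
    """

    dHgate: float
    dSgate: float
    bound_mean: float = 2.8
    bound_sd: float = 0.25
    unbound_mean: float = 4.5
    unbound_sd: float = 0.6

    def __post_init__(self) -> None:
        if self.unbound_mean <= self.bound_mean:
            raise ValueError("unbound mean distance must exceed bound mean")
        if self.bound_sd <= 0 or self.unbound_sd <= 0:
            raise ValueError("distance spreads must be positive")

    @property
    def cutoff(self) -> float:
        """Midpoint distance separating bound from unbound configurations."""
        return 0.5 * (self.bound_mean + self.unbound_mean)


@dataclass(frozen=True)
class RestraintSpec:
    """Harmonic distance restraint U(r) = k/2 (r - target)^2."""

    force_constant: float = 5.0
    target: float = 2.8

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise ValueError("force constant must be nonnegative")

    def energy(self, r):
        return 0.5 * self.force_constant * (np.asarray(r, float) - self.target) ** 2


@dataclass(frozen=True)
class DistanceDensity:
    """Normalized probability density of the contact distance at one T."""

    grid: np.ndarray
    pdf: np.ndarray
    T: float

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, float)
        pdf = np.asarray(self.pdf, float)
        if np.any(pdf < 0):
            raise ValueError("density must be nonnegative")
        area = np.trapezoid(pdf, grid)
        if not math.isclose(area, 1.0, abs_tol=1e-6):
            raise ValueError(f"density must integrate to 1 (got {area:.6f})")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "pdf", pdf)

    def mean(self) -> float:
        return float(np.trapezoid(self.grid * self.pdf, self.grid))

    def mass_above(self, r: float) -> float:
        """Probability mass at distances greater than r."""
        sel = self.grid >= r
        return float(np.trapezoid(self.pdf[sel], self.grid[sel]))


def gate_populations(
    T: float, g: GatingModel, R: float = DEFAULT_CONSTANTS.R
) -> tuple[float, float, float]:
    """(P_bound, P_unbound, Keq) of the gate at temperature T.

    Keq = exp(-(dHgate - T*dSgate)/(R*T)); van 't Hoff linearity of
    ln Keq in 1/T holds by construction.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    ln_keq = -(g.dHgate - T * g.dSgate) / (R * T)
    p_bound = 1.0 / (1.0 + math.exp(ln_keq))
    return p_bound, 1.0 - p_bound, math.exp(ln_keq)


def _gaussian(r, mu, sd):
    return np.exp(-0.5 * ((r - mu) / sd) ** 2) / (sd * math.sqrt(2.0 * math.pi))


def distance_density(
    T: float,
    g: GatingModel,
    restraint: Optional[RestraintSpec] = None,
    grid: Optional[np.ndarray] = None,
    R: float = DEFAULT_CONSTANTS.R,
) -> DistanceDensity:
    """Two-component Gaussian mixture weighted by the gate populations.

    A restraint multiplies the density by exp(-U(r)/(R*T)) and
    renormalizes, shifting probability mass toward the bound distance.
    """
    p_b, p_u, _ = gate_populations(T, g, R)
    if grid is None:
        lo = g.bound_mean - 6.0 * g.bound_sd
        hi = g.unbound_mean + 6.0 * g.unbound_sd
        grid = np.linspace(max(lo, 0.0), hi, 3501)
    grid = np.asarray(grid, float)
    pdf = p_b * _gaussian(grid, g.bound_mean, g.bound_sd) + p_u * _gaussian(
        grid, g.unbound_mean, g.unbound_sd
    )
    if restraint is not None:
        pdf = pdf * np.exp(-restraint.energy(grid) / (R * T))
    area = np.trapezoid(pdf, grid)
    if area <= 0 or not math.isfinite(area):
        raise ValueError("degenerate (zero-area) density after restraint")
    return DistanceDensity(grid=grid, pdf=pdf / area, T=T)


def bound_fraction(
    T: float,
    g: GatingModel,
    restraint: Optional[RestraintSpec] = None,
    R: float = DEFAULT_CONSTANTS.R,
) -> float:
    """Probability that the contact is closed.

    Without a restraint this is the thermodynamic population 1/(1+Keq);
    with one it is the reweighted probability mass at distances below the
    bound/unbound midpoint cutoff.
    """
    if restraint is None:
        return gate_populations(T, g, R)[0]
    dens = distance_density(T, g, restraint, R=R)
    return 1.0 - dens.mass_above(g.cutoff)


def effective_rate_curve(
    barriers: BarrierSeries,
    gate: Optional[GatingModel] = None,
    restraint: Optional[RestraintSpec] = None,
    constants: Constants = DEFAULT_CONSTANTS,
    temps: Optional[np.ndarray] = None,
) -> RateSeries:
    """Compose chemical-step barriers with the gate: kcat = k3 * P_bound.

    Barriers are interpolated linearly in dG/T against 1/T between the
    given temperatures; extrapolation outside the covered range is
    refused.  ``gate=None`` reduces to the pure TST conversion of the
    barrier series.
    """
    T = barriers.T if temps is None else np.sort(np.asarray(temps, float))
    if T.min() < barriers.T.min() - 1e-9 or T.max() > barriers.T.max() + 1e-9:
        raise ValueError(
            "requested temperatures extrapolate outside the barrier series"
        )
    x = 1.0 / barriers.T
    y = barriers.dG / barriers.T
    order = np.argsort(x)
    dG = np.interp(1.0 / T, x[order], y[order]) * T
    k3 = np.asarray(barrier_to_rate(dG, T, constants), float)
    if gate is None:
        k = k3
    else:
        pb = np.array([bound_fraction(float(t), gate, restraint, constants.R) for t in T])
        k = k3 * pb
    return RateSeries(T, k)


def interior_optimum(series: RateSeries) -> Optional[float]:
    """Temperature of the maximum rate if it is interior, else None."""
    i = int(np.argmax(series.k))
    if i == 0 or i == len(series) - 1:
        return None
    return float(series.T[i])
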