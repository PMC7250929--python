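"""Seeded generators for every input the analysis pipeline consumes.

Barrier series are generated on the standard eight-temperature ladder
(278-313 K, 5 K apart) from one of the barrier models (linear activation
parameters, two-state dead-end, heat-capacity) or from an actual toy EVB
temperature scan.  Noise is Gaussian on barriers — the replicate mean at
each temperature carries a standard error drawn from the 0.08-0.14
kcal/mol range characteristic of well-converged replicated free-energy
calculations — and rate noise is derived from the barrier noise through
the TST conversion (hence multiplicative/log-normal), never added
independently.  Every generator records the generating truth next to the
data so recovery tests never re-derive it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from . import evb
from .kinetic_models import (
    HeatCapacityParams,
    TwoStateParams,
    model_barrier,
)
from .thermokinetics import (
    DEFAULT_CONSTANTS,
    ActivationParameters,
    BarrierSeries,
    Constants,
    RateSeries,
    barrier_to_rate,
)

#: Default temperature ladder (K).
DEFAULT_TEMPS = evb.DEFAULT_SCAN_TEMPS

#: Range the per-temperature standard errors are drawn from (kcal/mol).
SEM_RANGE = (0.08, 0.14)

ParamsLike = Union[ActivationParameters, TwoStateParams, HeatCapacityParams, evb.EVBSystem]


@dataclass(frozen=True)
class GeneratorSpec:
    """Model choice, noise scale, temperature grid and seed for a dataset.

    ``sem=None`` draws a per-temperature target s.e.m. uniformly from
    ``SEM_RANGE``; ``sem=0`` produces exact model values.  ``n_replicas``
    Gaussian replicate draws are averaged per temperature, so the reported
    s.e.m. is estimated from the draws themselves.
    """

    model: str
    params: ParamsLike
    temps: Sequence[float] = DEFAULT_TEMPS
    sem: Optional[float] = None
    n_replicas: int = 300
    seed: int = 0
    protocol: Optional[evb.MappingProtocol] = None  # evb_toy only

    def __post_init__(self) -> None:
        if self.model not in ("linear", "two_state", "heat_capacity", "evb_toy"):
            raise ValueError(f"unknown generator model {self.model!r}")
        if len(self.temps) == 0:
            raise ValueError("temperature list must not be empty")
        if self.n_replicas < 1:
            raise ValueError("need at least one replicate draw")


@dataclass(frozen=True)
class GroundTruth:
    """Sidecar record of what generated a synthetic dataset."""

    model: str
    params: ParamsLike
    barriers: np.ndarray
    temps: np.ndarray
    seed: int

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "params": _params_dict(self.params),
            "temps": [float(t) for t in self.temps],
            "barriers": [float(b) for b in self.barriers],
            "seed": int(self.seed),
        }


def _params_dict(params: ParamsLike) -> dict:
    if isinstance(params, evb.EVBSystem):
        return {"type": "EVBSystem", "H12": params.H12}
    d = {k: float(v) for k, v in vars(params).items()}
    d["type"] = type(params).__name__
    return d


def _true_barriers(spec: GeneratorSpec) -> np.ndarray:
    temps = np.asarray(spec.temps, float)
    if spec.model == "evb_toy":
        protocol = spec.protocol or evb.MappingProtocol(seed=spec.seed)
        scan = evb.temperature_scan(spec.params, temps=temps, protocol=protocol)
        # align to requested temps; failed ones are absent by contract
        return np.interp(temps, scan.series.T, scan.series.dG)
    return np.asarray(model_barrier(temps, spec.params), float)


def generate_barrier_series(spec: GeneratorSpec):
    """Synthetic barrier series plus its ground-truth record.

    Per temperature, ``n_replicas`` Gaussian draws are taken around the
    model barrier with replicate spread ``sem * sqrt(n_replicas)`` so the
    replicate mean has the configured standard error; the reported s.e.m.
    comes from the draws.  The same spec and seed give bit-identical
    output.
    """
    temps = np.asarray(spec.temps, float)
    mu = _true_barriers(spec)
    rng = np.random.default_rng(spec.seed)
    values = np.empty_like(mu)
    sems = np.empty_like(mu)
    for i, m in enumerate(mu):
        target = (
            rng.uniform(*SEM_RANGE) if spec.sem is None else float(spec.sem)
        )
        if target == 0.0:
            values[i], sems[i] = m, 0.0
            # keep the stream position independent of the noise setting
            continue
        draws = m + target * math.sqrt(spec.n_replicas) * rng.standard_normal(
            spec.n_replicas
        )
        values[i] = draws.mean()
        sems[i] = draws.std(ddof=1) / math.sqrt(spec.n_replicas)
    series = BarrierSeries(temps, values, sems)
    truth = GroundTruth(
        model=spec.model, params=spec.params, barriers=mu, temps=temps, seed=spec.seed
    )
    return series, truth


def generate_rate_series(
    spec: GeneratorSpec, constants: Constants = DEFAULT_CONSTANTS
):
    """Synthetic rate series derived from the barrier generator.

    Rates are the TST conversion of the noisy barriers, so the noise is
    multiplicative (log-normal) by construction; the rate s.e.m. is
    propagated from the barrier s.e.m.
    """
    series, truth = generate_barrier_series(spec)
    k = np.asarray(barrier_to_rate(series.dG, series.T, constants), float)
    sem = None
    if series.has_sem:
        sem = k * series.sem / (constants.R * series.T)
    return RateSeries(series.T, k, sem), truth
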