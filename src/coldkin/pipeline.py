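"""End-to-end orchestration: simulate/generate -> Arrhenius -> fit -> compare.

A pipeline configuration is a plain mapping (usually loaded from YAML)
with a ``stages`` list and per-stage sections.  Every stochastic stage
derives its seed from the top-level ``seed``, so rerunning an identical
configuration reproduces the report bit-for-bit (no timestamps are
recorded for that reason).
"""

from __future__ import annotations

import math

import numpy as np

from . import evb, gating, synthetic_data
from .kinetic_models import (
    HeatCapacityParams,
    TwoStateParams,
    fit_model,
    model_rate,
    optimum_temperature,
)
from .thermokinetics import (
    ActivationParameters,
    BarrierSeries,
    barriers_from_rates,
    fit_arrhenius,
    fit_piecewise_arrhenius,
)

KNOWN_STAGES = ("generate", "evb_scan", "gate", "arrhenius", "fit", "compare")


class PipelineError(RuntimeError):
    pass


def _two_state_params(d: dict) -> TwoStateParams:
    return TwoStateParams(
        dH3=float(d["dH3"]), dS3=float(d["dS3"]),
        dHeq=float(d["dHeq"]), dSeq=float(d["dSeq"]),
    )


def _model_params(model: str, d: dict):
    if model == "two_state":
        return _two_state_params(d)
    if model == "heat_capacity":
        return HeatCapacityParams(
            dH0=float(d["dH0"]), dS0=float(d["dS0"]),
            dCp=float(d["dCp"]), T0=float(d.get("T0", 298.0)),
        )
    if model == "linear":
        return ActivationParameters(dH=float(d["dH"]), dS=float(d["dS"]))
    raise PipelineError(f"unknown generator model {model!r}")


def _params_out(p) -> dict:
    return {k: float(v) for k, v in vars(p).items()}


def _stage_generate(cfg: dict, seed: int, state: dict) -> dict:
    model = cfg.get("model", "two_state")
    params = _model_params(model, cfg.get("params", {}))
    spec = synthetic_data.GeneratorSpec(
        model=model,
        params=params,
        temps=tuple(cfg.get("temps", synthetic_data.DEFAULT_TEMPS)),
        sem=cfg.get("sem"),
        n_replicas=int(cfg.get("n_replicas", 300)),
        seed=seed,
    )
    series, truth = synthetic_data.generate_barrier_series(spec)
    state["barriers"] = series
    return {
        "model": model,
        "seed": seed,
        "n_points": len(series),
        "ground_truth": truth.as_dict(),
        "table": {
            "temperature_K": series.T,
            "value": series.dG,
            "sem": series.sem,
        },
    }


def _stage_evb_scan(cfg: dict, seed: int, state: dict) -> dict:
    sys_cfg = cfg.get("system", {})
    system = evb.EVBSystem(
        evb.HarmonicSurface(float(sys_cfg.get("k1", 200.0)), float(sys_cfg.get("x1", 0.0))),
        evb.HarmonicSurface(
            float(sys_cfg.get("k2", 200.0)), float(sys_cfg.get("x2", 1.0)),
            float(sys_cfg.get("alpha", 0.0)),
        ),
        float(sys_cfg.get("H12", 0.0)),
    )
    proto_cfg = cfg.get("protocol", {})
    protocol = evb.MappingProtocol(
        n_windows=int(proto_cfg.get("n_windows", 21)),
        steps_per_window=int(proto_cfg.get("steps_per_window", 3000)),
        equilibration_steps=int(proto_cfg.get("equilibration_steps", 500)),
        n_replicas=int(proto_cfg.get("n_replicas", 4)),
        seed=seed,
    )
    scan = evb.temperature_scan(
        system, temps=cfg.get("temps"), protocol=protocol
    )
    state["barriers"] = scan.series
    return {
        "seed": seed,
        "temperatures": scan.series.T,
        "barriers": scan.series.dG,
        "sem": scan.series.sem,
        "failures": {str(k): v for k, v in scan.failures.items()},
    }


def _stage_gate(cfg: dict, seed: int, state: dict) -> dict:
    gate = gating.GatingModel(
        dHgate=float(cfg["dHgate"]), dSgate=float(cfg["dSgate"])
    )
    chem = cfg.get("chemical_step", {"dH": 10.2, "dS": -0.00925})
    chem_params = ActivationParameters(float(chem["dH"]), float(chem["dS"]))
    temps = np.asarray(cfg.get("temps", synthetic_data.DEFAULT_TEMPS), float)
    barriers = BarrierSeries(temps, np.asarray(chem_params.barrier(temps)))
    restraint = None
    if cfg.get("restraint"):
        r = cfg["restraint"]
        restraint = gating.RestraintSpec(
            force_constant=float(r.get("force_constant", 5.0)),
            target=float(r.get("target", gate.bound_mean)),
        )
    rates = gating.effective_rate_curve(barriers, gate, restraint)
    state["rates"] = rates
    state["barriers"] = barriers_from_rates(rates)
    topt = gating.interior_optimum(rates)
    return {
        "restrained": restraint is not None,
        "optimum": (
            "no interior optimum" if topt is None else {"T_K": topt}
        ),
        "table": {"temperature_K": rates.T, "value": rates.k},
    }


def _stage_arrhenius(cfg: dict, seed: int, state: dict) -> dict:
    series = state.get("barriers")
    if series is None:
        raise PipelineError("arrhenius stage requires a prior data stage")
    single = fit_arrhenius(series, cfg.get("weighted"))
    out = {
        "single": {
            "dH": single.params.dH,
            "dS": single.params.dS,
            "r_squared": single.r_squared,
        }
    }
    if len(series) >= 6:
        pw = fit_piecewise_arrhenius(
            series, cfg.get("weighted"),
            improvement_factor=float(cfg.get("improvement_factor", 4.0)),
        )
        out["piecewise"] = {
            "breakpoint_K": pw.breakpoint,
            "accepted": pw.accepted,
            "selection_score": (
                pw.selection_score if math.isfinite(pw.selection_score) else "inf"
            ),
            "low": {"dH": pw.low.params.dH, "dS": pw.low.params.dS},
            "high": {"dH": pw.high.params.dH, "dS": pw.high.params.dS},
        }
    return out


def _stage_fit(cfg: dict, seed: int, state: dict) -> dict:
    series = state.get("barriers")
    if series is None:
        raise PipelineError("fit stage requires a prior data stage")
    out = {}
    for which in cfg.get("models", ["two_state", "heat_capacity"]):
        res = fit_model(series, which, objective=cfg.get("objective", "gibbs_over_T"))
        state[f"fit_{which}"] = res
        out[which] = {
            "params": _params_out(res.params),
            "wrss": res.wrss,
            "accepted": res.accepted,
            "rejection_reason": res.rejection_reason,
            "identifiable": res.identifiable,
            "condition_number": res.condition_number,
            "covariance": res.covariance,
        }
    return out


def _stage_compare(cfg: dict, seed: int, state: dict) -> dict:
    ts = state.get("fit_two_state")
    hc = state.get("fit_heat_capacity")
    if ts is None or hc is None:
        raise PipelineError("compare stage requires both model fits")
    series = state["barriers"]
    k_ts = np.log(model_rate(series.T, ts.params))
    k_hc = np.log(model_rate(series.T, hc.params))
    max_dlnk = float(np.max(np.abs(k_ts - k_hc)))
    flipped = ts.params.flipped()
    from .kinetic_models import reject_sign_degenerate

    flip_ok, flip_reason = reject_sign_degenerate(
        flipped, (series.T.min(), series.T.max())
    )
    topt_ts = optimum_temperature(ts.params, (series.T.min(), series.T.max()))
    return {
        "two_state_accepted": ts.accepted,
        "sign_flipped_rejected": not flip_ok,
        "sign_flipped_reason": flip_reason,
        "max_abs_delta_ln_k_on_fit_range": max_dlnk,
        "curves_indistinguishable": max_dlnk < float(cfg.get("tolerance", 0.05)),
        "two_state_optimum_K": topt_ts,
    }


_STAGE_FUNCS = {
    "generate": _stage_generate,
    "evb_scan": _stage_evb_scan,
    "gate": _stage_gate,
    "arrhenius": _stage_arrhenius,
    "fit": _stage_fit,
    "compare": _stage_compare,
}


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages and return a structured report.

    Stage failures are recorded under the stage name and abort the
    remaining stages; identical config (including seed) gives an
    identical report.
    """
    stages = config.get("stages")
    if not stages:
        raise PipelineError("configuration must list at least one stage")
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise PipelineError(f"unknown stages {unknown}; known: {list(KNOWN_STAGES)}")
    seed = int(config.get("seed", 0))
    seeds = {
        s: int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for s, ss in zip(KNOWN_STAGES, np.random.SeedSequence(seed).spawn(len(KNOWN_STAGES)))
    }
    state: dict = {}
    report: dict = {"seed": seed, "stages": list(stages)}
    for stage in stages:
        cfg = config.get(stage, {}) or {}
        try:
            report[stage] = _STAGE_FUNCS[stage](cfg, seeds[stage], state)
        except Exception as exc:  # noqa: BLE001 - reported, not swallowed
            report[stage] = {"error": f"{type(exc).__name__}: {exc}"}
            report["failed_stage"] = stage
            break
    return report
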