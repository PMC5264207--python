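"""Scenario configuration schema, fixtures, and the run harness.

A Scenario bundles a neuron model, a dual-control configuration, and run
settings into one validated (JSON/YAML) document.  Bundled fixtures
reproduce the canonical demonstration setups: wind-up and synapse
elimination under constant input, convergence under fluctuating input,
instability under exchanged control functions, tolerance (and failure)
under intrinsic noise, and integrator self-tuning.  Time constants that
the demonstrations leave open are package defaults chosen to respect the
slow-fast separation; parameters that are part of the setups themselves
(targets, input statistics, noise levels) are encoded per fixture.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .control_laws import (DualControlConfig, characteristic_moments,
                           quadratic)
from .coupled_simulation import simulate_averaged, simulate_dual
from .fixed_points import (averaged_jacobian, classify_stability,
                           find_fixed_point, nullclines)
from .integrator_experiments import (PulseProtocol, tune_then_test)
from .neuron_models import (ControlState, OURateUnit, PoissonCalciumUnit,
                            SelfExcitatoryUnit, StationaryInput,
                            moment_surface)

__all__ = ["Scenario", "load_scenario", "run_scenario",
           "bundled_scenario", "bundled_scenario_names"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class InputSpec(_Strict):
    kind: Literal["constant", "white", "ou_correlated", "pulses"] = "constant"
    phi: float = 1.0
    sigma: float = 0.0
    tau_I: float = 10.0
    sigma_I: float = 0.0
    pulse_amplitude: float = 0.0
    pulse_width: float = 0.0
    pulse_interval: float = 0.0
    n_pulses: int = 0
    pulse_start: float = 0.0

    def build(self) -> StationaryInput:
        return StationaryInput(**self.model_dump())


class ModelSpec(_Strict):
    type: Literal["ou", "poisson_calcium", "self_excitatory"] = "ou"
    tau_r: float = 0.1
    eta: float = 0.0
    delta: float = 1.0
    tau_d: float = 1.0
    input: InputSpec = Field(default_factory=InputSpec)

    def build(self):
        inp = self.input.build()
        if self.type == "ou":
            return OURateUnit(tau_r=self.tau_r, input=inp, eta=self.eta)
        if self.type == "poisson_calcium":
            return PoissonCalciumUnit(delta=self.delta, tau_d=self.tau_d,
                                      input=inp)
        return SelfExcitatoryUnit(eta=self.eta, input=inp)


class ControlFunctionSpec(_Strict):
    type: Literal["quadratic"] = "quadratic"
    c0: float = 0.0
    c1: float = 0.0
    c2: float = 0.0

    def build(self):
        return quadratic(self.c0, self.c1, self.c2)


class ControlSpec(_Strict):
    fa: ControlFunctionSpec
    fb: ControlFunctionSpec
    r_a: float
    r_b: float
    tau_a: float = 100.0
    tau_b: float = 1000.0
    epsilon: float = 1.0
    multiplicative_a: bool = False
    multiplicative_b: bool = True

    def build(self) -> DualControlConfig:
        return DualControlConfig(
            fa=self.fa.build(), fb=self.fb.build(), r_a=self.r_a,
            r_b=self.r_b, tau_a=self.tau_a, tau_b=self.tau_b,
            epsilon=self.epsilon, multiplicative_a=self.multiplicative_a,
            multiplicative_b=self.multiplicative_b)


class InitSpec(_Strict):
    a: float = 0.0
    b: float = 1.0


class RunSpec(_Strict):
    T: float = 1000.0
    dt: float = 0.002
    seed: int = 0
    burn_in_fraction: float = 0.5
    init: InitSpec = Field(default_factory=InitSpec)


class ProtocolSpec(_Strict):
    n_pulses: int = 5
    amplitude: float = 5.0
    width: float = 0.5
    interval: float = 3.0
    baseline: float = 1.0
    settle: float = 20.0
    T_homeo: float = 3000.0

    def build(self) -> PulseProtocol:
        return PulseProtocol(n_pulses=self.n_pulses, amplitude=self.amplitude,
                             width=self.width, interval=self.interval,
                             baseline=self.baseline, settle=self.settle)


class PhasePlaneSpec(_Strict):
    a_range: tuple[float, float] = (-2.0, 6.0)
    b_range: tuple[float, float] = (0.01, 6.0)
    n: int = 201


class Scenario(_Strict):
    name: str = "scenario"
    experiment: Literal["simulate", "averaged", "analyze",
                        "phase-plane", "integrator"] = "simulate"
    model: ModelSpec = Field(default_factory=ModelSpec)
    control: ControlSpec
    run: RunSpec = Field(default_factory=RunSpec)
    protocol: ProtocolSpec = Field(default_factory=ProtocolSpec)
    phase_plane: PhasePlaneSpec = Field(default_factory=PhasePlaneSpec)
    expected_outcome: str | None = None   # annotation, not enforced

    @model_validator(mode="after")
    def _targets_sane(self):
        if self.run.dt <= 0 or self.run.T <= 0:
            raise ValueError("run.T and run.dt must be positive")
        return self

    def dump(self) -> dict:
        return self.model_dump()


def load_scenario(source: str | Path | dict) -> Scenario:
    """Validate a scenario from a YAML/JSON file path, text, or dict.

    Unknown keys are rejected with the offending key named; defaults are
    filled in so that ``dump(load(s))`` is the normalized document.
    """
    if isinstance(source, dict):
        data = source
    else:
        text = Path(source).read_text() if _looks_like_path(source) else str(source)
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("scenario document must be a mapping")
    return Scenario.model_validate(data)


def _looks_like_path(source) -> bool:
    if isinstance(source, Path):
        return True
    s = str(source)
    if not s or "\n" in s:
        return False
    return s.endswith((".yaml", ".yml", ".json")) or Path(s).is_file()


def bundled_scenario_names() -> list[str]:
    root = importlib.resources.files("dualhomeo.scenarios")
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def bundled_scenario(name: str) -> Scenario:
    """Load one of the packaged demonstration fixtures by name."""
    root = importlib.resources.files("dualhomeo.scenarios")
    try:
        text = (root / f"{name}.yaml").read_text()
    except FileNotFoundError:
        raise KeyError(f"no bundled scenario {name!r}; "
                       f"available: {bundled_scenario_names()}") from None
    return load_scenario(text)


# ---------------------------------------------------------------------------
# Running


def _write_atomic(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    tmp.replace(path)


def _trace_csv(result) -> str:
    df = result.to_frame()
    return df.to_csv(index=False, lineterminator="\n")


def run_scenario(scn: Scenario, outdir: str | Path | None = None,
                 seed: int | None = None) -> dict:
    """Execute a scenario and return (optionally write) its summary.

    Writes ``<name>_trace.csv`` (columns time, r, x, g; repr-roundtrip
    floats) and ``<name>_summary.json`` atomically when ``outdir`` is
    given.  The summary always records the seed actually used, the outcome,
    the theoretical characteristic moments where defined, and — for
    converged stochastic runs — the equilibrium statistics with their
    agreement deltas against the theory.
    """
    seed = scn.run.seed if seed is None else seed
    unit = scn.model.build()
    cfg = scn.control.build()
    init = ControlState(a=scn.run.init.a, b=scn.run.init.b)
    summary: dict = {"name": scn.name, "experiment": scn.experiment,
                     "seed": seed}
    try:
        mom = characteristic_moments(cfg)
        summary["mu_star"] = mom.mu_star
        summary["nu_star"] = mom.nu_star
        summary["realizable"] = mom.realizable
    except ValueError as exc:
        summary["characteristic_moments_error"] = str(exc)
        mom = None

    result = None
    if scn.experiment == "simulate":
        result = simulate_dual(unit, cfg, init, scn.run.T, scn.run.dt,
                               seed=seed)
        summary["outcome"] = result.outcome
        summary["equilibrium"] = result.equilibrium
        if result.equilibrium and mom is not None:
            summary["delta_mean"] = result.equilibrium["mean_r"] - mom.mu_star
            summary["delta_var"] = result.equilibrium["var_r"] - mom.nu_star
    elif scn.experiment == "averaged":
        surface = moment_surface(unit)
        result = simulate_averaged(surface, cfg, init, scn.run.T)
        summary["outcome"] = result.outcome
        summary["equilibrium"] = result.equilibrium
        summary["endpoint"] = {"a": float(result.a[-1]), "b": float(result.b[-1])}
        if result.outcome == "converged":
            J = averaged_jacobian(surface, cfg,
                                  (float(result.a[-1]), float(result.b[-1])))
            summary["stability"] = classify_stability(J)
    elif scn.experiment == "analyze":
        surface = moment_surface(unit)
        report = find_fixed_point(surface, cfg)
        summary["fixed_point"] = report.to_dict()
    elif scn.experiment == "phase-plane":
        surface = moment_surface(unit)
        curves = nullclines(surface, cfg, scn.phase_plane.a_range,
                            scn.phase_plane.b_range, scn.phase_plane.n)
        summary["n_a_curves"] = len(curves["a"])
        summary["n_b_curves"] = len(curves["b"])
        if outdir is not None:
            rows = ["set,curve,a,b"]
            for key in ("a", "b"):
                for ci, poly in enumerate(curves[key]):
                    for a, b in poly:
                        rows.append(f"{key},{ci},{a!r},{b!r}")
            _write_atomic(Path(outdir) / f"{scn.name}_nullclines.csv",
                          "\n".join(rows) + "\n")
    elif scn.experiment == "integrator":
        if not isinstance(unit, SelfExcitatoryUnit):
            raise ValueError("integrator experiment requires the "
                             "self_excitatory model")
        res = tune_then_test(unit, cfg, scn.protocol.build(),
                             T_homeo=scn.protocol.T_homeo, seed=seed,
                             dt=scn.run.dt, init=init)
        result = res.trajectory
        summary["tuning_outcome"] = res.tuning_outcome
        summary["before"] = res.before.to_dict()
        summary["after"] = res.after.to_dict() if res.after else None
        if res.tuned_state is not None:
            summary["tuned_state"] = {"x": res.tuned_state.a,
                                      "g": res.tuned_state.b}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if result is not None:
            _write_atomic(outdir / f"{scn.name}_trace.csv", _trace_csv(result))
        _write_atomic(outdir / f"{scn.name}_summary.json",
                      json.dumps(_jsonable(summary), indent=2) + "\n")
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not math.isfinite(obj):
        return repr(obj)
    return obj
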