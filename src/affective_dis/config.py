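"""Scenario configuration, validation and presets.

A scenario bundles a network specification, the agent parameter block, the
network coupling and the run controls.  The parameter block accepts either
the microscopic pump rates (gamma_p, gamma_e) or the equivalent
(gamma_plus, sigma_z0) pair -- never both.  Presets named after the
standard simulation panels (fig5a..fig5i) reproduce the published
parameter combinations: rows of the 3x3 panel grid vary the damping/pump
triple, columns the coupling channel (none / coherent J_R / diffusive J_I).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from . import meanfield, network, steady_state
from .meanfield import AgentParams, CouplingSpec

__all__ = [
    "NetworkSpec",
    "ParamBlock",
    "CouplingBlock",
    "RunBlock",
    "ScenarioConfig",
    "load_config",
    "preset",
    "PRESETS",
    "run_scenario",
]

logger = logging.getLogger(__name__)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NetworkSpec(_Strict):
    N: int | None = 60
    nu: float | None = 2.3
    k_min: int | None = 2
    seed: int | None = 1
    edge_list: str | None = None

    def build(self) -> network.NetworkModel:
        if self.edge_list is not None:
            return network.read_edge_list(self.edge_list)
        return network.generate_scale_free(self.N, self.nu, self.k_min, self.seed)


class ParamBlock(_Strict):
    g_over_kappa: float = 0.5
    kappa: float = 1.0
    Gamma: float = 0.0
    gamma_p: float | None = None
    gamma_e: float | None = None
    gamma_plus: float | None = None
    sigma_z0: float | None = None
    Delta: float = 0.0
    hub_Delta: float | None = None   # per-agent override on the max-degree node

    @model_validator(mode="after")
    def _one_parameterization(self) -> "ParamBlock":
        micro = self.gamma_p is not None or self.gamma_e is not None
        macro = self.gamma_plus is not None or self.sigma_z0 is not None
        if micro and macro:
            bad = [k for k in ("gamma_p", "gamma_e", "gamma_plus", "sigma_z0")
                   if getattr(self, k) is not None]
            raise ValueError(
                f"conflicting pump parameterizations: give (gamma_p, gamma_e) "
                f"or (gamma_plus, sigma_z0), not both; offending keys: {bad}"
            )
        if micro and (self.gamma_p is None or self.gamma_e is None):
            raise ValueError("gamma_p and gamma_e must be given together")
        if not micro and not macro:
            # default: no pumping at all
            object.__setattr__(self, "gamma_plus", 0.0)
            object.__setattr__(self, "sigma_z0", 0.0)
        if macro:
            if self.gamma_plus is None:
                raise ValueError("sigma_z0 requires gamma_plus")
            if self.sigma_z0 is None:
                object.__setattr__(self, "sigma_z0", 0.0)
        return self

    def build(self, n: int, hub_index: int | None = None) -> AgentParams:
        delta = np.full(n, self.Delta)
        if self.hub_Delta is not None and hub_index is not None:
            delta[hub_index] = self.hub_Delta
        g = self.g_over_kappa * self.kappa
        if self.gamma_p is not None:
            return AgentParams.from_rates(
                n=n, Delta=delta, Gamma=self.Gamma,
                gamma_p=self.gamma_p, gamma_e=self.gamma_e,
                g=g, kappa=self.kappa,
            )
        return AgentParams(
            n=n, Delta=delta, Gamma=self.Gamma,
            gamma_plus=self.gamma_plus, sigma_z0=self.sigma_z0,
            g=g, kappa=self.kappa,
        )


class CouplingBlock(_Strict):
    J_R: float = 0.0
    J_I: float = 0.0
    Theta: float = 0.0

    def build(self) -> CouplingSpec:
        return CouplingSpec(J_R=self.J_R, J_I=self.J_I, Theta=self.Theta)


class RunBlock(_Strict):
    system: Literal["full", "reduced", "real"] = "real"
    t_end: float = 100.0
    dt_out: float = 0.1
    epsilon_init: float = 1e-2
    seed: int = 0


class ScenarioConfig(_Strict):
    name: str = "scenario"
    network: NetworkSpec = NetworkSpec()
    params: ParamBlock = ParamBlock()
    coupling: CouplingBlock = CouplingBlock()
    run: RunBlock = RunBlock()

    def content_hash(self) -> str:
        return hashlib.sha256(
            self.model_dump_json().encode()
        ).hexdigest()[:16]


def load_config(path: str | Path) -> ScenarioConfig:
    """Read and validate a JSON or TOML scenario file; unknown keys rejected."""
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        data = tomllib.loads(path.read_text())
    else:
        data = json.loads(path.read_text())
    return ScenarioConfig.model_validate(data)


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------

def _panel(row: str, col: str) -> dict:
    rows = {
        "free": dict(Gamma=0.0, gamma_plus=0.0, sigma_z0=0.0),         # a, d, g
        "grow": dict(Gamma=0.1, gamma_plus=0.5, sigma_z0=0.99),        # b, e, h
        "shrink": dict(Gamma=0.1, gamma_plus=0.05, sigma_z0=0.99),     # c, f, i
    }
    cols = {
        "none": dict(J_R=0.0, J_I=0.0, Theta=0.0),
        "coherent": dict(J_R=0.01, J_I=0.0, Theta=0.0),
        # published caption J = -J_I = -0.01i: J_I,eff = -0.01, i.e. J_I = 0.01
        # with reservoir phase Theta = pi (the active, synchronizing regime)
        "diffusive": dict(J_R=0.0, J_I=0.01, Theta=math.pi),
    }
    coupled = col != "none"
    params = dict(g_over_kappa=0.5, Delta=0.0, **rows[row])
    if coupled:
        params["hub_Delta"] = 0.5
    return {
        "params": params,
        "coupling": cols[col],
        # heterogeneous Delta (hub override) needs the complex reduced system
        "run": {"system": "reduced" if coupled else "real",
                "t_end": 100.0, "dt_out": 0.1, "epsilon_init": 1e-2, "seed": 0},
        "network": {"N": 60, "nu": 2.3, "k_min": 2, "seed": 1},
    }


PRESETS: dict[str, dict] = {
    f"fig5{letter}": _panel(row, col)
    for letter, (row, col) in zip(
        "abcdefghi",
        [(r, c) for c in ("none", "coherent", "diffusive")
         for r in ("free", "grow", "shrink")],
    )
}


def preset(name: str) -> ScenarioConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return ScenarioConfig.model_validate({"name": name, **PRESETS[name]})


# --------------------------------------------------------------------------
# scenario runner
# --------------------------------------------------------------------------

def run_scenario(config: ScenarioConfig, out_dir: str | Path | None = None) -> dict:
    """Execute a scenario end to end; optionally write the artifact bundle.

    Returns a dict with the trajectory, the built objects and the summary.
    When ``out_dir`` is given, writes <name>_trajectory.csv,
    <name>_summary.json and <name>.log (all deterministic for fixed seeds).
    """
    net = config.network.build()
    hub = int(np.argmax(net.degrees))
    params = config.params.build(net.n_nodes, hub_index=hub)
    coupling = config.coupling.build()
    init = meanfield.initial_state(
        net.n_nodes, epsilon=config.run.epsilon_init, seed=config.run.seed
    )
    traj = meanfield.integrate(
        config.run.system, net, params, coupling, init,
        t_end=config.run.t_end, dt_out=config.run.dt_out,
    )

    stats = net.summary()
    summary: dict = {
        "name": config.name,
        "config_hash": config.content_hash(),
        "seeds": {"network": config.network.seed, "run": config.run.seed},
        "network": stats,
        "hub_index": hub,
        "system": config.run.system,
        "final_sigma_z_mean": float(traj.sigma_z[-1].mean()),
        "final_sigma_perp_mean": float(traj.sigma_perp[-1].mean()),
    }
    if params.g > 0:
        ss = steady_state.summarize(params, coupling, net)
        summary["sigma_z_cr"] = ss.sigma_z_cr
        summary["A_eff"] = ss.A_eff
        summary["regime"] = ss.regime
        if ss.sphere_growth is not None:
            summary["sphere_growth"] = ss.sphere_growth
    try:
        summary["measured_frequency"] = meanfield.measure_frequency(traj, agent=hub)
    except ValueError:
        summary["measured_frequency"] = None
    try:
        summary["fitted_gain"] = steady_state.gain_from_trajectory(traj, net=net)
    except ValueError:
        summary["fitted_gain"] = None

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        traj.to_frame().to_csv(out / f"{config.name}_trajectory.csv", index=False)
        (out / f"{config.name}_summary.json").write_text(
            json.dumps(summary, indent=2, default=_json_default)
        )
        (out / f"{config.name}.log").write_text(
            "\n".join([
                f"scenario={config.name}",
                f"config_hash={config.content_hash()}",
                f"network_seed={config.network.seed}",
                f"run_seed={config.run.seed}",
                f"system={config.run.system}",
                f"config={config.model_dump_json()}",
            ]) + "\n"
        )
    return {"config": config, "network": net, "params": params,
            "coupling": coupling, "trajectory": traj, "summary": summary}


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and math.isnan(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")
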