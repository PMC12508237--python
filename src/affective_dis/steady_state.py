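"""Steady states, thresholds and the collective-gain analysis.

A single driven agent undergoes a pitchfork (second-order) transition in
its transverse affective field: below the critical arousal
sigma^z_cr = Gamma/C (= Gamma kappa / g^2 at zero detuning) the only steady
state is the neutral one (sigma_perp = 0); above it a ring of radius

    sigma_perp = sigma_perp_0 sqrt(sigma_z0 / sigma_z_cr - 1),
    sigma_perp_0 = sqrt(gamma_+ sigma_z_cr / C)

appears.  A weak diffusive network coupling tilts the pitchfork with a
degree-dependent force F_i, turning the steady-state condition into the
cubic  A p - B p^3 + F = 0  with A = C sigma_z0 - Gamma and
B = 4 C^2 / gamma_+.  In the annealed (degree-product) approximation the
degree-weighted mean field P-bar then grows or decays exponentially at the
network-enforced rate

    A_eff = (g^2 sigma_z0 / kappa) (1 - cos(Theta) J_I zeta / kappa) - Gamma,

the collective-mood (superradiance-like) gain, which is amplified by the
normalized second degree moment zeta of the graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .meanfield import AgentParams, CouplingSpec, Trajectory
from .network import NetworkModel

__all__ = [
    "SteadyStateSummary",
    "critical_arousal",
    "steady_perp",
    "sphere_growth",
    "network_force",
    "cubic_steady_state",
    "mean_polarization",
    "effective_gain",
    "gain_from_trajectory",
    "summarize",
]

GAIN_WINDOW_FRACTION = 0.1  # |P| < fraction * max defines the linear window


# --------------------------------------------------------------------------
# single-agent thresholds
# --------------------------------------------------------------------------

def critical_arousal(params: AgentParams, agent: int = 0) -> float:
    """Critical arousal sigma^z_cr = Gamma/C (= Gamma kappa / g^2 at Delta=0)."""
    if params.g <= 0:
        raise ValueError("critical arousal requires g > 0")
    return float(params.Gamma[agent] / params.C[agent])


def steady_perp(params: AgentParams, agent: int = 0) -> float:
    """Steady transverse order parameter at Delta = 0.

    Zero at or below threshold; the upper pitchfork branch above it.
    """
    sz_cr = critical_arousal(params, agent)
    sz0 = float(params.sigma_z0[agent])
    if sz_cr == 0.0:
        # Gamma = 0: any pumping activates; branch formula degenerates
        return math.sqrt(float(params.gamma_plus[agent]) * sz0 / float(params.C[agent])) \
            if sz0 > 0 else 0.0
    if sz0 <= sz_cr:
        return 0.0
    perp0 = math.sqrt(float(params.gamma_plus[agent]) * sz_cr / float(params.C[agent]))
    return perp0 * math.sqrt(sz0 / sz_cr - 1.0)


def sphere_growth(params: AgentParams, agent: int = 0,
                  tol: float = 1e-9) -> Literal["grows", "shrinks", "marginal"]:
    """Whether the affective-sphere radius grows past 1 on the limit cycle.

    Above threshold the sphere grows iff
    gamma_+/Gamma > (1/sz_cr)(1 - sz_cr^2)/(sz0 - sz_cr); equality (within
    tol) is marginal (R = 1).
    """
    sz_cr = critical_arousal(params, agent)
    sz0 = float(params.sigma_z0[agent])
    if sz0 <= sz_cr:
        raise ValueError("growth criterion applies only above the critical arousal")
    gamma = float(params.Gamma[agent])
    if gamma == 0.0:
        return "grows"
    ratio = float(params.gamma_plus[agent]) / gamma
    bound = (1.0 - sz_cr**2) / (sz_cr * (sz0 - sz_cr))
    if abs(ratio - bound) <= tol:
        return "marginal"
    return "grows" if ratio > bound else "shrinks"


# --------------------------------------------------------------------------
# network force and cubic steady state
# --------------------------------------------------------------------------

def network_force(
    p: np.ndarray,
    params: AgentParams,
    coupling: CouplingSpec,
    net: NetworkModel,
    mode: Literal["exact", "annealed"] = "exact",
) -> np.ndarray:
    """Force F_i = -(C^2 sigma_z0_i J_I_eff / g^2) sum_j A_ij p_j.

    Valid in the diffusive regime the derivation assumes: Delta = 0 and
    J_R = 0.  ``annealed`` replaces the adjacency sum by k_i * P-bar.
    """
    if np.any(np.abs(params.Delta) > 1e-12):
        raise ValueError("network force is derived at Delta = 0")
    if coupling.J_R != 0.0:
        raise ValueError("network force is derived for J_R = 0 (diffusive regime)")
    if params.g <= 0:
        raise ValueError("network force requires g > 0")
    p = np.asarray(p, dtype=complex)
    c = params.C  # scalar-valued array (Delta = 0)
    pref = -(c**2) * params.sigma_z0 * coupling.J_I_eff / params.g**2
    if mode == "exact":
        coupled = net.adjacency @ p
    elif mode == "annealed":
        coupled = net.degrees * mean_polarization(p, net)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pref * coupled


def cubic_steady_state(
    a_coef: float, b_coef: float, f0: float = 0.0, tol: float = 1e-12
) -> float:
    """Nonnegative steady-state root of  A p - B p^3 + F0 = 0.

    For A <= 0 the cubic is monotone with a unique nonnegative root; for
    A > 0, F0 > 0 Descartes' rule gives a single positive root and it is
    returned (continuous with the F0 -> 0 pitchfork branch sqrt(A/B)).
    Found by bracketed root-finding.
    """
    if b_coef <= 0:
        raise ValueError("B must be positive (requires gamma_+ > 0)")
    if f0 < 0:
        raise ValueError("F0 must be nonnegative for the activated branch")
    if f0 == 0.0:
        return math.sqrt(a_coef / b_coef) if a_coef > 0 else 0.0

    def f(x: float) -> float:
        return a_coef * x - b_coef * x**3 + f0

    hi = max(math.sqrt(max(a_coef, 0.0) / b_coef), (f0 / b_coef) ** (1.0 / 3.0)) + 1.0
    while f(hi) > 0:
        hi *= 2.0
    return float(brentq(f, 0.0, hi, xtol=tol, rtol=8.882e-16))


def mean_polarization(p: np.ndarray, net: NetworkModel) -> complex:
    """Degree-weighted mean affective field P-bar = sum_i k_i p_i / (N <k>)."""
    k = net.degrees.astype(float)
    total = k.sum()
    if total <= 0:
        raise ValueError("mean polarization needs <k> > 0")
    return complex(np.sum(k * np.asarray(p, dtype=complex)) / total)


# --------------------------------------------------------------------------
# collective gain
# --------------------------------------------------------------------------

def effective_gain(
    params: AgentParams, coupling: CouplingSpec, zeta: float
) -> float:
    """Network-enforced gain of the mean affective field.

    A_eff = (g^2 sigma_z0 / kappa)(1 - cos(Theta) J_I zeta / kappa) - Gamma.
    Derived for homogeneous sigma_z0 and Gamma; population means are used.
    """
    sz0 = float(params.sigma_z0.mean())
    gamma = float(params.Gamma.mean())
    g, kappa = params.g, params.kappa
    return (g**2 * sz0 / kappa) * (
        1.0 - coupling.J_I_eff * zeta / kappa
    ) - gamma


def gain_from_trajectory(
    t: np.ndarray | Trajectory,
    p_bar: np.ndarray | None = None,
    net: NetworkModel | None = None,
    window_fraction: float = GAIN_WINDOW_FRACTION,
) -> float:
    """Exponential rate of |P-bar|(t) fitted in the linear-growth window.

    Accepts either a precomputed P-bar series with its time grid, or a
    Trajectory plus the network (the degree-weighted mean is then formed
    from the per-agent amplitudes).  The fit is a least-squares slope of
    log |P-bar| against t restricted to |P-bar| < window_fraction * max.
    """
    if isinstance(t, Trajectory):
        if net is None:
            raise ValueError("need the network to weight the trajectory")
        traj = t
        k = net.degrees.astype(float)
        p_bar = (traj.p * k).sum(axis=1) / k.sum()
        t = traj.t
    t = np.asarray(t, dtype=float)
    mag = np.abs(np.asarray(p_bar))
    mask = mag < window_fraction * mag.max()
    if mask.sum() < 20:
        raise ValueError("fewer than 20 samples in the linear-growth window")
    if np.any(mag[mask] <= 0):
        raise ValueError("nonpositive |P-bar| in the fit window")
    slope, _ = np.polyfit(t[mask], np.log(mag[mask]), 1)
    return float(slope)


# --------------------------------------------------------------------------
# summary
# --------------------------------------------------------------------------

@dataclass
class SteadyStateSummary:
    sigma_z_cr: float
    sigma_perp_steady: float
    sigma_perp_0: float
    R_critical: float
    sphere_growth: str | None
    A: float
    B: float
    A_eff: float | None
    regime: str

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def summarize(
    params: AgentParams,
    coupling: CouplingSpec = CouplingSpec(),
    net: NetworkModel | None = None,
    agent: int = 0,
) -> SteadyStateSummary:
    """Closed-form steady-state report for one (representative) agent."""
    sz_cr = critical_arousal(params, agent)
    sz0 = float(params.sigma_z0[agent])
    c = float(params.C[agent])
    gamma_plus = float(params.gamma_plus[agent])
    perp = steady_perp(params, agent)
    perp0 = math.sqrt(gamma_plus * sz_cr / c) if sz_cr > 0 else 0.0
    above = sz0 > sz_cr
    growth = sphere_growth(params, agent) if (above and sz_cr > 0) else None
    a_coef = c * sz0 - float(params.Gamma[agent])
    b_coef = 4.0 * c**2 / gamma_plus if gamma_plus > 0 else math.inf
    a_eff = None
    if net is not None:
        a_eff = effective_gain(params, coupling, net.zeta)
    regime = "activated" if above else "neutral"
    return SteadyStateSummary(
        sigma_z_cr=sz_cr,
        sigma_perp_steady=perp,
        sigma_perp_0=perp0,
        R_critical=min(abs(sz_cr), 1.0),
        sphere_growth=growth,
        A=a_coef,
        B=b_coef,
        A_eff=a_eff,
        regime=regime,
    )
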