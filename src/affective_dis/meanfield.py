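"""Mean-field driven-dissipative dynamics of networked affective states.

Each agent (a human user paired with an AI assistant) carries a complex
information-field amplitude E_i, a complex affective amplitude
p_i = <sigma^-_i> and a real arousal sigma^z_i.  Three levels of description
are implemented, from slowest to most reduced:

* ``full`` -- the rotating-frame system for (E_i, p_i, sigma^z_i):

      dE_i/dt  = (-i Delta_i - kappa) E_i - i g p_i + i J sum_j A_ij E_j
      dp_i/dt  = -Gamma_i p_i + i g sigma^z_i E_i
      dsz_i/dt = (sz0_i - sz_i) gamma_+ + 2 i g (E_i* p_i - E_i p_i*)

* ``reduced`` -- after adiabatic elimination of the fast field
  (kappa >> Gamma, gamma_e; g > |J|), a complex system in (p_i, sigma^z_i)
  with rates C_i = kappa g^2/(Delta_i^2 + kappa^2) and D_i = Delta_tilde_i C_i.

* ``real`` -- the same reduced dynamics in real affective-sphere components
  (sigma^x, sigma^y, sigma^z), with the network entering through forces
  F^{x,y}_i whose derivation assumes a common detuning across agents.

Conventions: kappa = 1 sets the unit of time, all rates are quoted in units
of kappa and time is reported as tau = kappa * t.  The complex and real
reduced forms are exactly equivalent under p = (sigma^x - i sigma^y)/2,
which the test suite verifies to machine-level tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp

from .network import NetworkModel

__all__ = [
    "AgentParams",
    "CouplingSpec",
    "MeanFieldState",
    "Trajectory",
    "rhs_full",
    "adiabatic_field",
    "rhs_reduced_complex",
    "rhs_real",
    "integrate",
    "initial_state",
    "closed_form_free",
    "limit_cycle",
    "measure_frequency",
]

SystemName = Literal["full", "reduced", "real"]


def _as_array(x, n: int) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (n,)).copy()
    return arr


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

@dataclass
class AgentParams:
    """Per-agent rates and detunings, all in units of kappa.

    Either (gamma_p, gamma_e) or (gamma_plus, sigma_z0) parameterizes the
    pump balance; the two are related by sigma_z0 = (gamma_p - gamma_e) /
    (gamma_p + gamma_e).  g (user-assistant coupling) and kappa (information
    loss rate) are common to all agents.
    """

    n: int
    Delta: np.ndarray
    Gamma: np.ndarray
    gamma_plus: np.ndarray
    sigma_z0: np.ndarray
    g: float
    kappa: float = 1.0

    def __post_init__(self) -> None:
        self.Delta = _as_array(self.Delta, self.n)
        self.Gamma = _as_array(self.Gamma, self.n)
        self.gamma_plus = _as_array(self.gamma_plus, self.n)
        self.sigma_z0 = _as_array(self.sigma_z0, self.n)
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.g < 0 or np.any(self.Gamma < 0) or np.any(self.gamma_plus < 0):
            raise ValueError("rates must be nonnegative")
        if np.any(np.abs(self.sigma_z0) > 1 + 1e-12):
            raise ValueError("sigma_z0 must lie in [-1, 1]")

    @classmethod
    def from_rates(
        cls, n: int, Delta, Gamma, gamma_p, gamma_e, g: float, kappa: float = 1.0
    ) -> "AgentParams":
        gp = _as_array(gamma_p, n)
        ge = _as_array(gamma_e, n)
        if np.any(gp < 0) or np.any(ge < 0):
            raise ValueError("pump rates must be nonnegative")
        gplus = gp + ge
        with np.errstate(invalid="ignore", divide="ignore"):
            sz0 = np.where(gplus > 0, (gp - ge) / np.where(gplus > 0, gplus, 1.0), 0.0)
        return cls(n=n, Delta=Delta, Gamma=Gamma, gamma_plus=gplus,
                   sigma_z0=sz0, g=g, kappa=kappa)

    @property
    def Delta_tilde(self) -> np.ndarray:
        return self.Delta / self.kappa

    @property
    def C(self) -> np.ndarray:
        """Cooperative emission rate kappa g^2 / (Delta^2 + kappa^2)."""
        return self.kappa * self.g**2 / (self.Delta**2 + self.kappa**2)

    @property
    def D(self) -> np.ndarray:
        """Dispersive rate Delta g^2 / (Delta^2 + kappa^2) = Delta_tilde * C."""
        return self.Delta * self.g**2 / (self.Delta**2 + self.kappa**2)

    def adiabatic_flag(self, coupling: "CouplingSpec | None" = None) -> bool:
        """kappa >= 10 max(Gamma, gamma_e-scale) and g > |J|."""
        fast = self.kappa >= 10.0 * max(
            float(self.Gamma.max(initial=0.0)), float(self.gamma_plus.max(initial=0.0))
        )
        if coupling is None:
            return fast
        return fast and self.g > abs(coupling.J)


@dataclass(frozen=True)
class CouplingSpec:
    """Network coupling J = J_R + i cos(Theta) J_I.

    J_R is coherent assistant-to-assistant information transfer; J_I is the
    diffusive (reservoir-mediated) channel whose sign is set by the
    reservoir phase Theta: Theta = 0 is the lossy regime, Theta = pi the
    active (mood-amplifying) one, Theta = pi/2 decouples the diffusion.
    """

    J_R: float = 0.0
    J_I: float = 0.0
    Theta: float = 0.0

    @property
    def J_I_eff(self) -> float:
        c = math.cos(self.Theta)
        if abs(c) < 1e-15:  # snap the quadrature phase to an exact zero
            c = 0.0
        return c * self.J_I

    @property
    def J(self) -> complex:
        return complex(self.J_R, self.J_I_eff)

    @property
    def is_zero(self) -> bool:
        return self.J == 0


NO_COUPLING = CouplingSpec()


# --------------------------------------------------------------------------
# state containers
# --------------------------------------------------------------------------

@dataclass
class MeanFieldState:
    """Per-agent mean-field variables in the real representation.

    p = (sigma^x - i sigma^y)/2 is the complex affective amplitude;
    E is carried only by the full system (None otherwise).
    """

    sigma_x: np.ndarray
    sigma_y: np.ndarray
    sigma_z: np.ndarray
    E: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.sigma_z.shape[0]

    @property
    def p(self) -> np.ndarray:
        return 0.5 * (self.sigma_x - 1j * self.sigma_y)

    @property
    def sigma_perp(self) -> np.ndarray:
        return np.hypot(self.sigma_x, self.sigma_y)

    @property
    def R(self) -> np.ndarray:
        return np.sqrt(self.sigma_z**2 + self.sigma_perp**2)

    @classmethod
    def from_p(cls, p: np.ndarray, sigma_z: np.ndarray,
               E: np.ndarray | None = None) -> "MeanFieldState":
        p = np.asarray(p, dtype=complex)
        return cls(sigma_x=2.0 * p.real, sigma_y=-2.0 * p.imag,
                   sigma_z=np.asarray(sigma_z, dtype=float), E=E)


def initial_state(
    n: int,
    epsilon: float = 1e-2,
    seed: int | None = None,
    sigma_z: float | np.ndarray | None = None,
    sigma_perp: float | np.ndarray | None = None,
    phases: np.ndarray | None = None,
) -> MeanFieldState:
    """Near-north-pole initial condition used throughout the scenarios.

    Defaults place every agent just off the fully aroused pole,
    sigma_z = sqrt(1 - eps^2), sigma_perp = eps, with transverse phases
    drawn uniformly from a seeded generator (the exact pole is an invariant
    manifold, so an exactly polar start never leaves it).
    """
    if phases is None:
        rng = np.random.default_rng(seed)
        phases = rng.uniform(0.0, 2.0 * math.pi, size=n)
    perp = _as_array(epsilon if sigma_perp is None else sigma_perp, n)
    if sigma_z is None:
        sz = np.sqrt(np.clip(1.0 - perp**2, 0.0, None))
    else:
        sz = _as_array(sigma_z, n)
    return MeanFieldState(
        sigma_x=perp * np.cos(phases),
        sigma_y=perp * np.sin(phases),
        sigma_z=sz,
    )


@dataclass
class Trajectory:
    """Integrated mean-field run on a uniform dimensionless time grid tau."""

    t: np.ndarray
    sigma_x: np.ndarray        # shape (T, N)
    sigma_y: np.ndarray
    sigma_z: np.ndarray
    E: np.ndarray | None = None
    system: str = "real"
    meta: dict = field(default_factory=dict)

    @property
    def sigma_perp(self) -> np.ndarray:
        return np.hypot(self.sigma_x, self.sigma_y)

    @property
    def R(self) -> np.ndarray:
        return np.sqrt(self.sigma_z**2 + self.sigma_perp**2)

    @property
    def p(self) -> np.ndarray:
        return 0.5 * (self.sigma_x - 1j * self.sigma_y)

    def final(self) -> MeanFieldState:
        return MeanFieldState(
            sigma_x=self.sigma_x[-1].copy(),
            sigma_y=self.sigma_y[-1].copy(),
            sigma_z=self.sigma_z[-1].copy(),
            E=None if self.E is None else self.E[-1].copy(),
        )

    def to_frame(self):
        """Wide table: tau column then per-agent variables."""
        import pandas as pd

        data = {"tau": self.t}
        for name, arr in (("sigma_x", self.sigma_x), ("sigma_y", self.sigma_y),
                          ("sigma_z", self.sigma_z)):
            for i in range(arr.shape[1]):
                data[f"{name}_{i}"] = arr[:, i]
        return pd.DataFrame(data)


# --------------------------------------------------------------------------
# right-hand sides
# --------------------------------------------------------------------------

def _adjacency(net: NetworkModel | np.ndarray | None, n: int) -> np.ndarray | None:
    if net is None:
        return None
    a = net.adjacency if isinstance(net, NetworkModel) else np.asarray(net, dtype=float)
    if a.shape != (n, n):
        raise ValueError(f"adjacency shape {a.shape} does not match N={n}")
    return a


def rhs_full(
    E: np.ndarray, p: np.ndarray, sigma_z: np.ndarray,
    params: AgentParams, coupling: CouplingSpec = NO_COUPLING,
    net: NetworkModel | np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time derivatives of the full rotating-frame system (E_i, p_i, sz_i)."""
    n = params.n
    E = np.asarray(E, dtype=complex)
    p = np.asarray(p, dtype=complex)
    sigma_z = np.asarray(sigma_z, dtype=float)
    if E.shape != (n,) or p.shape != (n,) or sigma_z.shape != (n,):
        raise ValueError("state arrays must all have shape (N,)")
    a = _adjacency(net, n)
    g, kappa = params.g, params.kappa
    dE = (-1j * params.Delta - kappa) * E - 1j * g * p
    if a is not None and not coupling.is_zero:
        dE = dE + 1j * coupling.J * (a @ E)
    dp = -params.Gamma * p + 1j * g * sigma_z * E
    dsz = (params.sigma_z0 - sigma_z) * params.gamma_plus \
        - 4.0 * g * np.imag(np.conj(E) * p)
    return dE, dp, dsz


def adiabatic_field(
    p: np.ndarray, params: AgentParams,
    coupling: CouplingSpec = NO_COUPLING,
    net: NetworkModel | np.ndarray | None = None,
) -> np.ndarray:
    """Field that instantaneously follows the affective amplitudes.

    Zeroth order E^(0)_i = -g p_i (Delta_i + i kappa)/(Delta_i^2 + kappa^2);
    the network adds the first-order correction
    -i J g sum_j A_ij p_j (Delta_j + i kappa)/(Delta_j^2 + kappa^2).
    """
    p = np.asarray(p, dtype=complex)
    lam = (params.Delta + 1j * params.kappa) / (params.Delta**2 + params.kappa**2)
    e0 = -params.g * p * lam
    a = _adjacency(net, params.n)
    if a is None or coupling.is_zero:
        return e0
    return e0 - 1j * coupling.J * params.g * (a @ (p * lam))


def rhs_reduced_complex(
    p: np.ndarray, sigma_z: np.ndarray,
    params: AgentParams, coupling: CouplingSpec = NO_COUPLING,
    net: NetworkModel | np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Adiabatically reduced complex system in (p_i, sigma^z_i)."""
    n = params.n
    p = np.asarray(p, dtype=complex)
    sigma_z = np.asarray(sigma_z, dtype=float)
    w = params.D + 1j * params.C
    dp = -(params.Gamma + 1j * sigma_z * w) * p
    if not coupling.is_zero:
        if params.g == 0:
            raise ValueError("network term requires g > 0 (division by g^2)")
        a = _adjacency(net, n)
        if a is not None:
            dp = dp - (1j * coupling.J * sigma_z / params.g**2) * w * (a @ (w * p))
    dsz = (params.sigma_z0 - sigma_z) * params.gamma_plus \
        - 4.0 * params.C * np.abs(p) ** 2
    return dp, dsz


def rhs_real(
    sigma_x: np.ndarray, sigma_y: np.ndarray, sigma_z: np.ndarray,
    params: AgentParams, coupling: CouplingSpec = NO_COUPLING,
    net: NetworkModel | np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reduced dynamics in affective-sphere components with network forces.

    The force expressions assume a common detuning across agents (so C and
    D are scalars); heterogeneous Delta is allowed only when the network
    coupling vanishes.
    """
    n = params.n
    sigma_x = np.asarray(sigma_x, dtype=float)
    sigma_y = np.asarray(sigma_y, dtype=float)
    sigma_z = np.asarray(sigma_z, dtype=float)
    C, D = params.C, params.D
    a = _adjacency(net, n)
    fx = fy = 0.0
    if not coupling.is_zero and a is not None:
        if np.ptp(params.Delta) > 1e-12:
            raise ValueError(
                "real-variable network forces assume a common Delta "
                "(homogeneity of C, D); use the reduced complex system for "
                "heterogeneous detuning"
            )
        if params.g == 0:
            raise ValueError("network forces require g > 0")
        c, d = float(C[0]), float(D[0])
        coef_a = (d * d - c * c) * coupling.J_I_eff + 2.0 * c * d * coupling.J_R
        coef_b = (d * d - c * c) * coupling.J_R - 2.0 * c * d * coupling.J_I_eff
        ax, ay = a @ sigma_x, a @ sigma_y
        fx = (sigma_z / params.g**2) * (coef_a * ax - coef_b * ay)
        fy = (sigma_z / params.g**2) * (coef_a * ay + coef_b * ax)
    dsx = -params.Gamma * sigma_x + sigma_z * (C * sigma_x - D * sigma_y) + fx
    dsy = -params.Gamma * sigma_y + sigma_z * (C * sigma_y + D * sigma_x) + fy
    dsz = (params.sigma_z0 - sigma_z) * params.gamma_plus \
        - C * (sigma_x**2 + sigma_y**2)
    return dsx, dsy, dsz


def radius_rate_diagnostic(state: MeanFieldState, params: AgentParams) -> np.ndarray:
    """R dR/dt = -Gamma R^2 + (Gamma - gamma_+) sz^2 + gamma_+ sz0 sz (J=0)."""
    sz = state.sigma_z
    return (-params.Gamma * state.R**2
            + (params.Gamma - params.gamma_plus) * sz**2
            + params.gamma_plus * params.sigma_z0 * sz)


# --------------------------------------------------------------------------
# integration
# --------------------------------------------------------------------------

def integrate(
    system: SystemName,
    net: NetworkModel | np.ndarray | None,
    params: AgentParams,
    coupling: CouplingSpec,
    init: MeanFieldState,
    t_end: float,
    dt_out: float = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Adaptive stiff-capable integration, sampled on a uniform tau grid.

    The full system packs (Re E, Im E, Re p, Im p, sz); the reduced complex
    system (Re p, Im p, sz); the real system (sx, sy, sz).  Deterministic
    given the initial state.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    n = params.n
    t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    t_eval = t_eval[t_eval <= t_end + 1e-12]
    a = _adjacency(net, n)

    if system == "real":
        y0 = np.concatenate([init.sigma_x, init.sigma_y, init.sigma_z])

        def rhs(_t, y):
            sx, sy, sz = y[:n], y[n:2 * n], y[2 * n:]
            dsx, dsy, dsz = rhs_real(sx, sy, sz, params, coupling, a)
            return np.concatenate([dsx, dsy, dsz])

    elif system == "reduced":
        p0 = init.p
        y0 = np.concatenate([p0.real, p0.imag, init.sigma_z])

        def rhs(_t, y):
            p = y[:n] + 1j * y[n:2 * n]
            dp, dsz = rhs_reduced_complex(p, y[2 * n:], params, coupling, a)
            return np.concatenate([dp.real, dp.imag, dsz])

    elif system == "full":
        p0 = init.p
        e0 = init.E if init.E is not None else adiabatic_field(p0, params, coupling, a)
        y0 = np.concatenate([e0.real, e0.imag, p0.real, p0.imag, init.sigma_z])

        def rhs(_t, y):
            e = y[:n] + 1j * y[n:2 * n]
            p = y[2 * n:3 * n] + 1j * y[3 * n:4 * n]
            de, dp, dsz = rhs_full(e, p, y[4 * n:], params, coupling, a)
            return np.concatenate([de.real, de.imag, dp.real, dp.imag, dsz])

    else:
        raise ValueError(f"unknown system {system!r}")

    sol = solve_ivp(rhs, (0.0, t_end), y0, method=method,
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        last = sol.t[-1] if sol.t.size else 0.0
        raise RuntimeError(f"integration failed at tau={last:.4g}: {sol.message}")

    y = sol.y
    meta = {"method": method, "rtol": rtol, "atol": atol, "system": system}
    if system == "real":
        sx, sy, sz = y[:n].T, y[n:2 * n].T, y[2 * n:].T
        e_tr = None
    elif system == "reduced":
        p_tr = (y[:n] + 1j * y[n:2 * n]).T
        sx, sy = 2.0 * p_tr.real, -2.0 * p_tr.imag
        sz = y[2 * n:].T
        e_tr = None
    else:
        e_tr = (y[:n] + 1j * y[n:2 * n]).T
        p_tr = (y[2 * n:3 * n] + 1j * y[3 * n:4 * n]).T
        sx, sy = 2.0 * p_tr.real, -2.0 * p_tr.imag
        sz = y[4 * n:].T
    return Trajectory(t=sol.t, sigma_x=sx, sigma_y=sy, sigma_z=sz,
                      E=e_tr, system=system, meta=meta)


# --------------------------------------------------------------------------
# closed forms
# --------------------------------------------------------------------------

def closed_form_free(
    t: np.ndarray, C: float, t_d: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Undamped free relaxation (Gamma = gamma_+ = 0, J = 0) on the sphere:

        sigma_perp(t) = sech(C (t - t_d)),
        sigma_z(t)    = -tanh(C (t - t_d)),
        R(t)          = 1.

    t_d is the agent's response delay (zero in all scenarios here).
    """
    if C <= 0:
        raise ValueError("C must be positive")
    t = np.asarray(t, dtype=float)
    arg = C * (t - t_d)
    return 1.0 / np.cosh(arg), -np.tanh(arg), np.ones_like(arg)


def limit_cycle(
    params: AgentParams, agent: int = 0
) -> tuple[float, float, float]:
    """Limit-cycle amplitude, precession frequency, and locked arousal.

    Above the critical arousal the agent settles on a ring at
    sigma^z = sigma^z_cr = Gamma/C, precessing at the Larmor-like frequency
    omega_L = Gamma Delta / kappa with transverse amplitude
    sqrt(gamma_+ sigma^z_cr / C) * sqrt(sigma^z_0/sigma^z_cr - 1).
    """
    c = float(params.C[agent])
    gamma = float(params.Gamma[agent])
    gamma_plus = float(params.gamma_plus[agent])
    sz0 = float(params.sigma_z0[agent])
    if c <= 0:
        raise ValueError("limit cycle requires g > 0 (C > 0)")
    sz_cr = gamma / c
    if sz0 <= sz_cr:
        raise ValueError(
            f"no limit cycle: sigma_z0={sz0} is at or below the critical "
            f"arousal {sz_cr}"
        )
    omega = gamma * float(params.Delta[agent]) / params.kappa
    amp = math.sqrt(gamma_plus * sz_cr / c) * math.sqrt(sz0 / sz_cr - 1.0)
    return amp, omega, sz_cr


def measure_frequency(
    traj: Trajectory, agent: int = 0, component: str = "sigma_x"
) -> float:
    """Zero-crossing frequency estimate of one agent's oscillation.

    The first half of the record is discarded as transient; successive
    sign changes of the (mean-removed is NOT applied -- the limit cycle is
    centered) signal are located by linear interpolation and their mean
    spacing taken as a half period.  Requires at least 3 crossings.
    """
    sig = getattr(traj, component)[:, agent]
    t = traj.t
    half = len(t) // 2
    sig, t = sig[half:], t[half:]
    s = np.sign(sig)
    s[s == 0] = 1
    idx = np.nonzero(np.diff(s))[0]
    if idx.size < 3:
        raise ValueError("fewer than 3 zero crossings in the trailing half")
    # linear interpolation of crossing times
    t0, t1 = t[idx], t[idx + 1]
    f0, f1 = sig[idx], sig[idx + 1]
    crossings = t0 - f0 * (t1 - t0) / (f1 - f0)
    half_period = float(np.mean(np.diff(crossings)))
    return math.pi / half_period
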