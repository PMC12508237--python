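"""Qubit-like affective states on the emotional (Bloch) sphere.

A single agent's emotional state is the pure two-level state

    |Psi> = cos(theta/2) |0> + e^{i phi} sin(theta/2) |1>,

with ``|1>`` the aroused (excited) and ``|0>`` the unaroused (calm) basic
state.  The poles of the sphere encode arousal, the two equatorial axes the
pleasure--annoyance and dominance--submissiveness pairs of the PAD emotion
model (or Wundt's feeling pairs under the alternative labeling).  The sign
conventions for the expectation vector are

    sigma_x = sin(theta) cos(phi),
    sigma_y = -sin(theta) sin(phi),
    sigma_z = -cos(theta),

so ``theta = pi`` is the fully aroused state (sigma_z = +1) and
``theta = 0`` the calm one (sigma_z = -1).  All operator matrices are built
from the ladder-operator definitions sigma^+ = |1><0|, sigma^- = |0><1|,
which makes the conventions above a theorem rather than a choice.

The module also implements the "social tomography" estimator: repeated
two-outcome measurements in the computational, +/- and +/-i bases whose
normalized count differences estimate sigma^{x,y,z}.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "PureEmotionState",
    "LabelScheme",
    "BasisLabeling",
    "OperatorSet",
    "TomographyResult",
    "bloch_expectations",
    "rotate",
    "algebra_check",
    "uncertainty_check",
    "tomography",
    "collective_polarization",
]

_POLE_TOL = 1e-12


# --------------------------------------------------------------------------
# states and labelings
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PureEmotionState:
    """Point (theta, phi) on the affective sphere.

    theta in [0, pi], phi in [0, 2 pi).  At the poles phi is undefined and
    is canonicalized to 0.
    """

    theta: float
    phi: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= math.pi + 1e-15):
            raise ValueError(f"theta must lie in [0, pi], got {self.theta}")
        if not (0.0 <= self.phi < 2.0 * math.pi):
            raise ValueError(f"phi must lie in [0, 2*pi), got {self.phi}")
        if math.sin(self.theta) < _POLE_TOL and self.phi != 0.0:
            object.__setattr__(self, "phi", 0.0)

    @property
    def vector(self) -> np.ndarray:
        """Complex amplitudes (on |0>, on |1>); unit norm by construction."""
        return np.array(
            [math.cos(self.theta / 2.0),
             np.exp(1j * self.phi) * math.sin(self.theta / 2.0)],
            dtype=complex,
        )

    @classmethod
    def from_vector(cls, psi: Sequence[complex]) -> "PureEmotionState":
        """Recover (theta, phi) from a state vector, discarding global phase."""
        psi = np.asarray(psi, dtype=complex)
        norm = np.linalg.norm(psi)
        if norm < _POLE_TOL:
            raise ValueError("cannot normalize a zero vector")
        psi = psi / norm
        # rotate global phase so the |0> amplitude is real and nonnegative
        if abs(psi[0]) > _POLE_TOL:
            psi = psi * np.exp(-1j * np.angle(psi[0]))
        else:
            psi = psi * np.exp(-1j * np.angle(psi[1]))
        # atan2 chart stays well-conditioned at the poles (acos does not)
        theta = 2.0 * math.atan2(abs(psi[1]), abs(psi[0]))
        theta = float(np.clip(theta, 0.0, math.pi))
        if math.sin(theta / 2.0) < _POLE_TOL or abs(psi[1]) < _POLE_TOL:
            phi = 0.0
        else:
            phi = float(np.angle(psi[1])) % (2.0 * math.pi)
            if phi >= 2.0 * math.pi:  # float fold-over at the wrap point
                phi = 0.0
        return cls(theta=theta, phi=phi)

    def to_json(self, scheme: "LabelScheme | None" = None) -> str:
        rec = {"theta": self.theta, "phi": self.phi}
        if scheme is not None:
            rec["labeling_scheme"] = scheme.value
        return json.dumps(rec)

    @classmethod
    def from_json(cls, text: str) -> "PureEmotionState":
        rec = json.loads(text)
        return cls(theta=rec["theta"], phi=rec["phi"])


class LabelScheme(str, enum.Enum):
    PAD = "PAD"
    WUNDT = "Wundt"


_LABELS = {
    LabelScheme.PAD: {
        "|1>": "Aroused", "|0>": "Unaroused",
        "|+>": "Pleased", "|->": "Annoyed",
        "|+i>": "Dominant", "|-i>": "Submissive",
    },
    LabelScheme.WUNDT: {
        "|1>": "Excitement", "|0>": "Calm",
        "|+>": "Pleasantness", "|->": "Unpleasantness",
        "|+i>": "Strain", "|-i>": "Relaxation",
    },
}


@dataclass(frozen=True)
class BasisLabeling:
    """Mapping of the six basis states to emotion words for one scheme."""

    scheme: LabelScheme
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.labels:
            object.__setattr__(self, "labels", dict(_LABELS[self.scheme]))


# --------------------------------------------------------------------------
# operator algebra
# --------------------------------------------------------------------------

class OperatorSet:
    """2x2 matrix representations in the {|0>, |1>} basis.

    Built from sigma^+ = |1><0| and sigma^- = |0><1|; sigma^{x,y,z} and the
    identity-like sigma_0 follow from their defining combinations.  Note
    sigma^y = i(sigma^- - sigma^+) differs by a sign from the textbook Pauli
    y matrix; every downstream formula uses this convention consistently.
    """

    def __init__(self) -> None:
        # basis ordering (|0>, |1>): entry [row, col] = <row| Op |col>
        self.sigma_plus = np.array([[0, 0], [1, 0]], dtype=complex)
        self.sigma_minus = np.array([[0, 1], [0, 0]], dtype=complex)
        self.sigma_z = np.array([[-1, 0], [0, 1]], dtype=complex)
        self.sigma_0 = np.eye(2, dtype=complex)
        self.sigma_x = self.sigma_plus + self.sigma_minus
        self.sigma_y = 1j * (self.sigma_minus - self.sigma_plus)

    def axis(self, name: str) -> np.ndarray:
        try:
            return {"x": self.sigma_x, "y": self.sigma_y, "z": self.sigma_z}[name]
        except KeyError:
            raise ValueError(f"axis must be one of x, y, z, got {name!r}") from None


_OPS = OperatorSet()


def _comm(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return a @ b - b @ a


def algebra_check(ops: OperatorSet | None = None) -> dict:
    """Residual norms of the su(2) commutation relations.

    Checks [sigma^z, sigma^pm] = +-2 sigma^pm, [sigma^+, sigma^-] = sigma^z,
    [sigma^x, sigma^y] = 2i sigma^z, [sigma_0, sigma^{x,y,z}] = 0, plus
    hermiticity of sigma^{x,y,z} and (sigma^+)^dagger = sigma^-.
    """
    o = ops or _OPS
    residuals = {
        "[z,+] - 2+": _comm(o.sigma_z, o.sigma_plus) - 2 * o.sigma_plus,
        "[z,-] + 2-": _comm(o.sigma_z, o.sigma_minus) + 2 * o.sigma_minus,
        "[+,-] - z": _comm(o.sigma_plus, o.sigma_minus) - o.sigma_z,
        "[x,y] - 2iz": _comm(o.sigma_x, o.sigma_y) - 2j * o.sigma_z,
        "[0,x]": _comm(o.sigma_0, o.sigma_x),
        "[0,y]": _comm(o.sigma_0, o.sigma_y),
        "[0,z]": _comm(o.sigma_0, o.sigma_z),
        "x - x^dag": o.sigma_x - o.sigma_x.conj().T,
        "y - y^dag": o.sigma_y - o.sigma_y.conj().T,
        "z - z^dag": o.sigma_z - o.sigma_z.conj().T,
        "(+)^dag - (-)": o.sigma_plus.conj().T - o.sigma_minus,
    }
    report = {k: float(np.max(np.abs(v))) for k, v in residuals.items()}
    report["max_residual"] = max(report.values())
    return report


# --------------------------------------------------------------------------
# expectations, rotations, uncertainty
# --------------------------------------------------------------------------

def bloch_expectations(state: PureEmotionState) -> tuple[float, float, float]:
    """(sigma_x, sigma_y, sigma_z) = (sin t cos p, -sin t sin p, -cos t)."""
    t, p = state.theta, state.phi
    return (
        math.sin(t) * math.cos(p),
        -math.sin(t) * math.sin(p),
        -math.cos(t),
    )


def expectation(state: PureEmotionState, op: np.ndarray) -> complex:
    """<Psi| op |Psi> for an arbitrary 2x2 operator."""
    psi = state.vector
    return complex(psi.conj() @ op @ psi)


def rotate(state: PureEmotionState, axis: str, angle: float) -> PureEmotionState:
    """Rotate the state by ``angle`` about ``axis``: exp(-i angle sigma^axis / 2)."""
    if not math.isfinite(angle):
        raise ValueError("rotation angle must be finite")
    u = expm(-0.5j * angle * _OPS.axis(axis))
    return PureEmotionState.from_vector(u @ state.vector)


def uncertainty_check(state: PureEmotionState) -> tuple[float, float, bool]:
    """Robertson bound Var(sigma^x) Var(sigma^y) >= <sigma^z>^2.

    The commutator [sigma^x, sigma^y] = 2i sigma^z gives the bound
    |<[x, y]>|^2 / 4 = <sigma^z>^2; every pure state satisfies it, with
    equality iff sigma^x sigma^y = 0 (in particular at the poles, where
    both variances are 1 and <sigma^z>^2 = 1).  Returns (lhs, rhs,
    satisfied).
    """
    sx, sy, sz = bloch_expectations(state)
    # (sigma^{x,y})^2 = identity, so Var = 1 - <sigma>^2
    lhs = (1.0 - sx * sx) * (1.0 - sy * sy)
    rhs = sz * sz
    return lhs, rhs, lhs >= rhs - 1e-12


# --------------------------------------------------------------------------
# social tomography
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TomographyResult:
    """Count-difference estimates of the affective-vector components."""

    estimates: dict        # {"x": .., "y": .., "z": ..}
    counts: dict           # per-basis outcome counts
    samples_per_basis: int
    seed: int

    def to_json(self) -> str:
        return json.dumps({
            "estimates": self.estimates,
            "counts": self.counts,
            "M": self.samples_per_basis,
            "seed": self.seed,
        })


def _ket(amps: Sequence[complex]) -> np.ndarray:
    return np.asarray(amps, dtype=complex) / math.sqrt(2.0)


_PLUS = _ket([1, 1])
_MINUS = _ket([1, -1])
_PLUS_I = _ket([1, 1j])
_MINUS_I = _ket([1, -1j])


def tomography(
    state: PureEmotionState,
    samples_per_basis: int = 10_000,
    seed: int | None = None,
) -> TomographyResult:
    """Estimate sigma^{x,y,z} from Bernoulli draws in three bases.

    sigma^z is estimated in the computational basis as (n1 - n0)/M;
    sigma^x in the +/- basis as (n+ - n-)/M; sigma^y in the +/-i basis as
    (n_{-i} - n_{+i})/M, the ordering fixed by sigma^y = n^(-i) - n^(+i).
    A seed is required: the estimator is stochastic and runs must be
    reproducible.
    """
    if samples_per_basis < 1:
        raise ValueError("samples_per_basis must be >= 1")
    if seed is None:
        raise ValueError("an explicit seed is required")
    rng = np.random.default_rng(seed)
    psi = state.vector
    m = samples_per_basis

    p1 = float(np.clip(abs(psi[1]) ** 2, 0.0, 1.0))
    p_plus = float(np.clip(abs(_PLUS.conj() @ psi) ** 2, 0.0, 1.0))
    p_minus_i = float(np.clip(abs(_MINUS_I.conj() @ psi) ** 2, 0.0, 1.0))

    n1 = int(rng.binomial(m, p1))
    n_plus = int(rng.binomial(m, p_plus))
    n_minus_i = int(rng.binomial(m, p_minus_i))

    counts = {
        "computational": {"n1": n1, "n0": m - n1},
        "pm": {"n_plus": n_plus, "n_minus": m - n_plus},
        "pmi": {"n_minus_i": n_minus_i, "n_plus_i": m - n_minus_i},
    }
    estimates = {
        "z": (2 * n1 - m) / m,
        "x": (2 * n_plus - m) / m,
        "y": (2 * n_minus_i - m) / m,
    }
    return TomographyResult(estimates, counts, m, seed)


# --------------------------------------------------------------------------
# collective variables
# --------------------------------------------------------------------------

def collective_polarization(
    states: Iterable[PureEmotionState] | np.ndarray,
) -> tuple[complex, tuple[float, float, float]]:
    """Collective affective field P = sum_i <sigma^-_i> and component sums.

    Accepts either pure states (P from <Psi|sigma^-|Psi> = 1/2 sin(theta)
    e^{i phi}) or an array of complex amplitudes p_i already equal to
    <sigma^->.  The component sums follow from p via sigma^x = 2 Re p,
    sigma^y = -2 Im p together with sigma^z when states are given.
    """
    states = list(states) if not isinstance(states, np.ndarray) else states
    if len(states) == 0:
        raise ValueError("need at least one agent")
    if isinstance(states, np.ndarray) or not isinstance(states[0], PureEmotionState):
        p = np.asarray(states, dtype=complex)
        big_p = complex(p.sum())
        # sigma^- = (sigma^x - i sigma^y)/2  =>  sx = 2 Re p, sy = -2 Im p
        return big_p, (2.0 * float(p.real.sum()), -2.0 * float(p.imag.sum()), math.nan)
    p = np.array([expectation(s, _OPS.sigma_minus) for s in states])
    comps = np.array([bloch_expectations(s) for s in states]).sum(axis=0)
    return complex(p.sum()), (float(comps[0]), float(comps[1]), float(comps[2]))
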