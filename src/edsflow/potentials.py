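"""Enveloping distribution sampling (EDS) reference-state potentials.

An EDS reference state envelops ``N`` end-state potentials ``V_i`` in a
single smooth Hamiltonian

    V_R(r; s, E) = -(1 / (beta * s)) * ln( sum_i exp(-beta * s * (V_i(r) - E_i)) )

where ``beta = 1/(kB*T)``, ``s`` in ``(0, 1]`` is the smoothing parameter and
``E_i`` are per-state energy offsets.  ``s = 1`` preserves the physical
minima of all end states; as ``s -> 0`` the barriers between them are
flattened and all states contribute equally (the "undersampling" regime).

All mixture arithmetic is done in log space with a max shift so that
end-state energy gaps of hundreds of kJ/mol never overflow, even for
``s`` as small as 1e-5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "KB_KJ_PER_MOL_K",
    "ThermoContext",
    "PotentialEvaluationError",
    "EndStatePotential",
    "HarmonicPotential",
    "DoubleWellPotential",
    "CallablePotential",
    "ReferenceState",
    "state_energies",
    "eds_energy",
    "eds_weights",
    "eds_forces",
    "eds_energy_from_matrix",
    "eds_weights_from_matrix",
]

#: Boltzmann constant in kJ mol^-1 K^-1.
KB_KJ_PER_MOL_K = 0.00831446


class PotentialEvaluationError(RuntimeError):
    """Raised when an end-state energy or gradient cannot be evaluated."""


@dataclass(frozen=True)
class ThermoContext:
    """Thermodynamic context: temperature and the Boltzmann constant.

    Parameters
    ----------
    temperature : float
        Absolute temperature in K.  Default 300 K.
    boltzmann_constant : float
        kB in kJ mol^-1 K^-1.
    """

    temperature: float = 300.0
    boltzmann_constant: float = KB_KJ_PER_MOL_K

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if not (self.boltzmann_constant > 0):
            raise ValueError("boltzmann_constant must be positive")

    @property
    def kT(self) -> float:
        """Thermal energy kB*T in kJ/mol."""
        return self.boltzmann_constant * self.temperature

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(kB*T) in mol/kJ."""
        return 1.0 / self.kT


class EndStatePotential:
    """Base class for end-state potentials.

    Subclasses implement :meth:`energy` and (optionally) :meth:`gradient`,
    both vectorised over leading batch axes: for coordinates of shape
    ``(..., d)``, ``energy`` returns shape ``(...,)`` and ``gradient``
    returns shape ``(..., d)``.
    """

    identifier: str = "state"
    dimension: int = 1

    def energy(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:
        """Analytic gradient; default falls back to central differences.

        The finite-difference fallback uses a step of 1e-6 (nm) and is
        substantially slower than an analytic gradient.
        """
        x = np.asarray(x, dtype=float)
        h = 1e-6
        grad = np.empty_like(x)
        for k in range(x.shape[-1]):
            xp = x.copy()
            xm = x.copy()
            xp[..., k] += h
            xm[..., k] -= h
            grad[..., k] = (self.energy(xp) - self.energy(xm)) / (2 * h)
        return grad

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{type(self).__name__}({self.identifier!r})"


@dataclass(repr=False)
class HarmonicPotential(EndStatePotential):
    """Separable harmonic well ``V(x) = shift + 0.5 * sum_d k_d (x_d - x0_d)^2``.

    Force constants are in kJ mol^-1 nm^-2, positions in nm and the
    additive shift in kJ/mol.  This is the workhorse end state for the
    analytic toy systems: its configurational partition function is a
    Gaussian integral, so pairwise free-energy differences have a closed
    form.
    """

    force_constants: np.ndarray = field(default_factory=lambda: np.array([1000.0]))
    minimum: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    shift: float = 0.0
    identifier: str = "harmonic"

    def __post_init__(self) -> None:
        self.force_constants = np.atleast_1d(np.asarray(self.force_constants, dtype=float))
        self.minimum = np.atleast_1d(np.asarray(self.minimum, dtype=float))
        if self.force_constants.shape != self.minimum.shape:
            raise ValueError("force_constants and minimum must have the same shape")
        if np.any(self.force_constants <= 0):
            raise ValueError("force constants must be positive")
        self.dimension = self.force_constants.size

    def energy(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        d = x - self.minimum
        return self.shift + 0.5 * np.sum(self.force_constants * d * d, axis=-1)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.force_constants * (x - self.minimum)

    def boltzmann_sigma(self, thermo: ThermoContext) -> np.ndarray:
        """Per-dimension standard deviation sqrt(kT/k) of the Boltzmann ensemble."""
        return np.sqrt(thermo.kT / self.force_constants)


@dataclass(repr=False)
class DoubleWellPotential(EndStatePotential):
    """1D quartic double well ``V(x) = a*(x^2 - b^2)^2 + c*x + shift``.

    ``a`` in kJ mol^-1 nm^-4 sets the barrier height, ``b`` (nm) the well
    separation, ``c`` (kJ mol^-1 nm^-1) a linear tilt.  Used to exercise the
    generic (quadrature-based) free-energy oracle on a non-Gaussian state.
    """

    a: float = 1000.0
    b: float = 0.25
    c: float = 0.0
    shift: float = 0.0
    identifier: str = "doublewell"
    dimension: int = 1

    def energy(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        x0 = x[..., 0]
        return self.a * (x0 * x0 - self.b * self.b) ** 2 + self.c * x0 + self.shift

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        x0 = x[..., 0]
        g = 4.0 * self.a * x0 * (x0 * x0 - self.b * self.b) + self.c
        return g[..., np.newaxis]


@dataclass(repr=False)
class CallablePotential(EndStatePotential):
    """Wrap arbitrary energy / gradient callables as an end state.

    ``gradient_fn`` may be omitted, in which case the central-difference
    fallback of :class:`EndStatePotential` is used.
    """

    energy_fn: Callable[[np.ndarray], np.ndarray] = None  # type: ignore[assignment]
    gradient_fn: Callable[[np.ndarray], np.ndarray] | None = None
    identifier: str = "callable"
    dimension: int = 1

    def energy(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.energy_fn(np.asarray(x, dtype=float)))

    def gradient(self, x: np.ndarray) -> np.ndarray:
        if self.gradient_fn is None:
            return super().gradient(x)
        return np.asarray(self.gradient_fn(np.asarray(x, dtype=float)))


@dataclass
class ReferenceState:
    """EDS reference state: N end states, smoothing parameter s and offsets.

    Parameters
    ----------
    end_states : sequence of EndStatePotential
    s : float
        Smoothing parameter, in (0, 1].
    offsets : array-like, length N
        Energy offsets E_i in kJ/mol.  Internally absolute; reporting
        conventionally pins state 1 to zero.
    thermo : ThermoContext
    """

    end_states: Sequence[EndStatePotential]
    s: float = 1.0
    offsets: np.ndarray = None  # type: ignore[assignment]
    thermo: ThermoContext = field(default_factory=ThermoContext)

    def __post_init__(self) -> None:
        self.end_states = list(self.end_states)
        if len(self.end_states) < 1:
            raise ValueError("need at least one end state")
        dims = {st.dimension for st in self.end_states}
        if len(dims) != 1:
            raise ValueError(f"end states have mismatched dimensions: {sorted(dims)}")
        if not (0 < self.s <= 1.0):
            raise ValueError(f"smoothing parameter s must be in (0, 1], got {self.s}")
        if self.offsets is None:
            self.offsets = np.zeros(len(self.end_states))
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.offsets.shape != (len(self.end_states),):
            raise ValueError("offsets must have one entry per end state")
        if not np.all(np.isfinite(self.offsets)):
            raise ValueError("offsets must be finite")

    @property
    def n_states(self) -> int:
        return len(self.end_states)

    @property
    def dimension(self) -> int:
        return self.end_states[0].dimension

    def with_s(self, s: float) -> "ReferenceState":
        """Copy of this reference state at a different smoothing parameter."""
        return ReferenceState(self.end_states, s=s, offsets=self.offsets.copy(), thermo=self.thermo)

    def with_offsets(self, offsets: np.ndarray) -> "ReferenceState":
        return ReferenceState(self.end_states, s=self.s, offsets=np.asarray(offsets, float), thermo=self.thermo)

    # convenience method forms of the module-level functions
    def energy(self, x: np.ndarray) -> np.ndarray:
        return eds_energy(self, x)

    def weights(self, x: np.ndarray) -> np.ndarray:
        return eds_weights(self, x)

    def forces(self, x: np.ndarray) -> np.ndarray:
        return eds_forces(self, x)


def _check_conf(ref: ReferenceState, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != ref.dimension:
        raise ValueError(
            f"configuration dimension {x.shape[-1]} does not match end states ({ref.dimension})"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("configuration contains non-finite coordinates")
    return x


def state_energies(ref: ReferenceState, x: np.ndarray) -> np.ndarray:
    """End-state energy matrix V_i(x), shape ``(..., N)``.

    Raises :class:`PotentialEvaluationError` naming the offending state if
    any end-state energy is non-finite.
    """
    x = _check_conf(ref, x)
    cols = []
    for st in ref.end_states:
        v = np.asarray(st.energy(x), dtype=float)
        if not np.all(np.isfinite(v)):
            raise PotentialEvaluationError(
                f"end state {st.identifier!r} produced a non-finite energy"
            )
        cols.append(v)
    return np.stack(cols, axis=-1)


def eds_energy_from_matrix(
    energies: np.ndarray, offsets: np.ndarray, s: float, beta: float
) -> np.ndarray:
    """V_R from a precomputed end-state energy matrix ``(..., N)``.

    Shifted log-sum-exp; safe for end-state gaps of arbitrary size.
    """
    h = -beta * s * (np.asarray(energies, float) - np.asarray(offsets, float))
    return -logsumexp(h, axis=-1) / (beta * s)


def eds_weights_from_matrix(
    energies: np.ndarray, offsets: np.ndarray, s: float, beta: float
) -> np.ndarray:
    """Softmax weights w_i from a precomputed energy matrix; rows sum to 1."""
    h = -beta * s * (np.asarray(energies, float) - np.asarray(offsets, float))
    logw = h - logsumexp(h, axis=-1, keepdims=True)
    return np.exp(logw)


def eds_energy(ref: ReferenceState, x: np.ndarray) -> np.ndarray:
    """Reference-state potential energy V_R(x; s, E) in kJ/mol.

    For a single end state this reduces exactly to ``V_1(x) - E_1``.
    """
    v = state_energies(ref, x)
    return eds_energy_from_matrix(v, ref.offsets, ref.s, ref.thermo.beta)


def eds_weights(ref: ReferenceState, x: np.ndarray) -> np.ndarray:
    """Per-state mixture weights, shape ``(..., N)``; sum to 1 along the last axis.

    These are the softmax factors that weight the end-state forces in the
    reference state; at small ``s`` they tend to the uniform vector 1/N.
    """
    v = state_energies(ref, x)
    return eds_weights_from_matrix(v, ref.offsets, ref.s, ref.thermo.beta)


def eds_forces(ref: ReferenceState, x: np.ndarray) -> np.ndarray:
    """Reference-state force -dV_R/dx = -sum_i w_i * dV_i/dx, shape ``(..., d)``."""
    x = _check_conf(ref, x)
    w = eds_weights(ref, x)
    force = np.zeros_like(x)
    for i, st in enumerate(ref.end_states):
        g = np.asarray(st.gradient(x), dtype=float)
        if g.shape != x.shape:
            raise PotentialEvaluationError(
                f"end state {st.identifier!r} gradient has shape {g.shape}, expected {x.shape}"
            )
        if not np.all(np.isfinite(g)):
            raise PotentialEvaluationError(
                f"end state {st.identifier!r} produced a non-finite gradient"
            )
        force -= w[..., i, np.newaxis] * g
    return force


def pin_offsets(offsets: np.ndarray) -> np.ndarray:
    """Report offsets relative to state 1 (first entry pinned to zero)."""
    offsets = np.asarray(offsets, dtype=float)
    return offsets - offsets[0]
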