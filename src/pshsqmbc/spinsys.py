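"""Spin-1/2 systems, product operators and exact unitary propagation.

Sign and normalization conventions (fixed here, inherited project-wide)
----------------------------------------------------------------------
* Rotations are right-handed: a 90deg pulse of phase x takes Iz -> -Iy.
* Free precession under an offset ``Omega`` (Hz) uses the propagator
  ``U = exp(-i 2 pi H t)`` with ``H = Omega Iz + ...``, so
  ``Ix -> Ix cos(2 pi Omega t) + Iy sin(2 pi Omega t)``.
* The detection operator is ``I- = Ix - i Iy`` summed over the detected
  spins: ``signal = Tr(rho * sum I-)``.  With these two conventions an
  isolated spin at offset ``+Omega`` yields ``s(t) ~ exp(-i 2 pi Omega t)``
  and the Fourier transform in :mod:`pshsqmbc.recon` places it at
  ``+Omega`` on an ascending frequency axis.  The detection operator
  responds to the ``I+`` (coherence order +1) component of the density
  operator; the single-spin normalization constant is
  ``Tr(Ix I-) = 2**(N-2)`` for an N-spin system.
* Relaxation is not propagated in the density matrix: per-spin exponential
  decay at rate ``pi * linewidth`` is applied to detected amplitudes at
  acquisition time (see :mod:`pshsqmbc.sequence`).

Dense complex matrices are used throughout; the practical ceiling is
N = 8 spins (256 x 256 operators).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import yaml

from .isotopes import Isotope, get_isotope

__all__ = [
    "Spin",
    "SpinSystem",
    "SpinState",
    "Hamiltonian",
    "build_hamiltonian",
    "thermal_state",
    "pulse",
    "pulse_selective",
    "evolve",
    "detect",
]

_HERM_TOL = 1e-10

# single-spin operator blocks
_E2 = np.eye(2, dtype=complex)
_IX = np.array([[0.0, 0.5], [0.5, 0.0]], dtype=complex)
_IY = np.array([[0.0, -0.5j], [0.5j, 0.0]], dtype=complex)
_IZ = np.array([[0.5, 0.0], [0.0, -0.5]], dtype=complex)
_BLOCKS = {"x": _IX, "y": _IY, "z": _IZ}


@dataclass(frozen=True)
class Spin:
    """One spin-1/2 site: label, isotope, rotating-frame offset and linewidth.

    ``offset`` is the chemical shift in Hz on that isotope's own channel
    (each channel has its own rotating frame; absolute Larmor frequencies
    are never simulated).  ``linewidth`` is the FWHM in Hz applied as
    exponential decay of the detected signal.
    """

    label: str
    isotope: Isotope
    offset: float
    linewidth: float = 0.0

    def __post_init__(self) -> None:
        if self.linewidth < 0:
            raise ValueError(f"spin {self.label!r}: linewidth must be >= 0")


class SpinSystem:
    """An ordered collection of spins plus a symmetric J-coupling matrix (Hz)."""

    def __init__(self, spins: list[Spin], jcouplings) -> None:
        labels = [s.label for s in spins]
        if len(set(labels)) != len(labels):
            raise ValueError("spin labels must be unique")
        j = np.asarray(jcouplings, dtype=float)
        n = len(spins)
        if j.shape != (n, n):
            raise ValueError(f"J matrix must be {n}x{n}, got {j.shape}")
        if not np.allclose(j, j.T, atol=1e-12):
            raise ValueError("J matrix must be symmetric")
        if not np.allclose(np.diag(j), 0.0, atol=1e-12):
            raise ValueError("J matrix must have zero diagonal")
        self.spins: list[Spin] = list(spins)
        self.jcouplings = 0.5 * (j + j.T)
        np.fill_diagonal(self.jcouplings, 0.0)

    # -- bookkeeping ----------------------------------------------------
    @property
    def nspins(self) -> int:
        return len(self.spins)

    @property
    def dim(self) -> int:
        return 2 ** self.nspins

    def index(self, label: str) -> int:
        for i, s in enumerate(self.spins):
            if s.label == label:
                return i
        raise KeyError(f"no spin labelled {label!r}")

    def spin(self, label: str) -> Spin:
        return self.spins[self.index(label)]

    def channel_indices(self, isotope: str | Isotope) -> list[int]:
        iso = get_isotope(isotope)
        return [i for i, s in enumerate(self.spins) if s.isotope == iso]

    def proton_indices(self) -> list[int]:
        return self.channel_indices("1H")

    def hetero_isotopes(self) -> list[Isotope]:
        seen: list[Isotope] = []
        for s in self.spins:
            if s.isotope.name != "1H" and s.isotope not in seen:
                seen.append(s.isotope)
        return seen

    # -- product operators ----------------------------------------------
    @functools.lru_cache(maxsize=None)
    def op(self, i: int, axis: str) -> np.ndarray:
        """Product operator ``I_axis`` of spin ``i`` embedded in the full space."""
        mats = [_BLOCKS[axis] if k == i else _E2 for k in range(self.nspins)]
        out = mats[0]
        for m in mats[1:]:
            out = np.kron(out, m)
        return out

    def lowering(self, i: int) -> np.ndarray:
        return self.op(i, "x") - 1j * self.op(i, "y")

    @functools.lru_cache(maxsize=None)
    def zeeman_quantum_numbers(self) -> np.ndarray:
        """(nspins, dim) array of m = +-1/2 for each basis state, spin-major."""
        n = self.nspins
        m = np.empty((n, self.dim))
        for i in range(n):
            pattern = np.array([0.5, -0.5])
            reps_outer = 2 ** i
            reps_inner = 2 ** (n - i - 1)
            m[i] = np.tile(np.repeat(pattern, reps_inner), reps_outer)
        return m

    def __hash__(self) -> int:  # identity hash: operator caches are per-instance
        return id(self)

    def __eq__(self, other) -> bool:
        return self is other

    # -- configuration file IO ------------------------------------------
    def to_dict(self) -> dict:
        return {
            "spins": [
                {
                    "label": s.label,
                    "isotope": s.isotope.name,
                    "offset_hz": float(s.offset),
                    "linewidth_hz": float(s.linewidth),
                }
                for s in self.spins
            ],
            "jcouplings_hz": [
                {
                    "pair": [self.spins[i].label, self.spins[j].label],
                    "j_hz": float(self.jcouplings[i, j]),
                }
                for i in range(self.nspins)
                for j in range(i + 1, self.nspins)
                if self.jcouplings[i, j] != 0.0
            ],
        }

    def to_yaml(self, path) -> None:
        """Write the system as a human-editable YAML file (all values in Hz)."""
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SpinSystem":
        spins = [
            Spin(
                label=e["label"],
                isotope=get_isotope(e["isotope"]),
                offset=float(e["offset_hz"]),
                linewidth=float(e.get("linewidth_hz", 0.0)),
            )
            for e in d["spins"]
        ]
        n = len(spins)
        j = np.zeros((n, n))
        labels = [s.label for s in spins]
        for e in d.get("jcouplings_hz", []):
            a, b = e["pair"]
            ia, ib = labels.index(a), labels.index(b)
            j[ia, ib] = j[ib, ia] = float(e["j_hz"])
        return cls(spins, j)

    @classmethod
    def from_yaml(cls, path) -> "SpinSystem":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


class SpinState:
    """Density operator over the 2^N spin Hilbert space (trace 1 at thermal start)."""

    def __init__(self, rho: np.ndarray, system: SpinSystem) -> None:
        rho = np.asarray(rho, dtype=complex)
        if rho.shape != (system.dim, system.dim):
            raise ValueError("density matrix shape does not match system")
        self.rho = rho
        self.system = system

    def copy(self) -> "SpinState":
        return SpinState(self.rho.copy(), self.system)

    @property
    def trace(self) -> complex:
        return complex(np.trace(self.rho))

    def is_hermitian(self, tol: float = _HERM_TOL) -> bool:
        return bool(np.max(np.abs(self.rho - self.rho.conj().T)) < tol)


def thermal_state(system: SpinSystem) -> SpinState:
    """Thermal equilibrium: identity/2^N plus gamma-weighted Iz deviation.

    The deviation is scaled by ``4 / 2^N`` so that a fully excited isolated
    proton detects with amplitude exactly 1 (the per-spin polarization is
    additionally weighted by gamma_rel, as in a real spectrometer).
    """
    dim = system.dim
    rho = np.eye(dim, dtype=complex) / dim
    scale = 4.0 / dim
    for i, s in enumerate(system.spins):
        rho = rho + scale * s.isotope.gamma_rel * system.op(i, "z")
    return SpinState(rho, system)


class Hamiltonian:
    """A static Hamiltonian in Hz units with a cached eigendecomposition.

    The propagator is ``U(t) = V exp(-i 2 pi diag(evals) t) V^dagger``.
    """

    def __init__(self, matrix: np.ndarray) -> None:
        matrix = np.asarray(matrix, dtype=complex)
        if np.max(np.abs(matrix - matrix.conj().T)) > 1e-9:
            raise ValueError("Hamiltonian must be Hermitian")
        self.matrix = matrix
        self._evals, self._evecs = np.linalg.eigh(matrix)

    def propagator(self, duration: float) -> np.ndarray:
        phases = np.exp(-2j * np.pi * self._evals * duration)
        return (self._evecs * phases) @ self._evecs.conj().T


def build_hamiltonian(system: SpinSystem, weak_coupling: bool = False) -> Hamiltonian:
    """Isotropic liquid-state Hamiltonian: offsets + scalar couplings (Hz).

    Heteronuclear J terms are always secular (``Iz Sz`` only); homonuclear
    pairs use the full ``I.S`` form unless ``weak_coupling`` is set.
    Offsets are per-channel rotating-frame shifts.
    """
    h = np.zeros((system.dim, system.dim), dtype=complex)
    for i, s in enumerate(system.spins):
        h += s.offset * system.op(i, "z")
    for i in range(system.nspins):
        for j in range(i + 1, system.nspins):
            jij = system.jcouplings[i, j]
            if jij == 0.0:
                continue
            h += jij * system.op(i, "z") @ system.op(j, "z")
            same = system.spins[i].isotope == system.spins[j].isotope
            if same and not weak_coupling:
                h += jij * (
                    system.op(i, "x") @ system.op(j, "x")
                    + system.op(i, "y") @ system.op(j, "y")
                )
    return Hamiltonian(h)


def _rotation(system: SpinSystem, indices: list[int], angle_deg: float,
              phase_deg: float) -> np.ndarray:
    """Unitary for an ideal rotation of the given spins about an axis in xy."""
    a = np.deg2rad(angle_deg)
    p = np.deg2rad(phase_deg)
    axis2 = np.cos(p) * _IX + np.sin(p) * _IY
    # 2x2 rotation exp(-i a (cos p Ix + sin p Iy))
    r2 = np.cos(a / 2) * _E2 - 2j * np.sin(a / 2) * axis2
    mats = [r2 if k in indices else _E2 for k in range(system.nspins)]
    u = mats[0]
    for m in mats[1:]:
        u = np.kron(u, m)
    return u


def pulse(state: SpinState, channel: str | Isotope, angle: float,
          phase: float) -> SpinState:
    """Ideal (instantaneous) rotation of every spin on ``channel``.

    ``angle`` and ``phase`` are in degrees; phase 0 = x, 90 = y.
    """
    iso = get_isotope(channel)
    idx = state.system.channel_indices(iso)
    if not idx:
        raise ValueError(f"system has no spins on channel {iso.name}")
    u = _rotation(state.system, idx, angle, phase)
    return SpinState(u @ state.rho @ u.conj().T, state.system)


def pulse_selective(state: SpinState, labels, angle: float,
                    phase: float) -> SpinState:
    """Ideal rotation applied only to the named spins (selective pulse limit)."""
    if isinstance(labels, str):
        labels = [labels]
    idx = [state.system.index(lb) for lb in labels]
    u = _rotation(state.system, idx, angle, phase)
    return SpinState(u @ state.rho @ u.conj().T, state.system)


def evolve(state: SpinState, hamiltonian: Hamiltonian, duration: float) -> SpinState:
    """Free evolution ``rho -> U rho U^dagger`` with ``U = exp(-i 2 pi H t)``."""
    if duration < 0:
        raise ValueError("evolution duration must be >= 0")
    u = hamiltonian.propagator(duration)
    return SpinState(u @ state.rho @ u.conj().T, state.system)


def detect(state: SpinState, channel: str | Isotope, labels=None) -> complex:
    """Quadrature observable ``Tr(rho sum I-)`` over selected spins of a channel."""
    iso = get_isotope(channel)
    system = state.system
    if labels is None:
        idx = system.channel_indices(iso)
    else:
        if isinstance(labels, str):
            labels = [labels]
        idx = [system.index(lb) for lb in labels]
        for i in idx:
            if system.spins[i].isotope != iso:
                raise ValueError(
                    f"spin {system.spins[i].label!r} is not on channel {iso.name}"
                )
    if not idx:
        raise ValueError(f"no spins to detect on channel {iso.name}")
    m = sum(system.lowering(i) for i in idx)
    return complex(np.trace(state.rho @ m))
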