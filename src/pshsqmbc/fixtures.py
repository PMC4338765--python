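"""Synthetic spin systems emulating the demonstration compounds at desk scale.

Each fixture is a deterministic (name, seed) -> (SpinSystem, ExperimentParams)
pair small enough to simulate in seconds.  Heteronuclear couplings in the
``cump-demo`` fixture span the 1.6-21.3 Hz range demonstrated for the
cyclic-nucleotide example; all homonuclear couplings, offsets and linewidths
are invented but plausible desk-scale values and are recorded as such in the
provenance notes.  The seed only feeds the (optional) noise generator - the
systems themselves are fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .isotopes import get_isotope
from .sequence import CpmgParams, ExperimentParams, Interferogram, ZsParams
from .spinsys import Spin, SpinSystem

__all__ = ["FixtureSpec", "make_fixture", "add_noise", "FIXTURE_NAMES"]


@dataclass
class FixtureSpec:
    name: str
    system: SpinSystem
    params: ExperimentParams
    notes: str


def _cpmg(total: float = 81.7e-3) -> CpmgParams:
    return CpmgParams.from_duration(total, tau=150e-6)


def _spin(label, isotope, offset, lw):
    return Spin(label, get_isotope(isotope), offset, lw)


def _jmat(spins, pairs):
    labels = [s.label for s in spins]
    j = np.zeros((len(spins), len(spins)))
    for a, b, v in pairs:
        ia, ib = labels.index(a), labels.index(b)
        j[ia, ib] = j[ib, ia] = v
    return j


def _minimal_hx(seed):
    spins = [_spin("H1", "1H", 120.0, 0.3), _spin("P1", "31P", 40.0, 0.5)]
    j = _jmat(spins, [("H1", "P1", 10.0)])
    params = ExperimentParams(
        cpmg=_cpmg(),
        zs=ZsParams(sw=2000.0, sw2=40.0, n_chunks=32, pts_per_chunk=50),
        seed=seed,
    )
    notes = ("Isolated H-P pair, J(H,P)=10 Hz, no J(H,H); offsets/linewidths "
             "invented desk-scale values.")
    return FixtureSpec("minimal-hx", SpinSystem(spins, j), params, notes)


def _hhx_three_spin(seed):
    spins = [
        _spin("Ha", "1H", -100.0, 0.4),
        _spin("Hb", "1H", 100.0, 0.4),
        _spin("P1", "31P", 30.0, 0.5),
    ]
    j = _jmat(spins, [("Ha", "Hb", 7.0), ("Ha", "P1", 10.0), ("Hb", "P1", 6.0)])
    params = ExperimentParams(
        cpmg=_cpmg(),
        zs=ZsParams(sw=2000.0, sw2=25.0, n_chunks=32, pts_per_chunk=80),
        seed=seed,
    )
    notes = ("Two protons (delta nu = 200 Hz, J(H,H) = 7 Hz - invented) "
             "coupled to one 31P (10 / 6 Hz).")
    return FixtureSpec("hhx-three-spin", SpinSystem(spins, j), params, notes)


def _cump_demo(seed):
    # three mutually coupled protons + 31P; J(H,P) spans the demonstrated
    # 1.6-21.3 Hz range endpoints
    spins = [
        _spin("Ha", "1H", -700.0, 0.15),
        _spin("Hb", "1H", -100.0, 0.15),
        _spin("Hc", "1H", 500.0, 0.15),
        _spin("P1", "31P", 60.0, 0.4),
    ]
    j = _jmat(spins, [
        ("Ha", "Hb", 4.5), ("Hb", "Hc", 2.8), ("Ha", "Hc", 1.5),
        ("Ha", "P1", 21.3), ("Hb", "P1", 8.0), ("Hc", "P1", 1.6),
    ])
    params = ExperimentParams(
        cpmg=_cpmg(),
        # 64 x 40 ms chunks: 2.56 s of pure-shift acquisition so the 1.6 Hz
        # endpoint is resolved by the raw antiphase read-off
        zs=ZsParams(sw=2500.0, sw2=25.0, n_chunks=64, pts_per_chunk=100),
        seed=seed,
    )
    notes = ("Nucleotide-like 4-spin demo. J(H,P) = 21.3 / 8.0 / 1.6 Hz - "
             "range endpoints are the demonstrated values; 8.0 Hz and all "
             "J(H,H) (4.5 / 2.8 / 1.5 Hz), offsets and linewidths are "
             "invented fixture parameters.")
    return FixtureSpec("cump-demo", SpinSystem(spins, j), params, notes)


def _selenide_demo(seed):
    spins = [
        _spin("Ha", "1H", -150.0, 0.3),
        _spin("Hb", "1H", 150.0, 0.3),
        _spin("Se1", "77Se", 20.0, 1.0),
    ]
    j = _jmat(spins, [("Ha", "Hb", 7.0), ("Ha", "Se1", 12.4), ("Hb", "Se1", 6.5)])
    params = ExperimentParams(
        cpmg=_cpmg(),
        zs=ZsParams(sw=2000.0, sw2=25.0, n_chunks=32, pts_per_chunk=80),
        seed=seed,
    )
    notes = "Diglycosyl-selenide-like 3-spin demo; all values invented."
    return FixtureSpec("selenide-demo", SpinSystem(spins, j), params, notes)


def _diselenide_2d(seed):
    spins = [
        _spin("Ha", "1H", -400.0, 0.4),
        _spin("Hb", "1H", 0.0, 0.4),
        _spin("Hc", "1H", 450.0, 0.4),
        _spin("Se1", "77Se", -80.0, 1.5),
        _spin("Se2", "77Se", 120.0, 1.5),
    ]
    j = _jmat(spins, [
        ("Ha", "Hb", 6.0),
        ("Ha", "Se1", 9.8), ("Hb", "Se1", 3.9),
        ("Hc", "Se2", 11.7),
    ])
    params = ExperimentParams(
        dimensionality="pseudo2D",
        n_t1=8,
        sw1=400.0,
        cpmg=_cpmg(),
        zs=ZsParams(sw=2000.0, sw2=25.0, n_chunks=16, pts_per_chunk=80),
        seed=seed,
    )
    notes = ("Diselenide-like 5-spin pseudo-2D demo with two Se sites; all "
             "values invented.")
    return FixtureSpec("diselenide-2d", SpinSystem(spins, j), params, notes)


def _c13_demo(seed):
    spins = [
        _spin("Ha", "1H", -200.0, 0.3),
        _spin("Hb", "1H", 200.0, 0.3),
        _spin("C1", "13C", 50.0, 0.8),
    ]
    j = _jmat(spins, [("Ha", "Hb", 8.0), ("Ha", "C1", 5.0), ("Hb", "C1", 7.6)])
    params = ExperimentParams(
        cpmg=_cpmg(74.4e-3),
        zs=ZsParams(sw=2000.0, sw2=25.0, n_chunks=32, pts_per_chunk=80),
        seed=seed,
    )
    notes = "Monosaccharide-like 3-spin 13C demo; all values invented."
    return FixtureSpec("c13-demo", SpinSystem(spins, j), params, notes)


_REGISTRY = {
    "minimal-hx": _minimal_hx,
    "hhx-three-spin": _hhx_three_spin,
    "cump-demo": _cump_demo,
    "selenide-demo": _selenide_demo,
    "diselenide-2d": _diselenide_2d,
    "c13-demo": _c13_demo,
}

FIXTURE_NAMES = tuple(sorted(_REGISTRY))


def make_fixture(name: str, seed: int = 0) -> FixtureSpec:
    """Build a registered fixture; deterministic for a given (name, seed)."""
    try:
        builder = _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; registered: {list(FIXTURE_NAMES)}"
        ) from None
    return builder(int(seed))


def add_noise(interferogram: Interferogram, sigma: float,
              seed: int = 0) -> Interferogram:
    """Add independent complex Gaussian noise per sample (sigma=0: identity)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return Interferogram(
            {k: v.copy() for k, v in interferogram.data.items()},
            interferogram.params, interferogram.per_active)
    rng = np.random.default_rng(seed)
    data = {}
    for flag, grid in interferogram.data.items():
        data[flag] = grid + sigma * (rng.standard_normal(grid.shape)
                                     + 1j * rng.standard_normal(grid.shape))
    return Interferogram(data, interferogram.params, interferogram.per_active)
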