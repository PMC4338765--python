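"""Shared synthetic spin systems and pre-simulated datasets.

Everything is generated at test time; expensive end-to-end simulations are
session-scoped so several tests can share one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from pshsqmbc import (
    Spin,
    SpinSystem,
    get_isotope,
    make_fixture,
    process_pseudo1d,
    run_experiment,
)


def spin(label, isotope, offset, lw=0.0):
    return Spin(label, get_isotope(isotope), offset, lw)


@pytest.fixture(scope="session")
def hx_pair():
    """Isolated on-resonance H-X pair, J = 10 Hz, no relaxation."""
    return SpinSystem(
        [spin("H1", "1H", 0.0), spin("X1", "31P", 0.0)],
        [[0.0, 10.0], [10.0, 0.0]],
    )


@pytest.fixture(scope="session")
def three_spin():
    """Two coupled protons plus a phosphorus, generic test workhorse."""
    return SpinSystem(
        [spin("Ha", "1H", 80.0), spin("Hb", "1H", -120.0),
         spin("P1", "31P", 30.0)],
        [[0.0, 7.0, 10.0], [7.0, 0.0, 0.0], [10.0, 0.0, 0.0]],
    )


@pytest.fixture(scope="session")
def cump_run():
    """Decoupled pseudo-1D run of the cump-demo fixture plus its spectrum."""
    fx = make_fixture("cump-demo", 0)
    ig = run_experiment(fx.system, fx.params)
    spectrum = process_pseudo1d(ig, zerofill_to=32768)
    return fx, ig, spectrum


@pytest.fixture(scope="session")
def minimal_run():
    """Decoupled pseudo-1D run of minimal-hx plus its spectrum."""
    fx = make_fixture("minimal-hx", 0)
    ig = run_experiment(fx.system, fx.params)
    spectrum = process_pseudo1d(ig)
    return fx, ig, spectrum


def rng(seed=12345):
    return np.random.default_rng(seed)
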