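"""Pulse-sequence behaviour: CPMG-INEPT, coherence selection, the ZS element,
chunked acquisition and the full experiment."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from pshsqmbc import (
    CpmgParams,
    ExperimentParams,
    Interferogram,
    PhaseTable,
    SpinState,
    SpinSystem,
    ZsParams,
    acquire_decoupled,
    build_hamiltonian,
    coherence_select,
    cpmg_inept,
    echo_antiecho_gradient_ratio,
    evolve,
    make_fixture,
    pulse,
    run_experiment,
    rsnob_bandwidth,
    rsnob_duration,
    thermal_state,
    zs_decoupling_element,
    zs_sensitivity_fraction,
)
from pshsqmbc.sequence import FidChunk
from conftest import spin


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

def test_cpmg_params_consistency_enforced():
    with pytest.raises(ValueError, match="within one tau"):
        CpmgParams(tau=150e-6, n_cycles=16, total_duration=0.05)
    with pytest.warns(UserWarning, match="multiple of 16"):
        CpmgParams(tau=1e-3, n_cycles=10, total_duration=0.02)


def test_cpmg_from_duration_picks_xy16_multiple():
    cp = CpmgParams.from_duration(81.7e-3, 150e-6)
    assert cp.n_cycles % 16 == 0
    assert 2 * cp.tau * cp.n_cycles == pytest.approx(81.7e-3, rel=1e-12)


def test_phase_table_lengths_validated():
    with pytest.raises(ValueError, match="2/4/8/8"):
        PhaseTable(phi3=(0.0,))


def test_zs_params_timing_contract():
    zs = ZsParams(sw=2000.0, sw2=40.0, n_chunks=32, pts_per_chunk=50)
    assert zs.chunk_duration == pytest.approx(1.0 / zs.sw2)
    assert zs.tau_a == pytest.approx(1.0 / (4 * zs.sw2))
    assert zs.tau_b == pytest.approx(1.0 / (4 * zs.sw2) - 4.0 / zs.sw)
    with pytest.raises(ValueError, match="1/sw2"):
        ZsParams(sw=2000.0, sw2=40.0, n_chunks=32, pts_per_chunk=60)


# ---------------------------------------------------------------------------
# CPMG-INEPT
# ---------------------------------------------------------------------------

def _cpmg_antiphase_amplitude(total_duration):
    s = SpinSystem([spin("H1", "1H", 40.0), spin("X1", "31P", 25.0)],
                   [[0.0, 10.0], [10.0, 0.0]])
    h = build_hamiltonian(s)
    cp = CpmgParams.from_duration(total_duration, 150e-6)
    st = pulse(thermal_state(s), "1H", 90.0, 0.0)
    st = cpmg_inept(st, s, cp, hamiltonian=h)
    ap_ops = [2 * s.op(0, a) @ s.op(1, "z") for a in ("x", "y")]
    ip_ops = [s.op(0, a) for a in ("x", "y")]

    def norm(ops):
        return np.sqrt(sum(
            abs(np.trace(st.rho @ o) / np.sqrt(np.trace(o @ o).real)) ** 2
            for o in ops))

    # thermal deviation scale for one proton of a 2-spin system is 1
    return norm(ap_ops), norm(ip_ops)


def test_cpmg_inept_matched_duration_full_transfer():
    ap, ip = _cpmg_antiphase_amplitude(1.0 / 20.0)
    assert ap == pytest.approx(1.0, abs=1e-6)
    assert ip < 1e-6


def test_cpmg_inept_full_cycle_no_transfer():
    ap, _ = _cpmg_antiphase_amplitude(1.0 / 10.0)
    assert ap == pytest.approx(0.0, abs=1e-6)


def test_cpmg_suppresses_homonuclear_j_evolution():
    """J(H,H)-antiphase terms stay >=10x smaller under CPMG than under free
    evolution of the same duration (X spin present, uncoupled)."""
    import itertools

    s = SpinSystem([spin("Ha", "1H", 100.0), spin("Hb", "1H", -100.0),
                    spin("P1", "31P", 0.0)],
                   [[0.0, 7.0, 0.0], [7.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
    h = build_hamiltonian(s)
    cp = CpmgParams.from_duration(81.7e-3, 150e-6)
    st0 = pulse(thermal_state(s), "1H", 90.0, 0.0)

    blocks = {"e": np.eye(2), "x": 2 * np.array([[0, .5], [.5, 0]]),
              "y": 2 * np.array([[0, -.5j], [.5j, 0]]),
              "z": 2 * np.diag([.5, -.5])}

    def hh_antiphase_norm(rho):
        tot = 0.0
        for combo in itertools.product("exyz", repeat=3):
            a, b = combo[0], combo[1]
            if not ((a in "xy" and b == "z") or (b in "xy" and a == "z")):
                continue
            op = blocks[combo[0]]
            for c in combo[1:]:
                op = np.kron(op, blocks[c])
            tot += abs(np.trace(rho @ op.conj().T) / 8) ** 2
        return np.sqrt(tot)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        n_cpmg = hh_antiphase_norm(cpmg_inept(st0, s, cp, hamiltonian=h).rho)
    n_free = hh_antiphase_norm(evolve(st0, h, cp.total_duration).rho)
    assert n_free / n_cpmg >= 10.0


def test_cpmg_rejects_nonpositive_tau():
    with pytest.raises(ValueError, match="tau"):
        CpmgParams(tau=0.0, n_cycles=16, total_duration=0.0)


# ---------------------------------------------------------------------------
# coherence selection
# ---------------------------------------------------------------------------

def test_select_minus_one_keeps_lowering_half(hx_pair):
    st = SpinState(hx_pair.op(0, "x"), hx_pair)
    sel = coherence_select(st, {"1H": -1})
    lower = 0.5 * hx_pair.lowering(0)
    assert np.max(np.abs(sel.rho - lower)) < 1e-12


def test_selection_is_idempotent(three_spin):
    st = pulse(thermal_state(three_spin), "1H", 90.0, 30.0)
    once = coherence_select(st, {"1H": 1, "31P": 0})
    twice = coherence_select(once, {"1H": 1, "31P": 0})
    assert np.max(np.abs(once.rho - twice.rho)) < 1e-14


def test_selection_rejects_impossible_order(hx_pair):
    with pytest.raises(ValueError, match="exceeds"):
        coherence_select(thermal_state(hx_pair), {"31P": 2})


def test_echo_antiecho_reconstructs_x_offset():
    """Echo/antiecho t1 interferograms FT to the known X offset."""
    s = SpinSystem([spin("H1", "1H", 100.0), spin("X1", "31P", 60.0)],
                   [[0.0, 10.0], [10.0, 0.0]])
    params = replace(
        make_fixture("minimal-hx", 0).params,
        dimensionality="pseudo2D", n_t1=32, sw1=400.0,
        zs=ZsParams(sw=2000.0, sw2=100.0, n_chunks=4, pts_per_chunk=20))
    ig = run_experiment(s, params)
    e = ig.data["echo"][:, 2, 5]
    a = ig.data["antiecho"][:, 2, 5]
    m = 0.5 * (e + a) + 1j * ((e - a) / 2j)
    t1 = np.arange(params.n_t1) / params.sw1
    expected = m[0] * np.exp(-2j * np.pi * 60.0 * t1)
    assert np.max(np.abs(m - expected)) < 1e-10 * np.max(np.abs(m))
    # swapping flags conjugates the modulation
    m_swapped = 0.5 * (a + e) + 1j * ((a - e) / 2j)
    assert np.max(np.abs(m_swapped - np.conj(expected / m[0]) * m[0])) \
        < 1e-10 * np.max(np.abs(m))


# ---------------------------------------------------------------------------
# gradient-ratio arithmetic
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("isotope, printed, decimals", [
    ("13C", 20.1, 1),
    ("31P", 32.3846, 4),
    ("77Se", 15.257, 3),
    ("1H", 80.0, 6),
])
def test_echo_antiecho_gradient_ratio(isotope, printed, decimals):
    value = echo_antiecho_gradient_ratio(isotope, 80.0)
    assert round(value, decimals) == pytest.approx(printed)


def test_gradient_ratio_rejects_unregistered_isotope():
    with pytest.raises(KeyError):
        echo_antiecho_gradient_ratio("119Sn", 80.0)


# ---------------------------------------------------------------------------
# ZS decoupling element
# ---------------------------------------------------------------------------

def test_zs_element_single_proton_is_identity():
    s = SpinSystem([spin("H1", "1H", 50.0)], [[0.0]])
    st = pulse(thermal_state(s), "1H", 90.0, 20.0)
    out = zs_decoupling_element(st, "H1")
    assert np.max(np.abs(out.rho - st.rho)) < 1e-12


def test_zs_element_inverts_passive_only(three_spin):
    st = thermal_state(three_spin)  # both protons at Iz
    out = zs_decoupling_element(st, "Ha")
    za = np.trace(out.rho @ three_spin.op(0, "z")).real
    zb = np.trace(out.rho @ three_spin.op(1, "z")).real
    zx = np.trace(out.rho @ three_spin.op(2, "z")).real
    ref = np.trace(thermal_state(three_spin).rho @ three_spin.op(0, "z")).real
    assert za == pytest.approx(ref, abs=1e-12)
    assert zb == pytest.approx(-ref, abs=1e-12)
    # heteronucleus untouched (gamma-weighted thermal Iz)
    assert zx == pytest.approx(
        ref * three_spin.spins[2].isotope.gamma_rel, abs=1e-12)


def test_zs_element_rejects_non_proton(three_spin):
    with pytest.raises(ValueError, match="not a proton"):
        zs_decoupling_element(thermal_state(three_spin), "P1")


def test_tau_element_tau_refocuses_homonuclear_coupling():
    """In-phase magnetization survives tau-element-tau with no J(H,H)
    antiphase buildup (weak coupling)."""
    s = SpinSystem([spin("Ha", "1H", 80.0), spin("Hb", "1H", -120.0)],
                   [[0.0, 7.0], [7.0, 0.0]])
    hw = build_hamiltonian(s, weak_coupling=True)
    st = SpinState(s.op(0, "x"), s)
    st = evolve(st, hw, 0.01)
    st = zs_decoupling_element(st, "Ha")
    st = evolve(st, hw, 0.01)
    ip = sum(abs(np.trace(st.rho @ s.op(0, a))) ** 2 for a in "xy")
    ap = sum(abs(np.trace(st.rho @ (2 * s.op(0, a) @ s.op(1, "z")))) ** 2
             for a in "xy")
    assert np.sqrt(ip) == pytest.approx(1.0, abs=1e-10)
    assert np.sqrt(ap) < 1e-10


# ---------------------------------------------------------------------------
# chunked acquisition
# ---------------------------------------------------------------------------

def test_decoupled_acquisition_matches_continuous_without_jhh(minimal_run):
    """No J(H,H): concatenated chunks equal one continuously acquired FID."""
    fx, ig, _ = minimal_run
    ig_conv = run_experiment(fx.system, replace(fx.params, mode="conventional"))
    concat = np.concatenate([ig.data["echo"][0, k]
                             for k in range(ig.shape[1])])
    continuous = ig_conv.data["echo"][0, 0]
    assert np.max(np.abs(concat - continuous)) < 1e-10


def test_homonuclear_phase_zero_at_chunk_midpoints():
    """|signal| at each chunk midpoint equals the unmodulated amplitude."""
    s = SpinSystem([spin("Ha", "1H", 80.0), spin("Hb", "1H", -120.0)],
                   [[0.0, 7.0], [7.0, 0.0]])
    hw = build_hamiltonian(s, weak_coupling=True)
    params = make_fixture("hhx-three-spin", 0).params
    st = SpinState(s.op(0, "x"), s)
    chunks = acquire_decoupled(st, s, params, "Ha", hw)
    mid = params.zs.pts_per_chunk // 2
    full = abs(np.trace(s.op(0, "x") @ s.lowering(0)))
    for c in chunks:
        assert abs(abs(c.samples[mid]) - full) < 1e-10


def test_chunk_duration_longer_than_increment_rejected(hx_pair):
    params = make_fixture("minimal-hx", 0).params
    bad = replace(params, zs=ZsParams(sw=2000.0, sw2=40.0, n_chunks=4,
                                      pts_per_chunk=50))
    object.__setattr__(bad.zs, "sw2", 45.0)  # break invariant post-validation
    st = thermal_state(hx_pair)
    with pytest.raises(ValueError, match="1/sw2"):
        acquire_decoupled(st, hx_pair, bad, "H1")


def test_decoupled_spectrum_has_two_extrema_conventional_at_least_four():
    """Homodecoupling collapses the antiphase multiplet to a pure doublet."""
    from pshsqmbc import process_pseudo1d
    from pshsqmbc.jextract import _local_extrema

    fx = make_fixture("hhx-three-spin", 0)
    sp_d = process_pseudo1d(run_experiment(fx.system, fx.params))
    sp_c = process_pseudo1d(
        run_experiment(fx.system, replace(fx.params, mode="conventional")))
    for offset in (-100.0, 100.0):
        for sp, lo_count, hi_count in ((sp_d, 2, 2), (sp_c, 4, None)):
            sub = sp.slice(offset - 15, offset + 15)
            y = sub.values.real
            amax = np.max(np.abs(y))
            mx, mn = _local_extrema(y)
            n = len([i for i in mx if y[i] >= 0.2 * amax]) \
                + len([i for i in mn if -y[i] >= 0.2 * amax])
            if hi_count is None:
                assert n >= lo_count
            else:
                assert n == lo_count


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------

def test_pseudo1d_run_yields_one_antiphase_doublet_per_proton(cump_run):
    fx, ig, spectrum = cump_run
    from pshsqmbc import extract_all
    table = extract_all(spectrum, fx.system, "decoupled")
    assert len(table) == 3
    assert set(table.proton) == {"Ha", "Hb", "Hc"}


def test_noise_free_runs_are_deterministic(minimal_run):
    fx, ig, _ = minimal_run
    again = run_experiment(fx.system, fx.params)
    assert np.array_equal(ig.data["echo"], again.data["echo"])


def test_phase_cycle_equals_ideal_projection(minimal_run):
    """The printed 8-step cycle selects exactly the projected pathway."""
    fx, ig, _ = minimal_run
    cycled = run_experiment(fx.system, fx.params, phase_cycle=True)
    scale = np.max(np.abs(ig.data["echo"]))
    assert np.max(np.abs(cycled.data["echo"] - ig.data["echo"])) < 1e-10 * scale


def test_decoupled_equals_conventional_without_homonuclear_coupling(minimal_run):
    from pshsqmbc import process_pseudo1d
    fx, ig, sp_d = minimal_run
    sp_c = process_pseudo1d(
        run_experiment(fx.system, replace(fx.params, mode="conventional")))
    scale = np.max(np.abs(sp_d.values))
    assert np.max(np.abs(sp_d.values - sp_c.values)) < 1e-8 * scale


def test_no_signal_at_uncoupled_proton_positions():
    """Summing active-spin sub-experiments leaks nothing outside the
    populated regions (commensurate grid, weak coupling, no window)."""
    from pshsqmbc import concatenate_chunks, transform

    s = SpinSystem([spin("Ha", "1H", -500.0), spin("Hb", "1H", 500.0),
                    spin("P1", "31P", 0.0)],
                   [[0.0, 0.0, 10.0], [0.0, 0.0, 7.5], [10.0, 7.5, 0.0]])
    params = replace(make_fixture("minimal-hx", 0).params, weak_coupling=True)
    ig = run_experiment(s, params)
    sp = transform(concatenate_chunks(ig), 1600)
    peak = np.max(np.abs(sp.values))
    outside = np.ones(len(sp.axis), dtype=bool)
    for off in (-500.0, 500.0):
        outside &= np.abs(sp.axis - off) > 30.0
    assert np.max(np.abs(sp.values[outside])) < 1e-10 * peak


def test_run_warns_when_no_heteronuclear_pathway():
    s = SpinSystem([spin("H1", "1H", 100.0), spin("P1", "31P", 0.0)],
                   [[0.0, 0.0], [0.0, 0.0]])
    with pytest.warns(UserWarning, match="no proton-heteronucleus coupling"):
        run_experiment(s, make_fixture("minimal-hx", 0).params)


def test_two_heteronuclear_channels_rejected():
    s = SpinSystem([spin("H1", "1H", 0.0), spin("P1", "31P", 0.0),
                    spin("C1", "13C", 10.0)],
                   [[0.0, 5.0, 5.0], [5.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
    with pytest.raises(ValueError, match="exactly one heteronuclear"):
        run_experiment(s, make_fixture("minimal-hx", 0).params)


# ---------------------------------------------------------------------------
# interferogram container
# ---------------------------------------------------------------------------

def test_incomplete_chunk_grid_rejected(minimal_run):
    fx, ig, _ = minimal_run
    chunks = [FidChunk(0, k, "echo", None, ig.data["echo"][0, k])
              for k in range(ig.shape[1]) if k != 3]
    with pytest.raises(ValueError, match="t2_index=3"):
        Interferogram.from_chunks(chunks, fx.params)


def test_hdf5_container_roundtrip(tmp_path, minimal_run):
    fx, ig, _ = minimal_run
    path = tmp_path / "ig.h5"
    ig.to_hdf5(path)
    back = Interferogram.from_hdf5(path)
    assert np.array_equal(back.data["echo"], ig.data["echo"])
    assert back.params.zs.sw == fx.params.zs.sw
    assert set(back.per_active) == set(ig.per_active)
    for label in ig.per_active:
        assert np.array_equal(back.per_active[label]["echo"],
                              ig.per_active[label]["echo"])


# ---------------------------------------------------------------------------
# design calculators
# ---------------------------------------------------------------------------

def test_zs_sensitivity_proportionality():
    base = zs_sensitivity_fraction(50.0, 0.53, 1.8)
    assert zs_sensitivity_fraction(100.0, 0.53, 1.8) == pytest.approx(2 * base)
    assert zs_sensitivity_fraction(50.0, 1.06, 1.8) == pytest.approx(base / 2)


def test_zs_sensitivity_typical_band():
    """50 Hz pulse under 1% of 53 G/cm over 1.8 cm: a few percent of the
    conventional sensitivity."""
    f = zs_sensitivity_fraction(50.0, 0.01 * 53.0, 1.8)
    assert 0.01 <= f <= 0.10


def test_zs_sensitivity_rejects_nonpositive():
    with pytest.raises(ValueError):
        zs_sensitivity_fraction(0.0, 0.5, 1.8)


def test_rsnob_product_reproduces_published_pairs():
    for duration_ms, bandwidth in ((46.64, 50.0), (93.28, 25.0), (23.32, 100.0)):
        assert rsnob_duration(bandwidth) * 1e3 == pytest.approx(
            duration_ms, rel=5e-3)
        assert rsnob_bandwidth(duration_ms * 1e-3) == pytest.approx(
            bandwidth, rel=5e-3)
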