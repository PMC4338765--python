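"""The broadband proton-proton-decoupled CPMG-HSQMBC pulse sequence.

The experiment transfers proton magnetization to a heteronucleus X through
small long-range couplings J(H,X) using a CPMG-INEPT train (simultaneous
180deg pulses on both channels, XY-16 phase supercycle), optionally encodes
the X chemical shift in t1 with echo-antiecho gradient selection, transfers
back, and then acquires the proton FID in short chunks.  Between chunks a
Zangger-Sterk element (hard 180 on all protons + selective 180 on the
"active" proton of the current slice) inverts every proton except the active
one, so that proton-proton coupling evolution is refocused at the midpoint
of each chunk while chemical shift and J(H,X) evolve continuously.
Concatenating the chunks (see :mod:`pshsqmbc.recon`) yields a pure-shift FID
in which each proton carries only its antiphase J(H,X) splitting.

Idealizations (see docs/methods.md): gradients are not integrated spatially
- purge/selection gradients act as exact coherence-order projections, and
slice selection is modelled as one sub-experiment per active proton with
equal weights.  Pulses are ideal rotations; the selective RSNOB pulse enters
only through the design calculators below.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .isotopes import GAMMA_1H_HZ_PER_G, Isotope, get_isotope
from .spinsys import (
    Hamiltonian,
    SpinState,
    SpinSystem,
    build_hamiltonian,
    detect,
    evolve,
    pulse,
    pulse_selective,
    thermal_state,
)

__all__ = [
    "CpmgParams",
    "PhaseTable",
    "ZsParams",
    "GradientScheme",
    "ExperimentParams",
    "FidChunk",
    "Interferogram",
    "cpmg_inept",
    "coherence_select",
    "echo_antiecho_gradient_ratio",
    "zs_decoupling_element",
    "acquire_decoupled",
    "acquire_conventional",
    "run_experiment",
    "zs_sensitivity_fraction",
    "rsnob_duration",
    "rsnob_bandwidth",
    "RSNOB_PRODUCT",
]

#: dimensionless duration x bandwidth product of the RSNOB band-selective
#: refocusing pulse (46.64 ms x 50 Hz = 2.332).
RSNOB_PRODUCT = 2.332

# XY-16: the XY-8 supercycle (x y x y y x y x) plus its phase-inverted copy.
XY16_PHASES = [0.0, 90.0, 0.0, 90.0, 90.0, 0.0, 90.0, 0.0,
               180.0, 270.0, 180.0, 270.0, 270.0, 180.0, 270.0, 180.0]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CpmgParams:
    """CPMG-INEPT timing: ``n_cycles`` 180deg pulses at half-spacing ``tau``.

    ``total_duration`` is the heteronuclear coupling evolution time
    (e.g. 81.7 ms); it must satisfy ``2 tau n_cycles ~ total_duration``
    within one tau.
    """

    tau: float
    n_cycles: int
    total_duration: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if abs(2 * self.tau * self.n_cycles - self.total_duration) > self.tau:
            raise ValueError(
                "2*tau*n_cycles must equal total_duration within one tau"
            )
        if self.n_cycles % 16:
            warnings.warn(
                "n_cycles is not a multiple of 16; the XY-16 supercycle "
                "will be truncated", stacklevel=2,
            )

    @classmethod
    def from_duration(cls, total_duration: float, tau: float = 150e-6) -> "CpmgParams":
        """Pick the multiple-of-16 cycle count nearest ``total/(2 tau)``."""
        n = max(16, 16 * round(total_duration / (2 * tau) / 16))
        return cls(tau=total_duration / (2 * n), n_cycles=n,
                   total_duration=total_duration)


@dataclass(frozen=True)
class PhaseTable:
    """Phase lists in degrees for the cycled pulses and the receiver."""

    phi2: float = 90.0                     # fixed, y
    phi3: tuple = (0.0, 180.0)
    phi4: tuple = (0.0, 0.0, 180.0, 180.0)
    phi5: tuple = (0.0, 0.0, 0.0, 0.0, 90.0, 90.0, 90.0, 90.0)
    phi_rec: tuple = (0.0, 180.0, 180.0, 0.0, 180.0, 0.0, 0.0, 180.0)
    xy16: tuple = tuple(XY16_PHASES)

    def __post_init__(self) -> None:
        if (len(self.phi3), len(self.phi4), len(self.phi5), len(self.phi_rec)) \
                != (2, 4, 8, 8):
            raise ValueError("phase list lengths must be 2/4/8/8")
        if len(self.xy16) != 16:
            raise ValueError("xy16 must have 16 entries")


@dataclass(frozen=True)
class ZsParams:
    """Pure-shift acquisition geometry.

    ``sw`` is the proton spectral width (Hz), ``sw2`` the chunk-increment
    width (the t2 increment is 1/sw2), ``n_chunks`` the number of t2
    increments and ``pts_per_chunk`` the complex points per chunk; the chunk
    duration ``pts_per_chunk/sw`` must agree with 1/sw2 within one dwell.
    """

    sw: float
    sw2: float
    n_chunks: int
    pts_per_chunk: int
    selective_bandwidth: float = 50.0
    slice_gradient_fraction: float = 0.01
    rsnob_product: float = RSNOB_PRODUCT

    def __post_init__(self) -> None:
        if self.n_chunks < 1:
            raise ValueError("n_chunks must be >= 1")
        if self.selective_bandwidth <= 0:
            raise ValueError("selective_bandwidth must be > 0")
        if self.sw <= 0 or self.sw2 <= 0:
            raise ValueError("spectral widths must be > 0")
        dwell = 1.0 / self.sw
        if self.chunk_duration > 1.0 / self.sw2 + dwell / 2:
            raise ValueError(
                "chunk duration exceeds the t2 increment 1/sw2"
            )
        if abs(self.chunk_duration - 1.0 / self.sw2) > dwell:
            raise ValueError(
                "chunk duration pts_per_chunk/sw must match 1/sw2 within one dwell"
            )

    @property
    def chunk_duration(self) -> float:
        return self.pts_per_chunk / self.sw

    @property
    def tau_a(self) -> float:
        return 1.0 / (4 * self.sw2)

    @property
    def tau_b(self) -> float:
        return 1.0 / (4 * self.sw2) - 4.0 / self.sw


@dataclass(frozen=True)
class GradientScheme:
    """Fractional gradient amplitudes of the coherence-selection scheme.

    Only the bookkeeping is represented (gradients act as ideal projections
    in the simulator); ``g2``/``g4`` carry the echo-antiecho ratio contract
    G2:G4 = 80 : 80*|gamma_rel(X)|.
    """

    g1: float = 0.19
    g2: float = 0.80
    g3: float = 0.10
    g4: float | None = None     # derived from the detected isotope if None
    g5: float = 0.18
    g6: float = 0.01
    max_gradient_g_per_cm: float = 53.0

    def g4_for(self, isotope: str | Isotope) -> float:
        if self.g4 is not None:
            return self.g4
        return self.g2 * abs(get_isotope(isotope).gamma_rel)


@dataclass(frozen=True)
class ExperimentParams:
    """Everything needed to run one experiment."""

    mode: str = "decoupled"            # "decoupled" | "conventional"
    dimensionality: str = "pseudo1D"   # "pseudo1D" | "pseudo2D"
    phase_mode: str = "AP"             # "AP" | "IP"
    cpmg: CpmgParams = field(default_factory=lambda: CpmgParams.from_duration(81.7e-3))
    zs: ZsParams = field(default_factory=lambda: ZsParams(
        sw=2000.0, sw2=40.0, n_chunks=32, pts_per_chunk=50))
    phases: PhaseTable = field(default_factory=PhaseTable)
    gradients: GradientScheme = field(default_factory=GradientScheme)
    n_t1: int = 1
    t1_fixed: float = 3e-6
    sw1: float = 400.0                 # X-dimension spectral width (pseudo2D)
    n_conventional_points: int | None = None
    noise_sigma: float = 0.0
    seed: int = 0
    weak_coupling: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("decoupled", "conventional"):
            raise ValueError("mode must be 'decoupled' or 'conventional'")
        if self.dimensionality not in ("pseudo1D", "pseudo2D"):
            raise ValueError("dimensionality must be 'pseudo1D' or 'pseudo2D'")
        if self.phase_mode not in ("AP", "IP"):
            raise ValueError("phase_mode must be 'AP' or 'IP'")
        if self.dimensionality == "pseudo1D" and self.n_t1 != 1:
            raise ValueError("pseudo1D implies n_t1 == 1")

    @property
    def ea_flags(self) -> tuple:
        return ("echo",) if self.dimensionality == "pseudo1D" else ("echo", "antiecho")

    def t1_values(self) -> np.ndarray:
        if self.dimensionality == "pseudo1D":
            return np.array([self.t1_fixed])
        return np.arange(self.n_t1) / self.sw1

    # -- configuration file IO ------------------------------------------
    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "dimensionality": self.dimensionality,
            "phase_mode": self.phase_mode,
            "cpmg": {"tau_s": self.cpmg.tau, "n_cycles": self.cpmg.n_cycles,
                     "total_duration_s": self.cpmg.total_duration},
            "zs": {"sw_hz": self.zs.sw, "sw2_hz": self.zs.sw2,
                   "n_chunks": self.zs.n_chunks,
                   "pts_per_chunk": self.zs.pts_per_chunk,
                   "selective_bandwidth_hz": self.zs.selective_bandwidth,
                   "slice_gradient_fraction": self.zs.slice_gradient_fraction,
                   "rsnob_product": self.zs.rsnob_product},
            "n_t1": self.n_t1,
            "t1_fixed_s": self.t1_fixed,
            "sw1_hz": self.sw1,
            "n_conventional_points": self.n_conventional_points,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
            "weak_coupling": self.weak_coupling,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentParams":
        c = d["cpmg"]
        z = d["zs"]
        return cls(
            mode=d.get("mode", "decoupled"),
            dimensionality=d.get("dimensionality", "pseudo1D"),
            phase_mode=d.get("phase_mode", "AP"),
            cpmg=CpmgParams(tau=c["tau_s"], n_cycles=c["n_cycles"],
                            total_duration=c["total_duration_s"]),
            zs=ZsParams(sw=z["sw_hz"], sw2=z["sw2_hz"], n_chunks=z["n_chunks"],
                        pts_per_chunk=z["pts_per_chunk"],
                        selective_bandwidth=z.get("selective_bandwidth_hz", 50.0),
                        slice_gradient_fraction=z.get("slice_gradient_fraction", 0.01),
                        rsnob_product=z.get("rsnob_product", RSNOB_PRODUCT)),
            n_t1=d.get("n_t1", 1),
            t1_fixed=d.get("t1_fixed_s", 3e-6),
            sw1=d.get("sw1_hz", 400.0),
            n_conventional_points=d.get("n_conventional_points"),
            noise_sigma=d.get("noise_sigma", 0.0),
            seed=d.get("seed", 0),
            weak_coupling=d.get("weak_coupling", False),
        )


@dataclass
class FidChunk:
    """One acquired FID chunk of the interferogram grid."""

    t1_index: int
    t2_index: int
    echo_antiecho_flag: str
    active_spin_label: str | None
    samples: np.ndarray


class Interferogram:
    """Chunked raw data on the full (t1, t2-chunk, echo/antiecho) grid.

    ``data[flag]`` is a complex array of shape (n_t1, n_chunks, pts);
    ``per_active`` holds the noiseless per-active-spin sub-grids before
    summation (decoupled mode only).
    """

    def __init__(self, data: dict, params: ExperimentParams,
                 per_active: dict | None = None) -> None:
        self.data = {k: np.asarray(v, dtype=complex) for k, v in data.items()}
        self.params = params
        self.per_active = per_active or {}
        shapes = {v.shape for v in self.data.values()}
        if len(shapes) != 1:
            raise ValueError("echo/antiecho grids have mismatched shapes")

    @property
    def shape(self):
        return next(iter(self.data.values())).shape

    def chunks(self):
        """Iterate the grid as :class:`FidChunk` views."""
        for flag, grid in self.data.items():
            for it1 in range(grid.shape[0]):
                for it2 in range(grid.shape[1]):
                    yield FidChunk(it1, it2, flag, None, grid[it1, it2])

    @classmethod
    def from_chunks(cls, chunks: list, params: ExperimentParams) -> "Interferogram":
        """Assemble from a chunk list; rejects incomplete grids naming the gap."""
        flags = sorted({c.echo_antiecho_flag for c in chunks})
        n_t1 = max(c.t1_index for c in chunks) + 1
        n_t2 = max(c.t2_index for c in chunks) + 1
        pts = len(chunks[0].samples)
        data = {f: np.full((n_t1, n_t2, pts), np.nan, dtype=complex) for f in flags}
        for c in chunks:
            if len(c.samples) != pts:
                raise ValueError("chunk lengths are not uniform")
            data[c.echo_antiecho_flag][c.t1_index, c.t2_index] = c.samples
        for f, grid in data.items():
            bad = np.argwhere(np.isnan(grid[:, :, 0]))
            if bad.size:
                it1, it2 = bad[0]
                raise ValueError(
                    f"missing chunk: t1_index={it1}, t2_index={it2}, flag={f!r}"
                )
        return cls(data, params)

    # -- hierarchical container IO --------------------------------------
    def to_hdf5(self, path) -> None:
        """Persist the grid with axis metadata, sufficient to round-trip."""
        import json

        with h5py.File(path, "w") as fh:
            fh.attrs["format"] = "pshsqmbc-interferogram-1"
            fh.attrs["params_json"] = json.dumps(self.params.to_dict())
            for flag, grid in self.data.items():
                fh.create_dataset(f"data/{flag}", data=grid)
            for label, grids in self.per_active.items():
                for flag, grid in grids.items():
                    fh.create_dataset(f"per_active/{label}/{flag}", data=grid)
            zs = self.params.zs
            fh.create_dataset("axes/t1_s", data=self.params.t1_values())
            fh.create_dataset("axes/t2_s", data=np.arange(self.shape[1]) / zs.sw2)
            fh.create_dataset("axes/t3_s", data=np.arange(self.shape[2]) / zs.sw)

    @classmethod
    def from_hdf5(cls, path) -> "Interferogram":
        import json

        with h5py.File(path, "r") as fh:
            if fh.attrs.get("format") != "pshsqmbc-interferogram-1":
                raise ValueError(f"{path}: not a pshsqmbc interferogram container")
            params = ExperimentParams.from_dict(json.loads(fh.attrs["params_json"]))
            data = {k: fh[f"data/{k}"][...] for k in fh["data"]}
            per_active = {}
            if "per_active" in fh:
                per_active = {
                    label: {flag: fh[f"per_active/{label}/{flag}"][...]
                            for flag in fh[f"per_active/{label}"]}
                    for label in fh["per_active"]
                }
        return cls(data, params, per_active)


# ---------------------------------------------------------------------------
# sequence elements
# ---------------------------------------------------------------------------

def cpmg_inept(state: SpinState, system: SpinSystem, cpmg: CpmgParams,
               phases: PhaseTable | None = None,
               hamiltonian: Hamiltonian | None = None,
               x_channel: str | Isotope | None = None) -> SpinState:
    """CPMG train of simultaneous 180s on 1H and X with XY-16 phases.

    In the ideal-pulse fast-pulsing limit an isolated H-X pair acquires
    antiphase coherence 2HxXz with amplitude sin(pi J T) while homonuclear
    J modulation is suppressed (the rapid echoes average away chemical-shift
    differences, making coupled protons effectively equivalent).
    """
    phases = phases or PhaseTable()
    if hamiltonian is None:
        hamiltonian = build_hamiltonian(system)
    if x_channel is None:
        het = system.hetero_isotopes()
        x_channel = het[0] if het else None
    for k in range(cpmg.n_cycles):
        phi = phases.xy16[k % 16]
        state = evolve(state, hamiltonian, cpmg.tau)
        state = pulse(state, "1H", 180.0, phi)
        if x_channel is not None:
            state = pulse(state, x_channel, 180.0, phi)
        state = evolve(state, hamiltonian, cpmg.tau)
    return state


def coherence_select(state: SpinState, orders: dict) -> SpinState:
    """Ideal coherence-order projection (the gradient-selection idealization).

    ``orders`` maps isotope name -> required coherence order on that channel;
    density-operator elements whose per-channel order signature differs are
    zeroed.  Idempotent.  Channels not named are unconstrained.
    """
    system = state.system
    m = system.zeeman_quantum_numbers()
    mask = np.ones((system.dim, system.dim), dtype=bool)
    for channel, p in orders.items():
        idx = system.channel_indices(channel)
        if abs(p) > len(idx):
            raise ValueError(
                f"|order| {abs(p)} exceeds spin count on channel {channel}"
            )
        m_ch = m[idx].sum(axis=0) if idx else np.zeros(system.dim)
        diff = m_ch[:, None] - m_ch[None, :]
        mask &= np.abs(diff - p) < 1e-9
    return SpinState(np.where(mask, state.rho, 0.0), system)


def echo_antiecho_gradient_ratio(x: str | Isotope, g2: float = 80.0) -> float:
    """Echo-antiecho decode gradient for heteronucleus ``x`` given encode ``g2``.

    Returns ``g2 * |gamma_rel(x)|`` (the coherence-selection condition for a
    +-1 -> -1 H transfer), e.g. 80 -> 32.3846 for 31P.
    """
    iso = get_isotope(x)
    return g2 * abs(iso.gamma_rel)


def zs_decoupling_element(state: SpinState, active_spin: str) -> SpinState:
    """Zangger-Sterk inversion element for one slice.

    Hard 180 on all protons followed by a selective 180 on the active
    proton: net effect inverts every proton except the active one and
    leaves heteronuclei untouched.
    """
    system = state.system
    idx = system.index(active_spin)
    if system.spins[idx].isotope.name != "1H":
        raise ValueError(f"active spin {active_spin!r} is not a proton")
    state = pulse(state, "1H", 180.0, 0.0)
    state = pulse_selective(state, active_spin, 180.0, 0.0)
    return state


def acquire_decoupled(state_at_acq_start: SpinState, system: SpinSystem,
                      params: ExperimentParams, active_spin: str,
                      hamiltonian: Hamiltonian | None = None,
                      t1_index: int = 0,
                      ea_flag: str = "echo") -> list[FidChunk]:
    """Chunked pure-shift acquisition for one active spin.

    For chunk ``k`` the t2 block is  D1 - hard180(1H) - D2 - sel180(active)
    - D3 - acquire, with D1 = k/(2 sw2) + chunkdur/4, D2 = chunkdur/4 and
    D3 = k/(2 sw2).  This realizes the contract: active-spin shift and
    J(H,X) phases evolve for T(k,t3) = k/sw2 + t3 while each homonuclear
    coupling's phase is proportional to (t3 - chunkdur/2) only, i.e. zero at
    the chunk midpoint.  Detection is restricted to the active spin; its
    linewidth is applied as exponential decay over the effective time T.
    """
    zs = params.zs
    if zs.chunk_duration > 1.0 / zs.sw2 + 0.5 / zs.sw:
        raise ValueError("chunk duration exceeds 1/sw2")
    if hamiltonian is None:
        hamiltonian = build_hamiltonian(system, params.weak_coupling)
    idx = system.index(active_spin)
    lw = system.spins[idx].linewidth
    dwell = 1.0 / zs.sw
    chunkdur = zs.chunk_duration
    u_dwell = hamiltonian.propagator(dwell)
    chunks: list[FidChunk] = []
    for k in range(zs.n_chunks):
        d1 = k / (2 * zs.sw2) + chunkdur / 4
        d2 = chunkdur / 4
        d3 = k / (2 * zs.sw2)
        st = evolve(state_at_acq_start, hamiltonian, d1)
        st = pulse(st, "1H", 180.0, 0.0)
        st = evolve(st, hamiltonian, d2)
        st = pulse_selective(st, active_spin, 180.0, 0.0)
        st = evolve(st, hamiltonian, d3)
        rho = st.rho
        samples = np.empty(zs.pts_per_chunk, dtype=complex)
        m = system.lowering(idx)
        for p in range(zs.pts_per_chunk):
            t_eff = k / zs.sw2 + p * dwell
            samples[p] = np.trace(rho @ m) * np.exp(-np.pi * lw * t_eff)
            rho = u_dwell @ rho @ u_dwell.conj().T
        chunks.append(FidChunk(t1_index, k, ea_flag, active_spin, samples))
    return chunks


def acquire_conventional(state_at_acq_start: SpinState, system: SpinSystem,
                         params: ExperimentParams,
                         hamiltonian: Hamiltonian | None = None,
                         t1_index: int = 0,
                         ea_flag: str = "echo") -> list[FidChunk]:
    """Continuous proton acquisition (ZS loop bypassed), one long chunk.

    Every proton is detected; each spin's signal decays with its own
    linewidth (per-spin detection amplitudes are summed).
    """
    zs = params.zs
    npts = params.n_conventional_points or zs.n_chunks * zs.pts_per_chunk
    if hamiltonian is None:
        hamiltonian = build_hamiltonian(system, params.weak_coupling)
    dwell = 1.0 / zs.sw
    u_dwell = hamiltonian.propagator(dwell)
    protons = system.proton_indices()
    ops = [system.lowering(i) for i in protons]
    lws = [system.spins[i].linewidth for i in protons]
    rho = state_at_acq_start.rho
    samples = np.zeros(npts, dtype=complex)
    for p in range(npts):
        t = p * dwell
        for op, lw in zip(ops, lws):
            samples[p] += np.trace(rho @ op) * np.exp(-np.pi * lw * t)
        rho = u_dwell @ rho @ u_dwell.conj().T
    return [FidChunk(t1_index, 0, ea_flag, None, samples)]


# ---------------------------------------------------------------------------
# the full experiment
# ---------------------------------------------------------------------------

def _detected_channel(system: SpinSystem) -> Isotope:
    het = system.hetero_isotopes()
    if len(het) != 1:
        raise ValueError(
            f"exactly one heteronuclear channel required, found "
            f"{[i.name for i in het]}"
        )
    return het[0]


def _t1_decay(state: SpinState, t1: float) -> SpinState:
    """Per-X-spin transverse decay during t1 (elementwise, flip-mask weighted)."""
    system = state.system
    m = system.zeeman_quantum_numbers()
    factor = np.ones((system.dim, system.dim))
    for i, s in enumerate(system.spins):
        if s.isotope.name == "1H" or s.linewidth == 0.0:
            continue
        flipped = np.abs(m[i][:, None] - m[i][None, :]) > 1e-9
        factor = np.where(flipped, factor * np.exp(-np.pi * s.linewidth * t1),
                          factor)
    return SpinState(state.rho * factor, system)


def _prepare_acquisition(system: SpinSystem, params: ExperimentParams,
                         hamiltonian: Hamiltonian, x: Isotope, t1: float,
                         ea_flag: str, scan: int | None) -> tuple[SpinState, complex]:
    """Propagate from thermal equilibrium to the start of acquisition.

    ``scan=None`` uses the ideal coherence-projection shortcut; an integer
    selects one step of the 8-step phase cycle and returns the receiver
    factor to apply to the detected signal.
    """
    ph = params.phases
    if scan is None:
        phi3, phi4, phi5 = ph.phi3[0], ph.phi4[0], ph.phi5[0]
        receiver = 1.0 + 0.0j
    else:
        phi3 = ph.phi3[scan % 2]
        phi4 = ph.phi4[scan % 4]
        phi5 = ph.phi5[scan % 8]
        # receiver reference tracks the quadrature of the last proton pulse
        rec = ph.phi_rec[scan % 8] + (ph.phi5[scan % 8] - ph.phi5[0])
        receiver = np.exp(-1j * np.deg2rad(rec))
    p_x = +1 if ea_flag == "echo" else -1

    st = thermal_state(system)
    st = pulse(st, "1H", 90.0, 0.0)
    st = cpmg_inept(st, system, params.cpmg, ph, hamiltonian, x)
    st = pulse(st, "1H", 90.0, ph.phi2)
    st = pulse(st, x, 90.0, phi3)
    if scan is None:
        st = coherence_select(st, {"1H": 0, x.name: p_x})
    else:
        st = coherence_select(st, {x.name: p_x})
    # t1: X shift evolution, proton 180 at the midpoint decouples J(H,X)
    st = evolve(st, hamiltonian, t1 / 2)
    st = pulse(st, "1H", 180.0, 0.0)
    st = evolve(st, hamiltonian, t1 / 2)
    st = _t1_decay(st, t1)
    st = pulse(st, x, 90.0, phi4)
    st = pulse(st, "1H", 90.0, phi5)
    if scan is None:
        st = coherence_select(st, {"1H": +1, x.name: 0})
    if params.phase_mode == "IP":
        # additional refocusing period: antiphase 2HyXz -> in-phase proton
        st = cpmg_inept(st, system, params.cpmg, ph, hamiltonian, x)
    return st, receiver


def run_experiment(system: SpinSystem, params: ExperimentParams,
                   phase_cycle: bool = False) -> Interferogram:
    """Run the full experiment and return the chunked raw data.

    Decoupled mode loops the ZS acquisition over every proton as the active
    spin and sums the sub-experiments with equal weights; conventional mode
    acquires one continuous FID.  With ``phase_cycle=True`` the 8-step
    phase cycle of the sequence replaces the ideal pathway projections
    (the echo-antiecho gradient pair is projected in both variants).
    """
    x = _detected_channel(system)
    hamiltonian = build_hamiltonian(system, params.weak_coupling)

    protons = [system.spins[i] for i in system.proton_indices()]
    if not protons:
        raise ValueError("system has no protons")
    jhx = [abs(system.jcouplings[system.index(p.label), j])
           for p in protons for j in system.channel_indices(x)]
    if max(jhx, default=0.0) < 1e-3:
        warnings.warn("no proton-heteronucleus coupling above threshold; "
                      "the spectrum will be empty", stacklevel=2)

    zs = params.zs
    t1s = params.t1_values()
    if params.mode == "conventional":
        npts = params.n_conventional_points or zs.n_chunks * zs.pts_per_chunk
        shape = (len(t1s), 1, npts)
    else:
        shape = (len(t1s), zs.n_chunks, zs.pts_per_chunk)

    data = {f: np.zeros(shape, dtype=complex) for f in params.ea_flags}
    per_active: dict[str, dict] = {}
    actives = [p.label for p in protons] if params.mode == "decoupled" else [None]

    for flag in params.ea_flags:
        for it1, t1 in enumerate(t1s):
            scans = range(8) if phase_cycle else [None]
            for scan in scans:
                st, receiver = _prepare_acquisition(
                    system, params, hamiltonian, x, t1, flag, scan)
                weight = receiver / len(list(scans)) if phase_cycle else 1.0
                for active in actives:
                    if active is None:
                        chunks = acquire_conventional(
                            st, system, params, hamiltonian, it1, flag)
                    else:
                        chunks = acquire_decoupled(
                            st, system, params, active, hamiltonian, it1, flag)
                    for c in chunks:
                        data[flag][it1, c.t2_index] += weight * c.samples
                        if active is not None:
                            grid = per_active.setdefault(
                                active,
                                {f: np.zeros(shape, dtype=complex)
                                 for f in params.ea_flags})
                            grid[flag][it1, c.t2_index] += weight * c.samples

    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.seed)
        for flag in data:
            data[flag] += params.noise_sigma * (
                rng.standard_normal(shape) + 1j * rng.standard_normal(shape))

    return Interferogram(
        data, params,
        per_active={k: v for k, v in per_active.items()} or None)


# ---------------------------------------------------------------------------
# design calculators
# ---------------------------------------------------------------------------

def zs_sensitivity_fraction(selective_bandwidth: float, gradient: float,
                            active_length: float) -> float:
    """Fraction of the sample contributing signal in a ZS experiment.

    ``min(1, bandwidth / (gammaH[Hz/G] * gradient[G/cm] * length[cm]))`` -
    directly proportional to the selective-pulse bandwidth and inversely
    proportional to the slice-selection gradient strength.
    """
    if selective_bandwidth <= 0 or gradient <= 0 or active_length <= 0:
        raise ValueError("all arguments must be > 0")
    return min(1.0, selective_bandwidth /
               (GAMMA_1H_HZ_PER_G * gradient * active_length))


def rsnob_duration(bandwidth: float, product: float = RSNOB_PRODUCT) -> float:
    """RSNOB pulse duration (s) for a given refocusing bandwidth (Hz)."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    return product / bandwidth


def rsnob_bandwidth(duration: float, product: float = RSNOB_PRODUCT) -> float:
    """RSNOB refocusing bandwidth (Hz) for a given pulse duration (s)."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    return product / duration
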