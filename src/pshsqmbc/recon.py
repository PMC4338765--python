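"""Pure-shift FID reconstruction and spectrum processing.

Chunk concatenation, shifted sine-squared apodization, zero-filling,
Fourier transformation, echo-antiecho hypercomplex recombination for
phase-sensitive 2D planes, and 1D spectrum export (JCAMP-DX / two-column
text).

Conventions fixed here: the frequency axis is stored in ascending Hz (the
spin at rotating-frame offset ``+Omega`` appears at ``+Omega``; display in
the NMR sense, high frequency left, is a plotting matter); ppm values need
a stated spectrometer frequency, default 500.13 MHz; "16k" zero-filling
means 16384 complex points; no automatic phasing — inputs are simulated
with known phases, and the zero-order phase is chosen so that an
on-resonance in-phase singlet is pure positive absorption (antiphase
spectra from the AP experiment need ``phase=90``, exposed as
:data:`AP_PHASE_DEG`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence import ExperimentParams, Interferogram

__all__ = [
    "SyntheticFid",
    "Spectrum",
    "concatenate_chunks",
    "apodize",
    "transform",
    "echo_antiecho_combine",
    "process_pseudo1d",
    "write_jcampdx",
    "write_xy",
    "AP_PHASE_DEG",
    "IP_PHASE_DEG",
    "DEFAULT_SF_MHZ",
]

#: zero-order phases (degrees) that render the AP experiment's antiphase
#: doublets / the IP experiment's in-phase doublets in pure (positive)
#: absorption with the project detection convention
AP_PHASE_DEG = 90.0
IP_PHASE_DEG = 180.0

#: default spectrometer 1H frequency for ppm axes (Avance II 500-class)
DEFAULT_SF_MHZ = 500.13


@dataclass
class SyntheticFid:
    """A reconstructed (or directly acquired) FID: samples + dwell time."""

    samples: np.ndarray
    dwell: float
    origin: dict = field(default_factory=dict)

    @property
    def sw(self) -> float:
        return 1.0 / self.dwell

    @property
    def duration(self) -> float:
        return len(self.samples) * self.dwell


@dataclass
class Spectrum:
    """Frequency axis (ascending Hz) + complex amplitudes + processing record."""

    axis: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)
    sf_mhz: float = DEFAULT_SF_MHZ

    def __post_init__(self) -> None:
        d = np.diff(self.axis)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("frequency axis must be strictly monotone")

    @property
    def ppm(self) -> np.ndarray:
        return self.axis / self.sf_mhz

    @property
    def hz_per_point(self) -> float:
        return float(abs(self.axis[1] - self.axis[0]))

    def slice(self, lo: float, hi: float) -> "Spectrum":
        """Sub-spectrum on the closed Hz interval [lo, hi]."""
        sel = (self.axis >= lo) & (self.axis <= hi)
        if not np.any(sel):
            raise ValueError(f"window [{lo}, {hi}] Hz is outside the axis")
        return Spectrum(self.axis[sel], self.values[sel], dict(self.meta),
                        self.sf_mhz)


def concatenate_chunks(interferogram: Interferogram, t1_index: int = 0,
                       ea_flag: str = "echo",
                       active: str | None = None) -> SyntheticFid:
    """Concatenate the FID chunks at one t1 increment in t2 order.

    Yields the synthetic pure-shift FID of length n_chunks * pts_per_chunk;
    no samples are dropped or duplicated.  ``active`` selects a per-active-
    spin sub-grid instead of the summed data.
    """
    source = (interferogram.per_active[active] if active is not None
              else interferogram.data)
    if ea_flag not in source:
        raise ValueError(f"no {ea_flag!r} grid in interferogram")
    grid = source[ea_flag]
    if not 0 <= t1_index < grid.shape[0]:
        raise ValueError(f"t1_index {t1_index} out of range")
    samples = np.concatenate([grid[t1_index, k] for k in range(grid.shape[1])])
    return SyntheticFid(
        samples=samples,
        dwell=1.0 / interferogram.params.zs.sw,
        origin={"t1_index": t1_index, "ea_flag": ea_flag, "active": active},
    )


def _window(n: int, shift_deg: float) -> np.ndarray:
    """Shifted sine-squared window: sin^2 from ``shift`` to 180 degrees.

    At shift 90 this is the cosine-squared bell (1 at t=0, 0 at the end).
    """
    if not 0 < shift_deg <= 90:
        raise ValueError("shift parameter must be in (0, 90] degrees")
    phi0 = np.deg2rad(shift_deg)
    x = np.arange(n) / max(n - 1, 1)
    return np.sin(phi0 + (np.pi - phi0) * x) ** 2


def apodize(fid: SyntheticFid, shift_deg: float = 90.0) -> SyntheticFid:
    """Multiply by a shifted sine-squared window (no first-point scaling here;
    :func:`transform` halves the first point before the FT)."""
    w = _window(len(fid.samples), shift_deg)
    origin = dict(fid.origin)
    origin["window"] = {"kind": "sine-squared", "shift_deg": shift_deg}
    return SyntheticFid(fid.samples * w, fid.dwell, origin)


def transform(fid: SyntheticFid, zerofill_to: int = 16384,
              phase_deg: float = 0.0, sf_mhz: float = DEFAULT_SF_MHZ) -> Spectrum:
    """Zero-fill, Fourier transform and zero-order phase a 1D FID.

    The FT kernel is ``exp(+i 2 pi f t)`` so that the project detection
    convention places offset ``+Omega`` at ``+Omega``; Hz-per-point equals
    ``sw / zerofill_to``.  The first FID point is halved (standard trapezoid
    correction for the baseline offset).
    """
    n = len(fid.samples)
    if zerofill_to < n:
        raise ValueError("zero-fill size smaller than the data")
    buf = np.zeros(zerofill_to, dtype=complex)
    buf[:n] = fid.samples
    buf[0] *= 0.5
    values = np.fft.fftshift(np.fft.ifft(buf) * zerofill_to)
    axis = np.fft.fftshift(np.fft.fftfreq(zerofill_to, fid.dwell))
    values = values * np.exp(1j * np.deg2rad(phase_deg))
    meta = {
        "zerofill": zerofill_to,
        "phase_deg": phase_deg,
        "sw_hz": fid.sw,
        "window": fid.origin.get("window"),
        "origin": {k: v for k, v in fid.origin.items() if k != "window"},
    }
    return Spectrum(axis, values, meta, sf_mhz)


def process_pseudo1d(interferogram: Interferogram, shift_deg: float = 90.0,
                     zerofill_to: int = 16384, phase_deg: float | None = None,
                     sf_mhz: float = DEFAULT_SF_MHZ,
                     active: str | None = None) -> Spectrum:
    """Concatenate -> apodize -> transform the pseudo-1D (single t1) data.

    ``phase_deg=None`` picks the documented default for the experiment's
    phase mode (90 for AP, 180 for IP).
    """
    params = interferogram.params
    if phase_deg is None:
        phase_deg = AP_PHASE_DEG if params.phase_mode == "AP" else IP_PHASE_DEG
    fid = concatenate_chunks(interferogram, 0, "echo", active=active)
    fid = apodize(fid, shift_deg)
    return transform(fid, zerofill_to, phase_deg, sf_mhz)


def echo_antiecho_combine(interferogram: Interferogram,
                          shift_deg: float = 90.0,
                          zerofill_to: int = 8192,
                          zerofill_t1: int = 256,
                          phase_deg: float | None = None,
                          sf_mhz: float = DEFAULT_SF_MHZ) -> tuple:
    """Hypercomplex echo-antiecho recombination into a phase-sensitive plane.

    Returns ``(f1_axis_hz, f2_spectrum_axis_hz, plane)`` where ``plane`` has
    shape (len(f1), len(f2)) and a single X spin on resonance gives one
    absorptive ridge at its offset (the mirror image is suppressed).
    """
    params = interferogram.params
    if "echo" not in interferogram.data or "antiecho" not in interferogram.data:
        raise ValueError("both echo and antiecho grids are required")
    if interferogram.data["echo"].shape != interferogram.data["antiecho"].shape:
        raise ValueError("echo/antiecho grid shapes mismatch")
    if phase_deg is None:
        phase_deg = AP_PHASE_DEG if params.phase_mode == "AP" else IP_PHASE_DEG
    n_t1 = interferogram.shape[0]

    f2_rows = {}
    for flag in ("echo", "antiecho"):
        rows = []
        for it1 in range(n_t1):
            fid = concatenate_chunks(interferogram, it1, flag)
            fid = apodize(fid, shift_deg)
            spec = transform(fid, zerofill_to, phase_deg, sf_mhz)
            rows.append(spec.values)
        f2_rows[flag] = np.array(rows)
        f2_axis = spec.axis

    e, a = f2_rows["echo"], f2_rows["antiecho"]
    # echo (p_X = +1) modulates as exp(-i 2 pi Omega_X t1), antiecho as the
    # conjugate; recombine into the single rotating component that the FT
    # convention places at +Omega_X
    cos_part = 0.5 * (e + a)
    sin_part = (e - a) / 2j
    inter = cos_part + 1j * sin_part          # complex t1 interferogram

    if n_t1 == 1:
        return (np.zeros(1), f2_axis, inter)

    w1 = _window(n_t1, shift_deg)
    inter = inter * w1[:, None]
    buf = np.zeros((zerofill_t1, inter.shape[1]), dtype=complex)
    buf[:n_t1] = inter
    buf[0] *= 0.5
    plane = np.fft.fftshift(np.fft.ifft(buf, axis=0) * zerofill_t1, axes=0)
    f1_axis = np.fft.fftshift(np.fft.fftfreq(zerofill_t1, 1.0 / params.sw1))
    return (f1_axis, f2_axis, plane)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_jcampdx(spectrum: Spectrum, path, title: str = "pshsqmbc spectrum") -> None:
    """Write the real part of a 1D spectrum as a JCAMP-DX 5.01 XYPOINTS file."""
    axis = spectrum.axis
    real = spectrum.values.real
    with open(path, "w") as fh:
        fh.write(f"##TITLE={title}\n")
        fh.write("##JCAMP-DX=5.01\n")
        fh.write("##DATA TYPE=NMR SPECTRUM\n")
        fh.write("##XUNITS=HZ\n##YUNITS=ARBITRARY UNITS\n")
        fh.write(f"##OBSERVE FREQUENCY={spectrum.sf_mhz}\n")
        fh.write(f"##FIRSTX={axis[0]:.6f}\n##LASTX={axis[-1]:.6f}\n")
        fh.write(f"##NPOINTS={len(axis)}\n")
        fh.write("##XYPOINTS=(XY..XY)\n")
        for x, y in zip(axis, real):
            fh.write(f"{x:.6f}, {y:.8e}\n")
        fh.write("##END=\n")


def write_xy(spectrum: Spectrum, path) -> None:
    """Two-column text export: frequency (Hz) and real intensity."""
    np.savetxt(path, np.column_stack([spectrum.axis, spectrum.values.real]),
               header="freq_hz intensity", fmt="%.8e")
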