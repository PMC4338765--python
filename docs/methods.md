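# Model and methods

This note documents what the simulator computes, the idealizations it
makes, the conventions that every module inherits, and the places where the
design was genuinely open.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Spin model and conventions

Spins are spin-½; the state is a dense complex density matrix over the
2^N-dimensional product space (practical ceiling N = 8).  The Hamiltonian,
in Hz, is

    H = Σ_i Ω_i I_iz + Σ_{i<j} J_ij (I_iz I_jz [+ I_ix I_jx + I_iy I_jy])

with the transverse (flip-flop) terms included for homonuclear pairs only;
heteronuclear couplings are always secular.  A `weak_coupling` flag drops
the homonuclear flip-flop terms; the full Hamiltonian reduces to this limit
when |Δν/J| is large (tested at 10³).  Offsets are per-channel
rotating-frame shifts; absolute Larmor frequencies are never simulated, and
each isotope channel has an independent rotating frame.

Fixed sign conventions (everything downstream inherits them):

* right-handed rotations — a 90°ₓ pulse takes Iz → −Iy;
* free precession `U = exp(−i2πHt)` — Ix → Ix cos(2πΩt) + Iy sin(2πΩt);
* detection operator ΣI⁻ = Σ(Ix − iIy), so a spin at offset +Ω detects as
  exp(−i2πΩt) and the FT kernel exp(+i2πft) places it at +Ω on an
  ascending frequency axis (the NMR "high frequency left" display is a
  plotting choice, not a storage one);
* thermal state: identity/2^N plus γ-weighted Iz deviation scaled so one
  fully excited isolated proton detects with amplitude 1.

Relaxation is deliberately not propagated as Lindblad dynamics: each spin
carries a FWHM linewidth, applied as exponential decay exp(−π·lw·t) of its
*detected* amplitude — for pure-shift data over the concatenated effective
time k/sw2 + t₃, so the reconstructed FID decays smoothly.  This produces
correct Lorentzian lineshapes at a fraction of the cost; what it cannot
represent is relaxation *during* the transfer and t1 periods
(T2-weighting of the CPMG train, NOE, cross-correlation), so simulated
relative intensities are more favorable than experimental ones.

## The pulse sequence

The experiment is: 90°(¹H) — CPMG-INEPT — 90°(¹H,φ2=y) + 90°(X,φ3) —
[t1 with a proton 180° at its midpoint] — 90°(X,φ4) + 90°(¹H,φ5) —
[optional refocusing CPMG for the IP variant] — ZS chunked acquisition.

**CPMG-INEPT.**  n cycles of (τ — 180°(¹H)+180°(X) — τ) with the XY-16
phase supercycle (XY-8, x y x y y x y x, plus its phase-inverted copy; the
same phase list drives both channels).  Timing is built by
`CpmgParams.from_duration`, which picks the multiple-of-16 pulse count
nearest `T/(2τ)` and adjusts τ exactly.  With ideal pulses an isolated H–X
pair acquires antiphase coherence with amplitude sin(πJT).  Homonuclear
shift differences are averaged out in the fast-pulsing limit, which
suppresses J(H,H) evolution into antiphase — but only while the protons
remain effectively equivalent.  A nonzero J(H,X) term survives the
simultaneous 180° pairs and re-introduces inequivalence in the toggling
frame, so J(H,H) mixing partially proceeds over the long transfer period.
This is genuine CPMG-HSQMBC behavior (it is why proton–proton structure
still contaminates conventional spectra and why the pure-shift acquisition
is needed at all); the test suite quantifies the clean-suppression limit
with an uncoupled heteronucleus.

**Gradients as projections.**  No spatial integration is performed.  The
purge gradients and the echo/antiecho pair are replaced by exact
coherence-order projections: after the first transfer the pathway
{p(¹H)=0, p(X)=±1} is kept (echo: +1, antiecho: −1), after back-transfer
{p(¹H)=+1, p(X)=0} — the order the fixed detection operator observes.  The
printed 8-step phase cycle (φ3 = x,−x; φ4 = x,x,−x,−x; φ5 = x⁴,y⁴;
φrec = x,−x,−x,x,−x,x,x,−x) is also implemented; with the simulator's
receiver convention (the receiver reference tracks the quadrature of the
last proton pulse, i.e. the effective receiver phase is φrec + Δφ5) the
cycled average equals the projected pathway to machine precision, which the
suite asserts.  The gradient amplitudes themselves survive only as
bookkeeping: the echo–antiecho decode ratio G2:G4 = 80:80·|γ_X/γ_H| is
computed from the isotope registry (IUPAC frequency ratios, ≥ 6
significant figures).

**Slice selection.**  In the real experiment each sample slice yields
signal for the one proton resonant there.  The simulator runs one
sub-experiment per proton ("active spin") and sums them with equal
weights; the physical signal fraction is available separately through
`zs_sensitivity_fraction` = bandwidth/(γH·G·L), which for the typical
50 Hz selective pulse, 1 % of 53 G cm⁻¹ and a 1.8 cm active volume gives a
few percent — the documented sensitivity cost of ZS decoupling.  The
RSNOB selective pulse is modelled as an instantaneous 180° on the active
spin; its finite duration enters only through the design calculator via
the constant duration×bandwidth product 2.332 (46.64 ms·50 Hz =
93.28 ms·25 Hz = 23.32 ms·100 Hz).

**ZS chunk timing.**  Published timing gives τa = 1/(4·sw2) and
τb = 1/(4·sw2) − 4/sw around the inversion element, but the exact placement
is under-determined; this implementation pins the observable contract
instead.  For chunk k the t2 block is

    D1 — hard 180°(¹H) — D2 — selective 180°(active) — D3 — acquire,
    D1 = k/(2·sw2) + chunkdur/4,  D2 = chunkdur/4,  D3 = k/(2·sw2),

which yields exactly: active-spin shift and J(H,X) phase = k/sw2 + t₃
(continuous across chunks — for a J(H,H)-free system the concatenated FID
equals a continuously acquired one to 10⁻¹⁰), and J(H,H) phase
∝ (t₃ − chunkdur/2), zero at every chunk midpoint.  The chunk duration
pts_per_chunk/sw must equal the t2 increment 1/sw2 within one dwell.
Chunking residuals appear as sidebands at multiples of sw2 whose amplitude
shrinks with the chunk duration (tested at two durations).  The first
chunk is a full-length chunk starting at t = 0.

**t1 and echo/antiecho.**  During t1 the X shift evolves with a proton
180° at the midpoint (decoupling J(H,X)); transverse X decays with its own
linewidth.  Echo and antiecho grids modulate as exp(∓i2πΩx·t1); the
hypercomplex recombination (cos = (e+a)/2, sin = (e−a)/2i, FT of
cos + i·sin) places the peak at +Ωx with the quadrature image cancelled to
machine precision.  What *remains* at −Ωx in practice is f1
window/lineshape leakage of the +Ωx ridge, not a quadrature artifact; the
mirror-suppression test therefore reads the absorptive real part at the
proton's f2 column with a well-sampled decaying t1 record, where the
measured image ratio is several hundred.

## Processing

Shifted sine-squared window `sin²(φ0 + (π−φ0)·t/T)` with the shift in
(0°, 90°]; the default 90° (pure cosine-squared bell) is a choice — the
published processing states "shifted sine-squared" without the shift value.
Zero-fill default 16384 ("16k") in the direct dimension, 256/512 in the
indirect one; Hz-per-point = sw/zerofill (the published spectral width of
6.0371 ppm at 500.13 MHz with 16k zero-fill gives 0.184 Hz/pt, inside the
stated 0.1–0.3 Hz band, asserted in the suite).  The first FID point is
halved before the direct-dimension FT (baseline-offset correction of a
sampled decaying exponential) and likewise along t1.  Zero-order phase:
the IP experiment's in-phase doublet is rendered in positive absorption
with 180°, the AP experiment's antiphase doublet with 90°; no automatic
phasing exists because all phases are known by construction.

## J measurement

The raw observable is the separation of the positive and negative extrema
of an antiphase doublet (extrema located by three-point parabolic
interpolation, ties broken by magnitude; windows centred on the known
proton offsets).  For Lorentzian lobes of FWHM w the extrema are pushed
apart: the separation always *over*estimates |J|, approaching the
derivative-of-Lorentzian limit w/√3 as J → 0.  No closed form is assumed:
`antiphase_peak_separation(J, w)` finds the extrema of the closed-form
lineshape by root-finding on its analytic derivative, and
`correct_splitting` inverts that forward map (Brent's method; separations
at or below w/√3 are rejected as unresolvable).  The inversion is exact to
well under 1 % over J/w ∈ [0.5, 50].  IPAP editing (α/β = IP ± scale·AP,
scale defaulting to 1) gives displaced singlets whose maxima differ by
exactly J for ideal lineshapes, independent of linewidth — the preferred
reading when J ≲ w.

Sign information: for an isolated H–X pair the detected doublet is *even*
under J → −J (transfer ∝ sin(πJT) and acquisition evolution ∝ sin(πJt)
are both odd), so a single doublet encodes |J| only.  In a coupled proton
network the up/down patterns of different doublets flip *relative to each
other* when the relative sign of their couplings flips; couplings are
accordingly reported as magnitudes plus a relative sign flag.

## Synthetic fixtures — what they emulate and what they do not

The six registered fixtures are desk-scale stand-ins for the demonstration
compounds: 3–5 spins, spectral widths 2000–2500 Hz, 16–64 chunks, ≤ 8 t1
increments, linewidths 0.15–1.5 Hz, noise off by default.  Heteronuclear
couplings in `cump-demo` are pinned to the demonstrated range endpoints
(1.6 and 21.3 Hz); every other value (the 8.0 Hz mid coupling, all J(H,H)
of 1.5–7 Hz, offsets, linewidths) is invented and marked as such in each
fixture's provenance notes.  `cump-demo` uses 64 × 40 ms chunks (2.56 s of
pure-shift acquisition) so that the 1.6 Hz doublet is resolved by the raw
peak read-off: with the cosine-squared window the record-limited effective
linewidth is ≈ 0.6 Hz, giving a lineshape bias below 0.04 Hz; a 0.8 s
record would leave ≈ 1.4 Hz and push the raw read-off outside a 0.1 Hz
tolerance.  Chunk durations of 16–40 ms straddle the published 10–25 ms
band by design of the resolution argument above.

Passing tests on these fixtures show that the *sequence, reconstruction
and measurement pipeline* is internally correct at the stated tolerances.
They do not show robustness against what real samples add: dense
strongly-coupled proton networks, B1 inhomogeneity and pulse miscalibration,
finite selective-pulse profiles, relaxation during transfer, temperature
and lock instabilities, and realistic noise floors.  The real compounds'
spectra are not reproduced, only the mechanism that makes their couplings
measurable.

## Numerical choices

* Propagators by eigendecomposition of the (Hermitian) Hamiltonian, cached
  per Hamiltonian object; verified against scipy's scaling-and-squaring
  `expm` to 10⁻¹⁰.
* Unitarity bookkeeping: trace and Hermiticity preserved to 10⁻¹⁰ by every
  pulse/evolution (asserted); coherence projections are intentionally
  non-unitary bookkeeping steps.
* Noise: seeded complex Gaussian per sample, added to the summed grid only
  (the stored per-active sub-grids stay noiseless).
* Degenerate inputs: zero heteronuclear coupling is legal and produces an
  empty spectrum with a warning; non-symmetric J matrices, negative
  durations/linewidths, unknown isotopes/fixtures, incomplete chunk grids
  and over-long chunks are rejected with named diagnostics.
* Determinism: noise-free runs are bit-identical for identical inputs; all
  randomness flows through explicit integer seeds.

## Known limitations

Ideal pulses only (no shaped-pulse integration, no B1 maps, no composite-
pulse imperfections — the composite 90x–180y–90x is available and is an
exact inversion); gradients as projections (no diffusion or gradient-recovery
artifacts); relaxation only as detection-time decay; one detected
heteronuclear channel per experiment; dense matrices cap the system at
about 8 spins.  BIRD-based decoupling, PSYCHE and real-time decoupling
variants are out of scope.
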