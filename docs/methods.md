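# Methods

This note documents the models implemented in `deep3p`, their
assumptions, the defaults and why, the numerical choices, and what the
synthetic-data generators do and do not emulate.

## Excitation photon budget (`deep3p.tissue_optics`)

Three-photon (3P) fluorescence excited by a pulsed laser obeys

    <F(t)> ∝ Pfocus³ / (f τ)²  =  Efocus² · Pfocus / τ²,

with repetition rate `f`, pulse width `τ`, focal average power `Pfocus`
and focal pulse energy `Efocus = Pfocus/f`.  Ballistic excitation decays
exponentially with depth, `Pfocus = Psurface · A(z)` where
`A(z) = exp(−Σᵢ Δzᵢ/EALᵢ)` over piecewise-constant effective-attenuation-
length (EAL) layers; the deepest layer extends indefinitely.  A layered
model is used because grey and white matter attenuate differently; a
single uniform layer reproduces the textbook `exp(−z/EAL)`.

All proportionality constants (cross-section, collection efficiency,
quantum yield) are fixed to 1: only signal **ratios** are meaningful.
Comparisons between sources default to equal pulse width; an explicit
flag admits unequal-τ comparisons through the `(fτ)²` term.

Given a surface-power limit (tissue heating) and a focal pulse-energy
limit (fluorophore saturation / nonlinear damage), the repetition rate
that simultaneously saturates both is

    f(z) = A(z) · Psurface_max / Efocus_max,

50 MHz at the surface for the defaults `Psurface_max = 100 mW`,
`Efocus_max = 2 nJ`, and ~100 kHz at depths where `A(z) ≈ 1/500`.
`required_surface_energy` and `focus_pulse_energy` are exact inverses;
`f(z) · Esurface(z)` conserves the surface power at every depth.  These
identities are enforced by property tests.

Raw depths recorded as objective displacement underestimate true tissue
depth by ~5–10% (refractive-index mismatch); `calibrate_depth`
multiplies by a factor in [1.0, 1.2], default 1.075 (range midpoint).

Units: μm (depth, EAL), nJ (pulse energy), mW (average power), Hz
(rates), s (times).  Default EAL (300 μm) is a documented placeholder
typical of cortical grey matter at 1300 nm and is user-overridable;
measured in vivo EALs are sample-specific inputs, not package constants.

## Collection geometry (`deep3p.collection`)

Fluorescence from depth `z` exits the surface over a diffuse region of
FWHM ≈ 1.5 z; the "diameter" of the region is identified with this FWHM
(no Gaussian-tail modelling).  The collection field of view (FOV)
required is `1.5 z + scan_fov`.  An objective whose 80%-throughput
collection FOV is smaller than required loses light by the squared FOV
ratio; the penalty saturates at 1 when the spread fits (no credit for
oversized FOV).  Gains between objectives multiply the squared NA ratio
by the penalty ratio; because whether quoted gains include the NA factor
is a matter of convention, `collection_gain(..., include_na=False)`
isolates the FOV factor.  Excitation and collection improvements
combine multiplicatively.  Diffusion-theory or Monte-Carlo transport of
emitted light is out of scope.

## Transient detectability (`deep3p.detectability`)

A single calcium transient is modelled as an instantaneous rise of
amplitude ΔF/F with single-exponential decay τ1e (GCaMP8s-like
defaults: ΔF/F = 0.7 per action potential, τ1e = 0.29 s; τ1e = t½/ln 2).
Against Poisson baseline noise at F0 photons/neuron/s, the
matched-filter discriminability is

    d' = (ΔF/F) · sqrt(F0 · τ1e / 2).

`required_f0` inverts this exactly; `budget_table` evaluates the
standard set d' ∈ {4.65, 3.76, 3.29, 2.95}, giving required budgets
{304, 199, 152, 122} photons/neuron/s to the nearest integer.  The
widely quoted ≈305 for the 99% row corresponds to the unrounded
d' = 2·Φ⁻¹(0.99) = 4.6527; tabulated budgets are approximate at the
±1 photon level and the tests compare at that precision.

The d'↔confidence map is the equal-variance Gaussian observer with an
unbiased criterion, `confidence = Φ(d'/2)`.  This criterion is an
inference (detection tables rarely state one) but reproduces the
99/97/95/93% pairings to the nearest percent.

`monte_carlo_dprime` is an independent oracle: paired Poisson trials
(transient vs null) at a given frame rate, matched filter
`k(t) = e^{−t/τ1e}` applied to null-mean-subtracted counts, rates
evaluated at frame midpoints.  The default normalisation is the **null**
standard deviation, whose expectation equals the closed form above.
The symmetric "pooled" convention sqrt((σ²s+σ²n)/2) is also available;
it sits ≈ 1/sqrt(1 + (ΔF/F)/2 · Σk³/Σk²) (~10% at ΔF/F = 0.7) below the
closed form because the transient itself adds shot noise to signal
trials.  That shortfall is a property of the convention, not an error;
the test suite asserts its predicted size.  Monte-Carlo defaults: 2 s
window, onset at t = 0, 100 Hz sampling, 20 000 trials, bootstrap
standard errors, one explicit seed.

## SBR and depth limit (`deep3p.sbr`)

Pixel intensities convert to absolute photon counts by a conversion
factor fitted as a zero-intercept least-squares slope over paired
photon-counting/imaging measurements; the validated linear range is the
largest input with residual < 10% of the fit.  Per-slice SBR is
`mean(signal ROI) / mean(background ROI)` with caller-supplied,
hand-drawn adjacent background regions (no automatic background
detection).  A zero background mean yields `inf` — flagged, never
pseudo-counted — and such slices are ignored by the depth-limit search.

The depth limit is the first depth where SBR crosses a threshold
(default 1) from above, located by log-linear interpolation between
bracketing slices (SBR decays roughly exponentially, so interpolating
`ln SBR` is the natural choice).  Locating a crossing requires the
profile to bracket it; the synthetic default stack therefore extends a
few steps beyond its generating limit.

EAL estimation uses the cube-root transform: since signal ∝
`(Esurface·e^{−z/EAL})³`, `ln(signal^{1/3}/Esurface)` is linear in depth
with slope `−1/EAL`.  Normalising per-slice by the surface pulse energy
handles depth-ramped excitation.  The 95% CI is a bootstrap over depth
points (1000 resamples, seeded).  A non-negative slope raises
"no attenuation detected".

Line profiles sample the nearest pixel at 1-px arclength steps —
interpolation would break photon-count semantics.  Display stretching
rescales linearly to [0, 1], saturating the top 0.2–0.5% of pixels
(constant images map to zero).

## Activity-trace pipeline (`deep3p.traces`)

Stages (pure functions, metadata-preserving): ROI photon-count
integration over a soma (~100 px) → zero-phase Hamming low-pass →
lower-20% baseline F0 → ΔF/F = (F−F0)/F0 → baseline photon rate with a
150 photons/neuron/s fidelity flag.  Order (filter before normalise) is
switchable.  An optional initial discard handles photobleaching
settle-in (default 0 for synthetic data).

**Hamming window**: the 0.29 s "time constant" is read as the window
duration; taps = round(tc·frame rate), minimum 3, forced odd for zero
phase, normalised to unit DC gain, reflected edges.  At 6.18 Hz this is
3 taps.  The tap rule is a package decision; alternative readings change
the smoothing bandwidth, not the interfaces.

**Lower-20% baseline**: the mean of samples at or below the 20%
quantile.  On a stationary noisy trace this sits below the true mean by
≈ 1.40 σ_noise (the mean of a Gaussian's lower quintile).  At budgets of
a few hundred photons/neuron/s (tens of photons per frame per ROI) that
is a 10–25% systematic underestimate — inherent to the estimator, for
real and synthetic data alike.  Parameter-recovery tests therefore use
the mean over ground-truth transient-free frames as the unbiased
baseline reference, and treat the lower-20% value as what it is: a
robust, slightly conservative operational baseline (it biases measured
ΔF/F up and never spuriously passes the fidelity check).

**Kinetics recovery** (`fit_transient_kinetics`): at 6.18 Hz a 0.29 s
transient is heavily frame-averaged — the raw peak of a ΔF/F = 0.7
transient reads ~0.54 — so amplitude and τ1e are recovered by fitting
the forward model (exact per-frame integration of the exponential at
each event's sub-frame onset phase, then the same Hamming filter) to the
mean transient aligned across isolated events.

**Median-3D video filter**: per-voxel median over a
(2rx+1)×(2ry+1)×(2rt+1) neighbourhood with *truncated* edge
neighbourhoods — no padding values are invented — followed by trimming
9 frames at each end to discard edge artefacts.  Default radii
(1, 1, 18) span ~3 s temporally at 6.18 Hz.  Half-integer medians of
truncated even-sized windows round to nearest.  The implementation is
hand-written because library median filters offer padding modes but not
truncation.

## Synthetic data (`deep3p.synth`)

**Structural stacks**: sinusoidal vessel tubes in a layered attenuating
medium.  Signal pixels carry `photon_scale · (E(z)A(z)/E(0)A(0))³`
expected photons; background pixels `signal / SBR(z)` with SBR decaying
log-linearly from `sbr0` at the surface to 1 at the recipe's depth
limit — the simplest monotone model consistent with how SBR-depth
curves are used; the true functional form of background growth is not
modelled.  The default surface-energy ramp compensates attenuation
(`Esurface(z) = Efocus_target · e^{z/EAL}`), as done in practice; a
constant-energy option exists.  Background photons are spatially
uniform per slice (no out-of-focus PSF modelling).  Counts are Poisson.
Defaults: 28 slices × 100 μm (to 2700 μm, bracketing the 2500 μm
default limit), 64×64 px, sbr0 = 100, 50 signal photons/pixel.

**Activity movies**: 120×120 px over 100 μm at 6.18 Hz, up to 44
neurons of 10–15 μm diameter with nuclear exclusion (60% of soma
photons in a 2-px cytoplasmic ring).  Somata are placed on a jittered
lattice with radii clipped to the pitch — 44 somata of this size
approach the jamming density of random sequential placement, and the
lattice guarantees disjoint masks.  Spike trains are homogeneous
Poisson (default 0.1 Hz, sparse spontaneous activity); transient
modulation `F0·(1 + ΔF/F·Σ e^{−(t−ts)/τ1e})` is integrated exactly over
each frame; per-pixel counts are Poisson.  Default baseline
F0 = 300 photons/neuron/s — comfortably above the 150 photons/s
fidelity threshold, at the ~99% single-transient detection point — and
a small uniform background (0.1 photons/pixel/s), consistent with the
strong background suppression of 3P excitation (pixel-level SBR of
order 25, matching SBR > 10 deep-imaging conditions).

**What the generators do not emulate**, hence what passing tests do not
show about real data: motion (correction is delegated to external
tools), neuropil contamination, photobleaching dynamics, PMT
multiplication noise and dark counts, optical PSF blur, vessel
branching, depth-dependent soma visibility.  Recovery tests demonstrate
estimator correctness and calibration under the stated statistical
model, not robustness to those effects.  All generators are bitwise
deterministic given their seed, and every downstream recovery test
reads only the returned ground-truth record.

## Problem sizes

Recovery tests use 28-slice 64×64 stacks, 20 000-trial Monte-Carlo
detectability runs at F0 ∈ {500, 1000, 5000} photons/s, and one
300 s, 44-neuron session (~1850 frames) — sizes at which every recovery
tolerance has comfortable statistical margin while the whole suite runs
in well under a minute of compute for the stochastic parts.

## Known limitations

- The d'↔confidence criterion Φ(d'/2) is inferred, not measured.
- F0 is treated as the neuron's clean baseline rate; neuropil
  contamination is not modelled or subtracted.
- The FOV penalty uses the squared-ratio rule on 80%-throughput
  diameters; partial Gaussian capture is deliberately excluded.
- The lower-20% baseline bias described above propagates into any
  quantity normalised by it.
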