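# Methods

`needletrack` models a hybrid 3D ultrasound imaging / needle-tracking system:
a sparse 2D matrix-array probe alternates between volumetric plane-wave
imaging and a tracking phase in which individual elements fire one at a time
while a point hydrophone embedded at the needle tip records each transmission.
The packages implements the tracking chain only — waveform synthesis, a
propagation simulator standing in for the hydrophone hardware, matched-filter
pulse compression, reliability-gated time-of-arrival (ToA) estimation,
multilateration, a delay-and-sum (DAS) baseline, and the evaluation tools
around them.

Units are mm, µs and MHz throughout; the default sound speed is
c = 1.48 mm/µs (water near 20 °C).

## Array geometry

Elements are generated on a Fermat spiral, r_k = s·√k, θ_k = k·γ with γ the
golden angle, which samples a circular aperture with low redundancy.  The
default layout has 256 elements with s = 0.33 mm, snapped to a 0.3 mm
rectangular lattice (the pitch of a typical 3 MHz matrix array), giving an
outer radius of ≈ 5.3 mm — about half the aperture of a 32×35-element array
at that pitch.  Grid snapping resolves node collisions to the nearest free
node and guarantees no element moves more than one grid diagonal; layouts can
also be loaded from `element_id,x_mm,y_mm` CSV/JSON so measured probe maps
can be substituted.

Sparsification ranks elements by distance from the layout centroid and keeps
the *k outermost*.  Removing inner elements preserves the full aperture (and
hence the angular diversity that conditions 3D range intersection) while
cutting the number of tracking transmissions, which is what sets the frame
rate.  Subsets are nested by construction; the minimum admissible size is 3,
the smallest number of spheres with a unique front-half-space intersection.

## Excitation and simulator

Two transmit waveforms are supported at 26 MHz sampling: a 5 µs linear chirp
sweeping 1→5 MHz (the tracking excitation; time-bandwidth product T·B = 20),
and a four-cycle Gaussian tone burst at 3 MHz (the conventional pulse, with
its n cycles fitted between the envelope's half-amplitude points).

The simulator treats the needle-tip hydrophone as an ideal, omnidirectional
point receiver in a homogeneous medium.  Each element's trace is the
excitation delayed by τ_i = ‖p − s_i‖/c and scaled by 1/‖p − s_i‖
(spherical spreading; amplitudes are relative).  Delays are applied as
frequency-domain phase ramps with ≥ 2× zero padding, so the ground-truth τ_i
is exact and never quantised to the sample grid; this makes the simulator a
legitimate oracle for the sub-sample fidelity of the processing chain.  The
transmit trigger defines t = 0 and the excitation starts at t = 0, so ToA
means the delay of the excitation's *start* — the correlation lag axis is
calibrated to the same convention.  Optional ingredients: discrete multipath
echoes (extra delay + relative amplitude per path), frequency-proportional
attenuation in dB/(MHz·cm) (off by default, matching water), per-element
Gaussian ToA jitter, and additive white Gaussian noise, all reproducible
under a seed.  Not modelled: element directivity, lens delays, hydrophone
frequency response, full-wave propagation, and the 1 kHz sequential firing
timeline (traces are independent records; only the frame-rate model uses the
PRF).  Passing tests on this simulator therefore demonstrates correctness of
the *processing*, not robustness to transducer artefacts absent from the
model.

## Pulse compression

Traces are band-pass filtered 1–5 MHz with a 4th-order Butterworth applied
forward–backward.  Zero-phase filtering is required, not cosmetic: a causal
filter would delay every envelope peak by its group delay and bias the ToA.
Compression is the cross-correlation with the transmit template,
s_pc = r ⋆ c, returned on a lag axis aligned so a template delayed by τ
peaks at lag τ.  Envelopes are Hilbert magnitudes.  For white noise the
matched filter raises the envelope-peak SNR by ≈ √(T·B) ≈ 4.5 relative to
the band-passed uncompressed trace; the same path runs for tone bursts with
the burst as template, enabling the excitation-mode comparison.

## ToA reliability gates

Per element, after compression: the baseline noise level σ is the standard
deviation of the compressed envelope at lags below 5 µs.  The window is read
on the full correlation axis (including acausal lags, which carry the same
noise statistics); tracking scenes must keep the earliest arrival beyond the
window (z > 7.4 mm at c = 1.48 for the 5 µs default) or a warning is raised
and σ is contaminated.

Two gates run in fixed order:

1. **Noise gate.**  The printed rule "FWHM < 4σ" compares a time width with
   an amplitude deviation, which is dimensionally inconsistent; the default
   `amplitude_gate` implements the evident intent — reject when the
   half-maximum amplitude A₅₀ = 0.5·peak < 4σ (i.e. peak < 8σ).  A
   `literal_width` mode (half-max width in samples vs σ) exists for
   sensitivity analysis only.
2. **Consistency gate.**  The amplitude-weighted centre of mass of *all*
   samples above A₅₀ — deliberately including secondary lobes — is compared
   with the peak time; a displacement beyond 2 µs flags multipath and the
   trace is rejected as `inconsistent`.

Accepted peaks are refined with a three-point parabolic fit, giving noiseless
sub-sample ToA errors of ~10⁻⁴ µs; ties break to the earliest lag.  Raising
the σ multiplier or lowering the CoM limit can only reject more traces, and
both gates are invariant to overall amplitude scaling.

## Multilateration

Accepted ToAs convert to ranges d_i = c·t_i; the position minimises
Σ(‖p − s_i‖ − d_i)².  Gauss–Newton uses Jacobian rows (p − s_i)ᵀ/‖p − s_i‖
with step halving (≤ 8 halvings) on cost increase, step-norm tolerance
10⁻⁶ mm and a 50-iteration cap; noiseless fixtures converge in < 10
iterations to machine precision.  Initialisation is the closed-form
linearised solution from pairwise-differenced sphere equations.  Because the
transmitters are coplanar (z = 0) that system only constrains (x, y); z is
recovered from the sphere radii and projected into z > 0, which also resolves
the front/back mirror ambiguity — the needle is always in front of the probe
face.  Rank deficiency of the lateral system (collinear transmitters) raises
a degenerate-geometry error; fewer than three accepted ToAs raises an
insufficient-observations error and the frame is reported untrackable.  No
per-element weighting is applied (a hook exists, default uniform).

## Delay-and-sum baseline

The comparison localizer reconstructs a tracking volume: for each voxel v,
intensity(v) = |Σ_i a_i(τ_i(v))| with a_i the *analytic* compressed trace
interpolated linearly at the one-way delay τ_i(v) — a coherent sum with the
envelope taken after summation (an envelope-then-sum variant is available).
Only transmit→receiver delays exist; the hydrophone is a point receiver, so
there is no receive beamforming and no apodization.  The tip estimate is the
intensity-weighted centroid of voxels within −6 dB of the peak.  The default
grid is 0.2 mm isotropic over x, y ∈ [−12, 12] mm, z ∈ [5, 50] mm; the
Monte-Carlo sweep uses a coarser 0.5 mm grid over x, y ∈ [−8, 8],
z ∈ [6, 46] mm to keep the full sweep tractable, which is adequate because
the centroid interpolates well below the voxel size.

## Frame-rate model and SNR protocol

One acquisition frame is N_img imaging transmissions (9 plane waves) plus
one transmission per active tracking element, all at the PRF:
f_acq = PRF/(N_img + N_trk).  At PRF = 1 kHz this gives 45.45 Hz for 13
tracking elements and 3.77 Hz for 256 — the headline speed-up of
sparsification.  SNR is measured as the envelope peak divided by the
standard deviation of the baseline before 8 µs.

## Sparsification sweep: study conditions

Receiver positions follow the accuracy-measurement grid: depths
{10, 20, 30, 40} mm × lateral offsets {0, 2, 4} mm in x and y, three frames
per position (108 frames per condition).  Each frame simulates the full
256-element acquisition once; every nested subset of the plan
[256, 128, 64, 32, 13, 9] is then evaluated on the *same* frame with both
localizers — a paired design that removes most between-trial variance from
the size comparison.

The error model emulates the experimental regime rather than an idealised
simulator, because with additive noise alone the chain is unrealistically
precise (sub-0.1 mm).  Three calibrated components, fixed as package
defaults:

* **Additive noise** scaled so the post-compression envelope SNR is ≈ 15 at
  the median-distance element, the level reported for compressed chirp
  tracking in tissue.  The closed-form calibration uses the template energy
  E and the Rayleigh factor: SNR = √E/(√(2 − π/2)·σ_n·d).
* **Sound-speed mismatch**, σ = 1.25 % per frame between the medium and the
  value assumed by reconstruction — the scale of several degrees of
  uncontrolled water temperature plus registration/stylet-offset systematics
  expressed as a range-scale error.  This component is common to all
  elements, which is why multilateration accuracy is nearly independent of
  element count, as observed experimentally.
* **Per-element ToA jitter**, σ = 0.08 µs (≈ 2 sample periods), for residual
  per-channel timing errors.  This component averages down as 1/√N and is
  what degrades both localizers as the subset shrinks.

Under these conditions the 13-element multilateration mean error is
≈ 0.45 mm — inside the 0.24–2.71 mm span of the reference water-tank
measurements, and deliberately at its clean end since the simulator omits
directivity, aberration and mechanical registration errors.  DAS error grows
monotonically from ≈ 0.3 mm at 256 elements to ≈ 1.9 mm at 9, while
multilateration stays within 2× its full-aperture value; these are the
trend-level properties the evaluation asserts (experimental point values are
not reproducible in silico).

## Numerical choices and limitations

* Tolerances: solver step norm 10⁻⁶ mm; ToA parabolic refinement clamped to
  ±half a sample; envelope/width computations interpolate linearly.
* Degenerate inputs raise typed errors (flat envelopes, collinear arrays,
  empty signals, truncated records) rather than returning silent garbage.
* The end-to-end noiseless chain recovers random positions over
  z ∈ [5, 50] mm to better than c/(2·26 MHz) ≈ 0.03 mm for subsets from 256
  down to 4 elements; this bound is the natural half-sample range
  resolution.
* Known limitations: no time-difference-of-arrival formulation, no
  sound-speed estimation or aberration correction, no trajectory smoothing
  across frames, no element directivity or hydrophone response, and the
  imaging phase (plane-wave compounding) enters only through its
  transmission count in the frame-rate model.
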