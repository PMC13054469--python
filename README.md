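# needletrack

3D ultrasonic needle-tip tracking by time-of-arrival multilateration over a
sparse Fermat-spiral matrix array, with chirp pulse compression and a
delay-and-sum baseline.

## The problem

Needle tips are notoriously hard to see in ultrasound-guided interventions
(nerve blocks, biopsies): specular shafts, steep insertion angles and
out-of-plane geometry all cause tip "dropout".  An active alternative embeds
a point-like fiber-optic hydrophone in the needle and localizes it from the
ultrasound transmissions of the imaging probe itself.  The catch is speed:
if the tip is localized by beamforming a volumetric image from sequential
single-element transmissions, every active element costs one transmit event,
and a 256-element acquisition at a 1 kHz pulse repetition frequency leaves a
frame rate of only a few hertz.

`needletrack` implements the fast alternative.  Each transmitting element i
at known position **s**ᵢ gives a time of arrival tᵢ at the hydrophone, hence
a range dᵢ = c·tᵢ; the tip position **p** is the least-squares intersection
of the spheres,

    min_p Σᵢ ( ‖p − sᵢ‖ − c·tᵢ )² ,

solved by damped Gauss–Newton with Jacobian rows (p − sᵢ)ᵀ/‖p − sᵢ‖.  Three
elements suffice, so the array can be sparsified from the inside out
(keeping the outermost elements, i.e. the full aperture) and the acquisition
rate f_acq = PRF/(N_img + N_trk) climbs from 3.77 Hz (256 tracking
transmissions) to 45.45 Hz (13).  Reliable ToAs come from matched-filter
pulse compression of a 1–5 MHz, 5 µs chirp (amplitude SNR gain ≈ √(T·B) ≈
4.5) followed by two reliability gates: a noise gate on the envelope peak
versus the baseline level, and a multipath gate on the displacement between
the peak and the centre of mass of the supra-half-maximum envelope.

The package contains the complete chain as a library plus CLI: spiral-array
geometry and sparsification plans, transmit-waveform synthesis, a seeded
point-receiver propagation simulator (the stand-in for the hydrophone
hardware), band-pass + pulse compression + envelope detection, gated ToA
estimation, the Gauss–Newton solver, a one-way delay-and-sum volumetric
baseline with centre-of-mass localization, the frame-rate model, SNR
measurement, and a Monte-Carlo sparsification sweep comparing the two
localizers.  See `docs/methods.md` for the model details and the calibrated
error model.

## Worked example

Simulate one 13-element tracking frame for a hydrophone at (2, −1, 25) mm
with noise calibrated to a post-compression SNR of 15, then localize it:

```python
import numpy as np
import needletrack as nt

layout = nt.sparsify(nt.default_layout(), 13)     # 13 outermost elements
spec = nt.ExcitationSpec.chirp()                  # 5 µs, 1–5 MHz, 26 MHz fs
template = nt.waveform(spec)

sigma = nt.noise_sigma_for_snr(15.0, 25.5, template)
scene = nt.AcousticScene((2.0, -1.0, 25.0), noise_sigma=sigma, rng_seed=7)
frame = nt.synthesize_frame(layout, scene, spec, trace_duration=45.0)

est = nt.track_frame(frame, layout, template)
print(np.round(est.position, 3), round(est.residual_rms, 4),
      est.n_used, est.iterations, est.converged)
```

prints

```
[ 1.986 -1.019 25.009] 0.0196 13 2 True
```

i.e. all 13 ToAs passed the gates (`n_used = 13`), the solver converged in
two Gauss–Newton iterations, the range residuals are ~0.02 mm RMS, and the
tip estimate is 0.025 mm from the true position — at this noise level the
error is dominated by ToA peak jitter, not the solver.

The same workflow from the shell:

```sh
needletrack frame-rate --n-tracking 13          # -> 45.45
needletrack simulate --out frame.h5 --duration 60
needletrack track --frame frame.h5 --out pose.json
needletrack sweep --sizes 256,128,64,32,13,9 --seed 1 --out sweep.csv
```

The sweep simulates the depth/offset accuracy grid under the calibrated
error model and reports mean ± std localization error and frame rate per
subset size for both multilateration and the delay-and-sum baseline.

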