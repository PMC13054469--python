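"""Transmit waveforms and the point-receiver propagation simulator."""

import numpy as np
import pytest

import needletrack as nt
from needletrack.compression import envelope, pulse_compress
from needletrack.errors import ExcitationError, SceneError, TruncationError


def zero_crossing_frequencies(sig, fs):
    """Oracle: instantaneous frequency from successive zero-crossing intervals.

    Each pair of consecutive zero crossings spans half a period; returns
    (mid-times, frequency estimates).
    """
    s = np.sign(sig)
    idx = np.where(np.diff(s) != 0)[0]
    # linear interpolation of the crossing instant
    t = (idx - sig[idx] / (sig[idx + 1] - sig[idx])) / fs
    mids = 0.5 * (t[1:] + t[:-1])
    freqs = 0.5 / np.diff(t)
    return mids, freqs


class TestChirp:
    def test_sample_count(self, chirp_spec, template):
        assert len(template) == 130  # 5 µs × 26 MHz
        assert np.max(np.abs(template)) <= 1.0 + 1e-12

    def test_degenerate_sweep_is_pure_tone(self):
        spec = nt.ExcitationSpec.chirp(f_start=3.0, f_stop=3.0, duration=5.0)
        sig = nt.make_chirp(spec)
        _, freqs = zero_crossing_frequencies(sig, spec.sample_rate)
        assert np.allclose(freqs, 3.0, rtol=0.05)

    def test_instantaneous_frequency_sweeps_linearly(self, chirp_spec, template):
        mids, freqs = zero_crossing_frequencies(template, chirp_spec.sample_rate)
        # linear fit of the zero-crossing frequency estimates
        slope, intercept = np.polyfit(mids, freqs, 1)
        assert slope == pytest.approx((5.0 - 1.0) / 5.0, rel=0.05)
        assert intercept == pytest.approx(1.0, abs=0.15)
        assert slope * 5.0 + intercept == pytest.approx(5.0, rel=0.05)

    def test_invalid_specs_raise(self):
        with pytest.raises(ExcitationError):
            nt.ExcitationSpec.chirp(f_start=0.0)
        with pytest.raises(ExcitationError):
            nt.ExcitationSpec.chirp(f_stop=14.0)  # beyond Nyquist
        with pytest.raises(ExcitationError):
            nt.ExcitationSpec.chirp(duration=-1.0)


class TestToneburst:
    def test_half_amplitude_duration(self):
        spec = nt.ExcitationSpec.toneburst()
        sig = nt.make_toneburst(spec)
        env = envelope(sig)
        t = np.arange(len(sig)) / spec.sample_rate
        above = t[env >= 0.5 * env.max()]
        # four cycles of 3 MHz between half-amplitude points: 4/3 µs
        assert above[-1] - above[0] == pytest.approx(4.0 / 3.0, rel=0.08)

    def test_spectral_peak_at_center_frequency(self):
        spec = nt.ExcitationSpec.toneburst()
        sig = nt.make_toneburst(spec)
        freqs = np.fft.rfftfreq(len(sig), 1.0 / spec.sample_rate)
        spect = np.abs(np.fft.rfft(sig))
        assert abs(freqs[np.argmax(spect)] - 3.0) <= freqs[1] - freqs[0]

    def test_many_cycles_concentrate_spectrum(self):
        def rel_bandwidth(n_cycles):
            spec = nt.ExcitationSpec.toneburst(n_cycles=n_cycles)
            sig = nt.make_toneburst(spec)
            freqs = np.fft.rfftfreq(4096, 1.0 / spec.sample_rate)
            spect = np.abs(np.fft.rfft(sig, 4096))
            above = freqs[spect >= 0.5 * spect.max()]
            return above[-1] - above[0]

        assert rel_bandwidth(40) < 0.2 * rel_bandwidth(4)


class TestSynthesizeFrame:
    def test_arrival_delays_match_geometry(self, layout13, chirp_spec, template):
        scene = nt.AcousticScene((0.0, 0.0, 20.0))
        frame = nt.synthesize_frame(layout13, scene, chirp_spec, 40.0)
        radii = np.linalg.norm(layout13.positions[:, :2], axis=1)
        expected = np.sqrt(20.0**2 + radii**2) / 1.48
        for trace, tau in zip(frame.traces, expected):
            ct = pulse_compress(trace, template, chirp_spec.sample_rate)
            assert ct.peak_lag() == pytest.approx(tau, abs=1.0 / (2 * 26.0))

    def test_noiseless_trace_is_scaled_delayed_template(
        self, layout13, chirp_spec, template
    ):
        scene = nt.AcousticScene((0.0, 0.0, 25.0))
        frame = nt.synthesize_frame(layout13, scene, chirp_spec, 40.0)
        tr = frame.traces[0]
        # normalized matched-filter peak ≈ 1 for an undistorted copy
        ct = pulse_compress(tr, template, chirp_spec.sample_rate)
        norm = np.linalg.norm(tr) * np.linalg.norm(template)
        # fractional-delay interpolation of the finite-band chirp costs a few
        # percent of correlation; an undistorted copy stays near 1
        assert np.max(np.abs(ct.samples)) / norm > 0.95

    def test_amplitude_follows_inverse_distance(self, layout, chirp_spec):
        scene = nt.AcousticScene((0.0, 0.0, 15.0))
        lay = nt.sparsify(layout, 9)
        frame = nt.synthesize_frame(lay, scene, chirp_spec, 40.0)
        d = np.linalg.norm(scene.receiver - lay.positions, axis=1)
        # energy scaling is exact under the frequency-domain delay
        rms = np.linalg.norm(frame.traces, axis=1)
        assert np.allclose((rms / rms[0]) * (d / d[0]), 1.0, rtol=1e-6)
        # envelope peaks track 1/r too, within the chirp's Fresnel ripple
        peaks = envelope(frame.traces).max(axis=1)
        assert np.allclose((peaks / peaks[0]) * (d / d[0]), 1.0, rtol=0.06)

    def test_seeded_frames_are_bit_identical(self, layout13, chirp_spec):
        scene = nt.AcousticScene(
            (1.0, -2.0, 30.0), noise_sigma=0.05, toa_jitter_sigma=0.05, rng_seed=77
        )
        f1 = nt.synthesize_frame(layout13, scene, chirp_spec, 45.0)
        f2 = nt.synthesize_frame(layout13, scene, chirp_spec, 45.0)
        assert np.array_equal(f1.traces, f2.traces)

    def test_multipath_adds_second_arrival(self, layout13, chirp_spec, template):
        scene = nt.AcousticScene((0.0, 0.0, 20.0), multipath=((6.0, 0.5),))
        frame = nt.synthesize_frame(layout13, scene, chirp_spec, 45.0)
        ct = pulse_compress(frame.traces[0], template, chirp_spec.sample_rate)
        tau = np.linalg.norm(scene.receiver - layout13.positions[0]) / 1.48
        i_main = np.argmin(np.abs(ct.lag_axis - tau))
        i_echo = np.argmin(np.abs(ct.lag_axis - tau - 6.0))
        assert ct.envelope[i_echo] == pytest.approx(0.5 * ct.envelope[i_main], rel=0.05)

    def test_invalid_scene_and_truncation(self, layout13, chirp_spec):
        with pytest.raises(SceneError):
            nt.AcousticScene((0.0, 0.0, -5.0))
        scene = nt.AcousticScene((0.0, 0.0, 40.0))
        with pytest.raises(TruncationError):
            nt.synthesize_frame(layout13, scene, chirp_spec, 20.0)


class TestFrameIO:
    def test_h5_and_csv_roundtrip(self, tmp_path, layout13, chirp_spec):
        scene = nt.AcousticScene((0.0, 0.0, 20.0), noise_sigma=0.01, rng_seed=3)
        frame = nt.synthesize_frame(layout13, scene, chirp_spec, 40.0)
        h5 = tmp_path / "f.h5"
        frame.save_h5(h5)
        back = nt.RFFrame.load_h5(h5)
        assert np.array_equal(back.traces, frame.traces)
        assert back.sample_rate == frame.sample_rate
        csv = tmp_path / "f.csv"
        frame.save_csv(csv)
        back2 = nt.RFFrame.load_csv(csv)
        assert np.allclose(back2.traces, frame.traces, atol=1e-9)
        assert back2.sample_rate == pytest.approx(frame.sample_rate, rel=1e-6)
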