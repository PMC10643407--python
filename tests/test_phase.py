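"""Envelope recovery, trough detection, phase models, and onset tagging."""

import numpy as np
import pandas as pd
import pytest

from antiphase import phase, stimgen
from antiphase.phase import (AlignmentError, PhaseModelError,
                             build_phase_model, detect_troughs,
                             extract_envelope_random, extract_envelope_steady,
                             phase_model_from_cycles, simulate_silent_phase,
                             tag_call_onsets)
from antiphase.stimgen import MaskerSpec, Waveform, make_carrier_noise

FS = 192_000.0
TWO_PI = 2 * np.pi


def circ_diff(a, b):
    return np.mod(a - b + np.pi, TWO_PI) - np.pi


class TestSteadyEnvelope:
    def test_dominant_spectral_peak_at_modulation_rate(self, masker8):
        wav, _ = masker8
        env = extract_envelope_steady(wav, 8.0)
        core = env.values[phase.EDGE_PAD_SAMPLES:-phase.EDGE_PAD_SAMPLES]
        f = np.fft.rfftfreq(len(core), 1 / env.sample_rate)
        p = np.abs(np.fft.rfft(core))
        assert abs(f[np.argmax(p)] - 8.0) <= 0.2

    def test_envelope_tracks_analytic_modulation(self, masker8):
        wav, cycles = masker8
        env = extract_envelope_steady(wav, 8.0)
        t = env.times
        core = slice(phase.EDGE_PAD_SAMPLES + 500, -phase.EDGE_PAD_SAMPLES - 500)
        analytic = stimgen.am_envelope(t[core], 8.0, 1.0)
        r = np.corrcoef(env.values[core], analytic - analytic.mean())[0, 1]
        assert r > 0.95

    def test_unmodulated_noise_flagged(self):
        w = make_carrier_noise((10, 96), 4.0, FS, seed=9)
        with pytest.warns(UserWarning, match="unmodulated"):
            extract_envelope_steady(w, 8.0)

    def test_highfreq_masker_falls_back_to_alternate_probe_band(self):
        spec = MaskerSpec(carrier_band=(50, 96), sample_rate=FS, duration=3.0,
                          am_schedule=8.0, rng_seed=12)
        wav, _ = spec.render()
        with pytest.warns(UserWarning, match="probe band"):
            env = extract_envelope_steady(wav, 8.0)
        troughs = detect_troughs(env, [8.0])
        assert len(troughs) >= 20  # envelope still recoverable in-band


class TestRandomEnvelopeAlignment:
    def test_self_alignment_within_one_envelope_sample(self, random_masker):
        wav, seq = random_masker
        env, lag = extract_envelope_random(wav, seq)
        assert abs(lag) * env.sample_rate <= 1.0

    def test_constructed_delay_recovered(self, random_masker):
        wav, seq = random_masker
        delay_s = 0.050
        delayed = Waveform(
            np.concatenate([np.zeros(int(delay_s * FS)), wav.samples]), FS
        )
        env, lag = extract_envelope_random(delayed, seq)
        assert abs(lag - delay_s) * env.sample_rate <= 1.0

    def test_alignment_gain_invariant(self, random_masker):
        wav, seq = random_masker
        _, lag1 = extract_envelope_random(wav, seq)
        _, lag2 = extract_envelope_random(Waveform(wav.samples * 7.3, FS), seq)
        assert lag1 == lag2

    def test_unrelated_audio_raises_alignment_error(self, random_masker):
        _, seq = random_masker
        noise = make_carrier_noise((15, 60), 20.0, FS, seed=99)
        with pytest.raises(AlignmentError):
            extract_envelope_random(noise, seq)


class TestTroughDetection:
    def test_ideal_8hz_envelope(self, masker8):
        wav, _ = masker8
        env = extract_envelope_steady(wav, 8.0)
        troughs = detect_troughs(env, [8.0])
        # 10 s at 8 Hz: ~80 cycle boundaries, intervals 125 +/- 2 ms
        assert 72 <= len(troughs) <= 82
        intervals = np.diff(troughs)
        assert np.all(np.abs(intervals - 0.125) < 0.002)

    def test_4hz_cycle_period_is_250ms(self):
        spec = MaskerSpec(carrier_band=(10, 96), sample_rate=FS, duration=5.0,
                          am_schedule=4.0, rng_seed=13)
        wav, _ = spec.render()
        env = extract_envelope_steady(wav, 4.0)
        troughs = detect_troughs(env, [4.0])
        assert np.median(np.diff(troughs)) == pytest.approx(0.250, abs=0.002)

    def test_monotone_ramp_is_degenerate(self):
        env = phase.EnvelopeSignal(np.linspace(-1, 1, 1000), 1000.0)
        with pytest.raises(PhaseModelError):
            detect_troughs(env, [8.0])

    def test_gain_and_dc_invariance(self, masker8):
        wav, _ = masker8
        t1 = detect_troughs(extract_envelope_steady(wav, 8.0), [8.0])
        scaled = Waveform(wav.samples * 3.0 + 0.1, FS)
        t2 = detect_troughs(extract_envelope_steady(scaled, 8.0), [8.0])
        assert np.allclose(t1, t2)


class TestPhaseModel:
    def test_linear_interpolation_between_troughs(self):
        m = build_phase_model([0.0, 0.125, 0.250], cycle_rates=[8.0, 8.0])
        assert m.phase_at(0.0625)[0] == pytest.approx(np.pi)
        assert m.phase_at(0.125 + 0.03125)[0] == pytest.approx(np.pi / 2)

    def test_phase_zero_at_every_trough(self):
        troughs = np.array([0.0, 0.125, 0.251, 0.375])
        m = build_phase_model(troughs, expected_rates=[8.0])
        assert np.allclose(m.phase_at(troughs[:-1]), 0.0)
        assert m.phase_at(troughs[-1])[0] == pytest.approx(0.0)

    def test_timing_error_from_constructed_jitter(self):
        # alternate +/-1 ms trough displacement -> every interval off by 2 ms
        nominal = np.arange(0, 41) * 0.125
        jitter = np.where(np.arange(41) % 2 == 0, 1e-3, -1e-3)
        m = build_phase_model(nominal + jitter, expected_rates=[8.0])
        assert np.median(np.abs(m.timing_error)) == pytest.approx(2e-3, rel=1e-6)

    def test_non_monotone_troughs_rejected(self):
        with pytest.raises(PhaseModelError):
            build_phase_model([0.0, 0.2, 0.1])

    def test_cycle_count_is_troughs_minus_one(self):
        m = build_phase_model(np.arange(5) * 0.125, expected_rates=[8.0])
        assert m.n_cycles == 4
        assert len(m.cycle_rates) == 4
        assert len(m.timing_error) == 4


class TestTagging:
    def test_midcycle_onset_tagged_pi(self):
        m = build_phase_model([0.0, 0.125, 0.250], cycle_rates=[8.0, 8.0])
        ev = pd.DataFrame({"onset_s": [0.0625], "offset_s": [0.065]})
        out = tag_call_onsets(ev, m)
        assert out.loc[0, "onset_phase_rad"] == pytest.approx(np.pi)
        assert out.loc[0, "cycle_rate_hz"] == 8.0
        assert bool(out.loc[0, "tagged"])

    def test_onset_outside_model_untagged(self):
        m = build_phase_model([0.1, 0.225], cycle_rates=[8.0])
        ev = pd.DataFrame({"onset_s": [0.05, 0.15, 0.3], "offset_s": [0.06, 0.16, 0.31]})
        out = tag_call_onsets(ev, m)
        assert list(out["tagged"]) == [False, True, False]
        assert np.isnan(out.loc[0, "onset_phase_rad"])

    def test_full_pipeline_phase_accuracy_at_8hz(self, masker8, phase_model8,
                                                 ideal_model8):
        # events at known true phases; tagging through the audio-recovered
        # model must agree with the analytic model to < 0.1 rad on average
        rng = np.random.default_rng(21)
        onsets = np.sort(rng.uniform(0.3, 9.7, size=500))
        true_phase = ideal_model8.phase_at(onsets)
        tagged_phase = phase_model8.phase_at(onsets)
        err = np.abs(circ_diff(tagged_phase, true_phase))
        assert np.mean(err) < 0.1


class TestSilentModel:
    def test_cosine_conventions(self):
        m = simulate_silent_phase(8.0, 2.0)
        assert m.phase_at(0.0)[0] == pytest.approx(np.pi)
        assert m.phase_at(1 / 16.0)[0] == pytest.approx(0.0)
        assert np.allclose(np.diff(m.trough_times), 0.125)

    def test_uniform_onsets_pass_rayleigh(self):
        from antiphase.circstats import rayleigh_test

        m = simulate_silent_phase(8.0, 60.0)
        rng = np.random.default_rng(3)
        onsets = rng.uniform(0.0, 59.9, size=2000)
        p = rayleigh_test(m.phase_at(onsets)).p_value
        assert p > 0.05


def test_zero_phase_tagging_accuracy_across_rates():
    """Tagged phase vs analytic truth stays below 0.15 rad up to 16 Hz."""
    for rate in (4.0, 8.0, 16.0):
        spec = MaskerSpec(carrier_band=(10, 96), sample_rate=FS,
                          duration=4.0, am_schedule=rate, rng_seed=int(rate))
        wav, cycles = spec.render()
        env = extract_envelope_steady(wav, rate)
        model = phase.phase_model_from_envelope(env, [rate])
        ideal = phase_model_from_cycles(cycles)
        rng = np.random.default_rng(int(rate))
        t = np.sort(rng.uniform(0.5, 3.5, size=300))
        err = np.abs(circ_diff(model.phase_at(t), ideal.phase_at(t)))
        assert np.mean(err) < 0.15, f"rate {rate}"


def test_model_self_consistency(phase_model8):
    """Trough intervals match nominal periods within the reported timing error."""
    intervals = np.diff(phase_model8.trough_times)
    nominal = 1.0 / phase_model8.cycle_rates
    assert np.allclose(intervals - nominal, phase_model8.timing_error)
    assert np.max(np.abs(phase_model8.timing_error)) < 0.01
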