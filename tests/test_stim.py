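"""Schedules, trigger encoding, diode rectification and timestamp decoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

import cnpipe as cp
from cnpipe.errors import ConfigurationError, EncodingError

FS = 30000.0


class TestMakeSchedule:
    def test_default_sound_protocol_is_five_blocks_of_200(self, full_sound_schedule):
        onsets = full_sound_schedule.onsets("sound")
        assert onsets.size == 1000
        blocks = [e.block for e in full_sound_schedule.events]
        assert all(sum(b == k for b in blocks) == 200 for k in range(5))
        # 10 Hz within a block
        assert np.allclose(np.diff(onsets[:200]), 0.1)

    def test_sound_plus_light_leads_by_4_ms(self):
        sched = cp.make_schedule("sound_plus_light", n_blocks=1, pulses_per_block=20)
        sound = sched.onsets("sound")
        light = sched.onsets("light_pulse")
        assert sound.size == light.size == 20
        np.testing.assert_allclose(sound - light, 0.004, atol=1e-12)

    def test_green_continuous_blocks_and_gaps(self):
        sched = cp.make_schedule("green_continuous")
        events = sched.select("light_continuous")
        assert len(events) == 5
        assert all(e.duration == 20.0 for e in events)
        onsets = [e.onset for e in events]
        assert np.allclose(np.diff(onsets), 30.0)  # 20 s on + 10 s interval

    def test_impossible_rate_duration_combination_rejected(self):
        with pytest.raises(ConfigurationError):
            cp.make_schedule("sound_only", rate_hz=10.0, sound_pulse_s=0.06)


class TestEncode:
    def test_square_wave_is_twice_the_stimulus_duration(self):
        sched = cp.make_schedule("sound_only", n_blocks=1, pulses_per_block=1)
        rec = cp.encode_session_signals(sched, FS, np.random.default_rng(0))
        trig = rec["trigger"]
        onset = sched.onsets("sound")[0]
        i0 = int(round(onset * FS))
        n3ms = int(round(0.003 * FS))
        assert np.all(trig[i0 : i0 + n3ms] == 1.0)
        assert np.all(trig[i0 + n3ms : i0 + 2 * n3ms] == -1.0)
        assert np.all(trig[i0 + 2 * n3ms :] == 0.0)

    def test_combined_event_sums_square_amplitudes(self):
        sched = cp.make_schedule("sound_plus_light", n_blocks=1, pulses_per_block=1)
        rec = cp.encode_session_signals(sched, FS, np.random.default_rng(0))
        s = sched.onsets("sound")[0]
        i_overlap = int(round((s + 0.001) * FS))
        assert rec["trigger"][i_overlap] == pytest.approx(5.0 + 1.0)

    def test_empty_schedule_encodes_to_silence(self):
        sched = cp.StimulusSchedule(events=[], session_duration=1.0)
        rec = cp.encode_session_signals(sched, FS, np.random.default_rng(0))
        assert not np.any(rec["sound"]) and not np.any(rec["trigger"])
        assert rec.n_samples == int(FS)

    def test_overlapping_same_modality_squares_rejected(self):
        events = [
            cp.StimulusEvent("sound", 0.1, 0.003),
            cp.StimulusEvent("sound", 0.104, 0.003),  # inside previous square
        ]
        sched = cp.StimulusSchedule(events=events, session_duration=1.0)
        with pytest.raises(EncodingError):
            cp.encode_session_signals(sched, FS, np.random.default_rng(0))

    def test_sound_burst_band_and_level(self):
        sched = cp.make_schedule("sound_only", n_blocks=1, pulses_per_block=5)
        rec = cp.encode_session_signals(sched, 192000.0, np.random.default_rng(0))
        i0 = int(round(sched.onsets("sound")[0] * 192000))
        burst = rec["sound"][i0 : i0 + int(0.003 * 192000)]
        target = cp.rms_for_spl(80.0)
        assert np.sqrt(np.mean(burst**2)) == pytest.approx(target, rel=1e-6)


class TestRectify:
    @pytest.mark.parametrize(
        "value,drop,expected", [(-1.0, 0.0, 0.0), (2.0, 0.0, 2.0), (2.0, 0.6, 1.4)]
    )
    def test_definition(self, value, drop, expected):
        assert cp.rectify_diode(np.array([value]), drop)[0] == expected

    @settings(derandomize=True, max_examples=50)
    @given(arrays(np.float64, 32, elements=st.floats(-10, 10)))
    def test_idempotent_for_ideal_diode(self, x):
        once = cp.rectify_diode(x)
        np.testing.assert_array_equal(cp.rectify_diode(once), once)


class TestDecode:
    def test_round_trip_sound_protocol(self, small_sound_schedule):
        rec = cp.encode_session_signals(small_sound_schedule, FS, np.random.default_rng(1))
        dec = cp.decode_timestamps(cp.rectify_diode(rec["trigger"]), FS)
        truth = small_sound_schedule.onsets("sound")
        got = dec.onsets("sound")
        assert got.size == truth.size
        assert np.max(np.abs(got - truth)) <= 1 / FS
        assert all(e.modality == "sound" for e in dec.events)

    def test_round_trip_combined_recovers_both_modalities(self):
        sched = cp.make_schedule("sound_plus_light", n_blocks=1, pulses_per_block=30)
        rec = cp.encode_session_signals(sched, FS, np.random.default_rng(1))
        dec = cp.decode_timestamps(cp.rectify_diode(rec["trigger"]), FS)
        for mod in ("sound", "light_pulse"):
            truth, got = sched.onsets(mod), dec.onsets(mod)
            assert got.size == truth.size
            assert np.max(np.abs(got - truth)) <= 1 / FS
        # decoded lead is preserved
        np.testing.assert_allclose(
            dec.onsets("sound") - dec.onsets("light_pulse"), 0.004, atol=1 / FS
        )

    def test_all_zero_channel_gives_empty_schedule(self):
        dec = cp.decode_timestamps(np.zeros(1000), FS)
        assert len(dec) == 0

    def test_sub_resolution_pulse_discarded_and_counted(self):
        x = np.zeros(1000)
        x[500] = 2.0  # single-sample glitch
        dec = cp.decode_timestamps(x, FS)
        assert len(dec) == 0
        assert dec.n_discarded == 1

    def test_decoded_count_bounded_by_encoded_plus_warnings(self, small_sound_schedule):
        rec = cp.encode_session_signals(small_sound_schedule, FS, np.random.default_rng(1))
        dec = cp.decode_timestamps(cp.rectify_diode(rec["trigger"]), FS)
        assert len(dec) <= len(small_sound_schedule) + dec.n_discarded


class TestJitter:
    def test_exact_detection_gives_zero(self):
        t = np.arange(100) * 0.1
        assert cp.timestamp_jitter(t, t, 150e-6).fraction == 0.0

    def test_all_shifted_beyond_limit_gives_one(self):
        t = np.arange(100) * 0.1
        assert cp.timestamp_jitter(t + 200e-6, t, 150e-6).fraction == 1.0

    def test_partial_shift_counts_exactly(self):
        t = np.arange(100) * 0.1
        det = t.copy()
        det[:15] += 200e-6
        res = cp.timestamp_jitter(det, t, 150e-6)
        assert res.fraction == 0.15
        assert res.n_matched == 100 and res.n_unmatched == 0

    def test_unmatched_events_excluded_from_fraction(self):
        t = np.arange(10) * 0.1
        det = np.concatenate([t, [5.0]])  # extra spurious detection
        res = cp.timestamp_jitter(det, t, 150e-6)
        assert res.fraction == 0.0
        assert res.n_unmatched == 1
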