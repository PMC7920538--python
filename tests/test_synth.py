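"""Statistical and determinism contracts of the synthetic-session generator."""

import json

import numpy as np
import pytest
from scipy import stats as sp_stats

import cnpipe as cp
from cnpipe.errors import ConfigurationError


def small_config(**overrides):
    defaults = dict(
        units=[
            ("u00", cp.archetype("sound_responder")),
            ("u01", cp.archetype("nonresponder_high")),
        ],
        pulses_per_block=20,
        n_blocks=1,
        include_abr=True,
    )
    return cp.SessionConfig(**(defaults | overrides))


class TestMakeUnitSpiketrain:
    def test_poisson_count_within_99pct_interval(self):
        sched = cp.StimulusSchedule(events=[], session_duration=100.0)
        arch = cp.archetype("nonresponder_low", baseline_rate=2.0)
        st = cp.make_unit_spiketrain(arch, sched, 100.0, np.random.default_rng(0))
        lo, hi = sp_stats.poisson.interval(0.99, 200)
        assert lo <= st.n_spikes <= hi

    def test_sound_responder_peak_in_first_response_bin(self):
        sched = cp.make_schedule("sound_only")
        arch = cp.archetype("sound_responder", response_prob=1.0, response_onset=0.001)
        st = cp.make_unit_spiketrain(arch, sched, sched.session_duration, np.random.default_rng(1))
        psth = cp.build_psth(st, sched.onsets("sound"))
        assert psth.bin_edges[np.argmax(psth.counts)] == pytest.approx(0.0)

    def test_delayed_responder_latency_recovered(self):
        sched = cp.make_schedule("sound_only")
        arch = cp.archetype("delayed_responder")  # 19 ms onset
        st = cp.make_unit_spiketrain(arch, sched, sched.session_duration, np.random.default_rng(2))
        psth = cp.build_psth(st, sched.onsets("sound"))
        assert cp.response_latency(psth) == pytest.approx(19.0, abs=2.0)

    def test_suppressed_responder_thins_post_stimulus_spikes(self):
        sched = cp.make_schedule("sound_only")
        arch = cp.archetype("suppressed_responder")
        st = cp.make_unit_spiketrain(arch, sched, sched.session_duration, np.random.default_rng(3))
        psth = cp.build_psth(st, sched.onsets("sound"))
        assert cp.corrected_spike_count(psth) < 0

    def test_tonic_modulation_scales_rate_during_green_light(self):
        sched = cp.make_schedule("green_continuous")
        arch = cp.archetype("tonic_modulated", baseline_rate=16.4, modulation_gain=2.0)
        st = cp.make_unit_spiketrain(arch, sched, sched.session_duration, np.random.default_rng(4))
        t = st.spike_times
        in_light = np.zeros(t.size, dtype=bool)
        light_total = 0.0
        for ev in sched.select("light_continuous"):
            in_light |= (t >= ev.onset) & (t < ev.onset + ev.duration)
            light_total += ev.duration
        rate_on = in_light.sum() / light_total
        rate_off = (~in_light).sum() / (st.duration - light_total)
        assert rate_on / rate_off == pytest.approx(2.0, rel=0.2)

    def test_invalid_archetype_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            cp.archetype("nonresponder_low", baseline_rate=12.0)
        with pytest.raises(ConfigurationError):
            cp.archetype("sound_responder", response_prob=1.5)
        with pytest.raises(ConfigurationError):
            cp.archetype("no_such_kind")


class TestMakeRawTrace:
    def test_zero_noise_single_spike_reproduces_template(self):
        st = cp.SpikeTrain("u", np.array([0.05]), 0.1)
        tpl = cp.biphasic_template(30000.0, 1.0)
        rec = cp.make_raw_trace([st], tpl, 0.0, 30000.0, np.random.default_rng(0))
        x = rec["u"]
        trough = int(np.argmin(tpl))
        i = int(round(0.05 * 30000)) - trough
        np.testing.assert_allclose(x[i : i + tpl.size], tpl)
        assert np.min(x) == tpl.min()

    def test_no_spikes_gives_pure_noise_of_requested_sd(self):
        st = cp.SpikeTrain("u", np.array([]), 10.0)
        tpl = cp.biphasic_template(30000.0, 1.0)
        rec = cp.make_raw_trace([st], tpl, 2.5e-5, 30000.0, np.random.default_rng(1))
        assert rec["u"].std() == pytest.approx(2.5e-5, rel=0.05)


class TestMakeSession:
    def test_default_schedule_has_1000_sound_events_in_5_blocks(self):
        truth = cp.make_session(cp.SessionConfig(include_analog=False), seed=0)
        sound_only = truth.condition_events["sound"]
        assert sound_only.size == 1000
        sound_events = [e for e in truth.schedule.events if e.modality == "sound"]
        assert sum(e.block == 0 for e in sound_events[:1000]) == 200

    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        cfg = small_config()
        cp.make_session(cfg, 7, tmp_path / "a")
        cp.make_session(cfg, 7, tmp_path / "b")
        for name in ("schedule.csv", "spikes.csv", "truth.json", "analog.bin", "abr.bin"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_existing_output_requires_overwrite_flag(self, tmp_path):
        cfg = small_config(include_analog=False, include_abr=False)
        cp.make_session(cfg, 0, tmp_path / "s")
        with pytest.raises(FileExistsError):
            cp.make_session(cfg, 0, tmp_path / "s")
        cp.make_session(cfg, 0, tmp_path / "s", overwrite=True)

    def test_truth_ledger_lists_every_unit_archetype(self, tmp_path):
        units = [(f"u{k:02d}", cp.archetype("nonresponder_low")) for k in range(10)]
        cfg = small_config(units=units, include_analog=False, include_abr=False)
        truth = cp.make_session(cfg, 3, tmp_path / "s")
        on_disk = json.loads((tmp_path / "s" / "truth.json").read_text())
        assert len(on_disk["archetypes"]) == 10
        assert set(on_disk["archetypes"]) == {u for u, _ in units}
        assert set(truth.spike_times) == set(on_disk["spike_times"])

    def test_adding_a_unit_does_not_perturb_existing_spike_trains(self):
        cfg_a = small_config(include_analog=False, include_abr=False)
        cfg_b = small_config(
            units=cfg_a.units + [("u99", cp.archetype("nonresponder_low"))],
            include_analog=False,
            include_abr=False,
        )
        ta = cp.make_session(cfg_a, 11)
        tb = cp.make_session(cfg_b, 11)
        for uid in ("u00", "u01"):
            np.testing.assert_array_equal(ta.spike_times[uid], tb.spike_times[uid])
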