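"""Synthetic session generator with full ground truth.

Every downstream stage (timestamp decoding, spike detection, PSTH
classification, latency estimation, ABR extraction) is validated against
sessions built here, where the true event times, spike times and ABR wave
latencies are known by construction.  Unit archetypes emulate the firing
statistics seen in cochlear-nucleus recordings: most units fire slowly
(~1.5 Hz) with a minority firing fast (>9 Hz, up to tens of Hz); responders
add a tightly time-locked spike after their stimulus with some per-trial
probability; delayed responders respond ~20 ms late; suppressed units pause
after the stimulus; tonically modulated units scale their rate during
continuous light.

Baseline spiking is homogeneous Poisson; response spikes are additive on top
of the baseline (no interaction), and suppression is implemented as thinning.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from . import io as _io
from .errors import ConfigurationError, InvalidInputError
from .metrics import RATE_SPLIT_HZ
from .spikes import SpikeTrain
from .stim import AnalogRecord, StimulusEvent, StimulusSchedule, encode_session_signals, make_schedule

ArchetypeKind = Literal[
    "sound_responder",
    "light_responder",
    "delayed_responder",
    "suppressed_responder",
    "nonresponder_low",
    "nonresponder_high",
    "tonic_modulated",
]

#: Which stimulus modality each responder archetype locks to.
_RESPONSE_MODALITY = {
    "sound_responder": "sound",
    "delayed_responder": "sound",
    "suppressed_responder": "sound",
    "light_responder": "light_pulse",
}


@dataclass(frozen=True)
class UnitArchetype:
    """Parameters of one synthetic unit's firing model."""

    kind: ArchetypeKind
    baseline_rate: float
    response_prob: float = 0.0
    response_onset: float = 0.002
    response_jitter: float = 0.0005
    modulation_gain: float = 1.0
    pause_s: float = 0.030
    suppression_prob: float = 0.8

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ConfigurationError("baseline_rate must be >= 0")
        if not 0 <= self.response_prob <= 1:
            raise ConfigurationError("response_prob must be in [0, 1]")
        if not 0 <= self.suppression_prob <= 1:
            raise ConfigurationError("suppression_prob must be in [0, 1]")
        if self.response_jitter < 0 or self.pause_s < 0:
            raise ConfigurationError("jitter and pause must be >= 0")
        if self.modulation_gain < 0:
            raise ConfigurationError("modulation_gain must be >= 0")
        if self.kind == "nonresponder_low" and not self.baseline_rate < RATE_SPLIT_HZ:
            raise ConfigurationError("nonresponder_low requires baseline < 9 Hz")
        if self.kind == "nonresponder_high" and not self.baseline_rate > RATE_SPLIT_HZ:
            raise ConfigurationError("nonresponder_high requires baseline > 9 Hz")


def archetype(kind: ArchetypeKind, **overrides) -> UnitArchetype:
    """Named archetype with field-realistic defaults.

    Slow units fire around 1.5 Hz, fast units around 27 Hz; responders add a
    locked spike on 80% of trials, 2 ms after sound onset (19 ms for delayed
    responders, matching the ~20 ms polysynaptic delay regime); tonic
    modulation defaults to a doubling of rate under continuous light.
    """
    defaults: dict[ArchetypeKind, dict] = {
        "sound_responder": dict(baseline_rate=1.5, response_prob=0.8, response_onset=0.002),
        "light_responder": dict(baseline_rate=1.5, response_prob=0.8, response_onset=0.002),
        "delayed_responder": dict(baseline_rate=1.5, response_prob=0.8, response_onset=0.019),
        "suppressed_responder": dict(baseline_rate=20.0, suppression_prob=0.8, pause_s=0.030),
        "nonresponder_low": dict(baseline_rate=1.5),
        "nonresponder_high": dict(baseline_rate=26.8),
        "tonic_modulated": dict(baseline_rate=16.4, modulation_gain=2.0),
    }
    if kind not in defaults:
        raise ConfigurationError(f"unknown archetype kind {kind!r}")
    params = defaults[kind] | overrides
    return UnitArchetype(kind=kind, **params)


def _homogeneous_poisson(rate: float, duration: float, rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def make_unit_spiketrain(
    arch: UnitArchetype,
    schedule: StimulusSchedule,
    duration: float,
    rng: np.random.Generator,
    *,
    unit_id: str = "u0",
) -> SpikeTrain:
    """Simulate one unit's spike train under a stimulus schedule."""
    if duration < schedule.session_duration - 1e-9:
        raise InvalidInputError("duration must cover the schedule")

    spikes = _homogeneous_poisson(arch.baseline_rate, duration, rng)

    if arch.kind == "tonic_modulated" and arch.modulation_gain != 1.0:
        for ev in schedule.select("light_continuous"):
            in_block = (spikes >= ev.onset) & (spikes < ev.onset + ev.duration)
            if arch.modulation_gain < 1.0:
                keep = rng.random(spikes.size) < arch.modulation_gain
                spikes = spikes[~in_block | keep]
            else:
                extra_rate = (arch.modulation_gain - 1.0) * arch.baseline_rate
                extra = ev.onset + _homogeneous_poisson(extra_rate, ev.duration, rng)
                spikes = np.concatenate([spikes, extra])

    if arch.kind == "suppressed_responder":
        for ev in schedule.select("sound"):
            in_pause = (spikes > ev.onset) & (spikes < ev.onset + arch.pause_s)
            drop = in_pause & (rng.random(spikes.size) < arch.suppression_prob)
            spikes = spikes[~drop]

    modality = _RESPONSE_MODALITY.get(arch.kind)
    if modality is not None and arch.response_prob > 0:
        added = []
        for ev in schedule.select(modality):
            if rng.random() < arch.response_prob:
                t = ev.onset + arch.response_onset + rng.normal(0.0, arch.response_jitter)
                if 0.0 <= t <= duration:
                    added.append(t)
        spikes = np.concatenate([spikes, added]) if added else spikes

    return SpikeTrain(unit_id=unit_id, spike_times=np.sort(spikes), duration=duration)


def biphasic_template(
    sample_rate: float,
    peak_amplitude: float,
    *,
    neg_sigma_s: float = 8.0e-5,
    pos_sigma_s: float = 2.0e-4,
    pos_delay_s: float = 3.5e-4,
    pos_fraction: float = 0.35,
    span_s: float = 1.2e-3,
) -> np.ndarray:
    """Negative-dominant biphasic spike waveform (sharp trough, slow rebound)."""
    t = np.arange(-span_s / 2, span_s / 2, 1.0 / sample_rate)
    w = -np.exp(-(t**2) / (2 * neg_sigma_s**2)) + pos_fraction * np.exp(
        -((t - pos_delay_s) ** 2) / (2 * pos_sigma_s**2)
    )
    return peak_amplitude * w / np.max(np.abs(w))


def make_raw_trace(
    spiketrains: Sequence[SpikeTrain],
    template: np.ndarray,
    noise_sd: float,
    sample_rate: float,
    rng: np.random.Generator,
) -> AnalogRecord:
    """Gaussian-noise trace per unit with the spike template added at each
    spike time (trough aligned to the spike time); overlapping templates sum
    linearly."""
    template = np.asarray(template, dtype=float)
    trough = int(np.argmin(template))
    channels = {}
    for st in spiketrains:
        n = int(np.ceil(st.duration * sample_rate))
        x = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
        for t in st.spike_times:
            i = int(round(t * sample_rate)) - trough
            j0, j1 = max(i, 0), min(i + template.size, n)
            if j1 > j0:
                x[j0:j1] += template[j0 - i : j1 - i]
        channels[st.unit_id] = x
    return AnalogRecord(channels=channels, sample_rate=sample_rate)


def make_abr_lfp(
    events: Sequence[float],
    peak_spec: Sequence[tuple[float, float]],
    noise_sd: float,
    sample_rate: float,
    rng: np.random.Generator,
    *,
    duration: float | None = None,
    bump_sigma_s: float = 2.0e-4,
) -> AnalogRecord:
    """LFP with a deterministic ABR-like waveform after each sound onset.

    Each event adds narrow Gaussian bumps (sigma <= 0.3 ms, so they survive
    the 500-1500 Hz band) at the specified ``(latency_ms, amplitude)`` pairs,
    on top of Gaussian background noise.
    """
    events_arr = np.asarray(events, dtype=float)
    if events_arr.size == 0:
        raise InvalidInputError("need at least one sweep (events is empty)")
    for lat_ms, _ in peak_spec:
        if not 0.0 < lat_ms < 12.0:
            raise InvalidInputError("peak latencies must lie in (0, 12) ms")
    if bump_sigma_s > 3e-4:
        raise ConfigurationError("bump sigma must be <= 0.3 ms to survive the ABR band")
    if duration is None:
        duration = float(events_arr.max()) + 0.05
    n = int(np.ceil(duration * sample_rate))
    x = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)

    # one epoch worth of deterministic waveform, added per sweep
    span = int(round(0.015 * sample_rate))
    t_epoch = np.arange(span) / sample_rate - 0.003
    wave = np.zeros(span)
    for lat_ms, amp in peak_spec:
        wave += amp * np.exp(-((t_epoch - lat_ms * 1e-3) ** 2) / (2 * bump_sigma_s**2))
    for ev in events_arr:
        i0 = int(round((ev - 0.003) * sample_rate))
        j0, j1 = max(i0, 0), min(i0 + span, n)
        if j1 > j0:
            x[j0:j1] += wave[j0 - i0 : j1 - i0]
    return AnalogRecord(channels={"lfp": x}, sample_rate=sample_rate)


DEFAULT_ABR_PEAKS: list[tuple[float, float]] = [
    (1.5, 1.0),
    (2.5, 0.8),
    (3.5, 0.9),
    (4.5, 0.6),
    (5.5, 0.5),
]


@dataclass
class SessionConfig:
    """What a synthetic session contains."""

    units: list[tuple[str, UnitArchetype]] = field(
        default_factory=lambda: [
            ("u00", archetype("sound_responder")),
            ("u01", archetype("light_responder")),
            ("u02", archetype("delayed_responder")),
            ("u03", archetype("nonresponder_low")),
            ("u04", archetype("nonresponder_high")),
        ]
    )
    protocols: tuple[str, ...] = ("sound_only", "light_only", "sound_plus_light")
    sample_rate: float = 30000.0
    n_blocks: int | None = None
    pulses_per_block: int = 200
    protocol_gap_s: float = 5.0
    include_analog: bool = True
    include_raw: bool = False
    include_abr: bool = True
    raw_noise_sd_v: float = 10e-6
    raw_snr: float = 8.0
    abr_noise_sd_v: float = 1.0
    abr_peaks: list[tuple[float, float]] = field(default_factory=lambda: list(DEFAULT_ABR_PEAKS))


@dataclass
class SessionTruth:
    """Ground-truth ledger: fully determines the session given the seed."""

    seed: int
    schedule: StimulusSchedule
    condition_events: dict[str, np.ndarray]
    archetypes: dict[str, UnitArchetype]
    spike_times: dict[str, np.ndarray]
    abr_peaks: list[tuple[float, float]]
    duration: float

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "duration_s": self.duration,
            "condition_events": {k: v.tolist() for k, v in self.condition_events.items()},
            "archetypes": {k: asdict(v) for k, v in self.archetypes.items()},
            "spike_times": {k: v.tolist() for k, v in self.spike_times.items()},
            "abr_peaks": [list(p) for p in self.abr_peaks],
        }


def combine_protocols(
    protocols: Sequence[str],
    *,
    gap_s: float = 5.0,
    n_blocks: int | None = None,
    pulses_per_block: int = 200,
) -> tuple[StimulusSchedule, dict[str, np.ndarray]]:
    """Concatenate protocol schedules in time; return the merged schedule and
    the per-condition alignment onsets (sound onsets for sound-bearing
    conditions, light onsets for light-only)."""
    events: list[StimulusEvent] = []
    condition_events: dict[str, np.ndarray] = {}
    offset = 0.0
    for proto in protocols:
        sched = make_schedule(proto, n_blocks=n_blocks, pulses_per_block=pulses_per_block)
        shifted = [
            StimulusEvent(e.modality, e.onset + offset, e.duration, e.block) for e in sched.events
        ]
        events.extend(shifted)
        if proto in ("sound_only", "sound_plus_light"):
            align = "sound"
        elif proto == "light_only":
            align = "light_pulse"
        else:
            align = "light_continuous"
        key = {"sound_only": "sound", "light_only": "light", "sound_plus_light": "sound_light"}.get(
            proto, proto
        )
        condition_events[key] = np.array(
            [e.onset for e in shifted if e.modality == align]
        )
        offset = max(e.onset + 2 * e.duration for e in shifted) + gap_s
    schedule = StimulusSchedule(events=sorted(events, key=lambda e: (e.onset, e.modality)),
                                session_duration=offset)
    return schedule, condition_events


def make_session(
    config: SessionConfig,
    seed: int,
    outdir: str | Path | None = None,
    *,
    overwrite: bool = False,
) -> SessionTruth:
    """Generate a full session; optionally persist it under ``outdir``.

    Independent RNG streams are derived per component (trigger encoding, each
    unit, raw-trace noise, ABR noise) from the master seed, so adding a unit
    does not perturb the others and identical seeds yield byte-identical
    files.
    """
    schedule, condition_events = combine_protocols(
        config.protocols,
        gap_s=config.protocol_gap_s,
        n_blocks=config.n_blocks,
        pulses_per_block=config.pulses_per_block,
    )
    duration = schedule.session_duration

    def stream(*key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([seed, *key]))

    spike_times: dict[str, np.ndarray] = {}
    trains: list[SpikeTrain] = []
    archetypes: dict[str, UnitArchetype] = {}
    for k, (uid, arch) in enumerate(config.units):
        st = make_unit_spiketrain(arch, schedule, duration, stream(1, k), unit_id=uid)
        trains.append(st)
        spike_times[uid] = st.spike_times
        archetypes[uid] = arch

    truth = SessionTruth(
        seed=seed,
        schedule=schedule,
        condition_events=condition_events,
        archetypes=archetypes,
        spike_times=spike_times,
        abr_peaks=list(config.abr_peaks) if config.include_abr else [],
        duration=duration,
    )

    if outdir is None:
        return truth

    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()):
        if not overwrite:
            raise FileExistsError(f"{outdir} exists; pass overwrite=True to replace it")
        shutil.rmtree(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    schedule.save(outdir / "schedule.csv")
    _io.write_spike_tables(trains, outdir / "spikes.csv")
    (outdir / "truth.json").write_text(json.dumps(truth.to_json_dict(), indent=1))

    if config.include_analog:
        analog = encode_session_signals(schedule, config.sample_rate, stream(0))
        _io.write_flat_binary(analog, outdir / "analog")
    if config.include_raw:
        template = biphasic_template(
            config.sample_rate, config.raw_snr * config.raw_noise_sd_v
        )
        raw = make_raw_trace(trains, template, config.raw_noise_sd_v, config.sample_rate, stream(2))
        _io.write_flat_binary(raw, outdir / "raw")
    all_sound = schedule.onsets("sound")
    if config.include_abr and all_sound.size:
        # every sound pulse evokes an ABR, whichever protocol it belongs to
        lfp = make_abr_lfp(
            all_sound,
            config.abr_peaks,
            config.abr_noise_sd_v,
            config.sample_rate,
            stream(3),
            duration=duration,
        )
        _io.write_flat_binary(lfp, outdir / "abr")
    return truth
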