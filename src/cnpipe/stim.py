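"""Stimulus schedules, analog trigger encoding, and timestamp decoding.

A two-channel sound card both drives the stimuli and marks their times:
channel 1 carries the acoustic waveform (band-limited Gaussian noise bursts),
channel 2 carries, per event, a square wave of *twice* the stimulus duration
whose positive half coincides with the stimulus.  A diode in front of the
acquisition board's analog input clips the negative half, so the recorded
trigger pulse has exactly the stimulus duration.  When sound and light are
presented together their square waves are summed on channel 2: the light
plateau (above the laser trigger level) marks the light pulse, and the
amplitude steps inside it mark the embedded sound pulse.

Decoding inverts this scheme from the rectified trigger channel alone, which
is how recorded sessions recover their event times without a separate digital
input (whose timestamps jitter by >150 us on a noticeable fraction of pulses).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig

from . import calibration as _cal
from .errors import ConfigurationError, EncodingError, InvalidInputError

Modality = Literal["sound", "light_pulse", "light_continuous"]

#: Laser trigger level on the summed channel, V.
DEFAULT_LASER_THRESHOLD_V = 3.3
#: Square-wave amplitudes on the trigger channel, V.
DEFAULT_SOUND_SQUARE_V = 1.0
DEFAULT_LIGHT_SQUARE_V = 5.0
#: Threshold crossings closer than this are merged (noise chatter guard).
DEBOUNCE_S = 0.5e-3


@dataclass(frozen=True)
class StimulusEvent:
    modality: Modality
    onset: float
    duration: float
    block: int = 0

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise InvalidInputError("event duration must be > 0")
        if self.onset < 0:
            raise InvalidInputError("event onset must be >= 0")


@dataclass
class StimulusSchedule:
    """Typed event list for one session.

    Onsets must be strictly increasing within each modality and all events
    must fit inside ``session_duration``.
    """

    events: list[StimulusEvent]
    session_duration: float
    sound_band: tuple[float, float] = (5000.0, 15000.0)
    sound_level_db: float = 80.0
    light_amplitude_v: float = DEFAULT_LIGHT_SQUARE_V
    n_discarded: int = 0  # decoder bookkeeping: sub-resolution pulses dropped

    def __post_init__(self) -> None:
        if not self.session_duration > 0:
            raise InvalidInputError("session_duration must be > 0")
        for mod in ("sound", "light_pulse", "light_continuous"):
            onsets = [e.onset for e in self.events if e.modality == mod]
            if any(b <= a for a, b in zip(onsets, onsets[1:])):
                raise InvalidInputError(f"{mod} onsets must be strictly increasing")
        for e in self.events:
            if e.onset + e.duration > self.session_duration + 1e-12:
                raise InvalidInputError("event extends past session_duration")

    def onsets(self, modality: Modality) -> np.ndarray:
        return np.array([e.onset for e in self.events if e.modality == modality])

    def select(self, modality: Modality) -> list[StimulusEvent]:
        return [e for e in self.events if e.modality == modality]

    def __len__(self) -> int:
        return len(self.events)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "modality": [e.modality for e in self.events],
                "onset_s": [e.onset for e in self.events],
                "duration_s": [e.duration for e in self.events],
                "block": [e.block for e in self.events],
            }
        )

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path, session_duration: float | None = None) -> "StimulusSchedule":
        df = pd.read_csv(path)
        events = [
            StimulusEvent(r.modality, float(r.onset_s), float(r.duration_s), int(r.block))
            for r in df.itertuples()
        ]
        if session_duration is None:
            session_duration = max(e.onset + e.duration for e in events) + 1.0
        return cls(events=events, session_duration=session_duration)


@dataclass
class AnalogRecord:
    """Named, equal-length, uniformly sampled voltage channels."""

    channels: dict[str, np.ndarray]
    sample_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if not self.sample_rate > 0:
            raise InvalidInputError("sample_rate must be > 0")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise InvalidInputError("all channels must have equal length")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values()))) if self.channels else 0

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


# ---------------------------------------------------------------------------
# Schedule construction


def _pulse_block_onsets(
    n_blocks: int, pulses_per_block: int, rate_hz: float, block_gap_s: float, start_s: float
) -> tuple[np.ndarray, np.ndarray]:
    period = 1.0 / rate_hz
    onsets, blocks = [], []
    t = start_s
    for b in range(n_blocks):
        onsets.extend(t + np.arange(pulses_per_block) * period)
        blocks.extend([b] * pulses_per_block)
        t += pulses_per_block * period + block_gap_s
    return np.array(onsets), np.array(blocks)


def make_schedule(
    protocol: Literal["sound_only", "light_only", "sound_plus_light", "green_continuous"],
    *,
    n_blocks: int | None = None,
    pulses_per_block: int = 200,
    rate_hz: float = 10.0,
    sound_pulse_s: float = 0.003,
    light_pulse_s: float = 0.010,
    light_lead_s: float = 0.004,
    continuous_block_s: float = 20.0,
    block_gap_s: float = 10.0,
    start_s: float = 0.5,
    sound_level_db: float = 80.0,
    sound_band: tuple[float, float] = (5000.0, 15000.0),
    light_amplitude_v: float = DEFAULT_LIGHT_SQUARE_V,
) -> StimulusSchedule:
    """Build one of the four stimulation protocols.

    Defaults encode the standard session: 3 ms 80 dBSPL noise pulses at 10 Hz
    in five blocks of 200; 10 ms light pulses at 10 Hz (one block of 200 when
    presented alone); combined stimulation leads each sound pulse by 4 ms with
    its light pulse; continuous green light in five 20 s blocks with 10 s
    intervals.
    """
    if rate_hz <= 0:
        raise ConfigurationError("rate_hz must be > 0")
    period = 1.0 / rate_hz
    events: list[StimulusEvent] = []

    if protocol == "sound_only":
        n_blocks = 5 if n_blocks is None else n_blocks
        if 2 * sound_pulse_s > period:
            raise ConfigurationError("sound square wave (2x duration) exceeds the pulse period")
        onsets, blocks = _pulse_block_onsets(n_blocks, pulses_per_block, rate_hz, block_gap_s, start_s)
        events = [StimulusEvent("sound", float(t), sound_pulse_s, int(b)) for t, b in zip(onsets, blocks)]
    elif protocol == "light_only":
        n_blocks = 1 if n_blocks is None else n_blocks
        if 2 * light_pulse_s > period:
            raise ConfigurationError("light square wave (2x duration) exceeds the pulse period")
        onsets, blocks = _pulse_block_onsets(n_blocks, pulses_per_block, rate_hz, block_gap_s, start_s)
        events = [StimulusEvent("light_pulse", float(t), light_pulse_s, int(b)) for t, b in zip(onsets, blocks)]
    elif protocol == "sound_plus_light":
        n_blocks = 5 if n_blocks is None else n_blocks
        if 2 * max(sound_pulse_s, light_pulse_s) > period:
            raise ConfigurationError("square wave (2x duration) exceeds the pulse period")
        if light_lead_s < 0:
            raise ConfigurationError("light_lead_s must be >= 0")
        # light leads sound, so shift the grid right to keep onsets >= start
        onsets, blocks = _pulse_block_onsets(
            n_blocks, pulses_per_block, rate_hz, block_gap_s, start_s + light_lead_s
        )
        for t, b in zip(onsets, blocks):
            events.append(StimulusEvent("light_pulse", float(t - light_lead_s), light_pulse_s, int(b)))
            events.append(StimulusEvent("sound", float(t), sound_pulse_s, int(b)))
    elif protocol == "green_continuous":
        n_blocks = 5 if n_blocks is None else n_blocks
        for b in range(n_blocks):
            events.append(
                StimulusEvent(
                    "light_continuous",
                    start_s + b * (continuous_block_s + block_gap_s),
                    continuous_block_s,
                    b,
                )
            )
    else:
        raise ConfigurationError(f"unknown protocol {protocol!r}")

    events.sort(key=lambda e: (e.onset, e.modality))
    end = max(e.onset + 2 * e.duration for e in events) + start_s
    return StimulusSchedule(
        events=events,
        session_duration=end,
        sound_band=sound_band,
        sound_level_db=sound_level_db,
        light_amplitude_v=light_amplitude_v,
    )


# ---------------------------------------------------------------------------
# Encoding


def band_limited_noise(
    n_samples: int,
    sample_rate: float,
    band: tuple[float, float],
    rms_v: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """White Gaussian noise band-passed (4th-order Butterworth) and scaled to
    a target RMS voltage."""
    lo, hi = band
    if sample_rate < 2 * hi:
        raise ConfigurationError("sample_rate must be >= 2x the upper band edge")
    # a band edge at Nyquist is unrealisable; clip to the anti-aliased band
    hi_eff = min(hi, 0.45 * sample_rate)
    sos = _sig.butter(4, [lo, hi_eff], btype="bandpass", fs=sample_rate, output="sos")
    # pad so the filter transient does not truncate short bursts
    pad = int(0.01 * sample_rate)
    x = rng.standard_normal(n_samples + 2 * pad)
    y = _sig.sosfiltfilt(sos, x)[pad : pad + n_samples]
    cur = np.sqrt(np.mean(y**2))
    return y * (rms_v / cur) if cur > 0 else y


def encode_session_signals(
    schedule: StimulusSchedule,
    sample_rate: float,
    rng: np.random.Generator | None = None,
    *,
    sound_square_v: float = DEFAULT_SOUND_SQUARE_V,
    light_square_v: float | None = None,
    sound_rms_v: float | None = None,
) -> AnalogRecord:
    """Render a schedule as the two-channel analog signal.

    Channel ``sound`` carries band-limited noise bursts; channel ``trigger``
    carries, per event, a square wave of twice the event duration (positive
    half during the event, negative half after), with coincident sound and
    light square waves summed.  Continuous-light blocks use the same
    double-length square convention.
    """
    if rng is None:
        rng = np.random.default_rng()
    if light_square_v is None:
        light_square_v = schedule.light_amplitude_v
    lo, hi = schedule.sound_band
    has_sound = any(e.modality == "sound" for e in schedule.events)
    if has_sound and sample_rate < 2 * hi:
        raise ConfigurationError("sample_rate must be >= 2x the sound band's upper edge")
    if sound_rms_v is None:
        sound_rms_v = _cal.rms_for_spl(schedule.sound_level_db)

    n = int(np.ceil(schedule.session_duration * sample_rate))
    ch_sound = np.zeros(n)
    ch_trig = np.zeros(n)

    amp = {"sound": sound_square_v, "light_pulse": light_square_v, "light_continuous": light_square_v}
    last_square_end = {m: -np.inf for m in amp}
    ordered = sorted(schedule.events, key=lambda e: e.onset)
    next_same = {}
    seen: dict[str, float] = {}
    for ev in reversed(ordered):
        next_same[id(ev)] = seen.get(ev.modality, np.inf)
        seen[ev.modality] = ev.onset

    for ev in ordered:
        square_end = ev.onset + 2 * ev.duration
        if ev.modality == "light_continuous":
            # long blocks: the negative half is clipped at the next block so
            # 20 s on / 10 s off schedules remain encodable
            square_end = min(square_end, next_same[id(ev)])
        i0 = int(round(ev.onset * sample_rate))
        i1 = int(round((ev.onset + ev.duration) * sample_rate))
        i2 = int(round(square_end * sample_rate))
        if ev.onset < last_square_end[ev.modality]:
            raise EncodingError(
                f"overlapping {ev.modality} square waves at t={ev.onset:.4f} s"
            )
        last_square_end[ev.modality] = square_end
        if i2 > n:
            raise EncodingError("square wave extends past the session buffer")
        a = amp[ev.modality]
        ch_trig[i0:i1] += a
        ch_trig[i1:i2] -= a
        if ev.modality == "sound":
            ch_sound[i0:i1] += band_limited_noise(
                i1 - i0, sample_rate, schedule.sound_band, sound_rms_v, rng
            )
    return AnalogRecord(channels={"sound": ch_sound, "trigger": ch_trig}, sample_rate=sample_rate)


def rectify_diode(channel: np.ndarray, forward_drop: float = 0.0) -> np.ndarray:
    """Ideal(ish) diode: ``max(0, x - forward_drop)`` elementwise."""
    if forward_drop < 0:
        raise InvalidInputError("forward_drop must be >= 0")
    return np.maximum(0.0, np.asarray(channel, dtype=float) - forward_drop)


# ---------------------------------------------------------------------------
# Decoding


def _segments(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open [start, stop) index pairs."""
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    return list(zip(starts.tolist(), stops.tolist()))


def decode_timestamps(
    rectified: np.ndarray,
    sample_rate: float,
    thresholds: dict[str, float] | None = None,
    *,
    continuous_min_s: float = 1.0,
    block_gap_s: float = 1.0,
) -> StimulusSchedule:
    """Recover a stimulus schedule from the rectified trigger channel.

    Rising crossings of ``thresholds['event']`` open a pulse, falling
    crossings close it.  A plateau exceeding ``thresholds['laser']`` marks a
    light trigger; amplitude steps larger than the event threshold inside one
    supra-laser pulse split it into coincident light and sound events (the
    summed-square-wave case).  Pulses shorter than 2 samples are discarded and
    counted in ``n_discarded``.  Light pulses at least ``continuous_min_s``
    long are labelled ``light_continuous``.
    """
    if thresholds is None:
        thresholds = {}
    ev_thr = thresholds.get("event", DEFAULT_SOUND_SQUARE_V / 2)
    laser_thr = thresholds.get("laser", DEFAULT_LASER_THRESHOLD_V)
    if not ev_thr > 0:
        raise InvalidInputError("event threshold must be > 0")

    x = np.asarray(rectified, dtype=float)
    if x.size == 0 or not np.any(x >= ev_thr):
        return StimulusSchedule(events=[], session_duration=max(x.size, 1) / sample_rate)

    segs = _segments(x >= ev_thr)
    # debounce: merge segments separated by less than DEBOUNCE_S
    merge_gap = int(round(DEBOUNCE_S * sample_rate))
    merged: list[tuple[int, int]] = []
    for s in segs:
        if merged and s[0] - merged[-1][1] < merge_gap:
            merged[-1] = (merged[-1][0], s[1])
        else:
            merged.append(s)

    events: list[StimulusEvent] = []
    n_discarded = 0
    for i0, i1 in merged:
        if i1 - i0 < 2:
            n_discarded += 1
            continue
        onset = i0 / sample_rate
        duration = (i1 - i0) / sample_rate
        if np.max(x[i0:i1]) <= laser_thr:
            events.append(StimulusEvent("sound", onset, duration))
            continue
        modality: Modality = "light_continuous" if duration >= continuous_min_s else "light_pulse"
        events.append(StimulusEvent(modality, onset, duration))
        # split the summed waveform: steps > ev_thr inside the plateau mark
        # the embedded sound pulse's onset (up) and offset (down)
        steps = np.diff(x[i0:i1])
        ups = np.flatnonzero(steps > ev_thr) + 1
        downs = np.flatnonzero(steps < -ev_thr) + 1
        for k, u in enumerate(ups):
            d_after = downs[downs > u]
            stop = int(d_after[0]) if d_after.size else i1 - i0
            if stop - u < 2:
                n_discarded += 1
                continue
            events.append(StimulusEvent("sound", (i0 + u) / sample_rate, (stop - u) / sample_rate))

    events.sort(key=lambda e: (e.onset, e.modality))
    # assign blocks per modality from large inter-onset gaps
    final: list[StimulusEvent] = []
    for mod in ("sound", "light_pulse", "light_continuous"):
        mod_events = [e for e in events if e.modality == mod]
        block = 0
        prev_end = None
        for e in mod_events:
            if prev_end is not None and e.onset - prev_end > block_gap_s:
                block += 1
            final.append(replace(e, block=block))
            prev_end = e.onset + e.duration
    final.sort(key=lambda e: (e.onset, e.modality))
    return StimulusSchedule(
        events=final,
        session_duration=x.size / sample_rate,
        n_discarded=n_discarded,
    )


@dataclass(frozen=True)
class JitterResult:
    """Fraction of matched detections delayed beyond the limit."""

    fraction: float
    n_delayed: int
    n_matched: int
    n_unmatched: int


def timestamp_jitter(
    detected: Sequence[float],
    truth: Sequence[float],
    limit: float,
    *,
    match_window: float | None = None,
) -> JitterResult:
    """Fraction of detected onsets delayed more than ``limit`` past their
    matched true onsets.

    Matching is nearest-neighbour within ``match_window`` (default: half the
    median inter-onset interval of ``truth``).  Unmatched events on either
    side are counted separately and excluded from the fraction.
    """
    det = np.sort(np.asarray(detected, dtype=float))
    tru = np.sort(np.asarray(truth, dtype=float))
    if tru.size == 0:
        return JitterResult(0.0, 0, 0, int(det.size))
    if match_window is None:
        iti = np.median(np.diff(tru)) if tru.size > 1 else np.inf
        match_window = iti / 2

    used = np.zeros(tru.size, dtype=bool)
    delays = []
    n_unmatched = 0
    for d in det:
        j = int(np.argmin(np.abs(tru - d)))
        if abs(tru[j] - d) <= match_window and not used[j]:
            used[j] = True
            delays.append(d - tru[j])
        else:
            n_unmatched += 1
    n_unmatched += int(np.sum(~used))
    if not delays:
        return JitterResult(0.0, 0, 0, n_unmatched)
    delays_arr = np.asarray(delays)
    n_delayed = int(np.sum(delays_arr > limit))
    return JitterResult(n_delayed / len(delays), n_delayed, len(delays), n_unmatched)
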