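"""Auditory brainstem response (ABR) extraction and peak detection.

ABRs are sub-10 ms evoked potentials whose successive waves index stations of
the ascending auditory pathway.  They are recovered here from the same
intracerebral electrode used for unit recording: the local field potential is
band-passed 500-1500 Hz (4th-order Butterworth, zero-phase so wave latencies
are preserved), sliced 3 ms before to 12 ms after each sound pulse, and
averaged across sweeps.  Peaks are the samples that rise one SD above the
epoch mean, exceed the previous sample, and are at least the next sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .errors import ConfigurationError, InvalidInputError
from .stim import AnalogRecord

ABR_BAND_HZ = (500.0, 1500.0)
ABR_EPOCH_S = (-0.003, 0.012)


@dataclass
class AbrPeak:
    latency_ms: float  # relative to sound onset
    amplitude: float


@dataclass
class AbrTrace:
    """Filtered, epoch-averaged event-related waveform."""

    waveform: np.ndarray
    sample_rate: float
    epoch: tuple[float, float] = ABR_EPOCH_S
    n_sweeps: int = 0
    n_skipped: int = 0
    peaks: list[AbrPeak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        expected = int(round((self.epoch[1] - self.epoch[0]) * self.sample_rate))
        if abs(self.waveform.size - expected) > 1:
            raise InvalidInputError(
                f"waveform length {self.waveform.size} inconsistent with epoch "
                f"({expected} samples expected)"
            )

    @property
    def times_ms(self) -> np.ndarray:
        return (self.epoch[0] + np.arange(self.waveform.size) / self.sample_rate) * 1e3

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.times_ms, "voltage": self.waveform})

    def peaks_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peak_index": np.arange(1, len(self.peaks) + 1),
                "latency_ms": [p.latency_ms for p in self.peaks],
                "amplitude": [p.amplitude for p in self.peaks],
            }
        )


def abr_filter_sos(sample_rate: float, band: tuple[float, float] = ABR_BAND_HZ):
    lo, hi = band
    if sample_rate <= 2 * hi:
        raise ConfigurationError(f"sample_rate {sample_rate} Hz too low for {hi} Hz band edge")
    return _sig.butter(4, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")


def extract_abr(
    lfp: np.ndarray | AnalogRecord,
    events: np.ndarray,
    sample_rate: float | None = None,
    *,
    channel: str = "lfp",
    epoch: tuple[float, float] = ABR_EPOCH_S,
    band: tuple[float, float] = ABR_BAND_HZ,
    detect_peaks: bool = True,
) -> AbrTrace:
    """Filter, epoch and average an LFP channel around sound onsets.

    Events whose epoch falls outside the recording are skipped and counted in
    ``n_skipped``.
    """
    if isinstance(lfp, AnalogRecord):
        sample_rate = lfp.sample_rate
        trace = lfp[channel]
    else:
        if sample_rate is None:
            raise InvalidInputError("sample_rate required for raw-array input")
        trace = np.asarray(lfp, dtype=float)
    events = np.asarray(events, dtype=float)
    if events.size == 0:
        raise InvalidInputError("need at least one event")

    sos = abr_filter_sos(sample_rate, band)
    xf = _sig.sosfiltfilt(sos, trace)

    n0 = int(round(epoch[0] * sample_rate))
    n_epoch = int(round((epoch[1] - epoch[0]) * sample_rate))
    acc = np.zeros(n_epoch)
    n_used = 0
    n_skipped = 0
    for ev in events:
        i0 = int(round(ev * sample_rate)) + n0
        i1 = i0 + n_epoch
        if i0 < 0 or i1 > xf.size:
            n_skipped += 1
            continue
        acc += xf[i0:i1]
        n_used += 1
    if n_used == 0:
        raise InvalidInputError("no event epoch fits inside the recording")
    trace_out = AbrTrace(
        waveform=acc / n_used,
        sample_rate=sample_rate,
        epoch=epoch,
        n_sweeps=n_used,
        n_skipped=n_skipped,
    )
    if detect_peaks:
        trace_out.peaks = detect_abr_peaks(trace_out)
    return trace_out


def detect_abr_peaks(trace: AbrTrace) -> list[AbrPeak]:
    """Rule-based peak picking on the averaged waveform.

    Sample ``i`` is a peak iff ``w[i] > mean(w) + SD(w)``, ``w[i] > w[i-1]``
    and ``w[i] >= w[i+1]`` (a plateau's first sample wins).  The mean and SD
    are taken over the whole epoch; endpoints cannot be peaks.
    """
    w = trace.waveform
    if w.size == 0:
        raise InvalidInputError("waveform is empty")
    if w.size < 3:
        return []
    level = w.mean() + w.std()
    times = trace.times_ms
    peaks = [
        AbrPeak(latency_ms=float(times[i]), amplitude=float(w[i]))
        for i in range(1, w.size - 1)
        if w[i] > level and w[i] > w[i - 1] and w[i] >= w[i + 1]
    ]
    return peaks


def summarize_peaks(traces: dict[str, AbrTrace], n_peaks: int = 5) -> pd.DataFrame:
    """Group summary of the first ``n_peaks`` peaks per stimulation condition."""
    rows = []
    for condition, tr in traces.items():
        for k, p in enumerate(tr.peaks[:n_peaks], start=1):
            rows.append(
                {
                    "condition": condition,
                    "peak_index": k,
                    "latency_ms": p.latency_ms,
                    "amplitude": p.amplitude,
                }
            )
    return pd.DataFrame(rows, columns=["condition", "peak_index", "latency_ms", "amplitude"])
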