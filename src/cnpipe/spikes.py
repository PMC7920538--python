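"""Threshold-based spike detection on wide-band extracellular traces.

Detection is deliberately minimal: band-pass, robust noise estimate,
negative-peak threshold, snippet extraction.  Sorting detected events into
single units (clustering) is left to dedicated sorters; the pipeline's
synthetic sessions carry one unit per trace so detection alone suffices for
validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .errors import ConfigurationError, InvalidInputError

SPIKE_BAND_HZ = (300.0, 7500.0)
REFRACTORY_S = 1e-3


@dataclass
class SpikeTrain:
    """One unit's spike times within a recording of known duration."""

    unit_id: str
    spike_times: np.ndarray
    duration: float
    depth_dv: float | None = None
    waveforms: np.ndarray | None = None  # (n_events, n_samples)

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, dtype=float)
        if not self.duration > 0:
            raise InvalidInputError("duration must be > 0")
        if np.any(np.diff(t) < 0):
            raise InvalidInputError("spike_times must be sorted")
        if t.size and (t[0] < 0 or t[-1] > self.duration):
            raise InvalidInputError("spike_times must lie within [0, duration]")
        self.spike_times = t

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"unit_id": self.unit_id, "time_s": self.spike_times})


def spike_filter_sos(sample_rate: float, band: tuple[float, float] = SPIKE_BAND_HZ):
    lo, hi = band
    if sample_rate <= 2 * hi:
        raise ConfigurationError(
            f"sample_rate {sample_rate} Hz too low for the {hi} Hz band edge"
        )
    return _sig.butter(4, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")


def robust_noise_sd(filtered: np.ndarray) -> float:
    """Median-based noise SD, median(|x|)/0.6745 — insensitive to spikes."""
    return float(np.median(np.abs(filtered)) / 0.6745)


def detect_spikes(
    trace: np.ndarray,
    sample_rate: float,
    threshold_sd: float = 4.5,
    snippet_ms: float = 2.0,
    *,
    unit_id: str = "u0",
    band: tuple[float, float] = SPIKE_BAND_HZ,
) -> SpikeTrain:
    """Detect negative spikes on a single wide-band channel.

    The trace is band-passed 300-7500 Hz (4th-order Butterworth, zero-phase so
    peak times are unbiased), the noise SD estimated robustly, and events
    taken at local negative peaks below ``-threshold_sd * SD`` with a 1 ms
    refractory separation (the larger peak wins).  Each event yields a
    ``snippet_ms`` waveform centered on the peak; snippets that would overrun
    the trace are zero-padded.
    """
    trace = np.asarray(trace, dtype=float)
    snippet_n = int(round(snippet_ms * 1e-3 * sample_rate))
    if trace.size <= snippet_n:
        raise InvalidInputError("trace shorter than one snippet")
    if not 2.0 <= threshold_sd <= 4.5:
        warnings.warn(
            f"threshold_sd={threshold_sd} outside the usual 2-4.5 SD range",
            stacklevel=2,
        )
    sos = spike_filter_sos(sample_rate, band)
    xf = _sig.sosfiltfilt(sos, trace)
    sd = robust_noise_sd(xf)
    height = threshold_sd * sd
    distance = max(1, int(round(REFRACTORY_S * sample_rate)))
    peaks, _ = _sig.find_peaks(-xf, height=height, distance=distance)

    half = snippet_n // 2
    waves = np.zeros((peaks.size, snippet_n))
    for k, p in enumerate(peaks):
        lo_i = p - half
        hi_i = lo_i + snippet_n
        src_lo, src_hi = max(lo_i, 0), min(hi_i, xf.size)
        waves[k, src_lo - lo_i : src_hi - lo_i] = xf[src_lo:src_hi]

    return SpikeTrain(
        unit_id=unit_id,
        spike_times=peaks / sample_rate,
        duration=trace.size / sample_rate,
        waveforms=waves,
    )
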