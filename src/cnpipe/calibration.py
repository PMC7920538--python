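"""Sound-level calibration: spectral RMS, dBSPL conversion and the
amplification-factor lookup table.

The calibration chain mirrors a free-field speaker calibration: a known
voltage (scaled by an *amplification factor*) drives the speaker, the emitted
sound is recorded through a measurement microphone of known sensitivity
(V/Pa), and the recorded trace is reduced to a sound pressure level.  The
level of a band-limited noise burst is obtained from its power spectral
density rather than the raw trace so that out-of-band rumble does not inflate
the estimate:

    RMS   = sqrt( sum_i PSD_i * BinSize )            [V]
    dBSPL = 20 * log10( (RMS / MicSens) / p_ref )    [dB re 20 uPa]

Note the square root: summed ``PSD_i * BinSize`` is mean-square voltage
(Parseval), so the root is required for the level formula to be dimensionally
a pressure ratio.  Tabulating dBSPL against a logarithmically decreasing
factor ladder then lets the stimulus generator look up the factor that
realises a target level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .errors import InvalidInputError, OutOfRangeError

#: 1/4" free-field measurement microphone sensitivity, V/Pa.
DEFAULT_MIC_SENSITIVITY_V_PA = 0.00423643

#: Reference sound pressure, Pa (0 dBSPL = 20 uPa, the standard SPL reference).
P_REF_PA = 2e-5


@dataclass(frozen=True)
class SpectralEstimate:
    """One-sided power spectral density of a voltage trace.

    Attributes
    ----------
    psd : ndarray
        Power spectral density values, V^2/Hz, all non-negative.
    bin_size : float
        Spectral resolution, Hz.
    """

    psd: np.ndarray
    bin_size: float

    def __post_init__(self) -> None:
        psd = np.asarray(self.psd, dtype=float)
        if psd.ndim != 1 or psd.size == 0:
            raise InvalidInputError("psd must be a non-empty 1-D array")
        if np.any(psd < 0):
            raise InvalidInputError("psd values must be >= 0")
        if not self.bin_size > 0:
            raise InvalidInputError("bin_size must be > 0")
        object.__setattr__(self, "psd", psd)

    @property
    def n_bins(self) -> int:
        return int(self.psd.size)

    def rms(self) -> float:
        """Integrated RMS voltage, sqrt(sum(psd) * bin_size)."""
        return float(np.sqrt(np.sum(self.psd) * self.bin_size))


@dataclass(frozen=True)
class CalibrationConfig:
    """Microphone and table parameters for speaker calibration."""

    mic_sensitivity: float = DEFAULT_MIC_SENSITIVITY_V_PA
    p_ref: float = P_REF_PA
    n_factors: int = 300
    freq_band: tuple[float, float] = (5000.0, 15000.0)

    def __post_init__(self) -> None:
        if not self.mic_sensitivity > 0:
            raise InvalidInputError("mic_sensitivity must be > 0")
        if not self.p_ref > 0:
            raise InvalidInputError("p_ref must be > 0")
        if self.n_factors < 2:
            raise InvalidInputError("n_factors must be >= 2")
        lo, hi = self.freq_band
        if not 0 <= lo < hi:
            raise InvalidInputError("freq_band must satisfy 0 <= low < high")


@dataclass
class CalibrationTable:
    """Amplification factor -> measured dBSPL, factors strictly decreasing."""

    factors: np.ndarray
    spl_db: np.ndarray
    freq_band: tuple[float, float]
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        self.spl_db = np.asarray(self.spl_db, dtype=float)
        if self.factors.size == 0:
            raise InvalidInputError("calibration table must be non-empty")
        if self.factors.size != self.spl_db.size:
            raise InvalidInputError("factors and spl_db must align")
        if np.any(np.diff(self.factors) >= 0):
            raise InvalidInputError("amplification factors must be strictly decreasing")
        if self.valid is None:
            self.valid = np.isfinite(self.spl_db)
        self.valid = np.asarray(self.valid, dtype=bool)

    def __len__(self) -> int:
        return int(self.factors.size)

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.freq_band
        return pd.DataFrame(
            {
                "factor": self.factors,
                "spl_db": self.spl_db,
                "valid": self.valid.astype(int),
                "freq_low_hz": lo,
                "freq_high_hz": hi,
            }
        )

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path) -> "CalibrationTable":
        df = pd.read_csv(path)
        return cls(
            factors=df["factor"].to_numpy(),
            spl_db=df["spl_db"].to_numpy(),
            freq_band=(float(df["freq_low_hz"].iloc[0]), float(df["freq_high_hz"].iloc[0])),
            valid=df["valid"].to_numpy(dtype=bool),
        )


def estimate_psd(
    trace: np.ndarray, sample_rate: float, segment_length: int | None = None
) -> SpectralEstimate:
    """Hann-windowed, non-overlapping-segment (Welch) PSD of a voltage trace.

    ``segment_length`` defaults to the whole trace (a single window); shorter
    segments trade spectral resolution for variance reduction.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise InvalidInputError("signal is empty")
    if segment_length is None:
        segment_length = trace.size
    if not 0 < segment_length <= trace.size:
        raise InvalidInputError("segment_length must be in [1, len(signal)]")
    freqs, psd = _sig.welch(
        trace,
        fs=sample_rate,
        window="hann",
        nperseg=segment_length,
        noverlap=0,
        detrend=False,
        scaling="density",
    )
    return SpectralEstimate(psd=psd, bin_size=float(freqs[1] - freqs[0]))


def spectral_rms(
    trace: np.ndarray, sample_rate: float, segment_length: int | None = None
) -> float:
    """RMS voltage from the integrated PSD; equals time-domain RMS by Parseval
    up to Hann-window leakage (within ~2% for stationary signals)."""
    return estimate_psd(trace, sample_rate, segment_length).rms()


def spl_from_rms(rms: float, config: CalibrationConfig | None = None) -> float:
    """Convert an RMS microphone voltage to dB sound pressure level."""
    if config is None:
        config = CalibrationConfig()
    if not rms > 0:
        raise InvalidInputError("rms must be > 0")
    pressure_pa = rms / config.mic_sensitivity
    return 20.0 * np.log10(pressure_pa / config.p_ref)


def rms_for_spl(target_db: float, config: CalibrationConfig | None = None) -> float:
    """Inverse of :func:`spl_from_rms`: microphone RMS voltage for a level."""
    if config is None:
        config = CalibrationConfig()
    return config.mic_sensitivity * config.p_ref * 10.0 ** (target_db / 20.0)


def default_factors(config: CalibrationConfig, f_max: float = 1.0, f_min: float = 1e-3) -> np.ndarray:
    """Logarithmically decreasing amplification factor ladder."""
    return np.geomspace(f_max, f_min, config.n_factors)


def build_calibration_table(
    speaker_model: Callable[[float], np.ndarray],
    config: CalibrationConfig,
    sample_rate: float,
    factors: Sequence[float] | None = None,
    segment_length: int | None = None,
) -> CalibrationTable:
    """Drive ``speaker_model`` at each amplification factor and tabulate the
    measured dBSPL.

    ``speaker_model(factor)`` must return the recorded microphone trace (V) at
    ``sample_rate``.  Silent or otherwise non-finite rows are flagged invalid
    rather than dropped, so the table always has one row per factor.
    """
    if factors is None:
        factors = default_factors(config)
    factors = np.asarray(factors, dtype=float)
    if factors.size < 2:
        raise InvalidInputError("need at least 2 amplification factors")
    if np.any(np.diff(factors) >= 0):
        raise InvalidInputError("amplification factors must be strictly decreasing")

    spl = np.empty(factors.size)
    for i, f in enumerate(factors):
        recorded = np.asarray(speaker_model(float(f)), dtype=float)
        try:
            rms = spectral_rms(recorded, sample_rate, segment_length)
            spl[i] = spl_from_rms(rms, config) if rms > 0 else np.nan
        except InvalidInputError:
            spl[i] = np.nan
    return CalibrationTable(factors=factors, spl_db=spl, freq_band=config.freq_band)


def lookup_amplification(table: CalibrationTable, target_db: float) -> float:
    """Amplification factor whose measured SPL is nearest ``target_db``.

    Ties between two equally near rows resolve to the larger factor (the
    louder side).  Targets outside the table's measured range raise
    :class:`OutOfRangeError` naming the achievable range.
    """
    spl = table.spl_db[table.valid]
    factors = table.factors[table.valid]
    if spl.size == 0:
        raise InvalidInputError("calibration table has no valid rows")
    lo, hi = float(np.min(spl)), float(np.max(spl))
    if not lo <= target_db <= hi:
        raise OutOfRangeError(
            f"target {target_db:.2f} dBSPL outside achievable range "
            f"[{lo:.2f}, {hi:.2f}] dBSPL"
        )
    dist = np.abs(spl - target_db)
    best = dist == dist.min()
    return float(np.max(factors[best]))
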