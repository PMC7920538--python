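"""Per-unit firing metrics: overall rate and low/high split, modulation
direction between conditions, response latency, and group statistics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as _stats

from .errors import InvalidInputError
from .psth import Psth
from .spikes import SpikeTrain

#: Firing-rate boundary separating slow- from fast-spiking units, Hz.  The
#: observed rate distribution is bimodal with a gap around this value, so the
#: tie direction (strictly greater = high) is immaterial on realistic data.
RATE_SPLIT_HZ = 9.0

RateClass = Literal["low", "high"]
Direction = Literal["up", "down", "none"]


@dataclass
class UnitMetrics:
    unit_id: str
    firing_rate: float
    rate_class: RateClass
    latency_ms: float | None = None
    modulation: dict[str, Direction] | None = None
    depth_dv: float | None = None


def firing_rate_class(spikes: SpikeTrain) -> tuple[float, RateClass]:
    """Spikes per second over the whole recording (stimulation included);
    high iff rate > 9 Hz."""
    if not spikes.duration > 0:
        raise InvalidInputError("recording duration must be > 0")
    rate = spikes.n_spikes / spikes.duration
    return rate, ("high" if rate > RATE_SPLIT_HZ else "low")


def modulation_direction(rate_a: float, rate_b: float, tol: float = 0.0) -> Direction:
    """Direction of the rate change from condition a to condition b."""
    if rate_a < 0 or rate_b < 0:
        raise InvalidInputError("rates must be >= 0")
    if rate_b - rate_a > tol:
        return "up"
    if rate_a - rate_b > tol:
        return "down"
    return "none"


def response_latency(psth: Psth, criterion_sd: float = 3.0) -> float | None:
    """Latency of the first significant post-stimulus PSTH bin, in ms.

    The first response bin whose count exceeds baseline mean plus
    ``criterion_sd`` baseline SDs, with the following bin also above the
    baseline mean (one-bin persistence guard against isolated noise bins),
    names the latency as its bin center.  Returns None when no bin qualifies.
    """
    base = psth.baseline_counts().astype(float)
    resp = psth.response_counts().astype(float)
    if base.size == 0 or resp.size == 0:
        raise InvalidInputError("psth must have baseline and response bins")
    m, s = base.mean(), base.std()
    threshold = m + criterion_sd * s
    centers = psth.bin_centers[psth.response_mask]
    for j in range(resp.size - 1):
        if resp[j] > threshold and resp[j + 1] > m:
            return float(centers[j] * 1e3)
    return None


def group_compare(
    group_a: Sequence[float], group_b: Sequence[float], n_comparisons: int = 1
) -> float:
    """Welch two-sample two-tailed t-test with Bonferroni correction.

    The p-value is multiplied by ``n_comparisons`` and capped at 1.  Fully
    degenerate input (both groups constant and equal) returns 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("each group needs >= 2 values")
    if n_comparisons < 1:
        raise InvalidInputError("n_comparisons must be >= 1")
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    p = _stats.ttest_ind(a, b, equal_var=False).pvalue
    if not np.isfinite(p):
        return 1.0
    return float(min(1.0, p * n_comparisons))
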