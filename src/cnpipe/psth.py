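"""Peristimulus-time histograms and the Poisson-surrogate response test.

A unit's PSTH counts spikes in 2 ms bins within a 100 ms window centered on
each stimulus onset (50 ms before, 50 ms after), summed over trials.  The
pre-stimulus half estimates baseline firing; the test statistic is the
*baseline-corrected spike count*, the mean of the post-stimulus bins minus
the mean of the pre-stimulus bins.

Whether a unit responds to a stimulus is decided against a simulated null:
surrogate PSTHs are drawn with every bin an independent Poisson variate at
rate lambda equal to the observed mean baseline bin count, each surrogate is
reduced to its own corrected count, and

    p = (g + 1) / (N + 1)

where ``g`` counts surrogates whose corrected count strictly exceeds the
observed one and ``N`` is the number of surrogates.  The +1 terms make the
estimate a valid (slightly conservative) Monte-Carlo p-value.  A unit is
classified as responding to a stimulation when p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .spikes import SpikeTrain

DEFAULT_WINDOW = (-0.050, 0.050)
DEFAULT_BIN_WIDTH = 0.002
ALPHA = 0.05

Category = Literal[
    "sound_only", "light_only", "sound_plus_light_only", "sound_and_light", "non_responding"
]


@dataclass
class Psth:
    """Trial-summed binned spike counts around stimulus onsets.

    Bins are half-open ``[left, right)``; the bin starting at t=0 therefore
    belongs to the response (post-stimulus) side.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.bin_edges.size != self.counts.size + 1:
            raise InvalidInputError("need len(bin_edges) == len(counts) + 1")
        if np.any(self.counts < 0):
            raise InvalidInputError("counts must be >= 0")
        if self.n_trials < 1:
            raise InvalidInputError("n_trials must be >= 1")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2

    @property
    def baseline_mask(self) -> np.ndarray:
        """Bins entirely at or before the event (right edge <= 0)."""
        return self.bin_edges[1:] <= 1e-12

    @property
    def response_mask(self) -> np.ndarray:
        """Bins starting at or after the event (left edge >= 0)."""
        return self.bin_edges[:-1] >= -1e-12

    def baseline_counts(self) -> np.ndarray:
        return self.counts[self.baseline_mask]

    def response_counts(self) -> np.ndarray:
        return self.counts[self.response_mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left_s": self.bin_edges[:-1],
                "bin_right_s": self.bin_edges[1:],
                "count": self.counts,
            }
        )


def build_psth(
    spikes: SpikeTrain,
    events: Sequence[float],
    window: tuple[float, float] = DEFAULT_WINDOW,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> Psth:
    """Bin spike times relative to each event onset, summed over events."""
    events_arr = np.asarray(events, dtype=float)
    if events_arr.size == 0:
        raise InvalidInputError("events must be non-empty")
    w0, w1 = window
    if not (w0 < 0 < w1) or abs(w0 + w1) > 1e-12:
        raise InvalidInputError("window must be symmetric about 0")
    n_half = (w1 / bin_width)
    if abs(n_half - round(n_half)) > 1e-9:
        raise InvalidInputError("bin_width must divide each half-window")
    edges = np.round(np.arange(0, 2 * round(n_half) + 1) * bin_width + w0, 12)

    t = spikes.spike_times
    counts = np.zeros(edges.size - 1, dtype=int)
    for ev in events_arr:
        lo = np.searchsorted(t, ev + w0, side="left")
        hi = np.searchsorted(t, ev + w1, side="left")
        if hi > lo:
            rel = t[lo:hi] - ev
            idx = np.floor((rel - w0) / bin_width).astype(int)
            idx = idx[(idx >= 0) & (idx < counts.size)]
            np.add.at(counts, idx, 1)
    return Psth(bin_edges=edges, counts=counts, n_trials=int(events_arr.size))


def corrected_spike_count(psth: Psth) -> float:
    """Mean response-bin count minus mean baseline-bin count."""
    base = psth.baseline_counts()
    resp = psth.response_counts()
    if base.size == 0 or resp.size == 0:
        raise InvalidInputError("psth must have both baseline and response bins")
    return float(resp.mean() - base.mean())


@dataclass(frozen=True)
class NullSimulation:
    """Outcome of the Poisson-surrogate significance test."""

    lambda_baseline: float
    n_sim: int
    g: int
    p: float
    observed: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.g <= self.n_sim:
            raise InvalidInputError("need 0 <= g <= n_sim")
        lo, hi = 1 / (self.n_sim + 1), 1.0
        if not lo - 1e-12 <= self.p <= hi + 1e-12:
            raise InvalidInputError("p outside [1/(N+1), 1]")


def response_p_value(
    psth: Psth,
    n_sim: int | None = None,
    rng: np.random.Generator | None = None,
    *,
    seed: int | None = None,
) -> NullSimulation:
    """Poisson-surrogate p-value for stimulus responsiveness.

    ``n_sim`` defaults to the number of trials in the PSTH.  ``g`` uses a
    strict comparison (surrogate corrected count > observed); ties do not
    count against the unit.
    """
    if n_sim is None:
        n_sim = psth.n_trials
    if n_sim < 1:
        raise InvalidInputError("n_sim must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    base = psth.baseline_counts()
    if base.size == 0:
        raise InvalidInputError("psth has no baseline bins")
    lam = float(base.mean())
    observed = corrected_spike_count(psth)

    n_base = base.size
    n_resp = psth.response_counts().size
    sim = rng.poisson(lam, size=(n_sim, n_base + n_resp))
    sim_corrected = sim[:, n_base:].mean(axis=1) - sim[:, :n_base].mean(axis=1)
    g = int(np.sum(sim_corrected > observed))
    p = (g + 1) / (n_sim + 1)
    return NullSimulation(
        lambda_baseline=lam, n_sim=n_sim, g=g, p=p, observed=observed, seed=seed
    )


@dataclass(frozen=True)
class ResponseClass:
    """Per-condition p-values and the derived response category."""

    p_sound: float | None
    p_light: float | None
    p_sound_light: float | None
    category: Category
    alpha: float = ALPHA


def classify_responses(
    p_sound: float | None = None,
    p_light: float | None = None,
    p_sound_light: float | None = None,
    alpha: float = ALPHA,
) -> ResponseClass:
    """Map condition p-values to a response category.

    sound_and_light requires both pulsed conditions significant; otherwise a
    single significant condition names the category.  Combinations involving
    the combined condition alongside one pulsed condition resolve to the
    pulsed condition's category (the combined condition embeds both stimuli,
    so the pulsed modality is the more specific label); the full p-vector is
    retained on the result.
    """
    if p_sound is None and p_light is None and p_sound_light is None:
        raise InvalidInputError("at least one condition p-value is required")
    sig_s = p_sound is not None and p_sound < alpha
    sig_l = p_light is not None and p_light < alpha
    sig_sl = p_sound_light is not None and p_sound_light < alpha

    if sig_s and sig_l:
        category: Category = "sound_and_light"
    elif sig_s:
        category = "sound_only"
    elif sig_l:
        category = "light_only"
    elif sig_sl:
        category = "sound_plus_light_only"
    else:
        category = "non_responding"
    return ResponseClass(p_sound, p_light, p_sound_light, category, alpha)


def condition_seed(master_seed: int, unit_index: int, condition_index: int) -> int:
    """Counter-based per-(unit, condition) seed, stable under parallelism."""
    ss = np.random.SeedSequence([master_seed, unit_index, condition_index])
    return int(ss.generate_state(1)[0] % (2**31))
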