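#!/usr/bin/env python
"""Decode stimulus timestamps from the recorded trigger channel and measure
their accuracy against the generator's ground truth.

The trigger channel carries double-length square waves (summed for combined
sound+light events); decoding rectifies the channel and recovers onsets from
threshold crossings and amplitude steps.  The delayed fraction at the 150 us
limit quantifies decoding jitter the way digital-input timestamps are judged.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import cnpipe as cp
from cnpipe import io as cp_io

ROOT = Path(__file__).resolve().parents[1]
SESSION = ROOT / "scratch" / "session"
RESULTS = ROOT / "results"


def main() -> None:
    if not (SESSION / "analog.bin").exists():
        raise SystemExit("run analysis/02_simulate_session.py first")
    RESULTS.mkdir(exist_ok=True)

    analog = cp_io.read_flat_binary(SESSION / "analog")
    decoded = cp.decode_timestamps(cp.rectify_diode(analog["trigger"]), analog.sample_rate)
    truth = cp.StimulusSchedule.load(SESSION / "schedule.csv")

    rows = []
    for mod in ("sound", "light_pulse"):
        t, d = truth.onsets(mod), decoded.onsets(mod)
        jit = cp.timestamp_jitter(d, t, limit=150e-6)
        max_err_us = float(np.max(np.abs(np.sort(d) - np.sort(t)))) * 1e6 if d.size == t.size else float("nan")
        rows.append(
            {
                "modality": mod,
                "n_true": t.size,
                "n_decoded": d.size,
                "n_matched": jit.n_matched,
                "n_unmatched": jit.n_unmatched,
                "frac_delayed_over_150us": jit.fraction,
                "max_abs_error_us": max_err_us,
            }
        )
        print(f"{mod}: {d.size}/{t.size} onsets decoded, "
              f"max |error| {max_err_us:.1f} us, "
              f"fraction delayed >150 us: {jit.fraction:.3f}")
    print(f"discarded sub-resolution pulses: {decoded.n_discarded}")

    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "timestamp_validation.csv", index=False)
    print(f"wrote {RESULTS / 'timestamp_validation.csv'}")


if __name__ == "__main__":
    main()
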