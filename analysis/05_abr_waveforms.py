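#!/usr/bin/env python
"""Extract ABR waveforms from the session LFP and detect their peaks.

The LFP is band-passed 500-1500 Hz, sliced -3 to +12 ms around each sound
onset and averaged per stimulation condition (sound alone vs sound+light);
peaks are samples 1 SD above the epoch mean that exceed the previous sample
and at least equal the next.  Recovered latencies are compared with the
injected wave latencies from the generator's truth ledger.
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
    if not (SESSION / "abr.bin").exists():
        raise SystemExit("run analysis/02_simulate_session.py first")
    RESULTS.mkdir(exist_ok=True)

    lfp = cp_io.read_flat_binary(SESSION / "abr")
    truth = json.loads((SESSION / "truth.json").read_text())
    events = {
        "sound": np.array(truth["condition_events"]["sound"]),
        "sound_light": np.array(truth["condition_events"]["sound_light"]),
    }
    injected = [lat for lat, _ in truth["abr_peaks"]]

    traces = {cond: cp.extract_abr(lfp, ev) for cond, ev in events.items()}
    summary = cp.summarize_peaks(traces)
    summary.to_csv(RESULTS / "abr_peaks.csv", index=False)
    pd.concat(
        [t.to_frame().assign(condition=c) for c, t in traces.items()], ignore_index=True
    ).to_csv(RESULTS / "abr_traces.csv", index=False)

    for cond, tr in traces.items():
        lats = [round(p.latency_ms, 2) for p in tr.peaks[:5]]
        print(f"{cond}: {tr.n_sweeps} sweeps, {len(tr.peaks)} peaks, "
              f"first five at {lats} ms (injected {injected})")
    print(f"wrote {RESULTS / 'abr_peaks.csv'} and {RESULTS / 'abr_traces.csv'}")


if __name__ == "__main__":
    main()
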