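#!/usr/bin/env python
"""Build a speaker calibration table and look up the 80 dBSPL setting.

A synthetic linear speaker model stands in for the hardware chain
(amplifier + tweeter + measurement microphone): the recorded voltage is
proportional to the amplification factor.  The table maps 300
logarithmically spaced factors to measured dBSPL via the PSD-integrated RMS,
and the lookup returns the factor realising the stimulation level.
"""

from pathlib import Path

import numpy as np

import cnpipe as cp

RESULTS = Path(__file__).resolve().parents[1] / "results"
FS = 192000.0  # sound-card rate


def speaker_model(base_trace: np.ndarray):
    return lambda factor: factor * base_trace


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rng = np.random.default_rng(0)
    config = cp.CalibrationConfig()

    # a 2 s calibration pulse in the stimulation band, recorded at a level
    # that puts the table's midrange around typical stimulation intensities
    base = cp.stim.band_limited_noise(int(2 * FS), FS, config.freq_band, rms_v=0.02, rng=rng)

    table = cp.build_calibration_table(speaker_model(base), config, FS)
    table.save(RESULTS / "calibration_table.csv")

    factor = cp.lookup_amplification(table, 80.0)
    measured = table.spl_db[np.argmin(np.abs(table.factors - factor))]
    step = np.median(np.abs(np.diff(table.spl_db)))
    print(f"calibration table: {len(table)} factors, "
          f"{table.spl_db.min():.1f}-{table.spl_db.max():.1f} dBSPL, "
          f"median step {step:.3f} dB")
    print(f"80 dBSPL target -> amplification factor {factor:.6g} "
          f"(measured {measured:.2f} dBSPL)")
    print(f"wrote {RESULTS / 'calibration_table.csv'}")


if __name__ == "__main__":
    main()
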