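#!/usr/bin/env python
"""Simulate a full synthetic recording session with ground truth.

The session contains the three pulsed protocols (sound only, light only,
combined sound+light with the 4 ms light lead), encoded trigger/sound
channels, archetype unit spike trains, and an ABR-bearing LFP.  Everything
downstream (scripts 03-05) reads this session from scratch/session.
"""

from pathlib import Path

import cnpipe as cp

ROOT = Path(__file__).resolve().parents[1]
SESSION = ROOT / "scratch" / "session"
SEED = 42


def session_config() -> cp.SessionConfig:
    units = [
        ("u00_sound", cp.archetype("sound_responder")),
        ("u01_sound", cp.archetype("sound_responder", response_prob=0.6)),
        ("u02_light", cp.archetype("light_responder")),
        ("u03_delayed", cp.archetype("delayed_responder")),
        ("u04_suppressed", cp.archetype("suppressed_responder")),
        ("u05_low", cp.archetype("nonresponder_low")),
        ("u06_low", cp.archetype("nonresponder_low", baseline_rate=0.3)),
        ("u07_high", cp.archetype("nonresponder_high")),
        ("u08_high", cp.archetype("nonresponder_high", baseline_rate=12.0)),
        ("u09_low", cp.archetype("nonresponder_low", baseline_rate=4.0)),
    ]
    return cp.SessionConfig(units=units)


def main() -> None:
    truth = cp.make_session(session_config(), SEED, SESSION, overwrite=True)
    n_sound = truth.condition_events["sound"].size
    n_light = truth.condition_events["light"].size
    n_combined = truth.condition_events["sound_light"].size
    print(f"session written to {SESSION}")
    print(f"  duration {truth.duration:.1f} s, {len(truth.schedule)} stimulus events")
    print(f"  trials: {n_sound} sound, {n_light} light, {n_combined} sound+light")
    print(f"  units: {len(truth.archetypes)} "
          f"({sum(1 for a in truth.archetypes.values() if a.response_prob > 0)} responders)")
    print(f"  ABR waves injected at {[lat for lat, _ in truth.abr_peaks]} ms")


if __name__ == "__main__":
    main()
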