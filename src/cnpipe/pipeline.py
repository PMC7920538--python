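"""End-to-end orchestration: simulate/load -> decode -> classify -> metrics
-> ABR -> report.

The pipeline is a pure function of (inputs, config, seed): per-unit,
per-condition surrogate tests are seeded counter-style so reruns are
byte-identical and parallel evaluation order cannot change results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as _io
from .abr import extract_abr, summarize_peaks
from .errors import InvalidInputError
from .metrics import firing_rate_class, modulation_direction, response_latency
from .psth import ALPHA, build_psth, classify_responses, condition_seed, response_p_value
from .spikes import SpikeTrain
from .stim import StimulusSchedule, decode_timestamps, rectify_diode
from .synth import SessionConfig, make_session

log = logging.getLogger("cnpipe")

CONDITIONS = ("sound", "light", "sound_light")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    session_dir: str | Path
    outdir: str | Path
    alpha: float = ALPHA
    threshold_sd: float = 4.5
    n_sim: int | None = None  # None -> number of trials per condition
    latency_criterion_sd: float = 3.0
    seed: int = 0
    decode_from_analog: bool = False
    simulate: SessionConfig | None = None
    overwrite: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise InvalidInputError("alpha must be in (0, 1)")


def split_conditions(schedule: StimulusSchedule, light_lead_max_s: float = 0.012) -> dict[str, np.ndarray]:
    """Partition a schedule's events into alignment onsets per condition.

    Sound events preceded (within ``light_lead_max_s``) by a light pulse are
    combined-condition trials aligned on the sound onset; remaining sound
    events form the sound condition and unpaired light pulses the light
    condition.
    """
    sound = schedule.onsets("sound")
    light = schedule.onsets("light_pulse")
    paired_sound = []
    paired_light = np.zeros(light.size, dtype=bool)
    for i, s in enumerate(sound):
        if light.size:
            j = int(np.argmin(np.abs(light - s)))
            if 0 < s - light[j] <= light_lead_max_s:
                paired_sound.append(i)
                paired_light[j] = True
    paired_mask = np.zeros(sound.size, dtype=bool)
    paired_mask[paired_sound] = True
    out = {
        "sound": sound[~paired_mask],
        "light": light[~paired_light],
        "sound_light": sound[paired_mask],
    }
    return {k: v for k, v in out.items() if v.size}


def _condition_span(onsets: np.ndarray, pad_s: float = 0.5) -> tuple[float, float]:
    return float(onsets.min() - pad_s), float(onsets.max() + pad_s)


def _rate_in_span(spikes: SpikeTrain, span: tuple[float, float]) -> float:
    lo, hi = span
    n = int(np.sum((spikes.spike_times >= lo) & (spikes.spike_times < hi)))
    return n / (hi - lo)


def analyze_units(
    trains: list[SpikeTrain],
    condition_events: dict[str, np.ndarray],
    *,
    alpha: float = ALPHA,
    n_sim: int | None = None,
    latency_criterion_sd: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-unit classification and metrics table."""
    rows = []
    for u_idx, st in enumerate(trains):
        rate, rate_class = firing_rate_class(st)
        p_values: dict[str, float | None] = {c: None for c in CONDITIONS}
        latency = None
        for c_idx, cond in enumerate(CONDITIONS):
            if cond not in condition_events:
                continue
            events = condition_events[cond]
            psth = build_psth(st, events)
            null = response_p_value(
                psth, n_sim=n_sim, seed=condition_seed(seed, u_idx, c_idx)
            )
            p_values[cond] = null.p
            if cond == "sound":
                latency = response_latency(psth, criterion_sd=latency_criterion_sd)
        cls = classify_responses(
            p_sound=p_values["sound"],
            p_light=p_values["light"],
            p_sound_light=p_values["sound_light"],
            alpha=alpha,
        )
        modulation = None
        if "sound" in condition_events and "sound_light" in condition_events:
            r_a = _rate_in_span(st, _condition_span(condition_events["sound"]))
            r_b = _rate_in_span(st, _condition_span(condition_events["sound_light"]))
            modulation = modulation_direction(r_a, r_b)
        rows.append(
            {
                "unit_id": st.unit_id,
                "depth_dv_mm": st.depth_dv,
                "firing_rate_hz": rate,
                "rate_class": rate_class,
                "category": cls.category,
                "responding": cls.category != "non_responding",
                "p_sound": p_values["sound"],
                "p_light": p_values["light"],
                "p_sound_light": p_values["sound_light"],
                "latency_ms": latency,
                "modulation": modulation,
            }
        )
    columns = [
        "unit_id", "depth_dv_mm", "firing_rate_hz", "rate_class", "category",
        "responding", "p_sound", "p_light", "p_sound_light", "latency_ms", "modulation",
    ]
    return pd.DataFrame(rows, columns=columns)


def summarize_units(unit_table: pd.DataFrame) -> pd.DataFrame:
    """Counts by responding status x rate class x modulation direction."""
    rows = []
    for responding in (True, False):
        sub = unit_table[unit_table["responding"] == responding]
        for rate_class in ("low", "high"):
            sub2 = sub[sub["rate_class"] == rate_class]
            rows.append(
                {
                    "responding": responding,
                    "rate_class": rate_class,
                    "n_units": len(sub2),
                    "n_down": int((sub2["modulation"] == "down").sum()),
                    "n_up": int((sub2["modulation"] == "up").sum()),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["n_total"] = len(unit_table)
    return out


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write report artifacts; returns output paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    artifacts: dict[str, Path] = {"log": outdir / "run.log"}
    stage = "setup"
    try:
        log.info("cnpipe %s run: seed=%d alpha=%g threshold_sd=%g n_sim=%s",
                 __version__, config.seed, config.alpha, config.threshold_sd, config.n_sim)
        session_dir = Path(config.session_dir)

        if config.simulate is not None:
            stage = "simulate"
            log.info("simulating session into %s (seed=%d)", session_dir, config.seed)
            make_session(config.simulate, config.seed, session_dir, overwrite=config.overwrite)

        stage = "load"
        schedule = StimulusSchedule.load(session_dir / "schedule.csv")
        duration = _io.session_duration(session_dir, schedule.session_duration)

        if config.decode_from_analog:
            stage = "decode"
            analog = _io.read_flat_binary(session_dir / "analog")
            decoded = decode_timestamps(rectify_diode(analog["trigger"]), analog.sample_rate)
            log.info("decoded %d events (%d discarded)", len(decoded), decoded.n_discarded)
            condition_events = split_conditions(decoded)
        else:
            condition_events = split_conditions(schedule)
        log.info("conditions: %s", {k: v.size for k, v in condition_events.items()})

        stage = "spikes"
        trains = _io.read_spike_tables(session_dir / "spikes.csv", duration)
        if not trains:
            log.warning("empty spike table: report will contain 0 units")

        stage = "classify"
        unit_table = analyze_units(
            trains,
            condition_events,
            alpha=config.alpha,
            n_sim=config.n_sim,
            latency_criterion_sd=config.latency_criterion_sd,
            seed=config.seed,
        )
        unit_table.to_csv(outdir / "unit_table.csv", index=False)
        artifacts["unit_table"] = outdir / "unit_table.csv"

        stage = "summary"
        summary = summarize_units(unit_table)
        summary.to_csv(outdir / "summary.csv", index=False)
        artifacts["summary"] = outdir / "summary.csv"
        log.info("units: %d total, %d responding", len(unit_table), int(unit_table["responding"].sum()))

        stage = "abr"
        abr_bin = session_dir / "abr.bin"
        if abr_bin.exists():
            lfp = _io.read_flat_binary(session_dir / "abr")
            traces = {}
            for cond in ("sound", "sound_light"):
                if cond in condition_events:
                    traces[cond] = extract_abr(lfp, condition_events[cond])
            if traces:
                pd.concat(
                    [t.to_frame().assign(condition=c) for c, t in traces.items()],
                    ignore_index=True,
                ).to_csv(outdir / "abr_traces.csv", index=False)
                summarize_peaks(traces).to_csv(outdir / "abr_peaks.csv", index=False)
                artifacts["abr_traces"] = outdir / "abr_traces.csv"
                artifacts["abr_peaks"] = outdir / "abr_peaks.csv"
                for c, t in traces.items():
                    log.info("ABR[%s]: %d sweeps, %d peaks", c, t.n_sweeps, len(t.peaks))

        stage = "report"
        report = {
            "version": __version__,
            "seed": config.seed,
            "alpha": config.alpha,
            "n_sim": config.n_sim,
            "threshold_sd": config.threshold_sd,
            "n_units": int(len(unit_table)),
            "n_responding": int(unit_table["responding"].sum()),
            "artifacts": {k: str(v) for k, v in artifacts.items()},
        }
        (outdir / "report.json").write_text(json.dumps(report, indent=1))
        artifacts["report"] = outdir / "report.json"
        log.info("done")
        return artifacts
    except Exception:
        log.exception("pipeline failed at stage %r", stage)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
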