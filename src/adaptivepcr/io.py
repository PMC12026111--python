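"""CSV/JSON carriers for traces, amplification curves and run records,
plus the seeded fixture generator that makes every module testable without
any recorded instrument data."""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .adaptive_control import FluorescenceTrace
from .qpcr_analysis import AmplificationCurve

__all__ = [
    "read_trace",
    "write_trace",
    "read_amplification",
    "write_amplification",
    "write_run_record",
    "generate_fixture",
    "TraceFormatError",
    "CHANNELS",
]

CHANNELS = ("green", "yellow", "orange", "red")


class TraceFormatError(ValueError):
    """Malformed trace file; message names the offending row."""


def read_trace(path: str | Path) -> dict[str, FluorescenceTrace]:
    """Read a trace CSV (``time_s, channel, value``) into per-channel traces.

    Rows must be time-sorted within each channel; unknown channels are
    rejected.  Errors name the offending data row (1-based, excluding the
    header).
    """
    try:
        df = pd.read_csv(path, dtype={"channel": str})
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise TraceFormatError(f"{path}: cannot parse trace CSV: {exc}") from exc
    required = {"time_s", "channel", "value"}
    if not required.issubset(df.columns):
        raise TraceFormatError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    if df.empty:
        raise TraceFormatError(f"{path}: trace file contains no rows")
    for col in ("time_s", "value"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            row = int(converted.isna().idxmax()) + 1
            raise TraceFormatError(f"{path}: non-numeric {col!r} at data row {row}")
        df[col] = converted
    unknown = ~df["channel"].isin(CHANNELS)
    if unknown.any():
        row = int(unknown.idxmax()) + 1
        raise TraceFormatError(
            f"{path}: unknown channel {df['channel'][row - 1]!r} at data row {row}"
        )
    traces = {}
    for ch, grp in df.groupby("channel", sort=False):
        t = grp["time_s"].to_numpy()
        if t.size >= 2:
            diffs = np.diff(t)
            if np.any(diffs <= 0):
                bad_pos = int(np.argmax(diffs <= 0))
                row = int(grp.index[bad_pos + 1]) + 1
                raise TraceFormatError(
                    f"{path}: out-of-order timestamp for channel {ch!r} at data row {row}"
                )
        traces[str(ch)] = FluorescenceTrace(t, grp["value"].to_numpy(), channel=str(ch))
    return traces


def write_trace(traces: dict[str, FluorescenceTrace], path: str | Path) -> Path:
    """Write per-channel traces to a single ``time_s, channel, value`` CSV."""
    path = Path(path)
    frames = [
        pd.DataFrame({"time_s": tr.times, "channel": ch, "value": tr.values})
        for ch, tr in traces.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_amplification(path: str | Path) -> AmplificationCurve:
    """Read an amplification-curve CSV (``cycle, fluorescence[, timestamp_s]``)."""
    df = pd.read_csv(path)
    if not {"cycle", "fluorescence"}.issubset(df.columns):
        raise TraceFormatError(f"{path}: needs columns cycle, fluorescence")
    ts = df["timestamp_s"].to_numpy() if "timestamp_s" in df.columns else None
    return AmplificationCurve(
        cycles=df["cycle"].to_numpy(), fluorescence=df["fluorescence"].to_numpy(), timestamps=ts
    )


def write_amplification(curve: AmplificationCurve, path: str | Path) -> Path:
    path = Path(path)
    data = {"cycle": curve.cycles, "fluorescence": curve.fluorescence}
    if curve.timestamps is not None:
        data["timestamp_s"] = curve.timestamps
    pd.DataFrame(data).to_csv(path, index=False)
    return path


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_run_record(run, out_dir: str | Path, stem: str = "run") -> dict[str, Path]:
    """Serialize a run record: JSON (config, cycles, switches, seed) + trace CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "seed": run.seed,
        "config": _jsonable(run.config),
        "cycle_records": _jsonable(run.cycle_records),
        "switch_points": _jsonable(run.switch_points),
        "control_errors": list(run.control_errors),
    }
    json_path = out_dir / f"{stem}.json"
    json_path.write_text(json.dumps(meta, indent=2))
    paths = {"json": json_path}
    paths["traces"] = write_trace(run.traces, out_dir / f"{stem}_traces.csv")
    if run.amplification is not None:
        paths["amplification"] = write_amplification(
            run.amplification, out_dir / f"{stem}_amplification.csv"
        )
    return paths


# ---------------------------------------------------------------------------
# fixture generation

#: Serial-dilution design: 7 decades, 4 replicates each, plus NTCs.
DILUTION_CONCENTRATIONS = tuple(10.0**k for k in range(5, -2, -1))


def generate_fixture(kind: str, seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write a deterministic synthetic data set plus a ground-truth sidecar.

    Kinds
    -----
    ``melt_trace``
        One heating + cooling sensor-fluorescence trace pair (analytic
        logistic transitions under the default thermal model) with the true
        transition midpoints in the sidecar.
    ``amplification_curve``
        One positive curve and one NTC from the fast-path simulator.
    ``dilution_series``
        10^5..10^-1 copies/µL × 4 replicates + 3 NTCs, with a manifest CSV.
    ``gain_curves``
        A control and an attenuated sample gain-response curve with a known
        blocking fraction.

    Every file is a pure function of ``(kind, seed)``.
    """
    from .instrument_sim import (
        SimulationConfig,
        simulate_amplification,
        simulate_dilution_series,
        thermal_step,
        sensor_fluorescence,
    )
    from .adaptive_control import HEATING, COOLING

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    truth: dict = {"kind": kind, "seed": seed}

    if kind == "melt_trace":
        cfg = SimulationConfig(seed=seed, noise_sd=0.3)
        rng = np.random.default_rng(seed)
        temp = cfg.thermal.t_min
        dt = 1.0 / cfg.sampling_hz
        rows = {ch: [] for ch in CHANNELS}
        times = []
        t = 0.0
        # one full heat ramp to t_max, then cool back to t_min
        heat_s = (cfg.thermal.t_max - cfg.thermal.t_min) / cfg.thermal.heat_rate + 2.0
        phase_plan = [(HEATING, heat_s), (COOLING, heat_s * 1.3)]
        melt_cross = anneal_cross = None
        for phase, dur in phase_plan:
            n = int(round(dur / dt))
            for _ in range(n):
                prev = temp
                temp = thermal_step(temp, phase, dt, cfg.thermal)
                t += dt
                if phase == HEATING and prev < cfg.melt_sensor.tm_celsius <= temp:
                    melt_cross = t
                if phase == COOLING and prev > cfg.anneal_sensor.tm_celsius >= temp:
                    anneal_cross = t
                r = sensor_fluorescence(temp, cfg, rng=rng)
                times.append(t)
                for ch in rows:
                    rows[ch].append(r[ch])
        traces = {
            ch: FluorescenceTrace(np.array(times), np.array(v), channel=ch)
            for ch, v in rows.items()
        }
        paths["trace"] = write_trace(traces, out_dir / "melt_trace.csv")
        truth.update(
            {
                "melt_tm_celsius": cfg.melt_sensor.tm_celsius,
                "anneal_tm_celsius": cfg.anneal_sensor.tm_celsius,
                "melt_crossing_time_s": melt_cross,
                "anneal_crossing_time_s": anneal_cross,
                "noise_sd": cfg.noise_sd,
                "sampling_hz": cfg.sampling_hz,
            }
        )

    elif kind == "amplification_curve":
        cfg = SimulationConfig(seed=seed)
        pos = simulate_amplification(cfg)
        ntc_cfg = replace(
            cfg,
            chemistry=replace(cfg.chemistry, initial_copies=0.0),
            seed=seed + 1,
        )
        ntc = simulate_amplification(ntc_cfg)
        paths["positive"] = write_amplification(pos, out_dir / "amplification_positive.csv")
        paths["ntc"] = write_amplification(ntc, out_dir / "amplification_ntc.csv")
        truth.update(
            {
                "efficiency": cfg.chemistry.efficiency,
                "initial_copies": cfg.chemistry.initial_copies,
                "probe_gain": cfg.chemistry.probe_gain,
                "green_baseline": cfg.green_baseline,
                "noise_sd": cfg.noise_sd,
            }
        )

    elif kind == "dilution_series":
        base = SimulationConfig(seed=seed)
        runs = simulate_dilution_series(
            DILUTION_CONCENTRATIONS, n_replicates=4, n_ntc=3, base_config=base, seed=seed
        )
        manifest = []
        for i, (conc, curve) in enumerate(runs):
            role = "sample" if conc is not None else "NTC"
            name = f"sample_{i:02d}.csv"
            write_amplification(curve, out_dir / name)
            manifest.append(
                {
                    "sample_id": f"s{i:02d}",
                    "concentration_per_ul": conc if conc is not None else "",
                    "role": role,
                    "file": name,
                }
            )
        mpath = out_dir / "manifest.csv"
        pd.DataFrame(manifest).to_csv(mpath, index=False)
        paths["manifest"] = mpath
        truth.update(
            {
                "concentrations_per_ul": list(DILUTION_CONCENTRATIONS),
                "n_replicates": 4,
                "n_ntc": 3,
                "efficiency": base.chemistry.efficiency,
                "expected_dcq_per_decade": math.log(10) / math.log(base.chemistry.efficiency),
            }
        )

    elif kind == "gain_curves":
        rng = np.random.default_rng(seed)
        power = np.arange(1.0, 11.0)
        control = 50.0 * power * (1.0 + rng.normal(0, 0.01, power.size))
        blocking = 0.62
        sample = control * blocking
        pd.DataFrame(
            {"power": power, "fluorescence": control, "channel": "green"}
        ).to_csv(out_dir / "gain_control.csv", index=False)
        pd.DataFrame(
            {"power": power, "fluorescence": sample, "channel": "green"}
        ).to_csv(out_dir / "gain_sample.csv", index=False)
        paths["control"] = out_dir / "gain_control.csv"
        paths["sample"] = out_dir / "gain_sample.csv"
        truth["blocking_fraction"] = blocking

    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    sidecar = out_dir / f"{kind}_truth.json"
    sidecar.write_text(json.dumps(_jsonable(truth), indent=2))
    paths["truth"] = sidecar
    return paths


def read_gain_curve(path: str | Path):
    """Read a gain-curve CSV (``power, fluorescence[, channel]``)."""
    from .optics import GainCurve

    df = pd.read_csv(path)
    if not {"power", "fluorescence"}.issubset(df.columns):
        raise TraceFormatError(f"{path}: needs columns power, fluorescence")
    channel = str(df["channel"].iloc[0]) if "channel" in df.columns else "green"
    return GainCurve.from_arrays(df["power"], df["fluorescence"], channel=channel)
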