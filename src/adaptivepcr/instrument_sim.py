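"""Closed-loop simulator of the laser-heated adaptive PCR instrument.

A lumped (zero-dimensional) thermal model drives two-state L-DNA sensor melt
models and a logistic amplification chemistry, sampled at 30 Hz with detector
noise, under the command of the streaming adaptive controller.  Heating is
constant-rate (laser-dominated); cooling is Newtonian relaxation toward
ambient, with the rate constant calibrated so the *mean* cooling rate across
the working temperature band matches the configured value — only mean ramp
rates are typically measurable on such instruments (defaults 2.41 °C/s
heating, 2.49 °C/s cooling).

The probe chemistry is a hydrolysis (TaqMan-style) model: each replication
event irreversibly liberates fluorophore, so the green signal is cumulative
and saturates when the probe pool is exhausted.

A fast path (:func:`simulate_amplification`, :func:`simulate_dilution_series`)
runs the chemistry and detector model per cycle without the 30 Hz thermal
loop, for workflows that only need amplification curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .adaptive_control import (
    HEATING,
    COOLING,
    AdaptiveController,
    ControlParams,
    CycleRecord,
    FluorescenceTrace,
    SwitchPoint,
)
from .oligo_thermo import MeltModel, ss_fraction
from .qpcr_analysis import AmplificationCurve

__all__ = [
    "ThermalParams",
    "ChemistryParams",
    "SimulationConfig",
    "RunRecord",
    "thermal_step",
    "sensor_fluorescence",
    "amplify_cycle",
    "simulate_run",
    "simulate_amplification",
    "simulate_dilution_series",
    "REACTION_VOLUME_UL",
]

#: Standard reaction volume (µL) used to convert copies/µL to copies/reaction.
REACTION_VOLUME_UL = 20.0


@dataclass(frozen=True)
class ThermalParams:
    """Lumped thermal model parameters (°C, °C/s)."""

    heat_rate: float = 2.41
    cool_rate: float = 2.49
    ambient: float = 21.5
    t_min: float = 52.0
    t_max: float = 97.0

    def __post_init__(self) -> None:
        if self.heat_rate <= 0 or self.cool_rate <= 0:
            raise ValueError("heat_rate and cool_rate must be positive")
        if not self.ambient < self.t_min < self.t_max:
            raise ValueError("require ambient < t_min < t_max")

    @property
    def cooling_rate_constant(self) -> float:
        """Newtonian rate constant k (1/s) such that the mean cooling rate
        over [t_max, t_min] equals ``cool_rate``."""
        span = self.t_max - self.t_min
        log_ratio = math.log((self.t_max - self.ambient) / (self.t_min - self.ambient))
        return self.cool_rate * log_ratio / span


@dataclass(frozen=True)
class ChemistryParams:
    """Amplification chemistry and probe-signal parameters.

    efficiency:
        Per-cycle amplification factor E in (1, 2]; copies multiply by
        ~E each cycle while far from the carrying capacity.
    carrying_capacity:
        Copy number at plateau (reagent exhaustion), logistic cap.
    initial_copies:
        Template copies per reaction; 0 models a no-template control.
    probe_gain:
        Fluorescence units liberated per replication event (hydrolysis
        probe cleavage).
    probe_total:
        Saturation cap on cumulative probe fluorescence (finite probe pool).
    """

    efficiency: float = 2.0
    carrying_capacity: float = 2e13
    initial_copies: float = 2e6
    probe_gain: float = 1e-11
    probe_total: float = 100.0

    def __post_init__(self) -> None:
        if self.initial_copies < 0:
            raise ValueError("initial_copies must be >= 0")
        if self.initial_copies > 0 and not 1.0 < self.efficiency <= 2.0:
            raise ValueError("efficiency must be in (1, 2] for positive samples")
        if self.carrying_capacity <= 0 or self.probe_total <= 0:
            raise ValueError("carrying_capacity and probe_total must be positive")

    @classmethod
    def from_concentration(
        cls, copies_per_ul: float, volume_ul: float = REACTION_VOLUME_UL, **kwargs
    ) -> "ChemistryParams":
        """Build chemistry params from a template concentration (copies/µL)."""
        return cls(initial_copies=copies_per_ul * volume_ul, **kwargs)


@dataclass(frozen=True)
class SimulationConfig:
    """Full configuration of a closed-loop simulated run."""

    thermal: ThermalParams = field(default_factory=ThermalParams)
    chemistry: ChemistryParams = field(default_factory=ChemistryParams)
    anneal_sensor: MeltModel = field(default_factory=lambda: MeltModel(58.4, 2.5))
    melt_sensor: MeltModel = field(default_factory=lambda: MeltModel(90.8, 2.5))
    sampling_hz: float = 30.0
    noise_sd: float = 0.5
    blocking: dict | None = None  # per-channel attenuation fraction (1.0 = none)
    n_cycles: int = 40
    seed: int = 0
    sensor_baseline: float = 20.0
    sensor_span: float = 100.0
    green_baseline: float = 10.0

    def __post_init__(self) -> None:
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.anneal_sensor.tm_celsius >= self.melt_sensor.tm_celsius:
            raise ValueError("anneal sensor Tm must be below melt sensor Tm")

    def channel_blocking(self, channel: str) -> float:
        if not self.blocking:
            return 1.0
        return float(self.blocking.get(channel, 1.0))


@dataclass
class RunRecord:
    """Everything a closed-loop simulated run produced."""

    traces: dict[str, FluorescenceTrace]
    cycle_records: list[CycleRecord]
    switch_points: list[SwitchPoint]
    amplification: AmplificationCurve | None
    config: SimulationConfig
    seed: int
    control_errors: list[str] = field(default_factory=list)
    temperatures: np.ndarray | None = None

    @property
    def aborted(self) -> bool:
        return bool(self.control_errors)


def thermal_step(t: float, phase: str, dt: float, p: ThermalParams) -> float:
    """Advance the sample temperature by one time step.

    Heating is linear at ``heat_rate`` clipped at ``t_max``; cooling relaxes
    exponentially toward ambient and never crosses it.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if phase == HEATING:
        return min(t + p.heat_rate * dt, p.t_max)
    if phase == COOLING:
        return p.ambient + (t - p.ambient) * math.exp(-p.cooling_rate_constant * dt)
    raise ValueError(f"unknown phase {phase!r}")


def sensor_fluorescence(
    t: float,
    cfg: SimulationConfig,
    probe_signal: float = 0.0,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Detector readings (a.u.) for all channels at temperature ``t``.

    Yellow reports the melt sensor, orange the anneal sensor (both rise with
    single-stranded fraction as fluorophore escapes its quencher); green is
    the cumulative hydrolysis-probe signal, constant within a cycle.
    Per-channel blocking multipliers (nanorod attenuation) are applied last.
    """
    noiseless = {
        "yellow": cfg.sensor_baseline
        + cfg.sensor_span * ss_fraction(t, cfg.melt_sensor),
        "orange": cfg.sensor_baseline
        + cfg.sensor_span * ss_fraction(t, cfg.anneal_sensor),
        "green": cfg.green_baseline + probe_signal,
        "red": 0.0,
    }
    out = {}
    for ch, v in noiseless.items():
        noise = rng.normal(0.0, cfg.noise_sd) if rng is not None and cfg.noise_sd > 0 else 0.0
        out[ch] = (v + noise) * cfg.channel_blocking(ch)
    return out


def amplify_cycle(copies: float, chem: ChemistryParams) -> tuple[float, float]:
    """One PCR cycle of logistic growth.

    Returns ``(new_copies, probe_increment)`` where
    ``new_copies = copies·(1 + (E−1)·(1 − copies/K))`` and the probe
    increment is ``probe_gain`` per newly synthesized copy.  The caller caps
    the cumulative probe signal at ``probe_total``.
    """
    if copies < 0:
        raise ValueError("copies must be >= 0")
    growth = copies * (chem.efficiency - 1.0) * max(0.0, 1.0 - copies / chem.carrying_capacity)
    new_copies = copies + growth
    return new_copies, chem.probe_gain * growth


def simulate_run(
    cfg: SimulationConfig,
    controller: AdaptiveController | None = None,
) -> RunRecord:
    """Run the closed thermal/optical/chemical loop under adaptive control.

    The controller watches the simulated sensor channels; at each
    cool→heat switch the green channel is read, producing one amplification
    point per completed cycle.  Fully reproducible for a fixed config seed.
    """
    ctrl = controller or AdaptiveController(n_cycles=cfg.n_cycles)
    rng = np.random.default_rng(cfg.seed)
    dt = 1.0 / cfg.sampling_hz
    temp = cfg.thermal.ambient
    copies = cfg.chemistry.initial_copies
    probe = 0.0
    times: list[float] = []
    temps: list[float] = []
    rows: dict[str, list[float]] = {ch: [] for ch in ("green", "yellow", "orange", "red")}
    n_done = 0
    t_now = 0.0
    # hard cap so a pathological controller cannot run forever
    max_steps = int((ctrl.params.timeout_s * 2 * cfg.n_cycles + 60.0) * cfg.sampling_hz)
    for _ in range(max_steps):
        temp = thermal_step(temp, ctrl.phase, dt, cfg.thermal)
        t_now += dt
        readings = sensor_fluorescence(temp, cfg, probe_signal=probe, rng=rng)
        prev_phase = ctrl.phase
        ctrl.update(t_now, readings)
        times.append(t_now)
        temps.append(temp)
        for ch in rows:
            rows[ch].append(readings[ch])
        if prev_phase == COOLING and ctrl.phase == HEATING:
            # a cycle just completed: extension happened during annealing
            copies, inc = amplify_cycle(copies, cfg.chemistry)
            probe = min(probe + inc, cfg.chemistry.probe_total)
        if ctrl.done:
            break
        n_done = len(ctrl.cycle_records)

    t_arr = np.asarray(times)
    traces = {
        ch: FluorescenceTrace(t_arr, np.asarray(v), channel=ch, sampling_hz=cfg.sampling_hz)
        for ch, v in rows.items()
    }
    amplification = None
    if ctrl.cycle_records:
        amplification = AmplificationCurve(
            cycles=np.arange(1, len(ctrl.cycle_records) + 1),
            fluorescence=np.array([c.pcr_reading for c in ctrl.cycle_records]),
            timestamps=np.array([c.pcr_timestamp_s for c in ctrl.cycle_records]),
        )
    return RunRecord(
        traces=traces,
        cycle_records=list(ctrl.cycle_records),
        switch_points=list(ctrl.switch_points),
        amplification=amplification,
        config=cfg,
        seed=cfg.seed,
        control_errors=list(ctrl.control_errors),
        temperatures=np.asarray(temps),
    )


def nominal_cycle_time(p: ThermalParams) -> float:
    """Rough per-cycle duration implied by the thermal band and ramp rates."""
    span = p.t_max - p.t_min
    return span / p.heat_rate + span / p.cool_rate


def simulate_amplification(cfg: SimulationConfig) -> AmplificationCurve:
    """Per-cycle green-channel readings without the 30 Hz thermal loop.

    Runs the chemistry and detector-noise model only; timestamps use the
    nominal cycle time implied by the thermal parameters.  Orders of
    magnitude faster than :func:`simulate_run` when only amplification
    curves are needed (dilution series, standard curves).
    """
    rng = np.random.default_rng(cfg.seed)
    copies = cfg.chemistry.initial_copies
    probe = 0.0
    block = cfg.channel_blocking("green")
    cycle_s = nominal_cycle_time(cfg.thermal)
    readings = np.empty(cfg.n_cycles)
    # read-then-amplify matches the closed loop, where the PCR reading is
    # taken at the cool->heat switch before the next round of extension
    for c in range(cfg.n_cycles):
        noise = rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0
        readings[c] = (cfg.green_baseline + probe + noise) * block
        copies, inc = amplify_cycle(copies, cfg.chemistry)
        probe = min(probe + inc, cfg.chemistry.probe_total)
    return AmplificationCurve(
        cycles=np.arange(1, cfg.n_cycles + 1),
        fluorescence=readings,
        timestamps=cycle_s * np.arange(1, cfg.n_cycles + 1),
    )


def simulate_dilution_series(
    concentrations_per_ul,
    n_replicates: int = 4,
    n_ntc: int = 3,
    base_config: SimulationConfig | None = None,
    seed: int = 0,
) -> list[tuple[float | None, AmplificationCurve]]:
    """Simulate a serial-dilution experiment with replicates and NTCs.

    Returns ``(concentration, curve)`` pairs; NTC entries carry ``None`` as
    concentration.  Replicates get independent noise streams derived from
    ``seed`` via a seed sequence, so the whole series is reproducible.
    """
    base = base_config or SimulationConfig()
    concentrations = list(concentrations_per_ul)
    runs: list[tuple[float | None, AmplificationCurve]] = []
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(concentrations) * n_replicates + n_ntc))
    for conc in concentrations:
        for _ in range(n_replicates):
            child_seed = int(next(children).generate_state(1)[0] % (2**31))
            chem = replace(base.chemistry, initial_copies=conc * REACTION_VOLUME_UL)
            cfg = replace(base, chemistry=chem, seed=child_seed)
            runs.append((conc, simulate_amplification(cfg)))
    for _ in range(n_ntc):
        child_seed = int(next(children).generate_state(1)[0] % (2**31))
        chem = replace(base.chemistry, initial_copies=0.0, efficiency=2.0)
        cfg = replace(base, chemistry=chem, seed=child_seed)
        runs.append((None, simulate_amplification(cfg)))
    return runs
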