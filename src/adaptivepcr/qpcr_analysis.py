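"""qPCR quantification: normalization, Cq calling, efficiency, LoD.

All amplification curves are first normalized to a 0–100 relative scale
(baseline = mean of the first 15 cycles, then division by the post-subtraction
maximum).  A sample is called positive at the first cycle whose
baseline-subtracted fluorescence reaches 10 baseline standard deviations, with
a monotone cubic spline giving the fractional crossing (Cq).  Per-reaction
efficiency comes from a window-of-linearity fit in the style of LinRegPCR:
the slope of ln(fluorescence) vs cycle over 5 cycles centered on the nearest
cycle to Cq equals ln(E).  Dilution series yield a standard curve, Cq vs
log10(concentration), whose slope gives the conventional overall efficiency
E = 10^(−1/slope), and a limit of detection — the lowest concentration at
which every replicate is positive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

__all__ = [
    "AmplificationCurve",
    "NormalizedCurve",
    "CqResult",
    "EfficiencyResult",
    "StandardCurve",
    "CycleTimeSummary",
    "LodResult",
    "normalize",
    "call_cq",
    "single_sample_efficiency",
    "standard_curve",
    "average_cycle_time",
    "lod_call",
]


@dataclass(frozen=True)
class AmplificationCurve:
    """Per-cycle PCR fluorescence, optionally with wall-clock timestamps."""

    cycles: np.ndarray
    fluorescence: np.ndarray
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.cycles, dtype=int)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "cycles", c)
        object.__setattr__(self, "fluorescence", f)
        if c.shape != f.shape:
            raise ValueError("cycles and fluorescence must have equal length")
        if c.size == 0 or c[0] != 1 or not np.all(np.diff(c) == 1):
            raise ValueError("cycles must run consecutively from 1")
        if self.timestamps is not None:
            t = np.asarray(self.timestamps, dtype=float)
            object.__setattr__(self, "timestamps", t)
            if t.shape != f.shape:
                raise ValueError("timestamps must match curve length")

    def __len__(self) -> int:
        return int(self.cycles.size)


@dataclass(frozen=True)
class NormalizedCurve:
    """Curve on the 0–100 relative fluorescence scale plus baseline stats.

    ``values`` are 100·(f − baseline_mean)/max_raw where ``max_raw`` is the
    largest baseline-subtracted fluorescence; ``flat`` marks curves with no
    signal above baseline at all (no normalization possible).
    """

    values: np.ndarray
    cycles: np.ndarray
    baseline_mean: float
    baseline_sd: float
    max_raw: float
    flat: bool = False
    timestamps: np.ndarray | None = None
    baseline_cycles: int = 15

    @property
    def subtracted(self) -> np.ndarray:
        """Baseline-subtracted values in raw fluorescence units."""
        if self.flat:
            return self.values.copy()
        return self.values * self.max_raw / 100.0


@dataclass(frozen=True)
class CqResult:
    """Quantification cycle call for one amplification curve."""

    cq: float | None
    positive: bool
    threshold: float  # on the baseline-subtracted (raw-unit) scale
    quantification_time_s: float | None = None


@dataclass(frozen=True)
class EfficiencyResult:
    """Window-of-linearity single-sample efficiency estimate."""

    efficiency: float
    slope: float  # of ln(value) vs cycle; efficiency = exp(slope)
    window: tuple[int, ...]
    r_squared: float
    window_shifted: bool = False


@dataclass(frozen=True)
class StandardCurve:
    """Regression of Cq on log10 template concentration."""

    points: tuple[tuple[float, float, float], ...]  # (log10 conc, mean Cq, SD)
    slope: float
    intercept: float
    r_squared: float
    efficiency: float  # 10^(−1/slope)
    n_excluded_negative: int = 0


@dataclass(frozen=True)
class CycleTimeSummary:
    mean_s: float
    sd_s: float
    first_cycle: int
    last_cycle: int
    n_cycles: int


@dataclass(frozen=True)
class LodResult:
    """Limit of detection: lowest concentration with all replicates positive."""

    lod: float | None
    positivity: tuple[tuple[float, int, int], ...]  # (conc, n_positive, n_total)


def normalize(curve: AmplificationCurve, baseline_cycles: int = 15) -> NormalizedCurve:
    """Normalize to the 0–100 relative fluorescence scale.

    The baseline is the mean fluorescence of the first ``baseline_cycles``
    cycles; its SD is retained for threshold calling.  A curve whose maximum
    never rises above the baseline is flagged flat (it will be called
    negative downstream).
    """
    if len(curve) < baseline_cycles + 1:
        raise ValueError(
            f"curve has {len(curve)} cycles; needs > {baseline_cycles} for baseline"
        )
    f = curve.fluorescence
    base = f[:baseline_cycles]
    mean = float(base.mean())
    sd = float(base.std(ddof=1))
    sub = f - mean
    max_raw = float(sub.max())
    if max_raw <= 0.0:
        return NormalizedCurve(
            values=sub.copy(),
            cycles=curve.cycles.copy(),
            baseline_mean=mean,
            baseline_sd=sd,
            max_raw=0.0,
            flat=True,
            timestamps=curve.timestamps,
            baseline_cycles=baseline_cycles,
        )
    return NormalizedCurve(
        values=100.0 * sub / max_raw,
        cycles=curve.cycles.copy(),
        baseline_mean=mean,
        baseline_sd=sd,
        max_raw=max_raw,
        timestamps=curve.timestamps,
        baseline_cycles=baseline_cycles,
    )


def call_cq(norm: NormalizedCurve, k_sd: float = 10.0, sd_floor: float = 1e-3) -> CqResult:
    """Call the quantification cycle at baseline + ``k_sd`` standard deviations.

    The threshold is ``k_sd · baseline_sd`` on the baseline-subtracted scale
    (raw units).  The fractional Cq comes from a shape-preserving monotone
    cubic (PCHIP) spline through the cycles around the first crossing, which
    cannot overshoot between points the way a natural cubic spline can.  When
    timestamps are present the quantification time is interpolated at the
    fractional Cq the same way.

    A zero baseline SD (possible on idealized synthetic data) is replaced by
    ``sd_floor`` with a warning.
    """
    if norm.flat:
        return CqResult(cq=None, positive=False, threshold=0.0)
    sd = norm.baseline_sd
    if sd <= 0.0:
        warnings.warn(
            f"baseline SD is zero; using configured floor {sd_floor}", stacklevel=2
        )
        sd = sd_floor
    threshold = k_sd * sd
    v = norm.subtracted
    above = np.where(v >= threshold)[0]
    if above.size == 0:
        return CqResult(cq=None, positive=False, threshold=threshold)
    i = int(above[0])
    cycles = norm.cycles.astype(float)
    if i < norm.baseline_cycles:
        warnings.warn(
            f"threshold crossing at cycle {cycles[i]:.0f} falls inside the "
            f"{norm.baseline_cycles}-cycle baseline window; Cq may be biased",
            stacklevel=2,
        )
    if i == 0 or v[i] == threshold:
        cq = float(cycles[i])
    else:
        lo, hi = max(0, i - 3), min(v.size, i + 4)
        spline = PchipInterpolator(cycles[lo:hi], v[lo:hi])
        cq = float(brentq(lambda c: spline(c) - threshold, cycles[i - 1], cycles[i]))
    qt = None
    if norm.timestamps is not None:
        qt = float(np.interp(cq, cycles, norm.timestamps))
    return CqResult(cq=cq, positive=True, threshold=threshold, quantification_time_s=qt)


def single_sample_efficiency(
    norm: NormalizedCurve, cq: float, window: int = 5
) -> EfficiencyResult:
    """Window-of-linearity efficiency for a single reaction.

    Ordinary least squares of ln(normalized fluorescence) against cycle over
    ``window`` cycles centered on the nearest cycle to the fractional Cq;
    the slope equals ln(E).  If the window contains non-positive values it is
    shifted upward minimally (recorded in ``window_shifted``); if no
    all-positive window exists the call fails.
    """
    if window < 2:
        raise ValueError("window must span at least 2 cycles")
    v = norm.values
    cycles = norm.cycles
    n = v.size
    center = int(math.floor(cq + 0.5))  # nearest cycle, half rounds up
    half = window // 2
    start = center - 1 - half  # index of the first window cycle
    start = max(0, min(start, n - window))
    shifted = False
    while start + window <= n and np.any(v[start : start + window] <= 0.0):
        start += 1
        shifted = True
    if start + window > n:
        raise ValueError(
            "no all-positive window of linearity available for efficiency fit"
        )
    win_v = v[start : start + window]
    win_c = cycles[start : start + window].astype(float)
    res = stats.linregress(win_c, np.log(win_v))
    return EfficiencyResult(
        efficiency=float(math.exp(res.slope)),
        slope=float(res.slope),
        window=tuple(int(c) for c in win_c),
        r_squared=float(res.rvalue**2),
        window_shifted=shifted,
    )


def standard_curve(samples: list[tuple[float, CqResult]]) -> StandardCurve:
    """Fit Cq vs log10(concentration) across a dilution series.

    ``samples`` holds (log10 concentration, CqResult) pairs; negative calls
    are excluded (and counted).  Requires at least 3 distinct concentrations
    with positive calls.  Efficiency follows the standard convention
    E = 10^(−1/slope).
    """
    pos = [(x, r.cq) for x, r in samples if r.positive and r.cq is not None]
    n_excluded = len(samples) - len(pos)
    concs = sorted({x for x, _ in pos})
    if len(concs) < 3:
        raise ValueError(
            f"standard curve needs >= 3 distinct positive concentrations, got {len(concs)}"
        )
    x = np.array([p[0] for p in pos])
    y = np.array([p[1] for p in pos])
    res = stats.linregress(x, y)
    pts = []
    for c in concs:
        cqs = y[x == c]
        sd = float(cqs.std(ddof=1)) if cqs.size > 1 else 0.0
        pts.append((float(c), float(cqs.mean()), sd))
    return StandardCurve(
        points=tuple(pts),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        efficiency=float(10.0 ** (-1.0 / res.slope)),
        n_excluded_negative=n_excluded,
    )


def average_cycle_time(cycle_records, first: int = 2, last: int = 11) -> CycleTimeSummary:
    """Mean and SD of per-cycle durations over an inclusive cycle window.

    The first cycle is excluded by default because it starts from an
    arbitrary environmental temperature.
    """
    durations = [
        c.heat_duration_s + c.cool_duration_s
        for c in cycle_records
        if first <= c.cycle <= last
    ]
    n_expected = last - first + 1
    if len(durations) < n_expected:
        raise ValueError(
            f"need cycles {first}..{last}; run provides only {len(durations)} of them"
        )
    arr = np.asarray(durations)
    return CycleTimeSummary(
        mean_s=float(arr.mean()),
        sd_s=float(arr.std(ddof=1)),
        first_cycle=first,
        last_cycle=last,
        n_cycles=len(durations),
    )


def lod_call(results: dict[float, list[CqResult]]) -> LodResult:
    """Lowest concentration at which every replicate is called positive.

    Returns ``None`` as the LoD when no concentration qualifies, along with
    the full per-concentration positivity table.
    """
    if not results:
        raise ValueError("results must contain at least one concentration")
    table = []
    qualifying = []
    for conc in sorted(results):
        reps = results[conc]
        n_pos = sum(1 for r in reps if r.positive)
        table.append((float(conc), n_pos, len(reps)))
        if reps and n_pos == len(reps):
            qualifying.append(conc)
    lod = float(min(qualifying)) if qualifying else None
    return LodResult(lod=lod, positivity=tuple(table))
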