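"""Adaptive PCR cycling control from hybridization-sensor fluorescence.

Instead of preset temperatures and hold times, adaptive cycling watches
fluorophore/quencher-labelled L-DNA sensor duplexes.  During heating the melt
sensor (yellow channel) brightens as the duplex denatures; during cooling the
anneal sensor (orange channel) dims as it re-hybridizes.  A Gaussian is fitted
to the time-derivative of the watched channel, and the controller predicts
when the derivative "approaches zero" — when the fluorescence stops changing —
as t* = μ + α·σ.  At that instant it emits a switch point: heating→cooling at
the melt switch, or (after taking a PCR reading on the green channel)
cooling→heating at the anneal switch.

Because only the *shape* of the derivative matters, control is invariant to
gain and offset changes in the raw fluorescence — the property that makes the
approach robust to nanorod attenuation, alignment drift and sample-to-sample
brightness differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FluorescenceTrace",
    "ControlParams",
    "GaussianFit",
    "SwitchPoint",
    "CycleRecord",
    "SwitchStats",
    "FitError",
    "ControlError",
    "smoothed_derivative",
    "fit_gaussian",
    "predict_switch_time",
    "AdaptiveController",
    "replay",
    "switch_stats",
]

HEATING = "heating"
COOLING = "cooling"

#: Channel watched in each phase.
PHASE_CHANNEL = {HEATING: "yellow", COOLING: "orange"}
#: Expected derivative sign in each phase (melt brightens, anneal dims).
PHASE_SIGN = {HEATING: 1.0, COOLING: -1.0}


class FitError(RuntimeError):
    """Gaussian fit failed or was degenerate; caller retries on the next sample."""


class ControlError(RuntimeError):
    """A phase exceeded its timeout without a valid switch."""


@dataclass(frozen=True)
class FluorescenceTrace:
    """Uniformly sampled single-channel fluorescence time series."""

    times: np.ndarray
    values: np.ndarray
    channel: str = ""
    sampling_hz: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class ControlParams:
    """Tunable parameters of the cycling controller.

    smooth_window:
        Centered moving-average width (samples, odd) applied before finite
        differencing; 7 samples at 30 Hz spans ~0.23 s.
    alpha:
        Switch threshold in fitted sigmas past the derivative peak.  At
        α = 2 the Gaussian has decayed to exp(−α²/2) ≈ 13.5 % of its peak.
    min_phase_s:
        Guard time: never switch earlier than this after a phase starts.
    fit_min_points:
        Minimum derivative samples before a fit is attempted.
    timeout_s:
        A phase lasting longer than this without a valid switch is a
        control error.
    decline_samples:
        Consecutive declining smoothed-derivative samples required before the
        peak is considered passed (guards against noise-triggered fits).
    peak_snr:
        The fitted bell amplitude must exceed the fit-residual noise by this
        many robust standard deviations.  A *relative* guard, so control
        stays invariant to signal gain.
    refit_stride, refit_margin_s:
        Refit throttling: once a valid fit exists, refit every
        ``refit_stride`` samples while the predicted switch is more than
        ``refit_margin_s`` away, and on every sample inside that margin.
    prediction_tol_s:
        Two consecutive fits must agree on the predicted switch time within
        this tolerance before a switch is committed; transient fits to noise
        ripples do not produce stable predictions, real transitions do.
    """

    smooth_window: int = 7
    alpha: float = 2.0
    min_phase_s: float = 2.0
    fit_min_points: int = 25
    timeout_s: float = 60.0
    decline_samples: int = 3
    peak_snr: float = 6.0
    refit_stride: int = 5
    refit_margin_s: float = 0.5
    prediction_tol_s: float = 0.2

    def __post_init__(self) -> None:
        if self.smooth_window < 3 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 3")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.refit_stride < 1:
            raise ValueError("refit_stride must be >= 1")


@dataclass(frozen=True)
class GaussianFit:
    """Parameters of a·exp(−(t−μ)²/(2σ²)) + offset fitted to a derivative."""

    amplitude: float
    mean: float
    sigma: float
    offset: float
    rss: float


@dataclass(frozen=True)
class SwitchPoint:
    cycle: int
    kind: str  # "melt_switch" (heat→cool) | "anneal_switch" (cool→heat)
    time_s: float
    fluorescence_at_switch: float


@dataclass(frozen=True)
class CycleRecord:
    cycle: int
    heat_duration_s: float
    cool_duration_s: float
    pcr_reading: float
    pcr_timestamp_s: float

    @property
    def duration_s(self) -> float:
        return self.heat_duration_s + self.cool_duration_s


def smoothed_derivative(trace: FluorescenceTrace, window: int = 7):
    """Centered moving-average smoothing followed by central differences.

    Returns ``(times, derivative)`` aligned to the input timestamps with the
    edges truncated (the half-window lost to smoothing plus one sample on
    each side for the central difference).
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if len(trace) < window + 2:
        raise ValueError(
            f"trace has {len(trace)} samples; needs at least {window + 2} for "
            f"window {window}"
        )
    half = window // 2
    kernel = np.full(window, 1.0 / window)
    smooth = np.convolve(trace.values, kernel, mode="valid")
    t_s = trace.times[half : len(trace) - half]
    # central differences on the smoothed series
    d = (smooth[2:] - smooth[:-2]) / (t_s[2:] - t_s[:-2])
    return t_s[1:-1], d


_SQRT_8LN2 = math.sqrt(8.0 * math.log(2.0))


def _gauss(t, a, mu, sigma, c):
    return a * np.exp(-((t - mu) ** 2) / (2.0 * sigma**2)) + c


def fit_gaussian(
    times, deriv, p0: GaussianFit | None = None, min_sigma: float | None = None
) -> GaussianFit:
    """Nonlinear least squares of a Gaussian + offset to a derivative series.

    The series is assumed sign-adjusted so the bell points upward.
    Initialization comes from the empirical extremum (amplitude and mean),
    the half-width at half-maximum (sigma) and the first samples (offset),
    unless a previous fit is supplied as a warm start.

    Raises :class:`FitError` on non-convergence or a degenerate result
    (σ collapsing below ``min_sigma`` — by default half the sample spacing —
    or a fit no better than a flat line).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(deriv, dtype=float)
    if t.size < 5:
        raise FitError(f"too few points to fit ({t.size})")
    dt = float(np.median(np.diff(t)))
    if p0 is not None:
        guess = [p0.amplitude, p0.mean, p0.sigma, p0.offset]
    else:
        c0 = float(np.median(y[: max(3, t.size // 10)]))
        ipk = int(np.argmax(y))
        a0 = float(y[ipk] - c0)
        if a0 <= 0:
            raise FitError("no positive peak above baseline")
        # HWHM from first crossing of half-height on each side of the peak
        half_level = c0 + a0 / 2.0
        left = np.where(y[:ipk] < half_level)[0]
        right = np.where(y[ipk:] < half_level)[0]
        lw = t[ipk] - t[left[-1]] if left.size else dt
        rw = t[ipk + right[0]] - t[ipk] if right.size else dt
        sigma0 = max((lw + rw) / _SQRT_8LN2, dt)
        guess = [a0, float(t[ipk]), sigma0, c0]
    try:
        popt, _ = curve_fit(_gauss, t, y, p0=guess, maxfev=400)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"gaussian fit did not converge: {exc}") from exc
    a, mu, sigma, c = (float(x) for x in popt)
    sigma = abs(sigma)
    resid = y - _gauss(t, a, mu, sigma, c)
    rss = float(np.dot(resid, resid))
    flat_ss = float(np.sum((y - y.mean()) ** 2))
    sigma_floor = dt / 2.0 if min_sigma is None else min_sigma
    if sigma < sigma_floor:
        raise FitError(f"degenerate fit: sigma {sigma:.3g} below floor {sigma_floor:.3g}")
    if a <= 0:
        raise FitError("degenerate fit: non-positive amplitude")
    if flat_ss > 0 and rss >= flat_ss:
        raise FitError("degenerate fit: no better than a constant")
    return GaussianFit(amplitude=a, mean=mu, sigma=sigma, offset=c, rss=rss)


def predict_switch_time(fit: GaussianFit, alpha: float) -> float:
    """Time at which the fitted derivative has decayed to exp(−α²/2) of peak."""
    return fit.mean + alpha * fit.sigma


#: Cheap candidate-peak pre-filter level (robust SDs above the phase median).
#: Deliberately low: it only skips obviously-flat stretches; the decisive
#: significance test compares the fitted amplitude to the fit residuals.
_PREFILTER_SNR = 3.0


class _PhaseWatcher:
    """Streaming smoothed-derivative, peak detection and Gaussian refitting
    for a single heating or cooling phase."""

    def __init__(self, params: ControlParams, sign: float):
        self.p = params
        self.sign = sign
        self.times: list[float] = []
        self.values: list[float] = []
        self._winsum = 0.0
        self.s_times: list[float] = []
        self.smooth: list[float] = []
        self.d_times: list[float] = []
        self.deriv: list[float] = []
        self.peak_detected = False
        self._decline = 0
        self._max_d = -math.inf
        self._max_i = -1
        self._since_attempt = 0
        self.fit: GaussianFit | None = None
        self.predicted: float | None = None
        self.predicted_prev: float | None = None

    @property
    def peak_time(self) -> float:
        return self.d_times[self._max_i]

    def add(self, t: float, v: float) -> None:
        w = self.p.smooth_window
        self.times.append(t)
        self.values.append(v)
        self._winsum += v
        n = len(self.values)
        if n > w:
            self._winsum -= self.values[n - w - 1]
        if n >= w:
            # centered moving average for sample index n-1-(w//2)
            ci = n - 1 - w // 2
            self.s_times.append(self.times[ci])
            self.smooth.append(self._winsum / w)
            m = len(self.smooth)
            if m >= 3:
                dt2 = self.s_times[m - 1] - self.s_times[m - 3]
                d = self.sign * (self.smooth[m - 1] - self.smooth[m - 3]) / dt2
                self.d_times.append(self.s_times[m - 2])
                self.deriv.append(d)
                if d > self._max_d:
                    self._max_d = d
                    self._max_i = len(self.deriv) - 1
                self._update_peak()

    def _update_peak(self) -> None:
        """Flag a candidate derivative peak once the bell has visibly passed.

        Requires ``decline_samples`` consecutive declining smoothed samples,
        an interior maximum, and the maximum standing a few robust SDs above
        the phase median.  This is intentionally permissive — a spurious
        candidate merely triggers fit attempts, and an insignificant fit is
        rejected by the residual-based amplitude test in :meth:`try_fit`.
        """
        if self.peak_detected or len(self.deriv) < self.p.fit_min_points:
            return
        d = self.deriv
        if d[-1] < d[-2]:
            self._decline += 1
        else:
            self._decline = 0
        if self._decline < self.p.decline_samples:
            return
        if self._max_i <= 0 or self._max_i >= len(d) - 1:
            return
        arr = np.asarray(d)
        med = float(np.median(arr))
        noise = 1.4826 * float(np.median(np.abs(arr - med)))
        if noise > 0 and self._max_d - med < _PREFILTER_SNR * noise:
            return
        self.peak_detected = True

    def step_fit(self, time_s: float) -> GaussianFit | None:
        """Throttled Gaussian refitting with switch-time prediction tracking.

        Refits every ``refit_stride`` samples until a valid fit exists and
        while the predicted switch is comfortably in the future, and on
        every sample once the prediction is within ``refit_margin_s``.
        """
        if not self.peak_detected:
            return None
        self._since_attempt += 1
        due = self._since_attempt >= self.p.refit_stride
        if self.predicted is not None and time_s >= self.predicted - self.p.refit_margin_s:
            due = True
        if not due:
            return self.fit
        self._since_attempt = 0
        self._attempt_fit()
        return self.fit

    def _attempt_fit(self) -> None:
        # a credible transition cannot be much narrower than the smoothing
        # kernel: anything below half its span is unresolvable noise ripple
        dt = (self.times[-1] - self.times[0]) / max(len(self.times) - 1, 1)
        # the flat head of a long phase adds nothing to the fit; cap the
        # window so refits stay cheap
        t = np.asarray(self.d_times[-400:])
        y = np.asarray(self.deriv[-400:])
        try:
            fit = fit_gaussian(t, y, p0=self.fit, min_sigma=0.5 * self.p.smooth_window * dt)
        except FitError:
            return  # keep the previous fit, if any; retry at the next attempt
        # significance guard: the fitted bell must stand clear of the fit
        # residuals, or a noise ripple could masquerade as a transition.
        # A ratio test, so control stays invariant to signal gain/offset.
        resid = y - _gauss(t, fit.amplitude, fit.mean, fit.sigma, fit.offset)
        res_mad = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
        if res_mad > 0 and fit.amplitude < self.p.peak_snr * res_mad:
            return
        self.fit = fit
        self.predicted_prev = self.predicted
        self.predicted = predict_switch_time(fit, self.p.alpha)

    @property
    def prediction_stable(self) -> bool:
        return (
            self.predicted is not None
            and self.predicted_prev is not None
            and abs(self.predicted - self.predicted_prev) <= self.p.prediction_tol_s
        )


class AdaptiveController:
    """Streaming heat/cool state machine driven by sensor-derivative fits.

    Feed one multichannel reading per call to :meth:`update`; it returns the
    phase command (``"heating"`` or ``"cooling"``) to apply next.  Switch
    points, per-cycle records and control errors accumulate on the instance.
    """

    def __init__(self, params: ControlParams | None = None, n_cycles: int = 40):
        self.params = params or ControlParams()
        self.n_cycles = int(n_cycles)
        self.phase = HEATING
        self.cycle = 1
        self.switch_points: list[SwitchPoint] = []
        self.cycle_records: list[CycleRecord] = []
        self.control_errors: list[str] = []
        self._phase_start: float | None = None
        self._heat_duration: float | None = None
        self._watch = _PhaseWatcher(self.params, PHASE_SIGN[self.phase])

    @property
    def done(self) -> bool:
        return len(self.cycle_records) >= self.n_cycles or bool(self.control_errors)

    def update(self, time_s: float, readings: dict[str, float]) -> str:
        if self.done:
            return self.phase
        if self._phase_start is None:
            self._phase_start = time_s
        p = self.params
        elapsed = time_s - self._phase_start
        if elapsed > p.timeout_s:
            self.control_errors.append(
                f"cycle {self.cycle}: {self.phase} phase exceeded {p.timeout_s} s "
                f"without a valid switch point"
            )
            return self.phase
        channel = PHASE_CHANNEL[self.phase]
        value = readings[channel]
        self._watch.add(time_s, value)
        if elapsed < p.min_phase_s or not self._watch.peak_detected:
            return self.phase
        fit = self._watch.step_fit(time_s)
        if fit is None or not self._watch.prediction_stable:
            return self.phase
        t_star = self._watch.predicted
        # never switch before the observed derivative peak: the transition
        # midpoint must already be behind us
        if time_s >= t_star >= self._watch.peak_time:
            self._switch(time_s, value, readings)
        return self.phase

    def _switch(self, time_s: float, value: float, readings: dict[str, float]) -> None:
        if self.phase == HEATING:
            kind = "melt_switch"
            self._heat_duration = time_s - self._phase_start
            next_phase = COOLING
        else:
            kind = "anneal_switch"
            cool_duration = time_s - self._phase_start
            self.cycle_records.append(
                CycleRecord(
                    cycle=self.cycle,
                    heat_duration_s=self._heat_duration,
                    cool_duration_s=cool_duration,
                    pcr_reading=readings.get("green", float("nan")),
                    pcr_timestamp_s=time_s,
                )
            )
            next_phase = HEATING
        self.switch_points.append(
            SwitchPoint(cycle=self.cycle, kind=kind, time_s=time_s, fluorescence_at_switch=value)
        )
        if self.phase == COOLING:
            self.cycle += 1
        self.phase = next_phase
        self._phase_start = time_s
        self._watch = _PhaseWatcher(self.params, PHASE_SIGN[self.phase])


def replay(
    traces: dict[str, FluorescenceTrace],
    params: ControlParams | None = None,
    n_cycles: int = 40,
) -> AdaptiveController:
    """Run the controller over recorded traces as if they were streaming.

    ``traces`` maps channel names to :class:`FluorescenceTrace`; all supplied
    channels must share identical timestamps.  Returns the finished
    controller with its switch points and cycle records.
    """
    channels = list(traces)
    if "yellow" not in channels or "orange" not in channels:
        raise ValueError("replay requires 'yellow' and 'orange' channels")
    t0 = traces[channels[0]].times
    for ch in channels[1:]:
        if len(traces[ch]) != t0.size or not np.allclose(traces[ch].times, t0):
            raise ValueError("all channels must share identical timestamps")
    ctrl = AdaptiveController(params, n_cycles=n_cycles)
    for i in range(t0.size):
        if ctrl.done:
            break
        ctrl.update(float(t0[i]), {ch: float(traces[ch].values[i]) for ch in channels})
    return ctrl


@dataclass(frozen=True)
class SwitchStats:
    """Cycle-to-cycle stability of switch points over a baseline window."""

    first_cycle: int
    last_cycle: int
    melt_mean_fluorescence: float
    anneal_mean_fluorescence: float
    melt_deviations: np.ndarray  # per-cycle fluorescence − mean, melt switches
    anneal_deviations: np.ndarray
    heat_duration_sd: float
    cool_duration_sd: float


def switch_stats(run, first_cycle: int = 2, last_cycle: int = 16) -> SwitchStats:
    """Switch-point fluorescence deviations and heating/cooling time SDs.

    Operates on the baseline window (default cycles 2–16): the first cycle is
    excluded because it starts from ambient temperature, and later cycles are
    excluded because PCR probe fluorescence rises above baseline.  ``run``
    is any object with ``switch_points`` and ``cycle_records`` (a
    :class:`AdaptiveController` or a simulator run record).
    """
    cycles = [c for c in run.cycle_records if first_cycle <= c.cycle <= last_cycle]
    n_expected = last_cycle - first_cycle + 1
    if len(cycles) < n_expected:
        raise ValueError(
            f"need cycles {first_cycle}..{last_cycle} but run has "
            f"{len(run.cycle_records)} cycles"
        )

    def _f(kind: str) -> np.ndarray:
        return np.array(
            [
                sp.fluorescence_at_switch
                for sp in run.switch_points
                if sp.kind == kind and first_cycle <= sp.cycle <= last_cycle
            ]
        )

    melt_f = _f("melt_switch")
    anneal_f = _f("anneal_switch")
    heat = np.array([c.heat_duration_s for c in cycles])
    cool = np.array([c.cool_duration_s for c in cycles])
    return SwitchStats(
        first_cycle=first_cycle,
        last_cycle=last_cycle,
        melt_mean_fluorescence=float(melt_f.mean()),
        anneal_mean_fluorescence=float(anneal_f.mean()),
        melt_deviations=melt_f - melt_f.mean(),
        anneal_deviations=anneal_f - anneal_f.mean(),
        heat_duration_sd=float(np.std(heat, ddof=1)),
        cool_duration_sd=float(np.std(cool, ddof=1)),
    )
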