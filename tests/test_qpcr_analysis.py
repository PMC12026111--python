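import math

import numpy as np
import pytest

from adaptivepcr.adaptive_control import CycleRecord
from adaptivepcr.qpcr_analysis import (
    AmplificationCurve,
    CqResult,
    NormalizedCurve,
    average_cycle_time,
    call_cq,
    lod_call,
    normalize,
    single_sample_efficiency,
    standard_curve,
)
from adaptivepcr.instrument_sim import (
    ChemistryParams,
    SimulationConfig,
    simulate_amplification,
    simulate_dilution_series,
)


def make_curve(values, timestamps=None):
    values = np.asarray(values, dtype=float)
    return AmplificationCurve(
        cycles=np.arange(1, values.size + 1),
        fluorescence=values,
        timestamps=timestamps,
    )


def doubling_curve(n=40, baseline=0.0, noise_sd=0.0, amp=0.000625, seed=0, plateau=100.0):
    """Zero/flat baseline through cycle 15, then exact doubling, then plateau."""
    f = np.full(n, baseline)
    for c in range(16, n + 1):
        f[c - 1] = baseline + min(amp * 2.0 ** (c - 16), plateau)
    if noise_sd:
        f = f + np.random.default_rng(seed).normal(0, noise_sd, n)
    return make_curve(f)


class TestNormalize:
    def test_peak_maps_to_100_and_baseline_stats_kept(self):
        f = np.concatenate([np.full(15, 10.0), [30.0, 60.0, 110.0], np.full(22, 110.0)])
        norm = normalize(make_curve(f))
        assert norm.baseline_mean == pytest.approx(10.0)
        assert norm.max_raw == pytest.approx(100.0)
        assert norm.values.max() == pytest.approx(100.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        f = np.concatenate([rng.normal(10, 0.3, 15), np.geomspace(12, 300, 25)])
        a = normalize(make_curve(f))
        b = normalize(make_curve(f + 55.5))
        assert a.values == pytest.approx(b.values)
        assert a.baseline_sd == pytest.approx(b.baseline_sd)

    def test_idempotent_on_normalized_values(self):
        curve = doubling_curve(noise_sd=0.01, baseline=10.0, seed=5)
        once = normalize(curve)
        again = normalize(make_curve(once.values))
        assert again.values == pytest.approx(once.values, abs=1e-9)

    def test_flat_curve_flagged(self):
        norm = normalize(make_curve(np.full(20, 7.0)))
        assert norm.flat
        assert not call_cq(norm).positive

    def test_too_short_curve_rejected(self):
        with pytest.raises(ValueError):
            normalize(make_curve(np.arange(10.0)))


class TestCallCq:
    def test_noisy_ntc_negative(self):
        f = 10.0 + np.random.default_rng(3).normal(0, 0.5, 40)
        r = call_cq(normalize(make_curve(f)))
        assert not r.positive and r.cq is None

    def test_exact_crossing_at_cycle_value(self):
        """A curve whose cycle-20 value equals the threshold exactly."""
        f = np.zeros(40)
        f[:15] = [10.0, 10.1] * 7 + [10.0]  # baseline mean ~10.05, sd ~0.052
        norm0 = normalize(make_curve(f))
        thr = 10.0 * norm0.baseline_sd
        f[19] = norm0.baseline_mean + thr  # cycle 20 exactly at threshold
        f[20:] = norm0.baseline_mean + np.geomspace(2 * thr, 500, 20)
        r = call_cq(normalize(make_curve(f)))
        assert r.positive
        assert r.cq == pytest.approx(20.0, abs=1e-9)

    def test_fractional_cq_near_linear_oracle(self):
        curve = doubling_curve(baseline=10.0, noise_sd=0.05, seed=8)
        norm = normalize(curve)
        r = call_cq(norm)
        v = norm.subtracted
        i = int(np.argmax(v >= r.threshold))
        lin = (i + 1) - (v[i] - r.threshold) / (v[i] - v[i - 1])
        assert r.cq == pytest.approx(lin, abs=0.25)

    def test_affine_invariance(self):
        curve = doubling_curve(baseline=10.0, noise_sd=0.05, seed=1)
        r1 = call_cq(normalize(curve))
        r2 = call_cq(normalize(make_curve(3.0 * curve.fluorescence + 17.0)))
        assert r2.cq == pytest.approx(r1.cq, abs=1e-6)

    def test_zero_baseline_sd_uses_floor_with_warning(self):
        curve = doubling_curve(baseline=5.0)
        with pytest.warns(UserWarning, match="floor"):
            r = call_cq(normalize(curve))
        assert r.positive

    def test_quantification_time_interpolated(self):
        curve = doubling_curve(baseline=10.0, noise_sd=0.05, seed=4)
        ts = 22.0 * np.arange(1, 41)
        curve = AmplificationCurve(curve.cycles, curve.fluorescence, timestamps=ts)
        r = call_cq(normalize(curve))
        assert r.quantification_time_s == pytest.approx(22.0 * r.cq, rel=1e-6)


class TestSingleSampleEfficiency:
    def _norm_geometric(self, ratio, n=40, start=16):
        v = np.zeros(n)
        for c in range(start, n + 1):
            v[c - 1] = 0.01 * ratio ** (c - start)
        return NormalizedCurve(
            values=v,
            cycles=np.arange(1, n + 1),
            baseline_mean=0.0,
            baseline_sd=0.001,
            max_raw=float(v.max()),
        )

    def test_perfect_doubling_recovers_two(self):
        norm = self._norm_geometric(2.0)
        eff = single_sample_efficiency(norm, cq=20.0)
        assert eff.efficiency == pytest.approx(2.0, abs=1e-9)
        assert eff.window == (18, 19, 20, 21, 22)
        assert eff.r_squared == pytest.approx(1.0)

    @pytest.mark.parametrize("ratio", [1.1, 1.3, 1.5, 1.7, 1.9, 2.0])
    def test_exact_geometric_recovery(self, ratio):
        norm = self._norm_geometric(ratio)
        eff = single_sample_efficiency(norm, cq=22.0)
        assert eff.efficiency == pytest.approx(ratio, abs=1e-9)

    def test_constant_window_gives_unity(self):
        v = np.concatenate([np.zeros(15), np.full(25, 40.0)])
        norm = NormalizedCurve(v, np.arange(1, 41), 0.0, 0.001, 40.0)
        assert single_sample_efficiency(norm, cq=25.0).efficiency == pytest.approx(1.0)

    def test_window_shifts_past_nonpositive_values(self):
        norm = self._norm_geometric(2.0, start=20)
        eff = single_sample_efficiency(norm, cq=20.0)
        assert eff.window_shifted
        assert eff.window[0] >= 20
        assert eff.efficiency == pytest.approx(2.0, abs=1e-9)

    def test_error_when_no_positive_window(self):
        v = np.concatenate([np.zeros(38), [1.0, 2.0]])
        norm = NormalizedCurve(v, np.arange(1, 41), 0.0, 0.001, 2.0)
        with pytest.raises(ValueError):
            single_sample_efficiency(norm, cq=20.0)


class TestStandardCurve:
    def _samples(self, slope, intercept=38.0, concs=(5, 4, 3, 2, 1), reps=2, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for lc in concs:
            for _ in range(reps):
                cq = intercept + slope * lc + (rng.normal(0, jitter) if jitter else 0.0)
                out.append((float(lc), CqResult(cq=cq, positive=True, threshold=1.0)))
        return out

    def test_doubling_slope_gives_efficiency_two(self):
        sc = standard_curve(self._samples(slope=-math.log(10) / math.log(2)))
        assert sc.efficiency == pytest.approx(2.0, abs=1e-9)
        assert sc.r_squared == pytest.approx(1.0)

    def test_negatives_excluded_and_counted(self):
        samples = self._samples(slope=-3.3)
        samples.append((0.0, CqResult(cq=None, positive=False, threshold=1.0)))
        sc = standard_curve(samples)
        assert sc.n_excluded_negative == 1

    def test_requires_three_distinct_concentrations(self):
        with pytest.raises(ValueError):
            standard_curve(self._samples(slope=-3.3, concs=(2, 1)))

    def test_points_summarize_mean_and_sd(self):
        sc = standard_curve(self._samples(slope=-3.3, jitter=0.1, seed=7))
        assert len(sc.points) == 5
        for _, _, sd in sc.points:
            assert sd > 0


class TestCycleTimeAndLod:
    def _records(self, durations, start_cycle=1):
        return [
            CycleRecord(i, d / 2, d / 2, 0.0, 0.0)
            for i, d in enumerate(durations, start=start_cycle)
        ]

    def test_constant_durations(self):
        recs = self._records([22.5] * 12)
        s = average_cycle_time(recs)
        assert s.mean_s == pytest.approx(22.5) and s.sd_s == 0.0
        assert s.n_cycles == 10

    def test_hand_computed_mean(self):
        recs = self._records([99.0] + list(range(20, 30)))  # cycles 2..11 are 20..29
        assert average_cycle_time(recs).mean_s == pytest.approx(24.5)

    def test_first_cycle_excluded(self):
        a = self._records([50.0] + [22.0] * 11)
        b = self._records([5.0] + [22.0] * 11)
        assert average_cycle_time(a).mean_s == average_cycle_time(b).mean_s

    def test_insufficient_cycles(self):
        with pytest.raises(ValueError):
            average_cycle_time(self._records([22.0] * 5))

    def _cq(self, positive):
        return CqResult(cq=30.0 if positive else None, positive=positive, threshold=1.0)

    def test_lod_is_lowest_fully_positive_concentration(self):
        results = {
            10.0: [self._cq(True)] * 4,
            1.0: [self._cq(True)] * 4,
            0.1: [self._cq(False)] * 4,
        }
        assert lod_call(results).lod == pytest.approx(1.0)

    def test_partial_positivity_excluded(self):
        results = {1.0: [self._cq(True)] * 3 + [self._cq(False)]}
        assert lod_call(results).lod is None

    def test_all_negative_returns_none(self):
        res = lod_call({1.0: [self._cq(False)] * 4})
        assert res.lod is None
        assert res.positivity == ((1.0, 0, 4),)


class TestSimulatedRecovery:
    def test_standard_and_single_sample_estimates_agree(self):
        """The window-of-linearity estimator and the standard-curve slope
        are independent routes to the same per-cycle efficiency; on
        simulated data at E = 2 their estimates agree within 10 %
        (single-sample values averaged over replicates)."""
        concs = [10.0**k for k in range(5, -2, -1)]
        runs = simulate_dilution_series(concs, n_replicates=4, n_ntc=0, seed=5)
        samples, singles = [], []
        for conc, curve in runs:
            norm = normalize(curve)
            r = call_cq(norm)
            samples.append((math.log10(conc), r))
            if conc == 1e5:
                singles.append(single_sample_efficiency(norm, r.cq).efficiency)
        sc = standard_curve(samples)
        assert abs(np.mean(singles) - sc.efficiency) / sc.efficiency < 0.10

    def test_monotone_cq_with_template(self):
        runs = simulate_dilution_series([1e5, 1e3, 1e1], n_replicates=1, n_ntc=0, seed=3)
        cqs = [call_cq(normalize(curve)).cq for _, curve in runs]
        assert cqs[0] < cqs[1] < cqs[2]
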