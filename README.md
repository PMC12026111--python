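# adaptivepcr

Adaptive PCR cycling control, photothermal thermocycler simulation, and qPCR
quantification.

## The problem

Conventional PCR instruments cycle between preset temperatures on preset
schedules, which makes them sensitive to calibration, ambient conditions and
sample impurities that shift DNA hybridization.  *Adaptive* PCR replaces the
preset schedule with direct optical feedback: fluorophore/quencher-labelled
**L-DNA** sensor duplexes (mirror-image stereoisomers that hybridize exactly
like natural DNA but are invisible to polymerases) are added to the reaction.
A *melt sensor* matching the target's melting behaviour brightens as it
denatures during heating; an *anneal sensor* matching the primers dims as it
re-hybridizes during cooling.  The controller watches whichever sensor is
informative for the current phase and switches from heating to cooling (and
back) exactly when the chemistry says the transition is complete — no
temperature measurement required.  Combined with infrared laser heating this
supports ~15-minute, 40-cycle PCR in standard tubes.

This package is for instrumentation and assay developers who want to study,
tune or regression-test that control algorithm and its companion analysis
methods without hardware: it provides the controller itself, a closed-loop
simulator of the laser-heated instrument to exercise it, and the standard
qPCR quantification stack.

## What is implemented

- **`adaptive_control`** — the cycling algorithm.  The watched channel's
  fluorescence is smoothed (centered moving average), differentiated
  (central differences), and a Gaussian `a·exp(−(t−μ)²/2σ²) + c` is fitted
  to the derivative bell.  The phase switches at the predicted time
  `t* = μ + α·σ` (default α = 2, i.e. the derivative has decayed to
  `exp(−α²/2) ≈ 13.5 %` of its peak).  Because only the derivative's shape
  matters, control is invariant to fluorescence gain and offset.
- **`instrument_sim`** — a lumped-parameter closed loop: constant-rate laser
  heating (2.41 °C/s) and Newtonian cooling calibrated to a 2.49 °C/s mean
  rate, two-state logistic sensor melt models, logistic amplification
  chemistry with a hydrolysis (TaqMan-style) probe signal, 30 Hz sampling
  with Gaussian detector noise, and optional per-channel nanorod blocking.
- **`qpcr_analysis`** — normalization to a 0–100 scale (baseline = mean of
  cycles 1–15), Cq at 10 baseline SDs with monotone-spline fractional
  interpolation, quantification time from timestamps, LinRegPCR-style
  window-of-linearity single-sample efficiency (`slope of ln F = ln E` over
  5 cycles centered on Cq), standard curves (`E = 10^(−1/slope)`), cycle-time
  summaries, and limit-of-detection calls.
- **`oligo_thermo`** — salt-adjusted oligo melting temperatures
  (`Tm = 100.5 + 41·GC/N − 820/N + 16.6·log10([Na+])` for N > 13) and the
  reference sensor/primer/target sequence set.
- **`optics`** — Beer–Lambert transmittance `T = 10^(−ε·c·L)`, concentration
  rescaling `T_new = T_ref^(c_new/c_ref)`, and the gain-curve-averaged
  fluorescence-blocking metric for gold-nanorod interference.
- **`io` / `cli`** — CSV/JSON carriers, deterministic fixture generation,
  and a `adaptivepcr` command-line tool (`tm`, `optics`, `simulate`,
  `control`, `analyze`, `standard-curve`, `fixtures`).

## Worked example

Simulate a full 40-cycle run at 10⁵ template copies/µL under adaptive
control, then quantify it:

```python
from adaptivepcr import (SimulationConfig, ChemistryParams, simulate_run,
                         normalize, call_cq, single_sample_efficiency,
                         average_cycle_time, switch_stats)

cfg = SimulationConfig(chemistry=ChemistryParams.from_concentration(1e5), seed=42)
run = simulate_run(cfg)
norm = normalize(run.amplification)
cq = call_cq(norm)
eff = single_sample_efficiency(norm, cq.cq)
ct = average_cycle_time(run.cycle_records)
st = switch_stats(run)
```

which prints (via the obvious `print` statements):

```
cycles completed : 40
Cq               : 18.78
quantification   : 11.98 min
efficiency (WoL) : 1.91  (window (17, 18, 19, 20, 21))
cycle time       : 37.60 +/- 0.04 s (cycles 2-11)
heating/cooling time SD (cycles 2-16): 0.031 / 0.038 s
```

Reading: the simulated reaction crossed the 10-SD threshold at fractional
cycle 18.8 (≈12 min of instrument time), the window-of-linearity estimator
recovered a per-cycle amplification factor near the configured E = 2, and
the controller's cycle-to-cycle timing was stable to tens of milliseconds —
the property that makes derivative-based switching viable at 30 Hz.

The same things are available from the shell:

```bash
adaptivepcr tm ACTGGGTTTTACAAACCTGTGA          # -> Tm=58.4 C
adaptivepcr simulate --copies-per-ul 1e5 --seed 42 --out run/
adaptivepcr analyze run/run_amplification.csv
```

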