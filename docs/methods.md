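# Methods

This note records the models behind `adaptivepcr`, the parameters that
matter, and the numerical and design choices made where more than one
reasonable option existed.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Oligo thermodynamics

Melting temperatures use the classic salt-adjusted formulas.  For oligos of
length N ≥ 14:

    Tm = 100.5 + 41·GC/N − 820/N + 16.6·log10([Na+])

and for N ≤ 13 the Wallace-rule variant
`Tm = 2·(A+T) + 4·(G+C) − 16.6·log10(0.05) + 16.6·log10([Na+])`.
The default `[Na+]` is 50 mM — master-mix salt contents are typically
proprietary, and 50 mM reproduces the reference sensor/primer values
exactly; it is configurable.  The threshold between the two branches (13 nt)
follows the web-calculator convention this formula set comes from.  For the
two long reference oligos (77 and 83 nt) this implementation lands ~0.2 °C
away from their historically reported values; the discrepancy is a known
counting quirk of the original web tool, so the tests assert ±0.3 °C there
rather than forcing agreement.  Nearest-neighbor thermodynamics are out of
scope.  Fluorophore/quencher labels and chirality (D vs L) are metadata
only; L-DNA hybridizes identically to D-DNA, which is the entire point of
using it as an optically-labelled sensor.

Sensor melting is modelled two-state: single-stranded fraction
`f_ss(T) = 1/(1 + exp(−(T − Tm)/w))`, with transition width `w` defaulting
to 2.5 °C — a free parameter chosen as a realistic duplex transition width;
nothing downstream is sensitive to it except the sharpness of the derivative
bell the controller sees.

## Optics

Beer–Lambert arithmetic is decadic (`T = 10^(−ε·c·L)`) because the
instrument literature reasons in absorbance; helpers convert natural ↔
decadic.  Nanorod extinction coefficients and tube path lengths are inputs,
not constants: vendors keep coefficients proprietary, so
`calibrate_attenuation` derives an effective ε from any one measured or
published transmission fraction, and concentration rescaling
(`T^(c_new/c_ref)`) then needs no geometry at all.  Tube geometry is reduced
to scalar path lengths; wavelength-resolved plasmon spectra, scattering and
ray tracing are out of scope.  Fluorescence blocking is the mean
sample/control ratio across an LED gain-response curve; gain settings where
the control reads zero are excluded and counted.

## Instrument simulator

A zero-dimensional (lumped) thermal model: heating is linear at
`heat_rate` (default 2.41 °C/s, laser-dominated) clipped at `t_max`;
cooling is Newtonian relaxation toward ambient with the rate constant
chosen so the *mean* rate over `[t_max, t_min]` equals `cool_rate`
(default 2.49 °C/s) — instruments of this type report only mean ramp rates.
Defaults: ambient 21.5 °C, `t_min` 52 °C, `t_max` 97 °C.  `t_min`/`t_max`
are simulator conveniences bounding the trajectory, not claims about the
real instrument, whose switching is temperature-free by design.  Spatial
heterogeneity (laser heating from one side, cooling from the outside in) is
deliberately not modelled.

Chemistry is logistic: `copies' = copies·(1 + (E−1)·(1 − copies/K))` with
per-cycle efficiency E ∈ (1, 2] (default 2.0) and carrying capacity K
(default 2×10¹³ copies).  The probe signal is a hydrolysis model — the
reference assay uses a TaqMan-style probe — so fluorescence is cumulative
(`probe_gain` per newly synthesized copy, default 10⁻¹¹ a.u.) and saturates
at `probe_total` (default 100 a.u., a finite probe pool).  Template input is
`copies/µL × 20 µL` (the standard reaction volume), taken as the exact
expected copy number: sub-Poisson sampling of very dilute templates is *not*
simulated, so the simulated limit of detection is the lowest concentration
carrying at least one expected copy per reaction, whereas real reactions
near one copy per tube show stochastic false negatives.  With the defaults,
a 10⁵ copies/µL reaction crosses threshold near cycle 19 and a 10⁻¹
copies/µL reaction (2 copies) near cycle 39, inside a 40-cycle run.

Detection: four channels at 30 Hz.  Yellow = melt sensor, orange = anneal
sensor (each `baseline + span·f_ss(T)`), green = probe baseline + cumulative
probe signal (constant within a cycle, read at each cool→heat switch), red
unused.  Gaussian detector noise (default SD 0.5 a.u. against a 100 a.u.
sensor span) is applied per sample, then optional per-channel blocking
multipliers (nanorod attenuation).  All randomness flows from one
`numpy` generator seeded by the config, so runs are bitwise reproducible.

A fast path (`simulate_amplification`, `simulate_dilution_series`) runs the
per-cycle chemistry and detector model without the 30 Hz thermal loop —
orders of magnitude faster, and exactly consistent with the closed loop's
green readings in the noiseless case (asserted in the tests).  Dilution
series default to the reference design: 10⁵…10⁻¹ copies/µL, 4 replicates,
plus no-template controls, with replicate seeds spawned from one seed
sequence.

## Cycling controller

State machine HEATING → COOLING → HEATING…, watching yellow while heating
and orange while cooling.  Per phase:

1. **Smoothing/derivative** — centered moving average (`smooth_window` = 7
   samples ≈ 0.23 s at 30 Hz; the filter itself is a design choice) followed
   by central differences, sign-adjusted so the expected bell points up.
2. **Peak detection** — the derivative must decline for ≥ 3 consecutive
   smoothed samples, the maximum must be interior, and it must stand
   ~3 robust SDs (median/MAD) above the phase median.  This pre-filter is
   deliberately permissive; it only skips obviously flat stretches.
3. **Gaussian fit** — nonlinear least squares of `a·exp(−(t−μ)²/2σ²) + c`,
   initialized from the empirical extremum, half-width at half-maximum and
   early samples (warm-started from the previous fit thereafter).  A fit is
   rejected as degenerate if σ falls below half the smoothing-window span
   (features narrower than the kernel are unresolvable noise), if the
   amplitude is non-positive, if it beats a flat line by nothing, or if the
   fitted amplitude is within `peak_snr` (= 6) robust SDs of the fit
   residuals.  All guards are ratio tests, preserving gain/offset
   invariance.
4. **Switch decision** — predicted switch `t* = μ + α·σ` with α = 2 by
   default ("derivative approaches zero" is not otherwise quantified; at
   α = 2 the derivative has decayed to ≈13.5 % of peak).  A switch fires at
   the first sample with `t ≥ t*`, provided `t* ` is not before the observed
   peak, at least `min_phase_s` (2 s) has elapsed, and two consecutive fits
   agreed on `t*` within `prediction_tol_s` (0.2 s) — transient fits to
   noise ripples do not produce stable predictions, real transitions do.
   Refits run on every sample within `refit_margin_s` (0.5 s) of the
   predicted switch and every `refit_stride` (5) samples otherwise, purely
   as a throttle; predictions far from the switch change negligibly between
   samples.  Fits use at most the trailing 400 derivative samples — the flat
   head of a long phase adds no information.
5. **Bookkeeping** — heat→cool emits a melt switch point; cool→heat takes
   the green PCR reading (a single sample, at the switch), emits an anneal
   switch point and closes the cycle.  A phase exceeding `timeout_s` (60 s)
   without a valid switch is a control error and aborts the run with a
   diagnostic — the failure mode heavy fluorescence blocking produces.

**Known bias.**  The derivative of a logistic melt transition is a sech²
bell with heavier shoulders than a Gaussian.  The least-squares Gaussian
therefore predicts `μ + 2σ` slightly *early* relative to the true
13.5 %-of-peak crossing — by ≈ 0.25·s, where s is the transition time scale
(≈ 1 s under the default thermal model, i.e. ≈ 0.25 s early).  The bias is
conservative (the controller never switches late because of it) and
vanishes for transitions sharp relative to the sampling interval; the test
suite asserts one-sample agreement with a fit-free threshold oracle on
sharp logistic traces (s ≤ 0.2 s) and bounds the bias at realistic width.

`switch_stats` summarizes cycle-to-cycle stability over cycles 2–16 (first
cycle excluded for its arbitrary starting temperature, later cycles because
probe fluorescence rises): mean switch-point fluorescence per kind, per-cycle
deviations, and heating/cooling duration SDs.

## qPCR quantification

- **Normalization** — baseline = mean of cycles 1–15 (always, even if the
  crossing lands earlier — a warning flags that case); values scaled to
  0–100 by the post-subtraction maximum.  A curve with no signal above
  baseline is flagged flat and called negative.
- **Cq** — threshold `10 × baseline SD` applied on the baseline-subtracted
  (raw-unit) scale; the SD is computed on raw values (equivalent up to the
  common scale factor).  The fractional crossing comes from a
  shape-preserving monotone cubic (PCHIP) spline through the cycles around
  the first crossing, root-found with Brent's method; PCHIP cannot
  overshoot between points the way a natural cubic spline can, and a
  linear-interpolation oracle is kept in the tests (agreement within 0.25
  cycles asserted over 100 random curves).  A zero baseline SD — possible
  only on idealized synthetic data — is replaced by a configurable floor
  (10⁻³ a.u.) with a warning.  Note the threshold is anchored by *detector
  noise*; on perfectly noiseless curves the baseline SD is driven by early
  signal growth, which makes the call scale-invariant and hence degenerate
  across template concentrations.  Recovery tests therefore run at the
  default noise level.
- **Quantification time** — linear interpolation of the per-cycle
  timestamps at the fractional Cq.
- **Single-sample efficiency** — OLS of `ln(normalized F)` vs cycle over 5
  cycles centered on the nearest cycle to Cq (half-cycles round up);
  `E = exp(slope)`.  Non-positive values in the window shift it upward
  minimally, with the shift recorded on the result.
- **Standard curve** — OLS of Cq on log10 concentration over all positive
  replicates (negatives excluded and counted; ≥ 3 distinct concentrations
  required); `E = 10^(−1/slope)` by the standard convention.
- **Cycle time** — mean ± SD over cycles 2–11 inclusive (first cycle
  excluded for its environmental starting temperature).
- **LoD** — the lowest concentration at which every replicate is positive,
  reported with the full positivity table.

## What the simulator does and does not show

Passing tests demonstrate that the controller and estimators behave
correctly against a *faithful but idealized* physical model: lumped
thermals, exact logistic chemistry, white detector noise, deterministic
template input.  They do not exercise spatial temperature gradients,
evaporation, probe photobleaching, polymerase inhibition, Poisson template
sampling, or correlated detector drift — all of which affect real
instruments.  In particular, simulated switch-time SDs (tens of
milliseconds) are better than any real instrument's, and the simulated LoD
is deterministic where a real one is stochastic.

## Problem sizes

The default test and acceptance workloads were sized for quick desk runs:
closed-loop simulations use 40 cycles at 30 Hz (single runs), dilution
series use the 7-decade × 4-replicate design via the fast path, and oracle
sweeps use 100–200 random cases.  All are pure functions of their seeds.
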