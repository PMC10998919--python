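# Methods

`voltpls` is a desk-top emulation and analysis toolkit for a multi-analyte
electrochemical sensing workflow: fast-Fourier-transform square-wave
voltammetry (FFT-SWV) on a g-C₃N₄–CNT modified glassy-carbon electrode,
resolved into morphine (MOR), methadone (MET) and uric acid (UA)
concentrations by partial least squares (PLS) multivariate calibration.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic data can and cannot establish.

## Signal model

A sweep over the 0–1.1 V anodic window is modelled as

```
i(E) = background(E) + Σ_peaks h_p · exp(−(E − E_p)² / 2w²) + ε(E)
```

* **Peaks.** Each analyte contributes Gaussian anodic peaks at fixed
  potentials (MOR 0.39 and 0.81 V, MET 0.73 V, UA 0.34 V on the modified
  sensor; 0.42/0.83, 0.79, 0.33 V on the plain-CNT sensor). A Gaussian with
  default SD `w = 30 mV` is a smooth, additive surrogate for a net SWV
  peak; it is configurable per peak. The UA/MOR₁ pair (50 mV apart) and the
  MET/MOR₂ pair (80 mV apart) overlap strongly — the reason the calibration
  is multivariate.
* **Heights.** For concentration `c > 0`, `h = (m·c + b) × f(conditions)`,
  where `(m, b)` are the per-peak calibration slope and intercept embedded
  in the sensor profile. Including the intercept in the height means a
  noiseless univariate refit returns the embedded line exactly. At `c = 0`
  the peak is absent entirely (a blank carries no faradaic signal). A
  consequence worth knowing: the mixture signal is exactly additive across
  *different* analytes, but splitting one analyte's concentration across two
  scans double-counts its intercept, so same-analyte additivity holds only
  for the `m·c` part.
* **Background.** A deterministic quadratic ramp plus one sinusoid of
  period ≥ 0.5 V (default 0.7 V), both scaled by `drift_amplitude`
  (default 2 current units). This gives the filtering/blank-subtraction
  stage structured low-frequency interference to remove.
* **Noise.** I.i.d. Gaussian per grid point, `white_sd` default
  0.15 current units. Divided by the four calibration slopes
  (0.78–2.19 units/µM) this corresponds to roughly 0.1 µM single-point
  concentration precision, the intended realism level for the study
  conditions. Identical seeds give identical realizations.
* **Grid.** 0 → 1.1 V in 2 mV steps (551 points), matching the scan
  window; all printed peak potentials fall exactly on this grid.

## Condition response

Peak heights are scaled by a factor in [0, 1] that is 1.0 at the operating
optimum (pH 8, 120 s accumulation, 256 Hz, 20 mV) and on each peak's
observed plateau, ramps linearly up to the plateau, and decays linearly
beyond it. Hard zeros encode the no-response thresholds: MET and the second
MOR peak below pH 6, UA below pH 5, the first MOR peak below pH 4.
Plateaus per peak: accumulation 120 s (MOR, MET) / 90 s (UA); frequency
256–354 Hz (MOR₁), 177–256 Hz (MOR₂, MET), 256–443 Hz (UA); amplitude
15–25 mV (MOR peaks, MET), 10–20 mV (UA). The ramps are piecewise-linear
by choice — only the plateau membership and monotone decay are meaningful;
the slopes are not calibrated against any instrument.

The plain-CNT profile reuses the modified sensor's slopes and intercepts
scaled by 0.6 (the unmodified electrode shows the same peaks with lower
currents); it exists for qualitative comparison demos only.

## FFT processing

Denoising is an ideal brick-wall low-pass on the real DFT of the
current-vs-potential series: harmonics above `cutoff_fraction × n/2`
(default 0.1 of Nyquist) are zeroed. At the default grid this keeps
≤ 25 cycles/V — the background (≈ 1.4 cycles/V) and the Gaussian peaks
(spectral SD ≈ 5.3 cycles/V) pass essentially intact while ~90% of the
white-noise power is removed. The filter is linear and idempotent and
therefore commutes with blank subtraction when the blank is filtered with
the same spec. No padding or windowing is applied: simulated signals start
and end near zero, so edge effects are negligible; strongly non-periodic
real traces would need tapering (a known limitation).

"Two-dimensional integration" of a response is realized as a trapezoidal
integral over a potential window, with replicate sweeps averaged first
when present. The default PLS features are, however, full filtered,
blank-subtracted current vectors (one column per grid point); per-peak
window integrals are available as an alternative feature mode for
univariate work.

A numerical consequence of the brick-wall filter: it truncates a few
×10⁻⁵ of a Gaussian peak's height, so the exact-refit pathway used to
verify the embedded calibration lines bypasses the filter (blank
subtraction alone is exact for noiseless scans). The end-to-end pipeline
keeps the filter on.

## Univariate calibration

Straight lines are fit by ordinary least squares; R² = 1 − SS_res/SS_tot.
The blank standard deviation `S_b` uses the n−1 sample SD of ≥ 3 replicate
blank responses measured against a common reference blank. Detection
limits follow LOD = 3·S_b/m and LOQ = 10·S_b/m, so LOQ/LOD = 10/3
identically. The linear range is reported as the widest contiguous
concentration span (≥ 3 points) whose OLS refit reaches R² ≥ 0.995, a
stated heuristic (no standard rule exists); ties prefer more points, then
the lower endpoint, and if nothing qualifies the best span is returned
flagged.

## PLS calibration

`Y = X·B + E` is fit by NIPALS with deflation of both blocks. Choices:

* **Mean-centering only**, no autoscaling: all features share current
  units, so variance scaling would only amplify noise-dominated columns.
* **Deterministic initialization** from the Y-residual column of maximal
  variance; convergence when successive weight vectors differ by < 1e-10,
  capped at 500 iterations. No randomness anywhere in the fit.
* **Coefficients** `B = W(PᵀW)⁻¹Qᵀ`, predictions
  `ŷ = (x − x̄)B + ȳ`. Negative concentration predictions are reported
  unmodified — spiked-sample tables legitimately contain small negative
  "found before" values, and clipping would bias recovery arithmetic.
* **Rank safeguards.** Requesting more components than
  `min(n−1, p)` — or than deflation can deliver (e.g. a noiseless
  three-analyte signal has rank 3) — is rejected with the attainable
  maximum. Inside leave-one-out loops, exhausted subsets reuse the deepest
  attainable model, since further components cannot change predictions.

Leave-one-out RMSECV is computed per analyte and per LV count (one NIPALS
run per held-out sample, coefficient matrices assembled incrementally per
depth); the brute-force double loop exists independently in the tests as
the oracle. "Pooled" errors average per-analyte values in quadrature.
The LV count is chosen as the smallest whose pooled RMSECV lies within 2%
of the curve minimum — a parsimony rule; an explicit `n_lv` override is
available. On noiseless synthetic designs this selects 3 (the true signal
rank); with default noise, 3–4.

RMSEC/RMSEP are root-mean-square errors on training and test residuals;
R²_pred = 1 − SS_res/SS_tot on the test set.

## Standard addition and recovery

The original-sample concentration is |x-intercept| of the OLS line of
measured (PLS-predicted) concentration vs added spike, times the dilution
factor; non-positive slopes are rejected as signal-free series. Recovery
is `100 × found_after / (found_before + added)` — the standard spiked
convention, which reproduces published spiked-urine rows at their printed
rounding — and RSD is `100 × sample SD / |mean|` over replicates
(five in the pipeline demonstration).

## Interference tolerance

An interferent adds either its own Gaussian peak (sensitivity per µM) or a
flat broadband current, or both. The relative prediction deviation of an
analyte is `|ŷ_with − ŷ_without| / ŷ_without` on noiseless sweeps (a
true-concentration denominator is available as an option). The tolerance
ratio Ci/Ca is found by bisection of deviation = threshold (±5% default)
to 1% relative tolerance, capped at 1000 (the "> 1000" reporting
convention); non-electroactive species always cap. The shipped interferent
set is explicitly illustrative: its gains are synthetic and not calibrated
to any measured tolerance table, which reflects a real sensor property the
simulator has no basis to reproduce.

## Pipeline and reproducibility

`run_paper_emulation` executes design generation (17 train / 12 test by
default, uniform within each analyte's linear range; Latin-hypercube
optional), sweep simulation, feature building, univariate calibration of
all four peaks, LV selection, PLS validation, a standard-addition
demonstration (base sample MOR 2.0 / MET 1.5 / UA 6.0 µM, additions
0/2/4/6 µM, five replicates) and an interference scan. One master seed
feeds a deterministic sub-seed stream for every stochastic step; the JSON
report regenerates byte-identically for a fixed config. All effective
parameter defaults are logged at run start. Reported numbers are stored at
full precision; rounding is applied only at display time.

Problem sizes throughout (551-point grids, 29-sample designs, 8-LV LOO
curves, 20-seed recovery studies) were chosen so any single analysis runs
in seconds on one CPU while leaving the statistics stable.

## What the synthetic data does and does not show

The generator reproduces the *statistical structure* the calibration
assumes — additive linear peaks at the printed potentials with the printed
sensitivities, drifting background, white noise, condition plateaus — but
not electrochemical kinetics, scan-rate effects, peak asymmetry or
saturation above the linear range, electrode fouling, or real urine-matrix
chemistry. Passing tests therefore establish that the processing and
calibration machinery is correct and that the workflow recovers known
concentrations under its own assumptions; they do not certify performance
figures for any physical sensor. In particular, prediction errors on the
synthetic design come out markedly smaller than instrument-grade values at
comparable univariate precision, because 551 grid points with independent
noise average far more favourably than a real sensor's correlated
disturbances.
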