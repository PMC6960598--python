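# Methods

This note documents the models, the synthetic study conditions, the
numerical choices and the limitations of `ppgbp`.  Nothing here reports a
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Synthetic cohort

The generator emulates a bench-top acquisition campaign: synchronized
fingertip PPG and lead-II ECG at 500 Hz in 20 s records, one cuff
reference SBP/DBP pair per record, and per-subject anthropometry.

**Waveform model.** Each pulse is the sum of two Gaussians — a systolic
component centred at 0.30 T with width 0.09 T and a dicrotic component at
0.62 T with width 0.099 T, where T is the cardiac period — scaled by the
dicrotic amplitude ratio (DAR).  Two well-separated components guarantee
a dicrotic notch and peak at every admissible heart rate (widths scale
with T), so all six fiducial landmarks (b, a, c, e, f, g) exist and their
sample positions are computed analytically from the noiseless template
and stored as per-beat truth.  The ECG is a flat baseline with one 20 ms
triangular R-spike per beat, preceding the pulse onset by the transit
time; only R timing matters downstream.  Optional disturbances: baseline
sinusoid (≤ 0.5 Hz), 50 Hz powerline interference, white noise.

**Ground-truth pressure.** Reference pressures follow

    BP = β₀ + β₁/PTT + β₂·HR + β₃·DAR + ε,

with per-target slopes stored on the subject profile (defaults
SBP: β = (8, 0.35, −12), DBP: β = (4, 0.25, −6)) and ε ~ N(0, 1.5 mmHg)
representing cuff measurement noise.  β₀ is fixed so the subject's base
pressures hold at the nominal operating point (PTT 0.20 s, 70 bpm,
DAR 0.45).  The inverse-PTT, HR and DAR families were chosen because they
are the latent quantities the waveform features measure.  Base pressures
are themselves a documented function of anthropometry — SBP:
100 + 1.5·(BMI − 22) + 6·gender + N(0, 3); DBP:
65 + 0.9·(BMI − 22) + 3·gender + N(0, 2.5) — so that BMI and gender carry
genuine between-subject pressure information, as they do in real
cohorts; only the small idiosyncratic offset is unexplainable by the
feature set.  The full BP function is echoed into every record's
metadata, and a regression of noiseless references on the latents
recovers the coefficients to 1e-6 (tested).

**Cohort layout.** The default full-scale layout is 17 training subjects
with 20–64 records each (775 records) and 10 test subjects with 12
records each (120).  Per-record latents vary within subject: HR ~
N(72, 9) bpm clipped to [48, 110], PTT ~ N(0.21, 0.03) s clipped to
[0.12, min(0.32, 0.4 T)], DAR ~ N(0.45, 0.07) clipped to [0.25, 0.65].
All randomness descends from one integer seed through per-subject and
per-record substreams; identical seeds give bit-identical cohorts.

**What the generator does not emulate:** beat-to-beat HR variability
within a record, motion artifacts, waveform morphology changes with
vascular ageing or disease, sensor coupling drift, and arrhythmia.
Passing tests therefore demonstrate the correctness and internal
consistency of the chain under controlled conditions, not clinical
accuracy on real patients.

## Preprocessing

Wavelet-packet denoising uses `coif5`, depth 3, best basis by minimizing
the SURE-entropy cost over the packet tree (ties resolved toward the
parent, i.e. the shallower node), and per-node soft thresholding at the
universal threshold σ√(2 ln N) with σ estimated from the median absolute
deviation of the finest detail coefficients (σ = MAD/0.6745).  The pure
approximation chain is left unthresholded so slow trends survive for the
spline stage; when σ = 0 the signal is reconstructed unchanged.
Baseline correction subtracts a natural cubic spline through the detected
pulse onsets (≥ 4 anchors required).  Natural end conditions bias the two
boundary beats slightly; interior beat amplitudes are preserved within 2%
(tested).

## Fiducial detection

R-peaks: `scipy.signal.find_peaks` with an adaptive amplitude threshold
(median + half the median-to-maximum spread) and a 60/200 bpm refractory
distance.  PPG landmarks per beat window between consecutive R-peaks:
onset b as the last minimal sample between the R-peak (plus a 50 ms
pairing delay) and the systolic peak; a and e as the extrema of the
central-difference first derivative; f as the first local minimum after
e; g as the first local maximum after f.  Beats missing any landmark, or
violating the ordering R < b < a < c < e ≤ f ≤ g, are dropped and
counted with a reason; they are never imputed.  On noiseless synthetic
records every landmark is recovered within ±2 samples and the median
timing error is ≤ 1 sample (tested).

## Features

All amplitudes are measured from the beat foot (PPG value at b); areas
are trapezoidal integrals of the foot-referenced pulse; ratios divide by
the cycle length T = t(next b) − t(b).  The waveform factor defaults to
the conventional K = (S_m − H_b)/(H_c − H_b) (mean height over peak
height); the peak-referenced variant (S_m − H_c)/(H_c − H_b) is available
behind a flag and the choice is recorded in the output metadata.  HR is
reported in bpm from the adjacent R-R interval.  Records aggregate
per-beat features by the median (robust to residual artifacts) and
require at least 3 valid beats.  Gender is coded 0 = female, 1 = male.

## Networks and training

Single hidden layer, tanh hidden / linear output, min-max scaling of
inputs and target to [−1, 1] fitted on training data and stored with the
model.  Parameters live in one flat vector
[W₁ row-major, b₁, W₂, b₂].  The hidden-layer sizing rule is
m = √(n + l) + ∂ with ∂ ∈ [1, 10], rounded half-up, giving m ∈ [5, 14]
for 14 inputs.

Levenberg–Marquardt uses the analytic Jacobian, accepts a step only when
the sum of squared residuals decreases, and follows the
delayed-gratification damping schedule (λ ← 2λ on rejection, λ/3 on
acceptance, λ₀ = 1e-3).  The gentler schedule was adopted after the
classic ×10/÷10 variant stalled in the narrow curved valleys these
networks produce (on a 1-hidden-unit linear toy it plateaus at ~2e-3 RMSE
where the gentle schedule reaches ~6e-6).  Stopping: `max_epochs`
accepted steps, `goal_mse` on the scaled target (default 1e-4), or
damping overflow.  A plain gradient-descent trainer is available via the
config for cross-checks.

## MIV screening

MIV_j is the signed mean, over training samples, of the prediction
difference between the feature column scaled ×1.1 and ×0.9; Eq-style
contributions use |MIV|.  Ties in |MIV| keep original column order.
Screening keeps the smallest ranked prefix whose cumulative contribution
reaches the threshold; two rounds run at 0.91 and 0.89.  MIVs are
computed from a single trained network per round; averaging over k
retrainings is available but off by default.  Screening quality depends
on that network: on small cohorts an overfit screening net can produce
unstable rankings and occasionally drop informative features (see
Limitations).

## MPGA

Binary coding maps `bits_per_variable` bits linearly onto the variable
range (network search: 10 bits over [−0.5, 0.8]; coefficient
calibration: 25 bits, whose quantization step ≈ 4e-8 supports 5-decimal
coefficients).  Per generation and population: linear-ranking fitness
(pressure 2.0), stochastic universal sampling, single-point crossover
with the population's pc ∈ [0.7, 0.9], bit-flip mutation with its
pm ∈ [0.001, 0.05], elitist reinsertion of the previous best, ring
immigration of each population's best into the next population's worst
slot, and archiving of the overall best.  Termination: the archive best
unchanged for `min_preserve_generations` (default 3), or a safety cap.
NaN objectives are treated as +∞ with a warning.  Calibration searches
are warm-started at the uniform blend (0.2 per base model), so elitism
guarantees the calibrated ensemble never trails the equal-weight one on
the calibration set (up to coding quantization).

**Known limitation — Hamming cliffs.** Plain binary coding puts adjacent
real values on distant bitstrings; once all populations have converged
near such a cliff, mutation alone must cross it.  With small budgets
(5 populations × 20) roughly a quarter of seeded runs on a 3-variable
quadratic benchmark stall one cliff short of the optimum; with
10 populations × 30 the optimum (within 0.01 per coordinate) is reached
in ≥ 19/20 seeded runs.  The benchmark tests use the larger budget; the
network pipeline keeps the 5 × 20 study configuration, where exact
convergence of the initial weights is immaterial because LM refines them.

**Network initialization by MPGA.** The chromosome concatenates all
weights and thresholds; fitness is the training RMSE of the decoded
(untrained) network, and the winner is LM-polished by default.  The value
of this initialization is regime-dependent: under a tight LM budget the
genetically selected start clearly beats a random one on held-out records
(median test RMSE 2.89 vs 4.17 mmHg at 5 epochs on the 300-record test
cohort), while with generous budgets both arms converge — or overfit —
and the advantage dissipates.  The property test pins the comparison to
the budget-limited regime where initialization matters.

## Personalization and evaluation

Five base networks per target are trained on fold complements of a
seeded shuffle (fivefold CV), each fold with a fresh MPGA seed.
Calibration fits a₁…a₅ (SBP) and b₁…b₅ (DBP) independently on the
individual's first six records by minimizing calibration RMSE; the
coefficients stay in [−0.5, 0.8] by construction of the decoding (never
by clipping) and are not re-normalized.  Predictions below 40 mmHg raise
a plausibility warning.

Metrics: MAD is the mean absolute difference, STD the n−1 standard
deviation of the error, pooled RMSE combines per-individual RMSEs as
√(Σ nᵢRMSEᵢ²/Σ nᵢ).  AAMI bounds are inclusive (MAD ≤ 5 and STD ≤ 8
mmHg).  BHS cumulative error fractions use inclusive thresholds
(≤ 5/10/15 mmHg).  Bland–Altman differences are predicted minus
measured.

## Pipeline defaults and problem sizes

The demonstration pipeline generates 8 training subjects × 45 records
(360 records) and 4 test subjects × 12 records, screens with an
11-hidden-node network, and uses 5 hidden nodes (the sizing-range lower
end) and a 30-epoch LM budget for the base models — parameter counts are
then well below the available records, which the fold diagnostics showed
to be necessary at this cohort size; larger cohorts support the wider
topologies the sizing rule permits.  The full chain runs in well under a
minute; test-suite cohorts are scaled similarly so the whole suite stays
fast.  All artifacts are CSV/JSON and bit-reproducible per seed.

## Limitations

- Screening instability on small cohorts: a single overfit screening
  network can mis-rank features; one in several seeds degrades the SBP
  model noticeably (the suite pins seeds for reproducibility and the
  behaviour is documented rather than masked).  Averaging MIVs over
  retrainings (available flag) mitigates this at extra cost.
- The integration stage can only rescale base-model outputs; a subject
  whose idiosyncratic pressure offset is large relative to the base
  models' span is corrected only through the coefficient sum.
- Min-max scaling extrapolates linearly outside the training range;
  test subjects with out-of-range features inherit that extrapolation.
- The AAMI/BHS grades computed on synthetic cohorts characterize the
  pipeline under the generator's assumptions only.
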