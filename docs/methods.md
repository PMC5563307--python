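# Methods

`eznet` localizes the epileptogenic zone (EZ) from scalp EEG recorded
*between* seizures. The input is a multichannel recording (the default
montage is the 16-electrode extended 10–20 set at 256 Hz) together with a
table of manually labeled inter-ictal discharge peak times. The output is a
time-varying directed network over the electrodes and the identity of the
electrode whose strong information outflow appears earliest, apart from the
background outflow pattern.

## Preprocessing and epoching

Each recording is common-average referenced, band-pass filtered 0.5–30 Hz
(zero-phase Butterworth, 4th order per pass; family and order are
configurable since only the band is part of the protocol), and cut into 6-s
epochs centered on each labeled discharge peak (time 0, window [−3 s, +3 s),
half-open sample windows, peak index = round(peak_time · fs)). Epochs are
decimated by 8 with a zero-phase anti-aliasing low-pass, so 256 Hz
recordings become 192-sample epochs at 32 Hz with the peak at index 96.
Events closer than 3 s to a recording edge are dropped rather than padded.

Note that both the band-pass and the decimation filter are applied
forward–backward and are therefore acausal: structure concentrated at the
discharge can be smeared backward by a few hundred milliseconds (the
high-pass corner at 0.5 Hz has the longest tail). The localization step
accounts for this in its onset-uncertainty window (below).

## Time-varying MVAR model

Each epoch ensemble is modeled as a time-varying vector autoregression

    X(t) = Σ_{k=1..p} A_k(t) X(t−k) + E(t),

with the coefficient tensor tracked by a Kalman filter in the standard
"update constant" (UC) parameterization: the state is the vectorized
coefficient set, the state transition is a random walk whose process-noise
covariance is UC times the current state covariance, and the per-channel
measurement-noise variance is tracked adaptively from the innovations
(exponential smoothing at rate UC). Because all channels share the same
lagged regressor vector, the filter factorizes into independent
scalar-observation filters per target channel; the implementation runs them
batched (a numba-compiled kernel with a pure-numpy twin of identical
semantics). Initialization is neutral: coefficients at zero, state
covariance at identity, noise variances at the per-channel sample variance;
the first p samples serve only as regressors, so estimates exist for
t = p … N−1.

**Trial pooling.** A single 192-sample epoch cannot support a stable
16-channel fit — M²p coefficients are tracked from an effective window of
~1/UC samples — so reliable time-varying networks require several epochs, as
is standard for time-locked time-varying connectivity. The pipeline
therefore treats all of a patient's discharge epochs as peak-aligned trials
of one time-locked process: at every latency the filter absorbs one update
per trial, shrinking coefficient noise roughly with the trial count and
producing a single per-patient network. Per-epoch analysis plus
majority-vote aggregation of the per-epoch localizations remains available
(`pool_trials=false`).

**Order selection.** The model order p is chosen per epoch by

    AIC(p) = ln det(χ) + 2 M² p / N,    p = 2 … 20,

with χ the residual covariance of a stationary least-squares pre-fit (the
criterion has no time index, so a stationary pre-fit is the natural reading)
and N the epoch length. Two numerical safeguards matter at 16 channels ×
192 samples: χ is the *unbiased* estimate (divisor = residual degrees of
freedom (N−p) − Mp), and the search ceiling is clamped so that at least 4M
residual degrees of freedom remain — beyond that point the log-determinant's
downward small-sample bias makes AIC decrease monotonically and the
criterion meaningless. For 16-channel, 192-sample epochs the effective range
is 2–7. Ties go to the smaller order; the patient-level fit uses the lower
median of the per-epoch selections so all networks share one order.

**Update constant.** The adaptation time constant is ~1/UC samples per
trial, or 1/(UC·K) latencies with K pooled trials. The pipeline default is
UC = 0.02, giving a pooled memory of ~10 samples (0.3 s at 32 Hz) — fast
enough to track coupling that switches on half a second before a discharge,
smooth enough for usable single-trial fits. The library default for direct
`fit_kalman` calls is the conventional 1e-3, appropriate for long
recordings. An optional per-step ridge shrinkage of the coefficient state
(`leak`) is provided but off by default: at strengths that would tame
weakly-excited coefficient directions it visibly biases true coefficients.

## Adaptive directed transfer function

The frequency-domain coefficient matrix is

    A(f, t) = I − Σ_{k=1..p} A_k(t) e^{−j2πfΔt k},

(the identity-minus-lag-sum convention is the only one under which
H(f,t) = A(f,t)⁻¹ is the MVAR transfer matrix), evaluated on a 0.5-Hz grid
from 0.5 to 15.5 Hz by default. H is obtained by batched inversion; points
whose 1-norm condition estimate exceeds 1e12 are flagged unavailable. The
normalized ADTF from sender j to receiver i,

    γ²_ij(f,t) = |H_ij(f,t)|² / Σ_m |H_im(f,t)|²,

sums to one over senders for each receiver. Band integration averages γ²
over the frequency bins inside 0.5–14.5 Hz; the divisor is the in-band bin
count, which keeps Q²_ij(t) in [0, 1] on any grid and coincides with a
literal (f2−f1) divisor on a 1-Hz grid. The total outflow of node j is the
mean of Q²_kj(t) over receivers k ≠ j.

## Surrogate null and binary networks

ADTF has no tractable null distribution, so the null is built empirically:
each surrogate replaces the Fourier phases of every channel independently
with uniform draws (DC and Nyquist keep their real coefficients), preserving
each channel's amplitude spectrum exactly while destroying cross-channel
phase structure, and then runs through the identical Kalman/ADTF estimator —
for pooled fits, every trial is randomized independently and the surrogate
is fitted as an ensemble. 200 surrogates per analysis is the default. The
per-(time, edge) mean and variance of surrogate Q² parameterize a Gaussian
null; an edge is kept when its one-sided upper-tail p-value is below α =
0.01 (only abnormally strong flow is of interest; no multiple-comparison
correction by default, with a Bonferroni option). Zero-variance null cells
degrade to a direct comparison with the null mean; self-edges are always
absent.

Because surrogate data are stationary by construction, the null moments
drift only on the filter's own memory scale; surrogate draws inside a boxcar
window of round(1/UC) samples are therefore pooled when estimating the
per-time moments. This is a pure variance-reduction of the moment estimates
(the per-time structure is kept) and improves the calibration of the
α = 0.01 test, which otherwise suffers both from estimation noise in the
null moments and from the right skew of Q² under the null that a Gaussian
fit undercovers. The acceptance suite measures the resulting edge-wise
false-positive rate on independent-channel fixtures; the residual excess
over the nominal 0.01 is intrinsic to fitting a Gaussian to the skewed Q²
null.

## Localization

Out-degree: k_i(t) = number of significant outgoing edges of electrode i at
latency t. The out-degree matrix is binarized at a threshold of 3; the
strict reading (1 iff k > 3) is the default and `greater_equal` is available
because the protocol's prose leaves k = 3 ambiguous. Electrodes whose
binarized out-degree is active in at least half of the baseline window (the
first second of the analyzed grid, which precedes the peak) form the
*background* set and are excluded from candidacy — they model regions whose
outflow is part of the ongoing pattern rather than newly appearing.

The EZ electrode is the first non-background electrode, scanning forward
from the end of the baseline window, with a *sustained* activation run.
Three robustness elements define "sustained" and "first" in the pipeline:

- **Minimum duration, 1.0 s** (32 samples at 32 Hz). Spurious edges from the
  surrogate test are temporally clustered by the filter's memory and form
  sustained false runs on the sub-second scale, while genuine source
  activation persists from before the discharge through the spike-and-wave
  complex. The low-level `locate_ez` default remains 2 samples for
  protocol-faithful use.
- **Peak anchoring.** Only runs still active at the labeled peak (t = 0)
  qualify: the electrode sought is the source *of the labeled discharge*, so
  an outflow episode that dies out before the discharge is treated as an
  unrelated fluctuation.
- **Onset tolerance.** Onsets are uncertain on the scale of the filter
  adaptation time (1/(UC·K) samples) plus the acausal preprocessing smear
  (~0.25 s); onsets within that window of the earliest one count as
  co-earliest, are all reported as ties, and are ranked by run length, then
  total out-degree over the run. With strict ordering, a marginally earlier
  weak artifact would routinely beat a marginally later strong source.

Aggregation across epochs: in pooled mode there is one localization per
patient; in per-epoch mode a majority vote over epoch-level electrodes with
vote counts reported and ties left unbroken.

## Synthetic data

The generator emulates the structure the analysis assumes rather than a
biophysical head model. Channels carry independent AR(2) backgrounds with a
6-Hz resonance (pole radius 0.95 at 256 Hz) driven by 5-µV Gaussian
innovations. Directed interactions are lag-8 couplings at 256 Hz — exactly
one sample after factor-8 decimation, so the planted structure survives the
protocol's down-sampling as a lag-1 interaction. The planted source (F7 in
the 16-channel preset) starts driving five neighbors (coefficient 0.45)
0.5 s before each spike peak and stops 1 s after; an always-on background
driver (O1 → five posterior neighbors, coefficient 0.25) exercises the
background-exclusion logic. Spikes are biphasic spike-and-slow-wave
templates (70-ms peak of 120 µV, 200-ms wave of opposite sign at half
amplitude) added to the source at zero delay and to other channels with
20–60 ms propagation delays and 0.6 attenuation. Every schedule is validated
for stability via the companion-matrix spectral radius; generation is
sample-by-sample with a 2-s discarded burn-in and fully deterministic under
a seed, including the EDF/CSV/JSON files written.

What the generator does *not* emulate — volume conduction and a realistic
shared reference, non-Gaussian and nonstationary background, artifacts
(ocular, muscle), heavy-tailed innovation bursts — bounds what passing tests
show: they demonstrate that the estimator chain recovers planted directed
structure under the protocol's own assumptions, not performance on clinical
recordings.

Three presets: `null_independent` (16 independent channels, one event, no
couplings — calibration), `two_channel_driver` (minimal directed pair), and
`full16_planted_source` (the full localization scenario, ≥ 5 discharges).

## Numerical choices and degenerate inputs

- Common-average referencing makes the montage exactly rank-deficient; the
  AIC pre-fit floors the residual-covariance spectrum at 1e-12 of its mean
  eigenvalue so the log-determinant stays finite and order-comparable.
- Per-(f,t) inversion failures and ill-conditioned points (1-norm condition
  > 1e12) propagate as unavailable values, never as zeros.
- Zero input leaves Kalman coefficients at their zero initialization (the
  innovation is identically zero); measurement-noise variances are floored
  at 1e-12.
- Surrogate fits that diverge are dropped and counted; a run aborts if more
  than 10% drop.
- A `greater`/`greater_equal` switch covers the out-degree threshold
  boundary; α = 0 and α = 1 behave as the degenerate limits (no edges /
  every off-diagonal edge).
- All randomness flows from explicit seeds (numpy `SeedSequence` spawning
  per stage); localization reports contain no timestamps, so identical
  config + seed reproduces them bit-identically.

## Problem sizes used in the checks

The test suite and the acceptance script exercise the pipeline at the
protocol's native epoch geometry (16 channels, 192 samples at 32 Hz, 5
discharges per synthetic patient) with 50 surrogates per run for the
calibration and recovery studies (20 seeded replicates each) and 200 kept as
the analysis default. Kalman recovery studies use N = 2000 samples.

## Known limitations

- The Gaussian null on Q² is anti-conservative by a factor of ~2–3 at
  α = 0.01 (skewed null); the binarization threshold and persistence
  requirements downstream absorb this, but edge-level inference should not
  be read as exact 1% control.
- The surrogate null destroys *all* cross-channel structure, so any genuine
  standing dependence (a strong background driver, common-reference mixing)
  inflates apparent connectivity against it; with single short epochs this
  produced spurious sustained outflow from strongly driven receivers, and it
  is the main reason the pipeline pools trials.
- Out-degree localization resolves to the electrode, not to cortical
  sources; no inverse modeling is attempted.
- Automatic spike detection is out of scope; discharge peaks come from the
  event table.
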