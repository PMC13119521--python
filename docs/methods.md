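# Methods

## The problem and the model

Mobile EEG recorded during free full-body movement (sports, everyday
activity) is contaminated by transient, high-amplitude, non-periodic motion
artefacts that overlap spectrally with brain activity, so band-pass
filtering cannot separate them. `gedclean` treats the recorded signal as a
linear mixture

    X = A_b S_b + A_m S_m

of brain sources `S_b` and motion sources `S_m` mixed onto `C` channels by
matrices `A_b`, `A_m`. Two conditions are assumed available per subject:
*rest* recordings `X_r` with no motion term (the reference) and *motion*
recordings `X_m` containing artefacts. The statistical contrast between
their channel covariances identifies the artefact subspace.

## Denoising by generalized eigenvalue decomposition

The method finds spatial filters `w` maximizing the variance ratio

    lambda = (w' C_m w) / (w' C_r w),

i.e. it solves the generalized eigenproblem `C_m W = C_r W Lambda`. The
solver whitens by `C_r` (symmetric reduction via its inverse square root,
guaranteeing a real spectrum) and normalizes filters so `W' C_r W = I`;
each eigenvalue is then directly the motion/rest variance ratio of its
component, sorted descending, with a deterministic sign convention (the
largest-magnitude filter entry is positive). Component time courses are
`Y = W' X`; reconstruction patterns are `W^{-T} = C_r W`. Denoising zeroes
the flagged rows of `Y` and back-projects: `X_hat = W^{-T} Y_hat`. The
removed signal is stored as `X - X_hat`, so the additive decomposition is
exact to machine precision.

Covariances are estimated on non-overlapping 1 s windows (local mean
removed, `1/(N-1)` scaling), lightly regularized by trace-normalized
diagonal loading `(1-g)S + g (tr S / C) I` with `g = 1e-6` (interpolated
channels make window covariances rank-deficient), and aggregated with the
affine-invariant Riemannian (Karcher/Frechet) mean, which is robust to the
heavy-tailed variance bursts that artefacts induce. The rest aggregate
pools the windows of all available rest recordings and can be stored and
reused unchanged across an experiment (the operational mode).

### Karcher mean numerics

The mean is computed by the fixed-point flow
`M <- M^{1/2} exp(step * mean_i log(M^{-1/2} S_i M^{-1/2})) M^{1/2}`,
initialized at the arithmetic mean, stopped when the tangent-space mean
norm falls below `1e-8`. The step is halved whenever the tangent norm
grows and recovers gradually (x1.2, capped at 1) while it shrinks: on
widely spread inputs — burst windows carry ~100x the power of quiet
windows — the plain step-1 iteration oscillates or diverges, and the
measured linear rate can be as slow as ~0.7 per iteration, so the
iteration budget is capped at 500 (typical inputs converge in under 100).
The tangent norm also has a data-dependent round-off floor: near-singular
windows (low-rank EEG mixtures with 1e-6 diagonal loading at 64 channels)
leave ~2e-7 of evaluation noise, below any usable tolerance, so a flow
that stops improving returns its best iterate as converged provided the
residual is already below 1e-5 — far below covariance-level relevance —
and raises otherwise. Near the fixed point convergence is superlinear; at
the default tolerance the two-matrix mean agrees with the closed-form
geodesic midpoint `A^{1/2}(A^{-1/2} B A^{-1/2})^{1/2} A^{1/2}` to ~1e-14.

## Artefact-component identification

Three detectors operate on the descending eigenvalue spectrum, and only
components flagged by **all three** are zeroed:

1. **Robust outlier (MAD).** Flag `i` iff
   `(lambda_i - median) / (1.4826 MAD) > 3`, one-sided upper; an IQR
   fallback (scale `IQR/1.349`) covers a vanishing MAD.
2. **Kneedle elbow.** The descending curve is min-max normalized and
   flipped into the canonical concave-increasing form; the difference from
   the diagonal `d(x) = (1 - x) - y_norm(x)` peaks at the knee. The knee is
   declared only when the peak exceeds `S/(n-1)` with sensitivity `S = 1`
   (a linear spectrum yields no knee); components strictly above the knee
   are artefactual, the knee itself is the first retained component.
3. **Empirical null.** The rest windows are repeatedly (B = 200) split
   into two random disjoint halves; each half is Riemannian-averaged and
   the largest generalized eigenvalue between the two half-means is
   recorded. Eigenvalues above the empirical 95th percentile
   (linear-interpolated order statistic) of this "no contrast"
   distribution are flagged.

Null-building exploits two exact identities: the Karcher mean is
congruence-equivariant and generalized eigenvalues are
congruence-invariant, so all windows are whitened once by the pooled rest
mean, and each half-mean runs on near-identity matrices warm-started from
matrix logs precomputed once. The half-means stop at a tangent norm of
0.05 (reached after the first flow step on homogeneous rest windows);
against a tightly converged reference this shifts the null's 95th
percentile by under 1%, far below the Monte-Carlo spread of a
200-iteration quantile, and in the conservative direction.

Because the contrast pools twice as many windows (all vs half), the null
is slightly conservative by construction, which protects specificity: on
artefact-free contrasts the consensus is empty and denoising is the
identity.

## Streaming (operational) mode

Calibration computes the static rest covariance once, plus a null matched
to the per-window statistic: the largest GED eigenvalue of each individual
rest window against the pooled rest covariance. (The split-half null is
far too narrow here — a single 1 s, 64-channel window covariance has
Marchenko-Pastur-scale eigenvalue spread.) Each incoming non-overlapping
window then costs one GED plus matrix products; MAD, elbow and the
calibration null are intersected per window.

The null comparison is Sidak-corrected across the recording's windows
(`alpha_w = 1 - (1 - alpha)^{1/n_windows}`): the 95% confidence level is
read as applying to the recording's artefact decision. An uncorrected
per-window test would zero a genuine brain component in ~1 of 20 clean
windows, measurably distorting artefact-free data (median per-channel RMS
change ~15% in simulation, vs ~0 with the correction), while burst-window
eigenvalues (100-10000x) sit far above either threshold. A trailing
partial window is passed through unmodified and reported.

## Preprocessing

Recordings are downsampled to 256 Hz (polyphase FIR anti-aliasing,
group-delay compensated), high-passed at 1 Hz and low-passed at 40 Hz with
zero-phase Hamming-windowed sinc FIR filters applied forward-backward; the
default order is `3 * trunc(fs/cutoff)` taps (768 at 256 Hz / 1 Hz, giving
a ~1 Hz transition band). High-pass taps are shifted to an exact DC null.
Bad channels are detected on rest data by five criteria — extreme peak
amplitude (robust z > 4 across channels), drift (|trend slope| robust
z > 3, evaluated before the high-pass), kurtosis (robust z > 3),
improbable voltage distribution (mean Gaussian log-likelihood robust
z < -3), and muscle-band spectral slope (log10-power/log10-frequency slope
over 7-35 Hz above -0.59) — and replaced by spherical-spline interpolation
(Legendre-series kernel, stiffness 4, 50 terms, regularization 1e-5; the
interpolation operator depends only on electrode geometry). The
fixed-slope muscle criterion assumes 1/f-shaped EEG background; it flags
spectrally flat (white) channels by design. Bad-channel handling defaults
to rest recordings only, with a switch to extend it to motion data.

## Evaluation metrics

With `x` the preprocessed ("raw") signal and `d_hat` the signal the
denoiser removed:

* **SER** (dB, per channel): `10 log10( E{x^2} / E{d_hat^2} )` on
  artefact-free data — the model fitted on the rest/motion contrast is
  applied to the clean rest recording and SER measures what it wrongly
  removes there. High SER = little distortion.
* **ARR** (dB, per channel): with the raw signal substituted for the
  unknown artefact, `10 log10( E{x^2} / E{(x - d_hat)^2} )` on annotated
  artefactual segments. Valid when artefacts dominate the clean EEG in
  amplitude; high ARR = strong suppression. A do-nothing denoiser scores
  0 dB.
* **Weights**: per-channel artefact excess
  `max(0, E{x^2}_noisy - E{x^2}_clean)`, normalized to sum 1 (channels
  quieter during motion carry no excess and get zero weight); weighted
  SER/ARR are the weight-dot-products. Zero denominators yield explicit
  +Inf sentinels, never silent values.
* **High-frequency power change** (relative, per channel):
  `(P_band(denoised) - P_band(raw)) / P_band(raw)` for 30 Hz up to
  Nyquist, from a Welch PSD on 256-sample Hamming windows with 50%
  overlap, zero-padded to a 0.1 Hz grid (native resolution at 256 samples
  is 1 Hz; zero-padding reconciles the window length with the grid).
  Density scaling: integrating the white-noise PSD recovers its variance.
  Negative = suppression; a positive value means the method *introduced*
  high-frequency content. The periodograms are computed directly with an
  FFT (single-precision transform; band-power ratios are insensitive at
  that precision).
* **Sensitivity harness**: the full pipeline re-run per covariance window
  length (0.5/1/1.5/2 s), tabulating weighted SER/ARR.

## The synthetic-data generator

Sessions emulate the study conditions of the validation suite: a
64-channel equidistant cap (deterministic Fibonacci lattice on the upper
unit hemisphere) at 256 Hz, 300 s of rest and 300 s of motion, with
scalp-level brain RMS ~10 uV.

* **Brain sources** (20 by default): 1/f-power coloured noise (flat below
  1 Hz) plus one oscillation drawn uniformly from 8-12 Hz with random
  phase carrying ~1/5 of the source variance; unit variance per source.
* **Motion sources** (3 by default): zero except inside bursts; burst
  onsets are a Poisson process (0.4 bursts/s), durations uniform
  0.2-1.5 s, waveforms are Hann-tapered sums of two random sinusoids
  below 12 Hz with log-normal amplitudes — transient, non-periodic,
  low-frequency-dominated events.
* **Mixing**: columns are Gaussian random fields over the electrode layout
  (squared-exponential kernel, length scale 0.5 on the unit sphere),
  normalized to unit Euclidean norm, so all scale lives in the sources;
  smooth topographies mimic volume conduction without a forward model.
* **Calibration**: the artefact term is scaled so the within-burst RMS
  ratio of artefact to brain contribution equals `artefact_rms_ratio`
  (10 by default — artefacts dominate by an order of magnitude, the regime
  in which the ARR approximation is valid).

Rest recordings contain the brain term only; motion recordings use fresh
brain sources plus the artefact term; burst intervals are annotated as
noisy segments. Everything is seeded and bit-reproducible, and the exact
mixing matrices and source time courses are returned as ground truth.

What the generator does **not** emulate: biophysical volume conduction
(BEM/FEM), sensor noise (recordings are exact low-rank mixtures, so
covariances are singular without regularization — harder, not easier, than
real data in that respect), non-1/f artefact spectra, electrode-impedance
drift, and physiological artefact families (EMG/EOG/ECG). Passing the
suite therefore demonstrates correct recovery under the stated mixture
model, not performance on real recordings. One visible consequence of the
noiseless model: on synthetic sessions the weighted SER sits at a floor
regime (~70 dB — the denoiser removes ~1e-7 of clean-signal power), where
window-length changes move it by ~2 dB through numerically real but
scientifically meaningless filter rotations, while ARR varies by under
0.15 dB across the same sweep.

## Validation suite and problem sizes

The test suite validates, per run: exact recovery of the three planted
artefact components (consensus = top 3) on twenty seeded full-scale
sessions; principal-angle cosines > 0.95 between the true mixing columns
and the removed patterns; median per-channel correlation > 0.9 between
denoised and true brain signal; weighted ARR >= 10 dB and weighted SER >=
15 dB; empty consensus and < 5% median RMS change on twenty artefact-free
sessions (64 channels, 60 s per condition — long enough for 60 covariance
windows per condition); non-positive median high-frequency power change on
every channel; and < 2 dB SER spread across the four window lengths.
Artefact-free specificity sessions are shorter than recovery sessions
because the property under test (the null calibration) depends on window
counts, not recording length, beyond ~60 windows.

## Known limitations

* EDF/BDF files are read (via mne); writing EDF requires an optional
  backend (`edfio`) and is otherwise refused with a clear error — the
  plain binary+JSON sidecar format is the writable interchange format.
* The empirical-null resampling design (split-half) is one defensible
  choice among several; it is exposed in the API (`build_null`) rather
  than hard-wired.
* Whether one GED per recording (batch) or one per window (stream) is
  preferable depends on artefact stationarity; both are provided and the
  CLI exposes the switch. Stream mode assumes the artefact subspace can be
  re-estimated from each 1 s window, which degrades when per-window
  artefact energy varies over orders of magnitude.
* ARR interprets the raw signal as the artefact; on data where artefacts
  do not dominate, its absolute value is not meaningful (the valid-regime
  caveat travels with the metric).
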