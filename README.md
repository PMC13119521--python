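# gedclean

Suppression of non-stationary motion artefacts in mobile multichannel EEG
by generalized eigenvalue decomposition (GED).

EEG recorded during free full-body movement — sports, walking, everyday
activity — is contaminated by transient, high-amplitude, non-periodic
artefacts whose spectrum overlaps brain activity, so frequency filtering
cannot remove them. `gedclean` exploits a *covariance contrast* instead:
with a resting-state recording as artefact-free reference, it solves

$$C_m\,w \;=\; \lambda\, C_r\,w$$

where $C_m$ and $C_r$ are the channel covariances of the
motion-contaminated and resting EEG (estimated on 1 s windows and
aggregated with the Riemannian geometric mean). Each eigenvector $w$ is a
spatial filter; its eigenvalue $\lambda = \lVert w^\top X_m\rVert^2 /
\lVert w^\top X_r\rVert^2$ is the motion/rest variance ratio it extracts.
Components with outlying eigenvalues span the motion-artefact subspace;
they are identified by the consensus of three detectors (MAD outlier,
kneedle elbow, empirical null from rest data at 95% confidence), zeroed,
and the signal is reconstructed as $\hat X_m = W^{-\top}\hat Y$.

The package provides the full pipeline for practitioners working with
mobile EEG: preprocessing (resampling, zero-phase FIR filters,
five-criterion bad-channel detection, spherical-spline interpolation),
batch and streaming (static-reference) denoising, the SER/ARR/spectral
evaluation harness, and a seeded synthetic-session generator with exact
ground truth so that every stage is testable without real recordings.

## Worked example

```python
import numpy as np
import gedclean as g

# a 16-channel session: 30 s rest + 30 s motion, three motion sources
# ten times larger than brain activity within bursts
spec = g.SessionSpec(n_channels=16, rest_duration=30, motion_duration=30,
                     n_brain=8, n_motion=3, artefact_rms_ratio=10.0, seed=7)
rest, motion, truth = g.synthesize_session(spec)

cfg = g.RunConfig(null_b=50, seed=7)
result = g.denoise_batch(rest, motion, cfg)
metrics = g.evaluate_denoising(rest, motion, result)

print("flagged components:", result.artefact_indices)
print("top eigenvalues:   ", np.round(result.model.eigenvalues[:5], 1))
print("weighted SER:      ", round(metrics.ser_weighted, 1), "dB")
print("weighted ARR:      ", round(metrics.arr_weighted, 1), "dB")
print("median HF change:  ", round(float(np.median(metrics.hf_power_change)), 4))
```

prints

```
flagged components: (0, 1, 2)
top eigenvalues:    [3613.3 3344.7 2346.1    5.9    5.9]
weighted SER:       106.1 dB
weighted ARR:       21.2 dB
median HF change:   -0.0049
```

The three planted artefact components dominate the spectrum (variance
ratios in the thousands against an empirical-null 95th percentile of
~1.4) and are the exact consensus set. ARR ≈ 21 dB says the artefactual
segments retain under 1% of their raw power after denoising; the very
high SER says essentially nothing was removed from the clean reference
data; the negative high-frequency change confirms the method suppresses
rather than introduces >30 Hz power. The denoised channels correlate with
the true brain mixture at ~0.996 (median).

## Command line

```bash
gedclean simulate  --out sess --channels 64 --seed 1
gedclean preprocess --in raw.edf --out pre --rate 256 --hp 1 --lp 40 --detect-bad
gedclean denoise   --rest sess_rest.dat --motion sess_motion.dat \
                   --mode batch --out denoised --report report.json
gedclean sweep     --rest sess_rest.dat --motion sess_motion.dat --out sweep.csv
```

Recordings travel as EDF/BDF (read) or as a little-endian float64 binary
plus JSON sidecar (read/write); every run's JSON report carries the
eigenvalue spectrum, per-detector flags, consensus, metrics, config echo
and seed, so any result is reproducible from its report.

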