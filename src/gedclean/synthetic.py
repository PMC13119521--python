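"""Synthetic rest/motion EEG sessions with known mixing ground truth.

The generator emulates the linear mixture model underlying the denoiser:
``X = A_b S_b + A_m S_m``, a C-channel recording composed of 1/f-spectrum
brain sources with an alpha-band oscillation, plus transient high-amplitude
motion bursts with smooth scalp topographies. Sessions come in two
conditions: *rest* (brain sources only — the reference the denoiser
calibrates on) and *motion* (fresh brain sources plus the artefact term).

Everything is seeded and bit-reproducible, so downstream stages can be
tested against exact ground truth without any real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import Recording, Segment

__all__ = [
    "MixingGroundTruth",
    "SessionSpec",
    "equidistant_layout",
    "generate_brain_sources",
    "generate_motion_bursts",
    "synthesize_session",
]


# ---------------------------------------------------------------------------
# specs and ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SessionSpec:
    """Parameters of one synthetic rest+motion session.

    ``artefact_rms_ratio`` is the RMS of the artefact contribution over the
    RMS of the brain contribution, measured on burst samples only.
    Defaults mirror the study conditions of the validation suite: a
    64-channel cap at 256 Hz, five minutes per condition, three motion
    sources ten times larger than brain activity within bursts.
    """

    n_channels: int = 64
    fs: float = 256.0
    rest_duration: float = 300.0
    motion_duration: float = 300.0
    n_brain: int = 20
    n_motion: int = 3
    artefact_rms_ratio: float = 10.0
    burst_rate: float = 0.4  # bursts per second (Poisson onsets)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.rest_duration <= 0 or self.motion_duration <= 0:
            raise ValueError("durations must be positive")
        if self.n_brain < 1:
            raise ValueError("need at least one brain source")
        if self.n_motion < 0:
            raise ValueError("n_motion must be non-negative")
        if self.n_motion >= self.n_channels:
            raise ValueError(
                "n_motion must be smaller than n_channels (artefact subspace must be proper)"
            )
        if self.artefact_rms_ratio < 0:
            raise ValueError("artefact_rms_ratio must be >= 0")
        if self.burst_rate < 0:
            raise ValueError("burst_rate must be >= 0")


@dataclass
class MixingGroundTruth:
    """Exact mixing model of the *motion* recording of one session.

    ``brain_mixing @ brain_sources`` is the clean brain contribution the
    denoiser should recover; ``motion_mixing @ motion_sources`` is the
    artefact contribution it should remove. Mixing columns have unit
    Euclidean norm (all scale lives in the sources). ``rest_brain_sources``
    additionally exposes the sources behind the rest recording.
    """

    brain_mixing: np.ndarray  # C x n_b
    motion_mixing: np.ndarray  # C x n_m
    brain_sources: np.ndarray  # n_b x N (motion condition)
    motion_sources: np.ndarray  # n_m x N
    burst_intervals: list[tuple[int, int]]
    seed: int
    rest_brain_sources: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def brain_contribution(self) -> np.ndarray:
        return self.brain_mixing @ self.brain_sources

    @property
    def motion_contribution(self) -> np.ndarray:
        return self.motion_mixing @ self.motion_sources


# ---------------------------------------------------------------------------
# electrode layout
# ---------------------------------------------------------------------------


def equidistant_layout(n_channels: int) -> np.ndarray:
    """Deterministic quasi-equidistant layout of ``n_channels`` electrodes.

    Points are placed on the upper hemisphere of the unit sphere with a
    Fibonacci lattice, mimicking the even coverage of equidistant EEG caps
    without requiring a montage file.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be positive")
    i = np.arange(n_channels)
    golden = (1 + np.sqrt(5)) / 2
    # z spans the upper hemisphere, slightly off the pole and the rim
    z = 1 - (i + 0.5) / n_channels  # in (0, 1)
    r = np.sqrt(1 - z**2)
    theta = 2 * np.pi * i / golden
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _smooth_mixing(positions: np.ndarray, n_sources: int, rng: np.random.Generator,
                   length_scale: float = 0.5) -> np.ndarray:
    """Columns are Gaussian random fields over the electrode layout.

    Smoothing a white vector with a squared-exponential kernel over the
    3-D electrode positions yields spatially smooth scalp topographies;
    columns are normalized to unit Euclidean norm.
    """
    c = positions.shape[0]
    if n_sources == 0:
        return np.zeros((c, 0))
    d2 = np.sum((positions[:, None, :] - positions[None, :, :]) ** 2, axis=-1)
    k = np.exp(-d2 / (2 * length_scale**2))
    cols = k @ rng.standard_normal((c, n_sources))
    return cols / np.linalg.norm(cols, axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# sources
# ---------------------------------------------------------------------------


def generate_brain_sources(n_sources: int, n_samples: int, fs: float, seed: int) -> np.ndarray:
    """1/f coloured noise plus one alpha-band oscillation per source.

    Each row is normalized to unit sample variance. The oscillation
    frequency is drawn uniformly from 8-12 Hz with random phase and
    carries roughly a fifth of the source variance, producing the alpha
    bump riding on the 1/f background typical of resting EEG.
    """
    if n_sources < 1 or n_samples < 1:
        raise ValueError("n_sources and n_samples must be positive")
    if n_samples < fs:
        raise ValueError("need at least one second of signal")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_samples, d=1 / fs)
    # amplitude ~ f^-1/2 => power ~ 1/f; flat below 1 Hz to avoid blow-up
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    shaping[0] = 0.0  # no DC
    out = np.empty((n_sources, n_samples))
    t = np.arange(n_samples) / fs
    for k in range(n_sources):
        spec = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)) * shaping
        noise = np.fft.irfft(spec, n=n_samples)
        noise /= np.std(noise)
        f_alpha = rng.uniform(8.0, 12.0)
        phase = rng.uniform(0, 2 * np.pi)
        osc = np.sqrt(2 * 0.25) * np.sin(2 * np.pi * f_alpha * t + phase)
        src = noise + osc
        out[k] = src / np.std(src)
    return out


def generate_motion_bursts(
    n_sources: int,
    n_samples: int,
    fs: float,
    burst_rate: float,
    seed: int,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Transient low-frequency motion bursts with Poisson onsets.

    Burst onsets follow a Poisson process with rate ``burst_rate`` per
    second; durations are uniform in 0.2-1.5 s. Within a burst every
    source carries a Hann-tapered sum of two random sinusoids below 12 Hz
    with a log-normal amplitude, emulating the non-periodic, transient,
    high-amplitude character of motion artefacts. Samples outside the
    returned half-open intervals are exactly zero.
    """
    if n_sources < 0 or n_samples < 1:
        raise ValueError("invalid dimensions")
    if burst_rate < 0:
        raise ValueError("burst_rate must be >= 0")
    rng = np.random.default_rng(seed)
    sources = np.zeros((max(n_sources, 0), n_samples))
    raw_intervals: list[tuple[int, int]] = []
    if n_sources == 0 or burst_rate == 0:
        return sources, []

    t = 0.0
    duration_s = n_samples / fs
    while True:
        t += rng.exponential(1.0 / burst_rate)
        if t >= duration_s:
            break
        dur = rng.uniform(0.2, 1.5)
        start = int(round(t * fs))
        end = min(int(round((t + dur) * fs)), n_samples)
        if end - start < 2:
            continue
        length = end - start
        env = np.hanning(length)
        tt = np.arange(length) / fs
        for k in range(n_sources):
            wave = np.zeros(length)
            for _ in range(2):
                f = rng.uniform(0.5, 12.0)
                phase = rng.uniform(0, 2 * np.pi)
                amp = rng.lognormal(mean=0.0, sigma=0.5)
                wave += amp * np.sin(2 * np.pi * f * tt + phase)
            sources[k, start:end] += env * wave
        raw_intervals.append((start, end))

    return sources, _merge_intervals(raw_intervals)


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and non-overlapping."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------


def synthesize_session(spec: SessionSpec) -> tuple[Recording, Recording, MixingGroundTruth]:
    """Generate one (rest, motion, ground-truth) session.

    The rest recording contains only the brain term; the motion recording
    adds the artefact term, scaled so that the RMS ratio of artefact to
    brain contribution *within bursts* equals ``spec.artefact_rms_ratio``.
    Channel amplitudes are scaled so the brain contribution has an RMS of
    about 10 uV, a typical scalp-EEG magnitude.
    """
    rng = np.random.default_rng(spec.seed)
    s_mix, s_rest, s_motion_brain, s_bursts = (int(x) for x in rng.integers(2**31, size=4))

    positions = equidistant_layout(spec.n_channels)
    mix_rng = np.random.default_rng(s_mix)
    a_b = _smooth_mixing(positions, spec.n_brain, mix_rng)
    a_m = _smooth_mixing(positions, spec.n_motion, mix_rng)

    n_rest = int(round(spec.rest_duration * spec.fs))
    n_motion = int(round(spec.motion_duration * spec.fs))
    s_b_rest = generate_brain_sources(spec.n_brain, n_rest, spec.fs, s_rest)
    s_b_mot = generate_brain_sources(spec.n_brain, n_motion, spec.fs, s_motion_brain)
    s_m, intervals = generate_motion_bursts(
        spec.n_motion, n_motion, spec.fs, spec.burst_rate, s_bursts
    )

    brain_mot = a_b @ s_b_mot
    if spec.n_motion > 0 and intervals:
        mask = np.zeros(n_motion, dtype=bool)
        for start, end in intervals:
            mask[start:end] = True
        art = a_m @ s_m
        rms_art = np.sqrt(np.mean(art[:, mask] ** 2))
        rms_brain = np.sqrt(np.mean(brain_mot[:, mask] ** 2))
        if rms_art > 0:
            s_m *= spec.artefact_rms_ratio * rms_brain / rms_art

    # scale so the brain contribution sits at ~10 uV RMS
    scale = 10.0 / np.sqrt(np.mean((a_b @ s_b_rest) ** 2))
    s_b_rest = s_b_rest * scale
    s_b_mot = s_b_mot * scale
    s_m = s_m * scale

    labels = [f"E{i + 1:02d}" for i in range(spec.n_channels)]
    rest = Recording(
        data=a_b @ s_b_rest,
        fs=spec.fs,
        labels=labels,
        positions=positions,
        condition="rest",
        segments=[Segment(0, n_rest, "clean")],
    )

    motion_data = a_b @ s_b_mot + (a_m @ s_m if spec.n_motion else 0.0)
    motion = Recording(
        data=motion_data,
        fs=spec.fs,
        labels=labels,
        positions=positions,
        condition="motion",
        segments=_segment_annotations(intervals, n_motion),
    )

    truth = MixingGroundTruth(
        brain_mixing=a_b,
        motion_mixing=a_m,
        brain_sources=s_b_mot,
        motion_sources=s_m,
        burst_intervals=intervals,
        seed=spec.seed,
        rest_brain_sources=s_b_rest,
    )
    return rest, motion, truth


def _segment_annotations(intervals: list[tuple[int, int]], n_samples: int) -> list[Segment]:
    """Noisy segments at burst intervals, clean segments in the gaps."""
    segments: list[Segment] = []
    cursor = 0
    for start, end in intervals:
        if start > cursor:
            segments.append(Segment(cursor, start, "clean"))
        segments.append(Segment(start, end, "noisy"))
        cursor = end
    if cursor < n_samples:
        segments.append(Segment(cursor, n_samples, "clean"))
    return segments
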