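"""Shared fixtures: small sessions for unit tests, full suite for validation."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.linalg

from gedclean import (
    RunConfig,
    SessionSpec,
    denoise_batch,
    evaluate_denoising,
    synthesize_session,
)

#: Study conditions of the validation suite: 64-channel cap at 256 Hz,
#: five minutes per condition, three motion sources at a within-burst
#: artefact/brain RMS ratio of 10.
SUITE_CONDITIONS = dict(
    n_channels=64,
    fs=256.0,
    rest_duration=300.0,
    motion_duration=300.0,
    n_brain=20,
    n_motion=3,
    artefact_rms_ratio=10.0,
    burst_rate=0.4,
)

N_SUITE_SEEDS = 20


def random_spd(rng: np.random.Generator, dim: int, cond: tuple[float, float] = (0.5, 5.0)):
    """Random SPD matrix with eigenvalues uniform in ``cond``."""
    q, _ = np.linalg.qr(rng.standard_normal((dim, dim)))
    w = rng.uniform(*cond, dim)
    return (q * w) @ q.T


@pytest.fixture()
def small_session():
    """Quick 16-channel session for unit-level pipeline tests."""
    spec = SessionSpec(
        n_channels=16,
        rest_duration=30.0,
        motion_duration=30.0,
        n_brain=8,
        n_motion=3,
        artefact_rms_ratio=10.0,
        seed=7,
    )
    return synthesize_session(spec)


@pytest.fixture(scope="session")
def recovery_suite():
    """Twenty seeded full-scale sessions run through the batch pipeline.

    Stores per-session summaries only (the raw recordings are ~40 MB
    each): consensus indices, principal-angle cosines between the true
    artefact subspace and the removed patterns, the median per-channel
    correlation of the denoised signal with the true brain contribution,
    weighted SER/ARR, and the per-channel high-frequency power change.
    """
    summaries = []
    for seed in range(N_SUITE_SEEDS):
        rest, motion, truth = synthesize_session(SessionSpec(seed=seed, **SUITE_CONDITIONS))
        result = denoise_batch(rest, motion, RunConfig(seed=seed))
        metrics = evaluate_denoising(rest, motion, result)
        if result.artefact_indices:
            patterns = result.model.inverse_filters[:, list(result.artefact_indices)]
            cosines = np.cos(scipy.linalg.subspace_angles(truth.motion_mixing, patterns))
        else:
            cosines = np.array([])
        brain = truth.brain_contribution
        corrs = [
            np.corrcoef(result.denoised.data[i], brain[i])[0, 1]
            for i in range(motion.n_channels)
        ]
        summaries.append(
            dict(
                seed=seed,
                consensus=result.artefact_indices,
                cosines=cosines,
                corr_median=float(np.median(corrs)),
                ser_db=metrics.ser_weighted,
                arr_db=metrics.arr_weighted,
                hf_change=metrics.hf_power_change,
            )
        )
    return summaries
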