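"""Recording readers/writers and the JSON run report.

Two on-disk formats are supported:

* **Plain matrix format**: a little-endian float64 binary array
  (``<name>.dat``) plus a JSON sidecar (``<name>.json``) holding sampling
  rate, channel labels, optional positions, condition and segment
  annotations. Zero-dependency, byte-exact, used for fixtures and outputs.
* **EDF/BDF** (read-only): parsed through mne. Writing EDF requires the
  ``edfio`` backend, which is optional; without it an explicit error names
  the supported writable format.

Sample indexing is 0-based and all intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .evaluation import MetricsReport
from .ged import DenoisedResult
from .recording import Recording, Segment
from .synthetic import MixingGroundTruth

__all__ = [
    "save_recording",
    "load_recording",
    "read_recording",
    "read_positions_sfp",
    "save_ground_truth",
    "load_ground_truth",
    "write_report",
]


# ---------------------------------------------------------------------------
# plain matrix format
# ---------------------------------------------------------------------------


def save_recording(rec: Recording, path: str | Path) -> Path:
    """Write ``<path>.dat`` (little-endian float64) + ``<path>.json`` sidecar."""
    base = Path(path).with_suffix("")
    data = np.ascontiguousarray(rec.data, dtype="<f8")
    data.tofile(base.with_suffix(".dat"))
    sidecar = {
        "fs": rec.fs,
        "labels": rec.labels,
        "shape": list(rec.data.shape),
        "dtype": "<f8",
        "condition": rec.condition,
        "positions": None if rec.positions is None else rec.positions.tolist(),
        "segments": [[s.start, s.end, s.tag] for s in rec.segments],
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return base.with_suffix(".dat")


def load_recording(path: str | Path) -> Recording:
    """Read a plain-format recording from its ``.dat``/``.json`` pair."""
    base = Path(path).with_suffix("")
    sidecar_path = base.with_suffix(".json")
    dat_path = base.with_suffix(".dat")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"sidecar {sidecar_path} not found")
    if not dat_path.exists():
        raise FileNotFoundError(f"data file {dat_path} not found")
    meta = json.loads(sidecar_path.read_text())
    for key in ("fs", "labels", "shape", "dtype"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar_path} is missing required field {key!r}")
    shape = tuple(meta["shape"])
    data = np.fromfile(dat_path, dtype=meta["dtype"])
    if data.size != shape[0] * shape[1]:
        raise ValueError(
            f"data file holds {data.size} values but sidecar declares shape {shape}"
        )
    return Recording(
        data=data.reshape(shape),
        fs=float(meta["fs"]),
        labels=list(meta["labels"]),
        positions=None if meta.get("positions") is None else np.asarray(meta["positions"]),
        condition=meta.get("condition", "rest"),
        segments=[Segment(s[0], s[1], s[2]) for s in meta.get("segments", [])],
    )


# ---------------------------------------------------------------------------
# EDF / BDF via mne
# ---------------------------------------------------------------------------

_EDF_SUFFIXES = {".edf", ".bdf"}


def _read_edf(path: Path, condition: str) -> Recording:
    import mne

    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne loads volts; recordings are in microvolts
    positions = None
    montage = raw.get_montage()
    if montage is not None:
        pos = montage.get_positions()["ch_pos"]
        if all(ch in pos for ch in raw.ch_names):
            arr = np.array([pos[ch] for ch in raw.ch_names])
            norms = np.linalg.norm(arr, axis=1, keepdims=True)
            if np.all(norms > 0):
                positions = arr / norms
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        labels=list(raw.ch_names),
        positions=positions,
        condition=condition,
    )


def read_recording(path: str | Path, fmt: str | None = None, condition: str = "rest") -> Recording:
    """Read EDF/BDF or plain-format recordings, dispatching on suffix.

    ``fmt`` may force ``"edf"``, ``"bdf"`` or ``"plain"``; otherwise the
    file suffix decides.
    """
    p = Path(path)
    if fmt is None:
        fmt = p.suffix.lower().lstrip(".") or "plain"
        if fmt not in ("edf", "bdf"):
            fmt = "plain"
    if fmt in ("edf", "bdf"):
        if not p.exists():
            raise FileNotFoundError(p)
        return _read_edf(p, condition)
    if fmt == "plain":
        rec = load_recording(p)
        if condition != rec.condition:
            rec.condition = condition
        return rec
    raise ValueError(f"unsupported format {fmt!r}; supported: edf, bdf, plain")


def read_positions_sfp(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read an .sfp/.elc-style Cartesian electrode position file.

    Each non-comment line: ``label x y z``. Positions are normalized to
    the unit sphere.
    """
    labels, coords = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"malformed position line: {line!r}")
        labels.append(parts[0])
        coords.append([float(v) for v in parts[1:]])
    pos = np.asarray(coords)
    norms = np.linalg.norm(pos, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("electrode at the origin cannot be normalized")
    return labels, pos / norms


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


def save_ground_truth(truth: MixingGroundTruth, path: str | Path) -> None:
    np.savez(
        path,
        brain_mixing=truth.brain_mixing,
        motion_mixing=truth.motion_mixing,
        brain_sources=truth.brain_sources,
        motion_sources=truth.motion_sources,
        burst_intervals=np.asarray(truth.burst_intervals, dtype=int).reshape(-1, 2),
        seed=truth.seed,
        rest_brain_sources=truth.rest_brain_sources,
    )


def load_ground_truth(path: str | Path) -> MixingGroundTruth:
    with np.load(path) as f:
        return MixingGroundTruth(
            brain_mixing=f["brain_mixing"],
            motion_mixing=f["motion_mixing"],
            brain_sources=f["brain_sources"],
            motion_sources=f["motion_sources"],
            burst_intervals=[tuple(int(v) for v in row) for row in f["burst_intervals"]],
            seed=int(f["seed"]),
            rest_brain_sources=f["rest_brain_sources"],
        )


# ---------------------------------------------------------------------------
# run report
# ---------------------------------------------------------------------------


def write_report(
    result: DenoisedResult,
    metrics: MetricsReport | None,
    path: str | Path,
    config: RunConfig | None = None,
) -> dict:
    """JSON run report: spectrum, detector flags, consensus, metrics, config."""
    report = {
        "package_version": __version__,
        "config": (config or RunConfig()).to_dict(),
        "eigenvalues": result.model.eigenvalues.tolist() if result.model else None,
        "artefact_indices": list(result.artefact_indices),
        "passthrough": result.passthrough,
        "tail_passthrough_samples": result.tail_passthrough_samples,
        "decision": None if result.decision is None else result.decision.to_dict(),
        "metrics": None if metrics is None else metrics.to_dict(),
    }
    Path(path).write_text(json.dumps(report, indent=2))
    return report
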