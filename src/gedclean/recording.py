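"""Multichannel EEG recording container.

A :class:`Recording` is the unit every pipeline stage consumes and produces:
a channels x samples matrix in microvolts plus sampling rate, channel labels,
optional 3-D electrode positions on the unit sphere, a condition tag
(``rest`` or ``motion``) and half-open ``[start, end)`` segment annotations
(0-based sample indices) tagging stretches as ``clean`` or ``noisy``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Recording", "Segment"]

#: Allowed condition tags.
CONDITIONS = ("rest", "motion")

#: Allowed segment tags.
SEGMENT_TAGS = ("clean", "noisy")


@dataclass(frozen=True)
class Segment:
    """Half-open annotated interval ``[start, end)`` in samples."""

    start: int
    end: int
    tag: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid segment [{self.start}, {self.end})")
        if self.tag not in SEGMENT_TAGS:
            raise ValueError(f"segment tag must be one of {SEGMENT_TAGS}, got {self.tag!r}")


@dataclass
class Recording:
    """C x N multichannel recording with metadata.

    Parameters
    ----------
    data : ndarray, shape (C, N)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Unique channel names, length C.
    positions : ndarray, shape (C, 3), optional
        Electrode positions on the unit sphere; required only for
        spherical-spline interpolation.
    condition : {"rest", "motion"}
    segments : list of Segment
        Clean/noisy annotations; indices must lie within ``[0, N]``.
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    positions: np.ndarray | None = None
    condition: str = "rest"
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        c, n = self.data.shape
        if c < 2:
            raise ValueError("a Recording needs at least 2 channels")
        if n < 1:
            raise ValueError("a Recording needs at least 1 sample")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.labels) != c:
            raise ValueError(f"{len(self.labels)} labels for {c} channels")
        if len(set(self.labels)) != c:
            raise ValueError("channel labels must be unique")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (c, 3):
                raise ValueError("positions must have shape (C, 3)")
        self.segments = [s if isinstance(s, Segment) else Segment(*s) for s in self.segments]
        for s in self.segments:
            if s.end > n:
                raise ValueError(f"segment {s} exceeds recording length {n}")

    # -- shape helpers -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.data.shape[1] / self.fs

    # -- segment helpers -----------------------------------------------
    def sample_mask(self, tag: str) -> np.ndarray:
        """Boolean mask of samples covered by segments with ``tag``.

        If the recording carries no segment annotations at all, the whole
        recording is treated as ``clean``.
        """
        if tag not in SEGMENT_TAGS:
            raise ValueError(f"unknown tag {tag!r}")
        mask = np.zeros(self.n_samples, dtype=bool)
        if not self.segments:
            if tag == "clean":
                mask[:] = True
            return mask
        for s in self.segments:
            if s.tag == tag:
                mask[s.start : s.end] = True
        return mask

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "Recording":
        """Copy of this recording with ``data`` (and optionally ``fs``) replaced.

        Segment annotations are kept when the sample count is unchanged and
        clipped to the new length otherwise (empty segments are dropped).
        """
        data = np.asarray(data, dtype=float)
        n_new = data.shape[1] if data.ndim == 2 else 0
        segments = [
            Segment(s.start, min(s.end, n_new), s.tag)
            for s in self.segments
            if s.start < n_new
        ]
        return replace(
            self,
            data=data,
            fs=self.fs if fs is None else fs,
            labels=list(self.labels),
            positions=None if self.positions is None else self.positions.copy(),
            segments=segments,
        )

    def copy(self) -> "Recording":
        return self.with_data(self.data.copy())
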