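"""Core containers shared across the pipeline.

All topographic maps are stored average-referenced (zero spatial mean).
Sample indexing is 0-based, epoch intervals are half-open ``[start, stop)``,
and times in derived tables are milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

UNASSIGNED = -1

#: Canonical microstate class names in their conventional order.
CLASS_NAMES = ("A", "B", "C", "D")


def center_map(m: np.ndarray) -> np.ndarray:
    """Average-reference a topography (subtract the spatial mean)."""
    m = np.asarray(m, dtype=float)
    return m - m.mean(axis=-1, keepdims=True)


def normalize_map(m: np.ndarray) -> np.ndarray:
    """Average-reference and scale a topography to unit L2 norm."""
    m = center_map(m)
    nrm = np.linalg.norm(m, axis=-1, keepdims=True)
    if np.any(nrm == 0):
        raise ValueError("cannot normalize a flat (zero-variance) topography")
    return m / nrm


def canonical_sign(m: np.ndarray) -> np.ndarray:
    """Flip a map, if needed, so its largest-magnitude channel is positive.

    Gives every polarity-invariant map a deterministic representative that
    follows the map under channel permutation and is unchanged by sign flips
    of the input.
    """
    m = np.asarray(m, dtype=float)
    i = int(np.argmax(np.abs(m)))
    return -m if m[i] < 0 else m


def _validate_epochs(epochs: list[tuple[int, int]], n_samples: int) -> list[tuple[int, int]]:
    out = []
    prev_stop = 0
    for start, stop in epochs:
        start, stop = int(start), int(stop)
        if not (0 <= start < stop <= n_samples):
            raise ValueError(f"epoch ({start}, {stop}) outside [0, {n_samples})")
        if start < prev_stop:
            raise ValueError("epochs must be sorted and non-overlapping")
        prev_stop = stop
        out.append((start, stop))
    return out


@dataclass
class Recording:
    """Multichannel EEG: a channels x samples potential matrix in microvolts."""

    data: np.ndarray
    fs: float
    ch_names: list[str]
    epochs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 channels")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("channel name count does not match data rows")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.epochs:
            self.epochs = [(0, self.data.shape[1])]
        self.epochs = _validate_epochs(self.epochs, self.data.shape[1])

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, **kw) -> "Recording":
        return replace(self, **kw)


@dataclass
class GfpSeries:
    """Global field power per sample plus the detected peak indices."""

    values: np.ndarray
    fs: float
    epochs: list[tuple[int, int]]
    peak_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        if np.any(self.values < 0):
            raise ValueError("GFP values must be nonnegative")
        if self.peak_indices.size and np.any(np.diff(self.peak_indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")


@dataclass
class TemplateSet:
    """K labeled microstate template maps, average-referenced and unit-norm.

    ``level`` records provenance: templates fitted to one subject
    (``"individual"``), pooled over a group (``"group"``), or the built-in
    canonical atlas (``"atlas"``).
    """

    maps: np.ndarray
    labels: list[str]
    ch_names: list[str]
    level: str = "individual"

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise ValueError("maps must be K x channels")
        K, C = self.maps.shape
        if K < 2:
            raise ValueError("need at least 2 templates")
        if len(self.labels) != K or len(set(self.labels)) != K:
            raise ValueError("labels must be unique, one per map")
        if len(self.ch_names) != C:
            raise ValueError("channel name count does not match map columns")
        means = np.abs(self.maps.mean(axis=1))
        norms = np.linalg.norm(self.maps, axis=1)
        if np.any(means > 1e-8) or np.any(np.abs(norms - 1.0) > 1e-8):
            raise ValueError("template maps must be average-referenced and unit-norm")

    @property
    def K(self) -> int:
        return self.maps.shape[0]

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "ch_names": list(self.ch_names),
            "level": self.level,
            "maps": self.maps.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TemplateSet":
        return cls(
            maps=np.asarray(d["maps"], dtype=float),
            labels=list(d["labels"]),
            ch_names=list(d["ch_names"]),
            level=d.get("level", "individual"),
        )


@dataclass
class Segmentation:
    """Per-sample microstate labels plus the derived run-length segment list.

    ``labels`` holds a class index per sample (``UNASSIGNED`` = -1 outside any
    epoch or in epochs with no usable GFP peak).  ``segments`` is a structured
    array with fields ``label``, ``start``, ``length``, ``trunc_left``,
    ``trunc_right``; a run is flagged truncated on the side where it touches
    an epoch boundary.
    """

    labels: np.ndarray
    fs: float
    epochs: list[tuple[int, int]]
    n_classes: int
    segments: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.epochs = _validate_epochs(self.epochs, self.labels.size)
        self.segments = _run_segments(self.labels, self.epochs)

    @property
    def n_samples(self) -> int:
        return self.labels.size

    def labeled_samples(self) -> int:
        return int(sum((self.labels[a:b] != UNASSIGNED).sum() for a, b in self.epochs))


_SEGMENT_DTYPE = np.dtype(
    [("label", np.int64), ("start", np.int64), ("length", np.int64),
     ("trunc_left", np.bool_), ("trunc_right", np.bool_)]
)


def _run_segments(labels: np.ndarray, epochs: list[tuple[int, int]]) -> np.ndarray:
    rows = []
    for a, b in epochs:
        lab = labels[a:b]
        if lab.size == 0:
            continue
        change = np.flatnonzero(np.diff(lab)) + 1
        starts = np.concatenate(([0], change))
        stops = np.concatenate((change, [lab.size]))
        for s, e in zip(starts, stops):
            if lab[s] == UNASSIGNED:
                continue
            rows.append((lab[s], a + s, e - s, s == 0, e == lab.size))
    return np.array(rows, dtype=_SEGMENT_DTYPE)
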