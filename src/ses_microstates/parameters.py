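"""Temporal microstate parameters: duration, occurrence, coverage, transitions.

Conventions
-----------
* Runs truncated by an epoch boundary are excluded from mean **duration** by
  default (they are incomplete observations of a dwell and would bias the
  mean down) but always count toward **occurrence** and **coverage**.  With
  ``include_truncated=True`` every run counts everywhere, and the identity
  ``coverage == occurrence * duration / 1000`` holds exactly.
* **Transition probabilities** are conditional by default: ordered
  within-epoch segment pairs (i -> j, i != j), each row normalized by its
  outgoing count.  Rows with no outgoing transition are all-zero and
  reported in ``inactive_rows``.  A joint-frequency mode (counts over all
  transitions) is also available since published transition "%" figures use
  either convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Segmentation


@dataclass
class SubjectParams:
    """One subject's microstate parameter set."""

    duration_ms: np.ndarray      # per class; NaN if no counted segment
    occurrence_per_s: np.ndarray  # per class
    coverage: np.ndarray          # per class, sums to 1 over labeled time
    transition: np.ndarray        # K x K, rows conditional (or joint)
    inactive_rows: np.ndarray     # classes with no outgoing transition
    n_segments: int
    total_labeled_s: float


def _counted(seg: Segmentation, include_truncated: bool) -> np.ndarray:
    s = seg.segments
    if include_truncated or s.size == 0:
        return s
    return s[~(s["trunc_left"] | s["trunc_right"])]


def duration(seg: Segmentation, cls: int, include_truncated: bool = False) -> float:
    """Mean run length of one class in milliseconds (NaN if no counted run)."""
    s = _counted(seg, include_truncated)
    lens = s["length"][s["label"] == cls] if s.size else np.empty(0)
    if lens.size == 0:
        return float("nan")
    return float(lens.mean() / seg.fs * 1000.0)


def occurrence(seg: Segmentation, cls: int) -> float:
    """Onsets of one class per second of labeled time (all runs count)."""
    total = seg.labeled_samples() / seg.fs
    if total <= 0:
        raise ValueError("no labeled time")
    s = seg.segments
    n = int((s["label"] == cls).sum()) if s.size else 0
    return n / total


def coverage(seg: Segmentation, cls: int) -> float:
    """Fraction of labeled time spent in one class."""
    total = seg.labeled_samples()
    if total <= 0:
        raise ValueError("no labeled time")
    s = seg.segments
    covered = int(s["length"][s["label"] == cls].sum()) if s.size else 0
    return covered / total


def transition_matrix(seg: Segmentation, mode: str = "conditional") -> tuple[np.ndarray, np.ndarray]:
    """Segment-level transition probabilities, never across epoch boundaries.

    Returns ``(P, inactive_rows)``.  ``mode="conditional"`` row-normalizes the
    count matrix; ``mode="joint"`` divides by the total transition count.
    """
    if mode not in ("conditional", "joint"):
        raise ValueError("mode must be 'conditional' or 'joint'")
    K = seg.n_classes
    counts = np.zeros((K, K))
    s = seg.segments
    if s.size:
        # consecutive segments are within-epoch neighbors iff they tile and
        # the first does not end on an epoch boundary (epochs may touch)
        adjacent = (s["start"][:-1] + s["length"][:-1] == s["start"][1:]) \
            & ~s["trunc_right"][:-1]
        src = s["label"][:-1][adjacent]
        dst = s["label"][1:][adjacent]
        np.add.at(counts, (src, dst), 1.0)
    out_counts = counts.sum(axis=1)
    inactive = np.flatnonzero(out_counts == 0)
    P = np.zeros_like(counts)
    if mode == "conditional":
        active = out_counts > 0
        P[active] = counts[active] / out_counts[active, None]
    else:
        total = counts.sum()
        if total > 0:
            P = counts / total
    return P, inactive


def subject_parameters(
    seg: Segmentation,
    include_truncated: bool = False,
    transition_mode: str = "conditional",
) -> SubjectParams:
    """All four parameter families for one subject's segmentation."""
    K = seg.n_classes
    dur = np.array([duration(seg, k, include_truncated) for k in range(K)])
    occ = np.array([occurrence(seg, k) for k in range(K)])
    cov = np.array([coverage(seg, k) for k in range(K)])
    P, inactive = transition_matrix(seg, mode=transition_mode)
    return SubjectParams(
        duration_ms=dur, occurrence_per_s=occ, coverage=cov,
        transition=P, inactive_rows=inactive,
        n_segments=int(seg.segments.size),
        total_labeled_s=seg.labeled_samples() / seg.fs,
    )


def params_from_runs(
    labels: np.ndarray,
    lengths: np.ndarray,
    fs: float,
    n_classes: int,
    include_truncated: bool = False,
) -> dict[str, np.ndarray]:
    """Parameters straight from run-length encodings, batched over subjects.

    ``labels``/``lengths`` are (S, N) arrays of segment classes and segment
    lengths in samples, each row one subject's continuous (single-epoch)
    stream; the first and last run of a row count as boundary-truncated.
    Returns arrays ``duration_ms`` (S, K), ``occurrence`` (S, K),
    ``coverage`` (S, K) and ``transition`` (S, K, K) matching what
    :func:`subject_parameters` computes on the equivalent
    :class:`~ses_microstates.core.Segmentation`.
    """
    labels = np.atleast_2d(np.asarray(labels, dtype=np.int64))
    lengths = np.atleast_2d(np.asarray(lengths, dtype=np.int64))
    S, N = labels.shape
    K = n_classes
    total = lengths.sum(axis=1)  # samples per subject
    onehot = np.eye(K, dtype=np.int64)[labels]  # (S, N, K)
    cov_samples = np.einsum("snk,sn->sk", onehot, lengths)
    counts = onehot.sum(axis=1)
    if include_truncated:
        dur_sum, dur_n = cov_samples.astype(float), counts.astype(float)
    else:
        interior = onehot[:, 1:-1, :]
        dur_sum = np.einsum("snk,sn->sk", interior, lengths[:, 1:-1]).astype(float)
        dur_n = interior.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        duration_ms = np.where(dur_n > 0, dur_sum / dur_n / fs * 1000.0, np.nan)
    occ = counts / (total / fs)[:, None]
    cov = cov_samples / total[:, None]
    flat = (np.arange(S)[:, None] * K * K + labels[:, :-1] * K + labels[:, 1:]).ravel()
    trans_counts = np.bincount(flat, minlength=S * K * K).reshape(S, K, K).astype(float)
    out_counts = trans_counts.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        transition = np.where(out_counts > 0, trans_counts / out_counts, 0.0)
    return {"duration_ms": duration_ms, "occurrence": occ, "coverage": cov,
            "transition": transition}


def params_to_frame(params: dict[str, SubjectParams], class_names: list[str],
                    groups: dict[str, str] | None = None) -> pd.DataFrame:
    """Tidy per-subject x class parameter table."""
    rows = []
    for sid, p in params.items():
        for k, cname in enumerate(class_names):
            rows.append({
                "subject": sid,
                "group": (groups or {}).get(sid, ""),
                "class": cname,
                "duration_ms": p.duration_ms[k],
                "occurrence": p.occurrence_per_s[k],
                "coverage": p.coverage[k],
            })
    return pd.DataFrame(rows)


def transitions_to_frame(params: dict[str, SubjectParams], class_names: list[str],
                         groups: dict[str, str] | None = None) -> pd.DataFrame:
    """Tidy per-subject transition table with one row per ordered class pair."""
    rows = []
    for sid, p in params.items():
        K = len(class_names)
        for i in range(K):
            for j in range(K):
                if i == j:
                    continue
                rows.append({
                    "subject": sid,
                    "group": (groups or {}).get(sid, ""),
                    "from": class_names[i],
                    "to": class_names[j],
                    "probability": p.transition[i, j],
                })
    return pd.DataFrame(rows)
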