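"""Backfitting: label GFP peaks with templates and expand to every sample.

Microstate labels are categorical, so the expansion from peak labels to a
continuous stream is nearest-peak in time: every sample within an epoch takes
the label of its closest GFP peak, with an exact midpoint going to the
earlier peak.  Samples before the first (after the last) peak of an epoch
inherit that peak's label; epochs without any usable peak stay unassigned.
No temporal smoothing and no minimum-duration rejection are applied by
default.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import UNASSIGNED, GfpSeries, Recording, Segmentation, TemplateSet
from .cluster import correlation_matrix
from .signal import peak_maps

log = logging.getLogger(__name__)


def assign_peaks(maps: np.ndarray, templates: TemplateSet,
                 min_correlation: float | None = None) -> np.ndarray:
    """Label each peak map with its best-fitting template.

    Best fit is maximal polarity-invariant spatial correlation; ties take the
    lowest class index.  Flat maps (and, if ``min_correlation`` is set, maps
    below that correlation) come back UNASSIGNED.
    """
    maps = np.asarray(maps, dtype=float)
    centered = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    flat = norms == 0
    if flat.any():
        log.warning("assign_peaks: %d flat peak map(s) left unassigned", int(flat.sum()))
    labels = np.full(maps.shape[0], UNASSIGNED, dtype=int)
    ok = ~flat
    if ok.any():
        R = correlation_matrix(maps[ok], templates.maps)
        best = np.argmax(R, axis=1)
        if min_correlation is not None:
            best = np.where(R[np.arange(best.size), best] >= min_correlation,
                            best, UNASSIGNED)
        labels[ok] = best
    return labels


def interpolate_labels(
    peak_labels: np.ndarray,
    peak_indices: np.ndarray,
    epochs: list[tuple[int, int]],
    n_samples: int,
    fs: float,
    n_classes: int,
) -> Segmentation:
    """Expand peak labels to a per-sample stream by the nearest-peak rule."""
    peak_labels = np.asarray(peak_labels, dtype=int)
    peak_indices = np.asarray(peak_indices, dtype=int)
    ok = peak_labels != UNASSIGNED
    peak_labels, peak_indices = peak_labels[ok], peak_indices[ok]
    out = np.full(n_samples, UNASSIGNED, dtype=int)
    for a, b in epochs:
        sel = (peak_indices >= a) & (peak_indices < b)
        p = peak_indices[sel]
        lab = peak_labels[sel]
        if p.size == 0:
            continue
        # boundary between consecutive peaks: an exact midpoint belongs to the
        # earlier peak, so the earlier region ends at floor((p_i + p_{i+1}) / 2)
        cuts = (p[:-1] + p[1:]) // 2 + 1
        region = np.searchsorted(cuts, np.arange(a, b), side="right")
        out[a:b] = lab[region]
    return Segmentation(labels=out, fs=fs, epochs=list(epochs), n_classes=n_classes)


def backfit(rec: Recording, peaks: GfpSeries, templates: TemplateSet,
            min_correlation: float | None = None) -> Segmentation:
    """Full backfit of a recording: assign its GFP peaks, then expand."""
    maps, _ = peak_maps(rec, peaks)
    labels = assign_peaks(maps, templates, min_correlation=min_correlation)
    return interpolate_labels(labels, peaks.peak_indices, rec.epochs,
                              rec.n_samples, rec.fs, templates.K)
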