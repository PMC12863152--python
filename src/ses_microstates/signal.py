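"""Deterministic signal operations: band-pass, average reference, GFP, peaks.

Epochs are processed independently throughout: the filter never runs across
an epoch boundary and a boundary sample can never be a GFP peak.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.signal

from .core import GfpSeries, Recording

log = logging.getLogger(__name__)


def bandpass(
    rec: Recording,
    lo: float = 2.0,
    hi: float = 20.0,
    order: int = 3,
) -> Recording:
    """Zero-phase Butterworth band-pass, applied per channel per epoch.

    A Butterworth of the given order is run forward-backward (``sosfiltfilt``),
    so the effective magnitude response is the squared one and the phase is
    zero.  The default (3rd order, 6th-order magnitude after the double
    pass) is the highest order whose zero-phase ringing stays safely below a
    microstate dwell: longer impulse responses blend adjacent states into
    the peak topographies, while lower orders sag more than 1% at
    mid-band.  Epochs too short to support the filter's edge padding
    are dropped from the output's epoch list (with a logged warning); their
    samples are left untouched.
    """
    if not (0 < lo < hi < rec.fs / 2):
        raise ValueError(f"band ({lo}, {hi}) Hz invalid for fs={rec.fs}")
    sos = scipy.signal.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    # minimum length for sosfiltfilt's default edge padding, ~3x the filter span
    padlen = 3 * (2 * sos.shape[0] + 1)
    out = rec.data.copy()
    kept, dropped = [], 0
    for a, b in rec.epochs:
        if b - a <= padlen:
            dropped += 1
            continue
        out[:, a:b] = scipy.signal.sosfiltfilt(sos, rec.data[:, a:b], axis=1)
        kept.append((a, b))
    if dropped:
        log.warning("bandpass: dropped %d epoch(s) shorter than %d samples", dropped, padlen + 1)
    if not kept:
        raise ValueError("no epoch long enough to filter")
    return rec.copy_with(data=out, epochs=kept)


def average_reference(rec: Recording) -> Recording:
    """Re-reference to the instantaneous whole-scalp mean (idempotent)."""
    return rec.copy_with(data=rec.data - rec.data.mean(axis=0, keepdims=True))


def gfp(rec: Recording) -> GfpSeries:
    """Global field power: the spatial standard deviation of each map.

    Population form (divisor = number of channels), computed around the
    spatial mean so the result is reference-free.
    """
    return GfpSeries(values=rec.data.std(axis=0, ddof=0), fs=rec.fs, epochs=list(rec.epochs))


def _peaks_1d(v: np.ndarray) -> np.ndarray:
    """Strict local maxima of one epoch; a plateau counts once, at its first
    sample; the first and last samples are never peaks."""
    n = v.size
    if n < 3:
        return np.empty(0, dtype=int)
    d = np.sign(np.diff(v))
    # carry the last nonzero slope over plateaus so a flat top still registers
    rising = d.copy()
    for i in range(1, rising.size):
        if rising[i] == 0:
            rising[i] = rising[i - 1]
    peaks = np.flatnonzero((rising[:-1] > 0) & (d[1:] < 0)) + 1
    # shift each detection to the first sample of its plateau
    out = []
    for p in peaks:
        q = p
        while q > 1 and v[q - 1] == v[q]:
            q -= 1
        if q > 0:
            out.append(q)
    return np.unique(out).astype(int)


def find_gfp_peaks(
    g: GfpSeries,
    min_distance: int | None = None,
    min_prominence: float | None = None,
) -> GfpSeries:
    """Locate GFP peaks within each epoch.

    Default rule: strict local maxima (plateaus take their first sample),
    excluding epoch-boundary samples.  Optional minimum peak spacing (samples)
    and prominence constraints are available but off by default.
    """
    all_peaks = []
    empty = 0
    for a, b in g.epochs:
        v = g.values[a:b]
        if min_distance is not None or min_prominence is not None:
            idx, _ = scipy.signal.find_peaks(v, distance=min_distance, prominence=min_prominence)
        else:
            idx = _peaks_1d(v)
        if idx.size == 0:
            empty += 1
            continue
        all_peaks.append(idx + a)
    if empty:
        log.warning("find_gfp_peaks: %d epoch(s) contained no peak", empty)
    peaks = np.concatenate(all_peaks) if all_peaks else np.empty(0, dtype=int)
    return GfpSeries(values=g.values, fs=g.fs, epochs=list(g.epochs), peak_indices=peaks)


def peak_maps(rec: Recording, peaks: GfpSeries) -> tuple[np.ndarray, np.ndarray]:
    """Topographies and GFP weights at the detected peaks.

    Returns ``(maps, weights)`` with ``maps`` of shape (n_peaks, n_channels).
    """
    idx = peaks.peak_indices
    return rec.data[:, idx].T.copy(), peaks.values[idx].copy()
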