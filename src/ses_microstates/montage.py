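"""Working electrode montage and the canonical A-D reference atlas.

The pipeline operates on a 60-channel subset of the international 10-10
system (a typical 64-channel cap minus reference/ocular sites).  Electrode
positions come from MNE's standard montage and are flattened to 2-D by
azimuthal-equidistant projection about the vertex, which is all the atlas
needs: the canonical reference maps are smooth parametric patterns over that
disc, not measurements.

Atlas construction
------------------
The four canonical resting-state microstate classes are encoded as:

* **A** - diagonal gradient, left-posterior to right-frontal
  (the "left-right" orientation),
* **B** - the mirror diagonal, right-posterior to left-frontal,
* **C** - anterior-posterior gradient with an occipital extreme,
* **D** - a fronto-central radial maximum.

Gradients use direction cosines (0.8, 0.6) so that A and B are close to
orthogonal while each keeps the moderate correlation with C that real
canonical maps show.  All maps are average-referenced and unit-normalized;
polarity is a free sign everywhere downstream.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .core import TemplateSet, canonical_sign, normalize_map

#: 60-channel working montage (10-10 names, frontal to occipital).
CHANNELS_60: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "AF3", "AF4",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2",
)


@lru_cache(maxsize=4)
def channel_positions(ch_names: tuple[str, ...] = CHANNELS_60) -> np.ndarray:
    """2-D electrode positions, (n_channels, 2), x = right, y = anterior.

    Azimuthal-equidistant projection of the standard 10-05 sphere positions:
    radius is the polar angle from the vertex (normalized so the outermost
    electrode sits at 1), angle is the azimuth in the axial plane.
    """
    import mne  # deferred: mne import is slow

    with np.errstate(invalid="ignore"):
        try:
            std = mne.channels.make_standard_montage("colin27_1005")
        except ValueError:  # older MNE
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                std = mne.channels.make_standard_montage("standard_1005")
    pos3 = std.get_positions()["ch_pos"]
    missing = [n for n in ch_names if n not in pos3]
    if missing:
        raise KeyError(f"channels not in standard montage: {missing}")
    xyz = np.array([pos3[n] for n in ch_names], dtype=float)
    r = np.linalg.norm(xyz, axis=1)
    theta = np.arccos(np.clip(xyz[:, 2] / r, -1.0, 1.0))  # polar angle from vertex
    rho = np.hypot(xyz[:, 0], xyz[:, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        ux = np.where(rho > 0, xyz[:, 0] / rho, 0.0)
        uy = np.where(rho > 0, xyz[:, 1] / rho, 0.0)
    theta = theta / theta.max()
    return np.column_stack((theta * ux, theta * uy))


def _atlas_patterns(xy: np.ndarray) -> np.ndarray:
    x, y = xy[:, 0], xy[:, 1]
    a = 0.8 * x + 0.6 * y
    b = -0.8 * x + 0.6 * y
    c = -y
    d = np.exp(-((x - 0.0) ** 2 + (y - 0.25) ** 2) / (2 * 0.30**2))
    return np.stack([a, b, c, d])


def canonical_atlas(ch_names: tuple[str, ...] = CHANNELS_60) -> TemplateSet:
    """The canonical A-D reference TemplateSet on the working montage."""
    xy = channel_positions(tuple(ch_names))
    maps = _atlas_patterns(xy)
    maps = np.stack([canonical_sign(normalize_map(m)) for m in maps])
    return TemplateSet(maps=maps, labels=list("ABCD"), ch_names=list(ch_names), level="atlas")
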