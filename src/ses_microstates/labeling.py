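"""Sorting fitted templates into the canonical A/B/C/D order.

Maps are matched to a reference set by optimal one-to-one assignment on the
polarity-invariant spatial correlation matrix (Hungarian algorithm, so the
result never depends on input order), then reordered, relabeled, and
sign-aligned with their references.  Group templates are sorted against the
built-in canonical atlas; individual templates are sorted against their own
group's sorted templates.
"""

from __future__ import annotations

import numpy as np
import scipy.optimize

from .core import TemplateSet
from .cluster import correlation_matrix


def sort_templates(unsorted: TemplateSet, reference: TemplateSet) -> TemplateSet:
    """Reorder/relabel ``unsorted`` to best match ``reference``.

    Maximizes the total absolute spatial correlation over all one-to-one
    assignments; each map's sign is flipped if needed so it correlates
    positively with its reference.  Idempotent.
    """
    if unsorted.K != reference.K:
        raise ValueError(f"K mismatch: {unsorted.K} vs {reference.K}")
    if unsorted.ch_names != reference.ch_names:
        raise ValueError("montage mismatch between template sets")
    R = correlation_matrix(unsorted.maps, reference.maps)
    rows, cols = scipy.optimize.linear_sum_assignment(-R)
    order = np.empty(unsorted.K, dtype=int)
    order[cols] = rows  # order[j] = index of the unsorted map assigned to reference j
    maps = unsorted.maps[order].copy()
    signed = np.einsum("ij,ij->i", maps, reference.maps)
    maps[signed < 0] *= -1.0
    return TemplateSet(maps=maps, labels=list(reference.labels),
                       ch_names=list(unsorted.ch_names), level=unsorted.level)


def assignment_quality(sorted_set: TemplateSet, reference: TemplateSet) -> np.ndarray:
    """Per-class |r| between a sorted set and its reference (diagnostic)."""
    R = correlation_matrix(sorted_set.maps, reference.maps)
    return np.diag(R).copy()
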