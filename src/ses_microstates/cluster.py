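"""Polarity-invariant AAHC clustering of GFP-peak topographies, and GEV.

Atomize-Agglomerate Hierarchical Clustering starts from every map in its own
cluster and repeatedly dissolves ("atomizes") the cluster that contributes
least global explained variance, reassigning each freed map independently to
the surviving cluster whose centroid it matches best by absolute spatial
correlation.  Centroids are the first principal direction of the member maps
(the sign-aligned mean), which is the correct average when a map and its
polarity reverse count as the same state.  The procedure is deterministic
given the input order; ties go to the lowest cluster index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .core import TemplateSet, canonical_sign, center_map, normalize_map


def spatial_correlation(a: np.ndarray, b: np.ndarray, polarity_invariant: bool = True) -> float:
    """Pearson correlation between two topographies across channels.

    With ``polarity_invariant`` (the default everywhere in this pipeline) the
    absolute value is returned, treating a map and its sign reverse as the
    same state.  Flat maps have no defined correlation and are rejected.
    """
    ua = normalize_map(np.asarray(a, dtype=float))
    ub = normalize_map(np.asarray(b, dtype=float))
    r = float(ua @ ub)
    r = max(-1.0, min(1.0, r))
    return abs(r) if polarity_invariant else r


def correlation_matrix(maps: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Absolute spatial correlation of each map (rows) with each template."""
    U = np.stack([normalize_map(m) for m in np.asarray(maps, dtype=float)])
    V = np.stack([normalize_map(t) for t in np.asarray(templates, dtype=float)])
    return np.abs(np.clip(U @ V.T, -1.0, 1.0))


@dataclass
class ClusterFit:
    """Result of clustering one subject's (or one pool's) peak maps."""

    templates: TemplateSet
    assignment: np.ndarray  # per input map, cluster index
    gev_total: float
    gev_per_class: np.ndarray


def _leading_direction(S: np.ndarray) -> np.ndarray:
    """Unit leading eigenvector of a scatter matrix, sign-canonicalized."""
    w, v = scipy.linalg.eigh(S, subset_by_index=(S.shape[0] - 1, S.shape[0] - 1))
    return canonical_sign(v[:, 0])


def aahc(maps: np.ndarray, weights: np.ndarray, K: int) -> ClusterFit:
    """Cluster peak topographies into K classes by polarity-invariant AAHC.

    Parameters
    ----------
    maps : (n, C) array
        Average-referenced peak topographies (duplicates allowed).
    weights : (n,) array
        GFP at each peak; enters both the explained-variance criterion and,
        through the maps' own amplitudes, the centroids.
    K : int
        Number of clusters to stop at.
    """
    X = center_map(np.asarray(maps, dtype=float))
    n, C = X.shape
    if n < K:
        raise ValueError(f"need at least K={K} maps, got {n}")
    if K < 1:
        raise ValueError("K must be >= 1")
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValueError("flat (zero-variance) map in input")
    U = X / norms[:, None]
    w2 = np.asarray(weights, dtype=float) ** 2
    if w2.shape != (n,):
        raise ValueError("weights must be one scalar per map")
    total = float(w2.sum())

    members: list[list[int]] = [[i] for i in range(n)]
    centroids = np.stack([canonical_sign(u) for u in U])
    contrib = w2.copy().astype(float)  # singleton: |r| = 1
    scatter: list[np.ndarray | None] = [None] * n  # built lazily for multi-member clusters

    def recompute(t: int) -> None:
        idx = members[t]
        if scatter[t] is None:
            scatter[t] = X[idx].T @ X[idx]
        centroids[t] = _leading_direction(scatter[t])
        r = U[idx] @ centroids[t]
        contrib[t] = float(w2[idx] @ (r * r))

    while len(members) > K:
        victim = int(np.argmin(contrib))  # ties -> lowest index
        freed = members.pop(victim)
        scatter.pop(victim)
        centroids = np.delete(centroids, victim, axis=0)
        contrib = np.delete(contrib, victim)

        R = np.abs(U[freed] @ centroids.T)  # (m, n_clusters)
        targets = np.argmax(R, axis=1)  # argmax takes the lowest index on ties
        touched = set()
        for i, t in zip(freed, targets):
            t = int(t)
            if scatter[t] is None:
                idx = members[t]
                scatter[t] = X[idx].T @ X[idx]
            scatter[t] += np.outer(X[i], X[i])
            members[t].append(i)
            touched.add(t)
        for t in touched:
            recompute(t)

    assignment = np.empty(n, dtype=int)
    for k, idx in enumerate(members):
        assignment[idx] = k
    tset = TemplateSet(
        maps=np.stack([normalize_map(c) for c in centroids]),
        labels=[str(k) for k in range(len(members))],
        ch_names=[f"ch{j}" for j in range(C)],
        level="individual",
    )
    gt, gpc = gev(X, np.sqrt(w2), tset.maps, assignment)
    return ClusterFit(templates=tset, assignment=assignment, gev_total=gt, gev_per_class=gpc)


def gev(
    maps: np.ndarray,
    weights: np.ndarray,
    templates: np.ndarray | TemplateSet,
    assignment: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Global explained variance of an assignment of maps to templates.

    GEV = sum_t (GFP_t * r_t)^2 / sum_t GFP_t^2 where r_t is the spatial
    correlation between map t and its assigned template.  The per-class
    vector partitions the numerator by assigned class, so it sums to the
    total.
    """
    tmaps = templates.maps if isinstance(templates, TemplateSet) else np.asarray(templates, float)
    K = tmaps.shape[0]
    assignment = np.asarray(assignment, dtype=int)
    X = center_map(np.asarray(maps, dtype=float))
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValueError("flat map has undefined correlation")
    U = X / norms[:, None]
    V = np.stack([normalize_map(t) for t in tmaps])
    r = np.abs(np.einsum("ij,ij->i", U, V[assignment]))
    w2 = np.asarray(weights, dtype=float) ** 2
    num = w2 * r * r
    denom = float(w2.sum())
    per_class = np.array([num[assignment == k].sum() for k in range(K)]) / denom
    return float(num.sum() / denom), per_class


def fit_subject(maps: np.ndarray, weights: np.ndarray, K: int = 4,
                max_maps: int | None = None) -> ClusterFit:
    """AAHC for one subject, optionally on an evenly spaced subsample of peaks.

    ``max_maps`` caps the number of peak maps entering the clustering (taken
    evenly across the recording, so all conditions are represented); the
    final fit statistics are still computed on every peak by reassigning the
    full set to the fitted templates.
    """
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    if max_maps is not None and n > max_maps:
        keep = np.linspace(0, n - 1, max_maps).round().astype(int)
        sub = aahc(maps[keep], np.asarray(weights, float)[keep], K)
        R = correlation_matrix(maps, sub.templates.maps)
        assignment = np.argmax(R, axis=1)
        gt, gpc = gev(maps, weights, sub.templates.maps, assignment)
        return ClusterFit(templates=sub.templates, assignment=assignment,
                          gev_total=gt, gev_per_class=gpc)
    return aahc(maps, weights, K)


def group_templates_mean(individual: list[TemplateSet]) -> TemplateSet:
    """Label-wise polarity-aligned averaging of already-sorted template sets.

    Alternative to the re-clustering route: assumes every set carries the
    same labels in the same order (i.e. each subject's maps were sorted
    first).  Each class's group map is the first principal direction of the
    subjects' maps for that class.
    """
    if not individual:
        raise ValueError("no individual template sets given")
    first = individual[0]
    for i, ts in enumerate(individual):
        if ts.ch_names != first.ch_names:
            raise ValueError(f"montage mismatch for subject index {i}")
        if ts.labels != first.labels:
            raise ValueError(f"label order mismatch for subject index {i}; "
                             "sort the sets before averaging")
    maps = []
    for k in range(first.K):
        member = np.stack([ts.maps[k] for ts in individual])
        maps.append(_leading_direction(member.T @ member))
    return TemplateSet(maps=np.stack([normalize_map(m) for m in maps]),
                       labels=list(first.labels), ch_names=list(first.ch_names),
                       level="group")


def group_templates(individual: list[TemplateSet], K: int = 4) -> TemplateSet:
    """Pool subjects' individual templates and re-cluster them at the same K.

    The standard two-level procedure: each subject contributes its K fitted
    maps with uniform weight, and a second AAHC pass over the pool yields the
    group template set.
    """
    if not individual:
        raise ValueError("no individual template sets given")
    ch = individual[0].ch_names
    for i, ts in enumerate(individual):
        if ts.ch_names != ch:
            raise ValueError(f"montage mismatch for subject index {i}")
        if ts.K != individual[0].K:
            raise ValueError(f"K mismatch for subject index {i}")
    pool = np.concatenate([ts.maps for ts in individual], axis=0)
    fit = aahc(pool, np.ones(pool.shape[0]), K)
    return TemplateSet(maps=fit.templates.maps, labels=[str(k) for k in range(K)],
                       ch_names=list(ch), level="group")
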