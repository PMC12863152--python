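"""Synthetic resting-state EEG with known microstate ground truth.

The generator is the converse of the analysis pipeline: a semi-Markov label
stream selects one of K template topographies at each instant, the chosen map
is modulated by a sinusoidal carrier, and spatially white Gaussian noise is
added at a configurable signal-to-noise ratio.  Because the carrier changes
sign every half period, the emitted topography alternates polarity within a
microstate — exactly the property that motivates polarity-invariant analysis.

Microstate boundaries are quantized to half carrier periods by default
(``quantized=True``): states switch where the carrier crosses zero, i.e. at
GFP troughs, mirroring the empirical observation that topographies are stable
around GFP peaks and change in the troughs.  Dwell times are then a geometric
number of half-periods with the requested per-class mean.  Unquantized
geometric/gamma dwell laws are available for stream-level studies.

Every operation takes an explicit seed or generator; identical seeds give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import UNASSIGNED, Recording, Segmentation, TemplateSet
from .montage import CHANNELS_60, canonical_atlas


def _check_transition(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    K = P.shape[0]
    if P.shape != (K, K):
        raise ValueError("transition matrix must be square")
    if np.any(np.diag(P) != 0):
        raise ValueError("transition matrix diagonal must be exactly 0")
    sums = P.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-12)
    if bad.size:
        raise ValueError(f"transition row {bad[0]} sums to {sums[bad[0]]!r}, not 1")
    if np.any(P < 0):
        raise ValueError("transition probabilities must be nonnegative")
    return P


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of the embedded segment chain."""
    K = P.shape[0]
    A = np.vstack([P.T - np.eye(K), np.ones(K)])
    b = np.zeros(K + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return np.clip(pi, 0, None) / pi.sum()


@dataclass
class GroundTruth:
    """Generative parameters for one synthetic subject (or a whole cohort)."""

    templates: TemplateSet
    transition: np.ndarray
    mean_dwell_ms: np.ndarray
    carrier_freq: float = 10.0
    snr: float = 1.0
    gain: float = 30.0  # microvolt scale of the rendered maps
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition = _check_transition(self.transition)
        self.mean_dwell_ms = np.asarray(self.mean_dwell_ms, dtype=float)
        K = self.templates.K
        if self.transition.shape != (K, K) or self.mean_dwell_ms.shape != (K,):
            raise ValueError("transition / mean_dwell size must match template count")
        if np.any(self.mean_dwell_ms <= 0):
            raise ValueError("mean dwell times must be positive")
        if not (1.0 < self.carrier_freq < 40.0):
            raise ValueError("carrier frequency must lie in (1, 40) Hz")
        T = self.templates.maps
        R = np.abs(T @ T.T) - np.eye(K)
        if R.max() >= 0.95:
            raise ValueError("templates too similar (pairwise |r| >= 0.95)")


def default_ground_truth(seed: int = 0, snr: float = 1.0,
                         carrier_freq: float = 10.0) -> GroundTruth:
    """Study-like defaults: canonical A-D maps, uniform switching, field-typical
    dwell times (70-90 ms)."""
    atlas = canonical_atlas()
    K = atlas.K
    P = (np.ones((K, K)) - np.eye(K)) / (K - 1)
    return GroundTruth(
        templates=atlas,
        transition=P,
        mean_dwell_ms=np.array([80.0, 70.0, 90.0, 75.0]),
        carrier_freq=carrier_freq,
        snr=snr,
        seed=seed,
    )


def _draw_dwell(rng: np.random.Generator, mean_samples: float, law: str,
                quantum: int | None, gamma_shape: float) -> int:
    if quantum:
        mean_units = mean_samples / quantum
        if mean_units < 1.0:
            raise ValueError("mean dwell shorter than the dwell quantum")
        return quantum * int(rng.geometric(1.0 / mean_units))
    if law == "geometric":
        return int(rng.geometric(min(1.0, 1.0 / mean_samples)))
    if law == "gamma":
        return max(1, int(round(rng.gamma(gamma_shape, mean_samples / gamma_shape))))
    raise ValueError(f"unknown dwell law {law!r}")


def sample_label_stream(
    gt: GroundTruth,
    duration_s: float,
    fs: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    epoch_s: float | None = None,
    dwell_law: str = "geometric",
    gamma_shape: float = 2.0,
    quantized: bool = True,
) -> Segmentation:
    """Draw a semi-Markov microstate label stream.

    Segment classes follow ``gt.transition`` (consecutive segments never share
    a class since the diagonal is zero); segment lengths follow the chosen
    dwell law with per-class means ``gt.mean_dwell_ms``.  With ``quantized``
    the lengths are multiples of the half carrier period, so switches align
    with carrier zero crossings.  ``epoch_s`` chops the stream into equal
    epochs (the stream itself is continuous across the cuts).
    """
    if rng is None:
        rng = np.random.default_rng(gt.seed if seed is None else seed)
    n_samples = int(round(duration_s * fs))
    dwell = gt.mean_dwell_ms * fs / 1000.0
    if n_samples < 10 * dwell.max():
        raise ValueError("duration too short: need >= 10x the longest mean dwell")
    quantum = None
    if quantized:
        quantum = int(round(fs / (2.0 * gt.carrier_freq)))
        if abs(quantum - fs / (2.0 * gt.carrier_freq)) > 1e-9:
            raise ValueError("fs must be a multiple of twice the carrier frequency "
                             "for quantized dwell sampling")
    K = gt.transition.shape[0]
    cum = np.cumsum(gt.transition, axis=1)
    state = int(rng.choice(K, p=stationary_distribution(gt.transition)))
    labels = np.empty(n_samples, dtype=int)
    t = 0
    while t < n_samples:
        length = _draw_dwell(rng, dwell[state], dwell_law, quantum, gamma_shape)
        labels[t:t + length] = state
        t += length
        state = int(np.searchsorted(cum[state], rng.random(), side="right"))
    if epoch_s is None:
        epochs = [(0, n_samples)]
    else:
        step = int(round(epoch_s * fs))
        epochs = [(a, min(a + step, n_samples)) for a in range(0, n_samples, step)]
    return Segmentation(labels=labels, fs=fs, epochs=epochs, n_classes=K)


def render_eeg(
    seg: Segmentation,
    gt: GroundTruth,
    fs: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Recording:
    """Render a label stream to average-referenced multichannel EEG.

    Sample t is ``templates[label(t)] * sin(2 pi f t / fs) * gain`` plus
    spatially white Gaussian noise scaled so that total signal power over
    noise power equals ``gt.snr``.
    """
    if fs < 2.0 * gt.carrier_freq:
        raise ValueError("fs below twice the carrier frequency (aliasing)")
    if np.any(seg.labels == UNASSIGNED):
        raise ValueError("label stream must be fully assigned before rendering")
    if rng is None:
        rng = np.random.default_rng(gt.seed if seed is None else seed)
    T = seg.labels.size
    env = np.sin(2.0 * np.pi * gt.carrier_freq * np.arange(T) / fs)
    X = gt.templates.maps[seg.labels] * (gt.gain * env)[:, None]  # (T, C)
    if np.isfinite(gt.snr):
        p_signal = float(np.mean(X**2))
        sigma = np.sqrt(p_signal / gt.snr)
        X = X + rng.normal(0.0, sigma, size=X.shape)
    data = X.T - X.T.mean(axis=0, keepdims=True)
    return Recording(data=data, fs=fs, ch_names=list(gt.templates.ch_names),
                     epochs=list(seg.epochs))


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class GroupSpec:
    """Per-group generative offsets and covariate distributions.

    ``dwell_factors`` multiply the per-class mean dwell times;
    ``transition_factors`` multiply transition entries before row
    renormalization.  ``edu_range`` / ``occ_range`` are inclusive integer
    ranges for the parental education (1-5) and occupation (1-10) scales used
    to synthesize the demographic table.
    """

    n_subjects: int
    dwell_factors: np.ndarray = field(default_factory=lambda: np.ones(4))
    transition_factors: np.ndarray | None = None
    age_mean: float = 19.6
    age_sd: float = 1.7
    p_female: float = 0.64
    edu_range: tuple[int, int] = (1, 5)
    occ_range: tuple[int, int] = (1, 10)
    subject_jitter_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects per group")
        self.dwell_factors = np.asarray(self.dwell_factors, dtype=float)
        if self.transition_factors is not None:
            self.transition_factors = np.asarray(self.transition_factors, dtype=float)

    def apply(self, gt: GroundTruth) -> GroundTruth:
        """Ground truth with this group's offsets applied."""
        dwell = gt.mean_dwell_ms * self.dwell_factors
        P = gt.transition.copy()
        if self.transition_factors is not None:
            P = P * self.transition_factors
            np.fill_diagonal(P, 0.0)
            P = P / P.sum(axis=1, keepdims=True)
        return replace(gt, transition=P, mean_dwell_ms=dwell)


def low_ses_contrast_spec(n_subjects: int = 29, strength: float = 1.0) -> GroupSpec:
    """Direction-of-effect preset for the low-SES group.

    Encodes the reported qualitative pattern: longer/more frequent microstate
    A (class-A dwell up 30 percent at unit strength), depressed traffic into
    and out of C via B and D, and elevated A<->B / A<->D switching, which
    together lower C's occurrence and coverage.  ``strength`` scales the
    log-offsets (0 = null group).
    """
    up, down = 1.4**strength, 0.7**strength
    F = np.ones((4, 4))
    A, B, C, D = range(4)
    F[A, B] = F[B, A] = F[A, D] = F[D, A] = up
    F[B, C] = F[C, B] = F[C, D] = F[D, C] = down
    return GroupSpec(
        n_subjects=n_subjects,
        dwell_factors=np.array([1.3**strength, 1.0, 1.0, 1.0]),
        transition_factors=F,
        edu_range=(1, 3),
        occ_range=(1, 4),
    )


def high_ses_spec(n_subjects: int = 29) -> GroupSpec:
    """Reference (high-SES) group: no generative offsets, upper SES scales."""
    return GroupSpec(n_subjects=n_subjects, edu_range=(3, 5), occ_range=(6, 10))


def _jitter_subject(gt: GroundTruth, sd: float, rng: np.random.Generator,
                    seed: int) -> GroundTruth:
    dwell = gt.mean_dwell_ms * rng.lognormal(0.0, sd, size=gt.mean_dwell_ms.shape)
    P = gt.transition * rng.lognormal(0.0, sd, size=gt.transition.shape)
    np.fill_diagonal(P, 0.0)
    P = P / P.sum(axis=1, keepdims=True)
    return replace(gt, transition=P, mean_dwell_ms=dwell, seed=seed)


@dataclass
class Cohort:
    """A simulated two-group cohort: per-subject ground truths plus
    demographics.  Recordings are rendered on demand to keep memory flat."""

    subject_gt: dict[str, GroundTruth]
    demographics: pd.DataFrame
    duration_s: float
    fs: float
    epoch_s: float

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subject_gt)

    def groups(self) -> dict[str, str]:
        return dict(zip(self.demographics["subject_id"], self.demographics["group"]))

    def labels(self, subject_id: str) -> Segmentation:
        gt = self.subject_gt[subject_id]
        return sample_label_stream(gt, self.duration_s, self.fs, seed=gt.seed,
                                   epoch_s=self.epoch_s)

    def render(self, subject_id: str) -> Recording:
        gt = self.subject_gt[subject_id]
        seg = self.labels(subject_id)
        return render_eeg(seg, gt, self.fs, seed=gt.seed + 1)

    def manifest(self) -> dict:
        return {
            "duration_s": self.duration_s,
            "fs": self.fs,
            "epoch_s": self.epoch_s,
            "subjects": {
                sid: {
                    "seed": int(gt.seed),
                    "snr": gt.snr,
                    "carrier_freq": gt.carrier_freq,
                    "mean_dwell_ms": gt.mean_dwell_ms.tolist(),
                    "transition": gt.transition.tolist(),
                }
                for sid, gt in self.subject_gt.items()
            },
        }


def _demographic_rows(spec: GroupSpec, group: str, ids: list[str],
                      rng: np.random.Generator) -> list[dict]:
    rows = []
    for sid in ids:
        age = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 17, 26))
        rows.append({
            "subject_id": sid,
            "group": group,
            "age": round(age, 1),
            "gender": "F" if rng.random() < spec.p_female else "M",
            "parent_edu_1": int(rng.integers(spec.edu_range[0], spec.edu_range[1] + 1)),
            "parent_edu_2": int(rng.integers(spec.edu_range[0], spec.edu_range[1] + 1)),
            "parent_occ_1": int(rng.integers(spec.occ_range[0], spec.occ_range[1] + 1)),
            "parent_occ_2": int(rng.integers(spec.occ_range[0], spec.occ_range[1] + 1)),
        })
    return rows


def simulate_cohort(
    spec_low: GroupSpec,
    spec_high: GroupSpec,
    gt: GroundTruth | None = None,
    duration_s: float = 240.0,
    fs: float = 1000.0,
    epoch_s: float = 2.0,
    seed: int = 0,
) -> Cohort:
    """Simulate a two-group cohort mirroring an extreme-group study design.

    Each subject gets the shared ground truth with the group's offsets plus
    multiplicative log-normal subject jitter on dwell means and transition
    entries, and a private derived seed.  Recordings default to 240 s of
    1000 Hz EEG cut into 2-s epochs.
    """
    if gt is None:
        gt = default_ground_truth(seed=seed)
    rng = np.random.default_rng(seed)
    subject_gt: dict[str, GroundTruth] = {}
    demo_rows: list[dict] = []
    counter = 1
    for spec, group in ((spec_low, "low"), (spec_high, "high")):
        base = spec.apply(gt)
        ids = [f"S{counter + i:03d}" for i in range(spec.n_subjects)]
        counter += spec.n_subjects
        for sid in ids:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            subject_gt[sid] = _jitter_subject(base, spec.subject_jitter_sd, rng, sub_seed)
        demo_rows.extend(_demographic_rows(spec, group, ids, rng))
    demo = pd.DataFrame(demo_rows)
    return Cohort(subject_gt=subject_gt, demographics=demo,
                  duration_s=duration_s, fs=fs, epoch_s=epoch_s)


def sample_ses_survey(n: int = 107, seed: int = 0) -> pd.DataFrame:
    """A full-range demographic survey (for extreme-group splitting).

    One latent family SES factor drives correlated parental education and
    occupation scores, so the composite has realistic spread without ties
    dominating the ranking.
    """
    rng = np.random.default_rng(seed)
    latent = rng.normal(0.0, 1.0, size=n)
    rows = []
    for i in range(n):
        edu = np.clip(np.round(3.0 + 1.1 * latent[i] + rng.normal(0, 0.6, 2)), 1, 5)
        occ = np.clip(np.round(5.5 + 2.2 * latent[i] + rng.normal(0, 1.2, 2)), 1, 10)
        rows.append({
            "subject_id": f"P{i + 1:03d}",
            "group": "",
            "age": round(float(np.clip(rng.normal(19.6, 1.7), 17, 26)), 1),
            "gender": "F" if rng.random() < 0.64 else "M",
            "parent_edu_1": int(edu[0]), "parent_edu_2": int(edu[1]),
            "parent_occ_1": int(occ[0]), "parent_occ_2": int(occ[1]),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fast segment-level cohort simulation (for statistical calibration studies)


def sample_segment_cohort(
    transition: np.ndarray,
    mean_dwell_samples: np.ndarray,
    n_segments: int,
    fs: float,
    quantum: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized semi-Markov segment sampler for many subjects at once.

    ``transition`` is (S, K, K), ``mean_dwell_samples`` is (S, K); returns
    ``(labels, lengths)`` each (S, n_segments), lengths in samples (multiples
    of ``quantum``).  This is the segment-level equivalent of
    :func:`sample_label_stream` and is validated against it in the test
    suite; it exists so that thousand-replicate calibration studies of the
    statistics layer stay cheap.
    """
    S, K, _ = transition.shape
    cum = np.cumsum(transition, axis=2)
    labels = np.empty((S, n_segments), dtype=np.int64)
    rows = np.arange(S)
    state = rng.integers(0, K, size=S)
    for t in range(n_segments):
        labels[:, t] = state
        u = rng.random(S)
        state = (cum[rows, state] < u[:, None]).sum(axis=1)
    mean_units = np.maximum(mean_dwell_samples[rows[:, None], labels] / quantum, 1.0)
    lengths = quantum * rng.geometric(1.0 / mean_units)
    return labels, lengths
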