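"""End-to-end orchestration: filter -> reference -> GFP peaks -> AAHC ->
group templates -> canonical sorting -> backfit -> parameters -> statistics.

The driver is two-pass and memory-flat: recordings are consumed one at a
time, only each subject's GFP-peak topographies are retained for the second
(backfit) pass.  Group templates are fitted per group, sorted against the
canonical atlas, and each subject's individual templates are sorted against
their own group's sorted templates before backfitting — so every subject is
labeled with their *own* maps, in the canonical A-D order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from . import stats as st
from .backfit import assign_peaks, interpolate_labels
from .cluster import ClusterFit, fit_subject, gev, group_templates
from .core import CLASS_NAMES, Recording, Segmentation, TemplateSet
from .labeling import sort_templates
from .montage import canonical_atlas
from .parameters import (SubjectParams, params_to_frame, subject_parameters,
                         transitions_to_frame)
from .signal import average_reference, bandpass, find_gfp_peaks, gfp, peak_maps

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved pipeline settings; archived beside every run's outputs."""

    band_lo: float = 2.0
    band_hi: float = 20.0
    K: int = 4
    polarity_invariant: bool = True
    min_peak_distance: int | None = None
    min_peak_prominence: float | None = None
    min_correlation: float | None = None
    include_truncated: bool = False
    transition_mode: str = "conditional"
    split_fraction: float = 0.27
    correlation_sample: str = "grouped"  # or "all"
    max_maps_per_subject: int | None = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.polarity_invariant:
            raise ValueError("only polarity-invariant analysis is supported; "
                             "the flag exists to make the convention explicit")
        if self.transition_mode not in ("conditional", "joint"):
            raise ValueError("transition_mode must be 'conditional' or 'joint'")
        if self.correlation_sample not in ("grouped", "all"):
            raise ValueError("correlation_sample must be 'grouped' or 'all'")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)


@dataclass
class SubjectFit:
    """Stage-one result for one subject: peaks and individual templates."""

    subject: str
    peak_topographies: np.ndarray
    peak_gfp: np.ndarray
    peak_indices: np.ndarray
    fs: float
    epochs: list[tuple[int, int]]
    n_samples: int
    fit: ClusterFit
    n_peaks: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_peaks = self.peak_topographies.shape[0]


def preprocess(rec: Recording, config: PipelineConfig) -> Recording:
    """Band-pass then average-reference (the microstate-stage preprocessing;
    acquisition-stage cleaning is assumed already done upstream)."""
    return average_reference(bandpass(rec, config.band_lo, config.band_hi))


def fit_one_subject(subject: str, rec: Recording, config: PipelineConfig) -> SubjectFit:
    """Filter, reference, detect GFP peaks and cluster one subject."""
    clean = preprocess(rec, config)
    peaks = find_gfp_peaks(gfp(clean), min_distance=config.min_peak_distance,
                           min_prominence=config.min_peak_prominence)
    maps, weights = peak_maps(clean, peaks)
    if maps.shape[0] < config.K:
        raise RuntimeError(f"subject {subject}: only {maps.shape[0]} GFP peaks")
    fit = fit_subject(maps, weights, K=config.K, max_maps=config.max_maps_per_subject)
    log.info("subject %s: %d peaks, individual GEV %.4f", subject, maps.shape[0],
             fit.gev_total)
    return SubjectFit(subject=subject, peak_topographies=maps, peak_gfp=weights,
                      peak_indices=peaks.peak_indices, fs=rec.fs,
                      epochs=list(rec.epochs), n_samples=rec.n_samples, fit=fit)


@dataclass
class CohortResult:
    """Everything downstream analyses need from a fitted cohort."""

    group_template_sets: dict[str, TemplateSet]
    subject_templates: dict[str, TemplateSet]
    subject_params: dict[str, SubjectParams]
    subject_gev: pd.DataFrame
    params: pd.DataFrame
    transitions: pd.DataFrame
    segmentations: dict[str, Segmentation] | None = None


def analyze_cohort(
    recordings: Iterable[tuple[str, Recording]] | Iterator[tuple[str, Recording]],
    groups: dict[str, str],
    config: PipelineConfig | None = None,
    keep_segmentations: bool = False,
) -> CohortResult:
    """Run the full microstate pipeline over a cohort.

    ``recordings`` yields ``(subject_id, Recording)`` pairs (consumed once,
    so a generator keeps memory flat); ``groups`` maps each subject to its
    group label.
    """
    config = config or PipelineConfig()
    atlas = canonical_atlas()

    fits: dict[str, SubjectFit] = {}
    for sid, rec in recordings:
        if sid not in groups:
            raise ValueError(f"subject {sid} has no group assignment")
        fits[sid] = fit_one_subject(sid, rec, config)
    if not fits:
        raise ValueError("empty subject list")

    # group-level templates, sorted against the canonical atlas
    group_sets: dict[str, TemplateSet] = {}
    for g in sorted(set(groups[s] for s in fits)):
        members = [fits[s].fit.templates for s in fits if groups[s] == g]
        raw = group_templates(members, K=config.K)
        ref = atlas if atlas.ch_names == raw.ch_names else _rename(atlas, raw.ch_names)
        group_sets[g] = sort_templates(_rename(raw, ref.ch_names), ref)

    # individual templates sorted against their group's sorted set; backfit
    subject_templates: dict[str, TemplateSet] = {}
    subject_params: dict[str, SubjectParams] = {}
    gev_rows = []
    segmentations: dict[str, Segmentation] = {}
    class_names = list(group_sets[next(iter(group_sets))].labels)
    for sid, sf in fits.items():
        gset = group_sets[groups[sid]]
        ind = sort_templates(_rename(sf.fit.templates, gset.ch_names), gset)
        subject_templates[sid] = ind
        labels = assign_peaks(sf.peak_topographies, ind,
                              min_correlation=config.min_correlation)
        seg = interpolate_labels(labels, sf.peak_indices, sf.epochs,
                                 sf.n_samples, sf.fs, config.K)
        subject_params[sid] = subject_parameters(
            seg, include_truncated=config.include_truncated,
            transition_mode=config.transition_mode)
        ok = labels >= 0
        gt_total, _ = gev(sf.peak_topographies[ok], sf.peak_gfp[ok], ind.maps,
                          labels[ok])
        gev_rows.append({"subject": sid, "group": groups[sid],
                         "n_peaks": sf.n_peaks, "gev": gt_total,
                         "gev_individual": sf.fit.gev_total,
                         "n_segments": int(seg.segments.size)})
        if keep_segmentations:
            segmentations[sid] = seg

    params = params_to_frame(subject_params, class_names, groups)
    transitions = transitions_to_frame(subject_params, class_names, groups)
    return CohortResult(
        group_template_sets=group_sets,
        subject_templates=subject_templates,
        subject_params=subject_params,
        subject_gev=pd.DataFrame(gev_rows),
        params=params,
        transitions=transitions,
        segmentations=segmentations if keep_segmentations else None,
    )


def _rename(tset: TemplateSet, ch_names: list[str]) -> TemplateSet:
    """Reattach channel names (cluster output uses placeholder names)."""
    if len(ch_names) != tset.maps.shape[1]:
        raise ValueError("channel count mismatch")
    return TemplateSet(maps=tset.maps, labels=list(tset.labels),
                       ch_names=list(ch_names), level=tset.level)


def group_statistics(
    params: pd.DataFrame,
    transitions: pd.DataFrame,
    demographics: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """The full statistical layer on fitted parameter tables.

    SES is scored from the demographic table.  If the demographics carry a
    non-empty ``group`` column it is used directly (the simulated two-group
    design); otherwise subjects are split by the extreme-group rule at the
    configured fraction.  Middle-SES subjects are excluded from group
    analyses; correlations run on the grouped sample by default or the full
    range with ``correlation_sample="all"``.
    """
    config = config or PipelineConfig()
    demo = st.ses_score(demographics)
    if "group" not in demo.columns or (demo["group"] == "").any():
        demo = st.extreme_group_split(demo, fraction=config.split_fraction)
    grouped = demo[demo["group"].isin(["high", "low"])]

    def attach(df: pd.DataFrame, who: pd.DataFrame) -> pd.DataFrame:
        cols = ["subject_id", "group", "age", "gender", "ses_z"]
        return (df.drop(columns=["group"], errors="ignore")
                  .merge(who[cols], left_on="subject", right_on="subject_id"))

    p_grouped = attach(params, grouped)
    t_grouped = attach(transitions, grouped)
    corr_demo = demo if config.correlation_sample == "all" else grouped

    results = {}
    corr = st.ses_parameter_correlations(
        params, corr_demo, dvs=("duration_ms", "occurrence", "coverage"))
    results["correlations"] = st.results_to_frame(corr)

    ancova_rows, posthoc_rows = [], []
    for dv in ("duration_ms", "occurrence", "coverage"):
        for r in st.mixed_ancova(p_grouped, dv):
            d = r.to_dict()
            d["parameter"] = dv
            ancova_rows.append(d)
        for r in st.posthoc_bonferroni(p_grouped, dv):
            d = r.to_dict()
            d["parameter"] = dv
            posthoc_rows.append(d)
    results["ancova"] = pd.DataFrame(ancova_rows)
    results["posthoc"] = pd.DataFrame(posthoc_rows)
    results["transition_tests"] = st.results_to_frame(st.transition_ttests(t_grouped))
    results["ses"] = demo[["subject_id", "group", "age", "gender", "ses_z"]]
    return results


def write_results(results: dict[str, pd.DataFrame], out_dir: str | Path,
                  config: PipelineConfig | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in results.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")
    if config is not None:
        (out / "config.json").write_text(config.to_json())
    return out
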