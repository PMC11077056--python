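"""Five-way vulnerability classification of cassette exons.

Segments are binned by mean PSI; the CV thresholds are derived empirically as
bin medians and every segment then receives exactly one label:

- ``NA``             — junction coverage below the filters;
- ``not_spliced_in`` — mean PSI exactly 0;
- ``resilient``      — mean PSI above the resilient cutoff and CV below the
                       minimum threshold: robust, near-complete inclusion;
- ``vulnerable``     — mean PSI > 85 with CV between the two thresholds:
                       constitutively included but measurably variable, hence
                       prone to skipping when regulatory elements are hit;
- ``alternative``    — everything else.

Two published rule profiles exist and are kept switchable: the ``methods``
profile anchors the maximum-CV threshold on the [85,90) PSI bin and uses a
resilient PSI cutoff of 99; the ``figure`` profile anchors on [80,85) and
cuts resilience at 99.5.  ``methods`` is the default.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import Segment
from .junction_psi import (
    DEFAULT_MIN_MEAN_COUNT,
    DEFAULT_MIN_SAMPLE_COV,
    SegmentPSI,
    SegmentSummary,
    compute_psi,
    summarize_segment,
)

__all__ = [
    "PSI_BIN_EDGES",
    "CLASS_LABELS",
    "ClassThresholds",
    "ThresholdError",
    "bin_segments",
    "assign_bin",
    "derive_thresholds",
    "classify_segment",
    "classify_transcriptome",
    "ClassificationRun",
    "run_classification",
    "partition_by_group",
    "classification_to_bed9",
]

RuleProfile = Literal["methods", "figure"]

# Mean-PSI bin edges (percent); left-closed, right-open, last bin closed.
PSI_BIN_EDGES = (0.0, 80.0, 85.0, 90.0, 95.0, 96.0, 97.0, 98.0, 99.0, 99.5, 100.0)

CLASS_LABELS = ("resilient", "vulnerable", "alternative", "not_spliced_in", "NA")

# Anchor bin indices for threshold derivation per rule profile.
_CV_MAX_BIN = {"methods": 2, "figure": 1}   # [85,90) vs [80,85)
_CV_MIN_BIN = 8                             # [99,99.5)
_PSI_RESILIENT = {"methods": 99.0, "figure": 99.5}

# Genome-browser track colors per class.
CLASS_RGB = {
    "resilient": "0,128,0",
    "vulnerable": "0,0,255",
    "alternative": "128,128,128",
    "not_spliced_in": "0,0,0",
    "NA": "255,255,255",
}


class ThresholdError(ValueError):
    """Threshold derivation failed (empty anchor bin or inverted medians)."""


def assign_bin(mean_psi: float) -> int:
    """Bin index for one mean PSI value (percent)."""
    if not (0.0 <= mean_psi <= 100.0) or math.isnan(mean_psi):
        raise ValueError(f"mean PSI outside [0,100]: {mean_psi}")
    if mean_psi == 100.0:
        return len(PSI_BIN_EDGES) - 2
    return int(np.searchsorted(PSI_BIN_EDGES, mean_psi, side="right")) - 1


def bin_segments(summaries: Sequence[SegmentSummary]) -> dict[str, int]:
    """Map segment_id -> PSI bin index for summaries passing coverage."""
    return {s.segment_id: assign_bin(s.mean_psi)
            for s in summaries if not s.below_coverage}


@dataclass(frozen=True)
class ClassThresholds:
    """Empirically derived CV cutoffs.

    ``cv_min`` is the median CV of the [99,99.5) PSI bin, ``cv_max`` the
    median CV of the profile's mid-PSI anchor bin.
    """

    cv_min: float
    cv_max: float
    rule_profile: RuleProfile = "methods"
    bin_medians: tuple[float, ...] | None = None

    def to_json(self) -> str:
        return json.dumps({
            "cv_min": self.cv_min,
            "cv_max": self.cv_max,
            "rule_profile": self.rule_profile,
            "bin_medians": list(self.bin_medians) if self.bin_medians else None,
        }, indent=2)


def derive_thresholds(
    summaries: Sequence[SegmentSummary],
    rule_profile: RuleProfile = "methods",
) -> ClassThresholds:
    """Derive (cv_min, cv_max) as anchor-bin CV medians.

    Only summaries passing coverage with a defined CV participate.  Raises
    :class:`ThresholdError` when an anchor bin is empty or the medians are
    not ordered cv_min < cv_max.
    """
    if rule_profile not in _CV_MAX_BIN:
        raise ValueError(f"unknown rule profile {rule_profile!r}")
    by_bin: dict[int, list[float]] = {}
    for s in summaries:
        if s.below_coverage or math.isnan(s.cv) or s.mean_psi == 0:
            continue
        by_bin.setdefault(assign_bin(s.mean_psi), []).append(s.cv)

    max_bin = _CV_MAX_BIN[rule_profile]
    lo, hi = PSI_BIN_EDGES[max_bin], PSI_BIN_EDGES[max_bin + 1]
    if not by_bin.get(max_bin):
        raise ThresholdError(f"empty anchor bin [{lo},{hi}) for cv_max")
    if not by_bin.get(_CV_MIN_BIN):
        raise ThresholdError("empty anchor bin [99,99.5) for cv_min")
    cv_max = float(np.median(by_bin[max_bin]))
    cv_min = float(np.median(by_bin[_CV_MIN_BIN]))
    if cv_min >= cv_max:
        raise ThresholdError(
            f"cv_min ({cv_min:.4g}) >= cv_max ({cv_max:.4g}); "
            "CV does not decrease with inclusion in this population")
    n_bins = len(PSI_BIN_EDGES) - 1
    medians = tuple(float(np.median(by_bin[i])) if by_bin.get(i) else math.nan
                    for i in range(n_bins))
    return ClassThresholds(cv_min=cv_min, cv_max=cv_max,
                           rule_profile=rule_profile, bin_medians=medians)


def classify_segment(summary: SegmentSummary, thresholds: ClassThresholds) -> str:
    """Apply the decision order to one segment summary.

    Order: coverage -> zero inclusion -> resilient -> vulnerable ->
    alternative.  CV exactly equal to either threshold counts as vulnerable
    (resilience requires strictly smaller CV).
    """
    if summary.below_coverage:
        return "NA"
    if summary.mean_psi == 0:
        return "not_spliced_in"
    psi_cut = _PSI_RESILIENT[thresholds.rule_profile]
    cv = summary.cv
    if summary.mean_psi > psi_cut and not math.isnan(cv) and cv < thresholds.cv_min:
        return "resilient"
    if (summary.mean_psi > 85.0 and not math.isnan(cv)
            and thresholds.cv_min <= cv <= thresholds.cv_max):
        return "vulnerable"
    return "alternative"


def classify_transcriptome(
    segments: Sequence[Segment],
    summaries: Sequence[SegmentSummary],
    thresholds: ClassThresholds,
) -> pd.DataFrame:
    """Classification table: one row per cassette segment.

    Segments without a summary (no junction evidence at all) are NA.
    """
    by_id = {s.segment_id: s for s in summaries}
    rows = []
    for seg in segments:
        if not seg.is_cassette:
            continue
        summ = by_id.get(seg.segment_id)
        if summ is None:
            rows.append({"segment_id": seg.segment_id, "label": "NA",
                         "mean_psi": math.nan, "cv": math.nan, "n": 0})
        else:
            rows.append({"segment_id": seg.segment_id,
                         "label": classify_segment(summ, thresholds),
                         "mean_psi": summ.mean_psi, "cv": summ.cv,
                         "n": summ.n_samples_retained})
    df = pd.DataFrame(rows, columns=["segment_id", "label", "mean_psi", "cv", "n"])
    return df


def partition_by_group(
    seg_psis: Sequence[SegmentPSI],
    sample_groups: Mapping[str, str],
    thresholds: ClassThresholds,
    min_sample_cov: int = DEFAULT_MIN_SAMPLE_COV,
    min_mean_count: int = DEFAULT_MIN_MEAN_COUNT,
) -> pd.DataFrame:
    """Per-group (e.g. per-tissue) summaries and labels with global thresholds.

    Every sample id must be mapped to exactly one group.  Returns one row per
    (segment, group) with the group summary and label, plus per-segment
    ``min_group_mean_psi`` and ``n_groups_le85`` columns used for the
    tissue-specificity check (a vulnerable exon dipping to PSI <= 85% in some
    tissue).
    """
    if not seg_psis:
        return pd.DataFrame(columns=[
            "segment_id", "group", "label", "mean_psi", "cv", "n",
            "min_group_mean_psi", "n_groups_le85"])
    sample_ids = seg_psis[0].sample_ids
    unmapped = [s for s in sample_ids if s not in sample_groups]
    if unmapped:
        raise KeyError(f"samples without a group assignment: {unmapped[:5]}")
    groups: dict[str, np.ndarray] = {}
    for g in sorted(set(sample_groups[s] for s in sample_ids)):
        groups[g] = np.array([sample_groups[s] == g for s in sample_ids])

    rows = []
    for sp in seg_psis:
        if sp.psi is None:
            compute_psi(sp, min_sample_cov=min_sample_cov)
        per_group = {}
        for g, mask in groups.items():
            sub = SegmentPSI(
                segment_id=sp.segment_id,
                sample_ids=[s for s, m in zip(sample_ids, mask) if m],
                ju=sp.ju[mask], jd=sp.jd[mask], je=sp.je[mask],
                psi=sp.psi[mask], covered=sp.covered[mask])
            summ = summarize_segment(sub, min_mean_count=min_mean_count)
            per_group[g] = summ
        means = [s.mean_psi for s in per_group.values() if not math.isnan(s.mean_psi)]
        min_mean = min(means) if means else math.nan
        n_le85 = sum(1 for m in means if m <= 85.0)
        for g, summ in per_group.items():
            rows.append({
                "segment_id": sp.segment_id, "group": g,
                "label": classify_segment(summ, thresholds),
                "mean_psi": summ.mean_psi, "cv": summ.cv,
                "n": summ.n_samples_retained,
                "min_group_mean_psi": min_mean, "n_groups_le85": n_le85})
    return pd.DataFrame(rows)


@dataclass
class ClassificationRun:
    """End-to-end classification artifacts for one junction cohort."""

    seg_psis: list[SegmentPSI]
    summaries: list[SegmentSummary]
    thresholds: ClassThresholds
    classification: pd.DataFrame

    @property
    def class_counts(self) -> pd.Series:
        return self.classification["label"].value_counts()


def run_classification(
    segments: Sequence[Segment],
    jm,
    min_sample_cov: int = DEFAULT_MIN_SAMPLE_COV,
    min_mean_count: int = DEFAULT_MIN_MEAN_COUNT,
    rule_profile: RuleProfile = "methods",
    psi_formula: str = "two_junction",
    all_segments: bool = False,
) -> ClassificationRun:
    """Match junctions, summarize PSI, derive thresholds and classify.

    ``all_segments`` additionally classifies internal non-cassette segments
    (the permissive webservice behaviour); thresholds are always derived on
    cassette exons only.
    """
    from .junction_psi import compute_psi, match_junctions

    targets = [s for s in segments if s.is_cassette]
    seg_psis = []
    for seg in targets:
        sp = match_junctions(seg, jm)
        compute_psi(sp, min_sample_cov=min_sample_cov, formula=psi_formula)
        seg_psis.append(sp)
    summaries = [summarize_segment(sp, min_mean_count=min_mean_count)
                 for sp in seg_psis]
    thresholds = derive_thresholds(summaries, rule_profile=rule_profile)
    use_segments = segments if all_segments else targets
    classification = classify_transcriptome(use_segments, summaries, thresholds)
    return ClassificationRun(seg_psis=seg_psis, summaries=summaries,
                             thresholds=thresholds, classification=classification)


def classification_to_bed9(classification: pd.DataFrame,
                           segments: Sequence[Segment]) -> pd.DataFrame:
    """BED9 browser track with itemRgb coloring per class."""
    by_id = {s.segment_id: s for s in segments}
    rows = []
    for r in classification.itertuples(index=False):
        seg = by_id.get(r.segment_id)
        if seg is None:
            continue
        rows.append({
            "chrom": seg.chrom, "chromStart": seg.start, "chromEnd": seg.end,
            "name": f"{seg.gene_symbol}|{r.label}", "score": 0,
            "strand": seg.strand, "thickStart": seg.start,
            "thickEnd": seg.end, "itemRgb": CLASS_RGB[r.label]})
    return pd.DataFrame(rows, columns=[
        "chrom", "chromStart", "chromEnd", "name", "score", "strand",
        "thickStart", "thickEnd", "itemRgb"])
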