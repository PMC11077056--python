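"""Junction-count loading, junction-to-segment matching and PSI summaries.

Inclusion of a cassette segment is estimated from three junction read pools
per sample: reads supporting splicing into the segment's acceptor (Ju),
reads supporting splicing out of its donor (Jd), and reads on the exact
flank-to-flank junction that skips the segment (Je).  The per-sample percent
spliced in is the two-junction estimator

    PSI = (Ju + Jd) / (Ju + Jd + 2 * Je)

— every included molecule contributes two junction reads, every excluded
molecule one, so doubling Je balances the denominator and makes the estimator
unbiased in expectation.  Samples with fewer than ``min_sample_cov`` combined
junction reads (default 30) are masked, and segments whose retained-sample
mean junction count falls below ``min_mean_count`` (default 50) are flagged
``below_coverage``.  The between-sample variability statistic is
CV = SEM / mean of the PSI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .annotation import Segment

__all__ = [
    "JunctionMatrix",
    "SegmentPSI",
    "SegmentSummary",
    "JunctionError",
    "load_junctions",
    "match_junctions",
    "compute_sample_psi",
    "psi_from_counts",
    "summarize_segment",
    "summaries_to_tsv",
]

PsiFormula = Literal["two_junction", "max_side", "mean_side"]

DEFAULT_MIN_SAMPLE_COV = 30
DEFAULT_MIN_MEAN_COUNT = 50


class JunctionError(ValueError):
    """Malformed junction input (negative counts, duplicates, bad dialect)."""


@dataclass
class JunctionMatrix:
    """Splice-junction coordinates x samples count table.

    Junction intervals are stored internally as 0-based half-open *intron*
    intervals regardless of the input dialect.
    """

    junctions: pd.DataFrame          # columns chrom, start, end, strand
    counts: np.ndarray               # (n_junctions, n_samples) int
    sample_ids: list[str]
    _by_end: dict = field(default_factory=dict, repr=False)
    _by_start: dict = field(default_factory=dict, repr=False)
    _exact: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if (self.counts < 0).any():
            raise JunctionError("negative junction count")
        keys = list(zip(self.junctions["chrom"], self.junctions["start"],
                        self.junctions["end"], self.junctions["strand"]))
        if len(set(keys)) != len(keys):
            raise JunctionError("duplicate junction coordinates")
        for i, (chrom, start, end, strand) in enumerate(keys):
            self._by_end.setdefault((chrom, end), []).append(i)
            self._by_start.setdefault((chrom, start), []).append(i)
            self._exact[(chrom, start, end)] = i

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def rows_ending_at(self, chrom: str, pos: int) -> list[int]:
        return self._by_end.get((chrom, pos), [])

    def rows_starting_at(self, chrom: str, pos: int) -> list[int]:
        return self._by_start.get((chrom, pos), [])

    def row_exact(self, chrom: str, start: int, end: int) -> int | None:
        return self._exact.get((chrom, start, end))


def load_junctions(path, dialect: str = "snaptron_1based_inclusive") -> JunctionMatrix:
    """Load a junction TSV into a :class:`JunctionMatrix`.

    Layout: header row with sample ids; columns chrom, start, end, strand,
    then one integer count column per sample.  ``dialect`` declares the
    coordinate convention of the intron interval:

    - ``snaptron_1based_inclusive``: 1-based, both ends inclusive
      (the Snaptron export convention); [s, e] becomes [s-1, e).
    - ``bed_0based_halfopen``: already 0-based half-open; taken verbatim.
    """
    if dialect not in ("snaptron_1based_inclusive", "bed_0based_halfopen"):
        raise JunctionError(f"unknown junction dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 5:
        raise JunctionError("junction table needs chrom/start/end/strand + >=1 sample")
    coord = df.iloc[:, :4].copy()
    coord.columns = ["chrom", "start", "end", "strand"]
    coord["start"] = coord["start"].astype(int)
    coord["end"] = coord["end"].astype(int)
    if dialect == "snaptron_1based_inclusive":
        coord["start"] = coord["start"] - 1
    counts = df.iloc[:, 4:].to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise JunctionError("non-numeric junction counts")
    sample_ids = [str(c) for c in df.columns[4:]]
    return JunctionMatrix(junctions=coord.reset_index(drop=True),
                          counts=counts.astype(np.int64),
                          sample_ids=sample_ids)


@dataclass
class SegmentPSI:
    """Per-sample junction counts and PSI for one cassette segment."""

    segment_id: str
    sample_ids: list[str]
    ju: np.ndarray
    jd: np.ndarray
    je: np.ndarray
    psi: np.ndarray | None = None       # fraction in [0,1], NaN where masked
    covered: np.ndarray | None = None   # bool per sample

    @property
    def total(self) -> np.ndarray:
        return self.ju + self.jd + self.je


def _strand_ok(jx_strand: str, seg_strand: str) -> bool:
    return jx_strand in (seg_strand, ".", "?")


def match_junctions(segment: Segment, jm: JunctionMatrix) -> SegmentPSI:
    """Collect inclusion and exclusion junction counts for a cassette segment.

    In genomic orientation: inclusion reads into the segment are junctions
    ending exactly at ``segment.start`` whose donor lies within the left
    flanking exon, inclusion reads out of the segment are junctions starting
    exactly at ``segment.end`` whose acceptor lies within the right flank,
    and the exclusion junction is the exact left-flank-donor to
    right-flank-acceptor skip.  The left/right pools map to (Ju, Jd) on '+'
    and (Jd, Ju) on '-'.
    """
    if not segment.is_cassette:
        raise JunctionError(f"{segment.segment_id}: not a cassette segment")
    left = segment.flank_left_exon
    right = segment.flank_right_exon
    if left is None or right is None:
        raise JunctionError(f"{segment.segment_id}: missing flank exons")

    chrom = segment.chrom
    n = jm.n_samples
    inc_left = np.zeros(n, dtype=np.int64)
    inc_right = np.zeros(n, dtype=np.int64)
    je = np.zeros(n, dtype=np.int64)

    for i in jm.rows_ending_at(chrom, segment.start):
        row = jm.junctions.iloc[i]
        if _strand_ok(row["strand"], segment.strand) and left[0] <= row["start"] < segment.start:
            inc_left += jm.counts[i]
    for i in jm.rows_starting_at(chrom, segment.end):
        row = jm.junctions.iloc[i]
        if _strand_ok(row["strand"], segment.strand) and segment.end < row["end"] <= right[1]:
            inc_right += jm.counts[i]
    i = jm.row_exact(chrom, left[1], right[0])
    if i is not None and _strand_ok(jm.junctions.iloc[i]["strand"], segment.strand):
        je = jm.counts[i].copy()

    if segment.strand == "+":
        ju, jd = inc_left, inc_right
    else:
        ju, jd = inc_right, inc_left
    return SegmentPSI(segment_id=segment.segment_id, sample_ids=list(jm.sample_ids),
                      ju=ju, jd=jd, je=je)


def psi_from_counts(
    ju: np.ndarray,
    jd: np.ndarray,
    je: np.ndarray,
    min_sample_cov: int = DEFAULT_MIN_SAMPLE_COV,
    formula: PsiFormula = "two_junction",
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-sample PSI.  Returns (psi, covered); psi is NaN where
    the sample is masked (combined count below ``min_sample_cov``)."""
    ju = np.asarray(ju, dtype=float)
    jd = np.asarray(jd, dtype=float)
    je = np.asarray(je, dtype=float)
    total = ju + jd + je
    covered = total >= min_sample_cov
    with np.errstate(divide="ignore", invalid="ignore"):
        if formula == "two_junction":
            denom = ju + jd + 2.0 * je
            psi = (ju + jd) / denom
        elif formula == "max_side":
            m = np.maximum(ju, jd)
            psi = m / (m + je)
        elif formula == "mean_side":
            m = (ju + jd) / 2.0
            psi = m / (m + je)
        else:
            raise JunctionError(f"unknown PSI formula {formula!r}")
    psi = np.where(covered & np.isfinite(psi), psi, np.nan)
    return psi, covered & np.isfinite(psi)


def compute_sample_psi(
    ju: int, jd: int, je: int,
    min_sample_cov: int = DEFAULT_MIN_SAMPLE_COV,
    formula: PsiFormula = "two_junction",
) -> float | None:
    """Scalar PSI for one sample; ``None`` when the sample is masked."""
    psi, covered = psi_from_counts(
        np.array([ju]), np.array([jd]), np.array([je]),
        min_sample_cov=min_sample_cov, formula=formula)
    return float(psi[0]) if covered[0] else None


def compute_psi(seg_psi: SegmentPSI,
                min_sample_cov: int = DEFAULT_MIN_SAMPLE_COV,
                formula: PsiFormula = "two_junction") -> SegmentPSI:
    """Fill the psi/covered fields of a SegmentPSI in place (and return it)."""
    seg_psi.psi, seg_psi.covered = psi_from_counts(
        seg_psi.ju, seg_psi.jd, seg_psi.je,
        min_sample_cov=min_sample_cov, formula=formula)
    return seg_psi


@dataclass
class SegmentSummary:
    """Across-sample PSI statistics feeding the classifier.

    ``mean_psi`` and ``sem_psi`` are on the percent scale; ``cv`` (SEM/mean)
    is scale-free.  ``cv`` is NaN when undefined (mean 0, or <2 retained
    samples).
    """

    segment_id: str
    n_samples_retained: int
    mean_psi: float
    sem_psi: float
    cv: float
    mean_junction_count: float
    below_coverage: bool


def summarize_segment(seg_psi: SegmentPSI,
                      min_mean_count: int = DEFAULT_MIN_MEAN_COUNT) -> SegmentSummary:
    """Summarize per-sample PSI into mean, SEM and CV over retained samples.

    SEM uses the n-1 sample standard deviation.  A segment is flagged
    ``below_coverage`` when no (or a single) sample passes the per-sample
    filter or the retained-sample mean junction count is below
    ``min_mean_count``.
    """
    if seg_psi.psi is None or seg_psi.covered is None:
        seg_psi = compute_psi(seg_psi)
    mask = seg_psi.covered
    n = int(mask.sum())
    if n == 0:
        return SegmentSummary(seg_psi.segment_id, 0, math.nan, math.nan,
                              math.nan, math.nan, True)
    vals = seg_psi.psi[mask]
    mean_frac = float(np.mean(vals))
    if n >= 2:
        sd = float(np.std(vals, ddof=1))
        sem_frac = sd / math.sqrt(n)
        cv = sem_frac / mean_frac if mean_frac > 0 else math.nan
    else:
        sem_frac = math.nan
        cv = math.nan
    mean_count = float(np.mean(seg_psi.total[mask]))
    below = (n < 2) or (mean_count < min_mean_count)
    return SegmentSummary(
        segment_id=seg_psi.segment_id,
        n_samples_retained=n,
        mean_psi=100.0 * mean_frac,
        sem_psi=100.0 * sem_frac,
        cv=cv,
        mean_junction_count=mean_count,
        below_coverage=below,
    )


def summaries_to_tsv(summaries: Sequence[SegmentSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "segment_id": s.segment_id,
        "n": s.n_samples_retained,
        "mean_psi": s.mean_psi,
        "sem": s.sem_psi,
        "cv": s.cv,
        "mean_count": s.mean_junction_count,
        "below_coverage": s.below_coverage,
    } for s in summaries], columns=[
        "segment_id", "n", "mean_psi", "sem", "cv", "mean_count",
        "below_coverage"])
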