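"""Mapping point variants onto classified exons and enrichment statistics.

Implements the exonic-splicing-mutation (ESM) workflow: loading variants from
BED6 or a tabular database, assigning each to its host cassette segment with
the distance to the nearest exon edge, the curation filters (terminal three
exonic bases, new-splice-site creators, alternative host exons), 2x2
enrichment statistics (odds ratio with Wald CI, relative fold difference,
two-sided Fisher exact p), per-nucleotide variant densities by exon class,
MAF summaries, and detection of splicing-regulatory motifs created or
disrupted by a point variant (e.g. the hnRNPA1-binding TAGACA ESS or the
SRSF1-binding GAAGAA ESE).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .annotation import Segment
from .exon_features import reverse_complement

__all__ = [
    "VariantRecord",
    "EnrichmentResult",
    "MotifChange",
    "VariantError",
    "load_variants",
    "load_variant_table",
    "assign_variants",
    "filter_esm_candidates",
    "esm_enrichment",
    "variant_density",
    "maf_summary",
    "motif_change",
    "motif_change_at",
    "DEFAULT_MOTIF_SETS",
    "variants_to_tsv",
]

SPLICE_SITE_EDGE_BP = 3   # terminal exonic bases treated as splice-site region

DEFAULT_MOTIF_SETS: dict[str, tuple[str, ...]] = {
    "GAAGAA": ("GAAGAA",),
    "TAGACA": ("TAGACA",),
    "TAGG": ("TAGG",),
    "GGG": ("GGG",),
}


class VariantError(ValueError):
    pass


@dataclass
class VariantRecord:
    """One variant with (after assignment) its host-exon context."""

    chrom: str
    pos: int                       # 0-based genomic position
    ref: str | None = None
    alt: str | None = None
    label: str = ""
    consequence: str = "unknown"   # synonymous / missense / nonsense / other / unknown
    maf: float | None = None
    creates_splice_site: bool = False
    host_segment: str | None = None
    edge_distance: int | None = None   # 1 = terminal exonic base
    host_class: str | None = None

    @property
    def is_snv(self) -> bool:
        return (self.ref is not None and self.alt is not None
                and len(self.ref) == 1 and len(self.alt) == 1
                and self.ref in "ACGT" and self.alt in "ACGT")


_REF_ALT_RE = re.compile(r"([ACGTacgt])>([ACGTacgt])")


def load_variants(path) -> list[VariantRecord]:
    """Load a BED6 variant file.

    The name column is kept as the label; a ``REF>ALT`` pattern inside it
    (e.g. ``c.85C>A``) populates ref/alt.  Rows whose interval is not one
    base wide are warned about and treated by their start position.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "name", "score", "strand"],
                         dtype={"chrom": str, "name": str})
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError) as exc:
            raise VariantError(f"line {i}: malformed interval") from exc
        if start < 0 or end <= start:
            raise VariantError(f"line {i}: malformed interval [{start},{end})")
        name = "" if pd.isna(row.name) else str(row.name)
        m = _REF_ALT_RE.search(name)
        ref, alt = (m.group(1).upper(), m.group(2).upper()) if m else (None, None)
        if end != start + 1 and ref is not None:
            warnings.warn(f"line {i}: SNV-like row spans {end - start} bp; "
                          "using start position")
        records.append(VariantRecord(chrom=str(row.chrom), pos=start,
                                     ref=ref, alt=alt, label=name))
    return records


def load_variant_table(path) -> list[VariantRecord]:
    """Load a tabular variant database.

    Expected columns: chrom, pos (1-based), ref, alt; optional label,
    consequence, creates_splice_site (0/1), maf.  Positions are converted to
    0-based internally.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt"}
    if not required <= set(df.columns):
        raise VariantError(f"variant table needs columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(VariantRecord(
            chrom=str(row.chrom),
            pos=int(row.pos) - 1,
            ref=str(row.ref).upper() if pd.notna(row.ref) else None,
            alt=str(row.alt).upper() if pd.notna(row.alt) else None,
            label=str(getattr(row, "label", "")),
            consequence=str(getattr(row, "consequence", "unknown")),
            creates_splice_site=bool(int(getattr(row, "creates_splice_site", 0) or 0)),
            maf=float(row.maf) if hasattr(row, "maf") and pd.notna(row.maf) else None,
        ))
    return records


def assign_variants(
    variants: Sequence[VariantRecord],
    segments: Sequence[Segment],
    classification: pd.DataFrame | None = None,
) -> list[VariantRecord]:
    """Attach host cassette segment, edge distance and host class in place.

    ``edge_distance`` counts exonic bases from the nearest boundary (1 = the
    terminal base).  Intronic positions and positions on chromosomes without
    any cassette segment get host None.
    """
    trees: dict[str, IntervalTree] = {}
    by_id: dict[str, Segment] = {}
    for seg in segments:
        if not seg.is_cassette:
            continue
        trees.setdefault(seg.chrom, IntervalTree()).addi(seg.start, seg.end, seg.segment_id)
        by_id[seg.segment_id] = seg
    labels = {}
    if classification is not None:
        labels = dict(zip(classification["segment_id"], classification["label"]))

    unknown_chroms = set()
    for v in variants:
        v.host_segment = None
        v.edge_distance = None
        v.host_class = None
        tree = trees.get(v.chrom)
        if tree is None:
            if v.chrom not in unknown_chroms:
                unknown_chroms.add(v.chrom)
                warnings.warn(f"no cassette segments on {v.chrom}")
            continue
        hits = sorted(tree[v.pos], key=lambda iv: iv.data)
        if not hits:
            continue
        seg = by_id[hits[0].data]
        v.host_segment = seg.segment_id
        v.edge_distance = min(v.pos - seg.start + 1, seg.end - v.pos)
        v.host_class = labels.get(seg.segment_id)
    return list(variants)


def filter_esm_candidates(
    variants: Sequence[VariantRecord],
) -> tuple[list[VariantRecord], dict[int, list[str]]]:
    """Apply the ESM curation filters.

    Excluded: variants in the first or last three exonic bases (presumed
    splice-site disruption), variants flagged as creating a new splice site,
    and variants hosted by an alternative exon.  Returns (retained,
    exclusion reasons keyed by input index); the operation is idempotent and
    order-independent.
    """
    retained = []
    reasons: dict[int, list[str]] = {}
    for i, v in enumerate(variants):
        why = []
        if v.edge_distance is not None and v.edge_distance <= SPLICE_SITE_EDGE_BP:
            why.append("splice_site_region")
        if v.creates_splice_site:
            why.append("new_splice_site")
        if v.host_class == "alternative":
            why.append("alternative_exon")
        if why:
            reasons[i] = why
        else:
            retained.append(v)
    return retained, reasons


@dataclass
class EnrichmentResult:
    """2x2 enrichment: odds ratio, Wald 95% CI, fold difference, Fisher p."""

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    ci95: tuple[float, float]
    fold_difference: float
    p_fisher: float
    zero_cell_corrected: bool = False


def esm_enrichment(table: Sequence[Sequence[float]]) -> EnrichmentResult:
    """Enrichment statistics for a 2x2 table [[a, b], [c, d]].

    OR = ad/bc with a Wald 95% CI on log OR; fold difference is the ratio of
    row proportions (a/(a+b)) / (c/(c+d)); p is the two-sided Fisher exact
    test.  A zero cell triggers the Haldane-Anscombe 0.5 correction for the
    OR/CI (flagged); Fisher p uses the uncorrected table.
    """
    (a, b), (c, d) = table
    if min(a + b, c + d, a + c, b + d) <= 0:
        raise VariantError("2x2 table needs positive margins")
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if corrected else (a, b, c, d)
    odds = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci = (odds * math.exp(-1.96 * se), odds * math.exp(1.96 * se))
    fold = (aa / (aa + bb)) / (cc / (cc + dd))
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return EnrichmentResult(table=((int(a), int(b)), (int(c), int(d))),
                            odds_ratio=odds, ci95=ci, fold_difference=fold,
                            p_fisher=p, zero_cell_corrected=corrected)


def variant_density(
    variants: Sequence[VariantRecord],
    segments: Sequence[Segment],
    classification: pd.DataFrame,
    consequence: str | None = None,
    exclude_edges: bool = False,
) -> pd.DataFrame:
    """Variants per nucleotide by host-exon class.

    ``consequence`` filters variants (e.g. 'synonymous').  With
    ``exclude_edges`` the first and last three bases of each exon are dropped
    from both the variant counts and the class nucleotide totals.
    """
    labels = dict(zip(classification["segment_id"], classification["label"]))
    trim = 2 * SPLICE_SITE_EDGE_BP if exclude_edges else 0
    lengths: dict[str, int] = {}
    for seg in segments:
        if not seg.is_cassette or seg.segment_id not in labels:
            continue
        lengths[labels[seg.segment_id]] = (
            lengths.get(labels[seg.segment_id], 0) + max(seg.length - trim, 0))
    counts: dict[str, int] = {}
    for v in variants:
        if v.host_segment is None or v.host_class is None:
            continue
        if consequence is not None and v.consequence != consequence:
            continue
        if exclude_edges and (v.edge_distance or 0) <= SPLICE_SITE_EDGE_BP:
            continue
        counts[v.host_class] = counts.get(v.host_class, 0) + 1
    rows = []
    for cls in sorted(set(lengths) | set(counts)):
        total = lengths.get(cls, 0)
        n = counts.get(cls, 0)
        rows.append({"class": cls, "n_variants": n, "total_nt": total,
                     "density_per_nt": n / total if total else math.nan,
                     "flagged": total == 0})
    return pd.DataFrame(rows, columns=["class", "n_variants", "total_nt",
                                       "density_per_nt", "flagged"])


def maf_summary(variants: Sequence[VariantRecord]) -> pd.DataFrame:
    """Median and mean MAF per host class x consequence stratum."""
    rows = [{"host_class": v.host_class, "consequence": v.consequence,
             "maf": v.maf}
            for v in variants if v.maf is not None and v.host_class is not None]
    for v in variants:
        if v.maf is not None and not (0.0 <= v.maf <= 0.5):
            warnings.warn(f"MAF outside [0, 0.5]: {v.maf} ({v.label})")
    if not rows:
        return pd.DataFrame(columns=["host_class", "consequence",
                                     "median_maf", "mean_maf", "n"])
    df = pd.DataFrame(rows)
    out = (df.groupby(["host_class", "consequence"])["maf"]
             .agg(median_maf="median", mean_maf="mean", n="count")
             .reset_index())
    return out


@dataclass
class MotifChange:
    """Motifs created or disrupted at a variant locus."""

    wt_window: str
    mut_window: str
    created: set[str] = field(default_factory=set)
    disrupted: set[str] = field(default_factory=set)


def _hits_overlapping(window: str, motif: str, var_idx: int) -> bool:
    """True when the motif occurs in the window overlapping position var_idx."""
    k = len(motif)
    lo = max(0, var_idx - k + 1)
    hi = min(var_idx, len(window) - k)
    return any(window[p:p + k] == motif for p in range(lo, hi + 1))


def motif_change(
    wt_window: str,
    var_offset: int,
    ref: str,
    alt: str,
    motif_sets: Mapping[str, Iterable[str]] = DEFAULT_MOTIF_SETS,
    mut_window: str | None = None,
) -> MotifChange:
    """Motifs created/disrupted by a point variant inside a local window.

    Only motif occurrences overlapping the variant base count — matches
    elsewhere in the window are ignored, so results do not depend on window
    length.  ``mut_window`` can be supplied explicitly for non-SNV changes
    (then ref/alt are not checked against it).
    """
    wt_window = wt_window.upper()
    if not (0 <= var_offset < len(wt_window)):
        raise VariantError("variant offset outside window")
    if wt_window[var_offset] != ref.upper():
        raise VariantError(
            f"reference mismatch: window has {wt_window[var_offset]!r}, "
            f"expected {ref!r}")
    if mut_window is None:
        mut_window = wt_window[:var_offset] + alt.upper() + wt_window[var_offset + 1:]
    else:
        mut_window = mut_window.upper()
    created: set[str] = set()
    disrupted: set[str] = set()
    for motifs in motif_sets.values():
        for m in motifs:
            m = m.upper()
            in_wt = _hits_overlapping(wt_window, m, var_offset)
            in_mut = _hits_overlapping(mut_window, m, var_offset)
            if in_mut and not in_wt:
                created.add(m)
            elif in_wt and not in_mut:
                disrupted.add(m)
    return MotifChange(wt_window=wt_window, mut_window=mut_window,
                       created=created, disrupted=disrupted)


def motif_change_at(
    genome,
    variant: VariantRecord,
    strand: str = "+",
    motif_sets: Mapping[str, Iterable[str]] = DEFAULT_MOTIF_SETS,
    flank: int | None = None,
) -> MotifChange | None:
    """Run :func:`motif_change` on a genome-extracted window.

    The window is taken around the variant and put on the sense strand of
    ``strand`` (minus-strand loci are reverse-complemented, with ref/alt
    complemented accordingly).  Non-SNV records return None.
    """
    if not variant.is_snv:
        return None
    if flank is None:
        flank = max((len(m) for ms in motif_sets.values() for m in ms), default=6) - 1
    contig = genome[variant.chrom]
    start = max(0, variant.pos - flank)
    end = min(len(contig), variant.pos + flank + 1)
    window = str(contig[start:end]).upper()
    offset = variant.pos - start
    ref, alt = variant.ref, variant.alt
    if window[offset] != ref:
        raise VariantError(
            f"{variant.label or variant.chrom}: genome has {window[offset]!r} "
            f"at {variant.pos}, variant ref is {ref!r}")
    if strand == "-":
        window = reverse_complement(window)
        offset = len(window) - 1 - offset
        ref = reverse_complement(ref)
        alt = reverse_complement(alt)
    return motif_change(window, offset, ref, alt, motif_sets=motif_sets)


def variants_to_tsv(variants: Sequence[VariantRecord],
                    exclusions: Mapping[int, list[str]] | None = None
                    ) -> pd.DataFrame:
    rows = []
    for i, v in enumerate(variants):
        rows.append({
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "label": v.label, "consequence": v.consequence, "maf": v.maf,
            "host_segment": v.host_segment, "edge_distance": v.edge_distance,
            "host_class": v.host_class,
            "excluded": ";".join(exclusions.get(i, [])) if exclusions else "",
        })
    return pd.DataFrame(rows)
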