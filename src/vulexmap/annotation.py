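"""Transcript annotation handling: refGene parsing, gene-model flattening,
cassette-exon identification.

A gene's isoforms are projected onto the genome and the exonic union is cut at
every annotated exon boundary, yielding non-overlapping *segments* (the unit
on which inclusion is later quantified).  A segment is a *cassette exon* when
both of its boundaries are splice sites (an intron ends at its start and an
intron starts at its end, genomically) and at least one transcript carries it
as an internal exon, i.e. with annotated neighbours on both sides whose
junctions provide the inclusion and skipping evidence.

Coordinates are 0-based half-open throughout, matching the exonStarts /
exonEnds columns of the UCSC refGene table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Transcript",
    "Segment",
    "RefGeneParseError",
    "AnnotationError",
    "parse_refgene",
    "group_genes",
    "flatten_gene",
    "identify_cassette_exons",
    "resolve_primary_transcript",
    "build_segments",
    "segments_to_tsv",
    "segments_to_bed",
]


class RefGeneParseError(ValueError):
    """A refGene row could not be parsed; the message names the line."""


class AnnotationError(ValueError):
    """Inconsistent annotation input (mixed strands, empty gene, ...)."""


# UCSC refGene schema (genePredExt plus the leading bin column).
REFGENE_COLUMNS = [
    "bin", "name", "chrom", "strand", "txStart", "txEnd",
    "cdsStart", "cdsEnd", "exonCount", "exonStarts", "exonEnds",
    "score", "name2", "cdsStartStat", "cdsEndStat", "exonFrames",
]


@dataclass(frozen=True)
class Transcript:
    """One annotated isoform with its exon chain."""

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}")
        if len(self.exon_starts) != len(self.exon_ends):
            raise AnnotationError(
                f"{self.transcript_id}: {len(self.exon_starts)} starts vs "
                f"{len(self.exon_ends)} ends")
        prev_end = None
        for s, e in zip(self.exon_starts, self.exon_ends):
            if s >= e:
                raise AnnotationError(
                    f"{self.transcript_id}: empty/inverted exon [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise AnnotationError(
                    f"{self.transcript_id}: exons unsorted or overlapping at [{s},{e})")
            prev_end = e

    @property
    def exons(self) -> list[tuple[int, int]]:
        return list(zip(self.exon_starts, self.exon_ends))

    @property
    def n_exons(self) -> int:
        return len(self.exon_starts)


@dataclass
class Segment:
    """A flattened, non-overlapping exonic interval of one gene.

    ``flank_up_exon`` / ``flank_down_exon`` are the immediate neighbouring
    exons in transcription orientation, taken from the lowest-accession
    transcript that carries this segment as an internal exon.
    """

    segment_id: str
    gene_symbol: str
    chrom: str
    strand: str
    start: int
    end: int
    is_internal: bool = False
    is_cassette: bool = False
    upstream_donor: int | None = None
    downstream_acceptor: int | None = None
    flank_up_exon: tuple[int, int] | None = None
    flank_down_exon: tuple[int, int] | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    # Genomic-orientation views of the flanks (left = lower coordinates).
    @property
    def flank_left_exon(self) -> tuple[int, int] | None:
        return self.flank_up_exon if self.strand == "+" else self.flank_down_exon

    @property
    def flank_right_exon(self) -> tuple[int, int] | None:
        return self.flank_down_exon if self.strand == "+" else self.flank_up_exon


def _parse_coord_list(text: str, line_no: int) -> tuple[int, ...]:
    try:
        return tuple(int(x) for x in str(text).strip().rstrip(",").split(",") if x != "")
    except ValueError as exc:
        raise RefGeneParseError(f"line {line_no}: bad coordinate list {text!r}") from exc


def parse_refgene(path) -> list[Transcript]:
    """Read a UCSC refGene table (optionally gzipped) into Transcripts.

    Raises :class:`RefGeneParseError` naming the offending line for malformed
    rows, including rows whose exonCount disagrees with the coordinate lists.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype=str,
            names=REFGENE_COLUMNS, usecols=range(len(REFGENE_COLUMNS)),
        )
    except pd.errors.ParserError as exc:
        raise RefGeneParseError(f"unparseable refGene table: {exc}") from exc

    transcripts: list[Transcript] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        starts = _parse_coord_list(row.exonStarts, i)
        ends = _parse_coord_list(row.exonEnds, i)
        try:
            exon_count = int(row.exonCount)
        except (TypeError, ValueError) as exc:
            raise RefGeneParseError(f"line {i}: bad exonCount {row.exonCount!r}") from exc
        if len(starts) != exon_count or len(ends) != exon_count:
            raise RefGeneParseError(
                f"line {i}: exonCount={exon_count} but {len(starts)} starts / "
                f"{len(ends)} ends")
        try:
            transcripts.append(Transcript(
                transcript_id=row.name,
                gene_symbol=row.name2,
                chrom=row.chrom,
                strand=row.strand,
                exon_starts=starts,
                exon_ends=ends,
            ))
        except AnnotationError as exc:
            raise RefGeneParseError(f"line {i}: {exc}") from exc
    return transcripts


def group_genes(transcripts: Iterable[Transcript]) -> dict[tuple[str, str, str], list[Transcript]]:
    """Group transcripts into genes keyed by (symbol, chrom, strand).

    The same symbol on two chromosomes (or strands) yields two genes, which
    keeps paralogs and opposite-strand overlaps independent.
    """
    genes: dict[tuple[str, str, str], list[Transcript]] = {}
    for tx in transcripts:
        genes.setdefault((tx.gene_symbol, tx.chrom, tx.strand), []).append(tx)
    return genes


def _accession_key(transcript_id: str) -> tuple[int, str]:
    """Sort key: numeric part of the accession (prefix and version ignored),
    then the full id lexicographically as a tie-break."""
    core = transcript_id.split(".")[0]
    m = re.search(r"(\d+)", core)
    num = int(m.group(1)) if m else 2**63
    return (num, transcript_id)


def resolve_primary_transcript(transcripts: Sequence[Transcript]) -> Transcript:
    """The transcript with the numerically lowest accession identifier."""
    if not transcripts:
        raise AnnotationError("no transcripts to resolve")
    return min(transcripts, key=lambda t: _accession_key(t.transcript_id))


def flatten_gene(transcripts: Sequence[Transcript]) -> list[Segment]:
    """Partition one gene's exonic union at every annotated exon boundary.

    All transcripts must share chrom and strand.  Each output segment records
    whether both of its boundaries are splice sites (``is_internal``);
    cassette flags and flank exons are filled in by
    :func:`identify_cassette_exons`.
    """
    if not transcripts:
        raise AnnotationError("flatten_gene: empty transcript list")
    chroms = {t.chrom for t in transcripts}
    strands = {t.strand for t in transcripts}
    if len(chroms) > 1 or len(strands) > 1:
        raise AnnotationError(
            f"flatten_gene: mixed chrom/strand ({sorted(chroms)}, {sorted(strands)})")
    chrom = chroms.pop()
    strand = strands.pop()
    gene = transcripts[0].gene_symbol

    # Splice-site catalogues in genomic orientation: an intron [d, a) exists
    # between consecutive exons, so d is a donor on '+' (acceptor on '-').
    intron_starts: set[int] = set()
    intron_ends: set[int] = set()
    for tx in transcripts:
        for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
            intron_starts.add(e1)
            intron_ends.add(s2)

    boundaries = sorted({c for tx in transcripts for se in tx.exons for c in se})
    # Exonic union as sorted merged intervals.
    union: list[list[int]] = []
    for s, e in sorted(se for tx in transcripts for se in tx.exons):
        if union and s <= union[-1][1]:
            union[-1][1] = max(union[-1][1], e)
        else:
            union.append([s, e])

    segments: list[Segment] = []
    for us, ue in union:
        cuts = [us] + [b for b in boundaries if us < b < ue] + [ue]
        for s, e in zip(cuts, cuts[1:]):
            internal = s in intron_ends and e in intron_starts
            segments.append(Segment(
                segment_id=f"{gene}:{chrom}:{s}-{e}",
                gene_symbol=gene,
                chrom=chrom,
                strand=strand,
                start=s,
                end=e,
                is_internal=internal,
            ))
    return segments


def identify_cassette_exons(
    segments: Sequence[Segment], transcripts: Sequence[Transcript]
) -> list[Segment]:
    """Flag cassette segments and attach their flanking exons in place.

    A segment is a cassette exon when both boundaries are splice sites and at
    least one transcript has an exon containing it with neighbours on both
    sides.  Flanks come from the lowest-accession such transcript.
    """
    ordered = sorted(transcripts, key=lambda t: _accession_key(t.transcript_id))
    for seg in segments:
        seg.is_cassette = False
        if not seg.is_internal:
            continue
        for tx in ordered:
            exons = tx.exons
            for i, (s, e) in enumerate(exons):
                if s <= seg.start and seg.end <= e and 0 < i < len(exons) - 1:
                    left, right = exons[i - 1], exons[i + 1]
                    if seg.strand == "+":
                        seg.flank_up_exon, seg.flank_down_exon = left, right
                        seg.upstream_donor = left[1]
                        seg.downstream_acceptor = right[0]
                    else:
                        seg.flank_up_exon, seg.flank_down_exon = right, left
                        seg.upstream_donor = right[0]
                        seg.downstream_acceptor = left[1]
                    seg.is_cassette = True
                    break
            if seg.is_cassette:
                break
    return list(segments)


def build_segments(transcripts: Iterable[Transcript]) -> list[Segment]:
    """Flatten every gene and identify cassette exons; segments sorted by
    (chrom, start) for reproducible output independent of input order."""
    out: list[Segment] = []
    for _, txs in sorted(group_genes(transcripts).items()):
        segs = flatten_gene(txs)
        identify_cassette_exons(segs, txs)
        out.extend(segs)
    out.sort(key=lambda s: (s.chrom, s.start, s.end, s.gene_symbol))
    return out


def segments_to_tsv(segments: Sequence[Segment]) -> pd.DataFrame:
    rows = [{
        "segment_id": s.segment_id,
        "gene_symbol": s.gene_symbol,
        "chrom": s.chrom,
        "start": s.start,
        "end": s.end,
        "strand": s.strand,
        "is_internal": s.is_internal,
        "is_cassette": s.is_cassette,
    } for s in segments]
    return pd.DataFrame(rows, columns=[
        "segment_id", "gene_symbol", "chrom", "start", "end", "strand",
        "is_internal", "is_cassette"])


def segments_to_bed(segments: Sequence[Segment]) -> pd.DataFrame:
    """BED6 plus segment_id / is_cassette extra columns (0-based half-open)."""
    rows = [{
        "chrom": s.chrom,
        "chromStart": s.start,
        "chromEnd": s.end,
        "name": s.gene_symbol,
        "score": 0,
        "strand": s.strand,
        "segment_id": s.segment_id,
        "is_cassette": int(s.is_cassette),
    } for s in segments]
    return pd.DataFrame(rows, columns=[
        "chrom", "chromStart", "chromEnd", "name", "score", "strand",
        "segment_id", "is_cassette"])
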