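"""Exon-definition features and k-mer enrichment between exon groups.

Covers: ESE/ESS (PESE/PESS) motif densities, GC content, exon and flanking
intron lengths, splice-site strength via a pluggable scorer, flank splice-site
deltas, the 0..5 above-the-grand-mean feature profiles, hexamer enrichment by
two-proportion z-test with Bonferroni correction, and pairwise Wilcoxon
rank-sum comparisons between groups.

All sequence work is done on the mRNA sense strand: minus-strand exons are
reverse-complemented before motif or k-mer counting.  Splice-site contexts
follow the maximum-entropy model conventions — a 23-mer acceptor context
(20 intronic + 3 exonic bases) and a 9-mer donor context (3 exonic + 6
intronic).  Scores can come from any object implementing
:class:`SpliceSiteScorer`; a precomputed-table reader (for externally
computed maximum-entropy scores) and a simple PWM log-odds scorer are
provided.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Segment

__all__ = [
    "reverse_complement",
    "motif_density",
    "gc_content",
    "SpliceSiteScorer",
    "PrecomputedScorer",
    "PwmScorer",
    "ConstantScorer",
    "extract_acceptor_context",
    "extract_donor_context",
    "splice_site_scores",
    "flank_deltas",
    "POSITIVE_FEATURES",
    "NEGATIVE_FEATURES",
    "above_mean_profile",
    "count_kmers",
    "kmer_enrichment",
    "group_compare",
    "significance_tier",
    "load_motifs",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

ACCEPTOR_INTRON = 20   # intronic bases in the 3'ss context
ACCEPTOR_EXON = 3      # exonic bases in the 3'ss context
DONOR_EXON = 3         # exonic bases in the 5'ss context
DONOR_INTRON = 6       # intronic bases in the 5'ss context


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def load_motifs(path) -> list[str]:
    """One motif per line, upper-cased; blank lines and '#' comments skipped."""
    with open(path) as fh:
        return [ln.strip().upper() for ln in fh
                if ln.strip() and not ln.startswith("#")]


def motif_density(seq: str, motifs: Iterable[str]) -> float:
    """Occurrences of any motif per 100 bp of sequence.

    Overlapping occurrences (of the same or different motifs) each count.
    Windows containing ambiguous bases simply fail to match.
    """
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    motifs = list(motifs)
    if not motifs:
        raise ValueError("empty motif list")
    hits = 0
    for m in motifs:
        k = len(m)
        hits += sum(1 for i in range(len(seq) - k + 1) if seq[i:i + k] == m)
    return 100.0 * hits / len(seq)


def gc_content(seq: str) -> float:
    """(G+C) fraction with ambiguous bases excluded from both numerator and
    denominator."""
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    n_gc = seq.count("G") + seq.count("C")
    n_at = seq.count("A") + seq.count("T")
    if n_gc + n_at == 0:
        raise ValueError("sequence has no unambiguous bases")
    return n_gc / (n_gc + n_at)


class SpliceSiteScorer(Protocol):
    """Maps fixed-length splice-site contexts to strength scores."""

    def score_acceptor(self, context23: str) -> float: ...
    def score_donor(self, context9: str) -> float: ...


class ConstantScorer:
    """Degenerate scorer returning a fixed value; useful as a stub."""

    def __init__(self, value: float = 0.0):
        self.value = value

    def score_acceptor(self, context23: str) -> float:
        return self.value

    def score_donor(self, context9: str) -> float:
        return self.value


class PwmScorer:
    """Position-weight-matrix log2-odds scorer against a uniform background.

    ``acceptor_pwm`` / ``donor_pwm`` are mappings position -> {base: prob};
    positions absent from the mapping contribute 0.  A small pseudocount
    guards against log of zero.
    """

    def __init__(self,
                 acceptor_pwm: Mapping[int, Mapping[str, float]] | None = None,
                 donor_pwm: Mapping[int, Mapping[str, float]] | None = None,
                 pseudo: float = 1e-6):
        self.acceptor_pwm = dict(acceptor_pwm or {})
        self.donor_pwm = dict(donor_pwm or {})
        self.pseudo = pseudo

    def _score(self, seq: str, pwm: Mapping[int, Mapping[str, float]]) -> float:
        total = 0.0
        for pos, probs in pwm.items():
            if pos >= len(seq):
                return math.nan
            p = probs.get(seq[pos], 0.0) + self.pseudo
            if p <= 0.0:
                return -math.inf
            total += math.log2(p / 0.25)
        return total

    def score_acceptor(self, context23: str) -> float:
        return self._score(context23, self.acceptor_pwm)

    def score_donor(self, context9: str) -> float:
        return self._score(context9, self.donor_pwm)


class PrecomputedScorer:
    """Bit-exact ingestion of externally computed splice-site scores.

    Reads a TSV with columns segment_id, score_3ss, score_5ss and answers
    lookups by segment id (sequence contexts are ignored).
    """

    def __init__(self, path):
        df = pd.read_csv(path, sep="\t")
        self._by_id = {r.segment_id: (float(r.score_3ss), float(r.score_5ss))
                       for r in df.itertuples(index=False)}

    def lookup(self, segment_id: str) -> tuple[float, float]:
        return self._by_id.get(segment_id, (math.nan, math.nan))


def _fetch(genome, chrom: str, start: int, end: int) -> str | None:
    """Slice [start, end) from a pyfaidx.Fasta or a plain dict of strings.
    None when the window runs off the contig."""
    if start < 0:
        return None
    try:
        contig = genome[chrom]
    except KeyError:
        return None
    if end > len(contig):
        return None
    piece = contig[start:end]
    return str(piece).upper()


def extract_acceptor_context(genome, chrom: str, strand: str, acceptor_pos: int) -> str | None:
    """23-mer 3'ss context (20 intronic + 3 exonic) on the sense strand.

    ``acceptor_pos`` is the genomic position of the exon edge: exon start on
    '+', exon end on '-'.
    """
    if strand == "+":
        return _fetch(genome, chrom, acceptor_pos - ACCEPTOR_INTRON,
                      acceptor_pos + ACCEPTOR_EXON)
    seq = _fetch(genome, chrom, acceptor_pos - ACCEPTOR_EXON,
                 acceptor_pos + ACCEPTOR_INTRON)
    return reverse_complement(seq) if seq is not None else None


def extract_donor_context(genome, chrom: str, strand: str, donor_pos: int) -> str | None:
    """9-mer 5'ss context (3 exonic + 6 intronic) on the sense strand.

    ``donor_pos`` is the genomic position of the exon edge: exon end on '+',
    exon start on '-'.
    """
    if strand == "+":
        return _fetch(genome, chrom, donor_pos - DONOR_EXON, donor_pos + DONOR_INTRON)
    seq = _fetch(genome, chrom, donor_pos - DONOR_INTRON, donor_pos + DONOR_EXON)
    return reverse_complement(seq) if seq is not None else None


def splice_site_scores(segment: Segment, genome, scorer: SpliceSiteScorer
                       ) -> tuple[float, float]:
    """(score_3ss, score_5ss) of a segment's own splice sites.

    NaN marks a context window running off the contig.  A
    :class:`PrecomputedScorer` short-circuits sequence extraction entirely.
    """
    if isinstance(scorer, PrecomputedScorer):
        return scorer.lookup(segment.segment_id)
    if segment.strand == "+":
        acc_pos, don_pos = segment.start, segment.end
    else:
        acc_pos, don_pos = segment.end, segment.start
    acc = extract_acceptor_context(genome, segment.chrom, segment.strand, acc_pos)
    don = extract_donor_context(genome, segment.chrom, segment.strand, don_pos)
    s3 = scorer.score_acceptor(acc) if acc is not None else math.nan
    s5 = scorer.score_donor(don) if don is not None else math.nan
    return s3, s5


def flank_deltas(own_3ss: float, own_5ss: float,
                 downstream_3ss: float, upstream_5ss: float
                 ) -> tuple[float, float]:
    """Splice-site competition deltas: downstream-flank acceptor score minus
    own acceptor score, and upstream-flank donor score minus own donor score.
    NaN flanks propagate as NaN (flagged missing)."""
    return downstream_3ss - own_3ss, upstream_5ss - own_5ss


def exon_sequence(segment: Segment, genome) -> str | None:
    """Sense-strand sequence of the segment."""
    seq = _fetch(genome, segment.chrom, segment.start, segment.end)
    if seq is None:
        return None
    return reverse_complement(seq) if segment.strand == "-" else seq


def compute_exon_features(
    segments: Sequence[Segment],
    genome,
    pese_motifs: Sequence[str],
    pess_motifs: Sequence[str],
    scorer: SpliceSiteScorer,
) -> pd.DataFrame:
    """Per-exon feature table for cassette segments.

    Columns: pese_per_100bp, pess_per_100bp, gc_fraction, exon_length,
    up_intron_length, down_intron_length, score_3ss, score_5ss, delta_3ss,
    delta_5ss.  Flanking intron lengths are the full gap to the immediate
    flank exon.
    """
    rows = []
    for seg in segments:
        if not seg.is_cassette:
            continue
        seq = exon_sequence(seg, genome)
        if not seq:
            continue
        s3, s5 = splice_site_scores(seg, genome, scorer)
        left, right = seg.flank_left_exon, seg.flank_right_exon
        up_intron = down_intron = math.nan
        d3 = d5 = math.nan
        if left is not None and right is not None:
            left_gap = seg.start - left[1]
            right_gap = right[0] - seg.end
            if seg.strand == "+":
                up_intron, down_intron = left_gap, right_gap
                flank_acc = extract_acceptor_context(genome, seg.chrom, "+", right[0])
                flank_don = extract_donor_context(genome, seg.chrom, "+", left[1])
            else:
                up_intron, down_intron = right_gap, left_gap
                flank_acc = extract_acceptor_context(genome, seg.chrom, "-", left[1])
                flank_don = extract_donor_context(genome, seg.chrom, "-", right[0])
            if not isinstance(scorer, PrecomputedScorer):
                down_s3 = scorer.score_acceptor(flank_acc) if flank_acc else math.nan
                up_s5 = scorer.score_donor(flank_don) if flank_don else math.nan
                d3, d5 = flank_deltas(s3, s5, down_s3, up_s5)
        rows.append({
            "segment_id": seg.segment_id,
            "pese_per_100bp": motif_density(seq, pese_motifs),
            "pess_per_100bp": motif_density(seq, pess_motifs),
            "gc_fraction": gc_content(seq),
            "exon_length": seg.length,
            "up_intron_length": up_intron,
            "down_intron_length": down_intron,
            "score_3ss": s3,
            "score_5ss": s5,
            "delta_3ss": d3,
            "delta_5ss": d5,
        })
    return pd.DataFrame(rows)


# Feature sets for the 0..5 above-mean profiles: the first promotes exon
# inclusion, the second repression.
POSITIVE_FEATURES = ("pese_per_100bp", "gc_fraction", "exon_length",
                     "score_3ss", "score_5ss")
NEGATIVE_FEATURES = ("pess_per_100bp", "up_intron_length", "down_intron_length",
                     "delta_3ss", "delta_5ss")


def above_mean_profile(
    features: pd.DataFrame,
    groups: Mapping[str, Sequence[str]] | pd.Series,
    feature_set: Sequence[str] = POSITIVE_FEATURES,
) -> pd.DataFrame:
    """Density of exons with 0..len(feature_set) features above the grand mean.

    Grand means are computed over all exons of all groups; 'above' is strict.
    Exons missing any feature in the set are excluded.  Rows are groups,
    columns counts 0..n, each row summing to 1.
    """
    if isinstance(groups, pd.Series):
        grp_map = groups
    else:
        grp_map = pd.Series({sid: g for g, ids in groups.items() for sid in ids})
    df = features.set_index("segment_id")
    cols = list(feature_set)
    sub = df.loc[df.index.intersection(grp_map.index), cols].dropna()
    grand_mean = df[cols].mean()  # grand mean over every exon in the table
    n_above = (sub > grand_mean).sum(axis=1)
    out = {}
    for g in sorted(set(grp_map.loc[sub.index])):
        counts = n_above[grp_map.loc[sub.index] == g]
        dist = np.bincount(counts, minlength=len(cols) + 1).astype(float)
        total = dist.sum()
        out[g] = dist / total if total else dist
    return pd.DataFrame(out).T.rename_axis("group")


_BASES = "ACGT"


def _all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(_BASES, repeat=k)]


def count_kmers(seqs: Iterable[str], k: int) -> tuple[Counter, int]:
    """Count overlapping k-mers across sequences.

    Returns (counter, total) where total is the number of unambiguous k-mer
    windows, so that sum(counter.values()) == total.
    """
    counter: Counter = Counter()
    total = 0
    valid = set(_BASES)
    for seq in seqs:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if set(kmer) <= valid:
                counter[kmer] += 1
                total += 1
    return counter, total


def kmer_enrichment(group_a_seqs: Sequence[str], group_b_seqs: Sequence[str],
                    k: int = 6) -> pd.DataFrame:
    """Per-k-mer two-proportion z-test between two sequence groups.

    The pooled-proportion z statistic (no continuity correction) compares the
    k-mer's frequency among all k-mer positions of group A vs group B; p is
    two-sided with Bonferroni adjustment over all 4^k tests.  A k-mer absent
    from both groups gets z = 0, p = 1.  Sorted by z descending (A-enriched
    first).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ca, ta = count_kmers(group_a_seqs, k)
    cb, tb = count_kmers(group_b_seqs, k)
    if ta == 0 or tb == 0:
        raise ValueError("a group has zero k-mer positions")
    kmers = _all_kmers(k)
    na = np.array([ca.get(m, 0) for m in kmers], dtype=float)
    nb = np.array([cb.get(m, 0) for m in kmers], dtype=float)
    pa, pb = na / ta, nb / tb
    pooled = (na + nb) / (ta + tb)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / ta + 1.0 / tb))
        z = np.where(se > 0, (pa - pb) / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(na + nb == 0, 1.0, p)
    n_tests = 4 ** k
    df = pd.DataFrame({
        "kmer": kmers, "count_a": na.astype(int), "count_b": nb.astype(int),
        "total_a": ta, "total_b": tb, "z": z, "p": p,
        "p_bonferroni": np.minimum(1.0, p * n_tests)})
    return df.sort_values("z", ascending=False, kind="mergesort").reset_index(drop=True)


def significance_tier(p: float) -> str:
    """Star labels for group comparisons."""
    if math.isnan(p):
        return "na"
    if p <= 0.00005:
        return "*****"
    if p <= 0.0005:
        return "****"
    if p <= 0.005:
        return "***"
    if p <= 0.05:
        return "*"
    return "ns"


def group_compare(values_by_group: Mapping[str, Sequence[float]],
                  exact_max_total: int = 30) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests between groups.

    The exact null distribution is used for small, tie-free comparisons
    (combined n <= ``exact_max_total``); otherwise the normal approximation.
    Groups with fewer than two values are flagged (p = NaN).
    """
    names = list(values_by_group)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for a, b in itertools.combinations(names, 2):
        va = np.asarray(values_by_group[a], dtype=float)
        vb = np.asarray(values_by_group[b], dtype=float)
        flagged = len(va) < 2 or len(vb) < 2
        if flagged:
            p = math.nan
        else:
            combined = np.concatenate([va, vb])
            no_ties = len(np.unique(combined)) == len(combined)
            method = ("exact" if no_ties and len(combined) <= exact_max_total
                      else "asymptotic")
            p = float(stats.mannwhitneyu(va, vb, alternative="two-sided",
                                         method=method).pvalue)
        rows.append({"group_a": a, "group_b": b, "p": p,
                     "tier": significance_tier(p), "flagged": flagged})
    return pd.DataFrame(rows)
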