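"""Synthetic gene models and junction-count matrices with known truth.

The generator emulates the population structure a junction-based
vulnerability screen sees in a large RNA-seq cohort: most cassette exons are
nearly always included with tiny between-sample variability (resilient-like),
a sizeable fraction is highly included but measurably variable
(vulnerable-like), a minority is frankly alternative, plus zero-inclusion
exons and under-covered exons that must end up NA.

Noise model per cassette exon and sample: the sample's true inclusion is
beta-distributed around the exon's inclusion level pi with class-specific
concentration c (pi_s ~ Beta(pi*c, (1-pi)*c); larger c = tighter between-
sample spread), sequencing depth d_s is negative-binomial, and junction reads
are Poisson: the two inclusion junctions independently at rate d_s*pi_s and
the skip junction at rate d_s*(1-pi_s).  Splitting inclusion into two
independent Poisson draws mirrors real junction data, and the doubled
exclusion term in the PSI denominator then makes the estimator unbiased in
expectation.

For genes with more than three exons the rates generalize to a
product-of-inclusion model (an adjacent junction needs both its exons
present; a skip needs both neighbours present and the middle absent), so
shared junctions between neighbouring cassettes stay count-consistent.  The
truth class is drawn once per gene so a low-coverage gene cannot contain a
well-covered exon.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import Segment, Transcript, build_segments
from .junction_psi import JunctionMatrix

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate_gene_models",
    "simulate_junctions",
    "simulate",
    "recovery_report",
    "write_refgene",
    "write_junction_tsv",
    "write_fasta",
]

TRUTH_CLASSES = ("resilient", "vulnerable", "alternative", "not_spliced_in", "NA")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Defaults describe a 450-cassette, 400-sample cohort at depth 200 —
    3-exon genes so every gene contributes exactly one cassette exon and no
    junction row is shared between simulated cassettes.
    """

    n_genes: int = 450
    exons_per_gene: tuple[int, int] = (3, 3)
    exon_length: tuple[int, int] = (60, 240)
    intron_length: tuple[int, int] = (200, 2000)
    n_samples: int = 400
    depth_mean: float = 200.0
    depth_dispersion: float = 10.0     # negative-binomial size; larger = tighter
    low_coverage_depth_mean: float = 4.0
    # class mix over genes (fractions, must sum to 1)
    frac_resilient: float = 0.44
    frac_vulnerable: float = 0.30
    frac_alternative: float = 0.16
    frac_not_spliced_in: float = 0.05
    frac_na: float = 0.05
    # class-conditional inclusion levels and beta concentrations
    resilient_pi: tuple[float, float] = (0.9945, 0.9995)
    resilient_conc: float = 5000.0
    vulnerable_pi: tuple[float, float] = (0.90, 0.995)
    vulnerable_conc: float = 250.0
    alternative_pi: tuple[float, float] = (0.35, 0.895)
    alternative_conc: float = 50.0
    na_pi: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.frac_resilient + self.frac_vulnerable + self.frac_alternative
              + self.frac_not_spliced_in + self.frac_na)
        if abs(fr - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {fr}, not 1")
        for c in (self.resilient_conc, self.vulnerable_conc, self.alternative_conc):
            if c <= 0:
                raise ValueError("beta concentration must be > 0")
        if self.depth_mean <= 0 or self.low_coverage_depth_mean <= 0:
            raise ValueError("depth means must be > 0")
        if self.exons_per_gene[0] < 3:
            raise ValueError("genes need >= 3 exons to contain a cassette")
        if self.exon_length[0] < 1 or self.intron_length[0] < 1:
            raise ValueError("impossible geometry: non-positive lengths")


@dataclass
class SimResult:
    transcripts: list[Transcript]
    segments: list[Segment]
    junctions: JunctionMatrix
    truth: pd.DataFrame


def _rngs(config: SimConfig) -> tuple[np.random.Generator, np.random.Generator]:
    ss = np.random.SeedSequence(config.seed)
    child = ss.spawn(2)
    return np.random.default_rng(child[0]), np.random.default_rng(child[1])


def simulate_gene_models(config: SimConfig) -> tuple[list[Transcript], list[Segment]]:
    """Lay one multi-exon transcript per gene on its own synthetic contig.

    Deterministic under a fixed seed; flattening the output yields one
    cassette segment per internal exon.
    """
    rng, _ = _rngs(config)
    transcripts: list[Transcript] = []
    for i in range(config.n_genes):
        n_exons = int(rng.integers(config.exons_per_gene[0],
                                   config.exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        pos = 100
        starts, ends = [], []
        for j in range(n_exons):
            if j > 0:
                pos += int(rng.integers(config.intron_length[0],
                                        config.intron_length[1] + 1))
            length = int(rng.integers(config.exon_length[0],
                                      config.exon_length[1] + 1))
            starts.append(pos)
            ends.append(pos + length)
            pos += length
        transcripts.append(Transcript(
            transcript_id=f"NM_{100000 + i}",
            gene_symbol=f"SYN{i:04d}",
            chrom=f"chrS{i:04d}",
            strand=strand,
            exon_starts=tuple(starts),
            exon_ends=tuple(ends),
        ))
    return transcripts, build_segments(transcripts)


def _draw_class(rng: np.random.Generator, config: SimConfig) -> str:
    probs = [config.frac_resilient, config.frac_vulnerable,
             config.frac_alternative, config.frac_not_spliced_in, config.frac_na]
    return TRUTH_CLASSES[rng.choice(len(probs), p=probs)]


def _draw_pi(rng: np.random.Generator, config: SimConfig, cls: str) -> tuple[float, float]:
    """(pi, concentration) for one exon of a class."""
    if cls == "resilient":
        return float(rng.uniform(*config.resilient_pi)), config.resilient_conc
    if cls == "vulnerable":
        return float(rng.uniform(*config.vulnerable_pi)), config.vulnerable_conc
    if cls == "alternative":
        return float(rng.uniform(*config.alternative_pi)), config.alternative_conc
    if cls == "not_spliced_in":
        return 0.0, np.inf
    return config.na_pi, config.resilient_conc   # NA: normal inclusion, starved depth


def _sample_pi(rng: np.random.Generator, pi: float, conc: float, n: int) -> np.ndarray:
    if pi <= 0.0:
        return np.zeros(n)
    if pi >= 1.0 or not np.isfinite(conc):
        return np.full(n, pi)
    return rng.beta(pi * conc, (1.0 - pi) * conc, size=n)


def simulate_junctions(
    transcripts: Sequence[Transcript],
    segments: Sequence[Segment],
    config: SimConfig,
) -> tuple[JunctionMatrix, pd.DataFrame]:
    """Draw the junction-count matrix and the per-cassette truth table."""
    _, rng = _rngs(config)
    n = config.n_samples
    sample_ids = [f"S{j:04d}" for j in range(n)]
    seg_by_key = {(s.chrom, s.start, s.end): s for s in segments if s.is_cassette}

    jx_rows: list[tuple[str, int, int, str]] = []
    jx_counts: list[np.ndarray] = []
    truth_rows: list[dict] = []

    for tx in sorted(transcripts, key=lambda t: t.transcript_id):
        exons = tx.exons
        k = len(exons)
        gene_class = _draw_class(rng, config)
        depth_mean = (config.low_coverage_depth_mean if gene_class == "NA"
                      else config.depth_mean)
        size = config.depth_dispersion
        p = size / (size + depth_mean)
        depth = rng.negative_binomial(size, p, size=n).astype(float)

        # Per-exon per-sample inclusion; terminal exons always included.
        pi_s = np.ones((k, n))
        for i in range(1, k - 1):
            pi, conc = _draw_pi(rng, config, gene_class)
            pi_s[i] = _sample_pi(rng, pi, conc, n)
            seg = seg_by_key.get((tx.chrom, exons[i][0], exons[i][1]))
            if seg is not None:
                truth_rows.append({
                    "segment_id": seg.segment_id, "true_pi": pi,
                    "true_class": gene_class,
                    "concentration": conc if np.isfinite(conc) else -1.0})

        for i in range(k - 1):
            lam = depth * pi_s[i] * pi_s[i + 1]
            jx_rows.append((tx.chrom, exons[i][1], exons[i + 1][0], tx.strand))
            jx_counts.append(rng.poisson(lam))
        for i in range(1, k - 1):
            lam = depth * pi_s[i - 1] * (1.0 - pi_s[i]) * pi_s[i + 1]
            jx_rows.append((tx.chrom, exons[i - 1][1], exons[i + 1][0], tx.strand))
            jx_counts.append(rng.poisson(lam))

    jdf = pd.DataFrame(jx_rows, columns=["chrom", "start", "end", "strand"])
    jm = JunctionMatrix(junctions=jdf,
                        counts=np.vstack(jx_counts).astype(np.int64),
                        sample_ids=sample_ids)
    truth = pd.DataFrame(truth_rows,
                         columns=["segment_id", "true_pi", "true_class",
                                  "concentration"])
    return jm, truth


def simulate(config: SimConfig | None = None) -> SimResult:
    """Full generator run: models, segments, junction matrix and truth."""
    config = config or SimConfig()
    transcripts, segments = simulate_gene_models(config)
    jm, truth = simulate_junctions(transcripts, segments, config)
    return SimResult(transcripts=transcripts, segments=segments,
                     junctions=jm, truth=truth)


def recovery_report(classification: pd.DataFrame, truth: pd.DataFrame
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Confusion matrix (rows = truth, columns = predicted) and per-class
    recall/precision.  Raises on segment-id mismatch."""
    if truth.empty:
        empty = pd.DataFrame()
        return empty, pd.DataFrame(columns=["class", "n_true", "recall", "precision"])
    merged = truth.merge(classification, on="segment_id", how="left")
    if merged["label"].isna().any():
        missing = merged.loc[merged["label"].isna(), "segment_id"].head().tolist()
        raise KeyError(f"truth segments missing from classification: {missing}")
    confusion = pd.crosstab(merged["true_class"], merged["label"])
    confusion = confusion.reindex(index=list(TRUTH_CLASSES),
                                  columns=list(TRUTH_CLASSES), fill_value=0)
    metrics = []
    for cls in TRUTH_CLASSES:
        n_true = int(confusion.loc[cls].sum())
        n_pred = int(confusion[cls].sum())
        tp = int(confusion.loc[cls, cls])
        metrics.append({
            "class": cls, "n_true": n_true,
            "recall": tp / n_true if n_true else np.nan,
            "precision": tp / n_pred if n_pred else np.nan})
    return confusion, pd.DataFrame(metrics)


def write_refgene(transcripts: Sequence[Transcript], path) -> None:
    """Emit transcripts in the UCSC refGene column layout."""
    rows = []
    for tx in transcripts:
        starts = ",".join(str(s) for s in tx.exon_starts) + ","
        ends = ",".join(str(e) for e in tx.exon_ends) + ","
        frames = ",".join("-1" for _ in tx.exon_starts) + ","
        rows.append([0, tx.transcript_id, tx.chrom, tx.strand,
                     tx.exon_starts[0], tx.exon_ends[-1],
                     tx.exon_starts[0], tx.exon_starts[0],
                     tx.n_exons, starts, ends, 0, tx.gene_symbol,
                     "unk", "unk", frames])
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_junction_tsv(jm: JunctionMatrix, path,
                       dialect: str = "snaptron_1based_inclusive") -> None:
    """Write a junction matrix in the requested coordinate dialect."""
    coord = jm.junctions.copy()
    if dialect == "snaptron_1based_inclusive":
        coord["start"] = coord["start"] + 1
    elif dialect != "bed_0based_halfopen":
        raise ValueError(f"unknown dialect {dialect!r}")
    out = pd.concat(
        [coord, pd.DataFrame(jm.counts, columns=jm.sample_ids)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def write_fasta(transcripts: Sequence[Transcript], path,
                seed: int = 0, margin: int = 100, line_width: int = 70) -> None:
    """Random-sequence contigs long enough to cover every transcript."""
    rng = np.random.default_rng(seed)
    lengths: dict[str, int] = {}
    for tx in transcripts:
        lengths[tx.chrom] = max(lengths.get(tx.chrom, 0), tx.exon_ends[-1] + margin)
    bases = np.array(list("ACGT"))
    with open(path, "w") as fh:
        for chrom in sorted(lengths):
            seq = "".join(rng.choice(bases, size=lengths[chrom]))
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i:i + line_width] + "\n")
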