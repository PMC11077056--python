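import numpy as np
import pandas as pd
import pytest

from vulexmap.annotation import Transcript, build_segments
from vulexmap.junction_psi import JunctionMatrix


@pytest.fixture
def toy_transcripts():
    """One gene, two isoforms: the second skips the middle exon."""
    return [
        Transcript("NM_000010", "TOY", "chr1", "+",
                   (100, 300, 500), (200, 400, 600)),
        Transcript("NM_000002", "TOY", "chr1", "+",
                   (100, 500), (200, 600)),
    ]


@pytest.fixture
def toy_segments(toy_transcripts):
    return build_segments(toy_transcripts)


@pytest.fixture
def toy_cassette(toy_segments):
    (seg,) = [s for s in toy_segments if s.is_cassette]
    return seg


def make_junction_matrix(rows, counts, sample_ids=None):
    """rows: list of (chrom, start, end, strand) 0-based half-open introns."""
    counts = np.atleast_2d(np.asarray(counts, dtype=np.int64))
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(counts.shape[1])]
    return JunctionMatrix(
        junctions=pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"]),
        counts=counts, sample_ids=sample_ids)


@pytest.fixture
def toy_junctions():
    """Junctions for the toy gene: inclusion 40/60 reads, skipping 10."""
    return make_junction_matrix(
        [("chr1", 200, 300, "+"),   # exon1 -> exon2
         ("chr1", 400, 500, "+"),   # exon2 -> exon3
         ("chr1", 200, 500, "+")],  # exon1 -> exon3 (skip)
        [[40], [60], [10]])
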