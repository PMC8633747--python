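"""Shared fixtures: a session-scoped synthetic study dataset and toy genes."""

from __future__ import annotations

import pytest

from recombikit import fixtures, genome_io


@pytest.fixture(scope="session")
def study():
    """Synthetic 8-gene dataset covering every planted-feature pattern."""
    return fixtures.generate_fixture(fixtures.FixtureConfig(seed=7, n_genes=8))


def make_toy_genome(upstream: str, utr5: str, cds: str, utr3: str,
                    downstream: str, strand: str = "+",
                    chrom: str = "chrT", gene_id: str = "toy.g1"):
    """A single-gene chromosome built from explicit sense-strand parts."""
    sense = upstream + utr5 + cds + utr3 + downstream
    seq = sense if strand == "+" else genome_io.revcomp(sense)
    n = len(sense)
    up, u5, nc, u3 = len(upstream), len(utr5), len(cds), len(utr3)
    if strand == "+":
        utr5_iv = (up, up + u5)
        cds_iv = (up + u5, up + u5 + nc)
        utr3_iv = (up + u5 + nc, up + u5 + nc + u3)
        span = (utr5_iv[0], utr3_iv[1]) if u5 or u3 else cds_iv
        span = (min(utr5_iv[0], cds_iv[0]), max(utr3_iv[1], cds_iv[1]))
    else:
        utr5_iv = (n - up - u5, n - up)
        cds_iv = (n - up - u5 - nc, n - up - u5)
        utr3_iv = (n - up - u5 - nc - u3, n - up - u5 - nc)
        span = (min(utr3_iv[0], cds_iv[0]), max(utr5_iv[1], cds_iv[1]))
    genome = genome_io.GenomeSequences({chrom: seq})
    gene = genome_io.GeneModel(
        gene_id=gene_id, chromosome=chrom, strand=strand, gene_span=span,
        utr5_segments=[utr5_iv] if u5 else [],
        cds_segments=[cds_iv],
        utr3_segments=[utr3_iv] if u3 else [],
        transcript_ids=[f"{gene_id}.t1"])
    return genome, gene
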