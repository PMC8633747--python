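"""BAC/fosmid clone coverage search over gene targets.

A clone *covers* a gene when the gene's required interval — the gene span,
optionally extended upstream on the coding strand so the promoter window is
inside the clone — lies entirely within the clone's mapped interval.  An
optional relaxed mode accepts clones that terminate within the 3'-UTR (the
stop codon must still be inside).  For each gene the k smallest covering
clones are reported, smallest first.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .genome_io import GeneModel, GenomeSequences

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CloneRecord:
    clone_id: str
    chromosome: str
    start: int
    end: int
    library: str = "BAC"

    def __post_init__(self) -> None:
        if self.end - self.start <= 0:
            raise ValueError(f"clone {self.clone_id}: empty interval")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CoverageResult:
    gene_id: str
    covering_clones: list[str]
    covered: bool
    covered_with_utr3_allowance: bool
    required_interval: tuple[int, int]


def load_clone_map(path: str | Path,
                   genome: GenomeSequences | None = None) -> list[CloneRecord]:
    """Read a BED-like clone placement table.

    Columns: chromosome, start, end, clone_id[, library].  Intervals running
    past a chromosome end are clamped with a warning when a genome is given.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 4:
        raise ValueError("clone map needs columns chromosome/start/end/clone_id")
    records: list[CloneRecord] = []
    for row in df.itertuples(index=False):
        chrom, start, end, clone_id = row[0], int(row[1]), int(row[2]), row[3]
        library = row[4] if df.shape[1] > 4 and pd.notna(row[4]) else "BAC"
        if genome is not None:
            chrom_len = genome.lengths.get(chrom)
            if chrom_len is not None and end > chrom_len:
                warnings.warn(
                    f"clone {clone_id} end {end} beyond {chrom} length "
                    f"{chrom_len}; clamped", stacklevel=2)
                logger.warning("clamped clone %s to chromosome end", clone_id)
                end = chrom_len
        records.append(CloneRecord(clone_id, chrom, start, end, library))
    return records


def required_interval(gene: GeneModel, upstream_bp: int) -> tuple[int, int]:
    """Gene span extended ``upstream_bp`` on the coding strand."""
    s, e = gene.gene_span
    if gene.strand == "+":
        return max(0, s - upstream_bp), e
    return s, e + upstream_bp


def clones_covering(gene: GeneModel, upstream_bp: int,
                    clones: list[CloneRecord],
                    allow_utr3_termination: bool = False,
                    k: int = 5) -> CoverageResult:
    """Rank the k smallest clones covering the gene's required interval."""
    if upstream_bp < 0:
        raise ValueError("upstream_bp must be >= 0")
    req = required_interval(gene, upstream_bp)
    # with the 3'-UTR allowance the clone may stop inside the 3'-UTR, but
    # must still contain the stop codon
    if gene.cds_segments:
        stop_s, stop_e = gene.stop_span
        relaxed = (req[0], stop_e) if gene.strand == "+" else (stop_s, req[1])
    else:
        relaxed = req
    strict_hits: list[CloneRecord] = []
    relaxed_any = False
    for clone in clones:
        if clone.chromosome != gene.chromosome:
            continue
        if clone.start <= req[0] and req[1] <= clone.end:
            strict_hits.append(clone)
            relaxed_any = True
        elif clone.start <= relaxed[0] and relaxed[1] <= clone.end:
            relaxed_any = True
    pool = strict_hits if not allow_utr3_termination else [
        c for c in clones
        if c.chromosome == gene.chromosome
        and c.start <= relaxed[0] and relaxed[1] <= c.end]
    ranked = sorted(pool, key=lambda c: (c.length, c.clone_id))[:k]
    return CoverageResult(
        gene_id=gene.gene_id,
        covering_clones=[c.clone_id for c in ranked],
        covered=bool(strict_hits),
        covered_with_utr3_allowance=relaxed_any,
        required_interval=req)


@dataclass
class CoverageStatistics:
    fraction_covered: float
    fraction_covered_utr3: float
    per_gene: list[CoverageResult] = field(default_factory=list)


def coverage_statistics(genes: list[GeneModel], clones: list[CloneRecord],
                        upstream_bp: int = 0, k: int = 5) -> CoverageStatistics:
    """Fraction of genes covered by >= 1 clone (strict and 3'-UTR-relaxed).

    The headline statistic uses ``upstream_bp = 0`` (gene body, 5'-UTR start
    to 3'-UTR end); arm-aware searches pass 3000 so the homology window is
    inside the clone.
    """
    if not genes:
        raise ValueError("no genes supplied")
    results = [clones_covering(g, upstream_bp, clones, k=k) for g in genes]
    n = len(results)
    return CoverageStatistics(
        fraction_covered=sum(r.covered for r in results) / n,
        fraction_covered_utr3=sum(r.covered_with_utr3_allowance for r in results) / n,
        per_gene=results)


def coverage_to_frame(stats: CoverageStatistics, k: int = 5) -> pd.DataFrame:
    """Per-gene table mirroring a five-smallest-clones report."""
    rows = []
    for r in stats.per_gene:
        row = {"gene_id": r.gene_id, "covered": r.covered,
               "covered_with_utr3_allowance": r.covered_with_utr3_allowance,
               "required_start": r.required_interval[0],
               "required_end": r.required_interval[1]}
        for i in range(k):
            row[f"clone_{i + 1}"] = (r.covering_clones[i]
                                     if i < len(r.covering_clones) else "")
        rows.append(row)
    return pd.DataFrame(rows)
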