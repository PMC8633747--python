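"""Genome and annotation I/O: gene models and strand-correct subregion extraction.

All internal coordinates are 0-based half-open intervals on the forward
(assembly) strand.  Input files follow the GFF convention (1-based inclusive)
and are converted on read.  "Upstream" is always defined on the coding strand,
so for minus-strand genes upstream means higher genomic coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils
from Bio import SeqIO

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                           "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

STOP_CODONS = {"TAA", "TAG", "TGA"}

IUPAC = set("ACGTRYSWKMBDHVN")


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware, case preserved)."""
    return seq.translate(COMPLEMENT)[::-1]


class GenomeIOError(ValueError):
    pass


@dataclass
class GenomeSequences:
    """A set of named nucleotide sequences (chromosomes / scaffolds)."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.records.items():
            if not seq:
                raise GenomeIOError(f"empty sequence for record {name!r}")
            bad = set(seq.upper()) - IUPAC
            if bad:
                raise GenomeIOError(
                    f"record {name!r} contains non-IUPAC characters: {sorted(bad)}")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.records.items()}

    def slice(self, chrom: str, start: int, end: int) -> str:
        seq = self.records[chrom]
        if start < 0 or end > len(seq):
            raise GenomeIOError(
                f"interval [{start}, {end}) outside {chrom!r} (length {len(seq)})")
        return seq[start:end]


@dataclass
class GeneModel:
    """One gene locus with UTR/CDS structure for a chosen transcript.

    Segment lists hold 0-based half-open genomic intervals sorted by genomic
    coordinate; ``gene_span`` runs from the start of the 5'-UTR to the end of
    the 3'-UTR (or the CDS bounds where UTRs are unannotated).
    """

    gene_id: str
    chromosome: str
    strand: str
    gene_span: tuple[int, int]
    utr5_segments: list[tuple[int, int]] = field(default_factory=list)
    cds_segments: list[tuple[int, int]] = field(default_factory=list)
    utr3_segments: list[tuple[int, int]] = field(default_factory=list)
    transcript_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GenomeIOError(f"{self.gene_id}: bad strand {self.strand!r}")
        s, e = self.gene_span
        if e - s < 1:
            raise GenomeIOError(f"{self.gene_id}: empty gene span")
        for seg_s, seg_e in self.utr5_segments + self.cds_segments + self.utr3_segments:
            if not (s <= seg_s < seg_e <= e):
                raise GenomeIOError(
                    f"{self.gene_id}: segment [{seg_s},{seg_e}) outside span [{s},{e})")

    @property
    def has_utr5(self) -> bool:
        return bool(self.utr5_segments)

    @property
    def has_utr3(self) -> bool:
        return bool(self.utr3_segments)

    @property
    def length(self) -> int:
        return self.gene_span[1] - self.gene_span[0]

    @property
    def cds_span(self) -> tuple[int, int]:
        """Genomic bounds of the ATG-Stop region (unspliced)."""
        if not self.cds_segments:
            raise GenomeIOError(f"{self.gene_id}: no CDS segments")
        return self.cds_segments[0][0], self.cds_segments[-1][1]

    @property
    def atg_position(self) -> int:
        """Genomic coordinate of the first base of the start codon."""
        s, e = self.cds_span
        return s if self.strand == "+" else e - 1

    @property
    def stop_span(self) -> tuple[int, int]:
        """Genomic interval of the stop codon (last 3 coding bases)."""
        s, e = self.cds_span
        return (e - 3, e) if self.strand == "+" else (s, s + 3)

    def five_prime_point(self) -> int:
        """Genomic coordinate of the 5'-most point of the gene span."""
        return self.gene_span[0] if self.strand == "+" else self.gene_span[1]


@dataclass
class RegionSet:
    """Gene subregion sequences, all in mRNA-sense orientation."""

    whole_gene: str
    utr5: str
    atg_stop: str
    utr3: str


def read_genome(path: str | Path) -> GenomeSequences:
    """Read a multi-record FASTA; ids are the first whitespace token of each header."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise GenomeIOError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq)
        if not seq:
            raise GenomeIOError(f"empty sequence for FASTA record {rec.id!r}")
        records[rec.id] = seq
    if not records:
        raise GenomeIOError(f"no FASTA records found in {path}")
    return GenomeSequences(records)


def write_genome(genome: GenomeSequences, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _interval(start_1based: int, end_1based: int) -> tuple[int, int]:
    return start_1based - 1, end_1based


def _merge_sorted(segments: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    segs = sorted(segments)
    out: list[tuple[int, int]] = []
    for s, e in segs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class AnnotationReport:
    """Per-gene problems found while building models; offending genes are skipped."""

    errors: list[tuple[str, str]] = field(default_factory=list)

    def add(self, gene_id: str, message: str) -> None:
        self.errors.append((gene_id, message))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\terror\n")
            for gid, msg in self.errors:
                fh.write(f"{gid}\t{msg}\n")


def read_annotation(path: str | Path,
                    report: AnnotationReport | None = None) -> list[GeneModel]:
    """Read gene models from GFF3 or a Phytozome-style TSV.

    Multi-transcript loci are collapsed to the primary (first-listed)
    transcript; all transcript ids are retained on the model.
    """
    path = Path(path)
    if path.suffix.lower() in {".tsv", ".txt", ".tab"}:
        return _read_annotation_tsv(path, report)
    return _read_annotation_gff3(path, report)


_FEATURE_KEYS = {
    "five_prime_UTR": "utr5",
    "five_prime_utr": "utr5",
    "CDS": "cds",
    "cds": "cds",
    "three_prime_UTR": "utr3",
    "three_prime_utr": "utr3",
}


def _read_annotation_gff3(path: Path,
                          report: AnnotationReport | None) -> list[GeneModel]:
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = gene.id
        transcripts = list(db.children(gene, featuretype="mRNA", order_by="start"))
        tids = [t.id for t in transcripts]
        segs: dict[str, list[tuple[int, int]]] = {"utr5": [], "cds": [], "utr3": []}
        if transcripts:
            primary = transcripts[0]
            children = db.children(primary, order_by="start")
        else:  # features attached directly to the gene
            children = db.children(gene, order_by="start")
        for feat in children:
            key = _FEATURE_KEYS.get(feat.featuretype)
            if key is not None:
                segs[key].append(_interval(feat.start, feat.end))
        model = _build_model(gid, gene.seqid, gene.strand,
                             _interval(gene.start, gene.end), segs, tids, report)
        if model is not None:
            models.append(model)
    return models


def _read_annotation_tsv(path: Path,
                         report: AnnotationReport | None) -> list[GeneModel]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chromosome", "strand", "feature", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise GenomeIOError(f"annotation TSV missing columns: {sorted(missing)}")
    models: list[GeneModel] = []
    for gid, group in df.groupby("gene_id", sort=False):
        chrom = group["chromosome"].iloc[0]
        strand = group["strand"].iloc[0]
        segs: dict[str, list[tuple[int, int]]] = {"utr5": [], "cds": [], "utr3": []}
        span: tuple[int, int] | None = None
        if "transcript_id" in group.columns:
            tids = list(dict.fromkeys(group["transcript_id"].dropna()))
        else:
            tids = []
        primary = tids[0] if tids else None
        for row in group.itertuples(index=False):
            iv = _interval(int(row.start), int(row.end))
            feat = row.feature
            if feat == "gene":
                span = iv
            elif primary is None or getattr(row, "transcript_id", primary) == primary:
                key = _FEATURE_KEYS.get(feat)
                if key is not None:
                    segs[key].append(iv)
        if span is None:
            allsegs = segs["utr5"] + segs["cds"] + segs["utr3"]
            span = (min(s for s, _ in allsegs), max(e for _, e in allsegs))
        model = _build_model(gid, chrom, strand, span, segs, tids, report)
        if model is not None:
            models.append(model)
    return models


def _build_model(gid: str, chrom: str, strand: str, span: tuple[int, int],
                 segs: dict[str, list[tuple[int, int]]], tids: list[str],
                 report: AnnotationReport | None) -> GeneModel | None:
    try:
        return GeneModel(
            gene_id=gid, chromosome=chrom, strand=strand, gene_span=span,
            utr5_segments=_merge_sorted(segs["utr5"]),
            cds_segments=_merge_sorted(segs["cds"]),
            utr3_segments=_merge_sorted(segs["utr3"]),
            transcript_ids=tids,
        )
    except GenomeIOError as exc:
        if report is not None:
            report.add(gid, str(exc))
            return None
        raise


def _oriented(seq: str, strand: str) -> str:
    return seq if strand == "+" else revcomp(seq)


def extract_regions(gene: GeneModel, genome: GenomeSequences) -> RegionSet:
    """Extract whole-gene / 5'-UTR / ATG-Stop / 3'-UTR strings, mRNA-sense.

    The ATG-Stop string is the unspliced genomic span from start codon through
    stop codon (introns retained).  UTR strings concatenate the annotated UTR
    segments in transcript order, introns excluded.
    """
    chrom_len = genome.lengths.get(gene.chromosome)
    if chrom_len is None:
        raise GenomeIOError(f"{gene.gene_id}: chromosome {gene.chromosome!r} not in genome")
    s, e = gene.gene_span
    if s < 0 or e > chrom_len:
        raise GenomeIOError(
            f"{gene.gene_id}: span [{s},{e}) exceeds chromosome {gene.chromosome!r}")
    whole = _oriented(genome.slice(gene.chromosome, s, e), gene.strand)
    if gene.cds_segments:
        cs, ce = gene.cds_span
        atg_stop = _oriented(genome.slice(gene.chromosome, cs, ce), gene.strand)
    else:
        atg_stop = ""

    def spliced(segments: list[tuple[int, int]]) -> str:
        parts = [genome.slice(gene.chromosome, a, b) for a, b in segments]
        joined = "".join(parts)
        return _oriented(joined, gene.strand)

    return RegionSet(
        whole_gene=whole,
        utr5=spliced(gene.utr5_segments),
        atg_stop=atg_stop,
        utr3=spliced(gene.utr3_segments),
    )


def spliced_cds(gene: GeneModel, genome: GenomeSequences) -> str:
    """Spliced CDS in mRNA sense (starts with ATG for complete models)."""
    parts = [genome.slice(gene.chromosome, a, b) for a, b in gene.cds_segments]
    return _oriented("".join(parts), gene.strand)


def gc_content(seq: str) -> float:
    """GC fraction over annotated (A/C/G/T) bases only; NaN for no such bases."""
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return math.nan
    return (seq.count("G") + seq.count("C")) / acgt
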