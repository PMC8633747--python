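"""Deterministic synthetic genome / annotation / clone-library / vector
generator with a ground-truth manifest.

Every planted feature (tandem and inverted repeats, uORFs by class, clone
coverage, the best upstream homology-arm window) is recorded in the manifest
and re-detectable by the corresponding analysis module at default
parameters; the generator verifies this closure before returning, so
recovered counts equal planted counts with zero false positives.

Backgrounds are sampled at GC 0.64 — a whole-gene compromise for a genome
whose coding regions run near 68% GC — and sanitised with C-substitution:
replacing a base with C can never create an ATG or a stop codon (neither
contains C), so unwanted start codons and in-frame stops are removed without
introducing new ones.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import arm_design, clone_search, complexity, construct, genome_io, uorf
from .genome_io import revcomp
from .primer_qc import longest_dinucleotide_units, longest_homopolymer_run

STOPS = ("TAA", "TAG", "TGA")


class FixtureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class PlantedRepeat:
    kind: str          # mono | di | tri | tetra_plus | inverted | span_start
    region: str        # utr5 | cds | utr3 (span_start ignores this)


@dataclass
class GenePlan:
    gene_id: str
    strand: str
    utr5_len: int = 240
    cds_len: int = 1203          # includes the stop codon; multiple of 3
    utr3_len: int = 240
    repeats: list[PlantedRepeat] = field(default_factory=list)
    uorf_classes: list[int] = field(default_factory=list)
    covered: bool = True
    utr3_terminating_clone: bool = False


@dataclass
class FixtureConfig:
    n_genes: int = 12
    n_chromosomes: int = 2
    gc_target: float = 0.64
    clone_coverage: float = 0.75   # fraction of genes strictly covered
    upstream_flank: int = 3500     # room for the 2-3 kbp arm window
    downstream_flank: int = 300
    intergenic: int = 400
    cassette_len: int = 4600       # tagging-vector amplified path
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.clone_coverage <= 1:
            raise FixtureError("clone_coverage must be in [0, 1]")
        if self.n_genes < 1:
            raise FixtureError("need at least one gene")
        if self.upstream_flank < 3000 + 110:
            raise FixtureError("upstream_flank too small for the arm window")


# per-gene feature patterns cycled over the gene list
_DEFAULT_PATTERNS = [
    ([PlantedRepeat("mono", "utr3")], []),
    ([PlantedRepeat("di", "cds")], [3]),
    ([PlantedRepeat("tri", "cds")], [1]),
    ([PlantedRepeat("tetra_plus", "utr3")], [2]),
    ([PlantedRepeat("inverted", "cds")], [3, 3, 1]),
    ([PlantedRepeat("span_start", "cds")], []),
    ([], [2, 3]),
    ([PlantedRepeat("mono", "cds"), PlantedRepeat("inverted", "utr3")], [1]),
]


def default_gene_plans(config: FixtureConfig) -> list[GenePlan]:
    plans = []
    n_covered = round(config.clone_coverage * config.n_genes)
    for i in range(config.n_genes):
        repeats, uorfs = _DEFAULT_PATTERNS[i % len(_DEFAULT_PATTERNS)]
        plans.append(GenePlan(
            gene_id=f"synth{i + 1:02d}.g{100 + i}",
            strand="+" if i % 2 == 0 else "-",
            repeats=list(repeats), uorf_classes=list(uorfs),
            covered=i < n_covered,
            utr3_terminating_clone=(i == n_covered) and n_covered < config.n_genes))
    return plans


# ---------------------------------------------------------------------------
# sequence sampling helpers

BASES = np.array(list("ACGT"))


def _sample(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(BASES, size=n, p=p))


def _c_substitute(seq: list[str], idx: int) -> None:
    seq[idx] = "C"


def strip_atgs(seq: str, protect: set[int] | None = None) -> str:
    """Remove every ATG (any frame) by C-substituting its T."""
    protect = protect or set()
    s = list(seq)
    i = 0
    while i < len(s) - 2:
        if s[i] == "A" and s[i + 1] == "T" and s[i + 2] == "G" and i not in protect:
            _c_substitute(s, i + 1)
        i += 1
    return "".join(s)


def strip_frame_stops(seq: str, start: int, end: int | None = None,
                      protect: set[int] | None = None) -> str:
    """Remove stop codons at positions start, start+3, ... (< end)."""
    protect = protect or set()
    s = list(seq)
    end = len(s) if end is None else end
    for j in range(start, min(end, len(s)) - 2, 3):
        if "".join(s[j:j + 3]) in STOPS and j not in protect:
            _c_substitute(s, j + 1)
    return "".join(s)


def _clean_background(rng: np.random.Generator, n: int, gc: float,
                      params: complexity.RepeatParams,
                      max_tries: int = 50) -> str:
    """Sample a repeat-free background segment (rejection sampling)."""
    for _ in range(max_tries):
        seq = _sample(rng, n, gc)
        if n >= 10 and complexity.find_tandem_repeats(seq, params):
            continue
        if n >= 2 * params.inv_min_stem and complexity.find_inverted_repeats(seq, params):
            continue
        return seq
    raise FixtureError(f"could not sample a repeat-free {n}-bp background")


# ---------------------------------------------------------------------------
# planted blocks

_REPEAT_BLOCKS = {
    "mono": "A" * 12,
    "di": "AC" * 12,
    "tri": "GGC" * 8,
    "tetra_plus": "AAGC" * 6,
}


def _inverted_block(rng: np.random.Generator,
                    params: complexity.RepeatParams) -> str:
    """stem + 4-bp spacer + reverse complement of the stem (perfect)."""
    for _ in range(100):
        stem = _sample(rng, 12, 0.5)
        spacer = _sample(rng, 4, 0.5)
        block = stem + spacer + revcomp(stem)
        if not complexity.find_tandem_repeats(block, params):
            hits = complexity.find_inverted_repeats(block, params)
            if len(hits) == 1 and hits[0].start == 0 and hits[0].end == len(block):
                return block
    raise FixtureError("could not build an inverted-repeat block")


def _plant_in_segment(segment: str, block: str, offset: int) -> str:
    if offset + len(block) > len(segment):
        raise FixtureError("planted block exceeds its segment")
    return segment[:offset] + block + segment[offset + len(block):]


# ---------------------------------------------------------------------------
# upstream arm window engineering

GUARD = ("GGC" * 10)  # pure-GC guard flanks push overlapping windows past
                      # the arm GC ceiling or onto worse complexity scores


def _best_arm_candidate(rng: np.random.Generator) -> str:
    """A 50-mer with GC exactly 0.60, runs <= 2 and no repeated dinucleotide
    unit: by construction the lowest-scoring (best) window in its island."""
    letters = list("G" * 15 + "C" * 15 + "A" * 10 + "T" * 10)
    for _ in range(20000):
        rng.shuffle(letters)
        cand = "".join(letters)
        if arm_design.ISCEI_SITE in cand:
            continue
        if (longest_homopolymer_run(cand) <= 2
                and longest_dinucleotide_units(cand) <= 1):
            return cand
    raise FixtureError("could not build the clean arm window")


# ---------------------------------------------------------------------------
# gene assembly

@dataclass
class BuiltGene:
    plan: GenePlan
    upstream: str          # coding sense, ends at the 5'-UTR start
    utr5: str
    cds: str
    utr3: str
    downstream: str
    best_arm_seq: str
    best_arm_offset: int   # arm start relative to the ATG (negative)
    expected_counts: dict  # kind -> {whole, utr5, atg_stop, utr3}
    expected_uorfs: dict   # class -> count

    @property
    def sense_gene(self) -> str:
        return self.utr5 + self.cds + self.utr3

    @property
    def sense_block(self) -> str:
        return self.upstream + self.sense_gene + self.downstream


_SPAN_START_TAIL = "TGTGTGTGTGTGT"        # 13 bp of TG tiling ending the UTR
_SPAN_START_HEAD = "ATG" + "TGTGTGTGTGTGTG"  # start codon continues the tiling


def _build_utr5(rng: np.random.Generator, plan: GenePlan, gc: float,
                params: complexity.RepeatParams) -> tuple[str, dict]:
    """5'-UTR with planted uORFs; background is ATG-free and, in the frames
    of planted class-1/2 uORFs, stop-free.

    Class-3 blocks (ATG + 3 codons + TAA) sit in the 5' half; class-1/2
    uATGs sit 3'-ward of every class-3 block so that stripping stops from
    their reading frames cannot touch a planted class-3 stop.
    """
    n = plan.utr5_len
    seq = strip_atgs(_clean_background(rng, n, gc, params))
    expected: dict[int, int] = {}
    atg_protect: set[int] = set()
    read_through: list[int] = []   # class-1/2 uATG offsets
    cursor = 10
    for cls in plan.uorf_classes:
        if cls != 3:
            continue
        interior = strip_atgs(strip_frame_stops(_sample(rng, 9, gc), 0))
        block = "ATG" + interior + "TAA"
        seq = _plant_in_segment(seq, block, cursor)
        atg_protect.add(cursor)
        expected[3] = expected.get(3, 0) + 1
        cursor += len(block) + 6
    tail = max(cursor + 6, n - 60)
    for cls in plan.uorf_classes:
        if cls == 3:
            continue
        offset = tail + (n - tail) % 3        # in frame with the main ATG
        if cls == 2:
            offset += 1                        # knock out of frame
        if offset + 6 > n:
            raise FixtureError(f"{plan.gene_id}: 5'-UTR too short for uORFs")
        seq = seq[:offset] + "ATG" + seq[offset + 3:]
        atg_protect.add(offset)
        read_through.append(offset)
        expected[cls] = expected.get(cls, 0) + 1
        tail = offset + 4
    # junction-created ATGs, then stop removal along read-through frames
    seq = strip_atgs(seq, protect=atg_protect)
    for off in read_through:
        seq = strip_frame_stops(seq, off + 3)
    return seq, expected


def _verify_uorfs(seq_utr5: str, cds: str, expected: dict[int, int]) -> bool:
    found = uorf.find_uorfs(seq_utr5, cds)
    counts: dict[int, int] = {}
    for rec in found:
        counts[rec.u_class] = counts.get(rec.u_class, 0) + 1
    return counts == {k: v for k, v in expected.items() if v}


def _build_gene(rng: np.random.Generator, plan: GenePlan, config: FixtureConfig,
                params: complexity.RepeatParams,
                max_tries: int = 30) -> BuiltGene:
    gc = config.gc_target
    span_start = any(r.kind == "span_start" for r in plan.repeats)
    for _ in range(max_tries):
        # --- 5'-UTR with uORFs
        utr5, exp_uorfs = _build_utr5(rng, plan, gc, params)
        # --- CDS: ATG + stop-free interior + TAA
        interior = strip_frame_stops(
            _clean_background(rng, plan.cds_len - 6, gc, params), 0)
        cds = "ATG" + interior + "TAA"
        utr3 = _clean_background(rng, plan.utr3_len, gc, params)
        # --- plant repeats
        expected = {k: {"whole": 0, "utr5": 0, "atg_stop": 0, "utr3": 0}
                    for k in complexity.KINDS}
        if span_start:
            utr5 = utr5[:-len(_SPAN_START_TAIL)] + _SPAN_START_TAIL
            cds = _SPAN_START_HEAD + cds[len(_SPAN_START_HEAD):]
            cds = "ATG" + strip_frame_stops(cds[3:-3], 0) + "TAA"
            expected["di"]["whole"] += 1
        offsets = {"cds": 300, "utr3": 60}
        for planted in plan.repeats:
            if planted.kind == "span_start":
                continue
            block = (_inverted_block(rng, params)
                     if planted.kind == "inverted"
                     else _REPEAT_BLOCKS[planted.kind])
            region = planted.region
            off = offsets[region]
            offsets[region] = off + len(block) + 40
            if region == "cds":
                off = 3 * (off // 3)
                cds = _plant_in_segment(cds, block, off)
            else:
                utr3 = _plant_in_segment(utr3, block, off)
            expected[planted.kind]["whole"] += 1
            zone = "atg_stop" if region == "cds" else region
            expected[planted.kind][zone] += 1
        # re-sanitise CDS frame after planting (blocks contain no stops but
        # junctions might), protecting the terminal stop
        cds = "ATG" + strip_frame_stops(cds[3:-3], 0) + "TAA"
        if span_start:
            cds = _SPAN_START_HEAD + cds[len(_SPAN_START_HEAD):]
        # --- flanks and the engineered arm window
        best_arm = _best_arm_candidate(rng)
        island = GUARD + best_arm + GUARD
        arm_offset = -2500                      # arm start relative to ATG
        island_start_to_atg = 2500 + len(GUARD)  # island start offset upstream
        upstream_len = config.upstream_flank
        upstream = _sample(rng, upstream_len, gc)
        # the ATG sits at index upstream_len + utr5_len of the sense block
        pos = upstream_len + plan.utr5_len - island_start_to_atg
        upstream = _plant_in_segment(upstream, island, pos)
        downstream = _sample(rng, config.downstream_flank, gc)
        # --- verify closure for this gene before accepting it
        gene_seq = utr5 + cds + utr3
        if arm_design.ISCEI_SITE in gene_seq or arm_design.ISCEI_SITE in upstream:
            continue
        if not _verify_uorfs(utr5, cds, exp_uorfs):
            continue
        found = {k: {"whole": 0, "utr5": 0, "atg_stop": 0, "utr3": 0}
                 for k in complexity.KINDS}
        hits = (complexity.find_tandem_repeats(gene_seq, params)
                + [h for h in complexity.find_inverted_repeats(gene_seq, params)
                   if h.length >= params.inv_count_min_total])
        a, b = len(utr5), len(utr5) + len(cds)
        ok = True
        for h in hits:
            found[h.kind]["whole"] += 1
            if h.end <= a:
                found[h.kind]["utr5"] += 1
            elif a <= h.start and h.end <= b:
                found[h.kind]["atg_stop"] += 1
            elif h.start >= b:
                found[h.kind]["utr3"] += 1
        if found != expected:
            ok = False
        if ok:
            return BuiltGene(plan=plan, upstream=upstream, utr5=utr5, cds=cds,
                             utr3=utr3, downstream=downstream,
                             best_arm_seq=best_arm, best_arm_offset=arm_offset,
                             expected_counts=expected, expected_uorfs=exp_uorfs)
    raise FixtureError(f"could not build gene {plan.gene_id} "
                       f"satisfying its planted ground truth")


# ---------------------------------------------------------------------------
# genome / annotation / clones assembly

@dataclass
class Fixture:
    config: FixtureConfig
    genome: genome_io.GenomeSequences
    genes: list[genome_io.GeneModel]
    clones: list[clone_search.CloneRecord]
    vector: construct.VectorModel
    manifest: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fasta",
            "annotation": outdir / "genes.gff3",
            "clones": outdir / "clones.bed",
            "vector": outdir / "vector.gb",
            "manifest": outdir / "manifest.json",
        }
        genome_io.write_genome(self.genome, paths["genome"])
        _write_gff3(self.genes, paths["annotation"])
        with open(paths["clones"], "w") as fh:
            for c in self.clones:
                fh.write(f"{c.chromosome}\t{c.start}\t{c.end}\t{c.clone_id}\t{c.library}\n")
        construct.vector_to_genbank(self.vector, paths["vector"])
        checksums = {name: hashlib.sha256(p.read_bytes()).hexdigest()
                     for name, p in paths.items() if name != "manifest"}
        self.manifest["checksums"] = checksums
        with open(paths["manifest"], "w") as fh:
            json.dump(self.manifest, fh, indent=1, default=str)
        return paths


def _write_gff3(genes: list[genome_io.GeneModel], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.gene_span
            fh.write(f"{g.chromosome}\tsynth\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t."
                     f"\tID={g.gene_id}\n")
            tid = g.transcript_ids[0] if g.transcript_ids else f"{g.gene_id}.t1"
            fh.write(f"{g.chromosome}\tsynth\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t."
                     f"\tID={tid};Parent={g.gene_id}\n")
            for ftype, segs in (("five_prime_UTR", g.utr5_segments),
                                ("CDS", g.cds_segments),
                                ("three_prime_UTR", g.utr3_segments)):
                for a, b in segs:
                    phase = "0" if ftype == "CDS" else "."
                    fh.write(f"{g.chromosome}\tsynth\t{ftype}\t{a + 1}\t{b}\t.\t"
                             f"{g.strand}\t{phase}\tID={tid}.{ftype};Parent={tid}\n")


def build_vector(vector_id: str = "pLM099_synthetic", seed: int = 0,
                 cassette_len: int = 4600) -> construct.VectorModel:
    """A synthetic stand-in for the pLM099-family tagging vector.

    Same feature grammar as the real vector — linker + fluorophore + affinity
    tag + terminator + selection marker + ori + KanR inside the amplified
    cassette, ccdB outside it, one I-SceI site — with module contents
    sampled, not the deposited sequences.
    """
    rng = np.random.default_rng(seed)
    linker = "GGAGGCCTGGGCGGAAGCGGCGGACGC"    # GGLGGSGGR
    anneal_len = 24
    fluor = "ATG" + strip_frame_stops(_sample(rng, 714, 0.55), 0)
    tri_gly = "GGTGGAGGC"
    tag = strip_frame_stops(_sample(rng, 66, 0.55), 0)
    terminator = _sample(rng, 380, 0.55)
    marker = _sample(rng, 1000, 0.55)
    ori = _sample(rng, 600, 0.55)
    kanr = _sample(rng, 850, 0.55)
    fixed = (len(linker) + len(fluor) + len(tri_gly) + len(tag)
             + len(terminator) + len(marker) + len(ori) + len(kanr)
             + len(construct.ISCEI_SITE))
    pad_len = cassette_len - fixed
    if pad_len < 0:
        raise FixtureError("cassette_len too small for the module set")
    pad = _sample(rng, pad_len, 0.55)
    ccdb = strip_frame_stops(_sample(rng, 320, 0.55), 0)
    spacer1, spacer2 = _sample(rng, 60, 0.55), _sample(rng, 60, 0.55)

    parts = [("linker", linker), ("fluorophore", fluor), ("tri_gly", tri_gly),
             ("affinity_tag", tag), ("terminator", terminator),
             ("pad", pad), ("selection_marker", marker), ("ori", ori),
             ("iscei_site", construct.ISCEI_SITE), ("KanR", kanr)]
    seq = ""
    features: list[tuple[str, tuple[int, int], int]] = []
    for name, part in parts:
        start = len(seq)
        seq += part
        if name not in ("pad", "tri_gly"):
            features.append((name, (start, start + len(part)), 1))
    # reverse annealing site: the last anneal_len bases of the cassette
    core_end = cassette_len
    if len(seq) != core_end:
        raise FixtureError("vector layout error")
    features.append(("anneal_rev", (core_end - anneal_len, core_end), -1))
    features.append(("anneal_fwd", (0, anneal_len), 1))
    seq += spacer1 + ccdb + spacer2
    features.append(("ccdB", (core_end + len(spacer1),
                              core_end + len(spacer1) + len(ccdb)), 1))
    # scrub stray I-SceI occurrences outside the planted site
    planted = seq.find(construct.ISCEI_SITE)
    while True:
        pos = construct.find_isce1(seq, circular=True)
        extra = [p for p in pos if p != planted]
        if not extra:
            break
        p = extra[0]
        lst = list(seq)
        lst[(p + 9) % len(lst)] = "C"
        seq = "".join(lst)
    return construct.VectorModel(vector_id=vector_id, sequence=seq,
                                 features=features)


def generate_fixture(config: FixtureConfig | None = None,
                     plans: list[GenePlan] | None = None,
                     outdir: str | Path | None = None) -> Fixture:
    """Build the synthetic study dataset; optionally write it to ``outdir``."""
    config = config or FixtureConfig()
    plans = plans or default_gene_plans(config)
    if len(plans) != config.n_genes:
        raise FixtureError("plans must match n_genes")
    rng = np.random.default_rng(config.seed)
    params = complexity.RepeatParams()
    built: list[BuiltGene] = []
    for plan in plans:
        built.append(_build_gene(rng, plan, config, params))

    # --- place genes on chromosomes
    chrom_seqs: dict[str, list[str]] = {
        f"chr{i + 1}": [] for i in range(config.n_chromosomes)}
    chrom_pos = {c: 0 for c in chrom_seqs}
    genes: list[genome_io.GeneModel] = []
    clones: list[clone_search.CloneRecord] = []
    manifest_genes: dict[str, dict] = {}
    for i, bg in enumerate(built):
        chrom = f"chr{(i % config.n_chromosomes) + 1}"
        block = bg.sense_block if bg.plan.strand == "+" else revcomp(bg.sense_block)
        pad = _sample(rng, config.intergenic, config.gc_target)
        start = chrom_pos[chrom] + len(pad)
        chrom_seqs[chrom].extend([pad, block])
        chrom_pos[chrom] = start + len(block)
        up, u5, ncds, u3 = (len(bg.upstream), len(bg.utr5), len(bg.cds),
                            len(bg.utr3))
        if bg.plan.strand == "+":
            g5 = start + up
            utr5_iv = (g5, g5 + u5)
            cds_iv = (g5 + u5, g5 + u5 + ncds)
            utr3_iv = (g5 + u5 + ncds, g5 + u5 + ncds + u3)
            span = (utr5_iv[0], utr3_iv[1])
        else:
            end = start + len(block)
            g5 = end - up                     # sense 5' end in genomic coords
            utr5_iv = (g5 - u5, g5)
            cds_iv = (g5 - u5 - ncds, g5 - u5)
            utr3_iv = (g5 - u5 - ncds - u3, g5 - u5 - ncds)
            span = (utr3_iv[0], utr5_iv[1])
        model = genome_io.GeneModel(
            gene_id=bg.plan.gene_id, chromosome=chrom, strand=bg.plan.strand,
            gene_span=span, utr5_segments=[utr5_iv], cds_segments=[cds_iv],
            utr3_segments=[utr3_iv], transcript_ids=[f"{bg.plan.gene_id}.t1"])
        genes.append(model)
        # --- clones
        expected_clones: list[str] = []
        req = clone_search.required_interval(model, 3200)
        s0, e0 = max(0, req[0] - 50), req[1] + 200
        if bg.plan.covered:
            tiers = [(s0, e0, "a"), (s0 - 900, e0 + 900, "b"),
                     (s0 - 2200, e0 + 2200, "c")]
            for lo, hi, tag in tiers:
                cid = f"clone_{bg.plan.gene_id}_{tag}"
                clones.append(clone_search.CloneRecord(
                    cid, chrom, max(0, lo), hi, "BAC"))
                expected_clones.append(cid)
        elif bg.plan.utr3_terminating_clone:
            # ends 10 bp inside the 3'-UTR on the coding strand
            if bg.plan.strand == "+":
                iv = (max(0, s0), utr3_iv[1] - 10)
            else:
                iv = (utr3_iv[0] + 10, e0)
            clones.append(clone_search.CloneRecord(
                f"clone_{bg.plan.gene_id}_utr3", chrom, iv[0], iv[1], "BAC"))
        manifest_genes[bg.plan.gene_id] = {
            "strand": bg.plan.strand,
            "gene_span": list(span),
            "gene_length": span[1] - span[0],
            "repeat_counts": bg.expected_counts,
            "uorf_classes": {str(k): v for k, v in bg.expected_uorfs.items() if v},
            "covered": bg.plan.covered,
            "utr3_terminating_clone": bg.plan.utr3_terminating_clone,
            "expected_clones": expected_clones,
            "best_arm_sequence": bg.best_arm_seq,
            "best_arm_offset": bg.best_arm_offset,
        }
    for chrom in chrom_seqs:
        chrom_seqs[chrom].append(_sample(rng, 200, config.gc_target))
    genome = genome_io.GenomeSequences(
        {c: "".join(parts) for c, parts in chrom_seqs.items()})
    # clamp decoy clones to the assembled chromosome ends; the tight clone
    # never reaches past them, so planted coverage and ranking are unchanged
    lengths = genome.lengths
    clones = [clone_search.CloneRecord(c.clone_id, c.chromosome, c.start,
                                       min(c.end, lengths[c.chromosome]),
                                       c.library)
              for c in clones]
    # genome-wide guarantee used by construct validation
    for chrom, seq in genome.records.items():
        if construct.find_isce1(seq):
            raise FixtureError(f"I-SceI site leaked into {chrom}")
    vector = build_vector(seed=config.seed, cassette_len=config.cassette_len)
    n_covered = sum(1 for p in plans if p.covered)
    manifest = {
        "seed": config.seed,
        "n_genes": config.n_genes,
        "clone_coverage": n_covered / config.n_genes,
        "genes": manifest_genes,
    }
    fixture = Fixture(config=config, genome=genome, genes=genes,
                      clones=clones, vector=vector, manifest=manifest)
    self_check(fixture)
    if outdir is not None:
        fixture.write(outdir)
    return fixture


def self_check(fixture: Fixture) -> None:
    """Verify that every planted feature is re-detectable at default params.

    This is the generator's closure guarantee and the package's master
    integration check; it raises FixtureError on any mismatch.
    """
    params = complexity.RepeatParams()
    by_id = {g.gene_id: g for g in fixture.genes}
    for gid, info in fixture.manifest["genes"].items():
        gene = by_id[gid]
        regions = genome_io.extract_regions(gene, fixture.genome)
        prof = complexity.profile_gene(gene, regions, params)
        for kind in complexity.KINDS:
            exp = info["repeat_counts"][kind]
            got = {"whole": prof.whole_counts[kind],
                   "utr5": prof.utr5_counts[kind],
                   "atg_stop": prof.atg_stop_counts[kind],
                   "utr3": prof.utr3_counts[kind]}
            if got != exp:
                raise FixtureError(f"{gid}: {kind} counts {got} != planted {exp}")
        recs = uorf.find_uorfs(regions.utr5, genome_io.spliced_cds(gene, fixture.genome),
                               gene_id=gid)
        counts: dict[str, int] = {}
        for r in recs:
            counts[str(r.u_class)] = counts.get(str(r.u_class), 0) + 1
        if counts != info["uorf_classes"]:
            raise FixtureError(f"{gid}: uORFs {counts} != planted {info['uorf_classes']}")
        cov = clone_search.clones_covering(gene, 3000, fixture.clones)
        if cov.covered != info["covered"]:
            raise FixtureError(f"{gid}: coverage {cov.covered} != planted")
        if info["covered"] and cov.covering_clones != info["expected_clones"]:
            raise FixtureError(f"{gid}: clone ranking {cov.covering_clones} "
                               f"!= planted {info['expected_clones']}")
        if info["utr3_terminating_clone"]:
            relaxed = clone_search.clones_covering(gene, 3000, fixture.clones,
                                                   allow_utr3_termination=True)
            if cov.covered or not relaxed.covered_with_utr3_allowance:
                raise FixtureError(f"{gid}: 3'-UTR-terminating clone not honoured")
        arms = arm_design.design_5prime_arms(gene, fixture.genome)
        if arms[0].sequence != info["best_arm_sequence"]:
            raise FixtureError(f"{gid}: planted best arm does not rank first")
        if arms[0].offset_from_atg != info["best_arm_offset"]:
            raise FixtureError(f"{gid}: best arm offset {arms[0].offset_from_atg}")
    stats = clone_search.coverage_statistics(fixture.genes, fixture.clones,
                                             upstream_bp=3000)
    if abs(stats.fraction_covered - fixture.manifest["clone_coverage"]) > 1e-12:
        raise FixtureError("clone coverage fraction mismatch")
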