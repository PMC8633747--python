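"""Homology-arm and cloning/check-primer design for gene retrieval.

The 5' homology arm is a 50-bp window placed 2,000-3,000 bp upstream of the
annotated start codon on the coding strand, chosen to avoid local complexity
(homopolymer runs, dinucleotide tandems, extreme GC).  The 3' arm is the 50
genomic bases immediately upstream of the stop codon (stop excluded), so the
retrieved gene ends in frame with the cassette's linker-fluorophore fusion.
Cloning primers prepend these arms to the vector annealing sequences; check
primers are conventional PCR pairs for verifying a target's presence in a
clone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import GeneModel, GenomeSequences, revcomp, STOP_CODONS, gc_content
from .primer_qc import (PrimerThresholds, longest_dinucleotide_units,
                        longest_homopolymer_run, screen_pair)

ISCEI_SITE = "TAGGGATAACAGGGTAAT"


class ArmDesignError(ValueError):
    pass


@dataclass(frozen=True)
class ArmParams:
    arm_len: int = 50
    window_min: int = 2000        # bp upstream of the annotated ATG
    window_max: int = 3000
    max_homopolymer_run: int = 5
    max_dint_tandem_units: int = 4
    gc_bounds: tuple[float, float] = (0.40, 0.70)
    top_k: int = 5
    gc_target: float = 0.60       # scoring optimum
    offset_target: int = -2500    # preferred arm offset from the ATG

    def __post_init__(self) -> None:
        if self.window_min >= self.window_max:
            raise ValueError("window_min must be < window_max")
        if self.arm_len > self.window_max - self.window_min:
            raise ValueError("arm_len exceeds the window")


@dataclass(frozen=True)
class HomologyArm:
    gene_id: str
    side: str                     # 5prime | 3prime
    sequence: str                 # coding-strand sense
    genomic_interval: tuple[int, int]
    offset_from_atg: int          # 5' arms: arm start relative to ATG (negative)
    score: float = 0.0
    gc: float = 0.0
    longest_run: int = 0
    longest_dint: int = 0
    relaxed_filters: tuple[str, ...] = ()


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str
    reverse: str
    purpose: str                  # cloning | check | junction
    expected_amplicon_len: int
    anneal_len: int = 0


def _upstream_slice(gene: GeneModel, genome: GenomeSequences,
                    dist_near: int, dist_far: int) -> tuple[str, int]:
    """Coding-strand sequence from dist_far to dist_near bp upstream of the
    ATG; returns (sequence, genomic start of the slice)."""
    atg = gene.atg_position
    chrom_len = genome.lengths[gene.chromosome]
    if gene.strand == "+":
        lo, hi = atg - dist_far, atg - dist_near
        if lo < 0:
            raise ArmDesignError(
                f"{gene.gene_id}: only {atg} bp upstream available "
                f"(needs {dist_far}); feasible window 0-{atg} bp")
        return genome.slice(gene.chromosome, lo, hi), lo
    lo, hi = atg + 1 + dist_near, atg + 1 + dist_far
    if hi > chrom_len:
        avail = chrom_len - atg - 1
        raise ArmDesignError(
            f"{gene.gene_id}: only {avail} bp upstream available "
            f"(needs {dist_far}); feasible window 0-{avail} bp")
    return revcomp(genome.slice(gene.chromosome, lo, hi)), lo


def _arm_metrics(seq: str, params: ArmParams) -> tuple[float, int, int]:
    return gc_content(seq), longest_homopolymer_run(seq), longest_dinucleotide_units(seq)


def candidate_5prime_windows(gene: GeneModel, genome: GenomeSequences,
                             params: ArmParams | None = None) -> list[HomologyArm]:
    """All arm-length windows fully inside the upstream design window.

    Candidates containing N, or containing the I-SceI recognition site (which
    would be destroyed at cassette linearisation), are dropped.
    """
    params = params or ArmParams()
    window, genomic_lo = _upstream_slice(gene, genome,
                                         params.window_min, params.window_max)
    atg = gene.atg_position
    arms: list[HomologyArm] = []
    span = len(window) - params.arm_len + 1
    for i in range(span):
        seq = window[i:i + params.arm_len].upper()
        if "N" in seq:
            continue
        if ISCEI_SITE in seq or revcomp(ISCEI_SITE) in seq:
            continue
        # window string runs upstream->downstream in coding sense; index 0 is
        # window_max bp upstream of the ATG
        offset = -(params.window_max - i)
        if gene.strand == "+":
            interval = (atg + offset, atg + offset + params.arm_len)
        else:
            interval = (atg - offset - params.arm_len + 1, atg - offset + 1)
        gc, run, dint = _arm_metrics(seq, params)
        arms.append(HomologyArm(
            gene_id=gene.gene_id, side="5prime", sequence=seq,
            genomic_interval=interval, offset_from_atg=offset,
            gc=gc, longest_run=run, longest_dint=dint))
    if not arms:
        raise ArmDesignError(f"{gene.gene_id}: no N-free candidate arms in window")
    return arms


def _score(arm: HomologyArm, params: ArmParams) -> float:
    return (2.0 * abs(arm.gc - params.gc_target)
            + 0.1 * arm.longest_run + 0.1 * arm.longest_dint)


_RELAXATION_ORDER = ("gc_bounds", "max_dint_tandem_units", "max_homopolymer_run")


def rank_and_select(candidates: list[HomologyArm],
                    params: ArmParams | None = None) -> list[HomologyArm]:
    """Hard-filter then rank candidates; relax filters only if too few survive.

    Ranking is by ascending complexity score, ties broken by proximity to the
    preferred upstream offset and then by ascending genomic coordinate.
    Filters relax in the order gc_bounds -> dinucleotide -> homopolymer; any
    relaxation is recorded on the returned arms.
    """
    params = params or ArmParams()
    if not candidates:
        raise ArmDesignError("no candidate arms supplied")

    def passes(arm: HomologyArm, relaxed: set[str]) -> bool:
        if "gc_bounds" not in relaxed and not (
                params.gc_bounds[0] <= arm.gc <= params.gc_bounds[1]):
            return False
        if ("max_dint_tandem_units" not in relaxed
                and arm.longest_dint > params.max_dint_tandem_units):
            return False
        if ("max_homopolymer_run" not in relaxed
                and arm.longest_run > params.max_homopolymer_run):
            return False
        return True

    relaxed: set[str] = set()
    for step in (None,) + _RELAXATION_ORDER:
        if step is not None:
            relaxed.add(step)
        survivors = [a for a in candidates if passes(a, relaxed)]
        if len(survivors) >= min(params.top_k, len(candidates)) and survivors:
            break
    if not survivors:
        raise ArmDesignError(
            "no usable homology arm even after relaxing all filters; "
            "consider a fosmid or an alternative window")
    flag = tuple(sorted(relaxed))
    ranked = sorted(survivors, key=lambda a: (
        _score(a, params),
        abs(a.offset_from_atg - params.offset_target),
        a.genomic_interval[0]))
    out = []
    for arm in ranked[:params.top_k]:
        out.append(HomologyArm(**{**arm.__dict__, "score": _score(arm, params),
                                  "relaxed_filters": flag}))
    return out


def design_5prime_arms(gene: GeneModel, genome: GenomeSequences,
                       params: ArmParams | None = None) -> list[HomologyArm]:
    params = params or ArmParams()
    return rank_and_select(candidate_5prime_windows(gene, genome, params), params)


def utr5_override_arm(gene: GeneModel, genome: GenomeSequences,
                      params: ArmParams | None = None) -> HomologyArm:
    """Fallback when clone coverage forbids the upstream window: the first
    arm_len bases of the 5'-UTR serve as the 5' homology region."""
    params = params or ArmParams()
    if not gene.has_utr5:
        raise ArmDesignError(f"{gene.gene_id}: no annotated 5'-UTR for override arm")
    gs, ge = gene.gene_span
    if gene.strand == "+":
        interval = (gs, gs + params.arm_len)
        seq = genome.slice(gene.chromosome, *interval)
    else:
        interval = (ge - params.arm_len, ge)
        seq = revcomp(genome.slice(gene.chromosome, *interval))
    atg = gene.atg_position
    offset = interval[0] - atg if gene.strand == "+" else atg - interval[1] + 1
    gc, run, dint = _arm_metrics(seq.upper(), params)
    return HomologyArm(gene_id=gene.gene_id, side="5prime", sequence=seq.upper(),
                       genomic_interval=interval, offset_from_atg=offset,
                       gc=gc, longest_run=run, longest_dint=dint,
                       relaxed_filters=("utr5_override",))


def three_prime_arm(gene: GeneModel, genome: GenomeSequences,
                    params: ArmParams | None = None) -> HomologyArm:
    """The arm_len genomic bases immediately 5' of the stop codon.

    Homology is to the clone (genomic DNA), so introns within the region are
    retained.  The annotated stop codon is verified before design.
    """
    params = params or ArmParams()
    stop_s, stop_e = gene.stop_span
    stop = genome.slice(gene.chromosome, stop_s, stop_e)
    if gene.strand == "-":
        stop = revcomp(stop)
    if stop.upper() not in STOP_CODONS:
        raise ArmDesignError(
            f"{gene.gene_id}: no stop codon at annotated position "
            f"(found {stop.upper()!r}; possible annotation drift)")
    if gene.strand == "+":
        interval = (stop_s - params.arm_len, stop_s)
        seq = genome.slice(gene.chromosome, *interval)
    else:
        interval = (stop_e, stop_e + params.arm_len)
        seq = revcomp(genome.slice(gene.chromosome, *interval))
    cs, ce = gene.cds_span
    if ce - cs - 3 < params.arm_len:
        raise ArmDesignError(f"{gene.gene_id}: ATG-Stop region shorter than arm")
    seq = seq.upper()
    gc, run, dint = _arm_metrics(seq, params)
    return HomologyArm(gene_id=gene.gene_id, side="3prime", sequence=seq,
                       genomic_interval=interval, offset_from_atg=0,
                       gc=gc, longest_run=run, longest_dint=dint)


def build_cloning_primers(arm5: HomologyArm, arm3: HomologyArm,
                          vector) -> PrimerPair:
    """Assemble cassette-amplification primers against a vector model.

    forward = 5' arm + forward annealing sequence; reverse = revcomp(3' arm)
    + reverse annealing sequence, so the amplified cassette carries the 3'
    homology at its downstream junction.  Expected amplicon length is the
    cassette plus both arms.
    """
    fwd_anneal = vector.forward_anneal
    rev_anneal = vector.reverse_anneal
    forward = arm5.sequence + fwd_anneal
    reverse = revcomp(arm3.sequence) + rev_anneal
    return PrimerPair(
        name=f"{arm5.gene_id}_cloning_{vector.vector_id}",
        forward=forward, reverse=reverse, purpose="cloning",
        expected_amplicon_len=vector.cassette_length + 2 * len(arm5.sequence),
        anneal_len=len(fwd_anneal))


@dataclass
class CheckPrimerDesign:
    pairs: list[PrimerPair] = field(default_factory=list)
    unprimable_regions: list[str] = field(default_factory=list)


def _design_pair_in_region(template: str, name: str,
                           thresholds: PrimerThresholds,
                           amplicon_bounds: tuple[int, int] = (200, 800),
                           primer_len: int = 22) -> PrimerPair | None:
    """First QC-clean primer pair on the template with an in-bounds amplicon.

    Deterministic: forward starts scan from the template 5' end, reverse from
    the far end of the smallest allowed amplicon.
    """
    lo, hi = amplicon_bounds
    n = len(template)
    if n < lo:
        return None
    for f_start in range(0, min(60, n - lo)):
        fwd = template[f_start:f_start + primer_len]
        if len(fwd) < primer_len or "N" in fwd:
            continue
        amp_hi = min(hi, n - f_start)
        if amp_hi < lo:
            break
        for amp in range(lo, amp_hi + 1, 25):
            r_end = f_start + amp
            rev = revcomp(template[r_end - primer_len:r_end])
            if "N" in rev:
                continue
            verdict = screen_pair(fwd, rev, thresholds)
            if not verdict.pair_breach:
                return PrimerPair(name=name, forward=fwd, reverse=rev,
                                  purpose="check", expected_amplicon_len=amp,
                                  anneal_len=primer_len)
    return None


def design_check_primers(gene: GeneModel, genome: GenomeSequences,
                         n_pairs: int = 4,
                         params: ArmParams | None = None,
                         thresholds: PrimerThresholds | None = None,
                         ) -> CheckPrimerDesign:
    """Up to four check-primer pairs: two near the gene 5' end (upstream
    window and first-exon region), two near the 3' end."""
    params = params or ArmParams()
    th = thresholds or PrimerThresholds()
    result = CheckPrimerDesign()
    if n_pairs <= 0:
        return result
    atg = gene.atg_position
    cs, ce = gene.cds_span
    gs, ge = gene.gene_span
    chrom_len = genome.lengths[gene.chromosome]

    def sense(lo: int, hi: int) -> str:
        lo, hi = max(0, lo), min(chrom_len, hi)
        seq = genome.slice(gene.chromosome, lo, hi)
        return seq if gene.strand == "+" else revcomp(seq)

    if gene.strand == "+":
        regions = [
            ("upstream_window", sense(atg - params.window_max, atg - params.window_min)),
            ("five_prime_gene", sense(atg, min(atg + 1000, ce))),
            ("three_prime_gene", sense(max(cs, ce - 1000), ce)),
            ("three_prime_flank", sense(ce - 500, min(ge + 500, chrom_len))),
        ]
    else:
        regions = [
            ("upstream_window", sense(atg + params.window_min, atg + params.window_max)),
            ("five_prime_gene", sense(max(cs, atg - 1000), atg + 1)),
            ("three_prime_gene", sense(cs, min(cs + 1000, ce))),
            ("three_prime_flank", sense(max(gs - 500, 0), cs + 500)),
        ]
    for label, template in regions[:n_pairs]:
        pair = _design_pair_in_region(template, f"{gene.gene_id}_check_{label}", th)
        if pair is None:
            result.unprimable_regions.append(label)
        else:
            result.pairs.append(pair)
    return result
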