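"""Tagging-vector models and in-silico validation of recombineered products.

A vector is a circular plasmid carrying the tagging cassette (fluorophore
preceded by a flexible linker, affinity tag, terminator, selection markers,
p15A ori, KanR) plus the ccdB counter-selection gene and a unique I-SceI
linearisation site.  Cassette PCR amplifies the circular path between the
two primer annealing sites that excludes ccdB; recombination then joins the
retrieved genomic region to the cassette through the two 50-bp homology
arms, giving a circular product whose frame across the 3' junction fuses the
target's last codon to the linker-fluorophore reading frame.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .genome_io import revcomp

ISCEI_SITE = "TAGGGATAACAGGGTAAT"  # canonical 18-bp recognition sequence

#: canonical feature roles a tagging vector must annotate
REQUIRED_FEATURES = ("fluorophore", "linker", "affinity_tag", "terminator",
                     "selection_marker", "ori", "KanR", "ccdB",
                     "iscei_site", "anneal_fwd", "anneal_rev")

#: label aliases seen on real vector records, mapped to canonical roles
FEATURE_ALIASES = {
    "crvenus": "fluorophore", "venus": "fluorophore", "mneongreen": "fluorophore",
    "mscarlet-i": "fluorophore", "mturquoise2": "fluorophore",
    "3xflag": "affinity_tag", "3xha": "affinity_tag",
    "psad terminator": "terminator", "psad 3'utr": "terminator",
    "aphviii": "selection_marker", "aphvii": "selection_marker",
    "ble": "selection_marker", "sh ble": "selection_marker",
    "p15a": "ori", "p15a ori": "ori",
    "kanr": "KanR", "kan": "KanR",
    "ccdb": "ccdB",
    "i-scei": "iscei_site", "i-scei site": "iscei_site",
    "iscei_site": "iscei_site",
    "anneal_fwd": "anneal_fwd", "anneal_rev": "anneal_rev",
    "linker": "linker", "flexible linker": "linker",
}
# canonical role names map to themselves
FEATURE_ALIASES.update({r.lower(): r for r in REQUIRED_FEATURES})

# common 6-bp cutters for diagnostic digest suggestions
DEFAULT_ENZYMES = {
    "EcoRI": "GAATTC", "BamHI": "GGATCC", "HindIII": "AAGCTT",
    "XhoI": "CTCGAG", "KpnI": "GGTACC", "NdeI": "CATATG",
    "PstI": "CTGCAG", "SpeI": "ACTAGT", "NcoI": "CCATGG", "SacI": "GAGCTC",
}


class ConstructError(ValueError):
    pass


def _find_all(haystack: str, needle: str) -> list[int]:
    return [m.start() for m in re.finditer(f"(?={re.escape(needle)})", haystack)]


def find_isce1(seq: str, circular: bool = False) -> list[int]:
    """Top-strand start positions of the I-SceI site on either strand."""
    seq = seq.upper()
    search = seq + seq[:len(ISCEI_SITE) - 1] if circular else seq
    positions = set(_find_all(search, ISCEI_SITE))
    positions |= set(_find_all(search, revcomp(ISCEI_SITE)))
    return sorted(p % len(seq) if circular else p for p in positions)


@dataclass
class VectorModel:
    """A circular tagging vector with named, role-mapped features."""

    vector_id: str
    sequence: str
    features: list[tuple[str, tuple[int, int], int]]  # (role, interval, strand)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        roles = {name for name, _, _ in self.features}
        missing = [r for r in REQUIRED_FEATURES if r not in roles]
        if missing:
            raise ConstructError(f"{self.vector_id}: missing features {missing}")
        sites = find_isce1(self.sequence, circular=True)
        if len(sites) != 1:
            raise ConstructError(
                f"{self.vector_id}: expected exactly one I-SceI site, found {len(sites)}")
        for role in ("anneal_fwd", "anneal_rev"):
            s, e = self.feature_interval(role)
            top = self.sequence[s:e]
            # a unique site occurs exactly once per copy of the doubled circle
            if len(_find_all(self.sequence + self.sequence, top)) != 2:
                raise ConstructError(f"{self.vector_id}: {role} not unique on vector")
        ccdb = self.feature_interval("ccdB")
        lo, hi = self.cassette_span
        if self._in_cassette(ccdb, lo, hi):
            raise ConstructError(f"{self.vector_id}: ccdB inside the amplified cassette")

    def feature_interval(self, role: str) -> tuple[int, int]:
        for name, interval, _ in self.features:
            if name == role:
                return interval
        raise KeyError(role)

    def feature_strand(self, role: str) -> int:
        for name, _, strand in self.features:
            if name == role:
                return strand
        raise KeyError(role)

    def feature_seq(self, role: str) -> str:
        s, e = self.feature_interval(role)
        seq = self.sequence[s:e]
        return revcomp(seq) if self.feature_strand(role) == -1 else seq

    @property
    def forward_anneal(self) -> str:
        """Forward cloning-primer annealing sequence (primer sense)."""
        return self.feature_seq("anneal_fwd")

    @property
    def reverse_anneal(self) -> str:
        """Reverse cloning-primer annealing sequence (primer sense)."""
        return self.feature_seq("anneal_rev")

    @property
    def cassette_span(self) -> tuple[int, int]:
        """(start, end) of the amplified path on the circle; may wrap."""
        return self.feature_interval("anneal_fwd")[0], self.feature_interval("anneal_rev")[1]

    def _in_cassette(self, interval: tuple[int, int], lo: int, hi: int) -> bool:
        # any overlap with the amplified circular path counts as inside
        n = len(self.sequence)
        span = (hi - lo) % n or n
        off_s = (interval[0] - lo) % n
        length = interval[1] - interval[0]
        entirely_in_gap = off_s >= span and off_s + length <= n
        return not entirely_in_gap

    @property
    def cassette_core(self) -> str:
        """Top-strand amplified path between the annealing-site boundaries."""
        lo, hi = self.cassette_span
        if hi > lo:
            return self.sequence[lo:hi]
        return self.sequence[lo:] + self.sequence[:hi]

    @property
    def cassette_length(self) -> int:
        return len(self.cassette_core)


def load_vector(path: str | Path, vector_id: str | None = None) -> VectorModel:
    """Load a GenBank vector record, mapping feature labels to roles."""
    rec = SeqIO.read(str(path), "genbank")
    features: list[tuple[str, tuple[int, int], int]] = []
    for feat in rec.features:
        label = (feat.qualifiers.get("label") or feat.qualifiers.get("gene")
                 or feat.qualifiers.get("product") or [feat.type])[0]
        role = FEATURE_ALIASES.get(label.strip().lower())
        if role is None:
            continue
        features.append((role, (int(feat.location.start), int(feat.location.end)),
                         feat.location.strand or 1))
    return VectorModel(vector_id=vector_id or rec.id or rec.name,
                       sequence=str(rec.seq), features=features)


def simulate_cassette_pcr(vector: VectorModel, primers) -> str:
    """PCR product of the cassette primers on the circular vector.

    product = 5' arm + amplified path + 3' arm (coding sense); the product
    must exclude ccdB and carry exactly one I-SceI site.
    """
    fwd_anneal = vector.forward_anneal
    rev_anneal = vector.reverse_anneal
    if not primers.forward.upper().endswith(fwd_anneal.upper()):
        raise ConstructError("forward primer does not end with the vector "
                             "forward annealing sequence")
    if not primers.reverse.upper().endswith(rev_anneal.upper()):
        raise ConstructError("reverse primer does not end with the vector "
                             "reverse annealing sequence")
    arm5 = primers.forward.upper()[:-len(fwd_anneal)]
    arm3 = revcomp(primers.reverse.upper()[:-len(rev_anneal)])
    core = vector.cassette_core
    product = arm5 + core + arm3
    ccdb_seq = vector.feature_seq("ccdB")
    if ccdb_seq and (ccdb_seq in product or revcomp(ccdb_seq) in product):
        raise ConstructError("amplified cassette contains ccdB")
    if len(find_isce1(product)) != 1:
        raise ConstructError("cassette must carry exactly one I-SceI site")
    return product


@dataclass
class ConstructModel:
    """Simulated circular recombineering product."""

    sequence: str
    features: list[tuple[str, tuple[int, int], int]] = field(default_factory=list)
    junctions: list[tuple[int, str]] = field(default_factory=list)
    fusion_frame_ok: bool = True

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def isce1_positions(self) -> list[int]:
        return find_isce1(self.sequence, circular=True)


def _junction_context(seq: str, pos: int, width: int = 60) -> str:
    n = len(seq)
    half = width // 2
    idx = [(pos - half + i) % n for i in range(width)]
    return "".join(seq[i] for i in idx)


def assemble_product(gene_region: str, arm5, arm3, cassette: str,
                     cds_len_before_stop: int | None = None) -> ConstructModel:
    """Join the retrieved genomic region to the cassette at both arms.

    ``gene_region`` must span the 5' arm through the base before the stop
    codon; each arm must occur exactly once in it (recombination would be
    ambiguous otherwise).  ``cds_len_before_stop`` is the spliced coding
    length from the ATG through the 3' arm end; the fusion frame is intact
    when it is a multiple of 3.
    """
    region = gene_region.upper()
    a5, a3 = arm5.sequence.upper(), arm3.sequence.upper()
    n5 = _find_all(region, a5)
    n3 = _find_all(region, a3)
    if len(n5) != 1:
        raise ConstructError(f"5' arm found {len(n5)} times in gene region")
    if len(n3) != 1:
        raise ConstructError(f"3' arm found {len(n3)} times in gene region")
    retrieved = region[n5[0]:n3[0] + len(a3)]
    if not (cassette.upper().startswith(a5) and cassette.upper().endswith(a3)):
        raise ConstructError("cassette does not terminate in the homology arms")
    core = cassette.upper()[len(a5):-len(a3)]
    circular = retrieved + core
    junction_3 = len(retrieved)            # retrieved | cassette seam
    junction_5 = 0                         # cassette wrap | retrieved seam
    frame_ok = (cds_len_before_stop % 3 == 0
                if cds_len_before_stop is not None else True)
    features = [("retrieved_region", (0, len(retrieved)), 1),
                ("arm5", (0, len(a5)), 1),
                ("arm3", (len(retrieved) - len(a3), len(retrieved)), 1),
                ("cassette_core", (len(retrieved), len(circular)), 1)]
    return ConstructModel(
        sequence=circular, features=features,
        junctions=[(junction_5, _junction_context(circular, junction_5)),
                   (junction_3, _junction_context(circular, junction_3))],
        fusion_frame_ok=frame_ok)


@dataclass
class DigestResult:
    enzyme: str
    cut: bool
    fragments: list[int]


def digest_fragments(length: int, site_positions: list[int],
                     enzyme: str = "") -> DigestResult:
    """Fragment lengths of a circular molecule cut at the given positions."""
    if not site_positions:
        return DigestResult(enzyme=enzyme, cut=False, fragments=[length])
    pos = sorted(p % length for p in set(site_positions))
    frags = [pos[i + 1] - pos[i] for i in range(len(pos) - 1)]
    frags.append(length - pos[-1] + pos[0])
    return DigestResult(enzyme=enzyme, cut=True, fragments=sorted(frags))


def enzyme_sites(seq: str, recognition: str, circular: bool = True) -> list[int]:
    """Occurrences of a recognition sequence on both strands of a circle.

    Palindromic sites are counted once per occurrence (both strands collapse
    onto the same position).
    """
    seq = seq.upper()
    recognition = recognition.upper()
    n = len(seq)
    search = seq + seq[:len(recognition) - 1] if circular else seq
    hits = set(_find_all(search, recognition))
    rc = revcomp(recognition)
    if rc != recognition:
        hits |= set(_find_all(search, rc))
    return sorted(h % n if circular else h for h in hits)


def suggest_diagnostic_enzymes(construct: ConstructModel,
                               enzyme_table: dict[str, str] | None = None,
                               max_cuts: int = 3) -> list[dict]:
    """Rank enzymes cutting 1..max_cuts times by fragment distinguishability.

    Distinguishability is the minimum pairwise fragment-length difference
    (larger is better on a gel); single-fragment digests score the full
    construct length.  Ties break alphabetically.
    """
    if enzyme_table is not None and not enzyme_table:
        raise ConstructError("empty enzyme table")
    table = enzyme_table or DEFAULT_ENZYMES
    rows = []
    for name, site in sorted(table.items()):
        positions = enzyme_sites(construct.sequence, site, circular=True)
        if not 1 <= len(positions) <= max_cuts:
            continue
        digest = digest_fragments(construct.length, positions, enzyme=name)
        frags = digest.fragments
        if len(frags) == 1:
            min_diff = construct.length
        else:
            min_diff = min(abs(a - b) for i, a in enumerate(frags)
                           for b in frags[i + 1:])
        rows.append({"enzyme": name, "n_cuts": len(positions),
                     "fragments": frags, "min_pairwise_diff": min_diff})
    rows.sort(key=lambda r: (-r["min_pairwise_diff"], r["enzyme"]))
    return rows


def construct_to_genbank(construct: ConstructModel, path: str | Path,
                         name: str = "recombineered") -> None:
    """Write the construct with its features for visualisation."""
    rec = SeqRecord(Seq(construct.sequence), id=name[:16], name=name[:16],
                    description="simulated recombineering product",
                    annotations={"molecule_type": "DNA", "topology": "circular"})
    for role, (s, e), strand in construct.features:
        rec.features.append(SeqFeature(FeatureLocation(s, e, strand),
                                       type="misc_feature",
                                       qualifiers={"label": [role]}))
    SeqIO.write(rec, str(path), "genbank")


def vector_to_genbank(vector: VectorModel, path: str | Path) -> None:
    rec = SeqRecord(Seq(vector.sequence), id=vector.vector_id[:16],
                    name=vector.vector_id[:16],
                    description="tagging vector",
                    annotations={"molecule_type": "DNA", "topology": "circular"})
    for role, (s, e), strand in vector.features:
        rec.features.append(SeqFeature(FeatureLocation(s, e, strand),
                                       type="misc_feature",
                                       qualifiers={"label": [role]}))
    SeqIO.write(rec, str(path), "genbank")
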