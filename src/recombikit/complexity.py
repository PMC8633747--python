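"""Tandem and inverted repeat detection and per-gene complexity profiling.

Definitions
-----------
A *tandem repeat* of period ``p`` over a region ``[s, e)`` is scored against a
perfect tiling of a consensus unit: for each phase ``r`` (position mod ``p``)
the consensus base is the majority base among the region's positions in that
phase (ties broken alphabetically), and identity is the fraction of positions
matching the consensus tiling.  A region qualifies when identity >= 0.90 and
its length clears the class cutoff: 10 bp for mononucleotide repeats, 20 bp
for di-/trinucleotide and longer-unit (tetra+) repeats; at least two full
units are always required.  Reported hits are containment-maximal, hits of
the same period that overlap are merged, and a hit whose interval is covered
by a hit of a smaller period dividing its own is suppressed as a harmonic
(so a dinucleotide run is not additionally reported with period 4, 6, ...).

An *inverted repeat* is a stem-spacer-stem structure: a stem of >= 10 bp
followed within <= 10 bp by its reverse complement, allowing at most one
mismatch per 10 bp of stem and requiring >= 90% stem identity, with a total
structure length <= 210 bp.  The outermost and innermost base pairs of a
stem must match (a mismatched terminal pair is not part of the stem).
Reported structures are containment-maximal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import GeneModel, RegionSet, gc_content

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G, N->N'

KINDS = ("mono", "di", "tri", "tetra_plus", "inverted")


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


@dataclass(frozen=True)
class RepeatParams:
    """Detection thresholds for tandem and inverted repeats.

    The tandem cutoffs mirror the reporting convention of excluding
    mononucleotide repeats under 10 bp and di-/trinucleotide regions under
    20 bp while keeping regions with >= 90% identity.  ``max_period`` and
    ``max_region`` bound the native tandem detector's search space.
    """

    min_mono_len: int = 10
    min_ditri_len: int = 20
    min_tetraplus_len: int = 20
    min_identity: float = 0.90
    max_period: int = 8
    max_region: int = 500
    inv_min_stem: int = 10
    inv_max_spacer: int = 10
    inv_max_total: int = 210
    inv_max_mismatch_per_stem10: int = 1
    inv_count_min_total: int = 20

    def __post_init__(self) -> None:
        for name in ("min_mono_len", "min_ditri_len", "min_tetraplus_len",
                     "max_period", "max_region", "inv_min_stem",
                     "inv_max_total", "inv_count_min_total"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if self.inv_max_spacer < 0 or self.inv_max_mismatch_per_stem10 < 0:
            raise ValueError("inverted-repeat params must be non-negative")

    def min_len(self, period: int) -> int:
        if period == 1:
            return self.min_mono_len
        if period in (2, 3):
            return self.min_ditri_len
        return self.min_tetraplus_len


@dataclass(frozen=True)
class RepeatHit:
    """One detected repeat on the analysed string (0-based half-open)."""

    kind: str
    start: int
    end: int
    period: int
    identity: float
    spacer: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int) -> "RepeatHit":
        return replace(self, start=self.start + offset, end=self.end + offset)


def _kind_of_period(period: int) -> str:
    return {1: "mono", 2: "di", 3: "tri"}.get(period, "tetra_plus")


def _maximal_intervals(items: list[tuple[int, int, object]]) -> list[tuple[int, int, object]]:
    """Keep items whose [start, end) is not properly contained in another's."""
    if not items:
        return []
    items = sorted(items, key=lambda t: (t[0], -t[1]))
    out: list[tuple[int, int, object]] = []
    best_end = -1
    prev_start = None
    for s, e, payload in items:
        if e > best_end:
            out.append((s, e, payload))
            best_end = e
        prev_start = s
    # the sort guarantees: once kept, later equal intervals have e <= best_end
    _ = prev_start
    return out


def _qualifying_spans_for_period(codes: np.ndarray, period: int,
                                 params: RepeatParams,
                                 s_lo: int, s_hi: int) -> list[tuple[int, int, float]]:
    """All (s, M(s), identity) with M(s) the longest qualifying end for s.

    Only containment-maximal spans are returned.  ``codes`` is the full
    encoded sequence; candidate starts are restricted to [s_lo, s_hi).
    """
    n = len(codes)
    p = period
    lmin = max(params.min_len(p), 2 * p)
    if n < lmin:
        return []
    # prefix counts per (base, phase): shape (5, p, n+1)
    ps = np.zeros((5, p, n + 1), dtype=np.int32)
    idx = np.arange(n)
    phases = idx % p
    onehot = np.zeros((5, n), dtype=np.int32)
    onehot[codes, idx] = 1
    for r in range(p):
        mask = phases == r
        ps[:, r, 1:] = np.cumsum(onehot * mask, axis=1)
    spans: list[tuple[int, int, float]] = []
    best_end = -1
    lmax_global = min(params.max_region, n)
    for s in range(s_lo, min(s_hi, n - lmin + 1)):
        e_hi = min(s + lmax_global, n)
        if e_hi - s < lmin:
            break
        # counts for regions [s, e) for all e in (s+lmin-1, e_hi]
        window = ps[:, :, s + lmin: e_hi + 1] - ps[:, :, s][:, :, None]
        matches = window[:4].max(axis=0).sum(axis=0)  # N never consensus
        lengths = np.arange(lmin, e_hi - s + 1)
        ok = matches >= params.min_identity * lengths - 1e-9
        if not ok.any():
            continue
        j = int(np.flatnonzero(ok)[-1])
        e = s + lmin + j
        if e > best_end:
            ident = float(matches[j]) / (e - s)
            spans.append((s, e, ident))
            best_end = e
    return spans


def _match_islands(codes: np.ndarray, period: int,
                   params: RepeatParams) -> list[tuple[int, int]]:
    """Candidate start ranges that could host a qualifying region.

    Any qualifying region of period p and identity >= q has lag-p self-match
    density >= 1 - 4(1-q) over its first (len - p) positions, hence contains a
    sliding window of length (lmin - p) with at least half that density.
    Positions failing this cannot start or cover a hit; survivors are dilated
    by max_region so the exact scan misses nothing.
    """
    n = len(codes)
    p = period
    lmin = max(params.min_len(p), 2 * p)
    w0 = lmin - p
    dens = 1.0 - 4.0 * (1.0 - params.min_identity)
    if w0 <= 0 or dens <= 0:
        return [(0, n)]
    m = (codes[:-p] == codes[p:]) & (codes[:-p] != 4)
    if len(m) < w0:
        return []
    kern = np.convolve(m.astype(np.int32), np.ones(w0, dtype=np.int32), "valid")
    marked = np.flatnonzero(kern >= dens / 2.0 * w0 - 1e-9)
    if marked.size == 0:
        return []
    pad = params.max_region
    islands: list[tuple[int, int]] = []
    for i in marked:
        lo, hi = max(0, int(i) - pad), min(n, int(i) + pad)
        if islands and lo <= islands[-1][1]:
            islands[-1] = (islands[-1][0], hi)
        else:
            islands.append((lo, hi))
    return islands


def find_tandem_repeats(seq: str, params: RepeatParams | None = None) -> list[RepeatHit]:
    """Detect tandem repeats of period 1..max_period under the class cutoffs."""
    params = params or RepeatParams()
    if not seq:
        raise ValueError("empty sequence")
    codes = _encode(seq)
    n = len(codes)
    per_period: dict[int, list[tuple[int, int, float]]] = {}
    for p in range(1, params.max_period + 1):
        if n < max(params.min_len(p), 2 * p):
            continue
        spans: list[tuple[int, int, float]] = []
        for lo, hi in _match_islands(codes, p, params):
            spans.extend(_qualifying_spans_for_period(codes, p, params, lo, hi))
        if not spans:
            continue
        # containment-maximal, then merge overlapping same-period spans
        maximal = _maximal_intervals([(s, e, ident) for s, e, ident in spans])
        merged: list[tuple[int, int, float]] = []
        for s, e, ident in maximal:
            if merged and s < merged[-1][1]:
                ps_, pe_, pident = merged[-1]
                merged[-1] = (ps_, max(pe_, e), max(pident, ident))
            else:
                merged.append((s, e, ident))
        per_period[p] = merged
    hits: list[RepeatHit] = []
    for p, merged in sorted(per_period.items()):
        for s, e, ident in merged:
            # harmonic suppression: covered by a smaller period dividing p
            shadowed = any(
                p2 < p and p % p2 == 0 and any(s2 <= s and e2 >= e
                                               for s2, e2, _ in per_period.get(p2, []))
                for p2 in range(1, p))
            if not shadowed:
                hits.append(RepeatHit(_kind_of_period(p), s, e, p, ident))
    hits.sort(key=lambda h: (h.start, h.end, h.period))
    return hits


def find_inverted_repeats(seq: str, params: RepeatParams | None = None) -> list[RepeatHit]:
    """Detect stem-spacer-stem inverted repeats (hairpin/cruciform candidates)."""
    params = params or RepeatParams()
    codes = _encode(seq)
    n = len(codes)
    lmin = params.inv_min_stem
    if n < 2 * lmin:
        return []
    comp = _COMP_CODE[codes]
    candidates: list[tuple[int, int, tuple[int, int, float]]] = []
    # pairs (i, D - i) lie on anti-diagonal D = i + j; a structure with stem
    # start s, stem length L, spacer g spans [s, D + 1 - s) with D = 2(s+L)+g-1
    for d in range(2 * lmin - 1, 2 * n - 2):
        i_lo = max(0, d - n + 1)
        i_hi = (d - 1) // 2  # last i with i < d - i
        if i_hi - i_lo + 1 < lmin:
            continue
        ii = np.arange(i_lo, i_hi + 1)
        m = (codes[ii] == comp[d - ii]) & (codes[ii] != 4)
        pref = np.concatenate(([0], np.cumsum(m)))
        # a stem with <= k mismatches per 10 bp averages <= k mismatches per
        # 10-window, so some 10-window has >= 10-k matches; skip fast if none
        need = 10 - params.inv_max_mismatch_per_stem10
        if len(pref) > 10 and need > 0 and int((pref[10:] - pref[:-10]).max()) < need:
            continue
        for g in range(0, params.inv_max_spacer + 1):
            if (d + 1 - g) % 2:
                continue
            t = (d + 1 - g) // 2  # stem end (exclusive) in sequence coords
            lmax = min((params.inv_max_total - g) // 2, t - i_lo)
            if lmax < lmin:
                continue
            ss = np.arange(t - lmax, t - lmin + 1)
            ll = t - ss
            mm = ll - (pref[t - i_lo] - pref[ss - i_lo])
            allowed = (ll // 10) * params.inv_max_mismatch_per_stem10
            # stem terminal base pairs must match: a mismatched outermost or
            # innermost "pair" is not part of the stem
            ends_ok = m[ss - i_lo] & m[t - 1 - i_lo]
            ok = (mm <= allowed) & ((ll - mm) >= params.min_identity * ll - 1e-9) \
                & ends_ok
            for s, L, mmk in zip(ss[ok], ll[ok], mm[ok]):
                ident = float(L - mmk) / float(L)
                candidates.append((int(s), d + 1 - int(s), (int(L), g, ident)))
    # containment-maximal structures; for identical intervals keep longest stem
    best: dict[tuple[int, int], tuple[int, int, float]] = {}
    for s, e, payload in candidates:
        cur = best.get((s, e))
        if cur is None or (payload[0], payload[2]) > (cur[0], cur[2]):
            best[(s, e)] = payload
    maximal = _maximal_intervals([(s, e, best[(s, e)]) for s, e in best])
    hits = [RepeatHit("inverted", s, e, payload[0], payload[2], payload[1])
            for s, e, payload in maximal]
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


@dataclass
class ComplexityProfile:
    """Per-gene repeat counts and densities (whole gene and per subregion)."""

    gene_id: str
    gene_length: int
    gc: float
    whole_counts: dict[str, int]
    utr5_counts: dict[str, int]
    atg_stop_counts: dict[str, int]
    utr3_counts: dict[str, int]
    hits: list[RepeatHit] = field(default_factory=list)

    @property
    def density_per_kbp(self) -> dict[str, float]:
        kbp = self.gene_length / 1000.0
        return {k: v / kbp for k, v in self.whole_counts.items()}


def _countable(hit: RepeatHit, params: RepeatParams) -> bool:
    if hit.kind == "inverted":
        return hit.length >= params.inv_count_min_total
    return True


def _sense_boundaries(gene: GeneModel) -> tuple[int, int]:
    """(ATG offset, stop-end offset) in whole-gene mRNA-sense coordinates."""
    gs, ge = gene.gene_span
    cs, ce = gene.cds_span
    if gene.strand == "+":
        return cs - gs, ce - gs
    return ge - ce, ge - cs


def profile_gene(gene: GeneModel, regions: RegionSet,
                 params: RepeatParams | None = None) -> ComplexityProfile:
    """Count repeats on the whole unspliced gene and per subregion.

    Subregion counts include only hits fully contained in the 5'-UTR,
    ATG-Stop, or 3'-UTR span of the sense-oriented unspliced gene string;
    hits crossing the start or stop codon count at whole-gene level only.
    """
    params = params or RepeatParams()
    seq = regions.whole_gene
    hits = [h for h in find_tandem_repeats(seq, params) +
            find_inverted_repeats(seq, params) if _countable(h, params)]
    a, b = _sense_boundaries(gene)
    zones = {"utr5": (0, a), "atg_stop": (a, b), "utr3": (b, len(seq))}
    counts = {zone: {k: 0 for k in KINDS} for zone in zones}
    whole = {k: 0 for k in KINDS}
    for h in hits:
        whole[h.kind] += 1
        for zone, (zs, ze) in zones.items():
            if zs <= h.start and h.end <= ze:
                counts[zone][h.kind] += 1
    return ComplexityProfile(
        gene_id=gene.gene_id, gene_length=len(seq), gc=gc_content(seq),
        whole_counts=whole, utr5_counts=counts["utr5"],
        atg_stop_counts=counts["atg_stop"], utr3_counts=counts["utr3"],
        hits=hits)


DEFAULT_SIZE_BIN_EDGES_BP = tuple(range(0, 8001, 1000)) + (float("inf"),)


def dataset_summary(profiles: list[ComplexityProfile],
                    size_bin_edges: tuple = DEFAULT_SIZE_BIN_EDGES_BP,
                    ) -> dict[str, pd.DataFrame]:
    """Dataset-level complexity summary.

    Returns a per-kind table (genes with >= 1 hit, aggregate density =
    total hits / total kbp, per-gene mean density) plus a per-size-bin
    aggregation.  Aggregate density is the headline value; the per-gene mean
    is reported alongside because the two conventions differ.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    total_kbp = sum(p.gene_length for p in profiles) / 1000.0
    rows = []
    for kind in KINDS:
        n_with = sum(1 for p in profiles if p.whole_counts[kind] > 0)
        total = sum(p.whole_counts[kind] for p in profiles)
        rows.append({
            "kind": kind,
            "genes_with_hit": n_with,
            "fraction_genes_with_hit": n_with / len(profiles),
            "total_hits": total,
            "aggregate_density_per_kbp": total / total_kbp,
            "mean_per_gene_density_per_kbp": float(
                np.mean([p.density_per_kbp[kind] for p in profiles])),
        })
    n_mdt = sum(1 for p in profiles
                if any(p.whole_counts[k] > 0 for k in ("mono", "di", "tri")))
    tandem_total = sum(sum(p.whole_counts[k] for k in
                           ("mono", "di", "tri", "tetra_plus")) for p in profiles)
    per_kind = pd.DataFrame(rows)
    extras = pd.Series({
        "n_genes": len(profiles),
        "genes_with_mono_di_tri": n_mdt,
        "tandem_all_aggregate_density_per_kbp": tandem_total / total_kbp,
        "mean_gene_length_bp": float(np.mean([p.gene_length for p in profiles])),
        "mean_gc": float(np.nanmean([p.gc for p in profiles])),
    })
    lengths = pd.Series([p.gene_length for p in profiles])
    bins = pd.cut(lengths, bins=list(size_bin_edges), right=True, include_lowest=True)
    by_bin = pd.DataFrame({
        "size_bin": bins,
        "length": lengths,
        "tandem_hits": [sum(p.whole_counts[k] for k in
                            ("mono", "di", "tri", "tetra_plus")) for p in profiles],
        "inverted_hits": [p.whole_counts["inverted"] for p in profiles],
    }).groupby("size_bin", observed=False).agg(
        n_genes=("length", "size"),
        mean_length=("length", "mean"),
        tandem_hits=("tandem_hits", "sum"),
        inverted_hits=("inverted_hits", "sum"))
    return {"per_kind": per_kind, "totals": extras, "by_size_bin": by_bin}


def load_masked_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Load pre-masked global-repeat intervals (BED: chrom, start, end)."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split()[:3]
            out.setdefault(chrom, []).append((int(start), int(end)))
    for ivs in out.values():
        ivs.sort()
    return out


def masked_repeat_counts(genes: list[GeneModel],
                         masked: dict[str, list[tuple[int, int]]]) -> dict[str, int]:
    """Count masked intervals fully contained in each gene span."""
    counts: dict[str, int] = {}
    for gene in genes:
        gs, ge = gene.gene_span
        ivs = masked.get(gene.chromosome, [])
        counts[gene.gene_id] = sum(1 for s, e in ivs if gs <= s and e <= ge)
    return counts


def profiles_to_frame(profiles: list[ComplexityProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"gene_id": p.gene_id, "length": p.gene_length, "gc": p.gc}
        for kind in KINDS:
            row[f"{kind}_count"] = p.whole_counts[kind]
            row[f"{kind}_per_kbp"] = p.density_per_kbp[kind]
            row[f"{kind}_utr5"] = p.utr5_counts[kind]
            row[f"{kind}_atg_stop"] = p.atg_stop_counts[kind]
            row[f"{kind}_utr3"] = p.utr3_counts[kind]
        rows.append(row)
    return pd.DataFrame(rows)
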