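"""Independent brute-force oracles used to validate the repeat finders.

These enumerate every candidate region/structure explicitly, computing
identities from scratch with plain Python, and apply the same maximality,
merge and harmonic-suppression rules as the documented definitions.
"""

from __future__ import annotations

from collections import Counter

COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _consensus_matches(region: str, period: int) -> int:
    """Matches to the best perfect unit tiling (majority per phase,
    ties to the alphabetically first base; N never consensus)."""
    matches = 0
    for r in range(period):
        col = region[r::period]
        counts = Counter(b for b in col if b in "ACGT")
        if not counts:
            continue
        best = min(sorted(counts), key=lambda b: (-counts[b], b))
        matches += counts[best]
    return matches


def _containment_maximal(intervals):
    """Drop intervals properly contained in another; dedupe exact copies."""
    out = []
    for iv in intervals:
        if any(o != iv and o[0] <= iv[0] and o[1] >= iv[1] for o in intervals):
            continue
        if iv not in out:
            out.append(iv)
    return sorted(out)


def brute_tandem(seq: str, params) -> list[tuple[str, int, int, int, float]]:
    """(kind, start, end, period, identity) tuples, sorted like the finder."""
    seq = seq.upper()
    n = len(seq)
    per_period: dict[int, list[tuple[int, int, float]]] = {}
    for p in range(1, params.max_period + 1):
        lmin = max(params.min_len(p), 2 * p)
        qualifying: dict[tuple[int, int], float] = {}
        for s in range(n):
            for e in range(s + lmin, min(n, s + params.max_region) + 1):
                m = _consensus_matches(seq[s:e], p)
                if m >= params.min_identity * (e - s) - 1e-9:
                    qualifying[(s, e)] = m / (e - s)
        maximal = _containment_maximal(list(qualifying))
        merged: list[tuple[int, int, float]] = []
        for s, e in maximal:
            ident = qualifying[(s, e)]
            if merged and s < merged[-1][1]:
                ps, pe, pid = merged[-1]
                merged[-1] = (ps, max(pe, e), max(pid, ident))
            else:
                merged.append((s, e, ident))
        if merged:
            per_period[p] = merged
    hits = []
    kind_of = {1: "mono", 2: "di", 3: "tri"}
    for p, merged in sorted(per_period.items()):
        for s, e, ident in merged:
            shadowed = any(
                p2 < p and p % p2 == 0
                and any(s2 <= s and e2 >= e for s2, e2, _ in per_period.get(p2, []))
                for p2 in range(1, p))
            if not shadowed:
                hits.append((kind_of.get(p, "tetra_plus"), s, e, p, ident))
    return sorted(hits, key=lambda h: (h[1], h[2], h[3]))


def brute_inverted(seq: str, params) -> list[tuple[int, int, int, int, float]]:
    """(start, end, stem, spacer, identity) for containment-maximal
    stem-spacer-stem structures."""
    seq = seq.upper()
    n = len(seq)
    best_for_interval: dict[tuple[int, int], tuple[int, int, float]] = {}
    for s in range(n):
        for stem in range(params.inv_min_stem, (params.inv_max_total // 2) + 1):
            for g in range(params.inv_max_spacer + 1):
                total = 2 * stem + g
                if total > params.inv_max_total or s + total > n:
                    continue
                a = seq[s:s + stem]
                b = seq[s + stem + g:s + total]
                pairs = [a[k] == COMP.get(b[stem - 1 - k], "?") for k in range(stem)]
                if not (pairs[0] and pairs[-1]):
                    continue
                mm = stem - sum(pairs)
                if mm > (stem // 10) * params.inv_max_mismatch_per_stem10:
                    continue
                if (stem - mm) < params.min_identity * stem - 1e-9:
                    continue
                key = (s, s + total)
                cand = (stem, g, (stem - mm) / stem)
                cur = best_for_interval.get(key)
                if cur is None or (cand[0], cand[2]) > (cur[0], cur[2]):
                    best_for_interval[key] = cand
    maximal = _containment_maximal(list(best_for_interval))
    return sorted((s, e, *best_for_interval[(s, e)]) for s, e in maximal)
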