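"""Primer screening against four design thresholds, with NN thermodynamics.

The four rules: (1) length <= 30 nt; (2) the free energy needed to disrupt
predicted secondary structure (self-dimer, cross-dimer, hairpin) must be
above a floor of -9 kcal/mol at PCR-relevant annealing temperatures (66 and
72 C, worst case taken); (3) mono- or dinucleotide units may repeat at most
4 times in tandem; (4) the 3'-end may carry at most 4 consecutive G/C bases.

Duplex energies use the unified nearest-neighbor DNA parameter set
(SantaLucia-style dH/dS table) with no dangling-end terms; hairpins add a
loop-size penalty.  Structure energies are evaluated at the table's native
1 M monovalent reference: at 50 mM the -9 kcal/mol floor is unreachable at
66-72 C even for a full-length perfect duplex, which would leave the rule
inert, so the reference state preserves its discriminative intent.  The Tm
estimate (reporting only) applies a 50 mM salt correction.  These conditions
are a declared convention: the thresholds name a floor, not a parameter set,
and a fixed table keeps results reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .genome_io import revcomp

# Unified NN parameters (dH kcal/mol, dS cal/(mol*K)), 5'->3' top strand
# paired with its complement.
NN_TABLE: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
# equivalent stacks read from the complementary strand
for _pair, _val in list(NN_TABLE.items()):
    NN_TABLE.setdefault(revcomp(_pair), _val)

INITIATION = (0.2, -5.7)          # duplex initiation dH, dS
TERMINAL_AT_PENALTY = (2.2, 6.9)  # per terminal A-T pair
TM_SALT_MOLAR = 0.05              # monovalent salt used for the Tm estimate

# hairpin loop penalties, dG at 37 C treated as purely entropic
HAIRPIN_LOOP_DG37 = {3: 5.2, 4: 5.6, 5: 5.7, 6: 5.8, 7: 5.9, 8: 6.0,
                     9: 6.2, 10: 6.3, 11: 6.4, 12: 6.5}


@dataclass(frozen=True)
class PrimerThresholds:
    max_len: int = 30
    dg_floor: float = -9.0          # kcal/mol
    dg_temps: tuple[float, float] = (66.0, 72.0)   # Celsius
    max_unit_repeats: int = 4       # tandem mono-/dinucleotide units
    max_3prime_gc_run: int = 4
    end_window: int = 5             # 3' bases examined for duplex seeding
    hairpin_min_stem: int = 3
    hairpin_loop_range: tuple[int, int] = (3, 12)

    def __post_init__(self) -> None:
        if self.max_len <= 0:
            raise ValueError("max_len must be positive")
        if self.dg_floor >= 0:
            raise ValueError("dg_floor must be negative")


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"primer contains ambiguity codes: {sorted(bad)}")
    return seq


def _salt_corrected_ds(ds: float, n_pairs: int, salt_molar: float) -> float:
    return ds + 0.368 * n_pairs * math.log(salt_molar)


def duplex_dg(top: str, temperature_c: float) -> float:
    """dG (kcal/mol) of a fully matched duplex of ``top`` with its complement."""
    top = _check_sequence(top)
    if len(top) < 2:
        return 0.0
    dh, ds = INITIATION
    for i in range(len(top) - 1):
        h, s = NN_TABLE[top[i:i + 2]]
        dh += h
        ds += s
    for terminal in (top[0], top[-1]):
        if terminal in "AT":
            dh += TERMINAL_AT_PENALTY[0]
            ds += TERMINAL_AT_PENALTY[1]
    t_kelvin = temperature_c + 273.15
    return dh - t_kelvin * ds / 1000.0


def _complementary_runs(a: str, b_rc: str, offset: int) -> list[str]:
    """Matched stretches when ``a`` is aligned (ungapped, antiparallel)
    against primer ``b``; ``b_rc`` is revcomp(b) so matching is positional."""
    runs: list[str] = []
    current: list[str] = []
    lo = max(0, -offset)
    hi = min(len(a), len(b_rc) - offset)
    for i in range(lo, hi):
        if a[i] == b_rc[i + offset]:
            current.append(a[i])
        else:
            if len(current) >= 2:
                runs.append("".join(current))
            current = []
    if len(current) >= 2:
        runs.append("".join(current))
    return runs


def cross_dimer_dg(a: str, b: str, temperature_c: float) -> float:
    """Minimum duplex dG over all ungapped antiparallel alignments of a vs b.

    Each maximal complementary run forms its own duplex; the most stable
    single duplex over all offsets is reported (0.0 if nothing pairs).
    """
    a = _check_sequence(a)
    b = _check_sequence(b)
    b_rc = revcomp(b)
    best = 0.0
    for offset in range(-(len(a) - 2), len(b_rc) - 1):
        for run in _complementary_runs(a, b_rc, offset):
            best = min(best, duplex_dg(run, temperature_c))
    return best


def hairpin_dg(seq: str, temperature_c: float,
               min_stem: int = 3, loop_range: tuple[int, int] = (3, 12)) -> float:
    """Minimum hairpin dG: exhaustive perfect stems >= min_stem, loops 3-12 nt.

    dG = stem stacking (NN table, salt-corrected entropy, no bimolecular
    initiation) + an entropic loop-closure penalty from HAIRPIN_LOOP_DG37.
    """
    seq = _check_sequence(seq)
    n = len(seq)
    t_kelvin = temperature_c + 273.15
    best = 0.0
    lo, hi = loop_range
    for i in range(n):                       # stem 5' start
        for loop in range(lo, hi + 1):
            max_stem = (n - loop - i) // 2
            for stem in range(min_stem, max_stem + 1):
                j = i + 2 * stem + loop - 1  # stem 3' end
                if j >= n:
                    break
                top = seq[i:i + stem]
                bottom = seq[j - stem + 1:j + 1]
                if revcomp(bottom) != top:
                    continue
                dh = 0.0
                ds = 0.0
                for k in range(stem - 1):
                    h, s = NN_TABLE[top[k:k + 2]]
                    dh += h
                    ds += s
                ds += -HAIRPIN_LOOP_DG37[loop] / 310.15 * 1000.0
                best = min(best, dh - t_kelvin * ds / 1000.0)
    return best


def tm_estimate(seq: str, primer_conc: float = 5e-7) -> float:
    """NN melting temperature (reporting only), 50 mM salt, 500 nM primer."""
    seq = _check_sequence(seq)
    if len(seq) < 2:
        return float("nan")
    dh, ds = INITIATION
    for i in range(len(seq) - 1):
        h, s = NN_TABLE[seq[i:i + 2]]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        if terminal in "AT":
            dh += TERMINAL_AT_PENALTY[0]
            ds += TERMINAL_AT_PENALTY[1]
    ds = _salt_corrected_ds(ds, len(seq), TM_SALT_MOLAR)
    return dh * 1000.0 / (ds + 1.987 * math.log(primer_conc / 4.0)) - 273.15


def longest_homopolymer_run(seq: str) -> int:
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best if seq else 0


def longest_dinucleotide_units(seq: str) -> int:
    """Max tandem repeat count of any two-base unit with distinct bases."""
    best = 0
    n = len(seq)
    for i in range(n - 1):
        unit = seq[i:i + 2]
        if unit[0] == unit[1]:
            continue
        count = 1
        j = i + 2
        while j + 2 <= n and seq[j:j + 2] == unit:
            count += 1
            j += 2
        best = max(best, count)
    return best


def three_prime_gc_run(seq: str) -> int:
    run = 0
    for base in reversed(seq):
        if base in "GC":
            run += 1
        else:
            break
    return run


@dataclass
class PrimerReport:
    primer: str
    tm_estimate: float
    gc: float
    breaches: set[str] = field(default_factory=set)
    self_dimer_dg: float = 0.0
    hairpin_dg: float = 0.0

    @property
    def passed(self) -> bool:
        return not self.breaches


def screen_primer(seq: str, thresholds: PrimerThresholds | None = None) -> PrimerReport:
    """Evaluate all four rules; structure dG is the worst case at both temps."""
    th = thresholds or PrimerThresholds()
    seq = _check_sequence(seq)
    breaches: set[str] = set()
    if len(seq) > th.max_len:
        breaches.add("length")
    mono = longest_homopolymer_run(seq)
    dint = longest_dinucleotide_units(seq)
    if mono > th.max_unit_repeats or dint > th.max_unit_repeats:
        breaches.add("repeats")
    if three_prime_gc_run(seq) > th.max_3prime_gc_run:
        breaches.add("gc3")
    self_dg = min(cross_dimer_dg(seq, seq, t) for t in th.dg_temps)
    hp_dg = min(hairpin_dg(seq, t, th.hairpin_min_stem, th.hairpin_loop_range)
                for t in th.dg_temps)
    if min(self_dg, hp_dg) < th.dg_floor:
        breaches.add("structure")
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    return PrimerReport(primer=seq, tm_estimate=tm_estimate(seq), gc=gc,
                        breaches=breaches, self_dimer_dg=self_dg,
                        hairpin_dg=hp_dg)


@dataclass
class PairVerdict:
    fwd_report: PrimerReport
    rev_report: PrimerReport
    cross_dimer_dg: float
    pair_breach: bool
    category: str


_SEVERITY = ("cross_dimer", "self_dimer", "hairpin", "length", "repeats", "gc3")


def screen_pair(fwd: str, rev: str,
                thresholds: PrimerThresholds | None = None) -> PairVerdict:
    """Screen both primers and their cross-dimer; categorise the worst failure."""
    th = thresholds or PrimerThresholds()
    fr = screen_primer(fwd, th)
    rr = screen_primer(rev, th)
    cross = min(cross_dimer_dg(fwd.upper(), rev.upper(), t) for t in th.dg_temps)
    flags = {
        "cross_dimer": cross < th.dg_floor,
        "self_dimer": min(fr.self_dimer_dg, rr.self_dimer_dg) < th.dg_floor,
        "hairpin": min(fr.hairpin_dg, rr.hairpin_dg) < th.dg_floor,
        "length": "length" in fr.breaches | rr.breaches,
        "repeats": "repeats" in fr.breaches | rr.breaches,
        "gc3": "gc3" in fr.breaches | rr.breaches,
    }
    category = next((c for c in _SEVERITY if flags[c]), "clean")
    pair_breach = bool(fr.breaches or rr.breaches or flags["cross_dimer"])
    return PairVerdict(fwd_report=fr, rev_report=rr, cross_dimer_dg=cross,
                       pair_breach=pair_breach, category=category)


def dataset_primer_report(pairs: list[tuple[str, str]],
                          thresholds: PrimerThresholds | None = None,
                          ) -> dict[str, pd.DataFrame]:
    """Breach percentages per threshold for forward/reverse/pairs, GC by role,
    and a rejection-category tally."""
    th = thresholds or PrimerThresholds()
    if not pairs:
        return {"breach_percent": pd.DataFrame(),
                "gc": pd.DataFrame(), "categories": pd.DataFrame()}
    verdicts = [screen_pair(f, r, th) for f, r in pairs]
    rules = ("length", "structure", "repeats", "gc3")
    rows = []
    for rule in rules:
        fwd_b = sum(rule in v.fwd_report.breaches for v in verdicts)
        rev_b = sum(rule in v.rev_report.breaches for v in verdicts)
        pair_b = sum((rule in v.fwd_report.breaches)
                     or (rule in v.rev_report.breaches) for v in verdicts)
        n = len(verdicts)
        rows.append({"threshold": rule,
                     "forward_percent": 100.0 * fwd_b / n,
                     "reverse_percent": 100.0 * rev_b / n,
                     "pair_percent": 100.0 * pair_b / n})
    any_breach = sum(v.pair_breach for v in verdicts)
    rows.append({"threshold": "any",
                 "forward_percent": 100.0 * sum(bool(v.fwd_report.breaches)
                                                for v in verdicts) / len(verdicts),
                 "reverse_percent": 100.0 * sum(bool(v.rev_report.breaches)
                                                for v in verdicts) / len(verdicts),
                 "pair_percent": 100.0 * any_breach / len(verdicts)})
    gc = pd.DataFrame({
        "forward_gc": [v.fwd_report.gc for v in verdicts],
        "reverse_gc": [v.rev_report.gc for v in verdicts],
    })
    categories = pd.Series([v.category for v in verdicts]).value_counts()
    return {"breach_percent": pd.DataFrame(rows), "gc": gc,
            "categories": categories.rename_axis("category").reset_index(name="count")}
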