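"""Dataset-level statistics: Wilson intervals, clonability extrapolation,
and rank-sum group comparison.

The clonability extrapolation applies per-size-bin cloning success rates
observed on a tested gene panel to the genome-wide gene-size distribution,
yielding a predicted clonable fraction per bin (with Wilson 95% bands) and
genome wide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class BinnedOutcome:
    bin_label: str
    attempted: int
    succeeded: int

    def __post_init__(self) -> None:
        if not 0 <= self.succeeded <= self.attempted:
            raise ValueError(f"{self.bin_label}: succeeded must be in [0, attempted]")


def wilson_interval(k: int, n: int, z: float = 1.96) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion k/n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    phat = k / n
    denom = 1.0 + z * z / n
    centre = phat + z * z / (2 * n)
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n))
    lo = max(0.0, (centre - half) / denom)
    hi = min(1.0, (centre + half) / denom)
    return lo, hi


def extrapolate_clonability(success_bins: list[BinnedOutcome],
                            genome_size_distribution: dict[str, int],
                            z: float = 1.96) -> dict:
    """Apply per-bin success rates to a genome-wide size distribution.

    Bins with no attempts are excluded with a warning flag; genome bins with
    no matching success data are marked not-extrapolatable and omitted from
    the genome-wide fraction.
    """
    rates: dict[str, tuple[float, tuple[float, float]]] = {}
    skipped_bins: list[str] = []
    for b in success_bins:
        if b.attempted == 0:
            skipped_bins.append(b.bin_label)
            continue
        rates[b.bin_label] = (b.succeeded / b.attempted,
                              wilson_interval(b.succeeded, b.attempted, z))
    rows = []
    total_genes = 0
    total_clonable = 0.0
    not_extrapolatable = []
    for label, n_genes in genome_size_distribution.items():
        if label not in rates:
            not_extrapolatable.append(label)
            rows.append({"bin": label, "n_genes": n_genes, "rate": float("nan"),
                         "wilson_low": float("nan"), "wilson_high": float("nan"),
                         "predicted_clonable": float("nan"),
                         "extrapolatable": False})
            continue
        rate, (lo, hi) = rates[label]
        rows.append({"bin": label, "n_genes": n_genes, "rate": rate,
                     "wilson_low": lo, "wilson_high": hi,
                     "predicted_clonable": rate * n_genes,
                     "extrapolatable": True})
        total_genes += n_genes
        total_clonable += rate * n_genes
    genome_fraction = total_clonable / total_genes if total_genes else float("nan")
    return {
        "per_bin": pd.DataFrame(rows),
        "genome_clonable_fraction": genome_fraction,
        "genome_unclonable_fraction": (1.0 - genome_fraction
                                       if total_genes else float("nan")),
        "bins_without_attempts": skipped_bins,
        "not_extrapolatable": not_extrapolatable,
    }


def group_association(values_a, values_b) -> tuple[float, float]:
    """Mann-Whitney rank-sum comparison of two groups.

    Returns (U, p).  U convention: the number of (a, b) pairs with a < b
    plus half-ties, so U = 0 means every a exceeds every b.  The p-value is
    the two-tailed tie-corrected normal approximation.
    """
    a = list(values_a)
    b = list(values_b)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    # scipy's statistic counts pairs with a > b (plus half-ties)
    u_less = len(a) * len(b) - float(res.statistic)
    return u_less, float(res.pvalue)
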