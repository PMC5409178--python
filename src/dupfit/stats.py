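"""Exact small-count statistics for the chromosome-loss and localization
assays.

Fisher's exact test is computed by direct hypergeometric enumeration in log
space with the probability-mass two-sided rule (sum every table with the
observed margins whose probability does not exceed the observed table's).
Category fractions from manually scored cells get percentile-bootstrap
confidence intervals; pairwise strain comparisons use the same exact test
with Holm-Bonferroni adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SectoringTable",
    "LocalizationCounts",
    "fisher_exact_2x2",
    "sectoring_summary",
    "bootstrap_fraction_ci",
    "pairwise_fisher_corrected",
]


@dataclass(frozen=True)
class SectoringTable:
    """Sectored vs white colony counts for one genotype."""

    genotype: str
    sectored: int
    white: int

    def __post_init__(self) -> None:
        if self.sectored < 0 or self.white < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class LocalizationCounts:
    """Manually scored localization categories for one strain.

    Cells scored "both" contribute to both the nucleus and the puncta
    marginal fractions; discarded cells are excluded from every
    denominator.
    """

    strain: str
    nucleus_only: int
    puncta_only: int
    both: int
    discarded: int = 0

    def __post_init__(self) -> None:
        if min(self.nucleus_only, self.puncta_only, self.both, self.discarded) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def scored(self) -> int:
        return self.nucleus_only + self.puncta_only + self.both

    def in_category(self, category: str) -> int:
        if category == "nucleus":
            return self.nucleus_only + self.both
        if category == "puncta":
            return self.puncta_only + self.both
        if category == "both":
            return self.both
        raise ValueError("category must be 'nucleus', 'puncta' or 'both'")

    def fraction(self, category: str) -> float:
        if self.scored == 0:
            raise ValueError("no scored cells")
        return self.in_category(category) / self.scored


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Margins are held fixed and every table whose hypergeometric probability
    is at most the observed table's (within relative tolerance 1e-7) is
    summed; the computation runs in log space. The all-zero table returns
    p = 1 by convention.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be non-negative integers")
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1, col1 = a + b, a + c
    support = np.arange(max(0, col1 - (c + d)), min(col1, row1) + 1)
    logp = hypergeom.logpmf(support, n, col1, row1)
    log_obs = hypergeom.logpmf(a, n, col1, row1)
    keep = logp <= log_obs + math.log1p(1e-7)
    p = float(np.exp(logp[keep]).sum())
    return min(p, 1.0)


def sectoring_summary(
    tables: Sequence[SectoringTable],
    reference: str,
    star_threshold: float = 0.001,
) -> pd.DataFrame:
    """Per-genotype exact test of sectoring fraction against the reference.

    Stars mark genotypes whose sectored/white ratio differs from the
    reference at the ``star_threshold`` (default 0.001) level.
    """
    by_name = {t.genotype: t for t in tables}
    if reference not in by_name:
        raise KeyError(f"reference genotype {reference!r} missing")
    ref = by_name[reference]
    rows = []
    for t in tables:
        if t.genotype == reference:
            continue
        p = fisher_exact_2x2(t.sectored, t.white, ref.sectored, ref.white)
        rows.append(
            {
                "genotype": t.genotype,
                "sectored": t.sectored,
                "white": t.white,
                "ref_sectored": ref.sectored,
                "ref_white": ref.white,
                "p": p,
                "starred": p < star_threshold,
            }
        )
    return pd.DataFrame(rows)


def bootstrap_fraction_ci(
    counts: LocalizationCounts,
    category: str,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Percentile-bootstrap 95% CI of a localization-category fraction.

    Scored cells are resampled with replacement ``n_boot`` times and the
    fraction recomputed; the interval is the (2.5, 97.5) percentile pair.
    Deterministic given the seed.
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000 for a stable 95% interval")
    n = counts.scored
    if n == 0:
        raise ValueError("no scored cells")
    probs = np.array([counts.nucleus_only, counts.puncta_only, counts.both]) / n
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, probs, size=n_boot)
    if category == "nucleus":
        frac = (draws[:, 0] + draws[:, 2]) / n
    elif category == "puncta":
        frac = (draws[:, 1] + draws[:, 2]) / n
    elif category == "both":
        frac = draws[:, 2] / n
    else:
        raise ValueError("category must be 'nucleus', 'puncta' or 'both'")
    lo, hi = np.percentile(frac, [2.5, 97.5])
    return counts.fraction(category), (float(lo), float(hi))


def pairwise_fisher_corrected(
    counts: Sequence[LocalizationCounts],
    category: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All-pairs exact tests on in-category vs out-of-category cells, with
    Holm-Bonferroni adjustment; pairs are significant at adjusted p < alpha."""
    if len(counts) < 2:
        raise ValueError("need at least two strains")
    rows = []
    for i in range(len(counts)):
        for j in range(i + 1, len(counts)):
            x, y = counts[i], counts[j]
            a, b = x.in_category(category), x.scored - x.in_category(category)
            c, d = y.in_category(category), y.scored - y.in_category(category)
            rows.append(
                {
                    "strain_a": x.strain,
                    "strain_b": y.strain,
                    "p": fisher_exact_2x2(a, b, c, d),
                }
            )
    df = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(df["p"], alpha=alpha, method="holm")
    df["p_adj"] = p_adj
    df["significant"] = reject
    return df
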