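"""Functional-category enrichment of a gene set against a comparison pool.

Genes carry one or more labels from a functional-category palette (a gene
active in several processes counts once in each).  Enrichment of a study set
against a comparison pool is assessed per category with a 2x2 Pearson
chi-square test (no continuity correction by default), and the expected
profile of an equal-size random draw from the pool is estimated by repeated
sampling without replacement (mean and standard error per category).
Raw p-values are reported alongside a Bonferroni-adjusted column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

DEFAULT_ITERATIONS = 1000

__all__ = [
    "Chi2Result",
    "chi_square_2x2",
    "sample_category_profile",
    "compare_gene_sets",
]


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    pvalue: float
    undefined: bool = False

    def __iter__(self):
        return iter((self.statistic, self.pvalue))


def chi_square_2x2(
    a: int, b: int, c: int, d: int, continuity: bool = False
) -> Chi2Result:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]], 1 df.

    A zero row or column margin leaves the statistic undefined; the result
    is flagged rather than raised.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValidationError("table entries must be non-negative integers")
    if a + b + c + d == 0:
        raise ValidationError("table total must be positive")
    if min(a + b, c + d, a + c, b + d) == 0:
        return Chi2Result(math.nan, math.nan, undefined=True)
    stat, p, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=continuity)
    return Chi2Result(float(stat), float(p))


def _category_counts(
    genes: Iterable[str], annot: Mapping[str, set[str]], categories: Sequence[str]
) -> np.ndarray:
    counts = np.zeros(len(categories), dtype=int)
    index = {cat: i for i, cat in enumerate(categories)}
    for g in genes:
        for cat in annot.get(g, ()):
            if cat in index:
                counts[index[cat]] += 1
    return counts


def _palette(annot: Mapping[str, set[str]]) -> list[str]:
    return sorted({cat for cats in annot.values() for cat in cats})


def sample_category_profile(
    pool: Sequence[str],
    annot: Mapping[str, set[str]],
    k: int,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int | None = None,
    categories: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Reference category profile of equal-size random draws from ``pool``.

    Each iteration draws ``k`` genes without replacement and counts genes
    per category; mean and standard error over iterations are reported.
    With a single iteration the standard error is undefined (NaN).
    """
    if k > len(pool):
        raise ValidationError(f"sample size {k} exceeds pool size {len(pool)}")
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    cats = list(categories) if categories is not None else _palette(annot)
    pool = list(pool)
    draws = np.empty((iterations, len(cats)), dtype=int)
    for it in range(iterations):
        sample = rng.choice(len(pool), size=k, replace=False)
        draws[it] = _category_counts((pool[i] for i in sample), annot, cats)
    mean = draws.mean(axis=0)
    if iterations > 1:
        se = draws.std(axis=0, ddof=1) / math.sqrt(iterations)
    else:
        se = np.full(len(cats), math.nan)
    return pd.DataFrame({"category": cats, "mean": mean, "se": se}).set_index("category")


def compare_gene_sets(
    set_a: Sequence[str],
    pool_b: Sequence[str],
    annot: Mapping[str, set[str]],
    categories: Sequence[str] | None = None,
    continuity: bool = False,
) -> pd.DataFrame:
    """Per-category 2x2 chi-square comparison of a gene set vs a pool.

    Rows: category; columns: counts in each set, chi2, raw p and a
    Bonferroni-adjusted p (adjusted for the number of categories tested).
    Categories with a zero margin carry NaN statistics.
    """
    if not set_a or not pool_b:
        raise ValidationError("both gene sets must be non-empty")
    cats = list(categories) if categories is not None else _palette(annot)
    count_a = _category_counts(set_a, annot, cats)
    count_b = _category_counts(pool_b, annot, cats)
    n_a, n_b = len(set_a), len(pool_b)
    rows = []
    for i, cat in enumerate(cats):
        res = chi_square_2x2(
            int(count_a[i]),
            n_a - int(count_a[i]),
            int(count_b[i]),
            n_b - int(count_b[i]),
            continuity=continuity,
        )
        rows.append(
            {
                "category": cat,
                "count_a": int(count_a[i]),
                "count_b": int(count_b[i]),
                "n_a": n_a,
                "n_b": n_b,
                "chi2": res.statistic,
                "p": res.pvalue,
                "p_bonferroni": min(1.0, res.pvalue * len(cats))
                if not res.undefined
                else math.nan,
            }
        )
    return pd.DataFrame(rows).set_index("category")
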