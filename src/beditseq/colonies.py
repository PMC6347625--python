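"""Canavanine-selection statistics and diploid colony genotype classification.

Mutation frequency is the ratio of colony counts on canavanine plates to
colony counts on rich (YPAD) plates.  Colony genotypes are unordered pairs of
allele patterns over the focal cytidine offsets; a colony is homozygous when
both alleles share the pattern, heterozygous otherwise.  Category labels are
generated from the observed patterns (e.g. ``C-19T-18 homozygous``), never
hard-coded, so rare products such as C->G at a focal position form their own
categories exactly as residual table footnotes do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections import Counter

import pandas as pd

__all__ = [
    "AlleleGenotype",
    "ColonyGenotype",
    "mutation_frequency",
    "replicate_summary",
    "classify_genotype",
    "tabulate_genotypes",
    "allele_pattern_label",
]


AlleleGenotype = dict[int, str]  # offset -> observed base


@dataclass(frozen=True)
class ColonyGenotype:
    """Unordered pair of allele genotypes (phasing taken as given upstream)."""

    allele_1: tuple[tuple[int, str], ...]
    allele_2: tuple[tuple[int, str], ...]

    @classmethod
    def from_dicts(cls, a1: AlleleGenotype, a2: AlleleGenotype) -> "ColonyGenotype":
        return cls(tuple(sorted(a1.items())), tuple(sorted(a2.items())))


def mutation_frequency(n_canavanine: int, n_rich: int) -> float | None:
    """Resistant-colony fraction: canavanine-plate count over rich-plate count."""
    if n_canavanine < 0 or n_rich < 0:
        raise ValueError("colony counts must be non-negative")
    if n_rich == 0:
        return None
    return n_canavanine / n_rich


def replicate_summary(values: list[float]) -> tuple[float, float | None]:
    """Mean and sample (n-1) standard deviation across biological replicates."""
    if not values:
        raise ValueError("no replicate values")
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, None
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def allele_pattern_label(allele: tuple[tuple[int, str], ...]) -> str:
    """Pattern string in 5'->3' offset order, e.g. ``C-19T-18``."""
    return "".join(f"{base}{off}" for off, base in sorted(allele))


def _restrict(allele: tuple[tuple[int, str], ...],
              focal_offsets: frozenset[int]) -> tuple[tuple[int, str], ...]:
    d = dict(allele)
    missing = focal_offsets - d.keys()
    if missing:
        raise ValueError(f"incomplete genotype: allele lacks offsets {sorted(missing)}")
    return tuple(sorted((off, d[off]) for off in focal_offsets))


def classify_genotype(
    colony: ColonyGenotype, focal_offsets: frozenset[int] | set[int] = frozenset({-18, -19})
) -> str:
    """Category label over the focal offsets, insensitive to allele order."""
    focal = frozenset(focal_offsets)
    a = _restrict(colony.allele_1, focal)
    b = _restrict(colony.allele_2, focal)
    if a == b:
        return f"{allele_pattern_label(a)} homozygous"
    first, second = sorted((allele_pattern_label(a), allele_pattern_label(b)))
    return f"{first}/{second} heterozygous"


def tabulate_genotypes(
    colonies: list[ColonyGenotype],
    focal_offsets: frozenset[int] | set[int] = frozenset({-18, -19}),
) -> pd.DataFrame:
    """Category -> count table over colonies; counts always sum to the input size."""
    if not colonies:
        raise ValueError("no colonies to tabulate")
    counts = Counter(classify_genotype(c, focal_offsets) for c in colonies)
    n = len(colonies)
    rows = [
        {"category": cat, "count": cnt, "fraction": cnt / n}
        for cat, cnt in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows)
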