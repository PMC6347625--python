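"""Per-position conversion frequencies, edited-product distributions and purity.

All frequencies use the total number of matched (extracted) reads as the
denominator unless explicitly labelled "of edited reads".  Positions over the
protospacer are labelled with PAM-relative offsets (e.g. ``-18``); region
positions outside the protospacer are labelled by region index.

An "edited product" (haplotype) is the pattern of target cytidines in a read
that carry a non-reference base, together with the observed base at each —
keeping the observed base makes product purity (C->T vs C->A/C->G) recoverable
from the distribution without a second pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import numpy as np
import pandas as pd

from .amplicon import AmpliconReference
from .extraction import EditingRegionSet

__all__ = [
    "ConversionMatrix",
    "ProductDistribution",
    "PuritySummary",
    "conversion_matrix",
    "c_to_t_profile",
    "product_distribution",
    "single_edit_fraction",
    "purity_summary",
    "pattern_label",
]

BASES = ("A", "C", "G", "T")


@dataclass
class ConversionMatrix:
    """Per-position base frequencies among matched reads.

    ``table`` is indexed by region position with columns ``offset`` (PAM-relative
    where defined, else NA), ``ref_base``, ``A C G T`` (fractions of ``n_reads``).
    """

    table: pd.DataFrame
    n_reads: int

    def freq(self, offset: int, base: str) -> float:
        row = self.table[self.table["offset"] == offset]
        if row.empty:
            raise KeyError(f"offset {offset} not in conversion matrix")
        return float(row.iloc[0][base])

    def to_tsv(self, path) -> None:
        self.table.assign(n_reads=self.n_reads).to_csv(path, sep="\t", index=True)


Pattern = tuple[tuple[int, str], ...]  # ((offset, observed_base), ...) sorted by offset


@dataclass
class ProductDistribution:
    """Counts of edited-product haplotypes over the target cytidines."""

    target_positions: list[int]
    counts: dict[Pattern, int]
    n_reads: int

    @property
    def n_edited(self) -> int:
        return self.n_reads - self.counts.get((), 0)

    def fraction_of_reads(self, pattern: Pattern) -> float:
        return self.counts.get(pattern, 0) / self.n_reads

    def fraction_of_edited(self, pattern: Pattern) -> float | None:
        return self.counts.get(pattern, 0) / self.n_edited if self.n_edited else None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pat, cnt in sorted(self.counts.items(),
                               key=lambda kv: (-kv[1], kv[0])):
            rows.append({
                "product": pattern_label(pat),
                "n_edited_positions": len(pat),
                "count": cnt,
                "pct_of_reads": 100.0 * cnt / self.n_reads,
                "pct_of_edited_reads": (100.0 * cnt / self.n_edited
                                        if self.n_edited and pat else
                                        (0.0 if pat else None)),
            })
        return pd.DataFrame(rows)


@dataclass
class PuritySummary:
    """Per-target C->T / C->A / C->G fractions and the non-T edited-read share.

    ``per_position`` rows: offset, frac_C_to_T, frac_C_to_A, frac_C_to_G,
    frac_C_retained (fractions of all matched reads, summing to 1).
    ``nonT_edited_read_fraction``: fraction of edited reads carrying at least
    one non-T base at an edited target (None when no read is edited).
    """

    per_position: pd.DataFrame
    nonT_edited_read_fraction: float | None


def pattern_label(pattern: Pattern) -> str:
    """Human-readable product label, e.g. ``"T-19T-18"``; unedited is ``"unedited"``."""
    if not pattern:
        return "unedited"
    return "".join(f"{base}{off}" for off, base in pattern)


def conversion_matrix(
    regions: EditingRegionSet, ref: AmpliconReference
) -> ConversionMatrix:
    """Count each base at each region position over all matched reads.

    Frequencies are counts divided by the total number of matched reads — the
    same denominator at every position — so a position's four base fractions
    sum to one exactly.
    """
    if regions.n_matched == 0:
        raise ValueError("no matched reads: conversion matrix undefined")
    if any(len(r) != regions.region_len for r in regions.regions):
        raise ValueError("regions of unequal length")
    arr = np.frombuffer("".join(regions.regions).encode("ascii"), dtype="S1")
    arr = arr.reshape(regions.n_matched, regions.region_len)
    n = regions.n_matched
    cols = {b: (arr == b.encode()).sum(axis=0) / n for b in BASES}

    offsets: list[float] = []
    for i in range(regions.region_len):
        idx = ref.region_start + i
        offsets.append(idx - ref.pam_start if idx < ref.pam_start else np.nan)
    table = pd.DataFrame({
        "offset": offsets,
        "ref_base": list(ref.region_seq),
        **{b: cols[b] for b in BASES},
    })
    table.index.name = "region_pos"
    return ConversionMatrix(table=table, n_reads=n)


def c_to_t_profile(
    matrix: ConversionMatrix, targets: list[int]
) -> dict[int, float]:
    """C-to-T fraction (of all matched reads) at each target cytidine offset."""
    return {off: matrix.freq(off, "T") for off in targets}


def product_distribution(
    regions: EditingRegionSet, ref: AmpliconReference, targets: list[int]
) -> ProductDistribution:
    """Tally edited-product haplotypes over the target cytidines.

    Each matched read maps to the pattern of targets where it carries a
    non-C base (recording the observed base).  With an empty target set all
    reads fall in the single unedited bucket.
    """
    if regions.n_matched == 0:
        raise ValueError("no matched reads: product distribution undefined")
    tpos = sorted(targets)  # 5'->3' order inside each pattern key
    region_idx = [ref.offset_to_region_index(off) for off in tpos]
    for off, ri in zip(tpos, region_idx):
        if ref.region_seq[ri] != "C":
            raise ValueError(f"target offset {off} is not a reference C")
    counts: Counter[Pattern] = Counter()
    for region in regions.regions:
        pat = tuple(
            (off, region[ri])
            for off, ri in zip(tpos, region_idx)
            if region[ri] != "C"
        )
        counts[pat] += 1
    return ProductDistribution(
        target_positions=list(targets), counts=dict(counts),
        n_reads=regions.n_matched,
    )


def single_edit_fraction(
    dist: ProductDistribution, position: int
) -> float | None:
    """Share of edited reads that are edited solely at ``position``, to T.

    This is the quantity behind "predominantly single-C-modified products":
    count(pattern == {position -> T}) / count(all edited reads).  None (NA)
    when no read is edited.
    """
    if position not in dist.target_positions:
        raise ValueError(f"position {position} not among targets")
    if dist.n_edited == 0:
        return None
    return dist.counts.get(((position, "T"),), 0) / dist.n_edited


def purity_summary(
    matrix: ConversionMatrix,
    dist: ProductDistribution,
    targets: list[int],
) -> PuritySummary:
    rows = []
    for off in targets:
        rows.append({
            "offset": off,
            "frac_C_to_T": matrix.freq(off, "T"),
            "frac_C_to_A": matrix.freq(off, "A"),
            "frac_C_to_G": matrix.freq(off, "G"),
            "frac_C_retained": matrix.freq(off, "C"),
        })
    n_nonT = sum(
        cnt for pat, cnt in dist.counts.items()
        if any(base != "T" for _, base in pat)
    )
    frac = n_nonT / dist.n_edited if dist.n_edited else None
    return PuritySummary(per_position=pd.DataFrame(rows),
                         nonT_edited_read_fraction=frac)
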