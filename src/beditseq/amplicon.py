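"""Amplicon reference model and PAM-relative coordinates.

A cytosine base editor acts within a window of the 20-nt protospacer, and
positions are conventionally reported relative to the PAM: offset -1 is the
protospacer base immediately 5' of the PAM (in protospacer orientation),
offset -18 is 18 nt 5' of the PAM, and so on.  All quantification downstream
of this module is expressed in this coordinate frame.

Internally the amplicon is stored in protospacer orientation (the protospacer
on the stored strand, PAM immediately 3' of it); an amplicon supplied in the
opposite orientation is reverse-complemented at ingest and flagged with
``strand="minus"`` so that every report uses a single frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "AmpliconReference",
    "AmpliconError",
    "build_reference",
    "reverse_complement",
    "matches_pam",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")

# IUPAC codes usable in a PAM pattern (pattern side only; sequences stay ACGT).
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class AmpliconError(ValueError):
    """Raised for invalid reference construction or coordinate lookups."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_seq(seq: str, what: str) -> None:
    if not seq or not _VALID.issuperset(seq):
        raise AmpliconError(
            f"{what} must be non-empty uppercase A/C/G/T (got {seq!r})"
        )


def matches_pam(triplet: str, pattern: str) -> bool:
    """Exact IUPAC-pattern match, e.g. ``matches_pam("TGG", "NGG")``."""
    if len(triplet) != len(pattern):
        return False
    return all(b in _IUPAC[p] for b, p in zip(triplet, pattern.upper()))


@dataclass(frozen=True)
class AmpliconReference:
    """Amplicon with protospacer/PAM location and the fixed editing region.

    ``amplicon_seq`` is stored in protospacer orientation.  ``strand`` records
    whether the input amplicon was already in that orientation (``"plus"``) or
    was reverse-complemented at ingest (``"minus"``).  ``region_start`` /
    ``region_end`` delimit the fixed-length editing region (0-based half-open);
    ``left_flank`` / ``right_flank`` are the exact anchor sequences immediately
    outside the region, used by flank-anchored read extraction.
    """

    amplicon_seq: str
    protospacer_start: int
    protospacer_len: int
    pam_start: int
    pam_len: int
    strand: str
    region_start: int
    region_end: int
    left_flank: str
    right_flank: str

    def __post_init__(self) -> None:
        _check_seq(self.amplicon_seq, "amplicon_seq")
        if self.strand not in ("plus", "minus"):
            raise AmpliconError(f"strand must be plus/minus, got {self.strand!r}")
        n = len(self.amplicon_seq)
        if not (0 <= self.protospacer_start
                and self.protospacer_start + self.protospacer_len == self.pam_start
                and self.pam_start + self.pam_len <= n):
            raise AmpliconError("protospacer/PAM intervals invalid or not adjacent")
        if not (0 <= self.region_start <= self.protospacer_start
                and self.pam_start <= self.region_end <= n):
            raise AmpliconError("editing region must contain the protospacer")
        if self.region_start < len(self.left_flank) or self.left_flank != self.amplicon_seq[
                self.region_start - len(self.left_flank):self.region_start]:
            raise AmpliconError("left_flank does not match amplicon")
        if self.right_flank != self.amplicon_seq[
                self.region_end:self.region_end + len(self.right_flank)]:
            raise AmpliconError("right_flank does not match amplicon")

    # -- derived views ---------------------------------------------------

    @property
    def protospacer_seq(self) -> str:
        return self.amplicon_seq[self.protospacer_start:self.pam_start]

    @property
    def pam_seq(self) -> str:
        return self.amplicon_seq[self.pam_start:self.pam_start + self.pam_len]

    @property
    def region_seq(self) -> str:
        return self.amplicon_seq[self.region_start:self.region_end]

    @property
    def region_len(self) -> int:
        return self.region_end - self.region_start

    # -- coordinate maps -------------------------------------------------

    def offset_to_index(self, offset: int) -> int:
        """Map a PAM-relative offset (-1 adjacent to the PAM) to an amplicon index.

        Offsets are accepted anywhere inside the editing region, so targets a
        base or two 5' of the protospacer (as in a -13…-21 nonacytidine run
        against a 20-nt protospacer) remain addressable.
        """
        if offset >= 0:
            raise AmpliconError(f"offset must be negative, got {offset}")
        idx = self.pam_start + offset
        if not (self.region_start <= idx < self.region_end):
            raise AmpliconError(
                f"offset {offset} outside protospacer/editing region")
        return idx

    def index_to_offset(self, index: int) -> int:
        if not (self.region_start <= index < self.pam_start):
            raise AmpliconError(f"index {index} not 5' of the PAM within the region")
        return index - self.pam_start

    def offset_to_region_index(self, offset: int) -> int:
        return self.offset_to_index(offset) - self.region_start

    def target_cytidines(self, within: str = "protospacer") -> list[int]:
        """Offsets of reference Cs, sorted closest-to-PAM first.

        ``within="protospacer"`` (default) scans the protospacer only;
        ``within="region"`` scans every region base 5' of the PAM.
        """
        if within == "protospacer":
            lo = self.protospacer_start
        elif within == "region":
            lo = self.region_start
        else:
            raise AmpliconError(f"within must be protospacer/region, got {within!r}")
        return [
            i - self.pam_start
            for i in range(self.pam_start - 1, lo - 1, -1)
            if self.amplicon_seq[i] == "C"
        ]


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def build_reference(
    amplicon_seq: str,
    protospacer_seq: str,
    pam_pattern: str = "NGG",
    region_halfwidth: int = 5,
    flank_len: int = 10,
) -> AmpliconReference:
    """Locate a protospacer + adjacent PAM in an amplicon and build the reference.

    The protospacer is searched on both strands; a minus-strand hit
    reverse-complements the amplicon so downstream reports stay in
    protospacer orientation.  The editing region extends ``region_halfwidth``
    bases beyond the protospacer 5' end and beyond the PAM 3' end, and must
    leave ``flank_len`` anchor bases on each side.
    """
    _check_seq(amplicon_seq, "amplicon_seq")
    _check_seq(protospacer_seq, "protospacer_seq")
    if region_halfwidth < 0 or flank_len < 1:
        raise AmpliconError("region_halfwidth must be >= 0 and flank_len >= 1")

    hits_plus = _find_all(amplicon_seq, protospacer_seq)
    rc = reverse_complement(amplicon_seq)
    hits_minus = _find_all(rc, protospacer_seq)
    # A palindromic protospacer hits both strands at mirrored coordinates;
    # treat those as one ambiguity set.
    if len(hits_plus) + len(hits_minus) == 0:
        raise AmpliconError("protospacer not found in amplicon")
    if len(hits_plus) + len(hits_minus) > 1:
        raise AmpliconError("ambiguous protospacer: multiple occurrences")

    if hits_plus:
        seq, start, strand = amplicon_seq, hits_plus[0], "plus"
    else:
        seq, start, strand = rc, hits_minus[0], "minus"

    plen = len(protospacer_seq)
    pam_start = start + plen
    pam_len = len(pam_pattern)
    if pam_start + pam_len > len(seq) or not matches_pam(
            seq[pam_start:pam_start + pam_len], pam_pattern):
        raise AmpliconError("no adjacent PAM matching pattern "
                            f"{pam_pattern!r} 3' of the protospacer")

    region_start = start - region_halfwidth
    region_end = pam_start + pam_len + region_halfwidth
    if region_start - flank_len < 0 or region_end + flank_len > len(seq):
        raise AmpliconError(
            "amplicon too short for the requested editing region plus "
            f"{flank_len}-bp flanks")

    return AmpliconReference(
        amplicon_seq=seq,
        protospacer_start=start,
        protospacer_len=plen,
        pam_start=pam_start,
        pam_len=pam_len,
        strand=strand,
        region_start=region_start,
        region_end=region_end,
        left_flank=seq[region_start - flank_len:region_start],
        right_flank=seq[region_end:region_end + flank_len],
    )
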