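"""Demultiplexing, flank-anchored region extraction and indel scanning.

The extraction step is deliberately exact-match: a read contributes to the
substitution analysis only if both anchor flanks occur in it (each exactly
once), in order, and the enclosed segment has precisely the reference editing
region length.  Indel-containing and imperfectly anchored reads are thereby
excluded by construction, so every retained region aligns to the reference
column-for-column with no gapped alignment step.

The indel scan applies the same anchoring with (by default) 10-bp flanks and
classifies each anchored read by length alone: enclosed segment equal to the
reference region length means no indel, any other length means an indel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .amplicon import AmpliconReference

__all__ = [
    "Read",
    "ReadSet",
    "EditingRegionSet",
    "IndelSummary",
    "demultiplex",
    "extract_regions",
    "classify_indels",
    "quality_filter",
    "UNDETERMINED",
]

UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r} has an empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"read {self.id!r}: quality/sequence length mismatch")


@dataclass
class ReadSet:
    reads: list[Read]
    sample_id: str = ""

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)


@dataclass
class EditingRegionSet:
    """Fixed-length regions retained by extraction, plus rejection accounting."""

    regions: list[str]
    n_input: int
    n_matched: int
    n_rejected_flank: int
    n_rejected_length: int
    n_rejected_ambiguous: int
    region_len: int

    def __post_init__(self) -> None:
        assert self.n_matched == len(self.regions)
        assert self.n_input == (self.n_matched + self.n_rejected_flank
                                + self.n_rejected_length + self.n_rejected_ambiguous)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_matched": self.n_matched,
            "n_rejected_flank": self.n_rejected_flank,
            "n_rejected_length": self.n_rejected_length,
            "n_rejected_ambiguous": self.n_rejected_ambiguous,
            "region_len": self.region_len,
        }


@dataclass
class IndelSummary:
    n_scanned: int
    n_no_indel: int
    n_indel: int
    n_excluded_flank: int
    flank_len: int

    @property
    def indel_frequency(self) -> float | None:
        """Indel fraction among anchored reads; None (NA) with no anchored reads."""
        denom = self.n_indel + self.n_no_indel
        return self.n_indel / denom if denom else None

    def to_dict(self) -> dict:
        return {
            "n_scanned": self.n_scanned,
            "n_no_indel": self.n_no_indel,
            "n_indel": self.n_indel,
            "n_excluded_flank": self.n_excluded_flank,
            "flank_len": self.flank_len,
            "indel_frequency": self.indel_frequency,
        }


def demultiplex(
    reads: ReadSet,
    index_table: dict[str, str],
    tag_location: str = "prefix",
) -> dict[str, ReadSet]:
    """Partition reads into samples by exact index-tag match; tags are stripped.

    Every read lands in exactly one bin; reads matching no tag go to the
    reserved ``"undetermined"`` bin (always present in the output).
    """
    if not index_table:
        raise ValueError("empty index table")
    tags = list(index_table)
    if len(set(tags)) != len(tags) or len(set(index_table.values())) != len(index_table):
        raise ValueError("duplicate tags or duplicate sample ids in index table")
    tag_lens = {len(t) for t in tags}
    if len(tag_lens) != 1 or 0 in tag_lens:
        raise ValueError("index tags must be non-empty and of equal length")
    if tag_location not in ("prefix", "suffix"):
        raise ValueError(f"tag_location must be prefix/suffix, got {tag_location!r}")
    k = tag_lens.pop()

    bins: dict[str, ReadSet] = {sid: ReadSet([], sample_id=sid)
                                for sid in index_table.values()}
    bins[UNDETERMINED] = ReadSet([], sample_id=UNDETERMINED)
    for read in reads:
        tag = read.sequence[:k] if tag_location == "prefix" else read.sequence[-k:]
        sid = index_table.get(tag)
        if sid is None or len(read.sequence) <= k:
            bins[UNDETERMINED].reads.append(read)
            continue
        if tag_location == "prefix":
            seq = read.sequence[k:]
            qual = read.quality[k:] if read.quality is not None else None
        else:
            seq = read.sequence[:-k]
            qual = read.quality[:-k] if read.quality is not None else None
        bins[sid].reads.append(Read(read.id, seq, qual))
    return bins


def _count_occurrences(haystack: str, needle: str) -> tuple[int, int]:
    """(number of occurrences counting overlaps, leftmost start or -1)."""
    first = haystack.find(needle)
    if first == -1:
        return 0, -1
    n, i = 0, first
    while i != -1:
        n += 1
        i = haystack.find(needle, i + 1)
    return n, first


def extract_regions(reads: ReadSet, ref: AmpliconReference) -> EditingRegionSet:
    """Extract fixed-length editing regions anchored by exact flank matches.

    A read is matched iff ``left_flank`` and ``right_flank`` each occur exactly
    once, the left precedes the right, and the enclosed segment has exactly the
    reference region length.  Multiple occurrences of either flank reject the
    read as ambiguous; a wrong-length segment rejects it as a length mismatch
    (this is where indel-containing reads fall).
    """
    lf, rf = ref.left_flank, ref.right_flank
    if not lf or not rf:
        raise ValueError("reference flanks must be non-empty")
    want = ref.region_len
    regions: list[str] = []
    n_flank = n_len = n_ambig = 0
    for read in reads:
        nl, il = _count_occurrences(read.sequence, lf)
        nr, ir = _count_occurrences(read.sequence, rf)
        if nl == 0 or nr == 0:
            n_flank += 1
            continue
        if nl > 1 or nr > 1:
            n_ambig += 1
            continue
        start, end = il + len(lf), ir
        if end < start:
            n_flank += 1
            continue
        if end - start != want:
            n_len += 1
            continue
        regions.append(read.sequence[start:end])
    return EditingRegionSet(
        regions=regions,
        n_input=len(reads),
        n_matched=len(regions),
        n_rejected_flank=n_flank,
        n_rejected_length=n_len,
        n_rejected_ambiguous=n_ambig,
        region_len=want,
    )


def classify_indels(
    reads: ReadSet, ref: AmpliconReference, flank_len: int = 10
) -> IndelSummary:
    """Length-based indel classification between exact flanking anchors.

    Reads lacking either exact ``flank_len``-bp flank are excluded.  For
    anchored reads the enclosed segment is compared to the reference region
    length: equal means no indel (substitutions are allowed), different means
    an indel.  Neither indel position nor size is inferred.
    """
    if flank_len < 1:
        raise ValueError("flank_len must be >= 1")
    if ref.region_start < flank_len or ref.region_end + flank_len > len(ref.amplicon_seq):
        raise ValueError("amplicon lacks flank_len bases on both sides of the region")
    lf = ref.amplicon_seq[ref.region_start - flank_len:ref.region_start]
    rf = ref.amplicon_seq[ref.region_end:ref.region_end + flank_len]
    want = ref.region_len
    n_no = n_yes = n_excl = 0
    for read in reads:
        il = read.sequence.find(lf)
        if il == -1:
            n_excl += 1
            continue
        ir = read.sequence.find(rf, il + flank_len)
        if ir == -1:
            n_excl += 1
            continue
        if ir - (il + flank_len) == want:
            n_no += 1
        else:
            n_yes += 1
    return IndelSummary(
        n_scanned=len(reads),
        n_no_indel=n_no,
        n_indel=n_yes,
        n_excluded_flank=n_excl,
        flank_len=flank_len,
    )


def quality_filter(
    reads: ReadSet, min_mean_q: float = 0.0
) -> tuple[ReadSet, int]:
    """Retain reads whose mean Phred+33 quality is >= ``min_mean_q``.

    Reads without a quality string pass through unchanged.  Returns the
    filtered set and the count of reads dropped (including malformed quality
    strings, which are rejected per read rather than raising).
    """
    kept: list[Read] = []
    n_dropped = 0
    for read in reads:
        if read.quality is None or min_mean_q <= 0:
            kept.append(read)
            continue
        phred = [ord(c) - 33 for c in read.quality]
        if any(q < 0 for q in phred):
            n_dropped += 1
            continue
        if sum(phred) / len(phred) >= min_mean_q:
            kept.append(read)
        else:
            n_dropped += 1
    return ReadSet(kept, sample_id=reads.sample_id), n_dropped
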