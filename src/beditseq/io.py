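"""File-format front ends: FASTQ/FASTA, reference spec, index tables, colony TSVs.

FASTQ and FASTA parsing go through Biopython; writing is plain text so that a
fixed-seed simulation round-trips to byte-identical files.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .amplicon import AmpliconReference, build_reference
from .colonies import ColonyGenotype
from .extraction import Read, ReadSet

__all__ = [
    "read_fastq",
    "write_fastq",
    "load_reference_spec",
    "read_index_table",
    "read_colony_table",
    "read_plate_counts",
    "write_json",
]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path, sample_id: str = "") -> ReadSet:
    """Read a plain or gzipped Phred+33 FASTQ file."""
    reads = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            quals = rec.letter_annotations.get("phred_quality")
            qual = "".join(chr(q + 33) for q in quals) if quals else None
            reads.append(Read(rec.id, str(rec.seq).upper(), qual))
    return ReadSet(reads, sample_id=sample_id or Path(path).stem)


def write_fastq(reads: ReadSet, path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = r.quality if r.quality is not None else "I" * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def load_reference_spec(path) -> AmpliconReference:
    """Build an AmpliconReference from a YAML spec.

    Keys: ``amplicon_fasta`` (path, relative to the spec file), optional
    ``record_id``, ``protospacer``, optional ``pam_pattern`` (default NGG),
    ``region_halfwidth`` (default 5), ``flank_len`` (default 10).
    """
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    fasta = path.parent / cfg["amplicon_fasta"]
    records = list(SeqIO.parse(str(fasta), "fasta"))
    if not records:
        raise ValueError(f"no records in {fasta}")
    if "record_id" in cfg:
        matches = [r for r in records if r.id == cfg["record_id"]]
        if not matches:
            raise ValueError(f"record {cfg['record_id']!r} not in {fasta}")
        rec = matches[0]
    elif len(records) == 1:
        rec = records[0]
    else:
        raise ValueError(f"{fasta} has multiple records; set record_id")
    return build_reference(
        str(rec.seq).upper(),
        cfg["protospacer"].upper(),
        pam_pattern=cfg.get("pam_pattern", "NGG"),
        region_halfwidth=int(cfg.get("region_halfwidth", 5)),
        flank_len=int(cfg.get("flank_len", 10)),
    )


def read_index_table(path) -> dict[str, str]:
    """Two-column TSV (tag, sample_id), no header required."""
    df = pd.read_csv(path, sep="\t", header=None, names=["tag", "sample_id"],
                     dtype=str, comment="#")
    if df["tag"].iloc[0].lower() == "tag":  # tolerate a header row
        df = df.iloc[1:]
    return dict(zip(df["tag"], df["sample_id"]))


def read_colony_table(path) -> list[ColonyGenotype]:
    """Long-format TSV: colony_id, offset, allele_1_base, allele_2_base."""
    df = pd.read_csv(path, sep="\t", dtype={"colony_id": str, "offset": int,
                                            "allele_1_base": str, "allele_2_base": str})
    colonies = []
    for _, grp in df.groupby("colony_id", sort=True):
        a1 = dict(zip(grp["offset"], grp["allele_1_base"]))
        a2 = dict(zip(grp["offset"], grp["allele_2_base"]))
        colonies.append(ColonyGenotype.from_dicts(a1, a2))
    return colonies


def read_plate_counts(path) -> pd.DataFrame:
    """TSV with columns replicate, n_canavanine, n_rich."""
    df = pd.read_csv(path, sep="\t")
    required = {"replicate", "n_canavanine", "n_rich"}
    if not required.issubset(df.columns):
        raise ValueError(f"plate-count table needs columns {sorted(required)}")
    return df


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=2, default=str) + "\n")
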