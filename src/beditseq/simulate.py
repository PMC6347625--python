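"""Ground-truth simulator for base-edited amplicon reads and selected colonies.

The generative model couples edits within a read through a single latent
"engagement" event: with probability ``engagement`` the editor acted on the
molecule, and only then is each target cytidine edited independently with its
conditional probability.  This is the simplest mechanism that yields the
correlated multi-C products real editors produce while keeping closed-form
marginals — the marginal edit probability at offset *o* is
``engagement * cond_edit[o]``, and the covariance of edits at two offsets is
``engagement * (1 - engagement) * cond_edit[a] * cond_edit[b]``.

An edited base is T with probability ``1 - purity_rho``, else A or G
equiprobably (impure C->A/C->G products).  A read carries at most one indel
(probability ``indel_rate``; size uniform in +-1..3, position uniform within
the editing region), and uniform substitution sequencing error is applied
last over the whole read.  Every read has exactly one ground-truth record.

Diploid colonies draw two alleles independently from the same edit model; a
colony survives canavanine selection only when BOTH alleles carry at least
one edit among the inactivating offsets (recessive loss of the arginine
transporter), and resistant colonies are produced by rejection sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .amplicon import AmpliconReference, build_reference
from .colonies import ColonyGenotype
from .extraction import Read, ReadSet

__all__ = [
    "EditorProfile",
    "ReadTruth",
    "GroundTruth",
    "simulate_reads",
    "simulate_colonies",
    "write_fixture_bundle",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class EditorProfile:
    """Generative parameters of a simulated base editor.

    engagement
        Probability the editor acted on a read's molecule at all.
    cond_edit
        Per-offset C->T edit probability *given* engagement; keys must be
        target cytidines of the reference in use.
    purity_rho
        Probability an edited base becomes A or G (split equally) instead of T.
    indel_rate
        Per-read probability of one indel (size uniform +-1..3 nt, position
        uniform in the region).
    seq_error
        Per-base uniform substitution error rate, applied after editing.
    """

    engagement: float
    cond_edit: dict[int, float]
    purity_rho: float = 0.0
    indel_rate: float = 0.0
    seq_error: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        probs = [self.engagement, self.purity_rho, self.indel_rate,
                 self.seq_error, *self.cond_edit.values()]
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all profile probabilities must lie in [0, 1]")

    def marginal_edit_probability(self, offset: int) -> float:
        return self.engagement * self.cond_edit.get(offset, 0.0)


@dataclass
class ReadTruth:
    read_id: str
    engaged: bool
    edits: dict[int, str]          # offset -> base written by the editor
    indel_size: int                # 0 = none; negative = deletion
    error_positions: list[int]     # positions in the final read


@dataclass
class GroundTruth:
    records: list[ReadTruth] = field(default_factory=list)

    def n_indel_free(self) -> int:
        return sum(1 for r in self.records if r.indel_size == 0)

    def n_with_indel(self) -> int:
        return sum(1 for r in self.records if r.indel_size != 0)

    def empirical_edit_fraction(self, offset: int) -> float:
        return sum(1 for r in self.records if offset in r.edits) / len(self.records)

    def to_json(self, path) -> None:
        payload = [
            {
                "read_id": r.read_id,
                "engaged": r.engaged,
                "edits": {str(k): v for k, v in sorted(r.edits.items())},
                "indel_size": r.indel_size,
                "error_positions": r.error_positions,
            }
            for r in self.records
        ]
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=0) + "\n")


def _validate_targets(ref: AmpliconReference, profile: EditorProfile) -> dict[int, int]:
    """Map each cond_edit offset to its region index, insisting on reference Cs."""
    out = {}
    for off in profile.cond_edit:
        ri = ref.offset_to_region_index(off)
        if ref.region_seq[ri] != "C":
            raise ValueError(f"cond_edit offset {off} is not a reference C")
        out[off] = ri
    return out


def simulate_reads(
    ref: AmpliconReference,
    profile: EditorProfile,
    n: int,
    seed: int | None = None,
    id_prefix: str = "read",
    quality_char: str = "I",
) -> tuple[ReadSet, GroundTruth]:
    """Emit ``n`` reads spanning flank + editing region + flank, with truth records.

    Reads carry a constant quality string (default Q40).  Fully reproducible:
    the same reference, profile and seed give byte-identical output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed if seed is not None else profile.seed)
    target_idx = _validate_targets(ref, profile)
    offsets = sorted(target_idx)
    region_ref = ref.region_seq
    lf, rf = ref.left_flank, ref.right_flank

    reads: list[Read] = []
    truth = GroundTruth()
    for i in range(n):
        rid = f"{id_prefix}_{i:06d}"
        region = list(region_ref)
        edits: dict[int, str] = {}
        engaged = bool(rng.random() < profile.engagement)
        if engaged:
            for off in offsets:
                if rng.random() < profile.cond_edit[off]:
                    if rng.random() < profile.purity_rho:
                        base = "A" if rng.random() < 0.5 else "G"
                    else:
                        base = "T"
                    region[target_idx[off]] = base
                    edits[off] = base
        indel_size = 0
        if profile.indel_rate and rng.random() < profile.indel_rate:
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                size = -size
            indel_size = size
            if size > 0:
                pos = int(rng.integers(0, len(region) + 1))
                ins = "".join(_BASES[int(b)] for b in rng.integers(0, 4, size))
                region[pos:pos] = list(ins)
            else:
                k = min(-size, len(region))
                pos = int(rng.integers(0, len(region) - k + 1))
                del region[pos:pos + k]
        seq = list(lf + "".join(region) + rf)
        error_positions: list[int] = []
        if profile.seq_error:
            hits = np.nonzero(rng.random(len(seq)) < profile.seq_error)[0]
            for p in hits:
                old = seq[p]
                choices = [b for b in _BASES if b != old]
                seq[p] = choices[int(rng.integers(0, 3))]
                error_positions.append(int(p))
        seq_str = "".join(seq)
        reads.append(Read(rid, seq_str, quality_char * len(seq_str)))
        truth.records.append(ReadTruth(rid, engaged, edits, indel_size, error_positions))
    return ReadSet(reads, sample_id=id_prefix), truth


def _draw_allele(
    rng: np.random.Generator, profile: EditorProfile, targets: list[int]
) -> dict[int, str]:
    allele = {off: "C" for off in targets}
    if rng.random() < profile.engagement:
        for off in targets:
            if rng.random() < profile.cond_edit.get(off, 0.0):
                if rng.random() < profile.purity_rho:
                    allele[off] = "A" if rng.random() < 0.5 else "G"
                else:
                    allele[off] = "T"
    return allele


def simulate_colonies(
    profile: EditorProfile,
    targets: list[int],
    inactivating_offsets: frozenset[int] | set[int] = frozenset({-18, -19}),
    n_colonies: int = 24,
    seed: int | None = None,
    max_attempts: int | None = None,
) -> tuple[list[ColonyGenotype], GroundTruth]:
    """Rejection-sample canavanine-resistant diploid colonies.

    Each colony draws two alleles independently from the edit model and is
    kept iff both alleles carry >= 1 edit (base != C) among
    ``inactivating_offsets``.  Raises after ``max_attempts`` rejections when
    the profile makes resistance (near-)impossible.
    """
    inact = frozenset(inactivating_offsets)
    if not inact.issubset(targets):
        raise ValueError("inactivating offsets must be a subset of targets")
    if n_colonies < 1:
        raise ValueError("n_colonies must be >= 1")
    rng = np.random.default_rng(seed if seed is not None else profile.seed)
    if max_attempts is None:
        max_attempts = 10_000 + 2_000 * n_colonies

    colonies: list[ColonyGenotype] = []
    truth = GroundTruth()
    attempts = 0
    while len(colonies) < n_colonies:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"no resistant colony in {max_attempts} attempts: "
                "resistance probability is zero or negligible under this profile")
        attempts += 1
        a1 = _draw_allele(rng, profile, targets)
        a2 = _draw_allele(rng, profile, targets)
        resistant = all(
            any(allele[off] != "C" for off in inact) for allele in (a1, a2)
        )
        if not resistant:
            continue
        colony = ColonyGenotype.from_dicts(a1, a2)
        colonies.append(colony)
        # truth record: edited offsets of each allele, encoded "b1/b2" per offset
        truth.records.append(ReadTruth(
            read_id=f"colony_{len(colonies):04d}",
            engaged=True,
            edits={off: f"{a1[off]}/{a2[off]}" for off in sorted(a1)
                   if a1[off] != "C" or a2[off] != "C"},
            indel_size=0,
            error_positions=[],
        ))
    return colonies, truth


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

# Deterministic demo amplicon: random-looking context around a 20-nt
# protospacer whose Cs sit at offsets -16, -18 and -19, followed by an AGG PAM.
_DEMO_PROTO = "ACCTCGATTGAGTAAGGTTA"
_DEMO_LEFT = "GATTACAGGTTAGCAAGTGA"
_DEMO_RIGHT = "TGGATCAACGTTGAGCTTAG"


def demo_reference(region_halfwidth: int = 3, flank_len: int = 10) -> AmpliconReference:
    """Small deterministic reference used by the fixture bundle and docs."""
    amplicon = _DEMO_LEFT + _DEMO_PROTO + "AGG" + _DEMO_RIGHT
    return build_reference(amplicon, _DEMO_PROTO,
                           region_halfwidth=region_halfwidth, flank_len=flank_len)


def write_fixture_bundle(out_dir, seed: int = 0, n_reads_per_sample: int = 300):
    """Write a versioned toy dataset: reference spec, index table, multiplexed
    FASTQ over four samples with distinct editor profiles, simulated colony
    genotypes, and ground-truth JSON.  Byte-identical for a fixed seed.

    Returns the manifest (name -> path) and writes it as ``manifest.json``.
    """
    from . import io as bio  # late import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref = demo_reference()
    targets = ref.target_cytidines()

    fasta = out / "reference.fasta"
    fasta.write_text(f">demo_amplicon\n{ref.amplicon_seq}\n")
    spec = out / "reference.yaml"
    spec.write_text(
        "amplicon_fasta: reference.fasta\n"
        "record_id: demo_amplicon\n"
        f"protospacer: {ref.protospacer_seq}\n"
        "pam_pattern: NGG\n"
        "region_halfwidth: 3\n"
        "flank_len: 10\n"
    )

    tags = {"ACGT": "editor_flat", "CGTA": "editor_peaked",
            "GTAC": "editor_impure", "TACG": "control"}
    index = out / "index.tsv"
    index.write_text("".join(f"{t}\t{s}\n" for t, s in tags.items()))

    profiles = {
        "editor_flat": EditorProfile(0.6, {off: 0.5 for off in targets}),
        "editor_peaked": EditorProfile(0.6, {off: (0.8 if off == targets[1] else 0.05)
                                             for off in targets}),
        "editor_impure": EditorProfile(0.6, {targets[0]: 0.6}, purity_rho=0.2,
                                       indel_rate=0.05),
        "control": EditorProfile(0.0, {}),
    }
    all_reads: list[Read] = []
    truth_all: dict[str, list] = {}
    for k, (sample, prof) in enumerate(profiles.items()):
        rs, truth = simulate_reads(ref, prof, n_reads_per_sample,
                                   seed=seed * 13 + k, id_prefix=sample)
        tag = next(t for t, s in tags.items() if s == sample)
        for r in rs:
            all_reads.append(Read(r.id, tag + r.sequence, "I" * (len(tag) + len(r.sequence))))
        truth_all[sample] = [
            {"read_id": t.read_id, "engaged": t.engaged,
             "edits": {str(o): b for o, b in sorted(t.edits.items())},
             "indel_size": t.indel_size}
            for t in truth.records
        ]
    fastq = out / "multiplexed.fastq"
    bio.write_fastq(ReadSet(all_reads, sample_id="multiplexed"), fastq)

    col_profile = EditorProfile(0.9, {off: (0.9 if off in (-18, -19) else 0.1)
                                      for off in targets})
    colonies, _ = simulate_colonies(col_profile, targets,
                                    inactivating_offsets={-18, -19},
                                    n_colonies=24, seed=seed * 13 + 101)
    colony_tsv = out / "colonies.tsv"
    with colony_tsv.open("w") as fh:
        fh.write("colony_id\toffset\tallele_1_base\tallele_2_base\n")
        for i, col in enumerate(colonies):
            d1, d2 = dict(col.allele_1), dict(col.allele_2)
            for off in sorted(d1):
                fh.write(f"colony_{i:03d}\t{off}\t{d1[off]}\t{d2[off]}\n")

    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth_all, sort_keys=True, indent=0) + "\n")

    manifest = {
        "version": 1,
        "seed": seed,
        "reference_fasta": fasta.name,
        "reference_spec": spec.name,
        "index_table": index.name,
        "fastq": fastq.name,
        "colonies": colony_tsv.name,
        "truth": truth_path.name,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n")
    return manifest
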