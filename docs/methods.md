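# Methods

## Coordinate model

Amplicons are stored in protospacer orientation; an input amplicon whose
protospacer matches on the reverse strand is reverse-complemented at ingest
(`strand="minus"`), so every downstream report uses one frame. Offsets are
negative and PAM-relative: offset −1 is the protospacer base adjacent to the
PAM, offset −k is k bases 5′ of the PAM. Internal amplicon indices are
0-based half-open. Offsets are accepted anywhere in the editing region, not
just the protospacer, because dense C runs used in worst-case window assays
can extend a base past the protospacer 5′ end (nine consecutive Cs at
−13…−21 against a 20-nt protospacer); `target_cytidines` defaults to the
protospacer but can scan the full region. Lowercase and IUPAC ambiguity
codes in sequences are rejected rather than coerced — the pipeline's
semantics are exact matching, and silently coercing inputs would blur what
"exact" means. The degenerate PAM pattern defaults to NGG (SpCas9) and is
configurable; 5′-PAM nucleases are out of scope.

## Extraction and indel scanning

Extraction is anchored by the two flank sequences immediately outside the
fixed-length editing region (default 10 nt each, one parameter shared with
the indel scan). A read is matched iff each flank occurs exactly once
(occurrences counted with overlap), the left precedes the right, and the
enclosed segment has exactly the reference region length. Reads with a
repeated flank are rejected as ambiguous rather than guessed at: exactness
is the point of the procedure, and a multiply occurring anchor has no
canonical placement. Rejection accounting distinguishes flank, length and
ambiguity failures, and the counters always partition the input.

The indel scan anchors the same way but classifies by length alone: anchored
segment equal to the reference region length ⇒ no indel (substitutions
allowed), any other length ⇒ indel. Indel position and size are deliberately
not inferred — presence and length difference are all the downstream
statistics use. Frequencies with zero denominators are reported as NA
(`None`), never 0. Reads are searched in the given orientation only;
orientation is normalized upstream at the reference level, and no per-read
reverse-complement rescue is attempted, keeping the procedure deterministic.

Demultiplexing is an exact, equal-length index-tag match at the read prefix
(or suffix), tag stripped on assignment; unmatched reads land in a reserved
`undetermined` bin so the bins always partition the input. Mismatch-tolerant
tag matching is intentionally absent. The mean-quality read filter
(Phred+33) exists as optional plumbing and defaults to off.

## Quantification

The conversion matrix counts each base at each region position over all
matched reads — a single shared denominator, so the four base fractions at a
position sum to 1 exactly (asserted to 1e−9). Product (haplotype) patterns
record the observed base at each edited target, not just an edited flag, so
purity (C→T vs C→A/C→G) is recoverable from the distribution in one pass.
Both "% of all reads" and "% of edited reads" denominators are reported,
since comparative figures in this field use both. Non-target mismatches
within a read (sequencing error) do not disqualify it — filtering is by
flanks and length only — and they surface in the matrix at their positions.
No confidence intervals or tests are attached; the statistics are
descriptive.

## Window and selectivity rules

Published window statements ("4–5 nt", "nine nucleotides") come with no
formal rule, so the package defines its own and always emits it with the
number: the window is the minimal contiguous offset interval containing
every position with activity ≥ `rel_threshold` × max(profile), default 0.3.
A relative threshold makes the width scale-free (invariant under profile
rescaling) and reproduces the flat-vs-peaked ordering that motivates the
metric. An all-zero profile has width 0. Selectivity is
`profile[focal] / max(profile over neighbors)`, with neighbors defaulting to
all other profiled target Cs; a zero denominator with nonzero focal activity
is reported as a bounded "≥ focal/ε" value (ε default 1e−4), never infinity,
and all-zero profiles give NA.

## Colony statistics

Mutation frequency is the plain ratio of canavanine-plate to rich-plate
colony counts (NA when the rich plate is empty); replicate summaries are the
sample mean and n−1 standard deviation. Colony genotypes are unordered
allele pairs over the focal offsets (default {−18, −19}); classification is
homozygous iff the alleles agree there, with labels generated from the
observed patterns (`C-19T-18 homozygous`, `C-19T-18/T-19T-18 heterozygous`)
rather than hard-coded categories, so rare C→G/C→A products form their own
residual categories. Phasing is taken as given in the input (chromatogram
interpretation is upstream); it is never inferred.

## Simulator

The generative model is chosen for testability: a read's edits are coupled
through one latent engagement Bernoulli (probability `engagement`), and
given engagement each target C is edited independently with
`cond_edit[offset]`. This yields the correlated multi-C products real
editors produce while keeping closed forms — marginal edit probability
`engagement × cond_edit[o]`, and edit covariance between offsets a and b of
`engagement (1−engagement) cond_edit[a] cond_edit[b]` — both of which the
test suite checks against simulation at n = 20,000–40,000 within 3–4
binomial standard errors. An edited base is T with probability `1 −
purity_rho`, else A or G equiprobably. Each read carries at most one indel
(probability `indel_rate`; size uniform ±1..3 nt, position uniform within
the region) — a minimal model, since the analysis uses only presence and
length. Uniform per-base substitution error is applied last; quality strings
are constant Q40 (quality modeling is not part of the procedure; a
degradation option exists only to exercise the filter).

Diploid colonies draw two alleles independently from the same model and are
retained by rejection sampling iff both alleles carry at least one edit
among the inactivating offsets. Recessiveness (biallelic inactivation of the
arginine transporter) is a stated model assumption, consistent with
resistant colonies being biallelically edited; an editor profile under which
resistance is impossible raises after a bounded number of rejections instead
of looping.

What the simulator does **not** emulate: PCR bias and chimeras, realistic
Illumina error profiles, read pairs and overlap merging, multi-indel reads,
position-dependent error. Passing tests therefore demonstrate correctness of
the bookkeeping and estimators under the stated model, not robustness to
every artifact of real libraries; on real data the exact-match extraction
step is itself the guard, discarding reads the model does not cover.

## Problem sizes and determinism

All randomness flows through a single `numpy` `Generator` seed per call;
fixed seed plus fixed parameters gives byte-identical FASTQ and tables
(plain-text writers, sorted JSON keys). Default verification sizes — 10,000
reads for indel recovery, 20,000 for profile recovery, 1,000-read oracle
recounts, 24–400 colonies — put binomial sampling error well inside the
3-SD test tolerances while keeping the full suite a few seconds long. The
acceptance script uses the same sizes.

## Known limitations

- Exact flank matching discards reads with any flank-base error; with
  per-base error rate ε and 10-bp flanks, ~20ε of reads are lost. That loss
  is unbiased for substitution outcomes but slightly depresses measured
  indel counts when errors hit flanks of indel reads.
- The fixed-length rule cannot see balanced indel pairs (insertion plus
  deletion of equal size between the anchors); single-indel reads are always
  detected.
- Window width on a profile with a noisy maximum inherits that noise; no
  smoothing is applied by design.
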