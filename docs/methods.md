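# Methods

## The problem

Recurrent structural rearrangements in the first intron of *TP53* decouple
the gene body from its promoter and first exon. They were characterized in
osteosarcoma by mate-pair (DNA-PET) sequencing of tumors, targeted-capture
sequencing of a Li-Fraumeni family, break-apart FISH and high-density
copy-number arrays. This package rebuilds that analysis chain as testable
software: a simulator that plants rearrangements with fully specified
junction mechanics, a discordant read-pair caller, an exact junction-sequence
analyzer, a copy-number/LOH module, and cohort-level reporting. Nothing
downloads or depends on the original specimens; every quantity the package
reports is recomputed from synthetic data with known truth.

## Mate-pair geometry and the caller

A mate-pair library sequences both ends of long genomic fragments. The
simulator draws fragment lengths from a truncated normal (defaults: mean
3,000 bp, sd 300 bp, truncated to [1,000, 4,000] — the 1–4 kb library
design), places fragments uniformly on each haplotype, and reads `read_len`
bases (35 or 50) from each end, inward-facing by default with the same-strand
mate-pair chemistry available as a flag (normalized to inward at SAM ingest).
Substitution errors only; indel errors are out of scope. Reads that straddle
a planted junction are emitted unmapped, as a real aligner would fail to
place them as simple matches, and their pairs are dropped as orphans at
ingest. Physical coverage `C` means each haplotype position is covered by
`C` fragments in expectation; the emitted pair count is
`ceil(C × total_length / mean_fragment)`.

The caller estimates the insert model robustly (median and MAD of the
apparent outer span of inward intra-chromosomal pairs; concordance band
median ± k·MAD with k = 5, or ±1 % when MAD = 0). Discordant pairs cluster
by single-linkage within a `max_gap` (default: the concordance upper bound —
two pairs from one junction cannot map farther apart than one fragment),
requiring identical chromosome pair and strand pattern; clusters below
`min_support` (default 3; the source data print cluster sizes but no
threshold, so the default is explicit and configurable) are dropped.

Breakpoint intervals per cluster side start at the junction-proximal edge of
the union of member mapping regions and extend junction-ward by
`insert_max − read_len − span`, so a single 2×50 bp pair yields the
`frag_max − 2·read_len` worst case and more members shrink the interval
monotonically. Point estimates use the identity that, for a junction-spanning
fragment, the two junction-ward remainders sum to `fragment − 2·read_len`:

* per side, `junction ≈ mean(member edges) + (median_insert − 2·read_len)/2`
  (unbiased under uniform fragment placement);
* a DEL span is the mean apparent-insert excess over the insert median
  (variance ~ var(fragment)/n);
* an INS donor length is the sum of the two clusters' signed junction sums,
  which cancels the shared acceptor position (same variance scaling). The
  estimate includes the acceptor-site duplication when one exists (tens of
  bases on a 12.5 kb donor);
* an INV span takes the min/max of the two reciprocal clusters' junction
  estimates, so a net loss at one junction (2,275 bp in the germline event)
  does not bias the span.

Cluster pairing: opposite same-strand patterns flanking one segment within a
`pairing_window` (default 5 kb) form a balanced INV; reciprocal
inter-chromosomal clusters form a balanced TRA; two clusters joining both
ends of a donor segment (≤ 100 kb by default) to one acceptor locus form an
INS. Everything unmatched is emitted as UNCLASSIFIED rather than dropped —
complex loci with several independent one-junction translocations motivate
this. Somatic subtraction removes a tumor call when a same-type normal call
has both breakpoints within a window.

## Junction mechanics and their exact recovery

Planted junctions follow the overhang fill-in model: a duplication of length
`d` leaves the `d`-base break-adjacent segment on **both** products of a
balanced pair; a net loss of `g` removes `g` bases spanning the break from
both; micro-homology of `m` makes the join point ambiguous over `m` bases;
untemplated insertions add random non-reference bases. Micro-homology is
engineered into the partner-side reference flank before derivation (it is a
property of the reference, not of the junction sequence alone).

The analyzer is exact by design — its substrate is the in-silico analogue of
a Sanger-sequenced breakpoint amplicon, and sequencing error is handled
upstream (a mismatch allowance exists but defaults to 0). Single junctions
are decomposed by maximal prefix/suffix matching against the two reference
flanks (each anchor must reach 25 bases; shorter matches arise by chance in
random sequence). Balanced pairs are measured through locus coverage: the
longest exact match (either orientation, suffix-automaton search) between
each derivative junction window and a reference locus window gives the locus
interval that derivative retains; the signed intersection of the two
retained intervals is the signature — positive beyond 10 bp is a junctional
duplication, negative beyond 10 bp a net loss, |shared| ≤ 10 bp is
micro-homology-scale, and sign conflict across loci is "mixed". Anchoring
must be unique; a segment matching at two locus positions aborts the
analysis explicitly (repeat-rich breakpoint regions make a refusal safer
than a guess).

Because any exact analyzer is blurred by chance one-base identity at a
junction boundary (probability 1/4 per boundary in random sequence), the
simulator "sharpens" junctions by default: after building derivatives it
edits single reference bases adjacent to each junction so the expected match
length is exact, iterating one edit at a time until stable (simultaneous
edits at reciprocal junctions can otherwise oscillate). This makes planted
policy recovery a zero-tolerance contract, which the tests exploit; with
`sharpen=False` recovered lengths can exceed truth by one or two bases, as
they genuinely would for a real junction.

## Copy number and LOH

Probe tracks carry `log2(cn/2)` plus Gaussian noise (zero copies floored at
a small positive value to keep log2 finite). Segmentation is penalized
least-squares binary segmentation: an exhaustive single-split scan per
segment (cumulative-sum contrast), recursing while the residual-sum-of-squares
gain exceeds the penalty (default 10× a robust noise-variance estimate from
successive differences), with ≥ 10 probes per segment. This replaces the
closed-source segmentation used on the original arrays; the contract is
boundary recovery (within ±2 probes at noise sd 0.1 with unit steps), not
algorithm identity. States use fixed log2 thresholds (loss < −0.2, gain >
0.2 — deliberately loose for tumor-content robustness; the original
platform's thresholds are not published). Only state-changing boundaries
yield transition calls: neutral↔loss is "into-loss", neutral↔gain
"into-gain", and a direct loss↔gain flip "loss-to-gain"; window membership
is half-open. LOH is called when the mean |BAF − 0.5| in a region (≥ 20
SNPs) exceeds 0.3 — a purity-0.7 copy-neutral LOH centres BAF at 0.15/0.85,
deviation 0.35 — and is copy-neutral when the overlapping segment state is
neutral.

## Reporting

Recurrence counts call breakpoint ends inside a query window, one end per
contributing cluster junction, samples counted once. The break-apart scorer
uses interval logic on the two probe footprints (defaults mirror the
published 169/159 kb BAC probes): a call is separating when a breakend lies
strictly between the probes and the event type moves a flank away
(translocation, odd inversion-end count) or a deletion removes a probe
footprint; events confined between the probes (small insertions or
deletions) preserve the fusion signal — the assay's stated resolution limit —
and a sample is positive only at a carrier cell fraction ≥ 10 %. Cohort
frequencies are integer-rounded percentages per platform plus a pooled
value, with raw fractions retained. The expression utility returns
2^−ΔΔCq from four quantification cycles.

## Synthetic data: what it does and does not emulate

The generator reproduces the study conditions: 1–4 kb fragment libraries
with short tags at 15× physical coverage (the per-tumor coverage is not
published; 15× is this package's default and gives ~14 junction-spanning
pairs per haplotype-borne junction, comfortably above `min_support`),
substitution error 10⁻³, diploid samples as derivative + unrearranged
homolog, uniform-composition random references at GC 0.41. It does **not**
emulate repeats or mappability structure (reads are placed by construction,
so there is no mismapping), GC-coverage bias, chimeric library artifacts, or
indel sequencing errors. Passing tests therefore demonstrate correctness of
the geometric and arithmetic contracts — classification, clustering,
breakpoint arithmetic, junction accounting — not robustness to alignment
artifacts on real genomes.

Problem sizes used by the acceptance computations: 2 Mb (deletion run), 5 Mb
(inversion + capture run), 2.3 Mb two-chromosome (insertion run), ~1.3–1.7 Mb
per tumor for the three-tumor recurrence run; 23 tracks of 1,000 probes for
the transition composition. These sizes keep each run in seconds while
leaving every junction's evidence (~14 pairs) identical to what larger
genomes would give locally.

## Numerical and design choices

* Coordinates are 0-based half-open internally; 1-based conventions appear
  only at SAM boundaries (handled by pysam).
* Pairs below mapping quality 10 are dropped at ingest (the source data's
  exact filtering cascade is not restated anywhere; the floor is explicit).
* Capture filtering requires ≥ 1 base of read overlap with the target; no
  repeat masking is applied at filter time, and ranking exposes the full
  cluster-size ordering instead of a validation cutoff, since no cutoff is
  published.
* Tie-breaks are deterministic everywhere (sorted inputs, stable sorts,
  smallest-coordinate-first union in clustering), so a fixed seed reproduces
  byte-identical calls end to end.
* The insertion/translocation boundary is a donor-length ceiling (100 kb)
  plus the both-ends-join-one-locus requirement.
* The pooled cohort percentage merges two platforms with different
  sensitivities; per-platform values are always reported alongside, and the
  pooled figure is plain count pooling, not a calibrated joint estimate.

## Known limitations

* The caller assumes error-free mapping positions; it has no model of
  mismapping or multi-mapping, so `min_support` and the mapq floor are the
  only guards against spurious clusters.
* Junction analysis is exact-match only by default; heavily repetitive
  flanks abort rather than align approximately.
* The segmentation is univariate per track; no joint tumor/normal or
  allele-specific copy-number modelling.
* Balanced-pair analysis needs junction windows whose flanks exceed the
  duplication/net-loss lengths involved; callers choose window sizes.
* FISH emulation is interval logic on point breakends; it does not model
  signal intensity, probe efficiency or cell-level noise beyond the carrier
  fraction threshold.
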