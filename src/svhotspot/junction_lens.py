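"""Junction-sequence analysis: micro-homology, untemplated insertion, and the
duplicated-shared-sequence / net-loss signature of balanced rearrangements.

The substrate is a junction-spanning sequence (the in-silico analogue of a
breakpoint Sanger amplicon) analyzed against the unrearranged reference
flanks.  Matching is exact by default: this class of input is assumed
Sanger-grade, and sequencing error is handled upstream.  Anchoring uses a
unique maximal-exact-match search; a flank that anchors at several positions
aborts the analysis rather than guessing -- repeat-rich breakpoint regions
make explicit failure preferable to a silent wrong answer.

The balanced-pair analysis measures, for each participating locus, which
reference interval each derivative retains.  The signed size of the
intersection of the two retained intervals is the event's signature:

* positive and large -- the same segment is present on both derivatives
  (junctional duplication, the overhang fill-in signature);
* negative -- a stretch of the locus is on neither derivative (net loss);
* zero / a few bases -- blunt joining or micro-homology.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_forge import Genome, PlantResult, revcomp

__all__ = [
    "JunctionSignature",
    "BalancedPairSignature",
    "LocusEventGeometry",
    "PairwiseOverlap",
    "NotAnchoredError",
    "AmbiguousAnchorError",
    "analyze_junction",
    "analyze_balanced_pair",
    "locus_coverage",
    "pairwise_event_overlap",
    "balanced_pair_windows",
    "locus_window",
    "locus_geometry",
]

MICROHOMOLOGY_SCALE = 10  # |shared| up to this many bases is micro-homology-scale
MIN_ANCHOR = 25


class NotAnchoredError(ValueError):
    """The query sequence has no sufficiently long exact match in the flank."""


class AmbiguousAnchorError(ValueError):
    """The matched segment occurs more than once; the analysis refuses to guess."""


# ---------------------------------------------------------------------------
# exact matching primitives


class _SuffixAutomaton:
    """Linear-time suffix automaton for longest-common-substring queries."""

    def __init__(self, s: str) -> None:
        self.len = [0]
        self.link = [-1]
        self.next: list[dict[str, int]] = [{}]
        last = 0
        for c in s:
            cur = len(self.len)
            self.len.append(self.len[last] + 1)
            self.link.append(-1)
            self.next.append({})
            p = last
            while p != -1 and c not in self.next[p]:
                self.next[p][c] = cur
                p = self.link[p]
            if p == -1:
                self.link[cur] = 0
            else:
                q = self.next[p][c]
                if self.len[p] + 1 == self.len[q]:
                    self.link[cur] = q
                else:
                    clone = len(self.len)
                    self.len.append(self.len[p] + 1)
                    self.link.append(self.link[q])
                    self.next.append(dict(self.next[q]))
                    while p != -1 and self.next[p].get(c) == q:
                        self.next[p][c] = clone
                        p = self.link[p]
                    self.link[q] = clone
                    self.link[cur] = clone
            last = cur

    def longest_common(self, t: str) -> tuple[int, int]:
        """(length, end offset in t) of the longest common substring."""
        v, length = 0, 0
        best, best_end = 0, 0
        for i, c in enumerate(t):
            while v and c not in self.next[v]:
                v = self.link[v]
                length = self.len[v]
            if c in self.next[v]:
                v = self.next[v][c]
                length += 1
            else:
                v, length = 0, 0
            if length > best:
                best, best_end = length, i + 1
        return best, best_end


def _count_occurrences(haystack: str, needle: str, limit: int = 2) -> int:
    n, start = 0, 0
    while n < limit:
        pos = haystack.find(needle, start)
        if pos < 0:
            break
        n += 1
        start = pos + 1
    return n


def locus_coverage(
    der_seq: str, locus_seq: str, min_anchor: int = MIN_ANCHOR
) -> tuple[int, int]:
    """Reference-locus interval covered by a derivative sequence.

    The longest exact match between the derivative (either orientation) and
    the locus defines the covered interval, in locus coordinates.  Raises
    :class:`NotAnchoredError` below ``min_anchor`` and
    :class:`AmbiguousAnchorError` when the matched segment is not unique in
    the locus.
    """
    sam = _SuffixAutomaton(locus_seq)
    best = (0, 0, None)
    for seq in (der_seq, revcomp(der_seq)):
        length, end = sam.longest_common(seq)
        if length > best[0]:
            best = (length, end, seq)
    length, end, seq = best
    if length < min_anchor:
        raise NotAnchoredError(
            f"derivative anchors with only {length} exact bases (< {min_anchor})"
        )
    sub = seq[end - length : end]
    if _count_occurrences(locus_seq, sub) > 1 or _count_occurrences(locus_seq, revcomp(sub)) > 0:
        raise AmbiguousAnchorError("matched segment occurs more than once in the locus")
    start = locus_seq.find(sub)
    return (start, start + length)


def _longest_prefix_in(query: str, ref: str, max_mismatches: int = 0) -> int:
    """Length of the longest prefix of ``query`` occurring in ``ref``."""
    if max_mismatches == 0:
        lo, hi = 0, len(query)
        while lo < hi:  # monotone: a prefix occurs iff all shorter prefixes do
            mid = (lo + hi + 1) // 2
            if query[:mid] in ref:
                lo = mid
            else:
                hi = mid - 1
        return lo
    best = 0
    for off in range(len(ref)):
        mm, L = 0, 0
        while off + L < len(ref) and L < len(query):
            if ref[off + L] != query[L]:
                mm += 1
                if mm > max_mismatches:
                    break
            L += 1
            if L > best:
                best = L
    return best


# ---------------------------------------------------------------------------
# single-junction analysis


@dataclass(frozen=True)
class JunctionSignature:
    microhomology_len: int
    untemplated_len: int
    junction_position_ambiguity: tuple[int, int]

    def __post_init__(self) -> None:
        if self.microhomology_len > 0 and self.untemplated_len > 0:
            raise ValueError("micro-homology and untemplated insertion are exclusive")


def analyze_junction(
    junction_seq: str,
    ref_a_flank: str,
    ref_b_flank: str,
    max_mismatches: int = 0,
    min_anchor: int = MIN_ANCHOR,
) -> JunctionSignature:
    """Decompose a junction-spanning sequence against its two reference flanks.

    The maximal prefix matching flank A and the maximal suffix matching
    flank B either overlap (micro-homology: the join point is ambiguous over
    the overlap) or leave a gap (untemplated inserted bases).  Each matched
    span must reach ``min_anchor`` bases -- shorter matches occur by chance
    in random sequence and do not anchor a junction.
    """
    a_len = _longest_prefix_in(junction_seq, ref_a_flank, max_mismatches)
    b_len = _longest_prefix_in(junction_seq[::-1], ref_b_flank[::-1], max_mismatches)
    if a_len < min_anchor or b_len < min_anchor:
        raise NotAnchoredError("junction sequence is not anchored in both flanks")
    n = len(junction_seq)
    if a_len + b_len >= n:
        return JunctionSignature(
            microhomology_len=a_len + b_len - n,
            untemplated_len=0,
            junction_position_ambiguity=(n - b_len, a_len),
        )
    return JunctionSignature(
        microhomology_len=0,
        untemplated_len=n - a_len - b_len,
        junction_position_ambiguity=(a_len, n - b_len),
    )


# ---------------------------------------------------------------------------
# balanced-pair analysis


@dataclass(frozen=True)
class BalancedPairSignature:
    """Signed shared-sequence accounting across a balanced derivative pair.

    ``shared_a``/``shared_b``: positive = bases of the locus present on both
    derivatives (junctional duplication); negative = bases on neither (net
    loss); ``None`` when the locus was not supplied.
    """

    shared_a: int
    shared_b: int | None
    mechanism_class: str
    coverage_a: tuple[tuple[int, int], tuple[int, int]]
    coverage_b: tuple[tuple[int, int], tuple[int, int]] | None


def _signed_overlap(i1: tuple[int, int], i2: tuple[int, int]) -> int:
    return min(i1[1], i2[1]) - max(i1[0], i2[0])


def _classify(shared: list[int]) -> str:
    pos = max(shared)
    neg = min(shared)
    if pos > MICROHOMOLOGY_SCALE and neg < -MICROHOMOLOGY_SCALE:
        return "mixed"
    if pos > MICROHOMOLOGY_SCALE:
        return "duplication"
    if neg < -MICROHOMOLOGY_SCALE:
        return "net_loss"
    if any(s != 0 for s in shared):
        return "microhomology"
    return "blunt"


def analyze_balanced_pair(
    der1_seq: str,
    der2_seq: str,
    locus_a_seq: str,
    locus_b_seq: str | None = None,
    min_anchor: int = MIN_ANCHOR,
) -> BalancedPairSignature:
    """Shared/lost base accounting for the two junctions of a balanced event.

    Inputs are the two junction-spanning derivative sequences and the
    unrearranged reference locus windows.  Symmetric in der1/der2.
    """
    cov_a = (
        locus_coverage(der1_seq, locus_a_seq, min_anchor),
        locus_coverage(der2_seq, locus_a_seq, min_anchor),
    )
    shared_a = _signed_overlap(*cov_a)
    shared = [shared_a]
    cov_b = None
    shared_b = None
    if locus_b_seq is not None:
        cov_b = (
            locus_coverage(der1_seq, locus_b_seq, min_anchor),
            locus_coverage(der2_seq, locus_b_seq, min_anchor),
        )
        shared_b = _signed_overlap(*cov_b)
        shared.append(shared_b)
    return BalancedPairSignature(
        shared_a=shared_a,
        shared_b=shared_b,
        mechanism_class=_classify(shared),
        coverage_a=cov_a,
        coverage_b=cov_b,
    )


# ---------------------------------------------------------------------------
# cross-event overlap at one locus


@dataclass(frozen=True)
class LocusEventGeometry:
    """One event's footprint at a query locus: break position and the locus
    interval retained across its derivative(s), in shared coordinates."""

    break_pos: int
    retained: tuple[int, int]


@dataclass(frozen=True)
class PairwiseOverlap:
    spacing: int
    shared_len: int
    disjoint: bool


def pairwise_event_overlap(a: LocusEventGeometry, b: LocusEventGeometry) -> PairwiseOverlap:
    """Breakpoint spacing and retained-sequence overlap of two events at one locus."""
    inter = _signed_overlap(a.retained, b.retained)
    return PairwiseOverlap(
        spacing=abs(a.break_pos - b.break_pos),
        shared_len=max(inter, 0),
        disjoint=inter <= 0,
    )


def locus_geometry(
    der_seqs: list[str],
    locus_seq: str,
    break_pos: int,
    locus_offset: int = 0,
    min_anchor: int = MIN_ANCHOR,
) -> LocusEventGeometry:
    """Event footprint at a locus from its derivative junction sequences.

    The retained interval is the hull of the coverage intervals of all the
    event's derivatives, reported in reference coordinates via
    ``locus_offset`` (the reference position of the locus window start).
    """
    covs = [locus_coverage(d, locus_seq, min_anchor) for d in der_seqs]
    lo = min(c[0] for c in covs) + locus_offset
    hi = max(c[1] for c in covs) + locus_offset
    return LocusEventGeometry(break_pos=break_pos, retained=(lo, hi))


# ---------------------------------------------------------------------------
# convenience bridges from planted events


def balanced_pair_windows(result: PlantResult, flank: int) -> tuple[str, str]:
    """The two junction-spanning windows of a planted balanced event.

    For a single-derivative event (inversion, inverted insertion) these are
    the windows around its first and last junction; for a reciprocal
    translocation, the junction window of each derivative.
    """
    ders = result.derivatives
    if len(ders) == 2:
        return ders[0].junction_window(0, flank), ders[1].junction_window(0, flank)
    d = ders[0]
    n_junctions = len(d.junction_positions())
    if n_junctions < 2:
        raise ValueError("event has a single junction; no balanced pair to analyze")
    return d.junction_window(0, flank), d.junction_window(n_junctions - 1, flank)


def locus_window(genome: Genome, chrom: str, center: int, flank: int) -> tuple[str, int]:
    """Reference window of +-flank around a position; returns (seq, start)."""
    seq = genome.chromosomes[chrom]
    start = max(0, center - flank)
    return seq[start : center + flank], start
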