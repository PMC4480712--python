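"""Discordant mate-pair classification, clustering and SV calling.

The caller follows the DNA-PET logic: estimate the library insert
distribution from concordant pairs, flag pairs whose mapping geometry is
incompatible with it, group discordant pairs of like mapping pattern into
clusters (a cluster's size, the number of supporting pairs, is its evidence
weight), predict a breakpoint interval per cluster side, type the
rearrangement by combining reciprocal clusters, and subtract germline events
seen in a matched normal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import median_abs_deviation

from .pair_io import End, ReadPairAlignment

__all__ = [
    "LibraryStats",
    "DPETCluster",
    "SVCall",
    "estimate_library_stats",
    "classify_pair",
    "cluster_discordant",
    "predict_breakpoints",
    "call_svs",
    "somatic_subtract",
]

log = logging.getLogger(__name__)

DEFAULT_MIN_SUPPORT = 3
DEFAULT_PAIRING_WINDOW = 5000
DEFAULT_INSERTION_CEILING = 100_000


@dataclass(frozen=True)
class LibraryStats:
    """Robust insert-size model: median/MAD of the apparent insert (outer span)."""

    insert_median: float
    insert_mad: float
    k: float = 5.0
    read_len: int = 50
    concordant_orientation: str = "inward"

    def __post_init__(self) -> None:
        if self.insert_median <= 0 or self.insert_mad < 0:
            raise ValueError("insert_median must be > 0 and insert_mad >= 0")

    @property
    def insert_max(self) -> float:
        """Upper concordance bound; with MAD 0 fall back to +-1% of the median."""
        if self.insert_mad == 0:
            return self.insert_median * 1.01
        return self.insert_median + self.k * self.insert_mad

    @property
    def insert_min(self) -> float:
        if self.insert_mad == 0:
            return self.insert_median * 0.99
        return max(0.0, self.insert_median - self.k * self.insert_mad)


def apparent_insert(pair: ReadPairAlignment) -> int:
    """Outer span of the two mapped ends (only meaningful intra-chromosomally)."""
    return pair.end_b.end - pair.end_a.start


def _is_expected_orientation(pair: ReadPairAlignment) -> bool:
    # internal convention is inward (FR) after ingest normalization
    return pair.end_a.strand == "+" and pair.end_b.strand == "-"


def estimate_library_stats(
    pairs: list[ReadPairAlignment],
    k: float = 5.0,
    read_len: int | None = None,
    min_pairs: int = 1000,
) -> LibraryStats:
    """Median/MAD of apparent insert over intra-chromosomal inward pairs."""
    inserts = [
        apparent_insert(p)
        for p in pairs
        if p.end_a.chrom == p.end_b.chrom and _is_expected_orientation(p)
    ]
    if len(inserts) < min_pairs:
        raise ValueError(
            f"insufficient pairs for insert estimation: {len(inserts)} < {min_pairs}"
        )
    arr = np.asarray(inserts)
    rl = read_len if read_len is not None else int(pairs[0].end_a.end - pairs[0].end_a.start)
    return LibraryStats(
        insert_median=float(np.median(arr)),
        insert_mad=float(median_abs_deviation(arr)),
        k=k,
        read_len=rl,
    )


def classify_pair(pair: ReadPairAlignment, stats: LibraryStats) -> str:
    """Classify one pair: concordant, del-type, inv-type, dup-type or inter-chromosomal."""
    if pair.end_a.chrom != pair.end_b.chrom:
        return "inter-chromosomal"
    sa, sb = pair.end_a.strand, pair.end_b.strand
    if sa == sb:
        return "inv-type"
    if sa == "-":  # outward-facing (RF) pattern
        return "dup-type"
    ins = apparent_insert(pair)
    if stats.insert_min <= ins <= stats.insert_max:
        return "concordant"
    return "del-type" if ins > stats.insert_max else "dup-type"


# ---------------------------------------------------------------------------
# clustering


@dataclass
class DPETCluster:
    """A group of discordant pairs with the same mapping pattern.

    ``side_a``/``side_b`` are the unions of the member mapping regions;
    ``support`` is the dPET cluster size.
    """

    side_a: End
    side_b: End
    support: int
    member_ids: list[str]
    members: list[ReadPairAlignment]
    sample: str = "S"

    @property
    def pattern(self) -> tuple[str, str]:
        return (self.side_a.strand, self.side_b.strand)


def _interval_gap(s1: int, e1: int, s2: int, e2: int) -> int:
    """Signed gap between two intervals (negative when they overlap)."""
    return max(s1, s2) - min(e1, e2)


def pairs_colocate(p: ReadPairAlignment, q: ReadPairAlignment, max_gap: int) -> bool:
    """True when both end-regions of two like-pattern pairs are within max_gap."""
    if (p.end_a.chrom, p.end_b.chrom) != (q.end_a.chrom, q.end_b.chrom):
        return False
    if (p.end_a.strand, p.end_b.strand) != (q.end_a.strand, q.end_b.strand):
        return False
    return (
        _interval_gap(p.end_a.start, p.end_a.end, q.end_a.start, q.end_a.end) <= max_gap
        and _interval_gap(p.end_b.start, p.end_b.end, q.end_b.start, q.end_b.end) <= max_gap
    )


def cluster_discordant(
    pairs: list[ReadPairAlignment],
    max_gap: int,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[DPETCluster]:
    """Single-linkage clustering of discordant pairs of like mapping pattern.

    Two pairs join one cluster iff they share the chromosome pair and strand
    pattern and both end-regions lie within ``max_gap`` (transitively closed).
    Clusters below ``min_support`` are discarded; output is sorted by
    (chromA, startA).
    """
    groups: dict[tuple, list[ReadPairAlignment]] = {}
    for p in pairs:
        key = (p.end_a.chrom, p.end_b.chrom, p.end_a.strand, p.end_b.strand)
        groups.setdefault(key, []).append(p)

    clusters: list[DPETCluster] = []
    for key, members in groups.items():
        members.sort(key=lambda p: (p.end_a.start, p.end_b.start, p.pair_id))
        parent = list(range(len(members)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i: int, j: int) -> None:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)

        # sweep on side A: only pairs whose A-regions can be within max_gap
        # need a side-B comparison
        active: list[int] = []
        for j, pj in enumerate(members):
            active = [
                i for i in active if pj.end_a.start - members[i].end_a.end <= max_gap
            ]
            for i in active:
                if pairs_colocate(members[i], pj, max_gap):
                    union(i, j)
            active.append(j)

        comp: dict[int, list[ReadPairAlignment]] = {}
        for i, p in enumerate(members):
            comp.setdefault(find(i), []).append(p)
        for group in comp.values():
            if len(group) < min_support:
                continue
            side_a = End(
                key[0],
                min(p.end_a.start for p in group),
                max(p.end_a.end for p in group),
                key[2],
            )
            side_b = End(
                key[1],
                min(p.end_b.start for p in group),
                max(p.end_b.end for p in group),
                key[3],
            )
            clusters.append(
                DPETCluster(
                    side_a=side_a,
                    side_b=side_b,
                    support=len(group),
                    member_ids=[p.pair_id for p in group],
                    members=group,
                    sample=group[0].sample,
                )
            )
    clusters.sort(key=lambda c: (c.side_a.chrom, c.side_a.start, c.side_b.chrom, c.side_b.start))
    return clusters


# ---------------------------------------------------------------------------
# breakpoint prediction


def predict_breakpoints(
    cluster: DPETCluster, stats: LibraryStats, read_len: int | None = None
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Breakpoint interval per cluster side.

    The interval starts at the junction-proximal edge of the union of member
    mapping regions and extends junction-ward by (insert_max - span already
    covered); with error-free reads the true junction lies inside it.  More
    members shrink the interval monotonically.
    """
    rl = read_len if read_len is not None else stats.read_len
    insert_max = int(round(stats.insert_max))

    def side_interval(side: End) -> tuple[int, int]:
        span = side.end - side.start
        width = max(insert_max - rl - span, 1)
        if side.strand == "+":  # reads point right, junction right of the union
            return (side.end, side.end + width)
        return (side.start - width, side.start)

    return side_interval(cluster.side_a), side_interval(cluster.side_b)


def cluster_junction_point(
    cluster: DPETCluster, side: str, stats: LibraryStats, read_len: int | None = None
) -> float:
    """Unbiased junction point estimate for one cluster side.

    For a fragment spanning a junction the distance from a read's
    junction-proximal edge to the junction is uniform on
    [0, fragment - 2*read_len], so its expectation is (median insert -
    2*read_len)/2 beyond the mean member edge.
    """
    rl = read_len if read_len is not None else stats.read_len
    half = (stats.insert_median - 2 * rl) / 2.0
    ends = [getattr(p, f"end_{side}") for p in cluster.members]
    strand = ends[0].strand
    if strand == "+":
        return float(np.mean([e.end for e in ends]) + half)
    return float(np.mean([e.start for e in ends]) - half)


def cluster_junction_sum(
    cluster: DPETCluster, stats: LibraryStats, read_len: int | None = None
) -> float:
    """Signed junction-position sum estimated from per-pair insert arithmetic.

    For every member pair the two junction-ward remainders add up to
    (fragment - 2*read_len), so dir_a*junction_a + dir_b*junction_b (dir = +1
    for a '+' side, -1 for '-') equals the mean signed edge sum plus
    (median insert - 2*read_len).  Differences of these sums across
    reciprocal clusters cancel the shared locus position and estimate
    segment lengths with variance ~ var(fragment)/n.
    """
    rl = read_len if read_len is not None else stats.read_len
    terms = []
    for p in cluster.members:
        t = 0.0
        for e in (p.end_a, p.end_b):
            t += e.end if e.strand == "+" else -e.start
        terms.append(t)
    return float(np.mean(terms) + (stats.insert_median - 2 * rl))


# ---------------------------------------------------------------------------
# calling


@dataclass
class SVCall:
    """A typed rearrangement call, possibly combining reciprocal clusters."""

    sv_type: str  # DEL, INV, TRA, INS, UNCLASSIFIED
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    support: int
    balanced: bool = False
    span: int | None = None
    donor_len: int | None = None
    breakends: list[tuple[str, int]] = field(default_factory=list)
    interval_a: tuple[int, int] | None = None
    interval_b: tuple[int, int] | None = None
    cluster_refs: list[int] = field(default_factory=list)
    sample: str = "S"

    def to_bedpe_fields(self) -> list[str]:
        extras = (
            f"call={self.sv_type};support={self.support};balanced={int(self.balanced)};"
            f"span={self.span if self.span is not None else '.'};"
            f"donor_len={self.donor_len if self.donor_len is not None else '.'};"
            f"breakends={','.join(f'{c}:{p}' for c, p in self.breakends) or '.'}"
        )
        return [
            self.chrom_a,
            str(self.pos_a),
            str(self.pos_a + 1),
            self.chrom_b,
            str(self.pos_b),
            str(self.pos_b + 1),
            f"{self.sample}_{self.sv_type}",
            str(self.support),
            "+",
            "-",
            self.sample,
            extras,
        ]

    @classmethod
    def from_bedpe_fields(cls, fields: list[str]) -> "SVCall":
        kv = dict(item.split("=", 1) for item in fields[11].split(";"))
        breakends = []
        if kv.get("breakends", ".") != ".":
            for item in kv["breakends"].split(","):
                c, p = item.rsplit(":", 1)
                breakends.append((c, int(p)))
        return cls(
            sv_type=kv["call"],
            chrom_a=fields[0],
            pos_a=int(fields[1]),
            chrom_b=fields[3],
            pos_b=int(fields[4]),
            support=int(kv["support"]),
            balanced=bool(int(kv["balanced"])),
            span=None if kv["span"] == "." else int(kv["span"]),
            donor_len=None if kv["donor_len"] == "." else int(kv["donor_len"]),
            breakends=breakends,
            sample=fields[10],
        )


def _mk_call(
    sv_type: str,
    clusters: list[DPETCluster],
    stats: LibraryStats,
    read_len: int,
    **kw,
) -> SVCall:
    support = max(c.support for c in clusters)
    breakends = []
    for c in clusters:
        breakends.append((c.side_a.chrom, int(round(cluster_junction_point(c, "a", stats, read_len)))))
        breakends.append((c.side_b.chrom, int(round(cluster_junction_point(c, "b", stats, read_len)))))
    return SVCall(
        sv_type=sv_type,
        support=support,
        breakends=breakends,
        sample=clusters[0].sample,
        **kw,
    )


def call_svs(
    clusters: list[DPETCluster],
    stats: LibraryStats,
    read_len: int | None = None,
    pairing_window: int = DEFAULT_PAIRING_WINDOW,
    insertion_ceiling: int = DEFAULT_INSERTION_CEILING,
) -> list[SVCall]:
    """Type clusters into SV calls, pairing reciprocal clusters of balanced events.

    del-type clusters become DEL calls (span from the apparent-insert excess);
    opposite same-strand clusters flanking one segment become a balanced INV;
    reciprocal inter-chromosomal clusters become a balanced TRA; two clusters
    joining both ends of a short donor segment to one acceptor locus become an
    INS with the donor length reported; everything unmatched is emitted as an
    UNCLASSIFIED single-sided call, never dropped.
    """
    rl = read_len if read_len is not None else stats.read_len
    calls: list[SVCall] = []
    used: set[int] = set()
    jp = lambda c, s: cluster_junction_point(c, s, stats, rl)

    # deletions: single FR clusters with an oversized insert (a short-insert
    # FR cluster is dup-type evidence and falls through to UNCLASSIFIED)
    for i, c in enumerate(clusters):
        if c.side_a.chrom == c.side_b.chrom and c.pattern == ("+", "-"):
            excess = float(np.mean([apparent_insert(p) for p in c.members])) - stats.insert_median
            if excess <= stats.insert_max - stats.insert_median:
                continue
            used.add(i)
            pos_a = int(round(jp(c, "a")))
            span = int(round(excess))
            ia, ib = predict_breakpoints(c, stats, rl)
            calls.append(
                SVCall(
                    "DEL",
                    c.side_a.chrom,
                    pos_a,
                    c.side_b.chrom,
                    pos_a + span,
                    c.support,
                    span=span,
                    breakends=[(c.side_a.chrom, pos_a), (c.side_b.chrom, pos_a + span)],
                    interval_a=ia,
                    interval_b=ib,
                    cluster_refs=[i],
                    sample=c.sample,
                )
            )

    # inversions: pair (+,+) with (-,-) clusters on one chromosome
    intra_inv = [
        i
        for i, c in enumerate(clusters)
        if i not in used and c.side_a.chrom == c.side_b.chrom and c.pattern in (("+", "+"), ("-", "-"))
    ]
    for i in intra_inv:
        if i in used:
            continue
        ci = clusters[i]
        for j in intra_inv:
            if j <= i or j in used:
                continue
            cj = clusters[j]
            if ci.pattern == cj.pattern or ci.side_a.chrom != cj.side_a.chrom:
                continue
            if (
                abs(jp(ci, "a") - jp(cj, "a")) <= pairing_window
                and abs(jp(ci, "b") - jp(cj, "b")) <= pairing_window
            ):
                used.update((i, j))
                s = min(jp(ci, "a"), jp(cj, "a"))
                e = max(jp(ci, "b"), jp(cj, "b"))
                call = _mk_call(
                    "INV",
                    [ci, cj],
                    stats,
                    rl,
                    chrom_a=ci.side_a.chrom,
                    pos_a=int(round(s)),
                    chrom_b=ci.side_b.chrom,
                    pos_b=int(round(e)),
                    balanced=True,
                    span=int(round(e - s)),
                    cluster_refs=[i, j],
                )
                calls.append(call)
                break

    # inter-chromosomal: reciprocal translocations and insertions
    inter = [i for i, c in enumerate(clusters) if i not in used and c.side_a.chrom != c.side_b.chrom]
    for i in inter:
        if i in used:
            continue
        ci = clusters[i]
        for j in inter:
            if j <= i or j in used:
                continue
            cj = clusters[j]
            if (ci.side_a.chrom, ci.side_b.chrom) != (cj.side_a.chrom, cj.side_b.chrom):
                continue
            if abs(jp(ci, "a") - jp(cj, "a")) > pairing_window:
                continue
            pats = {ci.pattern, cj.pattern}
            b_dist = abs(jp(ci, "b") - jp(cj, "b"))
            if pats == {("+", "-"), ("-", "+")} and b_dist <= pairing_window:
                used.update((i, j))
                calls.append(
                    _mk_call(
                        "TRA",
                        [ci, cj],
                        stats,
                        rl,
                        chrom_a=ci.side_a.chrom,
                        pos_a=int(round((jp(ci, "a") + jp(cj, "a")) / 2)),
                        chrom_b=ci.side_b.chrom,
                        pos_b=int(round((jp(ci, "b") + jp(cj, "b")) / 2)),
                        balanced=True,
                        cluster_refs=[i, j],
                    )
                )
                break
            if pats in ({("+", "+"), ("-", "-")}, {("+", "-"), ("-", "+")}) and b_dist <= insertion_ceiling:
                # both donor ends join one acceptor locus: insertion; the
                # donor length comes from the junction-sum arithmetic, which
                # cancels the (shared) acceptor position
                donor = abs(cluster_junction_sum(ci, stats, rl) + cluster_junction_sum(cj, stats, rl))
                used.update((i, j))
                calls.append(
                    _mk_call(
                        "INS",
                        [ci, cj],
                        stats,
                        rl,
                        chrom_a=ci.side_a.chrom,
                        pos_a=int(round((jp(ci, "a") + jp(cj, "a")) / 2)),
                        chrom_b=ci.side_b.chrom,
                        pos_b=int(round(min(jp(ci, "b"), jp(cj, "b")))),
                        balanced=False,
                        donor_len=int(round(donor)),
                        cluster_refs=[i, j],
                    )
                )
                break

    # leftovers: emitted, never dropped
    for i, c in enumerate(clusters):
        if i in used:
            continue
        ia, ib = predict_breakpoints(c, stats, rl)
        calls.append(
            _mk_call(
                "UNCLASSIFIED",
                [c],
                stats,
                rl,
                chrom_a=c.side_a.chrom,
                pos_a=int(round(jp(c, "a"))),
                chrom_b=c.side_b.chrom,
                pos_b=int(round(jp(c, "b"))),
                interval_a=ia,
                interval_b=ib,
                cluster_refs=[i],
            )
        )

    calls.sort(key=lambda c: (c.chrom_a, c.pos_a, c.chrom_b, c.pos_b))
    return calls


def somatic_subtract(
    tumor_calls: list[SVCall], normal_calls: list[SVCall], window: int
) -> list[SVCall]:
    """Drop tumor calls matched by a same-type normal call within ``window``."""

    def matches(t: SVCall, n: SVCall) -> bool:
        return (
            t.sv_type == n.sv_type
            and t.chrom_a == n.chrom_a
            and t.chrom_b == n.chrom_b
            and abs(t.pos_a - n.pos_a) <= window
            and abs(t.pos_b - n.pos_b) <= window
        )

    kept = [t for t in tumor_calls if not any(matches(t, n) for n in normal_calls)]
    log.info("somatic subtraction: %d tumor calls, %d retained", len(tumor_calls), len(kept))
    return kept
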