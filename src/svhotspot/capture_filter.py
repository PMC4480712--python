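"""Targeted-capture breakpoint discovery: one-end-anchored pair filtering.

Mirrors the capture-sequencing analysis used to find a germline breakpoint at
a gene locus: keep read pairs with exactly one end inside the capture target,
cluster the anchored discordant pairs, and rank candidate junctions by
cluster size (the number of paired reads with a similar mapping pattern), the
quantity used to prioritize junctions for validation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dpet_caller import (
    DEFAULT_MIN_SUPPORT,
    DPETCluster,
    LibraryStats,
    classify_pair,
    cluster_discordant,
    cluster_junction_point,
)
from .pair_io import ReadPairAlignment

__all__ = ["TargetRegion", "FilterCounts", "filter_target_pairs", "rank_candidates"]


@dataclass(frozen=True)
class TargetRegion:
    chrom: str
    start: int
    end: int
    name: str = "target"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("target start must be < end")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return chrom == self.chrom and start < self.end and end > self.start


@dataclass
class FilterCounts:
    retained: int = 0
    both_in: int = 0
    both_out: int = 0

    def total(self) -> int:
        return self.retained + self.both_in + self.both_out


def filter_target_pairs(
    pairs: list[ReadPairAlignment], target: TargetRegion
) -> tuple[list[ReadPairAlignment], FilterCounts]:
    """Keep pairs with exactly one end overlapping the target (>= 1 base).

    The partition is exhaustive over the input: retained + both-in + both-out
    equals the number of pairs seen.
    """
    counts = FilterCounts()
    anchored: list[ReadPairAlignment] = []
    for p in pairs:
        in_a = target.overlaps(p.end_a.chrom, p.end_a.start, p.end_a.end)
        in_b = target.overlaps(p.end_b.chrom, p.end_b.start, p.end_b.end)
        if in_a and in_b:
            counts.both_in += 1
        elif not in_a and not in_b:
            counts.both_out += 1
        else:
            counts.retained += 1
            anchored.append(p)
    return anchored, counts


def rank_candidates(
    anchored: list[ReadPairAlignment],
    target: TargetRegion,
    stats: LibraryStats,
    max_gap: int | None = None,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[DPETCluster]:
    """Cluster anchored discordant pairs, ranked by support then mate locus.

    Concordant pairs that merely straddle a target boundary carry no
    rearrangement signal and are excluded before clustering.  The stable
    order is (support descending, mate chromosome, mate start), the mate
    being the cluster side outside the target.
    """
    gap = max_gap if max_gap is not None else int(round(stats.insert_max))
    discordant = [p for p in anchored if classify_pair(p, stats) != "concordant"]
    clusters = cluster_discordant(discordant, max_gap=gap, min_support=min_support)

    def mate_key(c: DPETCluster) -> tuple:
        side = c.side_b if target.overlaps(c.side_a.chrom, c.side_a.start, c.side_a.end) else c.side_a
        return (side.chrom, side.start)

    return sorted(clusters, key=lambda c: (-c.support, *mate_key(c)))
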