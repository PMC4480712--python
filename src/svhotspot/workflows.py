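"""End-to-end conveniences tying the modules into the standard call chain."""

from __future__ import annotations

from dataclasses import dataclass

from .dpet_caller import (
    DEFAULT_MIN_SUPPORT,
    DEFAULT_PAIRING_WINDOW,
    DPETCluster,
    LibraryStats,
    SVCall,
    call_svs,
    classify_pair,
    cluster_discordant,
    estimate_library_stats,
)
from .pair_io import ReadPairAlignment

__all__ = ["CallRun", "call_pipeline"]


@dataclass
class CallRun:
    stats: LibraryStats
    clusters: list[DPETCluster]
    calls: list[SVCall]
    census: dict[str, int]


def call_pipeline(
    pairs: list[ReadPairAlignment],
    min_support: int = DEFAULT_MIN_SUPPORT,
    max_gap: int | None = None,
    pairing_window: int = DEFAULT_PAIRING_WINDOW,
    k: float = 5.0,
    read_len: int | None = None,
) -> CallRun:
    """Insert-size estimation, discordance classification, clustering, calling.

    ``max_gap`` defaults to the concordance upper bound (pairs from one
    junction cannot map farther apart than one fragment).
    """
    stats = estimate_library_stats(pairs, k=k, read_len=read_len)
    census: dict[str, int] = {}
    discordant = []
    for p in pairs:
        c = classify_pair(p, stats)
        census[c] = census.get(c, 0) + 1
        if c != "concordant":
            discordant.append(p)
    gap = max_gap if max_gap is not None else int(round(stats.insert_max))
    clusters = cluster_discordant(discordant, max_gap=gap, min_support=min_support)
    calls = call_svs(clusters, stats, read_len=read_len, pairing_window=pairing_window)
    return CallRun(stats=stats, clusters=clusters, calls=calls, census=census)
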