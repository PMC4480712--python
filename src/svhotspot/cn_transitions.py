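"""Copy-number segmentation, gene-window transition classification and LOH.

Probe-level log2-ratio tracks are segmented with penalized least-squares
binary segmentation (exhaustive single-split scan, applied recursively; a
split is kept when it reduces the residual sum of squares by more than the
penalty).  Segment states are assigned by fixed log2 thresholds, boundaries
falling inside a gene window are classified as transitions into loss, into
gain, or abrupt loss-to-gain flips, and B-allele-fraction tracks are scored
for loss of heterozygosity, including the copy-neutral kind (allele
fractions collapse towards 0/1 while the total copy number stays at two).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Segment",
    "TransitionCall",
    "LOHCall",
    "segment_profile",
    "classify_window_transitions",
    "detect_loh",
]

LOSS_THRESHOLD = -0.2
GAIN_THRESHOLD = 0.2
DEFAULT_MIN_PROBES = 10
DEFAULT_LOH_THRESHOLD = 0.3
MIN_INFORMATIVE_SNPS = 20


@dataclass(frozen=True)
class Segment:
    start: int  # probe index, half-open
    end: int
    mean_log2: float
    state: str
    n_probes: int
    pos_start: int  # genomic coordinates of the probe range
    pos_end: int


@dataclass(frozen=True)
class TransitionCall:
    position: int
    transition_class: str  # into-loss, into-gain, loss-to-gain
    window_hit: bool


@dataclass(frozen=True)
class LOHCall:
    region: tuple[int, int]
    loh: bool
    copy_neutral: bool
    mean_baf_deviation: float


def _state(mean_log2: float, loss_thr: float, gain_thr: float) -> str:
    if mean_log2 < loss_thr:
        return "loss"
    if mean_log2 > gain_thr:
        return "gain"
    return "neutral"


def _best_split(y: np.ndarray, min_probes: int) -> tuple[int, float]:
    """Best single change point by residual-sum-of-squares gain.

    Returns (split index, RSS reduction); split -1 when no admissible split.
    Uses the identity RSS_total - RSS_split = contrast gain computed from
    cumulative sums, scanning every admissible split exhaustively.
    """
    n = len(y)
    if n < 2 * min_probes:
        return -1, 0.0
    csum = np.cumsum(y)
    total = csum[-1]
    k = np.arange(min_probes, n - min_probes + 1)
    left_mean = csum[k - 1] / k
    right_mean = (total - csum[k - 1]) / (n - k)
    gain = k * (n - k) / n * (left_mean - right_mean) ** 2
    i = int(np.argmax(gain))
    return int(k[i]), float(gain[i])


def estimate_noise_sd(values: np.ndarray) -> float:
    """Robust probe-noise estimate from successive differences."""
    d = np.diff(np.asarray(values, dtype=float))
    if len(d) == 0:
        return 0.0
    return float(np.median(np.abs(d)) / (np.sqrt(2.0) * 0.6745))


def segment_profile(
    track,
    penalty: float | None = None,
    min_probes: int = DEFAULT_MIN_PROBES,
    loss_threshold: float = LOSS_THRESHOLD,
    gain_threshold: float = GAIN_THRESHOLD,
) -> list[Segment]:
    """Segment a probe track (DataFrame with ``pos``/``log2``) into CN states.

    ``penalty`` defaults to 10x the estimated noise variance.  Segments tile
    the track; each has at least ``min_probes`` probes.  The segmentation is
    invariant under adding a constant to all probes (only the state labels
    move, via the fixed thresholds).
    """
    pos = np.asarray(track["pos"])
    y = np.asarray(track["log2"], dtype=float)
    n = len(y)
    if n < 2 * min_probes:
        raise ValueError(f"track too short: {n} probes < {2 * min_probes}")
    if penalty is None:
        penalty = 10.0 * estimate_noise_sd(y) ** 2

    boundaries: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        split, gain = _best_split(y[lo:hi], min_probes)
        if split < 0 or gain <= penalty:
            return
        boundaries.append(lo + split)
        recurse(lo, lo + split)
        recurse(lo + split, hi)

    recurse(0, n)
    edges = [0] + sorted(boundaries) + [n]
    segments = []
    for s, e in zip(edges, edges[1:]):
        m = float(np.mean(y[s:e]))
        segments.append(
            Segment(
                start=s,
                end=e,
                mean_log2=m,
                state=_state(m, loss_threshold, gain_threshold),
                n_probes=e - s,
                pos_start=int(pos[s]),
                pos_end=int(pos[e - 1]) + 1,
            )
        )
    return segments


def classify_window_transitions(
    segments: list[Segment], window: tuple[int, int]
) -> list[TransitionCall]:
    """Classify state-changing segment boundaries against a gene window.

    Any boundary between a neutral and a loss segment (either direction) is
    a transition into loss; neutral/gain is into gain; a direct loss/gain
    flip with no neutral segment between is loss-to-gain.  Boundaries in the
    half-open window get ``window_hit=True``; equal-state boundaries produce
    no call.
    """
    calls: list[TransitionCall] = []
    for left, right in zip(segments, segments[1:]):
        if left.end != right.start:
            raise ValueError("segments must tile the track")
        states = {left.state, right.state}
        if len(states) == 1:
            continue
        if states == {"neutral", "loss"}:
            klass = "into-loss"
        elif states == {"neutral", "gain"}:
            klass = "into-gain"
        else:
            klass = "loss-to-gain"
        boundary_pos = right.pos_start
        calls.append(
            TransitionCall(
                position=boundary_pos,
                transition_class=klass,
                window_hit=window[0] <= boundary_pos < window[1],
            )
        )
    return calls


def detect_loh(
    baf,
    region: tuple[int, int],
    cn_state: str,
    threshold: float = DEFAULT_LOH_THRESHOLD,
    min_snps: int = MIN_INFORMATIVE_SNPS,
) -> LOHCall:
    """Score a BAF track (DataFrame with ``pos``/``baf``) for LOH in a region.

    LOH is called when the mean absolute deviation of BAF from 0.5 exceeds
    ``threshold``; it is copy-neutral when the overlapping copy-number state
    is neutral.
    """
    pos = np.asarray(baf["pos"])
    vals = np.asarray(baf["baf"], dtype=float)
    mask = (pos >= region[0]) & (pos < region[1])
    if int(mask.sum()) < min_snps:
        raise ValueError(f"too few informative SNPs in region: {int(mask.sum())} < {min_snps}")
    dev = float(np.mean(np.abs(vals[mask] - 0.5)))
    loh = dev > threshold
    return LOHCall(
        region=region,
        loh=loh,
        copy_neutral=loh and cn_state == "neutral",
        mean_baf_deviation=dev,
    )
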