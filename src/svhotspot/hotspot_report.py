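"""Cross-sample recurrence, in-silico break-apart scoring, cohort pooling and
the ddCq fold-change utility.

``recurrence`` counts call breakpoint ends inside a query window (e.g. the
first intron of a gene) across samples.  ``breakapart_in_silico`` emulates a
two-color FISH assay with probes flanking the gene: an event is positive when
it puts the two probe footprints onto different derivatives (or removes one),
and at least the threshold fraction of cells carry it -- the published assay
scored a tumor positive at >= 10% of cells with separated signals.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dpet_caller import SVCall

__all__ = [
    "BreakApartConfig",
    "CohortCounts",
    "CqMeasurement",
    "RecurrenceResult",
    "recurrence",
    "breakapart_in_silico",
    "cohort_frequency",
    "foldchange_ddcq",
]


@dataclass(frozen=True)
class BreakApartConfig:
    probe_a: tuple[str, int, int]
    probe_b: tuple[str, int, int]
    positive_fraction_threshold: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.positive_fraction_threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        (ca, sa, ea), (cb, sb, eb) = self.probe_a, self.probe_b
        if ca == cb and sa < eb and sb < ea:
            raise ValueError("probes must not overlap")


@dataclass(frozen=True)
class CohortCounts:
    platform: str
    positives: int
    total: int

    def __post_init__(self) -> None:
        if not 0 <= self.positives <= self.total:
            raise ValueError("require 0 <= positives <= total")


@dataclass(frozen=True)
class CqMeasurement:
    cq_target: float
    cq_reference: float
    cq_target_ctrl: float
    cq_reference_ctrl: float

    def __post_init__(self) -> None:
        if min(self.cq_target, self.cq_reference, self.cq_target_ctrl, self.cq_reference_ctrl) <= 0:
            raise ValueError("Cq values must be > 0")


@dataclass
class RecurrenceResult:
    breakpoints_in_window: int
    samples_affected: int
    per_sample: dict[str, int]


def recurrence(
    calls_by_sample: dict[str, list[SVCall]],
    window: tuple[str, int, int],
) -> RecurrenceResult:
    """Count call breakpoint ends inside a half-open window across samples.

    Every breakend of every call is tested (a balanced call contributes one
    end per contributing cluster junction); a sample counts once regardless
    of how many of its ends fall in the window.
    """
    chrom, start, end = window
    per_sample: dict[str, int] = {}
    for sample, calls in calls_by_sample.items():
        n = 0
        for call in calls:
            for c, p in call.breakends:
                if c == chrom and start <= p < end:
                    n += 1
        if n:
            per_sample[sample] = n
    return RecurrenceResult(
        breakpoints_in_window=sum(per_sample.values()),
        samples_affected=len(per_sample),
        per_sample=per_sample,
    )


def _point_in(pos: tuple[str, int], interval: tuple[str, int, int]) -> bool:
    return pos[0] == interval[0] and interval[1] <= pos[1] < interval[2]


def breakapart_in_silico(
    calls: list[SVCall],
    config: BreakApartConfig,
    cell_fraction: float,
) -> str:
    """Score a sample 'positive' or 'negative' under the break-apart probe logic.

    A call separates the probes when a breakend lies strictly between their
    footprints and the event moves the flanks apart (translocation,
    inversion crossing one probe side, insertion-junction pair) or when a
    deletion removes a probe footprint entirely.  A small event fully
    contained between the probes that removes neither (e.g. a short intronic
    insertion or deletion) preserves the fusion signal and scores negative --
    the assay's stated resolution limit.  Positivity additionally requires
    ``cell_fraction`` at or above the configured threshold (the >= 10% rule).
    """
    if cell_fraction < config.positive_fraction_threshold:
        return "negative"
    (ca, sa, ea) = config.probe_a
    (cb, sb, eb) = config.probe_b
    if ca != cb:
        raise ValueError("break-apart probes must flank one locus on one chromosome")
    gap = (ca, min(ea, eb), max(sa, sb))  # region strictly between the probes

    for call in calls:
        between = [be for be in call.breakends if _point_in(be, gap)]
        if call.sv_type == "DEL":
            span = (call.chrom_a, call.pos_a, call.pos_b)
            for probe in (config.probe_a, config.probe_b):
                if span[0] == probe[0] and span[1] <= probe[1] and span[2] >= probe[2]:
                    return "positive"  # a probe footprint is lost
            continue  # a deletion removing neither probe keeps the flanks fused
        if call.sv_type in ("TRA", "UNCLASSIFIED"):
            if between:
                return "positive"
        elif call.sv_type == "INV":
            # an inversion with exactly one end between the probes relocates
            # one flank; fully contained (or fully spanning) inversions keep
            # the probe adjacency
            if len(between) % 2 == 1 or (
                between and abs(call.pos_b - call.pos_a) >= (gap[2] - gap[1])
            ):
                return "positive"
        elif call.sv_type == "INS":
            continue  # small insertions are below the assay's resolution
    return "negative"


def cohort_frequency(counts: list[CohortCounts]) -> dict:
    """Per-platform and pooled positive percentages (integer-rounded).

    Raw fractions are reported alongside, and the pooled value is invariant
    to platform order.
    """
    if any(c.total == 0 for c in counts):
        raise ValueError("platform total must be > 0")
    per_platform = {
        c.platform: {
            "percent": round(100.0 * c.positives / c.total),
            "fraction": c.positives / c.total,
            "positives": c.positives,
            "total": c.total,
        }
        for c in counts
    }
    pos = sum(c.positives for c in counts)
    tot = sum(c.total for c in counts)
    return {
        "per_platform": per_platform,
        "pooled": {
            "percent": round(100.0 * pos / tot),
            "fraction": pos / tot,
            "positives": pos,
            "total": tot,
        },
    }


def foldchange_ddcq(m: CqMeasurement) -> float:
    """Relative expression as 2^-ddCq, normalized to a reference gene and a
    control sample."""
    dcq_sample = m.cq_target - m.cq_reference
    dcq_ctrl = m.cq_target_ctrl - m.cq_reference_ctrl
    return 2.0 ** -(dcq_sample - dcq_ctrl)
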