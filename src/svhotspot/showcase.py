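"""Reference reconstructions of the named hotspot rearrangements.

Each function rebuilds one of the characterized intron-1 events in a
synthetic genome -- the 94 kb deletion (AJF), the balanced translocation
with 555/293 bp junctional duplications (YZH), the 12.5 kb inverted
insertion with a 59 bp acceptor overlap (PZP), the two closely spaced
translocations sharing 46 bp of intron 1 (KRD), and the germline 445 kb
inversion with a 2,275 bp net loss (the LFS family event) -- then runs the
corresponding pipeline stage and returns what it measured.  These double as
end-to-end recovery experiments: the printed quantities are outputs of the
caller or the junction analyzer, never of the truth records.

Simulations use the DNA-PET library defaults (3 kb +- 300 bp fragments
truncated to 1-4 kb, 2x50 bp tags, substitution rate 1e-3) at 15x physical
coverage per haplotype, diploid where a normal homolog is meaningful.
"""

from __future__ import annotations

import os
import tempfile

from . import genome_forge as gf
from . import pair_io
from .capture_filter import TargetRegion, filter_target_pairs, rank_candidates
from .dpet_caller import SVCall, call_svs, estimate_library_stats
from .hotspot_report import CohortCounts, cohort_frequency, recurrence
from .junction_lens import (
    analyze_balanced_pair,
    balanced_pair_windows,
    locus_geometry,
    locus_window,
    pairwise_event_overlap,
)
from .workflows import call_pipeline

__all__ = [
    "LIBRARY",
    "COVERAGE",
    "ajf_deletion_call",
    "lfs_inversion_capture_call",
    "lfs_net_loss",
    "pzp_insertion_overlap",
    "yzh_shared_segments",
    "krd_retained_overlap",
    "pzp_insertion_call",
    "three_tumor_recurrence",
    "cn_transition_composition",
    "cohort_percentages",
]

LIBRARY = gf.LibraryModel(
    frag_min=1000, frag_max=4000, frag_mean=3000.0, frag_sd=300.0,
    read_len=50, error_rate=0.001,
)
COVERAGE = 15.0


def _simulate_calls(genome, haplotypes, seed, sample):
    """Simulate, round-trip through SAM, ingest and call."""
    pairs = gf.simulate_mate_pairs(haplotypes, LIBRARY, COVERAGE, seed=seed, sample=sample)
    with tempfile.TemporaryDirectory() as d:
        sam = os.path.join(d, f"{sample}.sam")
        pair_io.write_sam(pairs, genome, sam, sample=sample)
        aligned, _ = pair_io.read_pairs_sam(sam, sample=sample)
    return call_pipeline(aligned)


# ---------------------------------------------------------------------------
# event-recovery simulations


def ajf_deletion_call(seed: int) -> dict:
    """94 kb deletion spanning the gene, recovered by the caller.

    Returns the DEL call's span in kb (nearest kb) plus bookkeeping.
    """
    genome = gf.make_reference(1, [2_000_000], 0.41, seed=seed, chrom_names=["chr17"])
    s = 900_000
    rec = gf.TruthRecord("deletion", ("chr17", s, s + 94_000), sample="AJF")
    res = gf.plant_sv(genome, rec)
    haps = res.derivatives + [gf.reference_haplotype(res.genome, "chr17")]
    run = _simulate_calls(res.genome, haps, seed + 1, "AJF")
    dels = [c for c in run.calls if c.sv_type == "DEL"]
    call = max(dels, key=lambda c: c.support)
    return {"span_kb": round(call.span / 1000), "span_bp": call.span, "n_pairs": sum(run.census.values())}


def lfs_inversion_capture_call(seed: int) -> dict:
    """445 kb germline inversion found through target-capture filtering.

    One junction sits inside the capture target (with a 2,275 bp net loss);
    anchored pairs are clustered, ranked and called; returns the balanced
    INV span in kb.
    """
    genome = gf.make_reference(1, [5_000_000], 0.41, seed=seed, chrom_names=["chr17"])
    s = 2_300_000
    rec = gf.TruthRecord(
        "inversion", ("chr17", s, s + 445_000),
        policy=gf.JunctionPolicy(net_loss=2275), sample="LFS",
    )
    res = gf.plant_sv(genome, rec)
    haps = res.derivatives + [gf.reference_haplotype(res.genome, "chr17")]
    pairs = gf.simulate_mate_pairs(haps, LIBRARY, COVERAGE, seed=seed + 1, sample="LFS")
    with tempfile.TemporaryDirectory() as d:
        sam = os.path.join(d, "lfs.sam")
        pair_io.write_sam(pairs, res.genome, sam, sample="LFS")
        aligned, _ = pair_io.read_pairs_sam(sam, sample="LFS")
    stats = estimate_library_stats(aligned)
    # the capture target mirrors a 160 kb gene-centred design
    target = TargetRegion("chr17", s - 80_000, s + 80_000, "tp53")
    anchored, counts = filter_target_pairs(aligned, target)
    ranked = rank_candidates(anchored, target, stats)
    calls = call_svs(ranked, stats)
    inv = [c for c in calls if c.sv_type == "INV" and c.balanced]
    call = max(inv, key=lambda c: c.support)
    return {"span_kb": round(call.span / 1000), "span_bp": call.span, "anchored": counts.retained}


def pzp_insertion_call(seed: int) -> dict:
    """12.5 kb inverted insertion from a donor chromosome, called as INS.

    Returns the donor length in kb rounded to 0.1 kb.
    """
    genome = gf.make_reference(
        2, [2_200_000, 100_000], 0.41, seed=seed, chrom_names=["chr17", "chr6"]
    )
    a, ds = 1_100_000, 40_000
    rec = gf.TruthRecord(
        "inverted_insertion", ("chr17", a, a + 1), ("chr6", ds, ds + 12_500),
        policy=gf.JunctionPolicy(duplication_len=59), sample="PZP",
    )
    res = gf.plant_sv(genome, rec)
    haps = res.derivatives + [
        gf.reference_haplotype(res.genome, "chr17"),
        gf.reference_haplotype(res.genome, "chr6"),
        gf.reference_haplotype(res.genome, "chr6"),
    ]
    run = _simulate_calls(res.genome, haps, seed + 1, "PZP")
    ins = [c for c in run.calls if c.sv_type == "INS"]
    call = max(ins, key=lambda c: c.support)
    return {"donor_kb": round(call.donor_len / 100) / 10, "donor_bp": call.donor_len}


def three_tumor_recurrence(seed: int) -> dict:
    """The three-tumor hotspot configuration: 7 breakpoint ends, 3 samples.

    YZH contributes the two reciprocal translocation junctions, PZP the two
    insertion junctions, KRD three independent one-sided translocations
    (separate clones, partners on three chromosomes); every end is recovered
    by the caller and counted inside the intron window.
    """
    window = ("chr17", 598_000, 606_000)
    calls_by_sample: dict[str, list[SVCall]] = {}

    genome = gf.make_reference(2, [1_200_000, 300_000], 0.41, seed=seed, chrom_names=["chr17", "chr1"])
    rec = gf.TruthRecord(
        "reciprocal_translocation", ("chr17", 600_000, 600_001), ("chr1", 150_000, 150_001),
        policy=gf.JunctionPolicy(duplication_len=555, duplication_len_b=293), sample="YZH",
    )
    res = gf.plant_sv(genome, rec)
    haps = res.derivatives + [
        gf.reference_haplotype(res.genome, "chr17"),
        gf.reference_haplotype(res.genome, "chr1"),
    ]
    calls_by_sample["YZH"] = _simulate_calls(res.genome, haps, seed + 11, "YZH").calls

    genome = gf.make_reference(2, [1_200_000, 100_000], 0.41, seed=seed + 1, chrom_names=["chr17", "chr6"])
    rec = gf.TruthRecord(
        "inverted_insertion", ("chr17", 600_000, 600_001), ("chr6", 40_000, 52_500),
        policy=gf.JunctionPolicy(duplication_len=59), sample="PZP",
    )
    res = gf.plant_sv(genome, rec)
    haps = res.derivatives + [
        gf.reference_haplotype(res.genome, "chr17"),
        gf.reference_haplotype(res.genome, "chr6"),
        gf.reference_haplotype(res.genome, "chr6"),
    ]
    calls_by_sample["PZP"] = _simulate_calls(res.genome, haps, seed + 12, "PZP").calls

    genome = gf.make_reference(
        4, [1_200_000, 100_000, 100_000, 100_000], 0.41, seed=seed + 2,
        chrom_names=["chr17", "chr1", "chr6", "chr5"],
    )
    recs = [
        gf.TruthRecord(
            "reciprocal_translocation", ("chr17", 600_000, 600_001), ("chr1", 50_000, 50_001),
            policy=gf.JunctionPolicy(duplication_len=91), one_sided="left", sample="KRD", name="KRD_chr1",
        ),
        gf.TruthRecord(
            "reciprocal_translocation", ("chr17", 600_045, 600_046), ("chr6", 50_000, 50_001),
            one_sided="right", sample="KRD", name="KRD_chr6",
        ),
        gf.TruthRecord(
            "reciprocal_translocation", ("chr17", 604_000, 604_001), ("chr5", 50_000, 50_001),
            one_sided="left", sample="KRD", name="KRD_chr5",
        ),
    ]
    genome, results = gf.plant_all(genome, recs, seed=seed + 3)
    haps = [r.derivatives[0] for r in results] + [gf.reference_haplotype(genome, "chr17")]
    calls_by_sample["KRD"] = _simulate_calls(genome, haps, seed + 13, "KRD").calls

    r = recurrence(calls_by_sample, window)
    return {
        "breakpoints": r.breakpoints_in_window,
        "samples": r.samples_affected,
        "per_sample": r.per_sample,
    }


# ---------------------------------------------------------------------------
# exact junction reconstructions


def lfs_net_loss(seed: int) -> dict:
    """Bases lost at the gene-side junction of the germline inversion: 2,275."""
    genome = gf.make_reference(1, [2_000_000], 0.41, seed=seed, chrom_names=["chr17"])
    s, e = 700_000, 1_145_000
    rec = gf.TruthRecord(
        "inversion", ("chr17", s, e), policy=gf.JunctionPolicy(net_loss=2275), sample="LFS",
    )
    res = gf.plant_sv(genome, rec)
    w1, w2 = balanced_pair_windows(res, flank=1000)
    la, _ = locus_window(res.genome, "chr17", s, 4000)
    lb, _ = locus_window(res.genome, "chr17", e, 4000)
    sig = analyze_balanced_pair(w1, w2, la, lb)
    return {"net_loss_bp": -sig.shared_a, "shared_b": sig.shared_b, "class": sig.mechanism_class}


def yzh_shared_segments(seed: int) -> dict:
    """Segments present on both derivatives of the balanced translocation: 555/293."""
    genome = gf.make_reference(2, [400_000, 400_000], 0.41, seed=seed, chrom_names=["chr17", "chr1"])
    a, b = 200_000, 200_000
    rec = gf.TruthRecord(
        "reciprocal_translocation", ("chr17", a, a + 1), ("chr1", b, b + 1),
        policy=gf.JunctionPolicy(duplication_len=555, duplication_len_b=293), sample="YZH",
    )
    res = gf.plant_sv(genome, rec)
    w1, w2 = balanced_pair_windows(res, flank=1000)
    la, _ = locus_window(res.genome, "chr17", a, 4000)
    lb, _ = locus_window(res.genome, "chr1", b, 4000)
    sig = analyze_balanced_pair(w1, w2, la, lb)
    return {"shared_tp53_bp": sig.shared_a, "shared_chr1_bp": sig.shared_b, "class": sig.mechanism_class}


def pzp_insertion_overlap(seed: int) -> dict:
    """Acceptor-locus sequence on both sides of the inverted insertion: 59."""
    genome = gf.make_reference(2, [400_000, 100_000], 0.41, seed=seed, chrom_names=["chr17", "chr6"])
    a = 200_000
    rec = gf.TruthRecord(
        "inverted_insertion", ("chr17", a, a + 1), ("chr6", 40_000, 52_500),
        policy=gf.JunctionPolicy(duplication_len=59), sample="PZP",
    )
    res = gf.plant_sv(genome, rec)
    w1, w2 = balanced_pair_windows(res, flank=1000)
    la, _ = locus_window(res.genome, "chr17", a, 2000)
    sig = analyze_balanced_pair(w1, w2, la)
    return {"overlap_bp": sig.shared_a, "class": sig.mechanism_class}


def krd_retained_overlap(seed: int) -> dict:
    """Intron sequence retained by both derivatives of the two close
    translocations: breakpoints 45 bp apart, 46 bp overlap.

    The first event keeps the centromeric side with a 91 bp junctional
    duplication; the second keeps the telomeric side from 45 bp further
    along, so the retained intervals intersect in 46 bp.
    """
    genome = gf.make_reference(
        3, [400_000, 100_000, 100_000], 0.41, seed=seed, chrom_names=["chr17", "chr1", "chr6"]
    )
    p1 = 200_000
    p2 = p1 + 45
    recs = [
        gf.TruthRecord(
            "reciprocal_translocation", ("chr17", p1, p1 + 1), ("chr1", 50_000, 50_001),
            policy=gf.JunctionPolicy(duplication_len=91), one_sided="left", sample="KRD",
        ),
        gf.TruthRecord(
            "reciprocal_translocation", ("chr17", p2, p2 + 1), ("chr6", 50_000, 50_001),
            one_sided="right", sample="KRD",
        ),
    ]
    genome, results = gf.plant_all(genome, recs, seed=seed)
    win, off = locus_window(genome, "chr17", p1, 2000)
    geo1 = locus_geometry([results[0].derivatives[0].junction_window(0, 1000)], win, p1, off)
    geo2 = locus_geometry([results[1].derivatives[0].junction_window(0, 1000)], win, p2, off)
    ov = pairwise_event_overlap(geo1, geo2)
    return {"spacing_bp": ov.spacing, "overlap_bp": ov.shared_len, "disjoint": ov.disjoint}


# ---------------------------------------------------------------------------
# array-cohort reconstructions


def cn_transition_composition(seed: int, noise_sd: float = 0.1) -> dict:
    """23 synthetic copy-number profiles with the observed transition mix.

    17 profiles step from two copies into loss, 3 into gain, 3 flip directly
    from loss to gain, each with its boundary planted inside the gene window;
    returns the per-class counts recovered by segmentation + classification.
    """
    from .cn_transitions import classify_window_transitions, segment_profile

    window = (100_000, 110_000)
    composition = ["into-loss"] * 17 + ["into-gain"] * 3 + ["loss-to-gain"] * 3
    counts = {"into-loss": 0, "into-gain": 0, "loss-to-gain": 0, "other": 0}
    for i, klass in enumerate(composition):
        b = 105_000
        if klass == "into-loss":
            segs = [(0, b, 2), (b, 200_000, 1)]
        elif klass == "into-gain":
            segs = [(0, b, 2), (b, 200_000, 3)]
        else:
            segs = [(0, b, 1), (b, 200_000, 3)]
        track = gf.simulate_cn_profile(segs, probe_spacing=200, noise_sd=noise_sd, seed=seed + i)
        segments = segment_profile(track)
        hits = [t for t in classify_window_transitions(segments, window) if t.window_hit]
        if len(hits) == 1 and hits[0].transition_class in counts:
            counts[hits[0].transition_class] += 1
        else:
            counts["other"] += 1
    return counts


def cohort_percentages() -> dict:
    """Screen percentages recomputed from the published positive/total counts.

    215 tumors screened by break-apart FISH (23 positive), 73 by high-density
    CN arrays (23 with an intron-1 transition; 54 with any alteration of the
    gene); the pooled rearrangement estimate merges the FISH and intron-1
    array counts.
    """
    fish = CohortCounts("fish", 23, 215)
    array_intron1 = CohortCounts("cn-array-intron1", 23, 73)
    array_any = CohortCounts("cn-array-any-alteration", 54, 73)
    pooled = cohort_frequency([fish, array_intron1])
    return {
        "fish_percent": pooled["per_platform"]["fish"]["percent"],
        "array_intron1_percent": pooled["per_platform"]["cn-array-intron1"]["percent"],
        "array_any_percent": cohort_frequency([array_any])["per_platform"][
            "cn-array-any-alteration"
        ]["percent"],
        "pooled_percent": pooled["pooled"]["percent"],
        "pooled_counts": (pooled["pooled"]["positives"], pooled["pooled"]["total"]),
    }
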