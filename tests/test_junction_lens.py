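import numpy as np
import pytest

from svhotspot import genome_forge as gf
from svhotspot import junction_lens as jl


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# single-junction analysis vs exhaustive split-point oracle


def split_point_oracle(junction, ref_a, ref_b):
    """Enumerate all split points; derive micro-homology / untemplated length.

    A split s is valid when the prefix occurs in ref A and the suffix in
    ref B.  With >= 1 valid split, the micro-homology is the number of extra
    valid splits; with none, the untemplated length is the shortest middle
    segment not attributable to either flank.
    """
    n = len(junction)
    valid = [s for s in range(n + 1) if junction[:s] in ref_a and junction[s:] in ref_b]
    valid = [s for s in valid if 0 < s < n]
    if valid:
        return (len(valid) - 1, 0)
    a_len = max((s for s in range(n + 1) if junction[:s] in ref_a), default=0)
    b_len = max((s for s in range(n + 1) if junction[n - s :] in ref_b), default=0)
    return (0, n - a_len - b_len)


def constructed_junction(rng, mh=0, unt=0, flank=120):
    """Junction assembled from two random flanks with known mechanics.

    Returns None when the random draw would blur the labelled mechanics with
    chance one-base identity at a boundary (the caller simply redraws).
    """
    a = random_seq(rng, 2 * flank)
    b = random_seq(rng, flank - mh) + (a[flank - mh : flank] if mh else "") + random_seq(rng, flank)
    middle = random_seq(rng, unt)
    junction = a[:flank] + middle + b[flank:]
    if a[flank] == junction[flank]:  # prefix would extend into the B side
        return None
    if unt:
        if middle[-1] == b[flank - 1] or middle[0] == a[flank]:
            return None
    elif a[flank - mh - 1] == b[flank - mh - 1]:  # homology would grow by one
        return None
    return junction, a, b


class TestAnalyzeJunction:
    def test_blunt_junction(self):
        rng = np.random.default_rng(0)
        built = None
        while built is None:
            built = constructed_junction(rng, mh=0, unt=0)
        junction, a, b = built
        sig = jl.analyze_junction(junction, a, b)
        assert (sig.microhomology_len, sig.untemplated_len) == (0, 0)

    @pytest.mark.parametrize("mh,unt", [(0, 0), (4, 0), (1, 0), (9, 0), (0, 3), (0, 1), (0, 12)])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_split_oracle(self, mh, unt, seed):
        rng = np.random.default_rng(10 * seed + mh + 100 * unt)
        for _ in range(10):
            built = constructed_junction(rng, mh=mh, unt=unt)
            if built is None:
                continue
            junction, a, b = built
            sig = jl.analyze_junction(junction, a, b)
            assert (sig.microhomology_len, sig.untemplated_len) == split_point_oracle(junction, a, b)

    def test_unanchored_junction_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(jl.NotAnchoredError):
            jl.analyze_junction(random_seq(rng, 100), random_seq(rng, 100), random_seq(rng, 100))

    def test_ambiguity_interval_width_equals_microhomology(self):
        rng = np.random.default_rng(4)
        built = constructed_junction(rng, mh=6)
        junction, a, b = built
        sig = jl.analyze_junction(junction, a, b)
        lo, hi = sig.junction_position_ambiguity
        assert hi - lo == sig.microhomology_len


# ---------------------------------------------------------------------------
# balanced-pair analysis on planted events


def plant(sv_type, policy, seed=5, **kw):
    g = gf.make_reference(2, [120_000, 120_000], 0.41, seed=seed, chrom_names=["chrA", "chrB"])
    if sv_type == "reciprocal_translocation":
        rec = gf.TruthRecord(sv_type, ("chrA", 60_000, 60_001), ("chrB", 60_000, 60_001), policy=policy, **kw)
    elif sv_type == "inverted_insertion":
        rec = gf.TruthRecord(sv_type, ("chrA", 60_000, 60_001), ("chrB", 20_000, 32_000), policy=policy, **kw)
    else:
        rec = gf.TruthRecord(sv_type, ("chrA", 40_000, 80_000), policy=policy, **kw)
    return gf.plant_sv(g, rec)


class TestAnalyzeBalancedPair:
    def test_translocation_with_two_duplications(self):
        res = plant("reciprocal_translocation", gf.JunctionPolicy(duplication_len=555, duplication_len_b=293))
        w1, w2 = jl.balanced_pair_windows(res, 1000)
        la, _ = jl.locus_window(res.genome, "chrA", 60_000, 4000)
        lb, _ = jl.locus_window(res.genome, "chrB", 60_000, 4000)
        sig = jl.analyze_balanced_pair(w1, w2, la, lb)
        assert (sig.shared_a, sig.shared_b, sig.mechanism_class) == (555, 293, "duplication")

    def test_inversion_with_net_loss(self):
        res = plant("inversion", gf.JunctionPolicy(net_loss=2275))
        w1, w2 = jl.balanced_pair_windows(res, 1000)
        la, _ = jl.locus_window(res.genome, "chrA", 40_000, 4000)
        lb, _ = jl.locus_window(res.genome, "chrA", 80_000, 4000)
        sig = jl.analyze_balanced_pair(w1, w2, la, lb)
        assert (sig.shared_a, sig.shared_b, sig.mechanism_class) == (-2275, 0, "net_loss")

    def test_blunt_translocation(self):
        res = plant("reciprocal_translocation", gf.JunctionPolicy())
        w1, w2 = jl.balanced_pair_windows(res, 1000)
        la, _ = jl.locus_window(res.genome, "chrA", 60_000, 4000)
        lb, _ = jl.locus_window(res.genome, "chrB", 60_000, 4000)
        sig = jl.analyze_balanced_pair(w1, w2, la, lb)
        assert (sig.shared_a, sig.shared_b, sig.mechanism_class) == (0, 0, "blunt")

    def test_symmetry_under_derivative_swap(self):
        res = plant("reciprocal_translocation", gf.JunctionPolicy(duplication_len=46))
        w1, w2 = jl.balanced_pair_windows(res, 1000)
        la, _ = jl.locus_window(res.genome, "chrA", 60_000, 4000)
        lb, _ = jl.locus_window(res.genome, "chrB", 60_000, 4000)
        s1 = jl.analyze_balanced_pair(w1, w2, la, lb)
        s2 = jl.analyze_balanced_pair(w2, w1, la, lb)
        assert (s1.shared_a, s1.shared_b, s1.mechanism_class) == (s2.shared_a, s2.shared_b, s2.mechanism_class)

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize(
        "sv_type,policy,expected",
        [
            ("reciprocal_translocation", dict(duplication_len=555, duplication_len_b=293), (555, 293)),
            ("reciprocal_translocation", dict(), (0, 0)),
            ("inversion", dict(net_loss=2275), (-2275, 0)),
            ("inversion", dict(duplication_len=46), (46, 0)),
        ],
    )
    def test_full_parameter_recovery_zero_tolerance(self, seed, sv_type, policy, expected):
        res = plant(sv_type, gf.JunctionPolicy(**policy), seed=50 + seed)
        w1, w2 = jl.balanced_pair_windows(res, 1000)
        if sv_type == "reciprocal_translocation":
            la, _ = jl.locus_window(res.genome, "chrA", 60_000, 4000)
            lb, _ = jl.locus_window(res.genome, "chrB", 60_000, 4000)
        else:
            la, _ = jl.locus_window(res.genome, "chrA", 40_000, 4000)
            lb, _ = jl.locus_window(res.genome, "chrA", 80_000, 4000)
        sig = jl.analyze_balanced_pair(w1, w2, la, lb)
        assert (sig.shared_a, sig.shared_b) == expected

    def test_acceptor_duplication_of_inverted_insertion(self):
        res = plant("inverted_insertion", gf.JunctionPolicy(duplication_len=59))
        w1, w2 = jl.balanced_pair_windows(res, 1000)
        la, _ = jl.locus_window(res.genome, "chrA", 60_000, 2000)
        sig = jl.analyze_balanced_pair(w1, w2, la)
        assert (sig.shared_a, sig.shared_b, sig.mechanism_class) == (59, None, "duplication")

    def test_repeat_locus_raises_ambiguous_anchor(self):
        rng = np.random.default_rng(9)
        unit = random_seq(rng, 400)
        locus = unit + unit  # perfect tandem repeat
        der = unit[100:300]  # anchors at two positions; must refuse to guess
        with pytest.raises(jl.AmbiguousAnchorError):
            jl.locus_coverage(der, locus)


class TestPairwiseOverlap:
    def test_close_translocations_spacing_and_overlap(self):
        # construction mirroring two events 45 bp apart with 46 shared bases
        g = gf.make_reference(3, [200_000, 80_000, 80_000], 0.41, seed=13, chrom_names=["chrA", "chrB", "chrC"])
        p1, p2 = 100_000, 100_045
        recs = [
            gf.TruthRecord("reciprocal_translocation", ("chrA", p1, p1 + 1), ("chrB", 40_000, 40_001),
                           policy=gf.JunctionPolicy(duplication_len=91), one_sided="left"),
            gf.TruthRecord("reciprocal_translocation", ("chrA", p2, p2 + 1), ("chrC", 40_000, 40_001),
                           one_sided="right"),
        ]
        g, results = gf.plant_all(g, recs, seed=13)
        win, off = jl.locus_window(g, "chrA", p1, 2000)
        geo1 = jl.locus_geometry([results[0].derivatives[0].junction_window(0, 1000)], win, p1, off)
        geo2 = jl.locus_geometry([results[1].derivatives[0].junction_window(0, 1000)], win, p2, off)
        ov = jl.pairwise_event_overlap(geo1, geo2)
        assert (ov.spacing, ov.shared_len, ov.disjoint) == (45, 46, False)

    def test_identical_breakpoints_have_zero_spacing(self):
        geo = jl.LocusEventGeometry(100, (50, 150))
        assert jl.pairwise_event_overlap(geo, geo).spacing == 0

    def test_disjoint_retained_intervals_reported_as_zero(self):
        a = jl.LocusEventGeometry(100, (0, 90))
        b = jl.LocusEventGeometry(300, (200, 400))
        ov = jl.pairwise_event_overlap(a, b)
        assert (ov.shared_len, ov.disjoint) == (0, True)
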