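"""Synthetic genomes, planted rearrangements and mate-pair library simulation.

This module builds everything the downstream callers consume, together with
exact ground truth, so the whole pipeline is testable without any external
sequencing data.  It emulates a DNA paired-end-tag (DNA-PET) experiment:
genomic fragments of 1-4 kb are "sequenced" from both ends with short tags
(2x35 bp or 2x50 bp), so that a fragment straddling a rearrangement junction
produces a discordantly mapping read pair.

Rearrangement junctions are modelled after the mechanics seen at the TP53
intron 1 hotspot in osteosarcoma:

* *junctional duplication* -- the same reference segment (tens to hundreds of
  bases) appears on **both** derivatives of a balanced event.  This is
  implemented as overhang fill-in: a double-strand break with long
  single-stranded overhangs is filled in on both products, so each derivative
  retains the overhang segment adjacent to its break.
* *net loss* -- a stretch of sequence spanning the break appears on neither
  derivative (the germline-inversion signature: an intron 1/exon 1 loss).
* *micro-homology / untemplated insertion* -- the classic small-scale NHEJ
  signatures at a single junction.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import truncnorm

__all__ = [
    "Genome",
    "JunctionPolicy",
    "TruthRecord",
    "LibraryModel",
    "Block",
    "Derivative",
    "PlantResult",
    "SimulatedPair",
    "revcomp",
    "make_reference",
    "plant_sv",
    "reference_haplotype",
    "simulate_mate_pairs",
    "simulate_cn_profile",
    "simulate_baf",
]

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

SV_TYPES = ("deletion", "inversion", "reciprocal_translocation", "inverted_insertion")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Genome:
    """A named collection of chromosomes (plain A/C/G/T strings)."""

    name: str
    chromosomes: dict[str, str]
    seed: int | None = None

    def __post_init__(self) -> None:
        for chrom, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {chrom!r} is empty")
            bad = set(seq) - set("ACGT")
            if bad:
                raise ValueError(
                    f"chromosome {chrom!r} contains non-ACGT characters: {sorted(bad)}"
                )

    def __len__(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())


@dataclass(frozen=True)
class JunctionPolicy:
    """Junction mechanics of a planted event.

    Exactly one mechanism class may be active: micro-homology, junctional
    duplication (possibly on both junctions of a balanced pair, hence the
    second length), untemplated insertion, or net loss.
    """

    microhomology_len: int = 0
    duplication_len: int = 0
    untemplated_len: int = 0
    net_loss: int = 0
    duplication_len_b: int = 0

    def __post_init__(self) -> None:
        for name in (
            "microhomology_len",
            "duplication_len",
            "untemplated_len",
            "net_loss",
            "duplication_len_b",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        active = [
            self.microhomology_len > 0,
            self.duplication_len > 0 or self.duplication_len_b > 0,
            self.untemplated_len > 0,
            self.net_loss > 0,
        ]
        if sum(active) > 1:
            raise ValueError(
                "at most one junction mechanism (micro-homology, duplication, "
                "untemplated insertion, net loss) may be set per event"
            )


@dataclass
class TruthRecord:
    """A planted SV with its junction mechanics; the ground truth record.

    ``locus_a``/``locus_b`` are ``(chrom, start, end)`` 0-based half-open.
    For translocations the breakpoint is ``start`` (a 1 bp interval is used);
    for an inverted insertion ``locus_a`` is the acceptor point and
    ``locus_b`` the donor segment.  ``one_sided`` restricts a reciprocal
    translocation to a single derivative ("left" keeps locus-A sequence left
    of the break, "right" keeps the right side) -- used for complex loci where
    independent clones each carry only one junction.
    """

    sv_type: str
    locus_a: tuple[str, int, int]
    locus_b: tuple[str, int, int] | None = None
    policy: JunctionPolicy = field(default_factory=JunctionPolicy)
    haplotype: int = 0
    sample: str = "S"
    one_sided: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        for locus in (self.locus_a, self.locus_b):
            if locus is not None and not locus[1] < locus[2]:
                raise ValueError(f"locus start must be < end, got {locus}")
        if self.sv_type in ("deletion", "inversion"):
            if self.locus_b is not None:
                raise ValueError(f"{self.sv_type} takes a single locus")
        else:
            if self.locus_b is None:
                raise ValueError(f"{self.sv_type} requires locus_b")
        if self.sv_type == "reciprocal_translocation":
            if self.locus_a[0] == self.locus_b[0]:
                raise ValueError("translocation loci must be on different chromosomes")
        if self.one_sided not in (None, "left", "right"):
            raise ValueError("one_sided must be None, 'left' or 'right'")
        if self.one_sided is not None and self.sv_type != "reciprocal_translocation":
            raise ValueError("one_sided applies to reciprocal_translocation only")
        if self.policy.net_loss and self.sv_type == "deletion":
            raise ValueError("net_loss is only meaningful for balanced event pairs")


@dataclass(frozen=True)
class LibraryModel:
    """Mate-pair library parameters (fragment-size law and tag reads)."""

    frag_min: int = 1000
    frag_max: int = 4000
    frag_mean: float = 3000.0
    frag_sd: float = 300.0
    read_len: int = 50
    error_rate: float = 0.0
    concordant_orientation: str = "inward"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.frag_min <= self.frag_mean <= self.frag_max):
            raise ValueError("require frag_min <= frag_mean <= frag_max")
        if not (0 <= self.error_rate < 0.1):
            raise ValueError("error_rate must be in [0, 0.1)")
        if self.read_len >= self.frag_min:
            raise ValueError("read_len must be shorter than frag_min")
        if self.concordant_orientation not in ("inward", "same-strand"):
            raise ValueError("orientation must be 'inward' or 'same-strand'")


@dataclass(frozen=True)
class Block:
    """One colinear piece of a derivative: derivative interval -> reference.

    ``chrom`` is None for untemplated (non-reference) sequence.  For strand
    '-' the derivative piece reads the reference interval right-to-left,
    complemented.
    """

    der_start: int
    der_end: int
    chrom: str | None
    ref_start: int
    ref_end: int
    strand: str


@dataclass
class Derivative:
    """A derivative haplotype sequence with its reference block map."""

    name: str
    seq: str
    blocks: list[Block]

    def junction_positions(self) -> list[int]:
        """Derivative coordinates of the block boundaries (the junctions)."""
        return [b.der_end for b in self.blocks[:-1]]

    def junction_window(self, index: int, flank: int) -> str:
        """Sequence of +-``flank`` bases around the ``index``-th junction.

        This is the in-silico analogue of a breakpoint-spanning Sanger
        amplicon, the substrate for junction-sequence analysis.
        """
        pos = self.junction_positions()[index]
        return self.seq[max(0, pos - flank) : pos + flank]

    def map_interval(self, start: int, end: int) -> tuple[str, int, int, str] | None:
        """Map a derivative interval to reference coordinates.

        Returns None when the interval crosses a junction or lies in
        untemplated sequence (a real aligner would clip or fail there).
        """
        i = bisect_right([b.der_start for b in self.blocks], start) - 1
        if i < 0:
            return None
        b = self.blocks[i]
        if end > b.der_end or b.chrom is None:
            return None
        off_s, off_e = start - b.der_start, end - b.der_start
        if b.strand == "+":
            return (b.chrom, b.ref_start + off_s, b.ref_start + off_e, "+")
        return (b.chrom, b.ref_end - off_e, b.ref_end - off_s, "-")


@dataclass
class PlantResult:
    derivatives: list[Derivative]
    truth: TruthRecord
    genome: Genome  # identical to the input unless micro-homology was engineered


# ---------------------------------------------------------------------------
# reference generation


def make_reference(
    n_chromosomes: int,
    lengths: list[int],
    gc: float,
    seed: int,
    name: str = "synthetic",
    chrom_names: list[str] | None = None,
) -> Genome:
    """Generate a random reference genome with the requested GC content.

    Deterministic for a fixed seed; chromosomes are named chr1..chrN unless
    ``chrom_names`` is given.
    """
    if n_chromosomes != len(lengths):
        raise ValueError("lengths must have one entry per chromosome")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    for L in lengths:
        if L <= 0:
            raise ValueError("chromosome lengths must be positive")
    names = chrom_names or [f"chr{i + 1}" for i in range(n_chromosomes)]
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    chroms = {
        nm: rng.choice(alphabet, size=L, p=p).tobytes().decode("ascii")
        for nm, L in zip(names, lengths)
    }
    return Genome(name=name, chromosomes=chroms, seed=seed)


def reference_haplotype(genome: Genome, chrom: str, name: str | None = None) -> Derivative:
    """An unrearranged haplotype of one reference chromosome."""
    seq = genome.chromosomes[chrom]
    return Derivative(
        name=name or chrom,
        seq=seq,
        blocks=[Block(0, len(seq), chrom, 0, len(seq), "+")],
    )


# ---------------------------------------------------------------------------
# SV planting


class _Assembler:
    def __init__(self, name: str) -> None:
        self.name = name
        self._parts: list[str] = []
        self._blocks: list[Block] = []
        self._pos = 0

    def add(self, seq: str, chrom: str | None, ref_start: int, ref_end: int, strand: str) -> None:
        if not seq:
            return
        self._parts.append(seq)
        self._blocks.append(
            Block(self._pos, self._pos + len(seq), chrom, ref_start, ref_end, strand)
        )
        self._pos += len(seq)

    def build(self) -> Derivative:
        return Derivative(self.name, "".join(self._parts), self._blocks)


def _engineer_microhomology(genome: Genome, rec: TruthRecord) -> Genome:
    """Rewrite the partner-side flank so the junction split point is ambiguous.

    For micro-homology of length m the m bases on the far side of the second
    break are set equal to the m bases preceding the first break, so that an
    exact analyzer genuinely cannot place the junction more precisely than an
    m-base interval.
    """
    m = rec.policy.microhomology_len
    chroms = dict(genome.chromosomes)
    ca, a = rec.locus_a[0], rec.locus_a[1]
    left = chroms[ca][a - m : a]
    if rec.sv_type == "deletion":
        s, e = rec.locus_a[1], rec.locus_a[2]
        left = chroms[ca][s - m : s]
        chroms[ca] = chroms[ca][: e - m] + left + chroms[ca][e :]
    elif rec.sv_type == "inversion":
        s, e = rec.locus_a[1], rec.locus_a[2]
        left = chroms[ca][s - m : s]
        # sequence following junction 1 continues on the minus strand from e
        chroms[ca] = chroms[ca][:e] + revcomp(left) + chroms[ca][e + m :]
    elif rec.sv_type == "reciprocal_translocation":
        cb, b = rec.locus_b[0], rec.locus_b[1]
        chroms[cb] = chroms[cb][: b - m] + left + chroms[cb][b:]
    else:  # inverted_insertion: junction 1 joins acceptor-left to donor top (minus)
        cb, de = rec.locus_b[0], rec.locus_b[2]
        chroms[cb] = chroms[cb][:de] + revcomp(left) + chroms[cb][de + m :]
    return Genome(genome.name, chroms, genome.seed)


def _build_derivatives(genome: Genome, rec: TruthRecord, ins: str) -> list[Derivative]:
    pol = rec.policy
    ca, sa, ea = rec.locus_a
    chroms = genome.chromosomes
    A = chroms[ca]
    name = rec.name or f"{rec.sample}_{rec.sv_type}"
    derivs: list[Derivative] = []

    if rec.sv_type == "deletion":
        s, e = sa, ea
        asm = _Assembler(f"{name}_der")
        asm.add(A[:s], ca, 0, s, "+")
        asm.add(ins, None, 0, len(ins), "+")
        asm.add(A[e:], ca, e, len(A), "+")
        derivs.append(asm.build())

    elif rec.sv_type == "inversion":
        s, e = sa, ea
        g = pol.net_loss
        d = pol.duplication_len
        db = pol.duplication_len_b
        if g >= e - s:
            raise ValueError("net_loss exceeds inverted segment")
        asm = _Assembler(f"{name}_der")
        asm.add(A[: s + d], ca, 0, s + d, "+")
        asm.add(ins, None, 0, len(ins), "+")
        asm.add(revcomp(A[s + g : e]), ca, s + g, e, "-")
        asm.add(A[e - db :], ca, e - db, len(A), "+")
        derivs.append(asm.build())

    elif rec.sv_type == "reciprocal_translocation":
        cb, sb, _ = rec.locus_b
        B = chroms[cb]
        a, b = sa, sb
        g = pol.net_loss
        if rec.one_sided in (None, "left"):
            asm = _Assembler(f"{name}_der1")
            asm.add(A[: a + pol.duplication_len], ca, 0, a + pol.duplication_len, "+")
            asm.add(ins, None, 0, len(ins), "+")
            asm.add(B[b:], cb, b, len(B), "+")
            derivs.append(asm.build())
        if rec.one_sided in (None, "right"):
            asm = _Assembler(f"{name}_der2")
            asm.add(B[: b + pol.duplication_len_b], cb, 0, b + pol.duplication_len_b, "+")
            asm.add(A[a + g :], ca, a + g, len(A), "+")
            derivs.append(asm.build())

    else:  # inverted_insertion
        cb, ds, de = rec.locus_b
        B = chroms[cb]
        a = sa
        t = pol.duplication_len  # acceptor-site duplication shared by both junctions
        asm = _Assembler(f"{name}_der")
        asm.add(A[: a + t], ca, 0, a + t, "+")
        asm.add(ins, None, 0, len(ins), "+")
        asm.add(revcomp(B[ds:de]), cb, ds, de, "-")
        asm.add(A[a:], ca, a, len(A), "+")
        derivs.append(asm.build())

    return derivs


def _sharpen_edits(genome: Genome, rec: TruthRecord, derivs: list[Derivative]) -> list[tuple[str, int, str]]:
    """Reference edits removing chance sequence identity at junction boundaries.

    A random reference can, with probability 1/4 per boundary, continue past a
    junction with the same base the derivative carries there, which would make
    the planted junction mechanics (duplication length, micro-homology, blunt
    ends) ambiguous by a base or two for any exact analyzer.  For each
    junction the base where the expected match must stop is forced to differ.
    Returns (chrom, pos, new_base) edits; positions adjacent to an engineered
    micro-homology are checked one base beyond the homology so the engineered
    signal itself is preserved.
    """
    edits: list[tuple[str, int, str]] = []

    def pick_base(current: str, *forbidden: str) -> str:
        for b in "ACGT":
            if b != current and b not in forbidden:
                return b
        raise AssertionError("unreachable")

    def ref_base(chrom: str, pos: int) -> str | None:
        seq = genome.chromosomes[chrom]
        if 0 <= pos < len(seq):
            return seq[pos]
        return None

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    m = rec.policy.microhomology_len

    def expected(d_idx: int, j_idx: int, n_junctions: int, direction: str) -> int:
        # a balanced event genuinely carries its micro-homology at both
        # junctions; where it shows up depends on the construction geometry
        if m == 0:
            return 0
        if direction == "backward":
            if j_idx == 0:
                return m
        else:  # forward
            if rec.sv_type == "inversion" and j_idx == n_junctions - 1 and j_idx > 0:
                return m
        return 0

    for d_idx, der in enumerate(derivs):
        n_j = len(der.blocks) - 1
        for j_idx, (left, right) in enumerate(zip(der.blocks, der.blocks[1:])):
            p = left.der_end
            # forward: the left block's reference continuation must stop
            # matching the derivative right at the expected homology length
            if left.chrom is not None:
                mf = expected(d_idx, j_idx, n_j, "forward")
                if p + mf < len(der.seq):
                    nxt = der.seq[p + mf]
                    if left.strand == "+":
                        pos, want_neq = left.ref_end + mf, nxt
                    else:
                        pos, want_neq = left.ref_start - 1 - mf, comp[nxt]
                    cur = ref_base(left.chrom, pos)
                    if cur is not None and cur == want_neq:
                        edits.append((left.chrom, pos, pick_base(cur, want_neq)))
            # backward: the reference context preceding the right block must
            # stop matching the derivative after the expected homology
            if right.chrom is not None:
                mb = expected(d_idx, j_idx, n_j, "backward")
                if p - 1 - mb >= 0:
                    prev = der.seq[p - 1 - mb]
                    if right.strand == "+":
                        pos, want_neq = right.ref_start - 1 - mb, prev
                    else:
                        pos, want_neq = right.ref_end + mb, comp[prev]
                    cur = ref_base(right.chrom, pos)
                    if cur is not None and cur == want_neq:
                        edits.append((right.chrom, pos, pick_base(cur, want_neq)))
    return edits


def plant_sv(
    genome: Genome, rec: TruthRecord, seed: int | None = None, sharpen: bool = True
) -> PlantResult:
    """Build the derivative haplotype(s) realizing a planted SV.

    Returns the derivatives (with block maps back to reference coordinates),
    the realized truth record and the genome.  The returned genome differs
    from the input when a micro-homology policy required engineering the
    partner flank, or when junction sharpening (on by default) edited single
    reference bases adjacent to a junction so that the planted mechanics are
    exactly recoverable rather than blurred by chance one-base identity.
    """
    pol = rec.policy
    ca, sa, ea = rec.locus_a
    if ca not in genome.chromosomes:
        raise ValueError(f"unknown chromosome {ca!r}")
    if ea > len(genome.chromosomes[ca]) or sa < 0:
        raise ValueError("locus_a outside chromosome bounds")
    if rec.locus_b is not None:
        cb, sb, eb = rec.locus_b
        if cb not in genome.chromosomes:
            raise ValueError(f"unknown chromosome {cb!r}")
        if eb > len(genome.chromosomes[cb]) or sb < 0:
            raise ValueError("locus_b outside chromosome bounds")
        if cb == ca and not (eb <= sa or ea <= sb):
            raise ValueError("event loci overlap")

    rng = np.random.default_rng(seed if seed is not None else genome.seed)
    ins = (
        "".join(rng.choice(list("ACGT"), size=pol.untemplated_len))
        if pol.untemplated_len
        else ""
    )

    # one edit per round: simultaneous edits at a reciprocal junction could
    # re-create each other's conflict and oscillate.  The engineered homology
    # is re-synchronized every round because an edit may touch its source.
    for _ in range(64):
        if pol.microhomology_len:
            genome = _engineer_microhomology(genome, rec)
        derivs = _build_derivatives(genome, rec, ins)
        if not sharpen:
            break
        edits = _sharpen_edits(genome, rec, derivs)
        if not edits:
            break
        chrom, pos, base = edits[0]
        chroms = dict(genome.chromosomes)
        chroms[chrom] = chroms[chrom][:pos] + base + chroms[chrom][pos + 1 :]
        genome = Genome(genome.name, chroms, genome.seed)
    else:  # pragma: no cover - each edit resolves one boundary for good
        raise RuntimeError("junction sharpening did not converge")

    return PlantResult(derivatives=derivs, truth=rec, genome=genome)


def plant_all(
    genome: Genome, recs: list[TruthRecord], seed: int | None = None, sharpen: bool = True
) -> tuple[Genome, list[PlantResult]]:
    """Plant several events on one genome, chaining any reference edits.

    Runs two passes so that every derivative is rebuilt against the final
    (possibly sharpened) reference; edits are single junction-adjacent bases,
    so the second pass is a fixed point.
    """
    results: list[PlantResult] = []
    for _ in range(2):
        results = []
        g = genome
        for i, rec in enumerate(recs):
            res = plant_sv(g, rec, seed=None if seed is None else seed + i, sharpen=sharpen)
            g = res.genome
            results.append(res)
        genome = g
    return genome, results


# ---------------------------------------------------------------------------
# mate-pair simulation


@dataclass
class SimulatedPair:
    """One simulated mate pair: tag sequences plus true reference placement.

    ``end_a``/``end_b`` are ``(chrom, start, end, strand)`` in reference
    coordinates, or None when the read crosses a planted junction (an aligner
    would not place it as a simple match).
    """

    pair_id: str
    read1: str
    read2: str
    end_a: tuple[str, int, int, str] | None
    end_b: tuple[str, int, int, str] | None
    haplotype: str
    frag_start: int
    frag_len: int


def _apply_errors(read: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return read
    n = rng.binomial(len(read), error_rate)
    if n == 0:
        return read
    pos = rng.choice(len(read), size=n, replace=False)
    out = list(read)
    for p in pos:
        out[p] = rng.choice([c for c in "ACGT" if c != out[p]])
    return "".join(out)


def simulate_mate_pairs(
    haplotypes: list[Derivative] | list[tuple[Derivative, float]],
    model: LibraryModel,
    coverage: float,
    seed: int | None = None,
    sample: str = "S",
) -> list[SimulatedPair]:
    """Simulate a mate-pair library at the given physical coverage.

    ``haplotypes`` may carry per-haplotype weights (default 1); sampling is
    proportional to weight x length so each unit-weight haplotype receives the
    full physical coverage.  Fragment lengths follow a truncated normal on
    [frag_min, frag_max].  Emits ceil(coverage x total_length / frag_mean)
    pairs.
    """
    haps: list[tuple[Derivative, float]] = [
        h if isinstance(h, tuple) else (h, 1.0) for h in haplotypes
    ]
    for d, _ in haps:
        if len(d.seq) <= model.frag_max:
            raise ValueError(f"haplotype {d.name!r} shorter than frag_max")
    rng = np.random.default_rng(seed if seed is not None else model.seed)
    total_len = sum(len(d.seq) for d, _ in haps)
    n_pairs = math.ceil(coverage * total_len / model.frag_mean)

    w = np.array([len(d.seq) * wt for d, wt in haps], dtype=float)
    hap_idx = rng.choice(len(haps), size=n_pairs, p=w / w.sum())
    lo = (model.frag_min - model.frag_mean) / model.frag_sd
    hi = (model.frag_max - model.frag_mean) / model.frag_sd
    frag_lens = (
        truncnorm.rvs(lo, hi, loc=model.frag_mean, scale=model.frag_sd, size=n_pairs, random_state=rng)
        .round()
        .astype(int)
        .clip(model.frag_min, model.frag_max)
    )
    starts = rng.random(n_pairs)

    rl = model.read_len
    pairs: list[SimulatedPair] = []
    for i in range(n_pairs):
        der, _ = haps[hap_idx[i]]
        f = int(frag_lens[i])
        x = int(starts[i] * (len(der.seq) - f + 1))
        read1 = der.seq[x : x + rl]
        tail = der.seq[x + f - rl : x + f]
        read2 = revcomp(tail) if model.concordant_orientation == "inward" else tail
        read1 = _apply_errors(read1, rng, model.error_rate)
        read2 = _apply_errors(read2, rng, model.error_rate)

        m1 = der.map_interval(x, x + rl)
        m2 = der.map_interval(x + f - rl, x + f)
        # read1 sequenced on the derivative plus strand, read2 on the minus
        # strand (inward) or plus strand (same-strand chemistry)
        end_a = m1
        end_b = None
        if m2 is not None:
            c, s, e, blk_strand = m2
            der_read_strand = "-" if model.concordant_orientation == "inward" else "+"
            strand = blk_strand if der_read_strand == "+" else ("-" if blk_strand == "+" else "+")
            end_b = (c, s, e, strand)
        pairs.append(
            SimulatedPair(
                pair_id=f"{sample}:{i}",
                read1=read1,
                read2=read2,
                end_a=end_a,
                end_b=end_b,
                haplotype=der.name,
                frag_start=x,
                frag_len=f,
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# array-track simulation


def simulate_cn_profile(
    segments: list[tuple[int, int, float]],
    probe_spacing: int,
    noise_sd: float,
    seed: int,
):
    """Probe-level log2-ratio track for a piecewise-constant copy-number state.

    ``segments`` are contiguous, non-overlapping ``(start, end, copy_number)``
    intervals; probes are placed every ``probe_spacing`` bases and report
    log2(cn/2) plus Gaussian noise.  Returns a DataFrame with columns
    ``pos``/``log2``.
    """
    import pandas as pd

    if not segments:
        raise ValueError("need at least one segment")
    for (s, e, cn) in segments:
        if cn < 0:
            raise ValueError("copy_number must be >= 0")
        if e <= s:
            raise ValueError("segment start must be < end")
    for prev, cur in zip(segments, segments[1:]):
        if cur[0] != prev[1]:
            raise ValueError("segments must be contiguous (no gaps, no overlap)")
    rng = np.random.default_rng(seed)
    pos = np.arange(segments[0][0], segments[-1][1], probe_spacing)
    bounds = np.array([s for s, _, _ in segments] + [segments[-1][1]])
    cn = np.array([c for _, _, c in segments], dtype=float)
    idx = np.searchsorted(bounds, pos, side="right") - 1
    # floor zero copies at a small positive value so log2 stays finite
    log2 = np.log2(np.maximum(cn[idx], 0.05) / 2.0)
    if noise_sd > 0:
        log2 = log2 + rng.normal(0.0, noise_sd, size=len(pos))
    return pd.DataFrame({"pos": pos, "log2": log2})


def simulate_baf(
    n_snps: int,
    state: str,
    purity: float,
    noise_sd: float,
    seed: int,
    spacing: int = 1000,
    start: int = 0,
):
    """B-allele-fraction track for heterozygous SNPs under a zygosity state.

    States: ``het-normal`` (BAF centred at 0.5), ``cn-neutral-LOH`` (one
    parental haplotype duplicated, the other lost; BAF centres mix linearly
    with tumor purity towards 0/1), ``deletion-LOH`` (hemizygous loss; centres
    follow the copy-number-weighted allele fractions).  Returns a DataFrame
    with columns ``pos``/``baf``.
    """
    import pandas as pd

    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    if state not in ("het-normal", "cn-neutral-LOH", "deletion-LOH"):
        raise ValueError(f"unknown state {state!r}")
    rng = np.random.default_rng(seed)
    pos = start + spacing * np.arange(n_snps)
    if state == "het-normal":
        centers = np.full(n_snps, 0.5)
    else:
        b_is_kept = rng.integers(0, 2, size=n_snps).astype(bool)
        if state == "cn-neutral-LOH":
            hi, lo = purity * 1.0 + (1 - purity) * 0.5, purity * 0.0 + (1 - purity) * 0.5
        else:  # hemizygous deletion at the given purity
            hi, lo = 1.0 / (2.0 - purity), (1.0 - purity) / (2.0 - purity)
        centers = np.where(b_is_kept, hi, lo)
    baf = centers + (rng.normal(0.0, noise_sd, size=n_snps) if noise_sd > 0 else 0.0)
    return pd.DataFrame({"pos": pos, "baf": np.clip(baf, 0.0, 1.0)})
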