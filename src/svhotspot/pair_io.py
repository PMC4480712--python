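"""Readers and writers for the formats the pipeline touches.

FASTA goes through Biopython, SAM through pysam; BEDPE/BED and the probe and
BAF tracks are plain tab-separated text.  SAM positions (1-based) are
converted to the internal 0-based half-open convention at ingest, and mate
pairs are normalized into :class:`ReadPairAlignment` with the two ends in
coordinate order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome_forge import (
    Derivative,
    Genome,
    JunctionPolicy,
    SimulatedPair,
    TruthRecord,
    revcomp,
)

__all__ = [
    "End",
    "ReadPairAlignment",
    "IngestStats",
    "read_fasta",
    "write_fasta",
    "write_derivatives_fasta",
    "read_pairs_sam",
    "write_sam",
    "write_fastq",
    "write_bedpe",
    "read_bedpe",
    "read_bed",
    "write_track",
    "read_track",
]

DEFAULT_MAPQ_FLOOR = 10


@dataclass(frozen=True)
class End:
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"end interval inverted: {self}")


@dataclass(frozen=True)
class ReadPairAlignment:
    """One mate pair's two mapped ends, in coordinate order (end_a <= end_b)."""

    pair_id: str
    end_a: End
    end_b: End
    sample: str = "S"
    mapq: int | None = None


@dataclass
class IngestStats:
    pairs: int = 0
    orphans: int = 0
    dropped_unmapped: int = 0
    dropped_low_mapq: int = 0


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str, name: str | None = None) -> Genome:
    """Read a FASTA file into a :class:`Genome` (uppercased, A/C/G/T only).

    A non-ACGT character raises with the record name and offset; duplicate
    record names and empty records are rejected.
    """
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in chroms:
            raise ValueError(f"duplicate sequence name {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty record {rec.id!r}")
        for i, c in enumerate(seq):
            if c not in "ACGT":
                raise ValueError(f"non-ACGT character {c!r} in record {rec.id!r} at offset {i}")
        chroms[rec.id] = seq
    if not chroms:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(name=name or path, chromosomes=chroms)


def write_fasta(genome: Genome, path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.chromosomes.items()
    ]
    SeqIO.write(records, path, "fasta")


def write_derivatives_fasta(derivatives: list[Derivative], path: str) -> None:
    records = [SeqRecord(Seq(d.seq), id=d.name, description="") for d in derivatives]
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------------------
# SAM


def _sam_header(genome: Genome) -> dict:
    return {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in genome.chromosomes.items()],
    }


def write_sam(pairs: list[SimulatedPair], genome: Genome, path: str, sample: str = "S") -> None:
    """Write simulated pairs as a name-paired SAM file (mandatory fields only).

    Reads that crossed a planted junction are written as unmapped records so
    that ingest treats the pair as an orphan, mimicking an aligner's failure
    to place them as simple matches.
    """
    header = pysam.AlignmentHeader.from_dict(_sam_header(genome))
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for p in pairs:
            for which, (seq, end, mate_end) in enumerate(
                [(p.read1, p.end_a, p.end_b), (p.read2, p.end_b, p.end_a)]
            ):
                a = pysam.AlignedSegment(header)
                a.query_name = p.pair_id
                flag = 0x1 | (0x40 if which == 0 else 0x80)
                if end is None:
                    flag |= 0x4
                else:
                    if end[3] == "-":
                        flag |= 0x10
                if mate_end is None:
                    flag |= 0x8
                elif mate_end[3] == "-":
                    flag |= 0x20
                a.flag = flag
                if end is not None:
                    a.reference_name = end[0]
                    a.reference_start = end[1]
                    a.mapping_quality = 60
                    a.cigarstring = f"{len(seq)}M"
                    a.query_sequence = seq if end[3] == "+" else revcomp(seq)
                else:
                    a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                if mate_end is not None:
                    a.next_reference_name = mate_end[0]
                    a.next_reference_start = mate_end[1]
                out.write(a)


def read_pairs_sam(
    path: str,
    sample: str = "S",
    mapq_floor: int = DEFAULT_MAPQ_FLOOR,
    library_orientation: str = "inward",
) -> tuple[list[ReadPairAlignment], IngestStats]:
    """Ingest a name-paired SAM into normalized pair records.

    Secondary and supplementary records are ignored; pairs with an unmapped
    end are counted and dropped, as are pairs below the mapq floor.  With
    ``library_orientation='same-strand'`` (SOLiD mate-pair chemistry) the
    second read's strand is flipped so that downstream classification can
    assume a single inward convention.
    """
    stats = IngestStats()
    pending: dict[str, tuple[End | None, int]] = {}
    pairs: list[ReadPairAlignment] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_unmapped:
                end = None
            else:
                end = End(
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                )
                if library_orientation == "same-strand" and rec.is_read2:
                    end = replace(end, strand="-" if end.strand == "+" else "+")
            mapq = rec.mapping_quality if not rec.is_unmapped else 0
            if rec.query_name not in pending:
                pending[rec.query_name] = (end, mapq)
                continue
            other_end, other_mapq = pending.pop(rec.query_name)
            if end is None or other_end is None:
                stats.dropped_unmapped += 1
                continue
            mq = min(mapq, other_mapq)
            if mq < mapq_floor:
                stats.dropped_low_mapq += 1
                continue
            e1, e2 = other_end, end
            if (e2.chrom, e2.start) < (e1.chrom, e1.start):
                e1, e2 = e2, e1
            pairs.append(
                ReadPairAlignment(pair_id=rec.query_name, end_a=e1, end_b=e2, sample=sample, mapq=mq)
            )
            stats.pairs += 1
    stats.orphans = len(pending)
    return pairs, stats


def write_fastq(pairs: list[SimulatedPair], path: str) -> None:
    """Interleaved FASTQ of the raw tag reads (as sequenced)."""
    with open(path, "w") as fh:
        for p in pairs:
            for i, seq in enumerate([p.read1, p.read2], start=1):
                fh.write(f"@{p.pair_id}/{i}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# BEDPE

_BEDPE_ABSENT = (".", -1, -1)


def _truth_to_bedpe(rec: TruthRecord) -> list[str]:
    ca, sa, ea = rec.locus_a
    cb, sb, eb = rec.locus_b if rec.locus_b is not None else _BEDPE_ABSENT
    pol = rec.policy
    extras = (
        f"sv_type={rec.sv_type};mh={pol.microhomology_len};dup={pol.duplication_len};"
        f"dup_b={pol.duplication_len_b};unt={pol.untemplated_len};loss={pol.net_loss};"
        f"haplotype={rec.haplotype};one_sided={rec.one_sided or '.'}"
    )
    return [
        ca,
        str(sa),
        str(ea),
        str(cb),
        str(sb),
        str(eb),
        rec.name or f"{rec.sample}_{rec.sv_type}",
        "0",
        "+",
        "-",
        rec.sample,
        extras,
    ]


def _truth_from_bedpe(fields: list[str]) -> TruthRecord:
    kv = dict(item.split("=", 1) for item in fields[11].split(";"))
    locus_b = None
    if fields[3] != ".":
        locus_b = (fields[3], int(fields[4]), int(fields[5]))
    one_sided = kv.get("one_sided", ".")
    return TruthRecord(
        sv_type=kv["sv_type"],
        locus_a=(fields[0], int(fields[1]), int(fields[2])),
        locus_b=locus_b,
        policy=JunctionPolicy(
            microhomology_len=int(kv["mh"]),
            duplication_len=int(kv["dup"]),
            untemplated_len=int(kv["unt"]),
            net_loss=int(kv["loss"]),
            duplication_len_b=int(kv["dup_b"]),
        ),
        haplotype=int(kv["haplotype"]),
        sample=fields[10],
        one_sided=None if one_sided == "." else one_sided,
        name=fields[6],
    )


def write_bedpe(records, path: str) -> None:
    """Write TruthRecords or SVCalls as BEDPE (10 standard + extension columns)."""
    from .dpet_caller import SVCall  # local import to avoid a cycle

    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, TruthRecord):
                fields = _truth_to_bedpe(rec)
            elif isinstance(rec, SVCall):
                fields = rec.to_bedpe_fields()
            else:
                raise TypeError(f"cannot serialize {type(rec).__name__} to BEDPE")
            fh.write("\t".join(fields) + "\n")


def read_bedpe(path: str):
    """Read a BEDPE written by :func:`write_bedpe` (truth or call dialect)."""
    from .dpet_caller import SVCall

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected >= 12 BEDPE columns")
            if fields[3] != "." and int(fields[4]) >= int(fields[5]):
                raise ValueError(f"{path}:{lineno}: inverted interval on side B")
            if int(fields[1]) >= int(fields[2]):
                raise ValueError(f"{path}:{lineno}: inverted interval on side A")
            if fields[11].startswith("sv_type="):
                out.append(_truth_from_bedpe(fields))
            else:
                out.append(SVCall.from_bedpe_fields(fields))
    return out


# ---------------------------------------------------------------------------
# BED and TSV tracks


def read_bed(path: str) -> list[tuple[str, int, int, str]]:
    """Minimal BED reader: (chrom, start, end, name) per interval."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            start, end = int(f[1]), int(f[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            out.append((f[0], start, end, f[3] if len(f) > 3 else f"region{lineno}"))
    return out


def write_track(df, path: str, value_col: str) -> None:
    df[["pos", value_col]].to_csv(path, sep="\t", index=False)


def read_track(path: str):
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if "pos" not in df.columns or df.shape[1] < 2:
        raise ValueError(f"{path}: expected a 'pos' column plus one value column")
    return df
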