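"""Input layer: reference FASTA, SAM/BAM alignments and BED regions.

All coordinates are 0-based half-open internally; 1-based coordinates
appear only at the VCF boundary and on the command line.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pysam
from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "Reference",
    "AlignedSequence",
    "load_reference",
    "load_alignments",
    "load_bed",
    "write_sam",
]

_VALID_BASES = set("ACGTN")

# CIGAR ops we keep. "=", "X" are normalized to M on ingest; hard clips are
# dropped (they consume neither query nor reference as stored).
_QUERY_OPS = {"M", "I", "S"}
_REF_OPS = {"M", "D"}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval on a named contig (0-based start, exclusive end)."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, contig: str, pos: int) -> bool:
        return contig == self.contig and self.start <= pos < self.end


class Reference:
    """In-memory linear reference: contig name -> uppercase sequence."""

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("reference has no contigs")
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"contig {name!r} contains non-nucleotide characters: "
                    f"{sorted(bad)}"
                )
            self._seqs[name] = seq

    @property
    def contigs(self) -> list[str]:
        return list(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    def __contains__(self, contig: str) -> bool:
        return contig in self._seqs

    def sequence(self, contig: str) -> str:
        return self._seqs[contig]

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Sequence of an in-bounds interval; length is always end - start."""
        seq = self._seqs[contig]
        if start < 0 or end > len(seq) or start >= end:
            raise ValueError(
                f"interval {contig}:{start}-{end} out of bounds "
                f"(contig length {len(seq)})"
            )
        return seq[start:end]

    def fetch_interval(self, interval: GenomicInterval) -> str:
        return self.fetch(interval.contig, interval.start, interval.end)


@dataclass
class AlignedSequence:
    """A read or haplotype contig aligned to the linear reference.

    ``origin`` distinguishes sample reads from pangenome haplotypes; for
    haplotypes the quality and strand attributes are legitimately absent.
    """

    name: str
    contig: str
    start: int  # 0-based leftmost reference position
    cigar: tuple[tuple[str, int], ...]
    bases: str
    base_qualities: Optional[tuple[int, ...]] = None
    mapping_quality: Optional[int] = None
    strand: Optional[str] = None  # "+", "-" or None
    origin: str = "read"  # "read" | "haplotype"

    def __post_init__(self) -> None:
        qlen = sum(n for op, n in self.cigar if op in _QUERY_OPS)
        if qlen != len(self.bases):
            raise ValueError(
                f"record {self.name!r}: CIGAR consumes {qlen} query bases "
                f"but sequence has {len(self.bases)}"
            )
        if self.base_qualities is not None and len(self.base_qualities) != len(
            self.bases
        ):
            raise ValueError(
                f"record {self.name!r}: {len(self.base_qualities)} qualities "
                f"for {len(self.bases)} bases"
            )
        for op, n in self.cigar:
            if op not in "MIDS" or n <= 0:
                raise ValueError(
                    f"record {self.name!r}: unsupported CIGAR element {op}{n}"
                )

    @property
    def end(self) -> int:
        """0-based exclusive rightmost reference position."""
        return self.start + sum(n for op, n in self.cigar if op in _REF_OPS)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.contig, self.start, self.end)

    def overlaps(self, interval: GenomicInterval) -> bool:
        return (
            self.contig == interval.contig
            and self.start < interval.end
            and interval.start < self.end
        )


def load_reference(path: str | os.PathLike) -> Reference:
    """Load a FASTA file; contig names are taken up to first whitespace."""
    path = os.fspath(path)
    with open(path) as fh:
        first = fh.readline()
        if first and not first.startswith((">", ";")):
            raise ValueError(
                f"malformed FASTA {path}: line 1 does not start a record: "
                f"{first.strip()!r}"
            )
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return Reference(seqs)


def _normalize_cigar(
    cigartuples: Sequence[tuple[int, int]], name: str
) -> tuple[tuple[str, int], ...]:
    # pysam op codes: 0=M 1=I 2=D 3=N 4=S 5=H 6=P 7== 8=X
    out: list[tuple[str, int]] = []
    for code, n in cigartuples:
        if code in (0, 7, 8):
            op = "M"
        elif code == 1:
            op = "I"
        elif code == 2:
            op = "D"
        elif code == 4:
            op = "S"
        elif code == 5:  # hard clip: absent sequence, drop
            continue
        else:
            raise ValueError(f"record {name!r}: unsupported CIGAR op code {code}")
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return tuple(out)


def _from_pysam(rec: pysam.AlignedSegment, origin: str) -> AlignedSequence:
    quals = rec.query_qualities
    return AlignedSequence(
        name=rec.query_name,
        contig=rec.reference_name,
        start=rec.reference_start,
        cigar=_normalize_cigar(rec.cigartuples or (), rec.query_name),
        bases=(rec.query_sequence or "").upper(),
        base_qualities=tuple(quals) if quals is not None else None,
        mapping_quality=rec.mapping_quality,
        strand="-" if rec.is_reverse else "+",
        origin=origin,
    )


def load_alignments(
    path: str | os.PathLike,
    region: Optional[GenomicInterval] = None,
    origin: str = "read",
) -> list[AlignedSequence]:
    """Load mapped primary records from a SAM/BAM file.

    Unmapped, secondary and supplementary records are excluded. With a
    ``region`` the file must be coordinate-sorted and indexed (BAM);
    records intersecting the region are returned in coordinate order.
    Mapping-quality-0 records are retained: they carry the mismapping
    signal this caller is designed to see through.
    """
    path = os.fspath(path)
    out: list[AlignedSequence] = []
    with pysam.AlignmentFile(path, check_sq=False) as af:
        if region is not None:
            try:
                af.check_index()
            except (ValueError, AttributeError, OSError) as exc:
                raise ValueError(
                    f"regional fetch from {path} requires a coordinate-sorted, "
                    f"indexed file: {exc}"
                ) from exc
            it: Iterable[pysam.AlignedSegment] = af.fetch(
                region.contig, region.start, region.end
            )
        else:
            it = af.fetch(until_eof=True)
        for rec in it:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            out.append(_from_pysam(rec, origin))
    return out


def load_bed(
    path: str | os.PathLike, with_labels: bool = False
) -> list[GenomicInterval] | list[tuple[GenomicInterval, str]]:
    """Parse a BED3(+) file into half-open intervals.

    With ``with_labels`` the 4th column is returned alongside each interval
    (used for labelled region partitions).
    """
    out: list = []
    with open(os.fspath(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"BED line {lineno}: fewer than 3 columns")
            contig, s, e = fields[0], int(fields[1]), int(fields[2])
            if s >= e:
                raise ValueError(
                    f"BED line {lineno}: start {s} >= end {e} ({line!r})"
                )
            iv = GenomicInterval(contig, s, e)
            if with_labels:
                if len(fields) < 4:
                    raise ValueError(f"BED line {lineno}: missing label column")
                out.append((iv, fields[3]))
            else:
                out.append(iv)
    return out


def write_sam(
    path: str | os.PathLike,
    reference: Reference,
    sequences: Iterable[AlignedSequence],
    sort: bool = True,
) -> None:
    """Write AlignedSequences as a SAM file with contig headers from the
    reference. Used by the simulator and for round-trip checks."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate" if sort else "unknown"},
        "SQ": [
            {"SN": name, "LN": length}
            for name, length in reference.lengths.items()
        ],
    }
    seqs = list(sequences)
    if sort:
        order = {name: i for i, name in enumerate(reference.contigs)}
        seqs.sort(key=lambda s: (order[s.contig], s.start, s.name))
    mode = "wb" if str(path).endswith(".bam") else "w"
    with pysam.AlignmentFile(os.fspath(path), mode, header=header) as out:
        for seq in seqs:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = seq.name
            rec.reference_name = seq.contig
            rec.reference_start = seq.start
            rec.cigarstring = "".join(f"{n}{op}" for op, n in seq.cigar)
            rec.query_sequence = seq.bases
            if seq.base_qualities is not None:
                rec.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in seq.base_qualities)
                )
            rec.mapping_quality = (
                seq.mapping_quality if seq.mapping_quality is not None else 255
            )
            rec.flag = 16 if seq.strand == "-" else 0
            out.write(rec)
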