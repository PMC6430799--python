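"""Lightweight alignment records and SAM text I/O.

The in-memory container is a plain dataclass so that coordinate transforms,
pileups and simulators can manipulate records without a file handle; pysam
handles the SAM boundary in :func:`read_sam` / :func:`write_sam`.
Coordinates are 0-based half-open internally (1-based only inside SAM text,
which pysam converts).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable

import pysam

# CIGAR operation classes
REF_CONSUMING = frozenset("MDN=X")
QUERY_CONSUMING = frozenset("MIS=X")
CLIP_OPS = frozenset("SH")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_OP_CODE = {op: i for i, op in enumerate("MIDNSHP=X")}
_CODE_OP = {i: op for op, i in _OP_CODE.items()}

Cigar = tuple[tuple[str, int], ...]


def parse_cigar(text: str) -> Cigar:
    ops = tuple((m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(text))
    if "".join(f"{n}{op}" for op, n in ops) != text:
        raise ValueError(f"malformed CIGAR {text!r}")
    return ops


def cigar_string(cigar: Cigar) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


def reference_span(cigar: Cigar) -> int:
    return sum(n for op, n in cigar if op in REF_CONSUMING)


def query_length(cigar: Cigar) -> int:
    return sum(n for op, n in cigar if op in QUERY_CONSUMING)


@dataclass
class Alignment:
    """One aligned (or unmapped) read, SAM-equivalent."""

    qname: str
    contig: str | None  # None = unmapped
    pos: int  # 0-based leftmost reference position
    mapq: int
    cigar: Cigar
    seq: str
    qual: str  # Phred+33
    strand: str = "+"  # storage strand of the aligned sequence
    mate: int = 0  # 1, 2, or 0 for unpaired
    mate_contig: str | None = None
    mate_pos: int = -1
    mate_strand: str | None = None
    tlen: int = 0
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seq and self.qual and len(self.seq) != len(self.qual):
            raise ValueError("sequence and quality lengths differ")
        if self.contig is not None and self.cigar and self.seq:
            qlen = query_length(self.cigar)
            if qlen != len(self.seq):
                raise ValueError(
                    f"CIGAR query length {qlen} inconsistent with sequence length {len(self.seq)}"
                )

    @property
    def is_mapped(self) -> bool:
        return self.contig is not None

    @property
    def is_paired(self) -> bool:
        return self.mate in (1, 2)

    @property
    def reference_span(self) -> int:
        return reference_span(self.cigar)

    @property
    def reference_end(self) -> int:
        return self.pos + self.reference_span

    def copy(self, **changes) -> "Alignment":
        return replace(self, **changes)


def _flag(a: Alignment) -> int:
    f = 0
    if a.is_paired:
        f |= 0x1 | (0x40 if a.mate == 1 else 0x80)
        if a.mate_contig is None:
            f |= 0x8
        if a.mate_strand == "-":
            f |= 0x20
    if not a.is_mapped:
        f |= 0x4
    if a.strand == "-":
        f |= 0x10
    return f


def sam_header(contig_lengths: dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": length} for name, length in contig_lengths.items()],
        }
    )


def to_pysam(a: Alignment, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = a.qname
    seg.flag = _flag(a)
    seg.reference_id = header.get_tid(a.contig) if a.contig else -1
    seg.reference_start = a.pos if a.is_mapped else -1
    seg.mapping_quality = a.mapq
    if a.is_mapped and a.cigar:
        seg.cigarstring = cigar_string(a.cigar)
    seg.next_reference_id = header.get_tid(a.mate_contig) if a.mate_contig else -1
    seg.next_reference_start = a.mate_pos if a.mate_contig else -1
    seg.template_length = a.tlen
    seg.query_sequence = a.seq or None
    if a.qual:
        seg.query_qualities = pysam.qualitystring_to_array(a.qual)
    for key, value in a.tags.items():
        seg.set_tag(key, value)
    return seg


def from_pysam(seg: pysam.AlignedSegment) -> Alignment:
    qual = (
        pysam.qualities_to_qualitystring(seg.query_qualities) if seg.query_qualities is not None else ""
    )
    cigar: Cigar = ()
    if seg.cigartuples:
        cigar = tuple((_CODE_OP[code], n) for code, n in seg.cigartuples)
    mate = 1 if seg.is_read1 else 2 if seg.is_read2 else 0
    return Alignment(
        qname=seg.query_name,
        contig=seg.reference_name if not seg.is_unmapped else None,
        pos=seg.reference_start if not seg.is_unmapped else -1,
        mapq=seg.mapping_quality,
        cigar=cigar,
        seq=seg.query_sequence or "",
        qual=qual,
        strand="-" if seg.is_reverse else "+",
        mate=mate if seg.is_paired else 0,
        mate_contig=seg.next_reference_name if seg.next_reference_id >= 0 else None,
        mate_pos=seg.next_reference_start,
        mate_strand=("-" if seg.mate_is_reverse else "+") if seg.is_paired else None,
        tlen=seg.template_length,
        tags=dict(seg.get_tags()),
    )


def write_sam(path: str, alignments: Iterable[Alignment], contig_lengths: dict[str, int]) -> None:
    header = sam_header(contig_lengths)
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for a in alignments:
            fh.write(to_pysam(a, header))


def read_sam(path: str) -> list[Alignment]:
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        return [from_pysam(seg) for seg in fh]
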