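"""Read- and alignment-level operations for chiral spike-in workflows.

After aligning a library to a combined fwd+rev genome index, reads from the
sample fall on fwd contigs and reads from chiral sequins on rev contigs, so
the two populations can be partitioned by contig namespace.  Chiral reads
are then either *flipped* (sequence order reversed, qualities kept paired
with their bases) for re-alignment to the fwd genome, or their alignments
are *transformed* directly into fwd coordinates.  Finally, chiral coverage
is downsampled to match the accompanying sample.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .alignment import Alignment
from .core import ContigPair, reverse_complement


@dataclass(frozen=True)
class ReadRecord:
    """An as-sequenced read: bases with per-base Phred+33 qualities."""

    id: str
    mate: int  # 1, 2, or 0 for unpaired
    bases: str
    quals: str
    stored_strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and quals lengths differ")


# ---------------------------------------------------------------------------
# partitioning


@dataclass
class PartitionResult:
    human: list[Alignment]
    chiral: list[Alignment]
    unmapped: list[Alignment]
    counts: dict[str, int] = field(default_factory=dict)
    cross_alignment: dict[str, float] | None = None

    @property
    def total(self) -> int:
        return len(self.human) + len(self.chiral) + len(self.unmapped)


def namespace_of(contig: str, table: dict[str, str] | None = None, suffix: str = "_rev") -> str:
    """Namespace (fwd/rev) of a contig, from an explicit table or the suffix."""
    if table is not None:
        if contig not in table:
            raise KeyError(f"contig {contig!r} not in contig table")
        return table[contig]
    return "rev" if contig.endswith(suffix) else "fwd"


def partition_alignments(
    records: Iterable[Alignment],
    table: dict[str, str] | None = None,
    suffix: str = "_rev",
    truth_tag: str = "XO",
) -> PartitionResult:
    """Bucket alignments by contig namespace: fwd -> human, rev -> chiral.

    Unmapped reads form a third bucket.  When records carry a truth-origin
    tag (the contig the read was simulated from), the per-origin
    cross-alignment fraction — mapped reads assigned to the wrong
    namespace — is reported.
    """
    human: list[Alignment] = []
    chiral: list[Alignment] = []
    unmapped: list[Alignment] = []
    origin_totals = {"fwd": 0, "rev": 0}
    origin_cross = {"fwd": 0, "rev": 0}
    any_truth = False
    for a in records:
        if not a.is_mapped:
            unmapped.append(a)
            continue
        ns = namespace_of(a.contig, table, suffix)
        (human if ns == "fwd" else chiral).append(a)
        if truth_tag in a.tags:
            any_truth = True
            true_ns = namespace_of(str(a.tags[truth_tag]), table, suffix)
            origin_totals[true_ns] += 1
            if ns != true_ns:
                origin_cross[true_ns] += 1
    counts = {"human": len(human), "chiral": len(chiral), "unmapped": len(unmapped)}
    cross = None
    if any_truth:
        cross = {
            ns: (origin_cross[ns] / origin_totals[ns]) if origin_totals[ns] else 0.0
            for ns in ("fwd", "rev")
        }
    return PartitionResult(human=human, chiral=chiral, unmapped=unmapped, counts=counts, cross_alignment=cross)


def cross_alignment_percent(misassigned: int, total: int) -> float:
    """Cross-alignment rate as a percentage (e.g. 133 of 732e6 -> 1.82e-5 %)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * misassigned / total


# ---------------------------------------------------------------------------
# flipping


def as_sequenced(a: Alignment) -> ReadRecord:
    """Recover the as-sequenced read from an alignment record.

    Reverse-strand storage is undone by reverse-complementing the bases and
    reversing the qualities.
    """
    if a.strand == "-":
        return ReadRecord(id=a.qname, mate=a.mate, bases=reverse_complement(a.seq), quals=a.qual[::-1])
    return ReadRecord(id=a.qname, mate=a.mate, bases=a.seq, quals=a.qual)


def flip_read(rec: ReadRecord) -> ReadRecord:
    """Reverse sequence orientation, keeping each base's own quality.

    Bases and qualities are both reversed (no complementation), so the
    transform is an involution and base--quality pairing is preserved.
    """
    return ReadRecord(id=rec.id, mate=rec.mate, bases=rec.bases[::-1], quals=rec.quals[::-1])


def flip_reads(
    records: Iterable[ReadRecord | Alignment],
) -> tuple[list[tuple[ReadRecord, ReadRecord]], list[ReadRecord]]:
    """Flip a stream of reads, emitting synchronized mate pairs.

    Returns (pairs, singles); an orphaned mate goes to the singles list.
    Read ids and mate labels are unchanged.
    """
    pending: dict[str, ReadRecord] = {}
    pairs: list[tuple[ReadRecord, ReadRecord]] = []
    singles: list[ReadRecord] = []
    for item in records:
        rec = as_sequenced(item) if isinstance(item, Alignment) else item
        flipped = flip_read(rec)
        if flipped.mate == 0:
            singles.append(flipped)
            continue
        if flipped.id in pending:
            other = pending.pop(flipped.id)
            first, second = (other, flipped) if other.mate == 1 else (flipped, other)
            pairs.append((first, second))
        else:
            pending[flipped.id] = flipped
    singles.extend(pending.values())
    return pairs, singles


def write_fastq(records: Iterable[ReadRecord], path: str) -> None:
    """Plain 4-line FASTQ, Phred+33."""
    with open(path, "w") as fh:
        for r in records:
            name = r.id if r.mate == 0 else f"{r.id}/{r.mate}"
            fh.write(f"@{name}\n{r.bases}\n+\n{r.quals}\n")


# ---------------------------------------------------------------------------
# direct coordinate transform


def transform_alignment(
    a: Alignment, pair: ContigPair, mate_ref_span: int | None = None
) -> Alignment:
    """Re-express an alignment in the coordinates of the twin contig.

    The mirrored reference carries the same bases in reverse order, so the
    record's footprint ``[pos, pos + span)`` maps to ``[L - pos - span,
    L - pos)``, the CIGAR operation order reverses (clips swap ends, types
    unchanged), and the stored sequence and qualities reverse without
    complementation.  The strand flag is preserved.  Alignment-specific
    tags (NM, MD) are dropped; others (e.g. read group) are kept.

    ``mate_ref_span`` is needed to transform the mate position exactly;
    when absent the record's own span is assumed (equal-length mates).
    """
    if a.contig == pair.fwd_name:
        target = pair.rev_name
    elif a.contig == pair.rev_name:
        target = pair.fwd_name
    else:
        raise ValueError(f"alignment contig {a.contig!r} is not a member of the pair")
    L = pair.length
    span = a.reference_span
    if a.pos + span > L:
        raise ValueError(f"alignment span [{a.pos}, {a.pos + span}) overruns contig length {L}")
    new_pos = L - (a.pos + span)
    new_cigar = tuple(reversed(a.cigar))
    tags = {k: v for k, v in a.tags.items() if k not in ("NM", "MD")}
    mate_contig = a.mate_contig
    mate_pos = a.mate_pos
    if mate_contig == a.contig and mate_pos >= 0:
        mspan = mate_ref_span if mate_ref_span is not None else span
        mate_contig = target
        mate_pos = L - (mate_pos + mspan)
    elif mate_contig is not None:
        mate_contig = target if mate_contig in (pair.fwd_name, pair.rev_name) else mate_contig
    return a.copy(
        contig=target,
        pos=new_pos,
        cigar=new_cigar,
        seq=a.seq[::-1],
        qual=a.qual[::-1],
        mate_contig=mate_contig,
        mate_pos=mate_pos,
        tlen=-a.tlen,
        tags=tags,
    )


def transform_alignments(records: Sequence[Alignment], pair: ContigPair) -> list[Alignment]:
    """Transform a set of alignments, pairing mates to get exact mate spans."""
    spans: dict[tuple[str, int], int] = {}
    for a in records:
        if a.is_paired:
            spans[(a.qname, a.mate)] = a.reference_span
    out = []
    for a in records:
        mspan = spans.get((a.qname, 3 - a.mate)) if a.is_paired else None
        out.append(transform_alignment(a, pair, mate_ref_span=mspan))
    return out


# ---------------------------------------------------------------------------
# downsampling


def _keep_score(qname: str, seed: int) -> float:
    digest = hashlib.blake2b(
        qname.encode(), digest_size=8, salt=seed.to_bytes(8, "little")
    ).digest()
    return int.from_bytes(digest, "big") / 2**64


def downsample_alignments(
    records: Iterable[Alignment], fraction: float, seed: int = 0
) -> list[Alignment]:
    """Retain each read pair (both mates jointly) with probability ``fraction``.

    Retention is decided by a seeded hash of the read id, so the result is
    deterministic, order-independent and pair-coherent, and the retained
    set at a smaller fraction is a subset of the set at a larger one
    (shared threshold).
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return list(records)
    return [a for a in records if _keep_score(a.qname, seed) < fraction]


def downsample_to_coverage(
    records: Sequence[Alignment], target_mean_cov: float, current_mean_cov: float, seed: int = 0
) -> list[Alignment]:
    if current_mean_cov <= 0:
        raise ValueError("current coverage must be positive")
    fraction = min(1.0, target_mean_cov / current_mean_cov)
    return downsample_alignments(records, fraction, seed)


# ---------------------------------------------------------------------------
# exact-match assignment (internal oracle standing in for an aligner in tests)


def exact_match_assign(bases: str, genome: dict[str, str]) -> list[str]:
    """Contigs containing the read (or its reverse complement) verbatim."""
    rc = reverse_complement(bases)
    return [name for name, seq in genome.items() if bases in seq or rc in seq]
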