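"""Synthetic data generation: genomes, planted repeats, and read simulation
with truth alignments.

The simulator emulates the statistical structure the chiral-control method
relies on: sequencing errors whose rates depend only on mirror-invariant
sequence context.  The per-position indel probability scales with the
length of the longest tandem repeat run covering the position (slippage),
so a sequence and its mirror have identical expected error profiles —
the structural assumption behind commutability, made explicit and testable.

Presets:

``error_free``
    no errors; reads reconstruct their templates exactly.
``pcr_free``
    low-indel short-read chemistry (PCR-free library preparation).
``standard``
    high-slippage short-read chemistry (PCR-amplified library preparation);
    indel errors at long repeat runs are abundant enough to smear
    microsatellite length measurements.
``nanopore_like``
    indel-dominated long-read errors.

Truth is emitted as alignment records whose CIGARs encode the injected
errors, so pileup and MSI tests need no external aligner.  All draws come
from one seeded generator in a fixed order; output is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alignment import Alignment, Cigar
from .core import ContigPair, build_mirrored_genome, repeat_run_lengths

_BASES = "ACGT"
_OTHER = {b: _BASES.replace(b, "") for b in _BASES}
_QUAL_CHAR = "I"  # constant Q40; empirical quality profiles are out of scope


@dataclass(frozen=True)
class ErrorModel:
    name: str
    mismatch_rate: float
    indel_rate: float
    slippage_coeff: float  # indel-rate multiplier per extra nt of repeat run

    def __post_init__(self) -> None:
        for r in (self.mismatch_rate, self.indel_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must be in [0, 1]")


ERROR_MODELS: dict[str, ErrorModel] = {
    "error_free": ErrorModel("error_free", 0.0, 0.0, 0.0),
    "pcr_free": ErrorModel("pcr_free", 0.002, 0.0008, 0.2),
    "standard": ErrorModel("standard", 0.003, 0.004, 1.0),
    "nanopore_like": ErrorModel("nanopore_like", 0.03, 0.05, 0.3),
}


def get_error_model(model: str | ErrorModel) -> ErrorModel:
    if isinstance(model, ErrorModel):
        return model
    return ERROR_MODELS[model]


def indel_probabilities(template: str, model: ErrorModel, max_unit: int = 3) -> np.ndarray:
    """Per-position indel probability: base rate scaled by local repeat run
    length (mirror-invariant context)."""
    runs = repeat_run_lengths(template, max_unit=max_unit)
    probs = model.indel_rate * (1.0 + model.slippage_coeff * (runs - 1))
    return np.minimum(probs, 0.5)


# ---------------------------------------------------------------------------
# genome simulation


@dataclass(frozen=True)
class PlantedFeature:
    contig: str
    pos: int
    unit: str
    copies: int

    @property
    def end(self) -> int:
        return self.pos + len(self.unit) * self.copies


@dataclass(frozen=True)
class SimGenomeSpec:
    contigs: tuple[tuple[str, int, float], ...]  # (name, length, GC target)
    features: tuple[PlantedFeature, ...] = ()
    seed: int = 0


def simulate_genome(spec: SimGenomeSpec) -> tuple[dict[str, str], list[PlantedFeature]]:
    """Seeded random genome with planted tandem-repeat features.

    Features must not overlap; the returned feature list is the truth
    annotation (BED-equivalent).
    """
    by_contig: dict[str, list[PlantedFeature]] = {}
    for f in spec.features:
        by_contig.setdefault(f.contig, []).append(f)
    for feats in by_contig.values():
        feats.sort(key=lambda f: f.pos)
        for a, b in zip(feats, feats[1:]):
            if a.end > b.pos:
                raise ValueError(f"overlapping features at {a.contig}:{a.pos} and {b.pos}")
    rng = np.random.default_rng(spec.seed)
    genome: dict[str, str] = {}
    for name, length, gc in spec.contigs:
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        seq = list(rng.choice(list(_BASES), size=length, p=p))
        for f in by_contig.get(name, ()):
            if f.end > length:
                raise ValueError(f"feature at {f.contig}:{f.pos} exceeds contig length")
            seq[f.pos : f.end] = list(f.unit * f.copies)
        genome[name] = "".join(seq)
    return genome, sorted(spec.features, key=lambda f: (f.contig, f.pos))


def write_features_bed(features: Sequence[PlantedFeature], path: str) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.contig}\t{f.pos}\t{f.end}\t{f.unit}x{f.copies}\n")


# ---------------------------------------------------------------------------
# read simulation


def _simulate_segment(
    rng: np.random.Generator,
    template: str,
    ind_prob: np.ndarray,
    mm_rate: float,
    start: int,
    target_qlen: int,
) -> tuple[str, Cigar, int]:
    """Walk the template from ``start`` emitting ``target_qlen`` query bases
    with context-dependent errors; returns (seq, cigar, reference span)."""
    seq: list[str] = []
    ops: list[tuple[str, int]] = []

    def push(op: str) -> None:
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))

    rpos = start
    n = len(template)
    while len(seq) < target_qlen and rpos < n:
        u = rng.random()
        p_ind = float(ind_prob[rpos])
        if seq and u < mm_rate:
            seq.append(_OTHER[template[rpos]][rng.integers(0, 3)])
            push("M")
            rpos += 1
        elif seq and u < mm_rate + p_ind:
            if rng.random() < 0.5:
                seq.append(template[rpos])  # slippage: duplicate the run base
                push("I")
            else:
                push("D")
                rpos += 1
        else:
            seq.append(template[rpos])
            push("M")
            rpos += 1
    while ops and ops[-1][0] == "D":  # no trailing deletion in a valid CIGAR
        rpos -= ops.pop()[1]
    return "".join(seq), tuple(ops), rpos - start


def simulate_reads(
    templates: dict[str, str],
    abundances: dict[str, float] | None = None,
    coverage: float = 100.0,
    fragment_mean: float = 300.0,
    fragment_sd: float = 30.0,
    read_length: int = 100,
    error_model: str | ErrorModel = "error_free",
    seed: int = 0,
    qname_prefix: str = "frag",
) -> list[Alignment]:
    """Paired-end reads from a molecule mixture, with truth alignments.

    Fragments are drawn per molecule proportional to abundance x length
    (equal-abundance equal-length molecules get equal coverage); fragment
    lengths are truncated-normal, start positions uniform, both strands
    equiprobable.  The returned records carry the injected-error CIGARs and
    the origin tag ``XO``; the mean pooled coverage approximates
    ``coverage``.
    """
    model = get_error_model(error_model)
    names = list(templates)
    if abundances is None:
        abundances = {t: 1.0 / len(names) for t in names}
    ab = np.array([abundances[t] for t in names], dtype=float)
    if abs(ab.sum() - 1.0) > 1e-6:
        raise ValueError(f"abundances sum to {ab.sum()}, expected 1")
    lens = np.array([len(templates[t]) for t in names], dtype=float)
    if (lens < read_length).any():
        raise ValueError("every template must be at least one read length long")
    weights = ab * lens
    weights = weights / weights.sum()
    n_frags = max(1, round(coverage * lens.sum() / (2 * read_length)))
    rng = np.random.default_rng(seed)
    ind_probs = {t: indel_probabilities(templates[t], model) for t in names}
    out: list[Alignment] = []
    t_indices = rng.choice(len(names), size=n_frags, p=weights)
    for i in range(n_frags):
        tname = names[int(t_indices[i])]
        template = templates[tname]
        tlen = len(template)
        flen = int(np.clip(round(rng.normal(fragment_mean, fragment_sd)), read_length, tlen))
        start = int(rng.integers(0, tlen - flen + 1))
        frag_strand = "+" if rng.random() < 0.5 else "-"
        qname = f"{qname_prefix}{i:07d}"
        seq1, cig1, span1 = _simulate_segment(
            rng, template, ind_probs[tname], model.mismatch_rate, start, read_length
        )
        start2 = max(start, start + flen - read_length)
        seq2, cig2, span2 = _simulate_segment(
            rng, template, ind_probs[tname], model.mismatch_rate, start2, read_length
        )
        left = dict(pos=start, cigar=cig1, seq=seq1, span=span1, strand="+")
        right = dict(pos=start2, cigar=cig2, seq=seq2, span=span2, strand="-")
        if frag_strand == "+":
            m1, m2 = left, right
        else:
            m1, m2 = right, left
            m1["strand"], m2["strand"] = "-", "+"
        for mate, me, other in ((1, m1, m2), (2, m2, m1)):
            out.append(
                Alignment(
                    qname=qname,
                    contig=tname,
                    pos=me["pos"],
                    mapq=60,
                    cigar=me["cigar"],
                    seq=me["seq"],
                    qual=_QUAL_CHAR * len(me["seq"]),
                    strand=me["strand"],
                    mate=mate,
                    mate_contig=tname,
                    mate_pos=other["pos"],
                    mate_strand=other["strand"],
                    tlen=flen if me["pos"] <= other["pos"] else -flen,
                    tags={"XO": tname},
                )
            )
    return out


def simulate_long_reads(
    templates: dict[str, str],
    abundances: dict[str, float] | None = None,
    coverage: float = 50.0,
    length_mean: float = 1500.0,
    length_sd: float = 300.0,
    min_length: int = 200,
    error_model: str | ErrorModel = "nanopore_like",
    seed: int = 0,
    qname_prefix: str = "long",
) -> list[Alignment]:
    """Single-end long reads with indel-dominated, repeat-scaled errors."""
    model = get_error_model(error_model)
    names = list(templates)
    if abundances is None:
        abundances = {t: 1.0 / len(names) for t in names}
    ab = np.array([abundances[t] for t in names], dtype=float)
    if abs(ab.sum() - 1.0) > 1e-6:
        raise ValueError(f"abundances sum to {ab.sum()}, expected 1")
    lens = np.array([len(templates[t]) for t in names], dtype=float)
    weights = ab * lens
    weights = weights / weights.sum()
    mean_len = min(length_mean, lens.mean())
    n_reads = max(1, round(coverage * lens.sum() / mean_len))
    rng = np.random.default_rng(seed)
    ind_probs = {t: indel_probabilities(templates[t], model) for t in names}
    out: list[Alignment] = []
    t_indices = rng.choice(len(names), size=n_reads, p=weights)
    for i in range(n_reads):
        tname = names[int(t_indices[i])]
        template = templates[tname]
        tlen = len(template)
        rlen = int(np.clip(round(rng.normal(length_mean, length_sd)), min_length, tlen))
        start = int(rng.integers(0, tlen - rlen + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        seq, cig, span = _simulate_segment(
            rng, template, ind_probs[tname], model.mismatch_rate, start, rlen
        )
        out.append(
            Alignment(
                qname=f"{qname_prefix}{i:07d}",
                contig=tname,
                pos=start,
                mapq=60,
                cigar=cig,
                seq=seq,
                qual=_QUAL_CHAR * len(seq),
                strand=strand,
                mate=0,
                tags={"XO": tname},
            )
        )
    return out


# ---------------------------------------------------------------------------
# lifting molecule alignments onto the reference


def lift_to_reference(
    a: Alignment,
    edit_ops: Cigar,
    ref_contig: str,
    ref_offset: int = 0,
) -> Alignment:
    """Re-express a read aligned to an edited molecule as an alignment to
    the molecule's source reference.

    ``edit_ops`` is the molecule-vs-reference edit script (M/I/D over the
    molecule's fwd axis, e.g. from :func:`chiralseq.design.molecule_edit_ops`);
    the read's CIGAR is composed with it, so a read crossing a molecule
    deletion gains a D operation, and bases the molecule inserted become
    insertions (soft clips at read ends).  ``ref_offset`` shifts the result
    to absolute reference coordinates (the region start).
    """
    # per-molecule-base map to reference, plus reference gaps between bases
    tmap: list[int | None] = []
    dgap: dict[int, int] = {}
    r = 0
    for op, n in edit_ops:
        if op == "M":
            tmap.extend(range(r, r + n))
            r += n
        elif op == "I":
            tmap.extend([None] * n)
        elif op == "D":
            dgap[len(tmap)] = dgap.get(len(tmap), 0) + n
            r += n
        else:
            raise ValueError(f"unsupported edit op {op!r}")
    ops: list[tuple[str, int]] = []

    def push(op: str, n: int = 1) -> None:
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    started = False

    def consume_template(t: int, query: bool) -> None:
        nonlocal started
        if started and t in dgap:
            push("D", dgap[t])
        mapped = tmap[t] is not None
        if query:
            push("M" if mapped else "I")
            started = started or mapped
        elif mapped:
            if started:
                push("D")
            started = True

    tpos = a.pos
    for op, n in a.cigar:
        if op in "M=X":
            for _ in range(n):
                consume_template(tpos, query=True)
                tpos += 1
        elif op == "I":
            push("I", n)
        elif op in "DN":
            for _ in range(n):
                consume_template(tpos, query=False)
                tpos += 1
        elif op == "S":
            push("S", n)
        else:
            raise ValueError(f"unsupported read op {op!r}")
    # a leading/trailing insertion has no reference anchor: soft clip it
    while ops and ops[0][0] in "DI":
        op, n = ops.pop(0)
        if op == "I":
            ops.insert(0, ("S", n))
            break
    while ops and ops[-1][0] in "DI":
        op, n = ops.pop()
        if op == "I":
            ops.append(("S", n))
            break
    # reference start: first molecule base of the read that maps
    start_ref = None
    t = a.pos
    while t < len(tmap):
        if tmap[t] is not None:
            start_ref = tmap[t]
            break
        t += 1
    if start_ref is None or not any(op in "MDN" for op, _ in ops):
        raise ValueError("read has no reference-anchored bases after lifting")
    return a.copy(
        contig=ref_contig,
        pos=ref_offset + start_ref,
        cigar=tuple(ops),
        mate_contig=None,
        mate_pos=-1,
        tags={**a.tags, "XO": a.contig},
    )


# ---------------------------------------------------------------------------
# mirror benchmark


@dataclass
class MirrorBenchmark:
    pairs: dict[str, ContigPair]
    genome: dict[str, str]  # fwd and rev contigs combined
    alignments: list[Alignment]


def _benchmark_template(rng: np.random.Generator, length: int) -> str:
    """Random template with tandem repeats of varied unit and length planted
    at template-specific positions, giving strong positional heterogeneity
    in indel-error rates (the signal that mirrored error profiles share
    while unrelated templates do not)."""
    seq = list(rng.choice(list(_BASES), size=length))
    pos = int(rng.integers(30, 150))
    while pos + 30 < length:
        u = int(rng.integers(1, 4))
        unit = "".join(rng.choice(list(_BASES), size=u))
        if u > 1 and len(set(unit)) == 1:
            unit = unit[:-1] + _OTHER[unit[0]][0]  # keep the unit primitive
        total = int(rng.integers(8, 25))
        copies = max(2, total // u)
        run = (unit * copies)[: copies * u]
        seq[pos : pos + len(run)] = list(run)
        pos += int(rng.integers(80, 220))
    return "".join(seq[:length])


def make_mirror_benchmark(
    n_pairs: int = 8,
    length: int = 1800,
    coverage: float = 200.0,
    error_model: str | ErrorModel = "standard",
    seed: int = 0,
    **read_kwargs,
) -> MirrorBenchmark:
    """Synthetic fwd regions plus mirrored twins at equal abundance, with
    simulated reads and truth alignments — ready for the metrics pipeline."""
    rng = np.random.default_rng(seed)
    fwd = {f"mb{i:02d}": _benchmark_template(rng, length) for i in range(n_pairs)}
    pairs = build_mirrored_genome(fwd)
    genome: dict[str, str] = {}
    for p in pairs.values():
        genome[p.fwd_name] = p.fwd_bases
        genome[p.rev_name] = p.rev_bases
    alignments = simulate_reads(
        genome,
        coverage=coverage,
        error_model=error_model,
        seed=int(rng.integers(0, 2**31 - 1)),
        **read_kwargs,
    )
    return MirrorBenchmark(pairs=pairs, genome=genome, alignments=alignments)
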