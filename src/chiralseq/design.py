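"""Design of chiral sequin molecules and their mixtures.

A sequin is a synthetic DNA molecule whose sequence is the mirror (reverse
nucleotide order, no complementation) of a chosen genome region, optionally
carrying planted variant alleles.  Mixtures of such molecules at controlled
mass fractions define expected variant allele frequencies (VAFs) that serve
as internal truth:

* genotype mixtures — heterozygous variants as paired reference/variant
  molecules at equal abundance, homozygous variants as the variant molecule
  alone;
* a two-fold dilution ladder from 100% down, level ``i`` at VAF ``2^-(i-1)``
  (11 levels ends at ~0.1%), with a matched wild-type-only "normal" mixture;
* microsatellite mixtures — a wild-type molecule alone (stable) or mixed
  with a one-repeat-unit insertion/deletion mutant (unstable);
* mirrored PCR primer pairs that amplify the mirrored amplicon, verified by
  in-silico PCR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

from .core import ContigPair, Interval, complement, mirror_sequence, reverse_complement

DEFAULT_REGION_LENGTH = 1800


# ---------------------------------------------------------------------------
# alleles and molecules


@dataclass(frozen=True)
class AlleleSpec:
    """A variant allele within a region, VCF-style anchored representation.

    ``fwd_offset`` is 0-based within the region (fwd orientation); ``ref``
    must match the region sequence starting at that offset.  SNV: single
    base ref/alt.  INS/DEL: first base is the shared anchor.
    """

    kind: Literal["SNV", "INS", "DEL"]
    fwd_offset: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.kind == "SNV" and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValueError("SNV requires single-base ref and alt")
        if self.kind == "INS" and len(self.alt) <= len(self.ref):
            raise ValueError("INS requires alt longer than ref")
        if self.kind == "DEL" and len(self.ref) <= len(self.alt):
            raise ValueError("DEL requires ref longer than alt")


def apply_alleles(region_seq: str, alleles: Sequence[AlleleSpec]) -> str:
    """Apply alleles to a fwd-orientation region sequence.

    Alleles are applied left-to-right with cumulative coordinate shifting
    for indels; overlapping alleles are rejected.
    """
    ordered = sorted(alleles, key=lambda a: a.fwd_offset)
    for prev, cur in zip(ordered, ordered[1:]):
        if prev.fwd_offset + len(prev.ref) > cur.fwd_offset:
            raise ValueError(
                f"overlapping alleles at offsets {prev.fwd_offset} and {cur.fwd_offset}"
            )
    out = []
    cursor = 0
    for a in ordered:
        found = region_seq[a.fwd_offset : a.fwd_offset + len(a.ref)]
        if found != a.ref:
            raise ValueError(
                f"allele ref mismatch at offset {a.fwd_offset}: expected {a.ref!r}, found {found!r}"
            )
        out.append(region_seq[cursor : a.fwd_offset])
        out.append(a.alt)
        cursor = a.fwd_offset + len(a.ref)
    out.append(region_seq[cursor:])
    return "".join(out)


@dataclass(frozen=True)
class SequinMolecule:
    """A chiral molecule: mirrored copy of a fwd region with alleles applied."""

    id: str
    source: Interval  # fwd space
    alleles: tuple[AlleleSpec, ...]
    role: Literal["wildtype", "variant"]
    bases: str  # chiral (mirrored) sequence

    @property
    def fwd_bases(self) -> str:
        """The molecule read back in fwd orientation."""
        return self.bases[::-1]


def extract_region(
    genome: dict[str, str], anchor: Interval, length: int = DEFAULT_REGION_LENGTH
) -> tuple[Interval, str]:
    """Interval of ``length`` centred on the anchor midpoint (ties to the
    lower coordinate).  No silent clamping: overruns are errors."""
    if anchor.contig not in genome:
        raise KeyError(f"unknown contig {anchor.contig!r}")
    contig_seq = genome[anchor.contig]
    mid = (anchor.start + anchor.end - 1) // 2
    start = mid - length // 2
    end = start + length
    if start < 0 or end > len(contig_seq):
        raise ValueError(
            f"region [{start}, {end}) exceeds contig {anchor.contig!r} bounds [0, {len(contig_seq)})"
        )
    iv = Interval(contig=anchor.contig, start=start, end=end, space="fwd")
    return iv, contig_seq[start:end]


def build_molecule(
    region: Interval,
    region_seq: str,
    alleles: Sequence[AlleleSpec],
    mol_id: str,
    role: Literal["wildtype", "variant"] | None = None,
) -> SequinMolecule:
    """Apply alleles to the fwd region sequence, then mirror."""
    edited = apply_alleles(region_seq, alleles)
    if role is None:
        role = "variant" if alleles else "wildtype"
    return SequinMolecule(
        id=mol_id,
        source=region,
        alleles=tuple(sorted(alleles, key=lambda a: a.fwd_offset)),
        role=role,
        bases=mirror_sequence(edited),
    )


# ---------------------------------------------------------------------------
# variant record projection between mirrored coordinate systems


def normalize_variant(seq: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align and minimise a variant against ``seq`` (VCF convention)."""
    if seq[pos : pos + len(ref)] != ref:
        raise ValueError(f"ref {ref!r} does not match sequence at position {pos}")
    ref_l, alt_l = list(ref), list(alt)
    while True:
        if len(ref_l) > 1 and len(alt_l) > 1 and ref_l[-1] == alt_l[-1]:
            ref_l.pop()
            alt_l.pop()
        elif (
            (len(ref_l) == 1 or len(alt_l) == 1)
            and ref_l[-1] == alt_l[-1]
            and len(ref_l) != len(alt_l)
            and pos > 0
        ):
            ref_l.pop()
            alt_l.pop()
            pos -= 1
            ref_l.insert(0, seq[pos])
            alt_l.insert(0, seq[pos])
        else:
            break
    while len(ref_l) > 1 and len(alt_l) > 1 and ref_l[0] == alt_l[0]:
        ref_l.pop(0)
        alt_l.pop(0)
        pos += 1
    return pos, "".join(ref_l), "".join(alt_l)


def project_variant(
    pos: int, ref: str, alt: str, pair: ContigPair, from_space: str = "rev"
) -> tuple[int, str, str]:
    """Project a variant record between mirrored coordinate systems.

    A record replacing ``[pos, pos + |ref|)`` of one member of the pair with
    ``alt`` corresponds, on the twin, to replacing ``[L - pos - |ref|, L - pos)``
    with ``reversed(alt)`` — letters are not complemented.  The projected
    record is re-anchored and left-normalized against the target sequence.
    Applying the projected variant to the twin and mirroring the result
    equals applying the original record directly (commutation).
    """
    L = pair.length
    src = pair.rev_bases if from_space == "rev" else pair.fwd_bases
    dst = pair.fwd_bases if from_space == "rev" else pair.rev_bases
    if src[pos : pos + len(ref)] != ref:
        raise ValueError(
            f"ref {ref!r} does not match {from_space} sequence at position {pos} "
            "(inconsistent genome build?)"
        )
    new_pos = L - pos - len(ref)
    new_ref = ref[::-1]
    new_alt = alt[::-1]
    if dst[new_pos : new_pos + len(new_ref)] != new_ref:
        raise ValueError("projected ref mismatch (inconsistent genome build?)")
    return normalize_variant(dst, new_pos, new_ref, new_alt)


# ---------------------------------------------------------------------------
# mixtures


@dataclass(frozen=True)
class ExpectedVariant:
    """Truth record: a variant at a fwd-genome locus with its expected VAF."""

    contig: str
    pos: int  # 0-based fwd coordinate
    ref: str
    alt: str
    vaf: float
    genotype: str  # het / hom / somatic
    level: int | None = None  # ladder level, when applicable


@dataclass
class MixtureManifest:
    """Molecule mass fractions plus the expected variants they encode."""

    label: str
    entries: dict[str, float]
    expected_variants: list[ExpectedVariant] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(self.entries.values())
        if self.entries and abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture fractions sum to {total}, expected 1")


@dataclass(frozen=True)
class LadderLevel:
    index: int

    @property
    def vaf(self) -> float:
        if self.index < 1:
            raise ValueError("ladder levels start at 1")
        return 2.0 ** -(self.index - 1)


def ladder_vaf(index: int) -> float:
    return LadderLevel(index).vaf


@dataclass(frozen=True)
class VariantDesign:
    """Input to mixture design: one variant in its own region."""

    name: str
    region: Interval
    region_seq: str
    allele: AlleleSpec
    genotype: str = "het"  # het / hom (genotype mixtures only)


def _abs_variant(v: VariantDesign, vaf: float, genotype: str, level: int | None = None) -> ExpectedVariant:
    pos, ref, alt = normalize_variant(v.region_seq, v.allele.fwd_offset, v.allele.ref, v.allele.alt)
    return ExpectedVariant(
        contig=v.region.contig,
        pos=v.region.start + pos,
        ref=ref,
        alt=alt,
        vaf=vaf,
        genotype=genotype,
        level=level,
    )


def design_genotype_mixture(variants: Sequence[VariantDesign]) -> tuple[list[SequinMolecule], MixtureManifest]:
    """Germline-style mixture: het -> paired ref/alt molecules at equal
    abundance (expected VAF 0.5); hom -> variant molecule alone (VAF 1.0)."""
    seen_loci: set[tuple[str, int]] = set()
    molecules: list[SequinMolecule] = []
    entries: dict[str, float] = {}
    expected: list[ExpectedVariant] = []
    share = 1.0 / len(variants)
    for v in variants:
        locus = (v.region.contig, v.region.start + v.allele.fwd_offset)
        if locus in seen_loci:
            raise ValueError(f"duplicate variant locus {locus}")
        seen_loci.add(locus)
        alt_mol = build_molecule(v.region, v.region_seq, [v.allele], f"{v.name}_alt", "variant")
        molecules.append(alt_mol)
        if v.genotype == "het":
            ref_mol = build_molecule(v.region, v.region_seq, [], f"{v.name}_ref", "wildtype")
            molecules.append(ref_mol)
            entries[alt_mol.id] = share / 2
            entries[ref_mol.id] = share / 2
            expected.append(_abs_variant(v, 0.5, "het"))
        elif v.genotype == "hom":
            entries[alt_mol.id] = share
            expected.append(_abs_variant(v, 1.0, "hom"))
        else:
            raise ValueError(f"unknown genotype {v.genotype!r}")
    return molecules, MixtureManifest(label="germline", entries=entries, expected_variants=expected)


def allocate_ladder(n_variants: int, levels: int, per_level: tuple[int, int]) -> list[int]:
    """Round-robin level assignment (variant i -> level i % levels + 1),
    checked against the per-level occupancy bounds."""
    lo, hi = per_level
    if not (levels * lo <= n_variants <= levels * hi):
        raise ValueError(
            f"cannot place {n_variants} variants on {levels} levels with {lo}-{hi} per level "
            f"(feasible range {levels * lo}-{levels * hi})"
        )
    assignment = [(i % levels) + 1 for i in range(n_variants)]
    return assignment


def design_vaf_ladder(
    variants: Sequence[VariantDesign],
    levels: int = 11,
    per_level: tuple[int, int] = (7, 9),
) -> tuple[list[SequinMolecule], MixtureManifest, MixtureManifest]:
    """Somatic VAF dilution ladder plus matched wild-type-only normal mixture.

    Level ``i`` carries VAF ``2^-(i-1)``: level 1 is 100%, level 5 is 6.25%,
    level 11 rounds to 0.1%.  Within each variant's site the tumor mixture
    holds variant and wild-type molecules at ``vaf`` and ``1 - vaf`` of the
    site mass; sites carry equal total mass.
    """
    assignment = allocate_ladder(len(variants), levels, per_level)
    share = 1.0 / len(variants)
    molecules: list[SequinMolecule] = []
    tumor_entries: dict[str, float] = {}
    normal_entries: dict[str, float] = {}
    expected: list[ExpectedVariant] = []
    for v, level in zip(variants, assignment):
        vaf = ladder_vaf(level)
        alt_mol = build_molecule(v.region, v.region_seq, [v.allele], f"{v.name}_alt", "variant")
        wt_mol = build_molecule(v.region, v.region_seq, [], f"{v.name}_wt", "wildtype")
        molecules.append(alt_mol)
        molecules.append(wt_mol)
        tumor_entries[alt_mol.id] = share * vaf
        if vaf < 1.0:
            tumor_entries[wt_mol.id] = share * (1.0 - vaf)
        normal_entries[wt_mol.id] = share
        expected.append(_abs_variant(v, vaf, "somatic", level=level))
    tumor = MixtureManifest(label="tumor", entries=tumor_entries, expected_variants=expected)
    normal = MixtureManifest(label="normal", entries=normal_entries, expected_variants=[])
    return molecules, tumor, normal


def molecule_edit_ops(alleles: Sequence[AlleleSpec], region_len: int) -> tuple[tuple[str, int], ...]:
    """CIGAR-style edit script aligning the edited (fwd-oriented) molecule
    to its source region: M consumes both, I consumes molecule only,
    D consumes reference only."""
    ops: list[tuple[str, int]] = []

    def push(op: str, n: int) -> None:
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    cursor = 0
    for a in sorted(alleles, key=lambda a: a.fwd_offset):
        pre = 0
        while pre < min(len(a.ref), len(a.alt)) and a.ref[pre] == a.alt[pre]:
            pre += 1
        push("M", a.fwd_offset - cursor + pre)
        rrest, arest = len(a.ref) - pre, len(a.alt) - pre
        push("M", min(rrest, arest))  # substituted bases stay M
        if arest > rrest:
            push("I", arest - rrest)
        elif rrest > arest:
            push("D", rrest - arest)
        cursor = a.fwd_offset + len(a.ref)
    push("M", region_len - cursor)
    return tuple(ops)


# ---------------------------------------------------------------------------
# microsatellite (MSI) sequins


@dataclass(frozen=True)
class MsiLocusSpec:
    """A microsatellite locus: ``unit`` repeated ``ref_copies`` times."""

    locus: Interval  # fwd space
    unit: str
    ref_copies: int

    def __post_init__(self) -> None:
        if self.ref_copies < 2:
            raise ValueError("microsatellite requires at least 2 repeat copies")
        if self.locus.width != len(self.unit) * self.ref_copies:
            raise ValueError("locus width does not equal unit length x copies")


def design_msi_sequins(
    region: Interval,
    region_seq: str,
    locus: MsiLocusSpec,
    mode: Literal["stable", "unstable"],
    mutant_fraction: float = 0.5,
    mutation: Literal["deletion", "insertion"] = "deletion",
    name: str = "msi",
) -> tuple[list[SequinMolecule], MixtureManifest, dict[int, float]]:
    """Wild-type microsatellite molecule, optionally mixed with a mutant
    differing by one repeat unit.

    Returns molecules, the manifest and the expected repeat-length offset
    distribution (nt offset relative to reference length -> mass).
    """
    off = locus.locus.start - region.start
    if off < 0 or locus.locus.end > region.end:
        raise ValueError("locus not contained in region")
    expected_repeat = locus.unit * locus.ref_copies
    found = region_seq[off : off + len(expected_repeat)]
    if found != expected_repeat:
        raise ValueError(f"reference at locus is {found!r}, expected {expected_repeat!r}")
    wt = build_molecule(region, region_seq, [], f"{name}_wt", "wildtype")
    if mode == "stable":
        manifest = MixtureManifest(label="msi_stable", entries={wt.id: 1.0})
        return [wt], manifest, {0: 1.0}
    if not (0.0 < mutant_fraction < 1.0):
        raise ValueError("mutant_fraction must be in (0, 1)")
    u = len(locus.unit)
    anchor = off - 1
    if anchor < 0:
        raise ValueError("locus must not start at region edge (anchor base required)")
    if mutation == "deletion":
        allele = AlleleSpec(
            kind="DEL",
            fwd_offset=anchor,
            ref=region_seq[anchor] + locus.unit,
            alt=region_seq[anchor],
        )
        delta = -u
    else:
        allele = AlleleSpec(
            kind="INS",
            fwd_offset=anchor,
            ref=region_seq[anchor],
            alt=region_seq[anchor] + locus.unit,
        )
        delta = u
    mut = build_molecule(region, region_seq, [allele], f"{name}_mut", "variant")
    manifest = MixtureManifest(
        label="msi_unstable",
        entries={wt.id: 1.0 - mutant_fraction, mut.id: mutant_fraction},
    )
    return [wt, mut], manifest, {0: 1.0 - mutant_fraction, delta: mutant_fraction}


# ---------------------------------------------------------------------------
# primer mirroring and in-silico PCR


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str
    amplicon: Interval


def insilico_pcr(template: str, forward: str, reverse: str, max_product: int = 5000) -> list[tuple[int, int]]:
    """Products where ``forward`` matches the template exactly and the
    reverse complement of ``reverse`` matches downstream within ``max_product``."""
    if not forward or not reverse:
        raise ValueError("primers must be non-empty")
    rc = reverse_complement(reverse)
    products = []
    f_start = template.find(forward)
    f_sites = []
    while f_start != -1:
        f_sites.append(f_start)
        f_start = template.find(forward, f_start + 1)
    r_sites = []
    r_start = template.find(rc)
    while r_start != -1:
        r_sites.append(r_start)
        r_start = template.find(rc, r_start + 1)
    for fs in f_sites:
        for rs in r_sites:
            end = rs + len(rc)
            if end - fs >= len(forward) + len(reverse) and end - fs <= max_product and rs >= fs:
                products.append((fs, end))
    return sorted(products)


def mirror_primer_pair(pair: PrimerPair, contig_pair: ContigPair, max_product: int = 5000) -> PrimerPair:
    """Primer pair for the mirrored template: ``(complement(reverse),
    complement(forward))`` — roles swapped — amplifying the mirrored amplicon.

    This is the unique recipe under which the mirrored reaction amplifies
    exactly the mirrored interval; both designs are verified by in-silico PCR.
    """
    fwd_template = contig_pair.bases(pair.amplicon.space)
    L = contig_pair.length
    products = insilico_pcr(fwd_template, pair.forward, pair.reverse, max_product)
    if (pair.amplicon.start, pair.amplicon.end) not in products:
        raise ValueError(
            f"input pair does not amplify the stated amplicon "
            f"[{pair.amplicon.start}, {pair.amplicon.end}); products: {products}"
        )
    other_space = "rev" if pair.amplicon.space == "fwd" else "fwd"
    mirrored = PrimerPair(
        forward=complement(pair.reverse),
        reverse=complement(pair.forward),
        amplicon=Interval(
            contig=contig_pair.name(other_space),
            start=L - pair.amplicon.end,
            end=L - pair.amplicon.start,
            space=other_space,
        ),
    )
    twin_template = contig_pair.bases(other_space)
    twin_products = insilico_pcr(twin_template, mirrored.forward, mirrored.reverse, max_product)
    if (mirrored.amplicon.start, mirrored.amplicon.end) not in twin_products:
        raise ValueError("mirrored pair failed in-silico verification")
    return mirrored
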