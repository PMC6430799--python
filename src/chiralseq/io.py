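"""File-format boundaries: FASTA, manifest TSV, expected-variant VCF, BED.

Coordinates are 0-based half-open in memory; the 1-based conventions of
VCF are handled by pysam at the boundary.  BED is 0-based half-open
already.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import ContigPair, Interval
from .design import ExpectedVariant, MixtureManifest, MsiLocusSpec

FASTA_WIDTH = 60


def write_fasta(seqs: dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WIDTH)
        writer.write_file(records)


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_combined_index(pairs: dict[str, ContigPair], fasta_path: str, table_path: str | None = None) -> None:
    """Combined fwd+rev FASTA plus the contig-namespace table."""
    seqs: dict[str, str] = {}
    for p in pairs.values():
        seqs[p.fwd_name] = p.fwd_bases
        seqs[p.rev_name] = p.rev_bases
    write_fasta(seqs, fasta_path)
    if table_path:
        from .core import contig_table

        contig_table(pairs).to_csv(table_path, sep="\t", index=False)


def read_contig_table(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["name"], df["namespace"]))


def write_manifest_tsv(manifest: MixtureManifest, path: str) -> None:
    df = pd.DataFrame(
        [(mol, frac, manifest.label) for mol, frac in manifest.entries.items()],
        columns=["molecule_id", "fraction", "mixture"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_manifest_tsv(path: str, expected_variants: Sequence[ExpectedVariant] = ()) -> MixtureManifest:
    df = pd.read_csv(path, sep="\t")
    labels = df["mixture"].unique()
    if len(labels) != 1:
        raise ValueError(f"manifest TSV holds {len(labels)} mixtures, expected one")
    entries = dict(zip(df["molecule_id"], df["fraction"].astype(float)))
    return MixtureManifest(label=str(labels[0]), entries=entries, expected_variants=list(expected_variants))


def _vcf_header(contig_lengths: dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.add_line(f"##contig=<ID={name},length={length}>")
    header.add_line('##INFO=<ID=VAF,Number=1,Type=Float,Description="Expected variant allele frequency">')
    header.add_line('##INFO=<ID=GENO,Number=1,Type=String,Description="Designed genotype">')
    header.add_line('##INFO=<ID=LEVEL,Number=1,Type=Integer,Description="Dilution ladder level">')
    return header


def write_expected_vcf(
    expected: Sequence[ExpectedVariant], contig_lengths: dict[str, int], path: str
) -> None:
    header = _vcf_header(contig_lengths)
    with pysam.VariantFile(path, "w", header=header) as vf:
        for e in sorted(expected, key=lambda e: (e.contig, e.pos)):
            rec = vf.new_record(
                contig=e.contig, start=e.pos, alleles=(e.ref, e.alt), id=".", qual=None
            )
            rec.info["VAF"] = e.vaf
            rec.info["GENO"] = e.genotype
            if e.level is not None:
                rec.info["LEVEL"] = e.level
            vf.write(rec)


def read_expected_vcf(path: str) -> list[ExpectedVariant]:
    out = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            out.append(
                ExpectedVariant(
                    contig=rec.contig,
                    pos=rec.start,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    vaf=float(rec.info["VAF"]),
                    genotype=str(rec.info["GENO"]),
                    level=int(rec.info["LEVEL"]) if "LEVEL" in rec.info else None,
                )
            )
    return out


def write_msi_bed(loci: Sequence[MsiLocusSpec], path: str) -> None:
    """BED with two extra columns: repeat unit and reference copy number."""
    with open(path, "w") as fh:
        for m in loci:
            fh.write(
                f"{m.locus.contig}\t{m.locus.start}\t{m.locus.end}\t{m.unit}\t{m.ref_copies}\n"
            )


def read_msi_bed(path: str) -> list[MsiLocusSpec]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            contig, start, end, unit, copies = line.rstrip("\n").split("\t")[:5]
            out.append(
                MsiLocusSpec(
                    locus=Interval(contig=contig, start=int(start), end=int(end), space="fwd"),
                    unit=unit,
                    ref_copies=int(copies),
                )
            )
    return out


def write_pileup_tsv(profile, path: str) -> None:
    df = pd.DataFrame(
        {
            "pos": range(profile.start, profile.end),
            "depth": profile.depth,
            "mismatch": profile.mismatch,
            "insertion": profile.insertion,
            "deletion": profile.deletion,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path: str, contig: str = "", mapq_floor: int = 0):
    from .profiles import PileupProfile

    df = pd.read_csv(path, sep="\t")
    return PileupProfile(
        contig=contig,
        start=int(df["pos"].iloc[0]),
        end=int(df["pos"].iloc[-1]) + 1,
        depth=df["depth"].to_numpy(),
        mismatch=df["mismatch"].to_numpy(),
        insertion=df["insertion"].to_numpy(),
        deletion=df["deletion"].to_numpy(),
        mapq_floor=mapq_floor,
    )
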