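"""Sequin molecule construction, mixture manifests, projection, primers."""

import numpy as np
import pytest

from chiralseq import (
    AlleleSpec,
    ContigPair,
    Interval,
    PrimerPair,
    VariantDesign,
    build_molecule,
    design_genotype_mixture,
    design_msi_sequins,
    design_vaf_ladder,
    extract_region,
    insilico_pcr,
    ladder_vaf,
    mirror_primer_pair,
    mirror_sequence,
    project_variant,
)
from chiralseq.design import (
    MsiLocusSpec,
    allocate_ladder,
    apply_alleles,
    molecule_edit_ops,
    normalize_variant,
)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestExtractRegion:
    def test_centered_interval(self):
        genome = {"c": "A" * 5000}
        iv, seq = extract_region(genome, Interval("c", 2500, 2501), length=1800)
        assert (iv.start, iv.end) == (1600, 3400)
        assert len(seq) == 1800

    def test_no_silent_clamping(self):
        with pytest.raises(ValueError):
            extract_region({"c": "A" * 5000}, Interval("c", 500, 501), length=1800)
        # the boundary case lands exactly at the contig start, unclamped
        iv, _ = extract_region({"c": "A" * 5000}, Interval("c", 900, 901), length=1800)
        assert (iv.start, iv.end) == (0, 1800)

    def test_sequence_matches_genome_slice(self):
        rng = np.random.default_rng(0)
        genome = {"c": _random_seq(rng, 4000)}
        iv, seq = extract_region(genome, Interval("c", 2000, 2001), length=1000)
        assert seq == genome["c"][iv.start : iv.end]
        for i in range(0, 1000, 97):
            assert seq[i] == genome["c"][iv.start + i]


class TestBuildMolecule:
    def test_no_alleles_is_pure_mirror(self):
        rng = np.random.default_rng(1)
        seq = _random_seq(rng, 300)
        mol = build_molecule(Interval("c", 0, 300), seq, [], "m0")
        assert mol.bases == mirror_sequence(seq)
        assert mol.role == "wildtype"

    def test_snv_lands_mirrored_uncomplemented(self):
        rng = np.random.default_rng(2)
        n = 200
        seq = _random_seq(rng, n)
        i = 57
        alt = "T" if seq[i] != "T" else "G"
        mol = build_molecule(
            Interval("c", 0, n), seq, [AlleleSpec("SNV", i, seq[i], alt)], "m1"
        )
        # apply-then-mirror vs mirror-then-project oracle
        assert mol.bases[n - 1 - i] == alt
        assert mol.bases == mirror_sequence(seq[:i] + alt + seq[i + 1 :])

    def test_insertion_appears_reversed_at_mirrored_junction(self):
        rng = np.random.default_rng(3)
        seq = _random_seq(rng, 100)
        i = 40
        allele = AlleleSpec("INS", i, seq[i], seq[i] + "GAT")
        mol = build_molecule(Interval("c", 0, 100), seq, [allele], "m2")
        edited = seq[: i + 1] + "GAT" + seq[i + 1 :]
        assert mol.bases == mirror_sequence(edited)
        j = len(edited) - 1 - (i + 3)  # mirrored position of the insert start
        assert mol.bases[j : j + 3] == "TAG"

    def test_ref_mismatch_names_offset(self):
        with pytest.raises(ValueError, match="offset 3"):
            apply_alleles("ACGTACGT", [AlleleSpec("SNV", 3, "A", "C")])

    def test_overlapping_alleles_rejected(self):
        seq = "ACGTACGTAC"
        alleles = [
            AlleleSpec("DEL", 2, seq[2:5], seq[2]),
            AlleleSpec("SNV", 4, seq[4], "C" if seq[4] != "C" else "G"),
        ]
        with pytest.raises(ValueError, match="overlapping"):
            apply_alleles(seq, alleles)


class TestProjectVariant:
    def test_snv_arithmetic(self):
        pair = ContigPair("c", "c_rev", "GGGGGGGAGG")  # fwd pos 7 = A
        # rev sequence is GGAGGGGGGG; SNV at rev pos 2 A->G
        pos, ref, alt = project_variant(2, "A", "G", pair, "rev")
        assert (pos, ref, alt) == (7, "A", "G")

    def test_commutation_on_random_indels(self):
        rng = np.random.default_rng(4)
        for _ in range(500):
            seq = _random_seq(rng, 60)
            pair = ContigPair("c", "c_rev", seq)
            rev = pair.rev_bases
            p = int(rng.integers(1, 54))
            kind = int(rng.integers(0, 3))
            if kind == 0:
                ref, alt = rev[p], "ACGT"[("ACGT".index(rev[p]) + 1) % 4]
            elif kind == 1:
                ref, alt = rev[p], rev[p] + _random_seq(rng, int(rng.integers(1, 4)))
            else:
                d = int(rng.integers(1, 4))
                ref, alt = rev[p : p + 1 + d], rev[p]
            fp, fref, falt = project_variant(p, ref, alt, pair, "rev")
            applied_fwd = seq[:fp] + falt + seq[fp + len(fref) :]
            applied_rev = rev[:p] + alt + rev[p + len(ref) :]
            assert applied_fwd[::-1] == applied_rev

    def test_double_projection_is_normalized_identity(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            seq = _random_seq(rng, 50)
            pair = ContigPair("c", "c_rev", seq)
            rev = pair.rev_bases
            p = int(rng.integers(1, 45))
            ref, alt = rev[p : p + 2], rev[p]  # 1 bp deletion
            norm = normalize_variant(rev, p, ref, alt)
            fwd_rec = project_variant(*norm, pair, "rev")
            back = project_variant(*fwd_rec, pair, "fwd")
            assert back == norm

    def test_ref_mismatch_rejected(self):
        pair = ContigPair("c", "c_rev", "AAAA")
        with pytest.raises(ValueError, match="genome build"):
            project_variant(0, "G", "T", pair, "rev")


class TestGenotypeMixture:
    def _designs(self, rng, genotypes):
        designs = []
        for i, gt in enumerate(genotypes):
            seq = _random_seq(rng, 120)
            off = 60
            designs.append(
                VariantDesign(
                    name=f"v{i}",
                    region=Interval("c", i * 120, (i + 1) * 120),
                    region_seq=seq,
                    allele=AlleleSpec("SNV", off, seq[off], "ACGT"[("ACGT".index(seq[off]) + 1) % 4]),
                    genotype=gt,
                )
            )
        return designs

    def test_het_gives_equal_pair_at_vaf_half(self):
        rng = np.random.default_rng(6)
        mols, manifest = design_genotype_mixture(self._designs(rng, ["het"]))
        assert len(mols) == 2
        assert sorted(manifest.entries.values()) == [0.5, 0.5]
        assert manifest.expected_variants[0].vaf == 0.5

    def test_hom_gives_single_molecule_at_vaf_one(self):
        rng = np.random.default_rng(7)
        mols, manifest = design_genotype_mixture(self._designs(rng, ["hom"]))
        assert len(mols) == 1
        assert manifest.expected_variants[0].vaf == 1.0

    def test_paper_scale_molecule_count(self):
        # 29 homozygous + 58 heterozygous variants -> 29 + 2*58 molecules
        rng = np.random.default_rng(8)
        designs = self._designs(rng, ["hom"] * 29 + ["het"] * 58)
        mols, manifest = design_genotype_mixture(designs)
        assert len(mols) == 145
        assert len(manifest.entries) == 145
        assert sum(manifest.entries.values()) == pytest.approx(1.0, abs=1e-12)


class TestVafLadder:
    def test_level_vafs_halve(self):
        assert ladder_vaf(1) == 1.0
        assert ladder_vaf(5) == pytest.approx(0.0625)  # 6.25%
        for i in range(1, 11):
            assert ladder_vaf(i + 1) == ladder_vaf(i) / 2

    def test_min_level_rounds_to_point_one_percent(self):
        assert round(ladder_vaf(11) * 100, 1) == 0.1

    def test_allocation_bounds(self):
        sizes = np.bincount(allocate_ladder(94, 11, (7, 9)))[1:]
        assert sizes.sum() == 94
        assert sizes.min() >= 7 and sizes.max() <= 9
        with pytest.raises(ValueError, match="feasible"):
            allocate_ladder(20, 11, (7, 9))

    def test_tumor_normal_manifests(self):
        rng = np.random.default_rng(9)
        designs = []
        for i in range(8):
            seq = _random_seq(rng, 100)
            designs.append(
                VariantDesign(
                    name=f"v{i}", region=Interval("c", i * 100, (i + 1) * 100),
                    region_seq=seq,
                    allele=AlleleSpec("SNV", 50, seq[50], "ACGT"[("ACGT".index(seq[50]) + 1) % 4]),
                )
            )
        mols, tumor, normal = design_vaf_ladder(designs, levels=4, per_level=(2, 2))
        assert sum(tumor.entries.values()) == pytest.approx(1.0, abs=1e-12)
        assert sum(normal.entries.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(mid.endswith("_wt") for mid in normal.entries)
        # expected VAFs are recoverable from the mixture fractions
        for e, d in zip(tumor.expected_variants, designs):
            alt_frac = tumor.entries[f"{d.name}_alt"]
            wt_frac = tumor.entries.get(f"{d.name}_wt", 0.0)
            assert alt_frac / (alt_frac + wt_frac) == pytest.approx(e.vaf, abs=1e-12)


class TestMsiDesign:
    def _setup(self, rng):
        # non-A bases abut the homopolymer so the planted run is exactly 25
        flank = _random_seq(rng, 99) + "G"
        region_seq = flank + "A" * 25 + "C" + _random_seq(rng, 99)
        region = Interval("c", 0, len(region_seq))
        locus = MsiLocusSpec(locus=Interval("c", 100, 125), unit="A", ref_copies=25)
        return region, region_seq, locus

    def test_deletion_mutant_drops_one_unit(self):
        rng = np.random.default_rng(10)
        region, region_seq, locus = self._setup(rng)
        mols, manifest, dist = design_msi_sequins(region, region_seq, locus, "unstable")
        mut = next(m for m in mols if m.role == "variant")
        assert "A" * 24 in mut.fwd_bases and "A" * 25 not in mut.fwd_bases

    def test_stable_is_single_wildtype(self):
        rng = np.random.default_rng(11)
        region, region_seq, locus = self._setup(rng)
        mols, manifest, dist = design_msi_sequins(region, region_seq, locus, "stable")
        assert len(mols) == 1 and manifest.entries[mols[0].id] == 1.0
        assert dist == {0: 1.0}

    def test_unstable_expected_offset_mass(self):
        rng = np.random.default_rng(12)
        region, region_seq, locus = self._setup(rng)
        _, manifest, dist = design_msi_sequins(region, region_seq, locus, "unstable", mutant_fraction=0.5)
        assert dist == {0: 0.5, -1: 0.5}
        assert sum(manifest.entries.values()) == pytest.approx(1.0)

    def test_too_few_copies_rejected(self):
        with pytest.raises(ValueError, match="2 repeat copies"):
            MsiLocusSpec(locus=Interval("c", 0, 1), unit="A", ref_copies=1)


class TestPrimers:
    def test_insilico_pcr_hand_verified(self):
        # revcomp("TACG") = "CGTA", found at [8, 12)
        assert insilico_pcr("ATCCAGGCCGTA", "ATCC", "TACG") == [(0, 12)]

    def test_unmatched_primer_gives_no_product(self):
        assert insilico_pcr("ATCCAGGCCGTA", "GGGG", "TACG") == []

    def test_tandem_duplication_gives_multiple_products(self):
        t = "ATGCAAACCGTA"
        assert len(insilico_pcr(t + t, "ATGC", "TACG", max_product=30)) >= 2

    def test_mirrored_pair_worked_example(self):
        pair = ContigPair("F", "F_rev", "ATGCCGGACCTA")
        pp = PrimerPair(forward="ATGC", reverse="TAGG", amplicon=Interval("F", 0, 12))
        mirrored = mirror_primer_pair(pp, pair)
        assert (mirrored.forward, mirrored.reverse) == ("ATCC", "TACG")
        assert (mirrored.amplicon.start, mirrored.amplicon.end) == (0, 12)

    def test_double_mirroring_returns_original(self):
        pair = ContigPair("F", "F_rev", "ATGCCGGACCTA")
        pp = PrimerPair(forward="ATGC", reverse="TAGG", amplicon=Interval("F", 0, 12))
        back = mirror_primer_pair(mirror_primer_pair(pp, pair), pair)
        assert (back.forward, back.reverse) == (pp.forward, pp.reverse)
        assert (back.amplicon.start, back.amplicon.end) == (0, 12)

    def test_random_designs_preserve_amplicon_width(self):
        rng = np.random.default_rng(13)
        checked = 0
        while checked < 100:
            seq = _random_seq(rng, 400)
            s = int(rng.integers(0, 200))
            w = int(rng.integers(60, 150))
            fwdp = seq[s : s + 18]
            from chiralseq import reverse_complement

            revp = reverse_complement(seq[s + w - 18 : s + w])
            if insilico_pcr(seq, fwdp, revp, 300) != [(s, s + w)]:
                continue  # primer happens to match elsewhere; skip design
            pair = ContigPair("c", "c_rev", seq)
            pp = PrimerPair(forward=fwdp, reverse=revp, amplicon=Interval("c", s, s + w))
            mirrored = mirror_primer_pair(pp, pair, max_product=300)
            assert mirrored.amplicon.width == w
            checked += 1

    def test_failing_input_pair_rejected(self):
        pair = ContigPair("F", "F_rev", "ATGCCGGACCTA")
        bad = PrimerPair(forward="ATGC", reverse="TAGG", amplicon=Interval("F", 0, 11))
        with pytest.raises(ValueError, match="amplify"):
            mirror_primer_pair(bad, pair)


class TestEditOps:
    def test_snv_is_all_match(self):
        ops = molecule_edit_ops([AlleleSpec("SNV", 5, "A", "C")], 20)
        assert ops == (("M", 20),)

    def test_deletion_and_insertion_scripts(self):
        del_ops = molecule_edit_ops([AlleleSpec("DEL", 4, "ATT", "A")], 20)
        assert del_ops == (("M", 5), ("D", 2), ("M", 13))
        ins_ops = molecule_edit_ops([AlleleSpec("INS", 4, "A", "AGG")], 20)
        assert ins_ops == (("M", 5), ("I", 2), ("M", 15))
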