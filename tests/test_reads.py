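"""Partitioning, read flipping, coordinate transform, downsampling, SAM I/O."""

import numpy as np
import pytest

from chiralseq import (
    Alignment,
    ContigPair,
    cross_alignment_percent,
    downsample_alignments,
    flip_read,
    flip_reads,
    partition_alignments,
    read_sam,
    reverse_complement,
    transform_alignment,
    transform_alignments,
    write_sam,
)
from chiralseq.alignment import cigar_string, parse_cigar
from chiralseq.reads import ReadRecord, as_sequenced, exact_match_assign


def _aln(contig="c", pos=0, cigar="10M", seq="A" * 10, **kw):
    defaults = dict(qname="r", mapq=60, qual="I" * len(seq))
    defaults.update(kw)
    return Alignment(contig=contig, pos=pos, cigar=parse_cigar(cigar), seq=seq, **defaults)


class TestCigar:
    def test_parse_roundtrip(self):
        for text in ("10M", "5S45M", "10M2D30M", "3M1I6M"):
            assert cigar_string(parse_cigar(text)) == text

    def test_malformed_rejected(self):
        with pytest.raises(ValueError):
            parse_cigar("10M3")


class TestPartition:
    def test_all_rev_contigs_go_chiral(self):
        records = [_aln(contig="chr1_rev", qname=f"r{i}") for i in range(5)]
        res = partition_alignments(records)
        assert res.counts == {"human": 0, "chiral": 5, "unmapped": 0}

    def test_counts_conserve_input(self):
        records = [
            _aln(contig="chr1", qname="a"),
            _aln(contig="chr1_rev", qname="b"),
            Alignment(qname="u", contig=None, pos=-1, mapq=0, cigar=(), seq="A" * 10, qual="I" * 10),
        ]
        res = partition_alignments(records)
        assert res.total == 3
        assert res.counts == {"human": 1, "chiral": 1, "unmapped": 1}

    def test_unknown_contig_rejected_with_table(self):
        with pytest.raises(KeyError):
            partition_alignments([_aln(contig="weird")], table={"chr1": "fwd"})

    def test_truth_tags_give_zero_cross_alignment(self):
        records = [
            _aln(contig="chr1", qname="a", tags={"XO": "chr1"}),
            _aln(contig="chr1_rev", qname="b", tags={"XO": "chr1_rev"}),
        ]
        res = partition_alignments(records)
        assert res.cross_alignment == {"fwd": 0.0, "rev": 0.0}

    def test_misassigned_read_counted_against_origin(self):
        records = [_aln(contig="chr1", qname="a", tags={"XO": "chr1_rev"})]
        res = partition_alignments(records)
        assert res.cross_alignment["rev"] == 1.0

    def test_worked_example_percent(self):
        assert f"{cross_alignment_percent(133, 732_000_000):.3g}" == "1.82e-05"


class TestFlip:
    def test_reversal_keeps_base_quality_pairing(self):
        rec = ReadRecord(id="r", mate=1, bases="ACCGT", quals="IIIFF")
        out = flip_read(rec)
        assert (out.bases, out.quals) == ("TGCCA", "FFIII")

    def test_involution(self):
        rec = ReadRecord(id="r", mate=2, bases="ACGTN", quals="ABCDE")
        assert flip_read(flip_read(rec)) == rec

    def test_reverse_strand_restored_then_flipped_maps_to_mirrored_interval(self):
        rng = np.random.default_rng(0)
        fwd = "".join(rng.choice(list("ACGT"), 120))
        pair = ContigPair("c", "c_rev", fwd)
        rev = pair.rev_bases
        # a read sampled from rev[40:60], stored on the minus strand
        segment = rev[40:60]
        a = _aln(contig="c_rev", pos=40, cigar="20M", seq=segment, strand="-", qual="I" * 20)
        restored = as_sequenced(a)
        assert restored.bases == reverse_complement(segment)
        flipped = flip_read(restored)
        # exact-match re-mapping of the flipped read onto the fwd genome
        # recovers the mirrored interval [L-60, L-40)
        assert flipped.bases == reverse_complement(fwd[60:80])
        hits = exact_match_assign(flipped.bases, {"c": fwd})
        assert hits == ["c"]
        assert reverse_complement(flipped.bases) == fwd[120 - 60 : 120 - 40]

    def test_pair_synchronization_and_orphans(self):
        recs = [
            ReadRecord(id="p", mate=1, bases="AC", quals="II"),
            ReadRecord(id="q", mate=1, bases="GG", quals="II"),
            ReadRecord(id="p", mate=2, bases="GT", quals="II"),
        ]
        pairs, singles = flip_reads(recs)
        assert len(pairs) == 1 and pairs[0][0].mate == 1 and pairs[0][1].mate == 2
        assert [s.id for s in singles] == ["q"]


class TestTransform:
    def test_simple_match(self):
        pair = ContigPair("c", "c_rev", "A" * 100)
        a = _aln(pos=10, cigar="50M", seq="A" * 50, qual="I" * 50)
        out = transform_alignment(a, pair)
        assert (out.contig, out.pos, cigar_string(out.cigar)) == ("c_rev", 40, "50M")

    def test_deletion_cigar_reverses(self):
        pair = ContigPair("c", "c_rev", "A" * 100)
        a = _aln(pos=5, cigar="10M2D30M", seq="A" * 40, qual="I" * 40)
        out = transform_alignment(a, pair)
        assert (out.pos, cigar_string(out.cigar)) == (53, "30M2D10M")

    def test_soft_clips_swap_ends(self):
        pair = ContigPair("c", "c_rev", "A" * 100)
        a = _aln(pos=0, cigar="5S45M", seq="A" * 50, qual="I" * 50)
        out = transform_alignment(a, pair)
        assert cigar_string(out.cigar) == "45M5S"
        assert out.pos == 100 - 45

    def test_involution_and_tag_policy(self):
        pair = ContigPair("c", "c_rev", "G" * 80)
        a = _aln(pos=7, cigar="3M1I6M", seq="G" * 10, qual="I" * 10,
                 tags={"NM": 1, "MD": "9", "RG": "lib1"}, strand="-")
        out = transform_alignment(a, pair)
        assert "NM" not in out.tags and "MD" not in out.tags and out.tags["RG"] == "lib1"
        assert out.strand == "-"
        back = transform_alignment(out, pair)
        assert (back.pos, back.cigar, back.seq, back.qual) == (a.pos, a.cigar, a.seq, a.qual)

    def test_span_overrun_rejected(self):
        pair = ContigPair("c", "c_rev", "A" * 20)
        with pytest.raises(ValueError, match="overruns"):
            transform_alignment(_aln(pos=15, cigar="10M", seq="A" * 10), pair)


class TestDownsample:
    def _pairs(self, n):
        out = []
        for i in range(n):
            out.append(_aln(qname=f"p{i}", mate=1, mate_contig="c", mate_pos=0, mate_strand="-"))
            out.append(_aln(qname=f"p{i}", mate=2, mate_contig="c", mate_pos=0, mate_strand="+"))
        return out

    def test_fraction_one_is_identity(self):
        recs = self._pairs(10)
        assert downsample_alignments(recs, 1.0, seed=1) == recs

    def test_binomial_bound_at_half(self):
        recs = self._pairs(10_000)
        kept = downsample_alignments(recs, 0.5, seed=3)
        n_pairs = len(kept) // 2
        assert abs(n_pairs - 5000) <= 3 * 50  # binomial 3 sigma

    def test_pair_coherence(self):
        kept = downsample_alignments(self._pairs(2000), 0.3, seed=5)
        from collections import Counter

        counts = Counter(a.qname for a in kept)
        assert set(counts.values()) == {2}

    def test_nested_subsets_across_fractions(self):
        recs = self._pairs(3000)
        k_large = {a.qname for a in downsample_alignments(recs, 0.6, seed=9)}
        k_small = {a.qname for a in downsample_alignments(recs, 0.2, seed=9)}
        assert k_small <= k_large

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            downsample_alignments([], 1.5, seed=0)


class TestSamRoundTrip:
    def test_write_read_preserves_records(self, tmp_path):
        path = str(tmp_path / "x.sam")
        records = [
            _aln(qname="a", pos=3, cigar="4M1I5M", seq="ACGTACGTAC", qual="IIIIHHHHGG",
                 strand="-", mate=1, mate_contig="c", mate_pos=40, mate_strand="+",
                 tlen=100, tags={"XO": "c", "RG": "lib"}),
            _aln(qname="a", pos=40, cigar="10M", seq="ACGTACGTAC", qual="I" * 10,
                 mate=2, mate_contig="c", mate_pos=3, mate_strand="-", tlen=-100,
                 tags={"XO": "c"}),
        ]
        write_sam(path, records, {"c": 200})
        back = read_sam(path)
        assert len(back) == 2
        for orig, rt in zip(records, back):
            for attr in ("qname", "contig", "pos", "cigar", "seq", "qual",
                         "strand", "mate", "mate_contig", "mate_pos", "tlen"):
                assert getattr(rt, attr) == getattr(orig, attr), attr
            assert rt.tags["XO"] == orig.tags["XO"]


class TestExactMatchAssignment:
    def test_unique_sequence_reads_never_cross_assign(self):
        rng = np.random.default_rng(21)
        fwd = "".join(rng.choice(list("ACGT"), 3000))
        pair = ContigPair("h", "h_rev", fwd)
        genome = {"h": fwd, "h_rev": pair.rev_bases}
        cross = 0
        n = 400
        for i in range(n):
            origin = "h" if i % 2 == 0 else "h_rev"
            start = int(rng.integers(0, 3000 - 150))
            read = genome[origin][start : start + 150]
            hits = exact_match_assign(read, genome)
            assert origin in hits
            cross += sum(1 for h in hits if h != origin)
        assert cross == 0
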