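import pytest

from trimtail import find_cross_mapping, load_mature_refs, mask_genome
from trimtail._seq import find_in_genome, revcomp
from trimtail.refs import MatureRef, MirnaLocus, extract_sequence, read_mirna_loci

from conftest import M1, write_fasta


def gff_line(chrom, start, end, strand, name, kind=None, ftype="miRNA"):
    attrs = f"ID={name};Name={name}"
    if kind:
        attrs += f";kind={kind}"
    return f"{chrom}\tsrc\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n"


class TestExtraction:
    def test_plus_strand_identity(self, toy_genome, toy_locus):
        assert extract_sequence(toy_genome, toy_locus) == M1

    def test_minus_strand_reverse_complement(self, toy_genome):
        locus = MirnaLocus("m", "chr1", 101, 121, "-", "guide")
        assert extract_sequence(toy_genome, locus) == revcomp(M1)

    def test_coordinates_beyond_chromosome_are_hard_error(self, toy_genome):
        locus = MirnaLocus("m", "chr1", 215, 240, "+", "guide")
        with pytest.raises(ValueError, match="m"):
            extract_sequence(toy_genome, locus)

    def test_locus_validation(self):
        with pytest.raises(ValueError):
            MirnaLocus("m", "chr1", 10, 5, "+", "guide")  # start > end
        with pytest.raises(ValueError):
            MirnaLocus("m", "chr1", 1, 40, "+", "guide")  # implausible length
        with pytest.raises(ValueError):
            MirnaLocus("m", "chr1", 1, 21, "x", "guide")  # bad strand


class TestLoadMatureRefs:
    def test_identical_sequences_collapse_into_one_ref(self, toy_genome, tmp_path):
        genome = dict(toy_genome)
        genome["chr2"] = "A" * 50 + M1 + "C" * 50
        gff = tmp_path / "ann.gff3"
        gff.write_text(
            "##gff-version 3\n"
            + gff_line("chr1", 101, 121, "+", "miR165a")
            + gff_line("chr2", 51, 71, "+", "miR165b")
        )
        refs = load_mature_refs(genome, gff)
        assert len(refs) == 1
        assert refs[0].ref_id == "miR165a/miR165b"
        assert refs[0].sequence == M1
        assert len(refs[0].member_loci) == 2

    def test_collapsing_partitions_all_loci(self, toy_genome, tmp_path):
        genome = dict(toy_genome)
        genome["chr2"] = "A" * 50 + M1 + "C" * 29 + revcomp(M1) + "G" * 30
        gff = tmp_path / "ann.gff3"
        gff.write_text(
            gff_line("chr1", 101, 121, "+", "miRa")
            + gff_line("chr2", 51, 71, "+", "miRb")
            + gff_line("chr2", 101, 121, "-", "miRc")  # revcomp stretch -> M1 again
        )
        refs = load_mature_refs(genome, gff)
        assert sum(len(r.member_loci) for r in refs) == 3
        assert len(refs) == 1  # all three extract to M1

    def test_star_label_from_attribute_and_suffix(self, toy_genome, tmp_path):
        genome = dict(toy_genome)
        genome["chr2"] = "T" * 40 + revcomp(M1)[:21] + "G" * 40
        gff = tmp_path / "ann.gff3"
        gff.write_text(
            gff_line("chr1", 101, 121, "+", "miR1", kind="guide")
            + gff_line("chr2", 41, 61, "+", "miR1-star")
        )
        refs = {r.ref_id: r for r in load_mature_refs(genome, gff)}
        assert refs["miR1"].kind == "guide"
        assert refs["miR1-star"].kind == "star"

    def test_non_mirna_features_ignored(self, toy_genome, tmp_path):
        gff = tmp_path / "ann.gff3"
        gff.write_text(
            gff_line("chr1", 50, 150, "+", "MIR1", ftype="gene")
            + gff_line("chr1", 101, 121, "+", "miR1")
        )
        assert len(read_mirna_loci(gff)) == 1

    def test_mature_fasta_mismatch_is_reported_not_silent(
        self, toy_genome, tmp_path, caplog
    ):
        gff = tmp_path / "ann.gff3"
        gff.write_text(gff_line("chr1", 101, 121, "+", "miR1"))
        fasta = tmp_path / "mature.fa"
        # RNA alphabet, deliberately disagreeing at the last base
        write_fasta(fasta, {"miR1": M1[:-1].replace("T", "U") + "C"})
        with caplog.at_level("WARNING"):
            refs = load_mature_refs(toy_genome, gff, mature_fasta=fasta)
        assert refs[0].sequence == M1  # annotation-derived wins
        assert any("conflict" in rec.message for rec in caplog.records)


class TestMaskGenome:
    def test_interval_replaced_by_n(self):
        masked = mask_genome({"c": "AAAACCCCGGGG"}, [("c", 5, 8)])
        assert masked.sequences["c"] == "AAAANNNNGGGG"
        assert masked.n_masked() == 4

    def test_union_of_overlapping_intervals(self):
        masked = mask_genome({"c": "ACGTACGTACGT"}, [("c", 3, 6), ("c", 5, 9)])
        assert masked.sequences["c"] == "AC" + "N" * 7 + "CGT"
        assert masked.n_masked() == 7

    def test_empty_locus_list_is_identity(self, toy_genome):
        masked = mask_genome(toy_genome, [])
        assert masked.sequences == toy_genome
        assert masked.n_masked() == 0

    def test_union_of_overlapping_loci(self, toy_genome, toy_locus):
        other = MirnaLocus("m2", "chr1", 110, 130, "+", "guide")
        masked = mask_genome(toy_genome, [toy_locus, other])
        seq = masked.sequences["chr1"]
        assert seq[100:130] == "N" * 30  # union of 101-121 and 110-130
        assert masked.n_masked() == 30
        assert seq[:100] == toy_genome["chr1"][:100]
        assert seq[130:] == toy_genome["chr1"][130:]

    def test_masking_is_idempotent(self, toy_genome, toy_locus):
        once = mask_genome(toy_genome, [toy_locus])
        twice = mask_genome(once.sequences, [toy_locus])
        assert twice.sequences == once.sequences

    def test_locus_beyond_chromosome_end_raises(self, toy_genome):
        locus = MirnaLocus("m", "chr1", 210, 230, "+", "guide")
        with pytest.raises(ValueError, match="beyond"):
            mask_genome(toy_genome, [locus])


class TestCrossMapping:
    def test_planted_second_copy_is_excluded(self, toy_genome, toy_locus, m1_ref):
        genome = dict(toy_genome)
        genome["chr2"] = "T" * 30 + M1 + "G" * 30  # unmasked verbatim copy
        masked = mask_genome(genome, [toy_locus])
        excluded, retained, report = find_cross_mapping([m1_ref], masked)
        assert [r.ref_id for r in excluded] == ["M1"]
        assert retained == []
        row = report.iloc[0]
        assert (row.match_chrom, row.match_pos, row.match_strand) == ("chr2", 31, "+")

    def test_reverse_complement_copy_is_excluded(self, toy_genome, toy_locus, m1_ref):
        genome = dict(toy_genome)
        genome["chr2"] = "T" * 30 + revcomp(M1) + "G" * 30
        masked = mask_genome(genome, [toy_locus])
        excluded, _, report = find_cross_mapping([m1_ref], masked)
        assert len(excluded) == 1
        assert report.iloc[0].match_strand == "-"

    def test_sequence_only_at_own_masked_locus_is_retained(
        self, toy_genome, toy_locus, m1_ref
    ):
        masked = mask_genome(toy_genome, [toy_locus])
        excluded, retained, _ = find_cross_mapping([m1_ref], masked)
        assert excluded == []
        assert [r.ref_id for r in retained] == ["M1"]

    def test_retained_refs_have_zero_hits_in_masked_genome(self, small_sim):
        _, reference, _, _ = small_sim
        excluded, retained, _ = find_cross_mapping(reference.refs, reference.masked)
        assert excluded == []
        for ref in retained:
            assert find_in_genome(ref.sequence, reference.masked.sequences) is None
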