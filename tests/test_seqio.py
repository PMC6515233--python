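"""File-format round trips and the curated block-table fixture."""

import pytest

from papmine import seqio


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nGDLG\n")
        recs = seqio.read_fasta(p)
        assert len(recs) == 1
        assert recs[0].id == "a" and recs[0].sequence == "GDLG"

    def test_terminal_stop_stripped_and_uppercased(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\ngdlgw*\n")
        assert seqio.read_fasta(p)[0].sequence == "GDLGW"

    def test_rare_letters_fold_to_x_with_warning(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nGBUG\n")
        with pytest.warns(UserWarning, match="mapped to X"):
            recs = seqio.read_fasta(p)
        assert recs[0].sequence == "GXXG"

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nGDLG\n>a\nGHVH\n")
        with pytest.raises(seqio.FormatError, match="'a'"):
            seqio.read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.raises(seqio.FormatError):
            seqio.read_fasta(p)

    def test_round_trip_identity(self, tmp_path, reference_proteome):
        records, _ = reference_proteome
        p = tmp_path / "all.fasta"
        seqio.write_fasta(records, p)
        back = seqio.read_fasta(p)
        assert [(r.id, r.sequence) for r in back] == [
            (r.id, r.sequence) for r in records
        ]


BED_LINE = (
    "scaffold1\t0\t4200\tgene_AS\t0\t+\t0\t4200\t0\t9\t"
    + ",".join(["200"] * 9)
    + "\t"
    + ",".join(str(500 * i) for i in range(9))
)


class TestGeneModels:
    def test_bed12_nine_exons_eight_introns(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text(BED_LINE + "\n")
        (model,) = seqio.read_gene_models(p, "bed12")
        assert len(model.exons) == 9
        assert len(model.introns) == 8
        assert model.exons[0] == (1, 200)  # 0-based half-open -> 1-based

    def test_single_exon_gene_has_no_introns(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("c\t10\t110\tg\t0\t+\t10\t110\t0\t1\t100\t0\n")
        (model,) = seqio.read_gene_models(p, "bed12")
        assert model.introns == []

    def test_gff3_and_bed12_agree(self, tmp_path):
        bed = tmp_path / "g.bed"
        bed.write_text(BED_LINE + "\n")
        gff_lines = ["##gff-version 3"]
        for i in range(9):
            s, e = 1 + 500 * i, 200 + 500 * i
            gff_lines.append(
                f"scaffold1\tsrc\texon\t{s}\t{e}\t.\t+\t.\tParent=gene_AS"
            )
        gff = tmp_path / "g.gff3"
        gff.write_text("\n".join(gff_lines) + "\n")
        (from_bed,) = seqio.read_gene_models(bed, "bed12")
        (from_gff,) = seqio.read_gene_models(gff, "gff3")
        assert from_bed == from_gff

    def test_bed_round_trip_reproduces_line(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text(BED_LINE + "\n")
        models = seqio.read_gene_models(p, "bed12")
        out = tmp_path / "out.bed"
        seqio.write_bed12(models, out)
        assert out.read_text().strip() == BED_LINE

    def test_overlapping_exons_rejected(self):
        with pytest.raises(seqio.FormatError, match="overlapping"):
            seqio.GeneModel("g", "c", "+", ((1, 100), (50, 150)))

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(seqio.FormatError, match="dialect"):
            seqio.read_gene_models(tmp_path / "x", "gtf")


class TestNewick:
    def test_two_leaf_string(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(A:0.1,B:0.2);\n")
        tree = seqio.read_newick(p)
        labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
        assert labels == ["A", "B"]

    def test_round_trip_up_to_float_format(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:0.1,B:0.2):0.05,(C:0.3,D:0.4):0.07);\n")
        tree = seqio.read_newick(p)
        out = tmp_path / "o.nwk"
        seqio.write_newick(tree, out)
        tree2 = seqio.read_newick(out)
        d1 = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        d2 = {l.taxon.label: l.edge.length for l in tree2.leaf_node_iter()}
        assert d1 == pytest.approx(d2)

    def test_unbalanced_parenthesis_rejected(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((A:0.1,B:0.2;\n")
        with pytest.raises(seqio.FormatError):
            seqio.read_newick(p)


class TestCountMatrixIO:
    def test_round_trip(self, tmp_path):
        cm = seqio.CountMatrix(
            ("g1", "g2"), ("s1", "s2"), ((3, 0), (10, 5)), (1000, 2000)
        )
        p = tmp_path / "counts.tsv"
        seqio.write_count_matrix(cm, p)
        assert seqio.read_count_matrix(p) == cm

    def test_missing_length_column_rejected(self, tmp_path):
        p = tmp_path / "counts.tsv"
        p.write_text("gene_id\ts1\ns1\t3\n")
        with pytest.raises(seqio.FormatError):
            seqio.read_count_matrix(p)


class TestReadAlignmentIO:
    def test_round_trip_split_and_contiguous(self, tmp_path):
        reads = [
            seqio.ReadAlignment("r1", "c", ((1, 50),)),
            seqio.ReadAlignment("r2", "c", ((10, 30), (100, 128))),
        ]
        p = tmp_path / "reads.tsv"
        seqio.write_alignment_table(reads, p)
        back = seqio.read_alignment_table(p)
        assert back == reads
        assert not back[0].is_split and back[1].is_split
        assert back[1].junctions == [(30, 100)]


class TestReferenceBlockTable:
    def test_nineteen_rows(self, reference_rows):
        assert len(reference_rows) == 19

    def test_known_complete_row(self, reference_rows):
        row = {r.name: r for r in reference_rows}["CsPAP15b"]
        assert row.block_strings == ("GDLG", "GDVTY", "GNHD", "ATWH", "GHVH")

    def test_known_slot1_missing_row(self, reference_rows):
        row = {r.name: r for r in reference_rows}["CsPAP2"]
        assert row.block_strings == ("", "GDISY", "GNHE", "VQGH", "GHVH")

    def test_exactly_three_rows_lack_slot1(self, reference_rows):
        missing = {r.name for r in reference_rows if not r.block_strings[0]}
        assert missing == {"CsPAP2", "CsPAP29b", "CsPAP3b"}
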