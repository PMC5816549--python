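"""Format readers, record normalisation and the repetitive-sequence collapse."""

import pytest

from hypmine.seqio import (
    AnnotationTable,
    SeqIOError,
    collapse_repetitive,
    read_blast_pairs,
    read_collinearity,
    read_gene_positions,
    read_proteome,
    write_proteome,
    ProteinRecord,
)


class TestReadProteome:
    def test_parses_ids_and_lengths(self, tmp_path):
        path = tmp_path / "p.faa"
        path.write_text(">A\nSPPPSPPP\n>B\nMKV\n")
        records = read_proteome(path)
        assert [(r.id, r.length) for r in records] == [("A", 8), ("B", 3)]

    def test_strips_stop_and_description(self, tmp_path):
        path = tmp_path / "p.faa"
        path.write_text(">seq1 desc\nMAST*\n")
        (rec,) = read_proteome(path)
        assert rec.id == "seq1" and rec.sequence == "MAST" and rec.length == 4

    def test_lowercase_is_uppercased(self, tmp_path):
        path = tmp_path / "p.faa"
        path.write_text(">x\nmast\n")
        assert read_proteome(path)[0].sequence == "MAST"

    def test_duplicate_id_is_an_error(self, tmp_path):
        path = tmp_path / "p.faa"
        path.write_text(">g1\nMAST\n>g1\nMKV\n")
        with pytest.raises(SeqIOError, match="g1"):
            read_proteome(path)

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "p.faa"
        path.write_text("")
        with pytest.raises(SeqIOError, match="no records"):
            read_proteome(path)

    def test_round_trip(self, tmp_path, toy_proteome):
        out = tmp_path / "out.faa"
        write_proteome(toy_proteome, out)
        again = read_proteome(out)
        assert [(r.id, r.sequence) for r in again] == [
            (r.id, r.sequence) for r in toy_proteome
        ]


class TestCollapseRepetitive:
    def test_exact_duplicates_collapse_to_smallest_id(self):
        records = [
            ProteinRecord("b", "MAST"),
            ProteinRecord("a", "MAST"),
            ProteinRecord("c", "MKV"),
        ]
        retained, report = collapse_repetitive(records)
        assert {r.id for r in retained} == {"a", "c"}
        assert report == {"a": ["b"]}

    def test_distinct_sequences_untouched(self, toy_proteome):
        retained, report = collapse_repetitive(toy_proteome)
        assert retained == list(toy_proteome) and report == {}

    def test_counts_are_conserved(self):
        records = [ProteinRecord(f"g{i}", "MAST") for i in range(10)]
        retained, report = collapse_repetitive(records)
        assert len(retained) == 1 and len(report["g0"]) == 9
        assert len(retained) + sum(len(v) for v in report.values()) == 10

    def test_idempotent(self, toy_proteome):
        once, _ = collapse_repetitive(toy_proteome + toy_proteome[:1])
        twice, report = collapse_repetitive(once)
        assert twice == once and report == {}


class TestGenePositions:
    def test_mcscanx_dialect_ranks(self, tmp_path):
        path = tmp_path / "genes.gff"
        path.write_text("chr1\tg1\t100\t200\nchr1\tg2\t300\t400\n")
        positions = {p.gene_id: p for p in read_gene_positions(path)}
        assert positions["g1"].rank == 0 and positions["g2"].rank == 1

    def test_gff3_dialect(self, tmp_path):
        path = tmp_path / "genes.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr2\tsrc\tgene\t50\t80\t.\t+\t.\tID=g5;Name=foo\n"
        )
        (pos,) = read_gene_positions(path)
        assert (pos.gene_id, pos.start, pos.end, pos.chromosome) == ("g5", 50, 80, "chr2")

    def test_tie_broken_by_gene_id(self, tmp_path):
        path = tmp_path / "genes.gff"
        path.write_text("chr1\tg_b\t100\t200\nchr1\tg_a\t100\t150\n")
        positions = {p.gene_id: p for p in read_gene_positions(path)}
        assert positions["g_a"].rank == 0 and positions["g_b"].rank == 1

    def test_ranks_are_a_permutation_per_chromosome(self, tmp_path, rng):
        lines = []
        for chrom in ("c1", "c2"):
            starts = rng.choice(10_000, size=25, replace=False)
            lines += [
                f"{chrom}\t{chrom}g{i}\t{s}\t{s + 10}" for i, s in enumerate(starts)
            ]
        path = tmp_path / "genes.gff"
        path.write_text("\n".join(lines) + "\n")
        positions = read_gene_positions(path)
        for chrom in ("c1", "c2"):
            ranks = sorted(p.rank for p in positions if p.chromosome == chrom)
            assert ranks == list(range(25))

    def test_bad_line_reports_line_number(self, tmp_path):
        path = tmp_path / "genes.gff"
        path.write_text("chr1\tg1\t100\t200\nchr1\tg2\tNOPE\t400\n")
        with pytest.raises(SeqIOError, match="line 2"):
            read_gene_positions(path)


class TestAnnotationTables:
    def test_signalp_short_parse(self, tmp_path):
        path = tmp_path / "sp.txt"
        path.write_text(
            "# SignalP-4.0 euk predictions\n"
            "# name Cmax pos Ymax pos Smax pos Smean D ? Dmaxcut Networks-used\n"
            "g1 0.85 23 0.80 23 0.90 15 0.75 0.78 Y 0.45 SignalP-noTM\n"
            "g2 0.10 2 0.08 2 0.12 1 0.05 0.06 N 0.45 SignalP-noTM\n"
        )
        table = AnnotationTable().load_signalp_short(path)
        assert table.get("g1").has_signal_peptide
        assert table.get("g1").sp_cleavage_site == 23
        assert not table.get("g2").has_signal_peptide
        assert table.is_annotated("g2") and not table.is_annotated("g3")

    def test_bigpi_keyword_parse(self, tmp_path):
        path = tmp_path / "gpi.txt"
        path.write_text(
            "Query: g1\n"
            "Potential GPI-modification site was found\n"
            "Query: g2\n"
            "No GPI-modification site was found\n"
        )
        table = AnnotationTable().load_bigpi(path)
        assert table.get("g1").has_gpi_anchor
        assert not table.get("g2").has_gpi_anchor

    def test_domtblout_parse(self, tmp_path):
        path = tmp_path / "hits.domtbl"
        fields = (
            "g1 - 250 fas1 PF02469.20 140 1e-40 130.0 0.1 1 1 "
            "1e-42 2.5e-38 128.0 0.1 5 130 10 140 8 145 0.98 desc"
        )
        path.write_text("# comment\n" + fields.replace(" ", "\t") + "\n")
        table = AnnotationTable().load_domtblout(path, {"g1": 250})
        (hit,) = table.get("g1").domain_hits
        assert hit.accession == "PF02469"
        assert hit.i_evalue == pytest.approx(2.5e-38)
        assert (hit.env_start, hit.env_end) == (7, 145)

    def test_domtblout_envelope_exceeding_length_is_error(self, tmp_path):
        path = tmp_path / "hits.domtbl"
        fields = (
            "g1 - 250 fas1 PF02469.20 140 1e-40 130.0 0.1 1 1 "
            "1e-42 2.5e-38 128.0 0.1 5 130 10 140 8 400 0.98 desc"
        )
        path.write_text(fields.replace(" ", "\t") + "\n")
        with pytest.raises(SeqIOError, match="envelope"):
            AnnotationTable().load_domtblout(path, {"g1": 250})


class TestPairTables:
    def test_blast_tabular(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "q1\ts1\t85.2\t100\t10\t2\t1\t100\t5\t104\t1e-30\t120\n"
        )
        assert read_blast_pairs(path) == [("q1", "s1", 85.2, 1e-30)]

    def test_collinearity_dialect(self, tmp_path):
        path = tmp_path / "blocks.collinearity"
        path.write_text(
            "############### Parameters ###############\n"
            "# MATCH_SCORE: 50\n"
            "## Alignment 0: score=500.0 e_value=0 N=2 c1&c2 plus\n"
            "  0-  0:\tgeneA\tgeneB\t  1e-50\n"
            "  0-  1:\tgeneC\tgeneD\t  0\n"
        )
        assert read_collinearity(path) == [("geneA", "geneB"), ("geneC", "geneD")]
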