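import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magdb.readers import (
    CrossFileInconsistencyError,
    FastaRecord,
    FormatError,
    MalformedFastaError,
    MalformedGffError,
    QualityRangeError,
    normalize_genome_name,
    parse_checkm2_report,
    parse_drep_tables,
    parse_gtdbtk_summary,
    parse_lineage,
    read_fasta,
    read_gff3,
    write_fasta,
)


@pytest.mark.parametrize("filename, expected", [
    ("bin1.fa", "bin1"),
    ("bin1.fasta", "bin1"),
    ("bin.1.fna", "bin.1"),
    ("bin1", "bin1"),
    ("/deep/path/MAG_007.FA", "MAG_007"),
])
def test_normalize_genome_name(filename, expected):
    assert normalize_genome_name(filename) == expected


class TestFasta:
    def test_case_and_concatenation(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">c1 circular\nACGT\nacgt\n")
        (rec,) = read_fasta(p)
        assert rec == FastaRecord("c1", "circular", "ACGTACGT")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        assert read_fasta(p) == []

    def test_sequence_before_header_rejected(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text("ACGT\n>c1\nACGT\n")
        with pytest.raises(MalformedFastaError):
            read_fasta(p)

    def test_fixture_bin_records_match_layout(self, project42):
        d, manifest = project42
        bins = sorted((d / "bins").glob("*.fa"))
        assert len(bins) == manifest.n_genomes
        total = sum(len(read_fasta(p)) for p in bins)
        assert total == manifest.n_contigs

    @settings(max_examples=40, derandomize=True)
    @given(st.lists(
        st.tuples(
            st.text(alphabet="abcXYZ019_", min_size=1, max_size=12),
            st.text(alphabet="abc def", max_size=20),
            st.text(alphabet="ACDEFGHIKLMNPQRSTVWY*-", min_size=1, max_size=300),
        ),
        min_size=1, max_size=8, unique_by=lambda t: t[0],
    ))
    def test_round_trip_identity(self, tmp_path_factory, records):
        """write -> re-read is identity on (id, description, sequence)."""
        recs = [FastaRecord(i, " ".join(d.split()), s) for i, d, s in records]
        path = tmp_path_factory.mktemp("rt") / "rt.fa"
        write_fasta(recs, path)
        assert read_fasta(path) == recs


class TestGff3:
    def test_directive_only_file_is_empty(self, tmp_path):
        p = tmp_path / "x.gff"
        p.write_text("##gff-version 3\n")
        assert list(read_gff3(p)) == []

    def test_field_mapping(self, tmp_path):
        p = tmp_path / "x.gff"
        p.write_text("c1\tProdigal\tCDS\t10\t39\t.\t+\t0\t"
                     "ID=g1;product=hypothetical protein\n")
        (f,) = read_gff3(p)
        assert (f.seqid, f.feature_type, f.start, f.end, f.strand) == \
            ("c1", "CDS", 10, 39, "+")
        assert f.score is None and f.frame == 0
        assert f.attributes == {"ID": "g1", "product": "hypothetical protein"}

    def test_percent_decoding(self, tmp_path):
        p = tmp_path / "x.gff"
        p.write_text("c1\tsrc\tCDS\t1\t9\t.\t+\t0\tnote=a%3Bb%2Cc\n")
        (f,) = read_gff3(p)
        assert f.attributes["note"] == "a;b,c"

    def test_wrong_column_count_names_line(self, tmp_path):
        p = tmp_path / "x.gff"
        p.write_text("##gff-version 3\nc1\tsrc\tCDS\t1\t9\n")
        with pytest.raises(MalformedGffError, match=":2:"):
            list(read_gff3(p))

    def test_start_beyond_end_rejected(self, tmp_path):
        p = tmp_path / "x.gff"
        p.write_text("c1\tsrc\tCDS\t10\t5\t.\t+\t0\tID=g\n")
        with pytest.raises(MalformedGffError):
            list(read_gff3(p))

    def test_trailing_fasta_block_ignored(self, project42):
        """Feature count must equal an independent scan of pre-##FASTA lines."""
        d, _ = project42
        gff = d / "gff" / "bin1.gff"  # the fixture embeds a ##FASTA block here
        text = gff.read_text().splitlines()
        assert "##FASTA" in text
        head = text[: text.index("##FASTA")]
        expected = sum(1 for ln in head if ln and not ln.startswith("#"))
        assert len(list(read_gff3(gff))) == expected

    def test_agrees_with_gffutils(self, project42):
        """Independent parser cross-check on a fixture file."""
        gffutils = pytest.importorskip("gffutils")
        d, _ = project42
        gff = d / "gff" / "bin2.gff"
        db = gffutils.create_db(str(gff), ":memory:", keep_order=True)
        theirs = [(f.seqid, f.featuretype, f.start, f.end, f.strand,
                   f.attributes["ID"][0])
                  for f in db.all_features(order_by=("seqid", "start"))]
        ours = sorted(
            (f.seqid, f.feature_type, f.start, f.end, f.strand, f.attributes["ID"])
            for f in read_gff3(gff)
        )
        assert ours == sorted(theirs)


class TestGtdbtkSummary:
    def _write(self, tmp_path, rows):
        p = tmp_path / "summary.tsv"
        p.write_text("user_genome\tclassification\n" +
                     "".join(f"{g}\t{c}\n" for g, c in rows))
        return p

    def test_partial_lineage(self, tmp_path):
        p = self._write(tmp_path, [
            ("bin1", "d__Bacteria;p__Bacillota;c__;o__;f__;g__;s__")])
        (row,) = parse_gtdbtk_summary(p)
        assert row.lowest_assigned_rank == "phylum"
        assert row.is_novel_species
        assert dict(row.lineage)["phylum"] == "Bacillota"

    def test_full_lineage_not_novel(self, tmp_path):
        p = self._write(tmp_path, [
            ("bin1", "d__Bacteria;p__P;c__C;o__O;f__F;g__G;s__G sp1")])
        (row,) = parse_gtdbtk_summary(p)
        assert not row.is_novel_species
        assert row.lowest_assigned_rank == "species"

    def test_unclassified(self, tmp_path):
        p = self._write(tmp_path, [("bin1", "Unclassified")])
        (row,) = parse_gtdbtk_summary(p)
        assert row.lowest_assigned_rank is None
        assert row.is_novel_species
        assert all(name is None for _, name in row.lineage)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "summary.tsv"
        p.write_text("genome\tlineage\nbin1\tx\n")
        with pytest.raises(FormatError):
            parse_gtdbtk_summary(p)

    def test_out_of_order_prefix_rejected(self, tmp_path):
        with pytest.raises(FormatError):
            parse_lineage("p__Bacillota;d__Bacteria")

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.sampled_from(["A", "B", "Cx"]) | st.just(""),
                    min_size=6, max_size=6))
    def test_novelty_is_monotone_in_species_slot(self, names):
        """Filling in the species slot flips novelty and changes nothing else."""
        base = ";".join(
            f"{p}{n}" for p, n in zip(("d__", "p__", "c__", "o__", "f__", "g__"),
                                      names))
        without = parse_lineage(base + ";s__")
        with_sp = parse_lineage(base + ";s__Genus sp1")
        assert without[:6] == with_sp[:6]
        assert dict(without)["species"] is None
        assert dict(with_sp)["species"] == "Genus sp1"


class TestDrep:
    def _write(self, tmp_path, cluster_rows, winners=None):
        c = tmp_path / "Cdb.csv"
        c.write_text("genome,secondary_cluster\n" +
                     "".join(f"{g},{l}\n" for g, l in cluster_rows))
        w = None
        if winners is not None:
            w = tmp_path / "Wdb.csv"
            w.write_text("genome\n" + "".join(f"{g}\n" for g in winners))
        return c, w

    def test_grouping(self, tmp_path):
        c, _ = self._write(tmp_path, [("g1.fa", "1_1"), ("g2.fa", "1_1"),
                                      ("g3.fa", "2_1")])
        rows = parse_drep_tables(c)
        labels = {}
        for r in rows:
            labels.setdefault(r.cluster_label, []).append(r.genome_name)
        assert {k: len(v) for k, v in labels.items()} == {"1_1": 2, "2_1": 1}

    def test_empty_table(self, tmp_path):
        c, _ = self._write(tmp_path, [])
        assert parse_drep_tables(c) == []

    def test_winner_flags(self, tmp_path):
        c, w = self._write(tmp_path,
                           [("g1.fa", "1_1"), ("g2.fa", "1_1"), ("g3.fa", "2_1")],
                           winners=["g1.fa", "g3.fa"])
        rows = parse_drep_tables(c, w)
        assert {r.genome_name for r in rows if r.is_winner} == {"g1", "g3"}

    def test_unknown_winner_rejected(self, tmp_path):
        c, w = self._write(tmp_path, [("g1.fa", "1_1")], winners=["ghost.fa"])
        with pytest.raises(CrossFileInconsistencyError):
            parse_drep_tables(c, w)


class TestCheckm2:
    def test_direct_mapping(self, tmp_path):
        p = tmp_path / "q.tsv"
        p.write_text("Name\tCompleteness\tContamination\nbin1\t98.5\t1.2\n")
        (row,) = parse_checkm2_report(p)
        assert (row.genome_name, row.completeness_pct, row.contamination_pct) == \
            ("bin1", 98.5, 1.2)

    def test_out_of_range_completeness_rejected(self, tmp_path):
        p = tmp_path / "q.tsv"
        p.write_text("Name\tCompleteness\tContamination\nbin1\t101.0\t1.2\n")
        with pytest.raises(QualityRangeError):
            parse_checkm2_report(p)

    def test_fixture_names_match_manifest(self, project42):
        d, manifest = project42
        rows = parse_checkm2_report(d / "checkm2" / "quality_report.tsv")
        assert len(rows) == manifest.n_genomes
        assert {r.genome_name for r in rows} == {f"bin{i}" for i in range(1, 6)}
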