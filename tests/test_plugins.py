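import logging

import pytest

from magdb import plugins
from magdb.plugins import (
    AmbiguousPluginError,
    FormatError,
    MalformedLineError,
    MalformedTermError,
    UnifiedAnnotation,
    discover_plugins,
    get_parser,
    parse_clean_output,
    parse_dbcan_overview,
    parse_interproscan_tsv,
    parse_proteinfer_output,
)

DBCAN_HEADER = "Gene ID\tEC#\tHMMER\tdbCAN_sub\tDIAMOND\t#ofTools\n"


class TestDbcan:
    def _write(self, tmp_path, rows):
        p = tmp_path / "overview.tsv"
        p.write_text(DBCAN_HEADER + "".join(rows))
        return p

    def test_subfamily_unit_yields_family_and_subfamily(self, tmp_path):
        p = self._write(tmp_path, ["p1\t-\tGH5_2(31-330)\t-\t-\t3\n"])
        fam, sub = parse_dbcan_overview(p)
        assert (fam.annotation_type, fam.accession, fam.coord_start,
                fam.coord_stop, fam.score) == ("family", "GH5", 31, 330, 3.0)
        assert (sub.annotation_type, sub.accession) == ("subfamily", "GH5_2")

    def test_compound_unit_yields_two_families(self, tmp_path):
        p = self._write(tmp_path, ["p2\t-\tCBM3(5-90)+GH5(120-400)\t-\t-\t2\n"])
        anns = parse_dbcan_overview(p)
        assert [(a.annotation_type, a.accession) for a in anns] == \
            [("family", "CBM3"), ("family", "GH5")]
        assert [(a.coord_start, a.coord_stop) for a in anns] == \
            [(5, 90), (120, 400)]

    def test_dash_prediction_yields_nothing(self, tmp_path):
        p = self._write(tmp_path, ["p3\t-\t-\t-\t-\t0\n"])
        assert parse_dbcan_overview(p) == []

    def test_malformed_class_code_skips_row_with_warning(self, tmp_path, caplog):
        p = self._write(tmp_path, ["p4\t-\tZZ9(1-5)\t-\t-\t1\n",
                                   "p5\t-\tGH13\t-\t-\t1\n"])
        with caplog.at_level(logging.WARNING, logger="magdb.plugins"):
            anns = parse_dbcan_overview(p)
        assert [a.accession for a in anns] == ["GH13"]
        assert any("skipped 1" in m for m in caplog.messages)

    def test_recommend_results_column_preferred(self, tmp_path):
        p = tmp_path / "overview.tsv"
        p.write_text("Gene ID\tHMMER\tRecommend Results\t#ofTools\n"
                     "p1\tGH99(1-2)\tGH5(3-4)\t2\n")
        (a,) = parse_dbcan_overview(p)
        assert (a.accession, a.coord_start) == ("GH5", 3)


class TestInterproscan:
    LINE13 = ("p1\t" + "a" * 32 + "\t350\tPfam\tPF00150\tCellulase\t40\t310\t"
              "1.2e-50\tT\t01-01-2026\tIPR001547\tGlycoside hydrolase family 5")

    def test_signature_and_interpro_domains(self, tmp_path):
        p = tmp_path / "ipr.tsv"
        p.write_text(self.LINE13 + "\n")
        sig, ipr = parse_interproscan_tsv(p)
        assert (sig.annotation_type, sig.accession, sig.coord_start,
                sig.coord_stop, sig.score) == ("domain", "PF00150", 40, 310, 1.2e-50)
        assert sig.source_tool == "interproscan:Pfam"
        assert (ipr.annotation_type, ipr.accession) == ("domain", "IPR001547")

    def test_dash_evalue_gives_no_score(self, tmp_path):
        line = self.LINE13.replace("1.2e-50", "-")
        p = tmp_path / "ipr.tsv"
        p.write_text(line + "\n")
        assert parse_interproscan_tsv(p)[0].score is None

    def test_go_column_split(self, tmp_path):
        p = tmp_path / "ipr.tsv"
        p.write_text(self.LINE13 + "\tGO:0004553|GO:0005975\t-\n")
        anns = parse_interproscan_tsv(p)
        gos = [a.accession for a in anns if a.annotation_type == "go_term"]
        assert gos == ["GO:0004553", "GO:0005975"]

    def test_short_line_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "ipr.tsv"
        p.write_text("p1\tonly\tthree\n")
        with pytest.raises(MalformedLineError, match=":1:"):
            parse_interproscan_tsv(p)


class TestClean:
    def test_multiple_ec_terms(self, tmp_path):
        p = tmp_path / "clean.csv"
        p.write_text("p7,EC:3.2.1.4/0.8731;EC:3.2.1.91/0.1012\n")
        a, b = parse_clean_output(p)
        assert (a.accession, a.score) == ("3.2.1.4", 0.8731)
        assert (b.accession, b.score) == ("3.2.1.91", 0.1012)
        assert {x.annotation_type for x in (a, b)} == {"ec_number"}

    def test_empty_file(self, tmp_path):
        p = tmp_path / "clean.csv"
        p.write_text("")
        assert parse_clean_output(p) == []

    def test_scores_not_range_constrained(self, tmp_path):
        p = tmp_path / "clean.csv"
        p.write_text("p1,EC:1.1.1.1/1.5\n")
        assert parse_clean_output(p)[0].score == 1.5

    def test_term_without_slash_rejected(self, tmp_path):
        p = tmp_path / "clean.csv"
        p.write_text("p1,EC:1.1.1.1\n")
        with pytest.raises(MalformedTermError):
            parse_clean_output(p)


class TestProteinfer:
    HEADER = "sequence_name\tpredicted_label\tconfidence\n"

    @pytest.mark.parametrize("label, atype, accession", [
        ("GO:0016787", "go_term", "GO:0016787"),
        ("EC:3.2.1.-", "ec_number", "3.2.1.-"),
        ("Pfam:PF00150", "description", "Pfam:PF00150"),
    ])
    def test_label_mapping(self, tmp_path, label, atype, accession):
        p = tmp_path / "pi.tsv"
        p.write_text(self.HEADER + f"p3\t{label}\t0.97\n")
        (a,) = parse_proteinfer_output(p)
        assert (a.annotation_type, a.accession, a.score) == (atype, accession, 0.97)

    def test_header_only_file(self, tmp_path):
        p = tmp_path / "pi.tsv"
        p.write_text(self.HEADER)
        assert parse_proteinfer_output(p) == []

    def test_non_numeric_confidence_rejected(self, tmp_path):
        p = tmp_path / "pi.tsv"
        p.write_text(self.HEADER + "p3\tGO:1\thigh\n")
        with pytest.raises(FormatError):
            parse_proteinfer_output(p)


class TestPluginContract:
    def test_all_reference_parsers_emit_valid_records(self, project42):
        d, manifest = project42
        files = {
            "dbcan": d / "annotations" / "dbcan_overview.tsv",
            "interpro": d / "annotations" / "interproscan.tsv",
            "clean": d / "annotations" / "clean.csv",
            "proteinfer": d / "annotations" / "proteinfer.tsv",
        }
        for name, path in files.items():
            anns = get_parser(name)(path)
            assert len(anns) == manifest.annotation_counts[name]
            assert all(isinstance(a, UnifiedAnnotation) for a in anns)

    def test_parser_determinism(self, project42):
        d, _ = project42
        path = d / "annotations" / "dbcan_overview.tsv"
        assert parse_dbcan_overview(path) == parse_dbcan_overview(path)

    def test_parsers_never_touch_the_catalog(self, populated42, project42):
        """Plugins populate tables; they must never create/drop/alter them."""
        db = populated42[0]
        d, _ = project42
        before = db.conn.execute(
            "SELECT name, sql FROM sqlite_master ORDER BY name").fetchall()
        for name, fname in (("dbcan", "dbcan_overview.tsv"),
                            ("clean", "clean.csv")):
            get_parser(name)(d / "annotations" / fname)
        after = db.conn.execute(
            "SELECT name, sql FROM sqlite_master ORDER BY name").fetchall()
        assert [tuple(r) for r in before] == [tuple(r) for r in after]


class TestDiscovery:
    def test_builtins_always_present(self):
        names = {d.name for d in discover_plugins()}
        assert {"dbcan", "interpro", "clean", "proteinfer"} <= names

    def test_disable_flag(self):
        by_name = {d.name: d for d in discover_plugins(disabled={"dbcan"})}
        assert not by_name["dbcan"].enabled
        assert by_name["interpro"].enabled

    def test_empty_scope_without_builtins(self):
        assert discover_plugins(include_builtins=False, entry_points=[]) == []

    def test_duplicate_names_rejected(self):
        class FakeEp:
            name = "dbcan"
            dist = None
        with pytest.raises(AmbiguousPluginError):
            discover_plugins(entry_points=[FakeEp()])

    def test_unknown_parser_lookup(self):
        with pytest.raises(plugins.PluginError, match="clean"):
            get_parser("nonexistent")
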