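import pytest

from magdb.assembler import (
    DuplicateGenomeError,
    StageOrderError,
    assemble_clusters,
    assemble_genes,
    assemble_genomes_and_contigs,
    assemble_proteins,
    assemble_quality,
    assemble_taxonomy,
    link_protein_annotations,
)
from magdb.plugins import UnifiedAnnotation
from magdb.readers import ClusterRow, QualityRow, TaxonomyRow, parse_lineage
from magdb.schema import UnresolvedReferenceError, insert_if_absent


def _tax_row(genome, classification):
    lineage = parse_lineage(classification)
    assigned = [r for r, n in lineage if n is not None]
    return TaxonomyRow(
        user_genome=genome, lineage=lineage,
        lowest_assigned_rank=assigned[-1] if assigned else None,
        is_novel_species=dict(lineage)["species"] is None,
        classification=classification,
    )


class TestGenomesAndContigs:
    def test_counts(self, mini_project):
        report = assemble_genomes_and_contigs(
            mini_project["db"], mini_project["assembly"])
        assert report.counts == {"genome": 2, "contig": 3}
        assert report.created == 5

    def test_rerun_is_noop(self, mini_project):
        db, asm = mini_project["db"], mini_project["assembly"]
        assemble_genomes_and_contigs(db, asm)
        report = assemble_genomes_and_contigs(db, asm)
        assert report.created == 0
        assert db.conn.execute("SELECT COUNT(*) FROM genome").fetchone()[0] == 2

    def test_colliding_bin_names_rejected(self, mini_project):
        db, asm = mini_project["db"], mini_project["assembly"]
        insert_if_absent(db, "fasta_file", [{
            "assembly_ref": asm, "path": "/elsewhere/binA.fasta",
            "sha256": "1" * 64, "file_role": "genome_bins"}],
            ("assembly_ref", "path"))
        with pytest.raises(DuplicateGenomeError):
            assemble_genomes_and_contigs(db, asm)


class TestGenes:
    def test_requires_genomes_first(self, mini_project):
        with pytest.raises(StageOrderError):
            assemble_genes(mini_project["db"], mini_project["assembly"])

    def test_cds_features_become_genes(self, mini_project):
        db, asm = mini_project["db"], mini_project["assembly"]
        assemble_genomes_and_contigs(db, asm)
        report = assemble_genes(db, asm)
        # 3 contigs x 2 CDS; the tRNA features stay file entities only
        assert report.created == 6
        types = db.conn.execute(
            "SELECT COUNT(*) FROM gene JOIN gff_entry "
            "ON gene.gff_entry_ref = gff_entry.gff_entry_id "
            "WHERE gff_entry.feature_type != 'CDS'").fetchone()[0]
        assert types == 0

    def test_ghost_seqid_strict_vs_lenient(self, mini_project):
        db, asm = mini_project["db"], mini_project["assembly"]
        gf = db.conn.execute("SELECT gff_file_id FROM gff_file LIMIT 1").fetchone()[0]
        insert_if_absent(db, "gff_entry", [{
            "gff_file_ref": gf, "line_number": 99, "seqid": "ghost",
            "source": "x", "feature_type": "CDS", "start": 1, "end": 9,
            "score": None, "strand": "+", "frame": 0,
            "attributes_json": '{"ID": "gx"}'}],
            ("gff_file_ref", "line_number"))
        assemble_genomes_and_contigs(db, asm)
        with pytest.raises(UnresolvedReferenceError, match="ghost"):
            assemble_genes(db, asm, strict=True)
        report = assemble_genes(db, asm, strict=False)
        assert report.unmatched_keys == ["ghost"]
        assert report.created == 6


class TestProteins:
    def _assembled(self, mini_project):
        db, asm = mini_project["db"], mini_project["assembly"]
        assemble_genomes_and_contigs(db, asm)
        assemble_genes(db, asm)
        return db, asm

    def test_requires_genes_first(self, mini_project):
        db, asm = mini_project["db"], mini_project["assembly"]
        assemble_genomes_and_contigs(db, asm)
        with pytest.raises(StageOrderError):
            assemble_proteins(db, asm)

    def test_one_protein_per_gene_with_stop_stripped(self, mini_project):
        db, asm = self._assembled(mini_project)
        report = assemble_proteins(db, asm)
        assert report.created == 6
        assert report.unmatched_keys == []
        # mini fixture proteins are 30 residues incl. the '*' stop
        lengths = {r[0] for r in db.conn.execute(
            "SELECT sequence_length_aa FROM protein")}
        assert lengths == {29}

    def test_protein_count_never_exceeds_genes(self, populated42):
        db = populated42[0]
        genes = db.conn.execute("SELECT COUNT(*) FROM gene").fetchone()[0]
        proteins = db.conn.execute("SELECT COUNT(*) FROM protein").fetchone()[0]
        assert proteins <= genes


class TestAnnotations:
    def _with_proteins(self, mini_project):
        db, asm = mini_project["db"], mini_project["assembly"]
        assemble_genomes_and_contigs(db, asm)
        assemble_genes(db, asm)
        assemble_proteins(db, asm)
        return db, asm

    def test_link_and_deduplicate(self, mini_project):
        db, asm = self._with_proteins(mini_project)
        ann = UnifiedAnnotation(protein_key="binA_c1_g1", source_tool="dbcan",
                                annotation_type="family", accession="GH5",
                                coord_start=3, coord_stop=40, score=2.0)
        report = link_protein_annotations(db, asm, [ann, ann])
        assert report.created == 1
        again = link_protein_annotations(db, asm, [ann])
        assert again.created == 0

    def test_unmatched_protein_key(self, mini_project):
        db, asm = self._with_proteins(mini_project)
        ann = UnifiedAnnotation(protein_key="nobody", source_tool="dbcan",
                                annotation_type="family", accession="GH5")
        with pytest.raises(UnresolvedReferenceError):
            link_protein_annotations(db, asm, [ann], strict=True)
        report = link_protein_annotations(db, asm, [ann], strict=False)
        assert report.unmatched_keys == ["nobody"]


class TestClustersTaxonomyQuality:
    def _with_genomes(self, mini_project):
        db, asm = mini_project["db"], mini_project["assembly"]
        assemble_genomes_and_contigs(db, asm)
        return db, asm

    def test_cluster_rows_and_winner(self, mini_project):
        db, asm = self._with_genomes(mini_project)
        rows = [ClusterRow("binA", "1_1", True), ClusterRow("binB", "1_1", False)]
        report = assemble_clusters(db, asm, rows)
        assert report.counts["genome_cluster"] == 1
        rep = db.conn.execute(
            "SELECT g.name FROM genome_cluster gc JOIN genome g "
            "ON gc.representative_ref = g.genome_id").fetchone()
        assert rep["name"] == "binA"
        refs = {r[0] for r in db.conn.execute("SELECT cluster_ref FROM genome")}
        assert None not in refs and len(refs) == 1

    def test_no_cluster_rows_leaves_null_refs(self, mini_project):
        db, asm = self._with_genomes(mini_project)
        report = assemble_clusters(db, asm, [])
        assert report.created == 0
        refs = {r[0] for r in db.conn.execute("SELECT cluster_ref FROM genome")}
        assert refs == {None}

    def test_unknown_genome_in_cluster_table(self, mini_project):
        db, asm = self._with_genomes(mini_project)
        with pytest.raises(UnresolvedReferenceError):
            assemble_clusters(db, asm, [ClusterRow("ghost", "1_1", False)])

    def test_shared_genus_creates_one_taxon(self, mini_project):
        db, asm = self._with_genomes(mini_project)
        rows = [
            _tax_row("binA", "d__Bacteria;p__P;c__C;o__O;f__F;g__Exemplum;s__"),
            _tax_row("binB", "d__Bacteria;p__P;c__C;o__O;f__F;g__Exemplum;s__"),
        ]
        report = assemble_taxonomy(db, asm, rows)
        genus = db.conn.execute(
            "SELECT COUNT(*) FROM taxon WHERE rank = 'genus'").fetchone()[0]
        assert genus == 1
        assert report.counts["taxonomy_assignment"] == 2
        # parent chain is wired rank by rank
        bad = db.conn.execute(
            "SELECT COUNT(*) FROM taxon WHERE rank != 'domain' "
            "AND parent_ref IS NULL").fetchone()[0]
        assert bad == 0

    def test_fully_unclassified_assignment(self, mini_project):
        db, asm = self._with_genomes(mini_project)
        report = assemble_taxonomy(db, asm, [_tax_row("binA", "Unclassified")])
        assert report.counts["taxon"] == 0
        row = db.conn.execute(
            "SELECT taxon_ref, is_novel_species FROM taxonomy_assignment").fetchone()
        assert row["taxon_ref"] is None and row["is_novel_species"] == 1

    def test_quality_links_genomes(self, mini_project):
        db, asm = self._with_genomes(mini_project)
        rows = [QualityRow("binA", 98.5, 1.2), QualityRow("binB", 85.0, 0.4)]
        report = assemble_quality(db, asm, rows)
        assert report.counts["genome_quality"] == 2
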