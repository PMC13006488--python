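from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from magdb import (
    Database,
    generate_project_fixture,
    initialize_schema,
    insert_if_absent,
    load_config,
    populate,
)

STANDARD = dict(seed=42, n_genomes=5, contigs_per_genome=4, genes_per_contig=6,
                novel_fraction=0.4, cazyme_density=0.2)


@pytest.fixture(scope="session")
def project42(tmp_path_factory):
    """The standard synthetic project plus its ground-truth manifest."""
    d = tmp_path_factory.mktemp("fixture42")
    manifest = generate_project_fixture(d, **STANDARD)
    return d, manifest


@pytest.fixture(scope="session")
def populated42(project42):
    """A database populated once from the standard project (read-mostly)."""
    d, manifest = project42
    config = load_config(d / "config.toml")
    db = Database(":memory:")
    initialize_schema(db)
    report = populate(config, db)
    return db, config, manifest, d, report


@pytest.fixture()
def empty_db():
    db = Database(":memory:")
    initialize_schema(db)
    yield db
    db.close()


@pytest.fixture()
def mini_project(empty_db):
    """A tiny hand-seeded assembly with file entities but no biological rows.

    Two genomes (binA: 2 contigs, binB: 1 contig), 2 CDS per contig plus one
    tRNA, protein entries mirroring the gene ids.
    """
    db = empty_db
    cache: dict = {}

    def one(table, row, key):
        return insert_if_absent(db, table, [row], key, cache).outcomes[0].key_id

    project = one("project", {"name": "mini"}, ("name",))
    sample = one("sample", {"project_ref": project, "name": "s1"},
                 ("project_ref", "name"))
    assembly = one("assembly", {"sample_ref": sample, "name": "a1"},
                   ("sample_ref", "name"))
    layout = {"binA": ["binA_c1", "binA_c2"], "binB": ["binB_c1"]}
    gene_ids = []
    for genome, contigs in layout.items():
        ff = one("fasta_file",
                 {"assembly_ref": assembly, "path": f"/data/bins/{genome}.fa",
                  "sha256": "0" * 64, "file_role": "genome_bins"},
                 ("assembly_ref", "path"))
        gf = one("gff_file",
                 {"assembly_ref": assembly, "path": f"/data/gff/{genome}.gff",
                  "sha256": "0" * 64},
                 ("assembly_ref", "path"))
        pf = one("fasta_file",
                 {"assembly_ref": assembly, "path": f"/data/proteins/{genome}.faa",
                  "sha256": "0" * 64, "file_role": "proteins"},
                 ("assembly_ref", "path"))
        line = 0
        for contig in contigs:
            one("fasta_entry",
                {"fasta_file_ref": ff, "record_id": contig, "description": "",
                 "sequence": "ACGT" * 250, "sequence_length": 1000},
                ("fasta_file_ref", "record_id"))
            for k in (1, 2):
                gid = f"{contig}_g{k}"
                gene_ids.append(gid)
                line += 1
                one("gff_entry",
                    {"gff_file_ref": gf, "line_number": line, "seqid": contig,
                     "source": "Prodigal", "feature_type": "CDS",
                     "start": 100 * k, "end": 100 * k + 89, "score": None,
                     "strand": "+", "frame": 0,
                     "attributes_json": f'{{"ID": "{gid}"}}'},
                    ("gff_file_ref", "line_number"))
                one("fasta_entry",
                    {"fasta_file_ref": pf, "record_id": gid, "description": "",
                     "sequence": "M" + "A" * 28 + "*", "sequence_length": 30},
                    ("fasta_file_ref", "record_id"))
            line += 1
            one("gff_entry",
                {"gff_file_ref": gf, "line_number": line, "seqid": contig,
                 "source": "Aragorn", "feature_type": "tRNA",
                 "start": 900, "end": 974, "score": None, "strand": "+",
                 "frame": None, "attributes_json": "{}"},
                ("gff_file_ref", "line_number"))
    return {"db": db, "assembly": assembly, "project": project,
            "gene_ids": gene_ids, "cache": cache}
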