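"""Assembly of biological entities from ingested file entities.

Biological entities are associative: a gene row exists only because a GFF
feature's ``seqid`` resolved to a contig, which exists only because a FASTA
record belonged to a bin file.  Each ``assemble_*`` stage therefore resolves
cross-file identifiers into foreign keys obtained from earlier stages, in a
fixed dependency order::

    genomes/contigs -> genes -> proteins -> annotations / clusters /
                                            taxonomy / quality

Stages run in two passes — resolve every reference first, insert second —
so a strict-mode resolution failure aborts before any write.  In lenient
mode unresolved keys are listed in the stage report instead.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .plugins import UnifiedAnnotation
from .readers import ClusterRow, QualityRow, TaxonomyRow, normalize_genome_name
from .schema import (
    Contig,
    Database,
    Gene,
    Genome,
    MagdbError,
    Protein,
    ProteinAnnotationRecord,
    Taxon,
    UnresolvedReferenceError,
    insert_if_absent,
    validate_record,
)

logger = logging.getLogger(__name__)


class StageOrderError(MagdbError):
    """A stage ran before its prerequisite stage populated the database."""


class DuplicateGenomeError(MagdbError):
    pass


class MissingIdentifierError(MagdbError):
    pass


class DuplicateProteinError(MagdbError):
    pass


@dataclass
class AssemblyLinkReport:
    stage: str
    created: int = 0
    linked: int = 0
    unmatched_keys: list[str] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)


def _require(db: Database, assembly_id: int, table: str, stage: str, prerequisite: str) -> None:
    n = db.conn.execute(
        f'SELECT COUNT(*) FROM "{table}" WHERE assembly_ref = ?', (assembly_id,)
    ).fetchone()[0]
    if n == 0:
        raise StageOrderError(
            f"{stage}: prerequisite stage {prerequisite!r} has not run "
            f"(no {table} rows for assembly {assembly_id})"
        )


def _genome_map(db: Database, assembly_id: int) -> dict[str, int]:
    rows = db.conn.execute(
        "SELECT genome_id, name FROM genome WHERE assembly_ref = ?", (assembly_id,)
    ).fetchall()
    return {r["name"]: r["genome_id"] for r in rows}


def _unmatched(stage: str, keys: list[str], strict: bool, report: AssemblyLinkReport) -> None:
    if not keys:
        return
    if strict:
        raise UnresolvedReferenceError(stage, sorted(set(keys)))
    report.unmatched_keys.extend(sorted(set(keys)))


# ---------------------------------------------------------------------------
# stage 1: genomes and contigs
# ---------------------------------------------------------------------------

def assemble_genomes_and_contigs(
    db: Database,
    assembly_id: int,
    cache: Optional[dict] = None,
    batch_size: int = 1000,
) -> AssemblyLinkReport:
    """One genome per bin FASTA file; one contig per FASTA record.

    The genome name is the bin filename's normalized stem; contig lengths
    come from the stored FASTA entry.  Two bin files normalizing to the same
    genome name abort (they would silently merge otherwise).
    """
    report = AssemblyLinkReport(stage="genomes_and_contigs")
    files = db.conn.execute(
        "SELECT fasta_file_id, path FROM fasta_file "
        "WHERE assembly_ref = ? AND file_role = 'genome_bins' ORDER BY path",
        (assembly_id,),
    ).fetchall()
    names: dict[str, int] = {}
    for f in files:
        name = normalize_genome_name(f["path"])
        if name in names:
            raise DuplicateGenomeError(
                f"bin files normalize to the same genome name {name!r}"
            )
        names[name] = f["fasta_file_id"]
    genome_rows = []
    for name, file_id in names.items():
        rec = validate_record(Genome(assembly_ref=assembly_id, name=name, fasta_file_ref=file_id))
        genome_rows.append({
            "assembly_ref": rec.assembly_ref, "name": rec.name,
            "fasta_file_ref": rec.fasta_file_ref,
        })
    res = insert_if_absent(db, "genome", genome_rows, ("assembly_ref", "name"), cache, batch_size)
    genomes = _genome_map(db, assembly_id)
    report.counts["genome"] = res.inserted

    contig_rows = []
    for name, file_id in names.items():
        entries = db.conn.execute(
            "SELECT fasta_entry_id, record_id, sequence_length FROM fasta_entry "
            "WHERE fasta_file_ref = ? ORDER BY fasta_entry_id",
            (file_id,),
        ).fetchall()
        if not entries:
            logger.warning("bin file for genome %r holds zero FASTA records", name)
        for e in entries:
            rec = validate_record(Contig(
                genome_ref=genomes[name], name=e["record_id"],
                length_bp=e["sequence_length"], fasta_entry_ref=e["fasta_entry_id"],
            ))
            contig_rows.append({
                "genome_ref": rec.genome_ref, "name": rec.name,
                "length_bp": rec.length_bp, "fasta_entry_ref": rec.fasta_entry_ref,
            })
    cres = insert_if_absent(db, "contig", contig_rows, ("genome_ref", "name"), cache, batch_size)
    report.counts["contig"] = cres.inserted
    report.created = res.inserted + cres.inserted
    report.linked = len(contig_rows)
    return report


# ---------------------------------------------------------------------------
# stage 2: genes
# ---------------------------------------------------------------------------

def assemble_genes(
    db: Database,
    assembly_id: int,
    strict: bool = True,
    cache: Optional[dict] = None,
    batch_size: int = 1000,
) -> AssemblyLinkReport:
    """One gene per ingested CDS feature, linked to its contig.

    The contig is resolved as (genome from the GFF filename stem, ``seqid``);
    the gene identifier is the GFF ``ID`` attribute, falling back to
    ``locus_tag``.  Non-CDS features stay as file entities only.
    """
    report = AssemblyLinkReport(stage="genes")
    _require(db, assembly_id, "genome", "assemble_genes", "assemble_genomes_and_contigs")
    contigs: dict[tuple[str, str], tuple[int, int]] = {}
    for r in db.conn.execute(
        "SELECT c.contig_id, c.name AS contig_name, c.length_bp, g.name AS genome_name "
        "FROM contig c JOIN genome g ON c.genome_ref = g.genome_id "
        "WHERE g.assembly_ref = ?", (assembly_id,),
    ):
        contigs[(r["genome_name"], r["contig_name"])] = (r["contig_id"], r["length_bp"])

    gene_rows = []
    missing: list[str] = []
    for f in db.conn.execute(
        "SELECT gff_file_id, path FROM gff_file WHERE assembly_ref = ? ORDER BY path",
        (assembly_id,),
    ).fetchall():
        genome_name = Path(f["path"]).stem
        for e in db.conn.execute(
            "SELECT gff_entry_id, seqid, start, \"end\", strand, attributes_json "
            "FROM gff_entry WHERE gff_file_ref = ? AND feature_type = 'CDS' "
            "ORDER BY line_number", (f["gff_file_id"],),
        ).fetchall():
            attrs = json.loads(e["attributes_json"])
            identifier = attrs.get("ID") or attrs.get("locus_tag")
            if not identifier:
                raise MissingIdentifierError(
                    f"{f['path']}: CDS at {e['seqid']}:{e['start']}-{e['end']} "
                    "lacks both ID and locus_tag attributes"
                )
            hit = contigs.get((genome_name, e["seqid"]))
            if hit is None:
                missing.append(e["seqid"])
                continue
            contig_id, contig_length = hit
            rec = validate_record(
                Gene(
                    contig_ref=contig_id, identifier=identifier,
                    start_1based=e["start"], end_1based=e["end"],
                    strand=e["strand"], gff_entry_ref=e["gff_entry_id"],
                ),
                contig_length=contig_length,
            )
            gene_rows.append({
                "contig_ref": rec.contig_ref, "identifier": rec.identifier,
                "start_1based": rec.start_1based, "end_1based": rec.end_1based,
                "strand": rec.strand, "gff_entry_ref": rec.gff_entry_ref,
            })
    _unmatched("assemble_genes", missing, strict, report)
    res = insert_if_absent(db, "gene", gene_rows, ("contig_ref", "identifier"), cache, batch_size)
    report.created = res.inserted
    report.linked = len(gene_rows)
    report.counts["gene"] = res.inserted
    return report


# ---------------------------------------------------------------------------
# stage 3: proteins
# ---------------------------------------------------------------------------

def assemble_proteins(
    db: Database,
    assembly_id: int,
    strict: bool = True,
    cache: Optional[dict] = None,
    batch_size: int = 1000,
) -> AssemblyLinkReport:
    """One protein per protein-FASTA record whose id names a gene.

    ``sequence_length_aa`` excludes a trailing ``*`` stop.  A second record
    mapping to an already-claimed gene under a different name is a
    uniqueness error.
    """
    report = AssemblyLinkReport(stage="proteins")
    _require(db, assembly_id, "genome", "assemble_proteins", "assemble_genes")
    genes: dict[tuple[str, str], int] = {}
    for r in db.conn.execute(
        "SELECT ge.gene_id, ge.identifier, g.name AS genome_name "
        "FROM gene ge JOIN contig c ON ge.contig_ref = c.contig_id "
        "JOIN genome g ON c.genome_ref = g.genome_id WHERE g.assembly_ref = ?",
        (assembly_id,),
    ):
        genes[(r["genome_name"], r["identifier"])] = r["gene_id"]
    if not genes:
        raise StageOrderError(
            "assemble_proteins: prerequisite stage 'assemble_genes' has not run"
        )

    protein_rows = []
    missing: list[str] = []
    claimed: dict[int, str] = {}
    for f in db.conn.execute(
        "SELECT fasta_file_id, path FROM fasta_file "
        "WHERE assembly_ref = ? AND file_role = 'proteins' ORDER BY path",
        (assembly_id,),
    ).fetchall():
        genome_name = normalize_genome_name(f["path"])
        for e in db.conn.execute(
            "SELECT fasta_entry_id, record_id, sequence FROM fasta_entry "
            "WHERE fasta_file_ref = ? ORDER BY fasta_entry_id", (f["fasta_file_id"],),
        ).fetchall():
            gene_id = genes.get((genome_name, e["record_id"]))
            if gene_id is None:
                missing.append(e["record_id"])
                continue
            seq = e["sequence"]
            length = len(seq) - 1 if seq.endswith("*") else len(seq)
            prior = claimed.get(gene_id)
            if prior is not None and prior != e["record_id"]:
                raise DuplicateProteinError(
                    f"gene claimed by two proteins: {prior!r} and {e['record_id']!r}"
                )
            claimed[gene_id] = e["record_id"]
            rec = validate_record(Protein(
                name=e["record_id"], gene_ref=gene_id,
                sequence_length_aa=length, fasta_entry_ref=e["fasta_entry_id"],
            ))
            protein_rows.append({
                "gene_ref": rec.gene_ref, "name": rec.name,
                "sequence_length_aa": rec.sequence_length_aa,
                "fasta_entry_ref": rec.fasta_entry_ref,
            })
    _unmatched("assemble_proteins", missing, strict, report)
    res = insert_if_absent(db, "protein", protein_rows, ("gene_ref",), cache, batch_size)
    report.created = res.inserted
    report.linked = len(protein_rows)
    report.counts["protein"] = res.inserted
    return report


# ---------------------------------------------------------------------------
# stage 4: protein annotations
# ---------------------------------------------------------------------------

def _protein_map(db: Database, assembly_id: int) -> dict[str, int]:
    rows = db.conn.execute(
        "SELECT p.protein_id, p.name FROM protein p "
        "JOIN gene ge ON p.gene_ref = ge.gene_id "
        "JOIN contig c ON ge.contig_ref = c.contig_id "
        "JOIN genome g ON c.genome_ref = g.genome_id WHERE g.assembly_ref = ?",
        (assembly_id,),
    ).fetchall()
    return {r["name"]: r["protein_id"] for r in rows}


def link_protein_annotations(
    db: Database,
    assembly_id: int,
    annotations: Sequence[UnifiedAnnotation],
    entry_lookup: Optional[dict[str, int]] = None,
    strict: bool = True,
    cache: Optional[dict] = None,
    batch_size: int = 1000,
) -> AssemblyLinkReport:
    """Resolve unified annotations to protein rows and store them.

    Deduplicated on the natural key (protein, source tool, type, accession,
    coordinates), so resubmitting the same annotation is a no-op.
    ``entry_lookup`` optionally maps a protein key to the file-entity entry
    the annotation came from, preserving provenance.
    """
    report = AssemblyLinkReport(stage="protein_annotations")
    _require(db, assembly_id, "genome", "link_protein_annotations", "assemble_proteins")
    proteins = _protein_map(db, assembly_id)
    if not proteins:
        raise StageOrderError(
            "link_protein_annotations: prerequisite stage 'assemble_proteins' has not run"
        )
    rows = []
    missing: list[str] = []
    for ann in annotations:
        protein_id = proteins.get(ann.protein_key)
        if protein_id is None:
            missing.append(ann.protein_key)
            continue
        entry_ref = entry_lookup.get(ann.protein_key) if entry_lookup else None
        rec = validate_record(ProteinAnnotationRecord(
            protein_ref=protein_id, entry_ref=entry_ref,
            source_tool=ann.source_tool, annotation_type=ann.annotation_type,
            accession=ann.accession, description=ann.description,
            score=ann.score, coord_start=ann.coord_start, coord_stop=ann.coord_stop,
        ))
        rows.append({
            "protein_ref": rec.protein_ref, "entry_ref": rec.entry_ref,
            "source_tool": rec.source_tool, "annotation_type": rec.annotation_type,
            "accession": rec.accession, "description": rec.description,
            "score": rec.score, "coord_start": rec.coord_start,
            "coord_stop": rec.coord_stop,
        })
    _unmatched("link_protein_annotations", missing, strict, report)
    res = insert_if_absent(
        db, "protein_annotation", rows,
        ("protein_ref", "source_tool", "annotation_type", "accession",
         "coord_start", "coord_stop"),
        cache, batch_size,
    )
    report.created = res.inserted
    report.linked = len(rows)
    report.counts["protein_annotation"] = res.inserted
    return report


# ---------------------------------------------------------------------------
# stage 5: dereplication clusters
# ---------------------------------------------------------------------------

def assemble_clusters(
    db: Database,
    assembly_id: int,
    cluster_rows: Sequence[ClusterRow],
    strict: bool = True,
    cache: Optional[dict] = None,
    batch_size: int = 1000,
) -> AssemblyLinkReport:
    """One genome_cluster per distinct label; wire each genome's cluster_ref.

    The dRep winner becomes the cluster's representative genome.
    """
    report = AssemblyLinkReport(stage="clusters")
    _require(db, assembly_id, "genome", "assemble_clusters", "assemble_genomes_and_contigs")
    genomes = _genome_map(db, assembly_id)
    missing = [r.genome_name for r in cluster_rows if r.genome_name not in genomes]
    _unmatched("assemble_clusters", missing, strict, report)
    usable = [r for r in cluster_rows if r.genome_name in genomes]
    labels = sorted({r.cluster_label for r in usable})
    res = insert_if_absent(
        db, "genome_cluster",
        [{"assembly_ref": assembly_id, "label": lb} for lb in labels],
        ("assembly_ref", "label"), cache, batch_size,
    )
    cluster_ids = {
        r["label"]: r["genome_cluster_id"]
        for r in db.conn.execute(
            "SELECT genome_cluster_id, label FROM genome_cluster WHERE assembly_ref = ?",
            (assembly_id,),
        )
    }
    with db.conn:
        for row in usable:
            db.conn.execute(
                "UPDATE genome SET cluster_ref = ? WHERE genome_id = ?",
                (cluster_ids[row.cluster_label], genomes[row.genome_name]),
            )
            if row.is_winner:
                db.conn.execute(
                    "UPDATE genome_cluster SET representative_ref = ? WHERE genome_cluster_id = ?",
                    (genomes[row.genome_name], cluster_ids[row.cluster_label]),
                )
    report.created = res.inserted
    report.linked = len(usable)
    report.counts["genome_cluster"] = res.inserted
    return report


# ---------------------------------------------------------------------------
# stage 6: taxonomy
# ---------------------------------------------------------------------------

def assemble_taxonomy(
    db: Database,
    assembly_id: int,
    taxonomy_rows: Sequence[TaxonomyRow],
    strict: bool = True,
    entry_lookup: Optional[dict[str, int]] = None,
    cache: Optional[dict] = None,
    batch_size: int = 1000,
) -> AssemblyLinkReport:
    """Create/reuse taxon rows per assigned rank and link genomes to them.

    Taxa are unique on (rank, name) and chained parent-to-child down the
    contiguous prefix of assigned ranks; each genome gets one assignment row
    pointing at its most specific taxon (or none, for fully unclassified
    genomes) with the taxonomic-novelty flag.
    """
    report = AssemblyLinkReport(stage="taxonomy")
    _require(db, assembly_id, "genome", "assemble_taxonomy", "assemble_genomes_and_contigs")
    genomes = _genome_map(db, assembly_id)
    missing = [r.user_genome for r in taxonomy_rows if r.user_genome not in genomes]
    _unmatched("assemble_taxonomy", missing, strict, report)
    created_taxa = 0
    assignment_rows = []
    for row in taxonomy_rows:
        if row.user_genome not in genomes:
            continue
        parent_id: Optional[int] = None
        deepest_id: Optional[int] = None
        for rank, name in row.lineage:
            if name is None:
                break
            rec = validate_record(Taxon(rank=rank, name=name, parent_ref=parent_id))
            res = insert_if_absent(
                db, "taxon",
                [{"rank": rec.rank, "name": rec.name, "parent_ref": rec.parent_ref}],
                ("rank", "name"), cache, batch_size,
            )
            created_taxa += res.inserted
            parent_id = deepest_id = res.outcomes[0].key_id
        entry_ref = entry_lookup.get(row.user_genome) if entry_lookup else None
        assignment_rows.append({
            "genome_ref": genomes[row.user_genome],
            "taxon_ref": deepest_id,
            "taxonomy_entry_ref": entry_ref,
            "lowest_assigned_rank": row.lowest_assigned_rank,
            "is_novel_species": int(row.is_novel_species),
        })
    ares = insert_if_absent(
        db, "taxonomy_assignment", assignment_rows, ("genome_ref",), cache, batch_size
    )
    report.created = created_taxa + ares.inserted
    report.linked = len(assignment_rows)
    report.counts["taxon"] = created_taxa
    report.counts["taxonomy_assignment"] = ares.inserted
    return report


# ---------------------------------------------------------------------------
# stage 7: genome quality
# ---------------------------------------------------------------------------

def assemble_quality(
    db: Database,
    assembly_id: int,
    quality_rows: Sequence[QualityRow],
    strict: bool = True,
    entry_lookup: Optional[dict[str, int]] = None,
    cache: Optional[dict] = None,
    batch_size: int = 1000,
) -> AssemblyLinkReport:
    """Link each genome to its CheckM2 quality-report entry."""
    report = AssemblyLinkReport(stage="quality")
    _require(db, assembly_id, "genome", "assemble_quality", "assemble_genomes_and_contigs")
    genomes = _genome_map(db, assembly_id)
    missing = [r.genome_name for r in quality_rows if r.genome_name not in genomes]
    _unmatched("assemble_quality", missing, strict, report)
    rows = []
    for row in quality_rows:
        if row.genome_name not in genomes:
            continue
        entry_ref = entry_lookup.get(row.genome_name) if entry_lookup else None
        rows.append({
            "genome_ref": genomes[row.genome_name],
            "quality_entry_ref": entry_ref,
        })
    res = insert_if_absent(db, "genome_quality", rows, ("genome_ref",), cache, batch_size)
    report.created = res.inserted
    report.linked = len(rows)
    report.counts["genome_quality"] = res.inserted
    return report
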