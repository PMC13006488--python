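"""Relational schema for the MAG workflow database.

The database integrates the file outputs of a prokaryotic
metagenome-assembled-genome (MAG) workflow into 28 tables grouped in three
categories:

* **project-management entities** — who ran what, when, with which tool
  (``project``, ``sample``, ``assembly``, ``run``, ``tool``, ``source``,
  ``plugin_registration``);
* **file entities** — near-verbatim rows parsed from the workflow's output
  files (FASTA, GFF3, dRep cluster tables, GTDB-Tk summaries, CheckM2
  reports, protein-annotation outputs);
* **biological entities** — the cross-file abstractions (genome, contig,
  gene, protein, taxon, annotation, cluster, quality) assembled from file
  entities via foreign keys.

The store is an embedded SQLite database so a project database is a single
local file; the DDL is kept to portable ANSI constructs (integer surrogate
keys, foreign keys, unique constraints, CHECK ranges) so a client-server
backend can host the same schema.  The schema version is recorded in the
database header (``PRAGMA user_version``); opening a database written by a
different schema version aborts rather than guessing at migrations.
"""

from __future__ import annotations

import itertools
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Literal, Optional

import pydantic
from pydantic import BaseModel, ValidationInfo, model_validator

SCHEMA_VERSION = 1

CANONICAL_RANKS: tuple[str, ...] = (
    "domain", "phylum", "class", "order", "family", "genus", "species",
)
RANK_INDEX = {r: i for i, r in enumerate(CANONICAL_RANKS)}

#: CAZyme class prefixes recognised in dbCAN family accessions.
CAZYME_CLASS_CODES: tuple[str, ...] = ("GH", "GT", "PL", "CE", "AA", "CBM")

ANNOTATION_TYPES: tuple[str, ...] = (
    "family", "subfamily", "domain", "ec_number", "go_term", "description",
)

STRANDS = ("+", "-", ".", "?")


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class MagdbError(Exception):
    """Base class for all package errors."""


class DatabaseConnectionError(MagdbError):
    pass


class SchemaVersionError(MagdbError):
    pass


class RecordValidationError(MagdbError):
    """A record failed a field-level type or invariant check."""

    def __init__(self, record_type: str, field_name: str, rule: str):
        self.record_type = record_type
        self.field_name = field_name
        self.rule = rule
        super().__init__(f"{record_type}.{field_name}: {rule}")


class UnresolvedReferenceError(MagdbError):
    """A foreign-key target is absent."""

    def __init__(self, table: str, missing: Any):
        self.table = table
        self.missing = missing
        super().__init__(f"unresolved reference while inserting into {table!r}: {missing}")


# ---------------------------------------------------------------------------
# table inventory
# ---------------------------------------------------------------------------

TABLE_CATEGORIES: dict[str, tuple[str, ...]] = {
    "project_management": (
        "project", "sample", "assembly", "run", "tool", "source",
        "plugin_registration",
    ),
    "file": (
        "fasta_file", "fasta_entry", "gff_file", "gff_entry",
        "dereplication_file", "dereplication_entry",
        "taxonomy_file", "taxonomy_entry",
        "quality_file", "quality_entry",
        "protein_annotation_file", "protein_annotation_entry",
    ),
    "biological": (
        "genome", "genome_cluster", "contig", "gene", "protein",
        "taxon", "taxonomy_assignment", "protein_annotation", "genome_quality",
    ),
}

ALL_TABLES: tuple[str, ...] = tuple(itertools.chain.from_iterable(TABLE_CATEGORIES.values()))

_RANK_CASE = "CASE {col} " + " ".join(
    f"WHEN '{r}' THEN {i}" for r, i in RANK_INDEX.items()
) + " ELSE -99 END"

_DDL = f"""
CREATE TABLE IF NOT EXISTS project (
    project_id INTEGER PRIMARY KEY,
    name TEXT NOT NULL,
    created_at TEXT,
    UNIQUE (name)
);
CREATE TABLE IF NOT EXISTS sample (
    sample_id INTEGER PRIMARY KEY,
    project_ref INTEGER NOT NULL REFERENCES project(project_id),
    name TEXT NOT NULL,
    UNIQUE (project_ref, name)
);
CREATE TABLE IF NOT EXISTS assembly (
    assembly_id INTEGER PRIMARY KEY,
    sample_ref INTEGER NOT NULL REFERENCES sample(sample_id),
    name TEXT NOT NULL,
    UNIQUE (sample_ref, name)
);
CREATE TABLE IF NOT EXISTS tool (
    tool_id INTEGER PRIMARY KEY,
    name TEXT NOT NULL,
    version TEXT NOT NULL DEFAULT 'unknown',
    UNIQUE (name, version)
);
CREATE TABLE IF NOT EXISTS source (
    source_id INTEGER PRIMARY KEY,
    label TEXT NOT NULL,
    UNIQUE (label)
);
CREATE TABLE IF NOT EXISTS run (
    run_id INTEGER PRIMARY KEY,
    project_ref INTEGER NOT NULL REFERENCES project(project_id),
    tool_ref INTEGER NOT NULL REFERENCES tool(tool_id),
    source_ref INTEGER NOT NULL REFERENCES source(source_id),
    started_at TEXT NOT NULL,
    UNIQUE (project_ref, tool_ref, source_ref),
    UNIQUE (project_ref, tool_ref, started_at)
);
CREATE TABLE IF NOT EXISTS plugin_registration (
    plugin_registration_id INTEGER PRIMARY KEY,
    name TEXT NOT NULL,
    target_tool TEXT NOT NULL,
    version TEXT NOT NULL DEFAULT '0',
    enabled INTEGER NOT NULL DEFAULT 1,
    UNIQUE (name)
);

CREATE TABLE IF NOT EXISTS fasta_file (
    fasta_file_id INTEGER PRIMARY KEY,
    assembly_ref INTEGER NOT NULL REFERENCES assembly(assembly_id),
    run_ref INTEGER REFERENCES run(run_id),
    path TEXT NOT NULL,
    sha256 TEXT NOT NULL,
    file_role TEXT NOT NULL CHECK (file_role IN ('genome_bins', 'proteins')),
    UNIQUE (assembly_ref, path)
);
CREATE TABLE IF NOT EXISTS fasta_entry (
    fasta_entry_id INTEGER PRIMARY KEY,
    fasta_file_ref INTEGER NOT NULL REFERENCES fasta_file(fasta_file_id),
    record_id TEXT NOT NULL,
    description TEXT NOT NULL DEFAULT '',
    sequence TEXT NOT NULL,
    sequence_length INTEGER NOT NULL CHECK (sequence_length >= 0),
    UNIQUE (fasta_file_ref, record_id)
);
CREATE TABLE IF NOT EXISTS gff_file (
    gff_file_id INTEGER PRIMARY KEY,
    assembly_ref INTEGER NOT NULL REFERENCES assembly(assembly_id),
    run_ref INTEGER REFERENCES run(run_id),
    path TEXT NOT NULL,
    sha256 TEXT NOT NULL,
    UNIQUE (assembly_ref, path)
);
CREATE TABLE IF NOT EXISTS gff_entry (
    gff_entry_id INTEGER PRIMARY KEY,
    gff_file_ref INTEGER NOT NULL REFERENCES gff_file(gff_file_id),
    line_number INTEGER NOT NULL,
    seqid TEXT NOT NULL,
    source TEXT NOT NULL,
    feature_type TEXT NOT NULL,
    start INTEGER NOT NULL,
    "end" INTEGER NOT NULL,
    score REAL,
    strand TEXT NOT NULL CHECK (strand IN ('+', '-', '.', '?')),
    frame INTEGER CHECK (frame IS NULL OR frame IN (0, 1, 2)),
    attributes_json TEXT NOT NULL DEFAULT '{{}}',
    UNIQUE (gff_file_ref, line_number),
    CHECK (start >= 1 AND start <= "end")
);
CREATE TABLE IF NOT EXISTS dereplication_file (
    dereplication_file_id INTEGER PRIMARY KEY,
    assembly_ref INTEGER NOT NULL REFERENCES assembly(assembly_id),
    run_ref INTEGER REFERENCES run(run_id),
    path TEXT NOT NULL,
    sha256 TEXT NOT NULL,
    table_role TEXT NOT NULL DEFAULT 'clusters' CHECK (table_role IN ('clusters', 'winners')),
    UNIQUE (assembly_ref, path)
);
CREATE TABLE IF NOT EXISTS dereplication_entry (
    dereplication_entry_id INTEGER PRIMARY KEY,
    dereplication_file_ref INTEGER NOT NULL REFERENCES dereplication_file(dereplication_file_id),
    genome_name TEXT NOT NULL,
    cluster_label TEXT NOT NULL,
    is_winner INTEGER NOT NULL DEFAULT 0,
    UNIQUE (dereplication_file_ref, genome_name)
);
CREATE TABLE IF NOT EXISTS taxonomy_file (
    taxonomy_file_id INTEGER PRIMARY KEY,
    assembly_ref INTEGER NOT NULL REFERENCES assembly(assembly_id),
    run_ref INTEGER REFERENCES run(run_id),
    path TEXT NOT NULL,
    sha256 TEXT NOT NULL,
    UNIQUE (assembly_ref, path)
);
CREATE TABLE IF NOT EXISTS taxonomy_entry (
    taxonomy_entry_id INTEGER PRIMARY KEY,
    taxonomy_file_ref INTEGER NOT NULL REFERENCES taxonomy_file(taxonomy_file_id),
    user_genome TEXT NOT NULL,
    classification TEXT NOT NULL,
    UNIQUE (taxonomy_file_ref, user_genome)
);
CREATE TABLE IF NOT EXISTS quality_file (
    quality_file_id INTEGER PRIMARY KEY,
    assembly_ref INTEGER NOT NULL REFERENCES assembly(assembly_id),
    run_ref INTEGER REFERENCES run(run_id),
    path TEXT NOT NULL,
    sha256 TEXT NOT NULL,
    UNIQUE (assembly_ref, path)
);
CREATE TABLE IF NOT EXISTS quality_entry (
    quality_entry_id INTEGER PRIMARY KEY,
    quality_file_ref INTEGER NOT NULL REFERENCES quality_file(quality_file_id),
    genome_name TEXT NOT NULL,
    completeness_pct REAL NOT NULL CHECK (completeness_pct >= 0 AND completeness_pct <= 100),
    contamination_pct REAL NOT NULL CHECK (contamination_pct >= 0),
    UNIQUE (quality_file_ref, genome_name)
);
CREATE TABLE IF NOT EXISTS protein_annotation_file (
    protein_annotation_file_id INTEGER PRIMARY KEY,
    assembly_ref INTEGER NOT NULL REFERENCES assembly(assembly_id),
    run_ref INTEGER REFERENCES run(run_id),
    path TEXT NOT NULL,
    sha256 TEXT NOT NULL,
    tool_name TEXT NOT NULL,
    UNIQUE (assembly_ref, path)
);
CREATE TABLE IF NOT EXISTS protein_annotation_entry (
    protein_annotation_entry_id INTEGER PRIMARY KEY,
    protein_annotation_file_ref INTEGER NOT NULL
        REFERENCES protein_annotation_file(protein_annotation_file_id),
    line_number INTEGER NOT NULL,
    protein_key TEXT NOT NULL,
    raw_line TEXT NOT NULL,
    UNIQUE (protein_annotation_file_ref, line_number)
);

CREATE TABLE IF NOT EXISTS genome_cluster (
    genome_cluster_id INTEGER PRIMARY KEY,
    assembly_ref INTEGER NOT NULL REFERENCES assembly(assembly_id),
    label TEXT NOT NULL,
    representative_ref INTEGER REFERENCES genome(genome_id),
    UNIQUE (assembly_ref, label)
);
CREATE TABLE IF NOT EXISTS genome (
    genome_id INTEGER PRIMARY KEY,
    assembly_ref INTEGER NOT NULL REFERENCES assembly(assembly_id),
    name TEXT NOT NULL,
    cluster_ref INTEGER REFERENCES genome_cluster(genome_cluster_id),
    fasta_file_ref INTEGER NOT NULL REFERENCES fasta_file(fasta_file_id),
    UNIQUE (assembly_ref, name)
);
CREATE TABLE IF NOT EXISTS contig (
    contig_id INTEGER PRIMARY KEY,
    genome_ref INTEGER NOT NULL REFERENCES genome(genome_id),
    name TEXT NOT NULL,
    length_bp INTEGER NOT NULL CHECK (length_bp >= 1),
    fasta_entry_ref INTEGER NOT NULL REFERENCES fasta_entry(fasta_entry_id),
    UNIQUE (genome_ref, name)
);
CREATE TABLE IF NOT EXISTS gene (
    gene_id INTEGER PRIMARY KEY,
    contig_ref INTEGER NOT NULL REFERENCES contig(contig_id),
    identifier TEXT NOT NULL,
    start_1based INTEGER NOT NULL,
    end_1based INTEGER NOT NULL,
    strand TEXT NOT NULL CHECK (strand IN ('+', '-', '.', '?')),
    gff_entry_ref INTEGER NOT NULL REFERENCES gff_entry(gff_entry_id),
    UNIQUE (contig_ref, identifier),
    CHECK (start_1based >= 1 AND start_1based <= end_1based)
);
CREATE TABLE IF NOT EXISTS protein (
    protein_id INTEGER PRIMARY KEY,
    gene_ref INTEGER NOT NULL UNIQUE REFERENCES gene(gene_id),
    name TEXT NOT NULL,
    sequence_length_aa INTEGER NOT NULL CHECK (sequence_length_aa >= 1),
    fasta_entry_ref INTEGER NOT NULL REFERENCES fasta_entry(fasta_entry_id)
);
CREATE TABLE IF NOT EXISTS taxon (
    taxon_id INTEGER PRIMARY KEY,
    rank TEXT NOT NULL CHECK (rank IN ({", ".join(repr(r) for r in CANONICAL_RANKS)})),
    name TEXT NOT NULL,
    parent_ref INTEGER REFERENCES taxon(taxon_id),
    UNIQUE (rank, name)
);
CREATE TABLE IF NOT EXISTS taxonomy_assignment (
    taxonomy_assignment_id INTEGER PRIMARY KEY,
    genome_ref INTEGER NOT NULL UNIQUE REFERENCES genome(genome_id),
    taxon_ref INTEGER REFERENCES taxon(taxon_id),
    taxonomy_entry_ref INTEGER REFERENCES taxonomy_entry(taxonomy_entry_id),
    lowest_assigned_rank TEXT,
    is_novel_species INTEGER NOT NULL
);
CREATE TABLE IF NOT EXISTS protein_annotation (
    protein_annotation_id INTEGER PRIMARY KEY,
    protein_ref INTEGER NOT NULL REFERENCES protein(protein_id),
    entry_ref INTEGER REFERENCES protein_annotation_entry(protein_annotation_entry_id),
    source_tool TEXT NOT NULL,
    annotation_type TEXT NOT NULL
        CHECK (annotation_type IN ({", ".join(repr(t) for t in ANNOTATION_TYPES)})),
    accession TEXT NOT NULL,
    description TEXT,
    score REAL,
    coord_start INTEGER,
    coord_stop INTEGER,
    CHECK (coord_start IS NULL OR coord_start >= 1),
    CHECK (coord_start IS NULL OR coord_stop IS NULL OR coord_start <= coord_stop)
);
CREATE UNIQUE INDEX IF NOT EXISTS ux_protein_annotation_natural
    ON protein_annotation (protein_ref, source_tool, annotation_type, accession,
                           COALESCE(coord_start, -1), COALESCE(coord_stop, -1));
CREATE TABLE IF NOT EXISTS genome_quality (
    genome_quality_id INTEGER PRIMARY KEY,
    genome_ref INTEGER NOT NULL UNIQUE REFERENCES genome(genome_id),
    quality_entry_ref INTEGER REFERENCES quality_entry(quality_entry_id)
);
CREATE INDEX IF NOT EXISTS ix_protein_annotation_accession
    ON protein_annotation (accession);
CREATE INDEX IF NOT EXISTS ix_gene_contig ON gene (contig_ref);
CREATE INDEX IF NOT EXISTS ix_contig_genome ON contig (genome_ref);
"""

#: declared foreign-key relationships, used by :func:`integrity_check`.
FOREIGN_KEYS: tuple[tuple[str, str, str], ...] = (
    ("sample", "project_ref", "project"),
    ("assembly", "sample_ref", "sample"),
    ("run", "project_ref", "project"),
    ("run", "tool_ref", "tool"),
    ("run", "source_ref", "source"),
    ("fasta_file", "assembly_ref", "assembly"),
    ("fasta_file", "run_ref", "run"),
    ("fasta_entry", "fasta_file_ref", "fasta_file"),
    ("gff_file", "assembly_ref", "assembly"),
    ("gff_file", "run_ref", "run"),
    ("gff_entry", "gff_file_ref", "gff_file"),
    ("dereplication_file", "assembly_ref", "assembly"),
    ("dereplication_entry", "dereplication_file_ref", "dereplication_file"),
    ("taxonomy_file", "assembly_ref", "assembly"),
    ("taxonomy_entry", "taxonomy_file_ref", "taxonomy_file"),
    ("quality_file", "assembly_ref", "assembly"),
    ("quality_entry", "quality_file_ref", "quality_file"),
    ("protein_annotation_file", "assembly_ref", "assembly"),
    ("protein_annotation_entry", "protein_annotation_file_ref", "protein_annotation_file"),
    ("genome", "assembly_ref", "assembly"),
    ("genome", "cluster_ref", "genome_cluster"),
    ("genome", "fasta_file_ref", "fasta_file"),
    ("genome_cluster", "assembly_ref", "assembly"),
    ("genome_cluster", "representative_ref", "genome"),
    ("contig", "genome_ref", "genome"),
    ("contig", "fasta_entry_ref", "fasta_entry"),
    ("gene", "contig_ref", "contig"),
    ("gene", "gff_entry_ref", "gff_entry"),
    ("protein", "gene_ref", "gene"),
    ("protein", "fasta_entry_ref", "fasta_entry"),
    ("taxon", "parent_ref", "taxon"),
    ("taxonomy_assignment", "genome_ref", "genome"),
    ("taxonomy_assignment", "taxon_ref", "taxon"),
    ("taxonomy_assignment", "taxonomy_entry_ref", "taxonomy_entry"),
    ("protein_annotation", "protein_ref", "protein"),
    ("protein_annotation", "entry_ref", "protein_annotation_entry"),
    ("genome_quality", "genome_ref", "genome"),
    ("genome_quality", "quality_entry_ref", "quality_entry"),
)


def primary_key_column(table: str) -> str:
    return f"{table}_id"


# ---------------------------------------------------------------------------
# database handle
# ---------------------------------------------------------------------------

class Database:
    """Thin handle around a SQLite connection to a project database."""

    def __init__(self, target: str | Path = ":memory:"):
        self.target = str(target)
        try:
            self.conn = sqlite3.connect(self.target)
        except sqlite3.Error as exc:  # unreachable file, bad path
            raise DatabaseConnectionError(f"cannot open database {target!r}: {exc}") from exc
        self.conn.row_factory = sqlite3.Row
        self.conn.execute("PRAGMA foreign_keys = ON")

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "Database":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- catalog introspection ------------------------------------------------

    def table_names(self) -> list[str]:
        rows = self.conn.execute(
            "SELECT name FROM sqlite_master "
            "WHERE type = 'table' AND name NOT LIKE 'sqlite_%' ORDER BY name"
        ).fetchall()
        return [r["name"] for r in rows]

    def row_counts(self) -> dict[str, int]:
        """Row count of every user table, from the live catalog."""
        return {
            t: self.conn.execute(f'SELECT COUNT(*) AS n FROM "{t}"').fetchone()["n"]
            for t in self.table_names()
        }

    @property
    def schema_version(self) -> int:
        return self.conn.execute("PRAGMA user_version").fetchone()[0]


def open_database(target: str | Path | Database) -> Database:
    return target if isinstance(target, Database) else Database(target)


# ---------------------------------------------------------------------------
# schema initialization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SchemaReport:
    total_tables: int
    categories: int
    tables_per_category: dict[str, int]
    constraint_count: int


def _count_constraints(db: Database) -> int:
    n = 0
    for t in db.table_names():
        n += 1  # primary key
        n += len(db.conn.execute(f'PRAGMA foreign_key_list("{t}")').fetchall())
        for ix in db.conn.execute(f'PRAGMA index_list("{t}")').fetchall():
            if ix["unique"]:
                n += 1
    return n


def initialize_schema(connection_target: str | Path | Database) -> SchemaReport:
    """Create all 28 tables, indexes and constraints; idempotent.

    A target that already holds tables from a different schema version (or a
    foreign table set) raises :class:`SchemaVersionError` instead of touching
    anything.
    """
    db = open_database(connection_target)
    existing = set(db.table_names())
    if existing:
        if db.schema_version != SCHEMA_VERSION or not existing.issubset(set(ALL_TABLES)):
            raise SchemaVersionError(
                f"target holds schema version {db.schema_version} with tables "
                f"{sorted(existing - set(ALL_TABLES)) or sorted(existing)}; "
                f"expected version {SCHEMA_VERSION}"
            )
    with db.conn:
        db.conn.executescript(_DDL)
        db.conn.execute(f"PRAGMA user_version = {SCHEMA_VERSION}")
    created = db.table_names()
    assert set(created) == set(ALL_TABLES)
    return SchemaReport(
        total_tables=len(created),
        categories=len(TABLE_CATEGORIES),
        tables_per_category={c: len(ts) for c, ts in TABLE_CATEGORIES.items()},
        constraint_count=_count_constraints(db),
    )


# ---------------------------------------------------------------------------
# entity records (validated with pydantic before any write)
# ---------------------------------------------------------------------------

class _Record(BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid", validate_assignment=True)


class RunRecord(_Record):
    run_id: Optional[int] = None
    project_ref: int
    tool_name: str
    tool_version: str = "unknown"
    source_label: str
    started_at: str


class Genome(_Record):
    genome_id: Optional[int] = None
    assembly_ref: int
    name: str = pydantic.Field(min_length=1)
    cluster_ref: Optional[int] = None
    fasta_file_ref: int


class Contig(_Record):
    contig_id: Optional[int] = None
    genome_ref: int
    name: str = pydantic.Field(min_length=1)
    length_bp: int = pydantic.Field(ge=1)
    fasta_entry_ref: int


class Gene(_Record):
    gene_id: Optional[int] = None
    contig_ref: int
    identifier: str = pydantic.Field(min_length=1)
    start_1based: int = pydantic.Field(ge=1)
    end_1based: int = pydantic.Field(ge=1)
    strand: Literal["+", "-", ".", "?"]
    gff_entry_ref: int

    @model_validator(mode="after")
    def _coords(self, info: ValidationInfo) -> "Gene":
        if self.start_1based > self.end_1based:
            raise ValueError("start_1based must be <= end_1based")
        ctx = info.context or {}
        contig_length = ctx.get("contig_length")
        if contig_length is not None and self.end_1based > contig_length:
            raise ValueError(
                f"end_1based {self.end_1based} exceeds contig length {contig_length}"
            )
        return self


class Protein(_Record):
    protein_id: Optional[int] = None
    name: str = pydantic.Field(min_length=1)
    gene_ref: int
    sequence_length_aa: int = pydantic.Field(ge=1)
    fasta_entry_ref: int


class Taxon(_Record):
    taxon_id: Optional[int] = None
    rank: Literal["domain", "phylum", "class", "order", "family", "genus", "species"]
    name: str = pydantic.Field(min_length=1)
    parent_ref: Optional[int] = None


class ProteinAnnotationRecord(_Record):
    id: Optional[int] = None
    protein_ref: int
    entry_ref: Optional[int] = None
    source_tool: str = pydantic.Field(min_length=1)
    annotation_type: Literal[
        "family", "subfamily", "domain", "ec_number", "go_term", "description"
    ]
    accession: str = pydantic.Field(min_length=1)
    description: Optional[str] = None
    score: Optional[float] = None
    coord_start: Optional[int] = pydantic.Field(default=None, ge=1)
    coord_stop: Optional[int] = None

    @model_validator(mode="after")
    def _coords(self) -> "ProteinAnnotationRecord":
        if (
            self.coord_start is not None
            and self.coord_stop is not None
            and self.coord_start > self.coord_stop
        ):
            raise ValueError("coord_start must be <= coord_stop")
        return self


def validate_record(record: BaseModel, **context: Any) -> BaseModel:
    """Re-validate an entity record; return it unchanged or raise.

    Contextual invariants (a gene's ``end <= contig.length_bp``) are checked
    when the caller supplies the context, e.g. ``contig_length=4521``.
    """
    try:
        return type(record).model_validate(record.model_dump(), context=context or None)
    except pydantic.ValidationError as exc:
        err = exc.errors()[0]
        field_name = ".".join(str(p) for p in err["loc"]) or "<record>"
        raise RecordValidationError(type(record).__name__, field_name, err["msg"]) from exc


# ---------------------------------------------------------------------------
# memoized, batched, idempotent insertion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InsertOutcome:
    status: Literal["inserted", "already_present"]
    key_id: int


@dataclass
class BatchResult:
    outcomes: list[InsertOutcome] = field(default_factory=list)
    transactions: int = 0

    @property
    def inserted(self) -> int:
        return sum(1 for o in self.outcomes if o.status == "inserted")

    @property
    def already_present(self) -> int:
        return sum(1 for o in self.outcomes if o.status == "already_present")


def _chunks(seq: list, size: int) -> Iterable[list]:
    for i in range(0, len(seq), size):
        yield seq[i:i + size]


def insert_if_absent(
    db: Database,
    table: str,
    records: list[dict[str, Any]],
    key_cols: tuple[str, ...],
    cache: Optional[dict] = None,
    batch_size: int = 1000,
) -> BatchResult:
    """Insert each record at most once per natural key.

    The natural key -> surrogate id mapping is memoized in ``cache`` so
    repeated submissions (within a run or across runs) never hit the database
    twice for the same key.  Records are committed in one transaction per
    ``batch_size`` rows; a failure rolls back the whole current batch and
    evicts its cache entries.
    """
    if cache is None:
        cache = {}
    pk = primary_key_column(table)
    result = BatchResult()
    for chunk in _chunks(list(records), batch_size):
        result.transactions += 1
        added_keys: list[tuple] = []
        try:
            with db.conn:
                for row in chunk:
                    key = (table,) + tuple(row[c] for c in key_cols)
                    if key in cache:
                        result.outcomes.append(InsertOutcome("already_present", cache[key]))
                        continue
                    where = " AND ".join(f'"{c}" IS ?' for c in key_cols)
                    hit = db.conn.execute(
                        f'SELECT "{pk}" FROM "{table}" WHERE {where}',
                        tuple(row[c] for c in key_cols),
                    ).fetchone()
                    if hit is not None:
                        cache[key] = hit[0]
                        added_keys.append(key)
                        result.outcomes.append(InsertOutcome("already_present", hit[0]))
                        continue
                    cols = list(row)
                    col_list = ", ".join(f'"{c}"' for c in cols)
                    placeholders = ", ".join("?" for _ in cols)
                    sql = f'INSERT INTO "{table}" ({col_list}) VALUES ({placeholders})'
                    cur = db.conn.execute(sql, tuple(row[c] for c in cols))
                    cache[key] = cur.lastrowid
                    added_keys.append(key)
                    result.outcomes.append(InsertOutcome("inserted", cur.lastrowid))
        except sqlite3.IntegrityError as exc:
            for k in added_keys:
                cache.pop(k, None)
            if "FOREIGN KEY" in str(exc).upper():
                raise UnresolvedReferenceError(table, str(exc)) from exc
            raise
        except Exception:
            for k in added_keys:
                cache.pop(k, None)
            raise
    return result


# ---------------------------------------------------------------------------
# integrity audit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntegrityReport:
    orphan_counts: dict[str, int]
    invariant_violations: dict[str, int]

    @property
    def total_orphans(self) -> int:
        return sum(self.orphan_counts.values())

    @property
    def total_violations(self) -> int:
        return sum(self.invariant_violations.values())

    @property
    def is_clean(self) -> bool:
        return self.total_orphans == 0 and self.total_violations == 0


_INVARIANT_SCANS: dict[str, str] = {
    "contig.length_bp >= 1":
        "SELECT COUNT(*) FROM contig WHERE length_bp < 1",
    "gene.1 <= start <= end":
        "SELECT COUNT(*) FROM gene WHERE start_1based < 1 OR start_1based > end_1based",
    "gene.end <= contig.length_bp":
        "SELECT COUNT(*) FROM gene g JOIN contig c ON g.contig_ref = c.contig_id "
        "WHERE g.end_1based > c.length_bp",
    "protein.sequence_length_aa >= 1":
        "SELECT COUNT(*) FROM protein WHERE sequence_length_aa < 1",
    "protein: one per gene":
        "SELECT COALESCE(SUM(n - 1), 0) FROM "
        "(SELECT COUNT(*) AS n FROM protein GROUP BY gene_ref)",
    "quality_entry ranges":
        "SELECT COUNT(*) FROM quality_entry WHERE completeness_pct < 0 "
        "OR completeness_pct > 100 OR contamination_pct < 0",
    "taxon.parent rank is immediately higher":
        "SELECT COUNT(*) FROM taxon c JOIN taxon p ON c.parent_ref = p.taxon_id "
        f"WHERE ({_RANK_CASE.format(col='c.rank')}) != ({_RANK_CASE.format(col='p.rank')}) + 1",
    "protein_annotation coords":
        "SELECT COUNT(*) FROM protein_annotation WHERE "
        "(coord_start IS NOT NULL AND coord_start < 1) OR "
        "(coord_start IS NOT NULL AND coord_stop IS NOT NULL AND coord_start > coord_stop)",
}


def integrity_check(connection_target: str | Path | Database) -> IntegrityReport:
    """Audit referential closure and stored-row invariants.

    Reports a zero count for every declared foreign-key relationship and
    every invariant scan iff the database is internally consistent.  Purely
    a reporting operation; never modifies the database.
    """
    db = open_database(connection_target)
    orphans: dict[str, int] = {}
    for child, col, parent in FOREIGN_KEYS:
        ppk = primary_key_column(parent)
        n = db.conn.execute(
            f'SELECT COUNT(*) FROM "{child}" c LEFT JOIN "{parent}" p '
            f'ON c."{col}" = p."{ppk}" WHERE c."{col}" IS NOT NULL AND p."{ppk}" IS NULL'
        ).fetchone()[0]
        orphans[f"{child}.{col} -> {parent}"] = n
    violations = {
        name: db.conn.execute(sql).fetchone()[0]
        for name, sql in _INVARIANT_SCANS.items()
    }
    return IntegrityReport(orphan_counts=orphans, invariant_violations=violations)
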