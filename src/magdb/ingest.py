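"""Ingestion orchestrator: configuration, population, audit.

A project is described by one TOML configuration file pointing at the
directory tree a MAG workflow left behind.  :func:`populate` drives the
whole pipeline per assembly, in a fixed serial order::

    ingest FASTA/GFF file entities
    -> assemble genomes/contigs -> genes -> proteins
    -> run enabled annotation plugins and link their records
    -> dereplication clusters -> taxonomy -> quality

Every configured file is audited (path, SHA-256 digest, rows ingested) and
every insertion goes through the memoized ``insert_if_absent`` path, so
re-running :func:`populate` on the same configuration is a no-op on all 28
tables.  A file whose digest changed under the same path aborts in strict
mode rather than silently mixing file versions.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import assembler, plugins
from .assembler import AssemblyLinkReport
from .readers import (
    parse_checkm2_report,
    parse_drep_tables,
    parse_gtdbtk_summary,
    read_fasta,
    read_gff3,
)
from .schema import Database, MagdbError, initialize_schema, insert_if_absent

logger = logging.getLogger(__name__)

BIN_GLOBS = ("*.fa", "*.fasta", "*.fna")
GFF_GLOBS = ("*.gff", "*.gff3")
PROTEIN_GLOBS = ("*.faa", "*.fa", "*.fasta")

#: default tool name recorded per stage when the config does not supply one
STAGE_TOOLS = {
    "bins": "binner",
    "gff": "prokka",
    "proteins": "prokka",
    "gtdbtk": "gtdbtk",
    "drep": "drep",
    "checkm2": "checkm2",
}


class ConfigError(MagdbError):
    pass


class ChangedFileError(MagdbError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class ToolInfo(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    version: str = "unknown"


class AnnotationSource(BaseModel):
    model_config = ConfigDict(extra="forbid")
    plugin_name: str
    path: Path


class AssemblyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str = Field(min_length=1)
    bins_dir: Path
    gff_dir: Optional[Path] = None
    proteins_dir: Optional[Path] = None
    gtdbtk_summary: Optional[Path] = None
    drep_cluster_table: Optional[Path] = None
    drep_winners_table: Optional[Path] = None
    checkm2_report: Optional[Path] = None
    annotations: list[AnnotationSource] = Field(default_factory=list)


class IngestOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    strict: bool = True
    batch_size: int = Field(default=1000, gt=0)
    database_target: str = "magdb.sqlite"
    disabled_plugins: list[str] = Field(default_factory=list)


class IngestConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    project_name: str = Field(min_length=1)
    assemblies: list[AssemblyConfig]
    options: IngestOptions = Field(default_factory=IngestOptions)
    #: per-stage upstream tool metadata (keys of STAGE_TOOLS or plugin names)
    tools: dict[str, ToolInfo] = Field(default_factory=dict)


def load_config(path: str | Path) -> IngestConfig:
    """Load and fully validate a project configuration from TOML.

    Every referenced path must exist at load time, and every annotation's
    plugin must be discovered and enabled; violations raise
    :class:`ConfigError` naming the offending key.
    """
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except FileNotFoundError:
        raise ConfigError(f"configuration file not found: {path}") from None
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{path}: invalid TOML: {exc}") from None
    base = path.parent
    for acfg_raw in raw.get("assemblies", []) or []:
        if not isinstance(acfg_raw, dict):
            continue
        for key in ("bins_dir", "gff_dir", "proteins_dir", "gtdbtk_summary",
                    "drep_cluster_table", "drep_winners_table", "checkm2_report"):
            value = acfg_raw.get(key)
            if isinstance(value, str) and not Path(value).is_absolute():
                acfg_raw[key] = str(base / value)
        for ann_raw in acfg_raw.get("annotations", []) or []:
            value = ann_raw.get("path") if isinstance(ann_raw, dict) else None
            if isinstance(value, str) and not Path(value).is_absolute():
                ann_raw["path"] = str(base / value)
    opts_raw = raw.get("options")
    if isinstance(opts_raw, dict):
        target = opts_raw.get("database_target")
        if (isinstance(target, str) and target != ":memory:"
                and not Path(target).is_absolute()):
            opts_raw["database_target"] = str(base / target)
    try:
        config = IngestConfig.model_validate(raw)
    except ValidationError as exc:
        err = exc.errors()[0]
        key = ".".join(str(p) for p in err["loc"])
        raise ConfigError(f"{path}: invalid key {key!r}: {err['msg']}") from exc

    for i, acfg in enumerate(config.assemblies):
        for key in ("bins_dir", "gff_dir", "proteins_dir", "gtdbtk_summary",
                    "drep_cluster_table", "drep_winners_table", "checkm2_report"):
            p = getattr(acfg, key)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"assemblies[{i}].{key}: path does not exist: {p}")
        for j, ann in enumerate(acfg.annotations):
            if not Path(ann.path).exists():
                raise ConfigError(
                    f"assemblies[{i}].annotations[{j}].path: path does not exist: {ann.path}"
                )
    enabled = {
        d.name
        for d in plugins.discover_plugins(disabled=config.options.disabled_plugins)
        if d.enabled
    }
    for i, acfg in enumerate(config.assemblies):
        for j, ann in enumerate(acfg.annotations):
            if ann.plugin_name not in enabled:
                raise ConfigError(
                    f"assemblies[{i}].annotations[{j}].plugin_name: "
                    f"unknown or disabled plugin {ann.plugin_name!r}"
                )
    return config


def config_to_toml(config: IngestConfig) -> str:
    """Serialize a configuration back to TOML (inverse of :func:`load_config`)."""
    lines = [f'project_name = "{config.project_name}"', ""]
    lines.append("[options]")
    lines.append(f"strict = {str(config.options.strict).lower()}")
    lines.append(f"batch_size = {config.options.batch_size}")
    lines.append(f'database_target = "{config.options.database_target}"')
    if config.options.disabled_plugins:
        quoted = ", ".join(f'"{p}"' for p in config.options.disabled_plugins)
        lines.append(f"disabled_plugins = [{quoted}]")
    lines.append("")
    for key, info in config.tools.items():
        lines.append(f"[tools.{key}]")
        lines.append(f'name = "{info.name}"')
        lines.append(f'version = "{info.version}"')
        lines.append("")
    for acfg in config.assemblies:
        lines.append("[[assemblies]]")
        lines.append(f'name = "{acfg.name}"')
        lines.append(f'bins_dir = "{acfg.bins_dir}"')
        for key in ("gff_dir", "proteins_dir", "gtdbtk_summary",
                    "drep_cluster_table", "drep_winners_table", "checkm2_report"):
            value = getattr(acfg, key)
            if value is not None:
                lines.append(f'{key} = "{value}"')
        lines.append("")
        for ann in acfg.annotations:
            lines.append("[[assemblies.annotations]]")
            lines.append(f'plugin_name = "{ann.plugin_name}"')
            lines.append(f'path = "{ann.path}"')
            lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# audit
# ---------------------------------------------------------------------------

def file_checksum(path: str | Path) -> str:
    """SHA-256 hex digest of a file's bytes."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


@dataclass(frozen=True)
class FileAudit:
    path: str
    sha256: str
    rows_ingested: int


@dataclass
class IngestReport:
    stages: list[AssemblyLinkReport] = field(default_factory=list)
    files: list[FileAudit] = field(default_factory=list)
    started_at: str = ""
    finished_at: str = ""


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

class _Populator:
    def __init__(self, config: IngestConfig, db: Database):
        self.config = config
        self.db = db
        self.cache: dict = {}
        self.report = IngestReport()
        self._clock = datetime.datetime.now(datetime.timezone.utc)
        self._tick = 0

    # -- project-management plumbing ---------------------------------------

    def _next_timestamp(self) -> str:
        self._tick += 1
        return (self._clock + datetime.timedelta(microseconds=self._tick)).isoformat()

    def _one(self, table: str, row: dict, key_cols: tuple[str, ...]) -> int:
        res = insert_if_absent(
            self.db, table, [row], key_cols, self.cache, self.config.options.batch_size
        )
        return res.outcomes[0].key_id

    def _run_for(self, project_id: int, stage_key: str, source_label: str) -> int:
        info = self.config.tools.get(stage_key)
        tool_name = info.name if info else STAGE_TOOLS.get(stage_key, stage_key)
        tool_version = info.version if info else "unknown"
        tool_id = self._one("tool", {"name": tool_name, "version": tool_version},
                            ("name", "version"))
        source_id = self._one("source", {"label": source_label}, ("label",))
        return self._one(
            "run",
            {"project_ref": project_id, "tool_ref": tool_id, "source_ref": source_id,
             "started_at": self._next_timestamp()},
            ("project_ref", "tool_ref", "source_ref"),
        )

    # -- file-entity ingestion ----------------------------------------------

    def _file_row(self, table: str, assembly_id: int, path: Path, run_id: int,
                  extra: Optional[dict] = None) -> int:
        digest = file_checksum(path)
        existing = self.db.conn.execute(
            f'SELECT sha256 FROM "{table}" WHERE assembly_ref = ? AND path = ?',
            (assembly_id, str(path)),
        ).fetchone()
        if existing is not None and existing["sha256"] != digest:
            msg = f"{path}: file contents changed since last ingest (digest mismatch)"
            if self.config.options.strict:
                raise ChangedFileError(msg)
            logger.warning(msg)
        row = {"assembly_ref": assembly_id, "run_ref": run_id,
               "path": str(path), "sha256": digest, **(extra or {})}
        file_id = self._one(table, row, ("assembly_ref", "path"))
        return file_id

    def _audit(self, path: Path, rows: int) -> None:
        self.report.files.append(FileAudit(str(path), file_checksum(path), rows))

    def _glob(self, directory: Path, patterns: tuple[str, ...]) -> list[Path]:
        seen: dict[Path, None] = {}
        for pat in patterns:
            for p in sorted(directory.glob(pat)):
                seen.setdefault(p, None)
        return list(seen)

    def _ingest_fasta(self, assembly_id: int, path: Path, run_id: int, role: str) -> int:
        file_id = self._file_row("fasta_file", assembly_id, path, run_id,
                                 {"file_role": role})
        records = read_fasta(path)
        rows = [
            {"fasta_file_ref": file_id, "record_id": r.id, "description": r.description,
             "sequence": r.sequence, "sequence_length": len(r.sequence)}
            for r in records
        ]
        insert_if_absent(self.db, "fasta_entry", rows, ("fasta_file_ref", "record_id"),
                         self.cache, self.config.options.batch_size)
        self._audit(path, len(rows))
        return len(rows)

    def _ingest_gff(self, assembly_id: int, path: Path, run_id: int) -> int:
        file_id = self._file_row("gff_file", assembly_id, path, run_id)
        rows = []
        for i, feat in enumerate(read_gff3(path), start=1):
            rows.append({
                "gff_file_ref": file_id, "line_number": i,
                "seqid": feat.seqid, "source": feat.source,
                "feature_type": feat.feature_type, "start": feat.start,
                "end": feat.end, "score": feat.score, "strand": feat.strand,
                "frame": feat.frame, "attributes_json": json.dumps(feat.attributes),
            })
        insert_if_absent(self.db, "gff_entry", rows, ("gff_file_ref", "line_number"),
                         self.cache, self.config.options.batch_size)
        self._audit(path, len(rows))
        return len(rows)

    # -- per-assembly pipeline ----------------------------------------------

    def populate_assembly(self, project_id: int, acfg: AssemblyConfig) -> None:
        db, opts = self.db, self.config.options
        sample_id = self._one("sample", {"project_ref": project_id, "name": acfg.name},
                              ("project_ref", "name"))
        assembly_id = self._one("assembly", {"sample_ref": sample_id, "name": acfg.name},
                                ("sample_ref", "name"))

        run_bins = self._run_for(project_id, "bins", "bins")
        for path in self._glob(acfg.bins_dir, BIN_GLOBS):
            self._ingest_fasta(assembly_id, path, run_bins, "genome_bins")
        if acfg.gff_dir is not None:
            run_gff = self._run_for(project_id, "gff", "gff")
            for path in self._glob(acfg.gff_dir, GFF_GLOBS):
                self._ingest_gff(assembly_id, path, run_gff)
        if acfg.proteins_dir is not None:
            run_prot = self._run_for(project_id, "proteins", "proteins")
            for path in self._glob(acfg.proteins_dir, PROTEIN_GLOBS):
                self._ingest_fasta(assembly_id, path, run_prot, "proteins")

        self.report.stages.append(assembler.assemble_genomes_and_contigs(
            db, assembly_id, self.cache, opts.batch_size))
        if acfg.gff_dir is not None:
            self.report.stages.append(assembler.assemble_genes(
                db, assembly_id, opts.strict, self.cache, opts.batch_size))
        if acfg.proteins_dir is not None:
            self.report.stages.append(assembler.assemble_proteins(
                db, assembly_id, opts.strict, self.cache, opts.batch_size))

        for ann in acfg.annotations:
            self._populate_annotation(project_id, assembly_id, ann)

        if acfg.drep_cluster_table is not None:
            self._populate_drep(project_id, assembly_id, acfg)
        if acfg.gtdbtk_summary is not None:
            self._populate_taxonomy(project_id, assembly_id, acfg.gtdbtk_summary)
        if acfg.checkm2_report is not None:
            self._populate_quality(project_id, assembly_id, acfg.checkm2_report)

    def _populate_annotation(self, project_id: int, assembly_id: int,
                             ann: AnnotationSource) -> None:
        opts = self.config.options
        descriptors = {d.name: d for d in plugins.discover_plugins(
            disabled=opts.disabled_plugins)}
        descriptor = descriptors.get(ann.plugin_name)
        if descriptor is None or not descriptor.enabled:
            raise ConfigError(f"unknown or disabled plugin {ann.plugin_name!r}")
        parser = plugins.get_parser(ann.plugin_name)
        run_id = self._run_for(project_id, ann.plugin_name,
                               f"annotation:{ann.plugin_name}")
        file_id = self._file_row("protein_annotation_file", assembly_id, Path(ann.path),
                                 run_id, {"tool_name": descriptor.target_tool})
        annotations = parser(ann.path)

        # one file-entity entry per data line; dbcan/proteinfer carry a header
        with open(ann.path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
        if ann.plugin_name in ("dbcan", "proteinfer") and lines:
            lines = lines[1:]
        entry_rows = []
        for i, line in enumerate(lines, start=1):
            key = line.split("\t")[0].split(",")[0]
            entry_rows.append({
                "protein_annotation_file_ref": file_id, "line_number": i,
                "protein_key": key, "raw_line": line,
            })
        insert_if_absent(self.db, "protein_annotation_entry", entry_rows,
                         ("protein_annotation_file_ref", "line_number"),
                         self.cache, opts.batch_size)
        entry_lookup: dict[str, int] = {}
        for r in self.db.conn.execute(
            "SELECT protein_annotation_entry_id, protein_key FROM protein_annotation_entry "
            "WHERE protein_annotation_file_ref = ? ORDER BY line_number", (file_id,),
        ):
            entry_lookup.setdefault(r["protein_key"], r["protein_annotation_entry_id"])
        self.report.stages.append(assembler.link_protein_annotations(
            self.db, assembly_id, annotations, entry_lookup,
            opts.strict, self.cache, opts.batch_size))
        self._audit(Path(ann.path), len(entry_rows))

    def _populate_drep(self, project_id: int, assembly_id: int,
                       acfg: AssemblyConfig) -> None:
        opts = self.config.options
        run_id = self._run_for(project_id, "drep", "drep")
        cluster_file_id = self._file_row(
            "dereplication_file", assembly_id, Path(acfg.drep_cluster_table), run_id,
            {"table_role": "clusters"})
        if acfg.drep_winners_table is not None:
            self._file_row("dereplication_file", assembly_id,
                           Path(acfg.drep_winners_table), run_id,
                           {"table_role": "winners"})
        rows = parse_drep_tables(acfg.drep_cluster_table, acfg.drep_winners_table)
        entry_rows = [
            {"dereplication_file_ref": cluster_file_id, "genome_name": r.genome_name,
             "cluster_label": r.cluster_label, "is_winner": int(r.is_winner)}
            for r in rows
        ]
        insert_if_absent(self.db, "dereplication_entry", entry_rows,
                         ("dereplication_file_ref", "genome_name"),
                         self.cache, opts.batch_size)
        self._audit(Path(acfg.drep_cluster_table), len(entry_rows))
        if acfg.drep_winners_table is not None:
            self._audit(Path(acfg.drep_winners_table),
                        sum(1 for r in rows if r.is_winner))
        self.report.stages.append(assembler.assemble_clusters(
            self.db, assembly_id, rows, opts.strict, self.cache, opts.batch_size))

    def _populate_taxonomy(self, project_id: int, assembly_id: int,
                           summary_path: Path) -> None:
        opts = self.config.options
        run_id = self._run_for(project_id, "gtdbtk", "gtdbtk")
        file_id = self._file_row("taxonomy_file", assembly_id, Path(summary_path), run_id)
        rows = parse_gtdbtk_summary(summary_path)
        entry_rows = [
            {"taxonomy_file_ref": file_id, "user_genome": r.user_genome,
             "classification": r.classification}
            for r in rows
        ]
        insert_if_absent(self.db, "taxonomy_entry", entry_rows,
                         ("taxonomy_file_ref", "user_genome"),
                         self.cache, opts.batch_size)
        entry_lookup = {
            r["user_genome"]: r["taxonomy_entry_id"]
            for r in self.db.conn.execute(
                "SELECT taxonomy_entry_id, user_genome FROM taxonomy_entry "
                "WHERE taxonomy_file_ref = ?", (file_id,))
        }
        self._audit(Path(summary_path), len(entry_rows))
        self.report.stages.append(assembler.assemble_taxonomy(
            self.db, assembly_id, rows, opts.strict, entry_lookup,
            self.cache, opts.batch_size))

    def _populate_quality(self, project_id: int, assembly_id: int,
                          report_path: Path) -> None:
        opts = self.config.options
        run_id = self._run_for(project_id, "checkm2", "checkm2")
        file_id = self._file_row("quality_file", assembly_id, Path(report_path), run_id)
        rows = parse_checkm2_report(report_path)
        entry_rows = [
            {"quality_file_ref": file_id, "genome_name": r.genome_name,
             "completeness_pct": r.completeness_pct,
             "contamination_pct": r.contamination_pct}
            for r in rows
        ]
        insert_if_absent(self.db, "quality_entry", entry_rows,
                         ("quality_file_ref", "genome_name"),
                         self.cache, opts.batch_size)
        entry_lookup = {
            r["genome_name"]: r["quality_entry_id"]
            for r in self.db.conn.execute(
                "SELECT quality_entry_id, genome_name FROM quality_entry "
                "WHERE quality_file_ref = ?", (file_id,))
        }
        self._audit(Path(report_path), len(entry_rows))
        self.report.stages.append(assembler.assemble_quality(
            self.db, assembly_id, rows, opts.strict, entry_lookup,
            self.cache, opts.batch_size))

    # -- entry point ---------------------------------------------------------

    def run(self) -> IngestReport:
        self.report.started_at = self._clock.isoformat()
        initialize_schema(self.db)
        disabled = set(self.config.options.disabled_plugins)
        for d in plugins.discover_plugins(disabled=disabled):
            self._one("plugin_registration",
                      {"name": d.name, "target_tool": d.target_tool,
                       "version": d.version, "enabled": int(d.enabled)},
                      ("name",))
        project_id = self._one("project",
                               {"name": self.config.project_name,
                                "created_at": self._clock.isoformat()},
                               ("name",))
        for acfg in self.config.assemblies:
            self.populate_assembly(project_id, acfg)
        self.report.finished_at = datetime.datetime.now(
            datetime.timezone.utc).isoformat()
        return self.report


def populate(config: IngestConfig, db: Optional[Database] = None) -> IngestReport:
    """Populate the project database from a validated configuration.

    Idempotent end-to-end: row counts and natural-key sets are identical
    after a second run on the same inputs.
    """
    own = db is None
    db = db or Database(config.options.database_target)
    try:
        return _Populator(config, db).run()
    finally:
        if own:
            db.close()
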