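"""Named biological queries and the read-only HTTP API.

The integration payoff of the relational model: questions that span many
workflow output files become single joins.  The two named queries mirror a
typical enzyme-discovery workflow over carbohydrate-active enzymes
(CAZymes):

* ``cazymes-novel-taxa`` — every (genome, protein, family) where the
  protein carries a dbCAN family/subfamily call and the genome is a
  taxonomic novelty (species rank unassigned by GTDB-Tk, or a configurable
  shallower rank);
* ``family-counts`` — per-genome distinct-protein counts for one exact
  family accession (e.g. GH5), optionally restricted to novel genomes.

The WSGI application exposes entities and queries over HTTP as JSON.  It is
strictly read-only: only GET is accepted and every handler runs SELECT
statements only.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass
from typing import Any, Callable, Optional
from urllib.parse import parse_qs

from .schema import (
    CANONICAL_RANKS,
    CAZYME_CLASS_CODES,
    RANK_INDEX,
    Database,
    MagdbError,
    open_database,
)


class QueryLookupError(MagdbError):
    pass


class QueryParamError(MagdbError):
    pass


@dataclass(frozen=True)
class NovelCazymeHit:
    project_name: str
    genome_name: str
    protein_name: str
    family_accession: str
    lowest_assigned_rank: Optional[str]

    def __post_init__(self):
        if not any(self.family_accession.startswith(c) for c in CAZYME_CLASS_CODES):
            raise ValueError(
                f"family accession {self.family_accession!r} lacks a CAZyme class prefix"
            )


@dataclass(frozen=True)
class FamilyCountRow:
    project_name: str
    genome_name: str
    family_accession: str
    protein_count: int


_RANK_CASE = "CASE ta.lowest_assigned_rank " + " ".join(
    f"WHEN '{r}' THEN {i}" for r, i in RANK_INDEX.items()
) + " ELSE -1 END"

_JOINS = """
FROM protein_annotation pa
JOIN protein p        ON pa.protein_ref = p.protein_id
JOIN gene ge          ON p.gene_ref = ge.gene_id
JOIN contig c         ON ge.contig_ref = c.contig_id
JOIN genome g         ON c.genome_ref = g.genome_id
JOIN assembly a       ON g.assembly_ref = a.assembly_id
JOIN sample s         ON a.sample_ref = s.sample_id
JOIN project pr       ON s.project_ref = pr.project_id
JOIN taxonomy_assignment ta ON ta.genome_ref = g.genome_id
"""


def _novelty_condition(novelty_rank: str) -> str:
    if novelty_rank not in CANONICAL_RANKS:
        raise QueryParamError(
            f"novelty_rank must be one of {CANONICAL_RANKS}, got {novelty_rank!r}"
        )
    if novelty_rank == "species":
        return "ta.is_novel_species = 1"
    # novel at rank r: the classification stops above r
    return (
        f"(ta.lowest_assigned_rank IS NULL OR ({_RANK_CASE}) < {RANK_INDEX[novelty_rank]})"
    )


def query_cazymes_novel_taxa(
    connection_target: Database | str,
    project: Optional[str] = None,
    novelty_rank: str = "species",
) -> list[NovelCazymeHit]:
    """All CAZyme (genome, protein, family) triples in taxonomically novel MAGs.

    A hit is a distinct (genome, protein, accession) over annotations of
    type family or subfamily from the dbCAN source.  ``project=None`` spans
    every project in the database.
    """
    db = open_database(connection_target)
    sql = (
        "SELECT DISTINCT pr.name AS project_name, g.name AS genome_name, "
        "p.name AS protein_name, pa.accession AS family_accession, "
        "ta.lowest_assigned_rank AS lowest_assigned_rank "
        + _JOINS
        + "WHERE pa.source_tool = 'dbcan' "
        "AND pa.annotation_type IN ('family', 'subfamily') "
        f"AND {_novelty_condition(novelty_rank)} "
    )
    params: list[Any] = []
    if project is not None:
        sql += "AND pr.name = ? "
        params.append(project)
    sql += "ORDER BY pr.name, g.name, p.name, pa.accession"
    return [
        NovelCazymeHit(
            r["project_name"], r["genome_name"], r["protein_name"],
            r["family_accession"], r["lowest_assigned_rank"],
        )
        for r in db.conn.execute(sql, params)
    ]


def query_family_counts_per_genome(
    connection_target: Database | str,
    family_accession: str,
    novel_only: bool = True,
    project: Optional[str] = None,
    novelty_rank: str = "species",
) -> list[FamilyCountRow]:
    """Per-genome distinct-protein counts for one exact family accession.

    Genomes with zero matching proteins are omitted; with ``novel_only``
    only taxonomically novel genomes are reported.
    """
    db = open_database(connection_target)
    sql = (
        "SELECT pr.name AS project_name, g.name AS genome_name, "
        "COUNT(DISTINCT p.protein_id) AS protein_count "
        + _JOINS
        + "WHERE pa.source_tool = 'dbcan' "
        "AND pa.annotation_type IN ('family', 'subfamily') "
        "AND pa.accession = ? "
    )
    params: list[Any] = [family_accession]
    if novel_only:
        sql += f"AND {_novelty_condition(novelty_rank)} "
    if project is not None:
        sql += "AND pr.name = ? "
        params.append(project)
    sql += "GROUP BY pr.name, g.name ORDER BY pr.name, g.name"
    return [
        FamilyCountRow(r["project_name"], r["genome_name"], family_accession,
                       r["protein_count"])
        for r in db.conn.execute(sql, params)
    ]


# ---------------------------------------------------------------------------
# named-query registry
# ---------------------------------------------------------------------------

def _parse_bool(value: Any) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, str) and value.lower() in ("true", "false", "1", "0"):
        return value.lower() in ("true", "1")
    raise QueryParamError(f"expected a boolean, got {value!r}")


def _q_cazymes(db: Database, params: dict[str, Any]) -> list[dict[str, Any]]:
    allowed = {"project", "novelty_rank"}
    unknown = set(params) - allowed
    if unknown:
        raise QueryParamError(f"unknown parameter(s) {sorted(unknown)}; allowed: {sorted(allowed)}")
    hits = query_cazymes_novel_taxa(
        db, project=params.get("project"),
        novelty_rank=params.get("novelty_rank", "species"),
    )
    return [asdict(h) for h in hits]


def _q_family_counts(db: Database, params: dict[str, Any]) -> list[dict[str, Any]]:
    allowed = {"family", "novel_only", "project", "novelty_rank"}
    unknown = set(params) - allowed
    if unknown:
        raise QueryParamError(f"unknown parameter(s) {sorted(unknown)}; allowed: {sorted(allowed)}")
    if "family" not in params:
        raise QueryParamError("missing required parameter 'family'")
    rows = query_family_counts_per_genome(
        db, family_accession=str(params["family"]),
        novel_only=_parse_bool(params.get("novel_only", True)),
        project=params.get("project"),
        novelty_rank=params.get("novelty_rank", "species"),
    )
    return [asdict(r) for r in rows]


NAMED_QUERIES: dict[str, Callable[[Database, dict[str, Any]], list[dict[str, Any]]]] = {
    "cazymes-novel-taxa": _q_cazymes,
    "family-counts": _q_family_counts,
}


def run_named_query(
    connection_target: Database | str,
    name: str,
    params: Optional[dict[str, Any]] = None,
    output_format: str = "rows",
) -> list[dict[str, Any]] | str:
    """Dispatch a registered query by name and serialize the result.

    ``output_format``: ``rows`` (list of dicts), ``json``, or ``tsv``
    (header row plus one tab-separated line per hit).
    """
    if name not in NAMED_QUERIES:
        raise QueryLookupError(
            f"unknown query {name!r}; registered: {sorted(NAMED_QUERIES)}"
        )
    db = open_database(connection_target)
    rows = NAMED_QUERIES[name](db, dict(params or {}))
    if output_format == "rows":
        return rows
    if output_format == "json":
        return json.dumps(rows, indent=2)
    if output_format == "tsv":
        if not rows:
            return ""
        header = list(rows[0])
        lines = ["\t".join(header)]
        for row in rows:
            lines.append("\t".join("" if row[c] is None else str(row[c]) for c in header))
        return "\n".join(lines) + "\n"
    raise QueryParamError(f"unknown output format {output_format!r}")


# ---------------------------------------------------------------------------
# read-only WSGI application
# ---------------------------------------------------------------------------

_ROUTES: list[tuple[re.Pattern, str]] = [
    (re.compile(r"^/projects/?$"), "projects"),
    (re.compile(r"^/projects/(?P<id>\d+)/genomes/?$"), "project_genomes"),
    (re.compile(r"^/genomes/(?P<id>\d+)/?$"), "genome"),
    (re.compile(r"^/genomes/(?P<id>\d+)/proteins/?$"), "genome_proteins"),
    (re.compile(r"^/proteins/(?P<id>\d+)/annotations/?$"), "protein_annotations"),
    (re.compile(r"^/queries/(?P<name>[\w-]+)/?$"), "named_query"),
]


class _HttpError(Exception):
    def __init__(self, status: int, message: str):
        self.status = status
        self.message = message


def _page(qs: dict[str, list[str]]) -> tuple[int, int]:
    try:
        limit = int(qs.get("limit", ["100"])[0])
        offset = int(qs.get("offset", ["0"])[0])
    except ValueError:
        raise _HttpError(400, "limit/offset must be integers") from None
    if limit < 1 or offset < 0:
        raise _HttpError(400, "limit must be >= 1 and offset >= 0")
    return limit, offset


def create_app(connection_target: Database | str) -> Callable:
    """Build a WSGI application serving the database read-only as JSON."""

    def _db() -> Database:
        return open_database(connection_target)

    def handle(name: str, match: re.Match, qs: dict[str, list[str]]) -> Any:
        db = _db()
        limit, offset = _page(qs)
        if name == "projects":
            return [dict(r) for r in db.conn.execute(
                "SELECT project_id, name, created_at FROM project "
                "ORDER BY project_id LIMIT ? OFFSET ?", (limit, offset))]
        if name == "project_genomes":
            return [dict(r) for r in db.conn.execute(
                "SELECT g.genome_id, g.name, g.cluster_ref FROM genome g "
                "JOIN assembly a ON g.assembly_ref = a.assembly_id "
                "JOIN sample s ON a.sample_ref = s.sample_id "
                "WHERE s.project_ref = ? ORDER BY g.genome_id LIMIT ? OFFSET ?",
                (int(match["id"]), limit, offset))]
        if name == "genome":
            row = db.conn.execute(
                "SELECT g.genome_id, g.name, g.assembly_ref, g.cluster_ref, "
                "ta.is_novel_species, ta.lowest_assigned_rank "
                "FROM genome g LEFT JOIN taxonomy_assignment ta "
                "ON ta.genome_ref = g.genome_id WHERE g.genome_id = ?",
                (int(match["id"]),)).fetchone()
            if row is None:
                raise _HttpError(404, f"no genome with id {match['id']}")
            return dict(row)
        if name == "genome_proteins":
            return [dict(r) for r in db.conn.execute(
                "SELECT p.protein_id, p.name, p.sequence_length_aa FROM protein p "
                "JOIN gene ge ON p.gene_ref = ge.gene_id "
                "JOIN contig c ON ge.contig_ref = c.contig_id "
                "WHERE c.genome_ref = ? ORDER BY p.protein_id LIMIT ? OFFSET ?",
                (int(match["id"]), limit, offset))]
        if name == "protein_annotations":
            return [dict(r) for r in db.conn.execute(
                "SELECT protein_annotation_id, source_tool, annotation_type, "
                "accession, description, score, coord_start, coord_stop "
                "FROM protein_annotation WHERE protein_ref = ? "
                "ORDER BY protein_annotation_id LIMIT ? OFFSET ?",
                (int(match["id"]), limit, offset))]
        if name == "named_query":
            qname = match["name"]
            params = {k: v[0] for k, v in qs.items() if k not in ("limit", "offset")}
            try:
                rows = run_named_query(db, qname, params)
            except QueryLookupError as exc:
                raise _HttpError(404, str(exc)) from None
            except QueryParamError as exc:
                raise _HttpError(400, str(exc)) from None
            assert isinstance(rows, list)
            return rows[offset:offset + limit]
        raise _HttpError(404, "not found")  # pragma: no cover

    def app(environ: dict, start_response: Callable):
        method = environ.get("REQUEST_METHOD", "GET").upper()
        path = environ.get("PATH_INFO", "/")
        qs = parse_qs(environ.get("QUERY_STRING", ""))
        if method != "GET":
            body = json.dumps({"error": "read-only API: only GET is allowed"}).encode()
            start_response("405 Method Not Allowed",
                           [("Content-Type", "application/json"),
                            ("Allow", "GET"),
                            ("Content-Length", str(len(body)))])
            return [body]
        for pattern, name in _ROUTES:
            match = pattern.match(path)
            if match is not None:
                try:
                    payload: Any = handle(name, match, qs)
                    status = "200 OK"
                except _HttpError as exc:
                    payload = {"error": exc.message}
                    status = f"{exc.status} " + {400: "Bad Request", 404: "Not Found"}.get(
                        exc.status, "Error")
                body = json.dumps(payload).encode()
                start_response(status, [("Content-Type", "application/json"),
                                        ("Content-Length", str(len(body)))])
                return [body]
        body = json.dumps({"error": f"unknown path {path!r}"}).encode()
        start_response("404 Not Found", [("Content-Type", "application/json"),
                                         ("Content-Length", str(len(body)))])
        return [body]

    return app


def serve(connection_target: str, host: str = "127.0.0.1", port: int = 8000) -> None:
    """Serve the read-only API with the stdlib WSGI reference server."""
    from wsgiref.simple_server import make_server

    with make_server(host, port, create_app(connection_target)) as httpd:
        print(f"serving read-only API on http://{host}:{port}/")
        httpd.serve_forever()
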