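"""Protein-annotation parser plugins.

Annotation tools come and go faster than any schema should; tool-specific
parsing therefore lives behind a plugin contract rather than in the core.
A plugin is a parser entry point (``path -> sequence of UnifiedAnnotation``)
plus a :class:`PluginDescriptor`; plugins populate the existing
protein-annotation tables and never touch the schema itself.

Four reference plugins ship built in:

* ``dbcan`` — dbCAN CAZyme overview tables (family/subfamily calls);
* ``interpro`` — InterProScan TSV (signature domains, InterPro entries,
  GO terms);
* ``clean`` — CLEAN enzyme-commission predictions (CSV);
* ``proteinfer`` — ProteInfer GO/EC predictions (TSV).

Third-party plugins are discovered from installed distributions named
``magdb-plugin-<name>`` exposing a ``magdb.plugins`` entry point.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import metadata as importlib_metadata
from pathlib import Path
from typing import Callable, Iterable, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .schema import CAZYME_CLASS_CODES, MagdbError

logger = logging.getLogger(__name__)

ENTRY_POINT_GROUP = "magdb.plugins"
PLUGIN_DIST_PREFIX = "magdb-plugin-"


class PluginError(MagdbError):
    pass


class AmbiguousPluginError(PluginError):
    pass


class MalformedLineError(MagdbError):
    pass


class MalformedTermError(MagdbError):
    pass


class FormatError(MagdbError):
    pass


# ---------------------------------------------------------------------------
# the unified record every plugin emits
# ---------------------------------------------------------------------------

class UnifiedAnnotation(BaseModel):
    """Tool-agnostic protein-annotation record.

    ``protein_key`` must match a protein FASTA record id so the assembler
    can resolve it to a protein row.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    protein_key: str = Field(min_length=1)
    source_tool: str = Field(min_length=1)
    annotation_type: str
    accession: str = Field(min_length=1)
    description: Optional[str] = None
    score: Optional[float] = None
    coord_start: Optional[int] = Field(default=None, ge=1)
    coord_stop: Optional[int] = None

    @model_validator(mode="after")
    def _coords(self) -> "UnifiedAnnotation":
        if self.annotation_type not in (
            "family", "subfamily", "domain", "ec_number", "go_term", "description"
        ):
            raise ValueError(f"invalid annotation_type {self.annotation_type!r}")
        if (
            self.coord_start is not None
            and self.coord_stop is not None
            and self.coord_start > self.coord_stop
        ):
            raise ValueError("coord_start must be <= coord_stop")
        return self


class PluginDescriptor(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    target_tool: str
    version: str = "0"
    enabled: bool = True


ParserFunc = Callable[[str | Path], list[UnifiedAnnotation]]


# ---------------------------------------------------------------------------
# dbCAN overview
# ---------------------------------------------------------------------------

# one consensus unit: family, optional _subfamily, optional (start-end)
_DBCAN_UNIT = re.compile(
    r"^(?P<family>[A-Za-z]+\d+)(?:_(?P<sub>[\w.]+))?(?:\((?P<start>\d+)-(?P<stop>\d+)\))?$"
)


def _family_class(token: str) -> Optional[str]:
    for code in sorted(CAZYME_CLASS_CODES, key=len, reverse=True):
        if token.startswith(code):
            return code
    return None


def parse_dbcan_overview(path: str | Path) -> list[UnifiedAnnotation]:
    """Parse a dbCAN overview table into family/subfamily annotations.

    The consensus prediction column (``Recommend Results`` when present,
    otherwise ``HMMER``) is authoritative; it is split on ``+`` into units
    like ``GH5`` or ``GH5_2(31-330)``.  Each unit yields a ``family``
    annotation (plus a ``subfamily`` annotation when a ``_SUB`` suffix is
    present) with coordinates from the parenthesized range and the per-row
    tool-agreement count (``#ofTools``) carried as the score.  Rows with a
    family token outside the six CAZyme classes are skipped with a warning.
    """
    path = Path(path)
    annotations: list[UnifiedAnnotation] = []
    skipped = 0
    with open(path) as handle:
        header_line = handle.readline()
        if not header_line:
            return []
        header = header_line.rstrip("\n").split("\t")
        try:
            gene_col = header.index("Gene ID")
            ntools_col = header.index("#ofTools")
        except ValueError as exc:
            raise FormatError(f"{path}: missing required dbCAN column: {exc}") from None
        if "Recommend Results" in header:
            consensus_col = header.index("Recommend Results")
        elif "HMMER" in header:
            consensus_col = header.index("HMMER")
        else:
            raise FormatError(f"{path}: no consensus prediction column found")
        for line in handle:
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            protein_key = cols[gene_col]
            consensus = cols[consensus_col].strip()
            try:
                score = float(cols[ntools_col])
            except (ValueError, IndexError):
                score = None
            if consensus in ("", "-"):
                continue
            row_annotations: list[UnifiedAnnotation] = []
            ok = True
            for unit in consensus.split("+"):
                unit = unit.strip()
                m = _DBCAN_UNIT.match(unit)
                if m is None or _family_class(m.group("family")) is None:
                    logger.warning("%s: malformed dbCAN family token %r, row skipped", path, unit)
                    ok = False
                    break
                start = int(m.group("start")) if m.group("start") else None
                stop = int(m.group("stop")) if m.group("stop") else None
                row_annotations.append(UnifiedAnnotation(
                    protein_key=protein_key,
                    source_tool="dbcan",
                    annotation_type="family",
                    accession=m.group("family"),
                    score=score,
                    coord_start=start,
                    coord_stop=stop,
                ))
                if m.group("sub"):
                    row_annotations.append(UnifiedAnnotation(
                        protein_key=protein_key,
                        source_tool="dbcan",
                        annotation_type="subfamily",
                        accession=f"{m.group('family')}_{m.group('sub')}",
                        score=score,
                        coord_start=start,
                        coord_stop=stop,
                    ))
            if ok:
                annotations.extend(row_annotations)
            else:
                skipped += 1
    if skipped:
        logger.warning("%s: skipped %d malformed row(s)", path, skipped)
    return annotations


# ---------------------------------------------------------------------------
# InterProScan TSV
# ---------------------------------------------------------------------------

def parse_interproscan_tsv(path: str | Path) -> list[UnifiedAnnotation]:
    """Parse a headerless InterProScan TSV.

    Per line (>= 11 columns): a ``domain`` annotation for the member-database
    signature (source ``interproscan:<analysis>``, e-value as score, start/
    stop coordinates); a second ``domain`` annotation for the InterPro entry
    when column 12 is present and not ``-``; one ``go_term`` annotation per
    GO id in the ``|``-separated GO column.
    """
    path = Path(path)
    annotations: list[UnifiedAnnotation] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 11:
                raise MalformedLineError(
                    f"{path}:{lineno}: expected >= 11 columns, got {len(cols)}"
                )
            protein_key, analysis = cols[0], cols[3]
            signature, sig_desc = cols[4], cols[5]
            start, stop = int(cols[6]), int(cols[7])
            try:
                score = float(cols[8])
            except ValueError:
                score = None
            source = f"interproscan:{analysis}"
            annotations.append(UnifiedAnnotation(
                protein_key=protein_key, source_tool=source,
                annotation_type="domain", accession=signature,
                description=sig_desc or None, score=score,
                coord_start=start, coord_stop=stop,
            ))
            if len(cols) > 11 and cols[11] not in ("", "-"):
                ipr_desc = cols[12] if len(cols) > 12 and cols[12] not in ("", "-") else None
                annotations.append(UnifiedAnnotation(
                    protein_key=protein_key, source_tool=source,
                    annotation_type="domain", accession=cols[11],
                    description=ipr_desc,
                ))
            if len(cols) > 13 and cols[13] not in ("", "-"):
                for go_id in cols[13].split("|"):
                    go_id = go_id.strip()
                    if go_id:
                        annotations.append(UnifiedAnnotation(
                            protein_key=protein_key, source_tool=source,
                            annotation_type="go_term", accession=go_id,
                        ))
    return annotations


# ---------------------------------------------------------------------------
# CLEAN
# ---------------------------------------------------------------------------

def parse_clean_output(path: str | Path) -> list[UnifiedAnnotation]:
    """Parse CLEAN EC predictions.

    Each CSV line is ``protein_id,EC:a.b.c.d/score;EC:.../score...``; every
    term becomes one ``ec_number`` annotation.  Scores are the model's
    confidence values and are not range-constrained.
    """
    path = Path(path)
    annotations: list[UnifiedAnnotation] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            protein_key, _, terms = line.partition(",")
            for term in terms.split(";"):
                term = term.strip()
                if not term:
                    continue
                if "/" not in term:
                    raise MalformedTermError(
                        f"{path}:{lineno}: term {term!r} lacks '/' separator"
                    )
                label, _, score_s = term.partition("/")
                accession = label.removeprefix("EC:")
                annotations.append(UnifiedAnnotation(
                    protein_key=protein_key, source_tool="clean",
                    annotation_type="ec_number", accession=accession,
                    score=float(score_s),
                ))
    return annotations


# ---------------------------------------------------------------------------
# ProteInfer
# ---------------------------------------------------------------------------

def parse_proteinfer_output(path: str | Path) -> list[UnifiedAnnotation]:
    """Parse ProteInfer predictions (TSV: sequence_name, predicted_label,
    confidence).

    ``GO:``-prefixed labels map to ``go_term`` annotations (the full GO id
    kept as accession), ``EC:``-prefixed labels to ``ec_number`` (prefix
    stripped), anything else to ``description``.
    """
    path = Path(path)
    annotations: list[UnifiedAnnotation] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        required = ("sequence_name", "predicted_label", "confidence")
        if not all(c in header for c in required):
            raise FormatError(f"{path}: expected header columns {required}")
        idx = {c: header.index(c) for c in required}
        for lineno, raw in enumerate(handle, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            protein_key = cols[idx["sequence_name"]]
            label = cols[idx["predicted_label"]]
            try:
                score = float(cols[idx["confidence"]])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric confidence {cols[idx['confidence']]!r}"
                ) from None
            if label.startswith("GO:"):
                atype, accession = "go_term", label
            elif label.startswith("EC:"):
                atype, accession = "ec_number", label.removeprefix("EC:")
            else:
                atype, accession = "description", label
            annotations.append(UnifiedAnnotation(
                protein_key=protein_key, source_tool="proteinfer",
                annotation_type=atype, accession=accession, score=score,
            ))
    return annotations


# ---------------------------------------------------------------------------
# discovery and management
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BuiltinPlugin:
    name: str
    target_tool: str
    parser: ParserFunc


BUILTIN_PLUGINS: tuple[BuiltinPlugin, ...] = (
    BuiltinPlugin("dbcan", "dbcan", parse_dbcan_overview),
    BuiltinPlugin("interpro", "interproscan", parse_interproscan_tsv),
    BuiltinPlugin("clean", "clean", parse_clean_output),
    BuiltinPlugin("proteinfer", "proteinfer", parse_proteinfer_output),
)

_BUILTIN_BY_NAME = {p.name: p for p in BUILTIN_PLUGINS}


def discover_plugins(
    include_builtins: bool = True,
    disabled: Iterable[str] = (),
    entry_points: Optional[Iterable] = None,
) -> list[PluginDescriptor]:
    """List every available annotation-parser plugin.

    Built-in reference plugins are always present (unless explicitly
    excluded); external plugins are found through the ``magdb.plugins``
    entry-point group of installed ``magdb-plugin-*`` distributions.  Two
    plugins sharing one name is an error, not a silent shadowing.
    """
    disabled_set = set(disabled)
    descriptors: list[PluginDescriptor] = []
    seen: set[str] = set()
    if include_builtins:
        from importlib.metadata import version as dist_version
        try:
            own_version = dist_version("magdb")
        except importlib_metadata.PackageNotFoundError:
            own_version = "0"
        for p in BUILTIN_PLUGINS:
            descriptors.append(PluginDescriptor(
                name=p.name, target_tool=p.target_tool, version=own_version,
                enabled=p.name not in disabled_set,
            ))
            seen.add(p.name)
    eps = entry_points
    if eps is None:
        eps = importlib_metadata.entry_points(group=ENTRY_POINT_GROUP)
    for ep in eps:
        name = ep.name
        if name in seen:
            raise AmbiguousPluginError(f"two plugins named {name!r} discovered")
        seen.add(name)
        dist_name = getattr(getattr(ep, "dist", None), "name", f"{PLUGIN_DIST_PREFIX}{name}")
        dist_ver = getattr(getattr(ep, "dist", None), "version", "0")
        descriptors.append(PluginDescriptor(
            name=name, target_tool=dist_name.removeprefix(PLUGIN_DIST_PREFIX),
            version=dist_ver, enabled=name not in disabled_set,
        ))
    return descriptors


def get_parser(name: str) -> ParserFunc:
    """Resolve a plugin name to its parser entry point."""
    if name in _BUILTIN_BY_NAME:
        return _BUILTIN_BY_NAME[name].parser
    for ep in importlib_metadata.entry_points(group=ENTRY_POINT_GROUP):
        if ep.name == name:
            return ep.load()
    raise PluginError(
        f"unknown plugin {name!r}; available: {sorted(_BUILTIN_BY_NAME)}"
    )
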