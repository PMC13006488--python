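"""Streaming readers for standard MAG-workflow output formats.

Covers the file formats a typical prokaryotic MAG pipeline leaves behind:
multi-record FASTA (genome bins and Prokka-style protein files), GFF3 gene
annotations, GTDB-Tk classification summary TSVs, dRep cluster/winner CSVs
and CheckM2 quality-report TSVs.  Each reader yields light transient records
that the entity assembler later resolves into relational rows.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .schema import CANONICAL_RANKS, STRANDS, MagdbError

#: recognized FASTA filename extensions, stripped when normalizing bin names
FASTA_EXTENSIONS = (".fa", ".fasta", ".fna", ".faa")

RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")


class MalformedFastaError(MagdbError):
    pass


class MalformedGffError(MagdbError):
    pass


class FormatError(MagdbError):
    pass


class CrossFileInconsistencyError(MagdbError):
    pass


def normalize_genome_name(filename: str | Path) -> str:
    """Strip one recognized FASTA extension from a bin filename.

    All cross-file joins (dRep, GTDB-Tk, CheckM2 rows against bin files) use
    this normalized stem, so ``bin1.fa``, ``bin1.fasta`` and ``bin1`` all
    name the same genome.
    """
    name = Path(filename).name
    for ext in FASTA_EXTENSIONS:
        if name.lower().endswith(ext):
            return name[: -len(ext)]
    return name


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FastaRecord:
    id: str
    description: str
    sequence: str


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Parse a multi-record FASTA file.

    The record id is the header token before the first whitespace; the
    description is the remainder (possibly empty).  Sequence lines are
    concatenated, whitespace-stripped and uppercased; the alphabet is
    permissive (protein files carry ``*`` stops and alignments ``-`` gaps).
    """
    path = Path(path)
    with open(path) as handle:
        for line in handle:
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise MalformedFastaError(
                    f"{path}: sequence data before first '>' header"
                )
            break
        handle.seek(0)
        records = []
        for title, seq in SimpleFastaParser(handle):
            parts = title.split(None, 1)
            if not parts:
                raise MalformedFastaError(f"{path}: header with empty record id")
            rec_id = parts[0]
            description = parts[1] if len(parts) > 1 else ""
            records.append(FastaRecord(rec_id, description, "".join(seq.split()).upper()))
    return records


def write_fasta(records: Sequence[FastaRecord], path: str | Path, width: int = 80) -> None:
    """Write records back out with ``width``-column sequence wrapping."""
    with open(path, "w") as out:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            out.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GffFeature:
    seqid: str
    source: str
    feature_type: str
    start: int
    end: int
    score: Optional[float]
    strand: str
    frame: Optional[int]
    attributes: dict[str, str]


def read_gff3(path: str | Path) -> Iterator[GffFeature]:
    """Stream features from a GFF3 file.

    ``#``-prefixed lines are skipped and everything after a ``##FASTA``
    directive is ignored, so Prokka-style files with an embedded sequence
    block parse to the same features as files without one.  Coordinates stay
    1-based inclusive on the forward axis; ``.`` in score/frame maps to
    absent; attribute values are percent-decoded.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise MalformedGffError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            seqid, source, ftype, start_s, end_s, score_s, strand, frame_s, attr_s = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise MalformedGffError(f"{path}:{lineno}: non-integer coordinates") from None
            if not 1 <= start <= end:
                raise MalformedGffError(
                    f"{path}:{lineno}: invalid coordinates {start}..{end}"
                )
            if strand not in STRANDS:
                raise MalformedGffError(f"{path}:{lineno}: invalid strand {strand!r}")
            score = None if score_s == "." else float(score_s)
            if frame_s == ".":
                frame = None
            elif frame_s in ("0", "1", "2"):
                frame = int(frame_s)
            else:
                raise MalformedGffError(f"{path}:{lineno}: invalid frame {frame_s!r}")
            attributes: dict[str, str] = {}
            for item in attr_s.split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, value = item.partition("=")
                key = urllib.parse.unquote(key)
                if key in attributes:
                    raise MalformedGffError(
                        f"{path}:{lineno}: duplicate attribute key {key!r}"
                    )
                attributes[key] = urllib.parse.unquote(value)
            yield GffFeature(seqid, source, ftype, start, end, score, strand, frame, attributes)


# ---------------------------------------------------------------------------
# GTDB-Tk classification summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonomyRow:
    user_genome: str
    #: seven (rank, name-or-None) slots in canonical order
    lineage: tuple[tuple[str, Optional[str]], ...]
    lowest_assigned_rank: Optional[str]
    is_novel_species: bool
    #: the raw lineage string, kept for the taxonomy_entry file entity
    classification: str = ""


def parse_lineage(classification: str) -> tuple[tuple[str, Optional[str]], ...]:
    """Split a GTDB-Tk lineage string into the 7 canonical rank slots.

    ``d__Bacteria;p__Bacillota;c__;...`` — an empty suffix after the rank
    prefix means unassigned at that rank.  ``Unclassified`` (or any string
    without rank prefixes) yields all-unassigned; a truncated string leaves
    the remaining ranks unassigned.  Prefixes out of canonical order raise.
    """
    slots: list[Optional[str]] = [None] * 7
    text = classification.strip()
    if text and text.lower() != "unclassified":
        parts = [p.strip() for p in text.split(";") if p.strip()]
        for i, part in enumerate(parts):
            prefix = part[:3]
            if prefix not in RANK_PREFIXES:
                raise FormatError(f"unrecognized rank prefix in {part!r}")
            expected_idx = RANK_PREFIXES.index(prefix)
            if expected_idx != i:
                raise FormatError(
                    f"rank prefix {prefix!r} out of canonical order in {classification!r}"
                )
            name = part[3:].strip()
            slots[i] = name or None
    return tuple(zip(CANONICAL_RANKS, slots))


def _row_from_lineage(user_genome: str, classification: str) -> TaxonomyRow:
    lineage = parse_lineage(classification)
    assigned = [rank for rank, name in lineage if name is not None]
    lowest = assigned[-1] if assigned else None
    species_name = dict(lineage)["species"]
    return TaxonomyRow(
        user_genome=user_genome,
        lineage=lineage,
        lowest_assigned_rank=lowest,
        is_novel_species=species_name is None,
        classification=classification,
    )


def parse_gtdbtk_summary(path: str | Path) -> list[TaxonomyRow]:
    """Parse a GTDB-Tk classification summary TSV.

    Requires ``user_genome`` and ``classification`` columns.  A genome whose
    species slot is unassigned is flagged as a taxonomic novelty.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("user_genome", "classification"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return [
        _row_from_lineage(normalize_genome_name(row.user_genome), row.classification)
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# dRep cluster tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterRow:
    genome_name: str
    cluster_label: str
    is_winner: bool


def parse_drep_tables(
    cluster_csv_path: str | Path,
    winner_csv_path: Optional[str | Path] = None,
) -> list[ClusterRow]:
    """Parse dRep's cluster table (and optional winners table).

    Only cluster membership is consumed: the ``genome`` and
    ``secondary_cluster`` columns, plus the winners table's ``genome``
    column; score/ANI columns are ignored.  Genome filenames are normalized
    to bin stems for cross-file joins.
    """
    df = pd.read_csv(cluster_csv_path, dtype=str, keep_default_na=False)
    for col in ("genome", "secondary_cluster"):
        if col not in df.columns:
            raise FormatError(f"{cluster_csv_path}: missing required column {col!r}")
    winners: set[str] = set()
    if winner_csv_path is not None:
        wdf = pd.read_csv(winner_csv_path, dtype=str, keep_default_na=False)
        if "genome" not in wdf.columns:
            raise FormatError(f"{winner_csv_path}: missing required column 'genome'")
        winners = {normalize_genome_name(g) for g in wdf["genome"]}
    rows = [
        ClusterRow(
            genome_name=normalize_genome_name(r.genome),
            cluster_label=r.secondary_cluster,
            is_winner=normalize_genome_name(r.genome) in winners,
        )
        for r in df.itertuples(index=False)
    ]
    for row in rows:
        if not row.cluster_label:
            raise FormatError(f"{cluster_csv_path}: empty cluster label for {row.genome_name}")
    known = {r.genome_name for r in rows}
    missing = winners - known
    if missing:
        raise CrossFileInconsistencyError(
            f"winner genomes absent from cluster table: {sorted(missing)}"
        )
    return rows


# ---------------------------------------------------------------------------
# CheckM2 quality report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QualityRow:
    genome_name: str
    completeness_pct: float
    contamination_pct: float


class QualityRangeError(MagdbError):
    pass


def parse_checkm2_report(path: str | Path) -> list[QualityRow]:
    """Parse a CheckM2 ``quality_report.tsv`` (Name/Completeness/Contamination)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("Name", "Completeness", "Contamination"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    rows = []
    for r in df.itertuples(index=False):
        try:
            comp, cont = float(r.Completeness), float(r.Contamination)
        except ValueError:
            raise FormatError(
                f"{path}: non-numeric quality values for {r.Name!r}"
            ) from None
        if not 0.0 <= comp <= 100.0:
            raise QualityRangeError(f"{path}: completeness {comp} outside [0, 100] for {r.Name!r}")
        if cont < 0.0:
            raise QualityRangeError(f"{path}: negative contamination for {r.Name!r}")
        rows.append(QualityRow(normalize_genome_name(r.Name), comp, cont))
    return rows
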