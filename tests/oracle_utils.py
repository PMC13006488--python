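"""Independent flat-file oracle for the enzyme-discovery queries.

Recomputes the two named queries directly from a generated project's files
with plain string handling — no database, none of the package's parsers —
so agreement with the SQL route is a genuine two-route check.
"""

from __future__ import annotations

import re
from collections import defaultdict
from pathlib import Path

_UNIT = re.compile(r"^([A-Za-z]+\d+)(?:_([\w.]+))?(?:\((\d+)-(\d+)\))?$")
_CLASSES = ("GH", "GT", "PL", "CE", "AA", "CBM")


def protein_to_genome(project_dir: Path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for faa in sorted((project_dir / "proteins").glob("*.faa")):
        genome = faa.name.rsplit(".", 1)[0]
        for line in faa.read_text().splitlines():
            if line.startswith(">"):
                mapping[line[1:].split()[0]] = genome
    return mapping


def novel_genomes(project_dir: Path) -> set[str]:
    """Genomes whose GTDB-Tk species slot is empty."""
    novel: set[str] = set()
    lines = (project_dir / "gtdbtk" / "gtdbtk.bac120.summary.tsv").read_text().splitlines()
    header = lines[0].split("\t")
    gi, ci = header.index("user_genome"), header.index("classification")
    for line in lines[1:]:
        cols = line.split("\t")
        genome, classification = cols[gi], cols[ci]
        fields = classification.split(";")
        species = ""
        for f in fields:
            if f.strip().startswith("s__"):
                species = f.strip()[3:].strip()
        if not species:
            novel.add(genome)
    return novel


def dbcan_calls(project_dir: Path) -> dict[str, set[str]]:
    """protein -> set of family/subfamily accessions from the dbCAN overview."""
    calls: dict[str, set[str]] = defaultdict(set)
    lines = (project_dir / "annotations" / "dbcan_overview.tsv").read_text().splitlines()
    header = lines[0].split("\t")
    pi = header.index("Gene ID")
    hi = header.index("Recommend Results") if "Recommend Results" in header \
        else header.index("HMMER")
    for line in lines[1:]:
        cols = line.split("\t")
        protein, value = cols[pi], cols[hi].strip()
        if value in ("", "-"):
            continue
        for unit in value.split("+"):
            m = _UNIT.match(unit.strip())
            if m is None or not any(m.group(1).startswith(c) for c in _CLASSES):
                continue
            calls[protein].add(m.group(1))
            if m.group(2):
                calls[protein].add(f"{m.group(1)}_{m.group(2)}")
    return dict(calls)


def oracle_cazymes_novel_taxa(project_dir: Path, project_name: str
                              ) -> set[tuple[str, str, str, str]]:
    """(project, genome, protein, accession) hits recomputed from files."""
    owner = protein_to_genome(project_dir)
    novel = novel_genomes(project_dir)
    hits = set()
    for protein, accessions in dbcan_calls(project_dir).items():
        genome = owner.get(protein)
        if genome is None or genome not in novel:
            continue
        for acc in accessions:
            hits.add((project_name, genome, protein, acc))
    return hits


def oracle_family_counts(project_dir: Path, project_name: str,
                         family: str, novel_only: bool
                         ) -> dict[tuple[str, str], int]:
    """(project, genome) -> distinct proteins carrying exactly `family`."""
    owner = protein_to_genome(project_dir)
    novel = novel_genomes(project_dir)
    per_genome: dict[tuple[str, str], set[str]] = defaultdict(set)
    for protein, accessions in dbcan_calls(project_dir).items():
        genome = owner.get(protein)
        if genome is None:
            continue
        if novel_only and genome not in novel:
            continue
        if family in accessions:
            per_genome[(project_name, genome)].add(protein)
    return {k: len(v) for k, v in per_genome.items()}
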