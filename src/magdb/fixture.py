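"""Seeded synthetic MAG-project generator and its ground-truth manifest.

Emulates the directory tree a prokaryotic MAG workflow leaves behind —
genome bin FASTAs, Prokka-style GFF3 and protein FASTAs, a GTDB-Tk
classification summary, dRep cluster/winner tables, a CheckM2 quality
report and dbCAN/InterProScan/CLEAN/ProteInfer annotation outputs — plus a
TOML configuration ready for ingestion and a JSON manifest recording every
count the populated database must reproduce.  The manifest is the test
oracle: after ingesting a fixture, each of the 28 tables must hold exactly
the row count the generator promised.

Sequences are uniform random nucleotides/amino acids; genes are laid out as
sequential non-overlapping windows with a fixed inter-gene gap so the
coordinate invariants hold by construction.  Each file type draws from its
own random stream derived from the master seed, so adding a file type never
perturbs the others' content.
"""

from __future__ import annotations

import json
import math
import random
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict

from .plugins import BUILTIN_PLUGINS

_NUCLEOTIDES = "ACGT"
_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_PHYLA = ("Bacillota", "Pseudomonadota")
_CAZY_POOL = ("GH5", "GH13", "GH43", "GT2", "CE1", "PL9", "AA3")

#: stage -> (tool name, version) recorded in the generated configuration
_FIXTURE_TOOLS = {
    "bins": ("metabat2", "2.15"),
    "gff": ("prokka", "1.14.6"),
    "proteins": ("prokka", "1.14.6"),
    "gtdbtk": ("gtdbtk", "2.3.2"),
    "drep": ("drep", "3.4.3"),
    "checkm2": ("checkm2", "1.0.2"),
    "dbcan": ("run_dbcan", "4.0.0"),
    "interpro": ("interproscan", "5.63"),
    "clean": ("clean", "1.0.1"),
    "proteinfer": ("proteinfer", "1.0.0"),
}


class FixtureManifest(BaseModel):
    """Ground-truth counts for a generated project."""

    model_config = ConfigDict(extra="forbid")

    seed: int
    n_genomes: int
    n_contigs: int
    n_genes: int
    n_proteins: int
    n_clusters: int
    n_novel_genomes: int
    novel_genomes: list[str]
    annotation_counts: dict[str, int]
    #: genome -> accession -> distinct annotated proteins
    family_counts: dict[str, dict[str, int]]
    expected_table_rows: dict[str, int]


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def _wrap(seq: str, width: int = 80) -> str:
    return "\n".join(seq[i:i + width] for i in range(0, len(seq), width))


def generate_project_fixture(
    out_dir: str | Path,
    seed: int = 42,
    n_genomes: int = 5,
    contigs_per_genome: int = 4,
    genes_per_contig: int = 6,
    novel_fraction: float = 0.4,
    cazyme_density: float = 0.2,
    project_name: Optional[str] = None,
) -> FixtureManifest:
    """Write a complete synthetic project under ``out_dir``.

    Deterministic for a given seed (byte-identical trees; the configuration
    uses paths relative to itself).  ``novel_fraction`` controls the share
    of genomes left species-unassigned in the GTDB-Tk summary;
    ``cazyme_density`` the share of proteins given dbCAN families.
    """
    if n_genomes < 1 or contigs_per_genome < 1 or genes_per_contig < 1:
        raise ValueError("n_genomes, contigs_per_genome, genes_per_contig must be positive")
    if not (0.0 <= novel_fraction <= 1.0 and 0.0 <= cazyme_density <= 1.0):
        raise ValueError("novel_fraction and cazyme_density must lie in [0, 1]")
    out = Path(out_dir)
    for sub in ("bins", "gff", "proteins", "gtdbtk", "drep", "checkm2", "annotations"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    def stream(name: str) -> random.Random:
        return random.Random(f"{seed}:{name}")

    rng_seq = stream("sequences")
    rng_genes = stream("genes")
    rng_prot = stream("proteins")
    rng_tax = stream("taxonomy")
    rng_quality = stream("quality")
    rng_dbcan = stream("dbcan")
    rng_ipr = stream("interpro")
    rng_clean = stream("clean")
    rng_pi = stream("proteinfer")

    genomes = [f"bin{i}" for i in range(1, n_genomes + 1)]
    n_clusters = math.ceil(n_genomes / 2)
    group = {g: (i % n_clusters) for i, g in enumerate(genomes)}

    # ---- bins / GFF / proteins --------------------------------------------
    gene_lengths: dict[str, int] = {}          # gene id -> nt length
    protein_of_genome: dict[str, list[str]] = {g: [] for g in genomes}
    gff_feature_rows = 0
    for g in genomes:
        contig_seqs: list[tuple[str, str]] = []
        gff_lines = ["##gff-version 3"]
        faa_records: list[tuple[str, str]] = []
        for j in range(1, contigs_per_genome + 1):
            contig = f"{g}_c{j}"
            pos = 11
            features: list[str] = []
            for k in range(1, genes_per_contig + 1):
                gid = f"{g}_c{j}_g{k}"
                length = rng_genes.choice(range(90, 303, 3))
                start, end = pos, pos + length - 1
                strand = rng_genes.choice("+-")
                features.append(
                    f"{contig}\tProdigal\tCDS\t{start}\t{end}\t.\t{strand}\t0\t"
                    f"ID={gid};locus_tag={gid};product=hypothetical protein"
                )
                gene_lengths[gid] = length
                protein_of_genome[g].append(gid)
                aa = "".join(rng_prot.choice(_AMINO_ACIDS) for _ in range(length // 3))
                faa_records.append((gid, aa + "*"))
                pos = end + 1 + 20
            if j == 1:  # one non-CDS feature per genome, kept as file entity only
                trna = f"{g}_trna1"
                features.append(
                    f"{contig}\tAragorn\ttRNA\t{pos}\t{pos + 74}\t.\t+\t.\t"
                    f"ID={trna};product=tRNA-Ala"
                )
                pos = pos + 75 + 20
            contig_len = pos + 9
            contig_seqs.append((
                contig,
                "".join(rng_seq.choice(_NUCLEOTIDES) for _ in range(contig_len)),
            ))
            gff_lines.extend(features)
            gff_feature_rows += len(features)
        with open(out / "bins" / f"{g}.fa", "w") as fh:
            for name, seq in contig_seqs:
                fh.write(f">{name} length={len(seq)}\n{_wrap(seq)}\n")
        if g == genomes[0]:  # exercise the trailing ##FASTA block dialect
            gff_lines.append("##FASTA")
            for name, seq in contig_seqs:
                gff_lines.append(f">{name}")
                gff_lines.append(_wrap(seq))
        with open(out / "gff" / f"{g}.gff", "w") as fh:
            fh.write("\n".join(gff_lines) + "\n")
        with open(out / "proteins" / f"{g}.faa", "w") as fh:
            for name, seq in faa_records:
                fh.write(f">{name} hypothetical protein\n{_wrap(seq)}\n")

    all_proteins = [p for g in genomes for p in protein_of_genome[g]]
    genome_of_protein = {p: g for g in genomes for p in protein_of_genome[g]}
    n_genes = len(all_proteins)

    # ---- taxonomy ----------------------------------------------------------
    n_novel = _round_half_up(novel_fraction * n_genomes)
    novel = sorted(rng_tax.sample(genomes, n_novel))
    taxa_seen: set[tuple[str, str]] = set()
    tax_lines = ["user_genome\tclassification\tclosest_genome_reference"]
    for g in genomes:
        gi = group[g]
        phylum = _PHYLA[gi % 2]
        genus = f"Genus{gi + 1}"
        lineage = [
            ("domain", "Bacteria"),
            ("phylum", phylum),
            ("class", f"{phylum}_class"),
            ("order", f"{phylum}_order"),
            ("family", f"{phylum}_fam"),
            ("genus", genus),
        ]
        species = "" if g in novel else f"{genus} sp{g.removeprefix('bin')}"
        if species:
            lineage.append(("species", species))
        taxa_seen.update(lineage)
        prefix_names = dict(lineage)
        classification = ";".join(
            f"{p}{prefix_names.get(r, '')}"
            for p, r in zip(("d__", "p__", "c__", "o__", "f__", "g__", "s__"),
                            ("domain", "phylum", "class", "order", "family",
                             "genus", "species"))
        )
        tax_lines.append(f"{g}\t{classification}\t-")
    (out / "gtdbtk" / "gtdbtk.bac120.summary.tsv").write_text("\n".join(tax_lines) + "\n")

    # ---- dRep cluster / winner tables -------------------------------------
    cdb_lines = ["genome,secondary_cluster"]
    winners: list[str] = []
    first_of_group: set[int] = set()
    for g in genomes:
        label = f"{group[g] + 1}_1"
        cdb_lines.append(f"{g}.fa,{label}")
        if group[g] not in first_of_group:
            first_of_group.add(group[g])
            winners.append(g)
    (out / "drep" / "Cdb.csv").write_text("\n".join(cdb_lines) + "\n")
    (out / "drep" / "Wdb.csv").write_text(
        "genome,score\n" + "\n".join(f"{g}.fa,{100 - i}" for i, g in enumerate(winners)) + "\n"
    )

    # ---- CheckM2 quality report -------------------------------------------
    q_lines = ["Name\tCompleteness\tContamination"]
    for g in genomes:
        comp = round(rng_quality.uniform(80.0, 100.0), 2)
        cont = round(rng_quality.uniform(0.0, 5.0), 2)
        q_lines.append(f"{g}\t{comp}\t{cont}")
    (out / "checkm2" / "quality_report.tsv").write_text("\n".join(q_lines) + "\n")

    # ---- dbCAN overview ----------------------------------------------------
    n_cazy = _round_half_up(cazyme_density * n_genes)
    cazy_proteins = sorted(rng_dbcan.sample(all_proteins, n_cazy))
    family_counts: dict[str, dict[str, int]] = {g: {} for g in genomes}
    dbcan_lines = ["Gene ID\tEC#\tHMMER\tdbCAN_sub\tDIAMOND\t#ofTools"]
    n_dbcan_annotations = 0
    for idx, p in enumerate(cazy_proteins):
        def coords() -> tuple[int, int]:
            s = rng_dbcan.randint(1, 30)
            return s, s + rng_dbcan.randint(50, 200)

        roll = rng_dbcan.random()
        accessions: list[str] = []
        if idx == 0 or roll < 0.55:         # single family (GH5 guaranteed once)
            fam = "GH5" if idx == 0 else rng_dbcan.choice(_CAZY_POOL)
            s, e = coords()
            unit = f"{fam}({s}-{e})"
            accessions = [fam]
        elif roll < 0.75:                   # family with subfamily
            sub = rng_dbcan.randint(1, 30)
            s, e = coords()
            unit = f"GH5_{sub}({s}-{e})"
            accessions = ["GH5", f"GH5_{sub}"]
        else:                               # two families on one protein
            fam2 = rng_dbcan.choice(("GH5", "GH13", "CE1"))
            s1, e1 = coords()
            s2, e2 = coords()
            unit = f"CBM3({s1}-{e1})+{fam2}({s2}-{e2})"
            accessions = ["CBM3", fam2]
        n_tools = rng_dbcan.randint(1, 3)
        dbcan_lines.append(f"{p}\t-\t{unit}\t-\t-\t{n_tools}")
        n_dbcan_annotations += len(accessions)
        g = genome_of_protein[p]
        for acc in accessions:
            family_counts[g][acc] = family_counts[g].get(acc, 0) + 1
    (out / "annotations" / "dbcan_overview.tsv").write_text("\n".join(dbcan_lines) + "\n")

    # ---- InterProScan ------------------------------------------------------
    n_ipr_lines = max(1, _round_half_up(0.1 * n_genes))
    ipr_proteins = sorted(rng_ipr.sample(all_proteins, n_ipr_lines))
    ipr_lines = []
    n_ipr_annotations = 0
    for p in ipr_proteins:
        plen = gene_lengths[p] // 3
        md5 = "".join(rng_ipr.choice("0123456789abcdef") for _ in range(32))
        sig = f"PF{rng_ipr.randint(0, 99999):05d}"
        s = rng_ipr.randint(1, max(1, plen // 2))
        e = rng_ipr.randint(s, plen)
        evalue = f"{rng_ipr.uniform(1, 9):.1f}e-{rng_ipr.randint(5, 80)}"
        cols = [p, md5, str(plen), "Pfam", sig, "Domain of unknown function",
                str(s), str(e), evalue, "T", "01-01-2026"]
        n_ipr_annotations += 1
        if rng_ipr.random() < 0.6:
            cols.append(f"IPR{rng_ipr.randint(0, 999999):06d}")
            cols.append("InterPro domain")
            n_ipr_annotations += 1
        else:
            cols.extend(["-", "-"])
        if rng_ipr.random() < 0.4:
            gos = sorted({f"GO:{rng_ipr.randint(0, 9999999):07d}"
                          for _ in range(rng_ipr.randint(1, 2))})
            cols.append("|".join(gos))
            n_ipr_annotations += len(gos)
        else:
            cols.append("-")
        cols.append("-")
        ipr_lines.append("\t".join(cols))
    (out / "annotations" / "interproscan.tsv").write_text("\n".join(ipr_lines) + "\n")

    # ---- CLEAN -------------------------------------------------------------
    n_clean_lines = max(1, _round_half_up(0.1 * n_genes))
    clean_proteins = sorted(rng_clean.sample(all_proteins, n_clean_lines))
    clean_lines = []
    n_clean_annotations = 0
    for p in clean_proteins:
        n_terms = rng_clean.randint(1, 2)
        ecs = sorted({
            f"{rng_clean.randint(1, 6)}.{rng_clean.randint(1, 20)}."
            f"{rng_clean.randint(1, 20)}.{rng_clean.randint(1, 99)}"
            for _ in range(n_terms)
        })
        terms = ";".join(f"EC:{ec}/{rng_clean.uniform(0.1, 1.0):.4f}" for ec in ecs)
        clean_lines.append(f"{p},{terms}")
        n_clean_annotations += len(ecs)
    (out / "annotations" / "clean.csv").write_text("\n".join(clean_lines) + "\n")

    # ---- ProteInfer --------------------------------------------------------
    n_pi_lines = max(1, _round_half_up(0.1 * n_genes))
    pi_proteins = sorted(rng_pi.sample(all_proteins, n_pi_lines))
    pi_lines = ["sequence_name\tpredicted_label\tconfidence"]
    for p in pi_proteins:
        if rng_pi.random() < 0.5:
            label = f"GO:{rng_pi.randint(0, 9999999):07d}"
        else:
            label = (f"EC:{rng_pi.randint(1, 6)}.{rng_pi.randint(1, 20)}."
                     f"{rng_pi.randint(1, 20)}.-")
        pi_lines.append(f"{p}\t{label}\t{rng_pi.uniform(0.5, 1.0):.2f}")
    (out / "annotations" / "proteinfer.tsv").write_text("\n".join(pi_lines) + "\n")
    n_pi_annotations = n_pi_lines

    # ---- configuration -----------------------------------------------------
    project = project_name or f"synthetic-project-{seed}"
    config_lines = [
        f'project_name = "{project}"',
        "",
        "[options]",
        "strict = true",
        "batch_size = 1000",
        'database_target = "magdb.sqlite"',
        "",
    ]
    for key, (tname, tversion) in _FIXTURE_TOOLS.items():
        config_lines += [f"[tools.{key}]", f'name = "{tname}"',
                         f'version = "{tversion}"', ""]
    config_lines += [
        "[[assemblies]]",
        'name = "asm1"',
        'bins_dir = "bins"',
        'gff_dir = "gff"',
        'proteins_dir = "proteins"',
        'gtdbtk_summary = "gtdbtk/gtdbtk.bac120.summary.tsv"',
        'drep_cluster_table = "drep/Cdb.csv"',
        'drep_winners_table = "drep/Wdb.csv"',
        'checkm2_report = "checkm2/quality_report.tsv"',
        "",
    ]
    for plugin, fname in (("dbcan", "dbcan_overview.tsv"),
                          ("interpro", "interproscan.tsv"),
                          ("clean", "clean.csv"),
                          ("proteinfer", "proteinfer.tsv")):
        config_lines += ["[[assemblies.annotations]]",
                         f'plugin_name = "{plugin}"',
                         f'path = "annotations/{fname}"', ""]
    (out / "config.toml").write_text("\n".join(config_lines))

    # ---- manifest ----------------------------------------------------------
    tool_rows = {(_FIXTURE_TOOLS[k]) for k in _FIXTURE_TOOLS}
    n_sources = 6 + 4          # six workflow stages + four annotation files
    n_runs = n_sources
    annotation_total = (n_dbcan_annotations + n_ipr_annotations
                        + n_clean_annotations + n_pi_annotations)
    expected = {
        "project": 1, "sample": 1, "assembly": 1,
        "tool": len(tool_rows), "source": n_sources, "run": n_runs,
        "plugin_registration": len(BUILTIN_PLUGINS),
        "fasta_file": 2 * n_genomes,
        "fasta_entry": n_genomes * contigs_per_genome + n_genes,
        "gff_file": n_genomes,
        "gff_entry": gff_feature_rows,
        "dereplication_file": 2,
        "dereplication_entry": n_genomes,
        "taxonomy_file": 1, "taxonomy_entry": n_genomes,
        "quality_file": 1, "quality_entry": n_genomes,
        "protein_annotation_file": 4,
        "protein_annotation_entry": (n_cazy + n_ipr_lines + n_clean_lines
                                     + n_pi_lines),
        "genome": n_genomes,
        "genome_cluster": n_clusters,
        "contig": n_genomes * contigs_per_genome,
        "gene": n_genes,
        "protein": n_genes,
        "taxon": len(taxa_seen),
        "taxonomy_assignment": n_genomes,
        "protein_annotation": annotation_total,
        "genome_quality": n_genomes,
    }
    manifest = FixtureManifest(
        seed=seed,
        n_genomes=n_genomes,
        n_contigs=n_genomes * contigs_per_genome,
        n_genes=n_genes,
        n_proteins=n_genes,
        n_clusters=n_clusters,
        n_novel_genomes=n_novel,
        novel_genomes=novel,
        annotation_counts={
            "dbcan": n_dbcan_annotations,
            "interpro": n_ipr_annotations,
            "clean": n_clean_annotations,
            "proteinfer": n_pi_annotations,
        },
        family_counts={g: dict(sorted(c.items())) for g, c in family_counts.items()},
        expected_table_rows=expected,
    )
    (out / "manifest.json").write_text(
        json.dumps(manifest.model_dump(), indent=2, sort_keys=True) + "\n"
    )
    return manifest


def load_manifest(path: str | Path) -> FixtureManifest:
    with open(path) as fh:
        return FixtureManifest.model_validate(json.load(fh))
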