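# magdb

A local relational database for the outputs of prokaryotic
metagenome-assembled-genome (MAG) workflows.

A typical MAG pipeline — assembly, binning, dereplication, gene calling,
taxonomy, quality estimation, functional annotation — leaves its results
scattered across dozens of flat files in half a dozen formats.  Questions
that span those files ("which carbohydrate-active enzymes live in the MAGs
GTDB-Tk could not place at species level?") are painful to answer with
`grep` and joins-by-hand.  magdb parses the standard outputs (bin FASTAs,
Prokka-style GFF3 and protein FASTAs, dRep cluster tables, GTDB-Tk
classification summaries, CheckM2 quality reports, dbCAN / InterProScan /
CLEAN / ProteInfer annotation tables) into a normalized 28-table embedded
SQLite database, assembles cross-file biological entities — genome, contig,
gene, protein, taxon, annotation — via foreign keys, and answers integrated
queries locally and reproducibly.  It is aimed at microbiome researchers
who have already run the upstream tools and want their project queryable on
a laptop.

Core design points:

* **Three entity categories.** Project-management tables record tools,
  sources, runs and timestamps; file-entity tables hold the parsed rows of
  every input file (provenance); biological-entity tables are associative
  rows assembled from file entities in dependency order
  (genomes/contigs → genes → proteins → annotations/clusters/taxonomy/quality).
* **Validated, idempotent ingestion.** Every record passes pydantic
  validation; inserts are memoized, batched and keyed on natural
  uniqueness constraints, so re-running an ingest changes nothing and an
  interrupted ingest leaves a referentially closed database.
* **Plugin architecture for annotations.** Tool-specific parsers for
  protein annotations live behind a plugin contract that emits one unified
  record type; four reference plugins ship built in (`dbcan`, `interpro`,
  `clean`, `proteinfer`) and external `magdb-plugin-*` packages are
  discovered via entry points.
* **Named queries + read-only HTTP API.** The enzyme-discovery queries
  (`cazymes-novel-taxa`, `family-counts`) run in-process, over the CLI, or
  over a WSGI JSON API that accepts only GET.
* **A seeded synthetic-project generator** writes a complete fake workflow
  directory (all formats above, plus the TOML config and a ground-truth
  manifest), so everything is testable without external data.

See `docs/methods.md` for the data model, dialects and design rationale.

## Worked example

Generate a synthetic project (5 genomes × 4 contigs × 6 genes, 40 % of
genomes species-unassigned, 20 % of proteins CAZyme-annotated), ingest it,
and ask which taxonomically novel MAGs carry glycoside hydrolase family 5:

```console
$ magdb fixture generate --out demo --seed 42
wrote demo: 5 genomes, 20 contigs, 120 genes, 2 taxonomic novelties

$ magdb populate --config demo/config.toml
populated demo/magdb.sqlite: 23 files, 10 assembly stages
  genomes_and_contigs: created 25, linked 20
  genes: created 120, linked 120
  proteins: created 120, linked 120
  protein_annotations: created 34, linked 34
  ...
  clusters: created 3, linked 5
  taxonomy: created 20, linked 5
  quality: created 5, linked 5

$ magdb query family-counts --db demo/magdb.sqlite \
      --param family=GH5 --param novel_only=true
project_name	genome_name	family_accession	protein_count
synthetic-project-42	bin5	GH5	2
```

Reading the output: ingestion created 25 biological rows in the first stage
(5 genomes + 20 contigs), promoted all 120 CDS features to genes with their
120 proteins, linked the four annotation sources, and wired 3 dereplication
clusters, 20 taxon rows and 5 taxonomy assignments.  The query reports that
among the 2 species-unassigned MAGs, `bin5` encodes 2 distinct proteins
annotated as GH5 — the kind of shortlist used to prioritize MAGs for
biomass-degradation follow-up.  The broader sweep
`magdb query cazymes-novel-taxa --db demo/magdb.sqlite` lists every
(genome, protein, family) hit in novel MAGs, one row per family per
protein.

The same answers are served over HTTP:

```sh
magdb serve --db demo/magdb.sqlite --port 8000
curl 'http://127.0.0.1:8000/queries/family-counts?family=GH5&novel_only=true'
```

All commands and subcommands accept `--help`.  For real projects, start
from `magdb setup` to scaffold the TOML configuration, then
`magdb populate --config <file>`.

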