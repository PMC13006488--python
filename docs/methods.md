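# Methods

## The data-integration model

A prokaryotic MAG (metagenome-assembled genome) workflow scatters its
results across many loosely coupled files: binned contigs as FASTA, gene
calls as GFF3, translated proteins as FASTA, dereplication clusters as dRep
CSV tables, taxonomy as a GTDB-Tk summary TSV, genome quality as a CheckM2
TSV, and protein function as tool-specific annotation tables.  magdb
normalizes all of this into a single embedded relational database of 28
tables in three categories:

* **project-management entities** (7): `project`, `sample`, `assembly`,
  `run`, `tool`, `source`, `plugin_registration` — who ran what, when,
  with which tool and version.
* **file entities** (12): near-verbatim parsed rows per input file
  (`fasta_file`/`fasta_entry`, `gff_file`/`gff_entry`, and the analogous
  pairs for dereplication, taxonomy, quality and protein-annotation files).
  These preserve provenance: every biological row can be traced to the file
  line it came from.
* **biological entities** (9): `genome`, `genome_cluster`, `contig`,
  `gene`, `protein`, `taxon`, `taxonomy_assignment`, `protein_annotation`,
  `genome_quality` — cross-file abstractions assembled by resolving
  identifiers (filename stems, FASTA record ids, GFF `seqid`/`ID`
  attributes) into foreign keys.

The design follows third normal form: every fact is stored once (taxonomy
names only in `taxon`, sequences only in `fasta_entry`) and biological
entities are associative rows of foreign keys plus their own attributes.
Surrogate integer keys are used throughout, with natural-key uniqueness
constraints (e.g. `genome` unique on (assembly, name), `protein_annotation`
unique on (protein, tool, type, accession, coordinates)) guarding against
redundancy.

### Backend

The store is SQLite: a project database is a single local file, tests run
against `:memory:`, and no server is needed.  The DDL sticks to portable
constructs (integer PKs, FKs, UNIQUE, CHECK) so the same schema can be
hosted on a client-server RDBMS.  The schema version is recorded in
SQLite's `user_version` header field rather than a metadata table, keeping
the catalog at exactly the 28 domain tables; opening a database with a
different version aborts (no migrations are attempted).

### Insertion discipline

All writes go through `insert_if_absent`: records are pydantic-validated,
looked up by natural key (memoized in an in-process cache), and inserted in
one transaction per batch (default 1000 rows, configurable).  This makes
every stage — and the whole `populate` — idempotent: re-running on the same
inputs changes no row counts.  A batch failure rolls back the current
transaction and evicts its cache entries; previously committed batches are
internally consistent (their foreign keys all resolve), so a crashed ingest
leaves a referentially closed database that a re-run simply completes.
`integrity_check` audits this property by scanning every declared FK
relationship for orphans and every stored-row invariant (coordinate bounds,
quality ranges, taxon parent-rank chaining).

## Coordinates and identifier conventions

* Gene coordinates are stored exactly as GFF3 gives them: 1-based,
  inclusive, on the contig's forward axis regardless of strand, and are
  validated against `1 <= start <= end <= contig.length_bp`.
* Genome names are normalized bin-file stems: one recognized FASTA
  extension (`.fa/.fasta/.fna/.faa`, case-insensitive) is stripped; all
  cross-file joins (dRep, GTDB-Tk, CheckM2) use the stem.
* Gene identifiers come from the GFF `ID` attribute, falling back to
  `locus_tag`; protein FASTA record ids must match gene identifiers within
  the same genome.  Only CDS features are promoted to genes; tRNA/rRNA
  features remain queryable file entities.
* Protein lengths exclude a trailing `*` stop.
* Strict mode (default) fails an assembly stage on any unresolved
  cross-file reference, after a resolution-only first pass so nothing is
  half-written; lenient mode records unmatched keys in the stage report.
* A configured file whose SHA-256 digest changed under the same path since
  the previous ingest is treated as a different file version and aborts in
  strict mode.

## Annotation plugins

Tool-specific parsing is isolated behind a plugin contract: a parser
(`path -> list[UnifiedAnnotation]`) plus a descriptor.  `UnifiedAnnotation`
is the tool-agnostic record (protein key, source tool, one of six
annotation types, accession, optional description/score/coordinates).
Plugins populate existing tables only; they cannot touch the schema.

Four reference plugins ship built in.  Their dialects:

* **dbcan** — overview TSV with `Gene ID` and `#ofTools` columns; the
  consensus column (`Recommend Results` when present, else `HMMER`) is
  authoritative and is split on `+` into units `FAM` or
  `FAM_SUB(start-end)`.  Each unit emits a `family` annotation (plus a
  `subfamily` annotation for `_SUB` forms) with the tool-agreement count as
  score.  Units whose class prefix is not one of GH/GT/PL/CE/AA/CBM skip
  the row with a logged warning.  Per-tool prediction columns are kept
  verbatim in the file-entity row but deliberately not expanded, to avoid
  double-counting families in queries.
* **interpro** — standard headerless InterProScan TSV (>= 11 columns): one
  `domain` per member-database signature (source `interproscan:<analysis>`,
  e-value as score, start/stop), one `domain` for the InterPro entry when
  present, one `go_term` per `|`-separated GO id.
* **clean** — CSV lines `protein,EC:a.b.c.d/score;...`; one `ec_number`
  per term.  CLEAN's published outputs vary by version, so this dialect is
  fixed here and used by the fixture generator.
* **proteinfer** — TSV with `sequence_name`/`predicted_label`/`confidence`;
  `GO:` labels map to `go_term`, `EC:` to `ec_number`, anything else to
  `description`.  Fixed dialect, same reasoning as CLEAN.

External plugins are discovered from installed `magdb-plugin-<name>`
distributions exposing a `magdb.plugins` entry point; no network
installation is in scope.  Enable/disable state lives in the configuration
(`options.disabled_plugins`) and is mirrored into `plugin_registration`.

## Taxonomic novelty

GTDB-Tk lineage strings are split into the seven canonical rank slots;
an empty suffix after a rank prefix, a truncated string, or the literal
`Unclassified` mean "unassigned" from that point on.  A genome is a
*taxonomic novelty* when its species slot is unassigned.  Because that
operationalization is a choice, the queries expose a `novelty_rank`
threshold: novelty at rank *r* means the classification stops above *r*
(so `genus` is stricter than the default `species`).  Taxon rows are
deduplicated on (rank, name) and parent-chained along the contiguous prefix
of assigned ranks.

## Queries and the API

A CAZyme hit is a distinct (genome, protein, accession) triple over
`family`/`subfamily` annotations from the dbcan source; a protein
annotated `GH5_2(31-330)` therefore contributes hits for both `GH5` and
`GH5_2`, and a `CBM3+GH5` protein one hit per family.  Family counts are
distinct proteins, not annotation rows.  Annotations from other sources
(InterProScan domains etc.) are excluded from these two queries by design.

The HTTP API is a WSGI application over the same SQL, serving entities and
the named queries as JSON with limit/offset pagination.  It is read-only:
only GET is accepted and handlers execute SELECT statements exclusively.
The in-process registry (`run_named_query`) serializes results as rows,
JSON, or TSV.

## The synthetic fixture

`generate_project_fixture` writes a complete project tree plus manifest.
Defaults are 5 genomes x 4 contigs x 6 genes, novel fraction 0.4, CAZyme
density 0.2 — a desk-scale project with every file type, several genomes
per taxon/cluster, and both novel and classified genomes, small enough
that the whole suite ingests it in seconds.  Within it:

* genes are sequential non-overlapping windows (length 90–300 nt in codon
  multiples, 20 nt gaps) so coordinate invariants hold by construction;
  protein sequences have `floor(gene_length / 3)` residues plus a `*` stop;
* one tRNA feature per genome exercises the CDS-only promotion rule, and
  one GFF file carries a trailing `##FASTA` block to exercise truncation;
* `round(novel_fraction x n_genomes)` genomes get an empty `s__` slot;
  genomes sharing a dereplication cluster share their genus and phylum;
* `round(cazyme_density x n_proteins)` proteins get dbCAN units (single
  family, `GH5_<sub>` subfamily, or `CBM3+X` compounds; one GH5 single
  guaranteed); a tenth of proteins get InterProScan, CLEAN and ProteInfer
  lines each;
* each file type draws from its own `random.Random(f"{seed}:{stream}")`
  stream, so trees are byte-identical per seed and a new file type never
  perturbs existing ones.

The manifest records the expected post-ingest row count of all 28 tables,
per-tool annotation counts and per-genome family counts, all derived from
what the generator actually wrote.

**What passing fixture tests does not show:** the sequences are
compositionally random (no codon structure, GC skew or homology), identifiers
are perfectly consistent across files, and files are well-formed.  Real
workflow outputs can disagree across files (renamed bins, filtered
proteins) — that is what strict/lenient matching and the integrity audit
are for — and real annotation tables can use column layouts other than the
dialects fixed above.

## Verification strategy

The enzyme-discovery queries are verified against an independent
brute-force oracle that re-derives protein→genome ownership, novelty and
dbCAN calls from the flat files with plain string handling and no database
(tests/oracle_utils.py, duplicated inline in scripts/acceptance.py); query
and oracle must agree exactly across 20 seeds.  The GFF3 reader is
cross-checked against gffutils on a fixture file.  `scripts/acceptance.py`
re-runs the whole pipeline from scratch and reports the measured numbers;
it computes everything at run time from its own generated inputs.

## Known limitations

* Single-writer, serial ingestion; no parallelism or incremental watch.
* No gzip transparency, FASTQ/SAM/VCF reading, or GFF2/GTF dialects.
* dbCAN substrate/CGC outputs and eggNOG/KOfam parsers are natural future
  plugins, not included.
* No schema migrations: a version mismatch is an error, not an upgrade.
* The CLEAN and ProteInfer dialects are this package's fixed contracts and
  may require adapter plugins for other versions of those tools.
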