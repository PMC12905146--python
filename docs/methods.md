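# Methods

This note documents the modeling and numerical choices behind `seacdm`: what
the engine computes, under which assumptions, and what its synthetic test
data does and does not establish about real studies.

## The data model

The schema fixes 13 classes — 10 core (Study, Experiment, Assay, Subject,
Sample, Group, Intervention, Occurrence, Analysis, Result) and 3 accessory
(Material, Ontology, Documentation) — each tagged with a Basic Formal
Ontology category (process / material entity / data item). The canonical
definition lives in `src/seacdm/data/sea_cdm_schema.yaml` and is the single
source of truth for templates, DDL, validation, the store, and the graph
export.

Design choices where the model itself leaves room:

* **Sample typing.** Biosamples, experimental samples, and control samples
  share one `Sample` table discriminated by a controlled `type` column
  (`biosample` / `expsample` / `control`). This keeps the three source
  tables of relational immune-study dumps losslessly mergeable.
* **Study linkage.** `study_id` is housed on Experiment; Subject carries
  `experiment_id`. Summary queries resolve a sample's study through the
  Subject→Experiment join. Many-to-many subject/experiment membership is
  out of scope.
* **Attribute completions.** Beyond the published representative attribute
  lists and query-visible columns, attribute sets are implementer-defined
  completions and are flagged `provisional: true` in the schema file (e.g.
  `Subject.organism`, `Sample.suspension`, `Result.cell_type`, added so the
  single-cell connector's ten common variables all land on schema columns).
  Group and Analysis carry minimal definitions (id, name, description,
  FKs).
* **Extended attributes.** Unknown input fields are data, not errors: they
  are routed to a long-format `extended_attribute` table keyed by (class,
  record id, name), with an `ontology_id` companion column.
* **DDL idempotence.** Emitted DDL uses `CREATE TABLE IF NOT EXISTS`;
  loading is append-only and rejects duplicate primary keys, so re-running
  a load cannot silently overwrite records. Bundles failing referential
  validation are rejected atomically, before any row is written.
* **Template dialect.** CSV templates are UTF-8, comma-delimited, RFC 4180
  quoted; nulls serialize as empty strings, booleans as `true`/`false`;
  each ontology-paired attribute is immediately followed by its
  `<attr>_ontology_id` column (adjacency chosen for readability — the
  alternative, grouping all id columns at the end, is equivalent up to
  column order). When reading a template directory, files named like a
  class (TitleCase) but unknown to the registry are errors; lowercase-named
  files (expression matrices, truth files) are treated as auxiliary
  artifacts and skipped.

## Ontology handling

Hierarchies are loaded either from a 3-column term table (id, label,
'|'-separated parent ids) or from RDF (any rdflib-parsable format),
restricted to `rdfs:subClassOf` between named classes; no reasoning beyond
the transitive closure is attempted. Hierarchies must be acyclic over
subClassOf (a cycle is an error naming the cycle); multiple parents are
expected (FluMist is both a trivalent and a live attenuated influenza
vaccine). Two closure semantics are exposed: `include_self=False`
(one-or-more hops, SPARQL `subClassOf+`) and `include_self=True`
(zero-or-more hops, Cypher `subClassOf*`); material lookups in the graph
use the starred form. Label lookup is exact and case-insensitive, with
deterministic lowest-id tie-breaking under a warning.

The bundled fixture `mini_vo_synthetic.csv` is a synthetic nine-term
subset: only `VO_0001236` (trivalent influenza vaccine) and `VO_0000047`
(Fluzone) are real Vaccine Ontology CURIEs; all other ids use a reserved
`VO_9xxxxxx` range. On the real Vaccine Ontology the trivalent closure
contains hundreds of terms and is version-dependent, which is why no test
asserts a count on it.

## The stimulated-gene statistic

Inputs: a genes × samples matrix of normalized log2 expression keyed by
sample reference names, per-sample batch flags, and one
(baseline, follow-up) expsample pair per subject selected by metadata
(material, species, optional sex, day vs baseline day). Defaults:
`min_log2_fc = 1.0` (2-fold), `expr_floor_log2 = 0.2` on either day,
`min_subjects = 3`, `exclude_batch = true`. All thresholds are inclusive.

Interpretation choices:

* "Fewer than three samples" is read as *fewer than three passing
  subject-pairs per gene*, counted after the fold-change/floor filter and
  after batch removal; the count is configurable.
* "Same gene profile" across subjects is read as the same pass outcome for
  that gene.
* Batch handling is removal, not correction: a pair is dropped when either
  member carries a batch flag.
* Duplicate samples for one subject-day resolve to the lexicographically
  first reference name, with a warning, for determinism.
* When a query material is an ontology term id and a graph is supplied,
  matching expands to the term's zero-or-more-hop closure, matched against
  both intervention material ontology ids and term labels; this provably
  equals the union of the per-vaccine string queries on the test fixtures.
* Per-gene output is the list of passing per-subject Δlog2 values, their
  count, and their mean (mean over passing pairs only; `null` when none
  pass). Pathway enrichment is deliberately not computed — gene lists
  export as CSV/JSON for external enrichment tools.

Monotonicity (tightening any threshold never adds genes) and agreement with
an exhaustive per-gene/per-pair oracle are enforced by tests.

## ETL connectors

All three connectors are mapping-config-driven (defaults in
`src/seacdm/data/mappings/`), prefix their primary keys (`VIGET:`,
`IMMPORT:`, `CXG:`) so converted sources merge into one store, and conserve
rows: a source row maps to exactly one record in its destination class.

* **Two-file layout** (metadata table + expression matrix): builds the
  full Study→Result chain per metadata row, dedup-ing studies, subjects,
  materials, and interventions; the expression file path is recorded in a
  Documentation row; metadata/matrix sample mismatches warn rather than
  fail.
* **Per-table dump layout**: intervention-like tables concatenate into
  Intervention (each row keeps its `source_table`); sample-like tables
  concatenate into Sample with `type` set per source; each assay-specific
  table becomes one Assay row plus per-record Results. Consequently Assay
  counts are not conserved 1:1 with a per-expsample source representation —
  the merge rule is many-results-per-assay by construction. Key collisions
  across merged tables are errors naming both tables. Column assignments in
  the default config are provisional and flagged as such.
* **Observation-table layout** (flattened CSV, DataFrame, or H5ad `obs`):
  each row yields one Subject, Sample, Assay, Result, and (when a disease
  value is present) one Occurrence. The ten common variables map to fixed
  schema targets with their ontology-id companions; the two metadata
  columns key the generated records; every other column is an author
  variable attached to the Sample record and serialized to the
  extended-attribute table. A missing common variable warns and stays
  null.

## Synthetic data generator

The generator emulates the canonical vaccine immune-response pattern: each
study runs one experiment; subjects receive one vaccine (assigned per study
round-robin over Fluarix/Fluvirin/Fluzone/FluMist) at day 0; each visit day
produces a blood biosample and a derived PBMC expsample assayed by
transcription profiling.

Defaults and why: 4 studies × 10 subjects (one study per vaccine; 10
subjects so the day-7 pairing yields 10 pairs, comfortably above the
3-subject rule), days 0/7/14/28 (the timepoints used in influenza
vaccine-response analyses), 200 genes with 20 planted, planted gain
Δlog2 = 2 (a 4-fold response, twice the detection threshold), noise sd 0.1
log2 units, batch fraction 0.1, all subjects responders (a responder
fraction parameter exists for boundary tests). Baseline expression is
Normal(μ = 5, σ = noise_sd) per gene and sample.

The noise model is independent Gaussian on the log2 scale. Real
transcriptomes are correlated, heteroskedastic, and have mean-variance
structure; passing recovery tests here demonstrates the *filter logic* —
inclusive boundaries, pairing, batch removal, subject counting — not
detection power on real data. Determinism is per-seed: identical configs
produce byte-identical files.

## Verification strategy and problem sizes

Every non-trivial computation is checked against an independent oracle
implemented the slow, obvious way: the vectorized gene filter against pure
per-gene/per-pair loops (200 random 100 × 12 matrices), SQL summary joins
against in-memory join+distinct over record lists, graph material lookups
against ontology-closure + list-filter (100 random bundle/ontology pairs),
descendant closure against breadth-first search (DAGs up to 500 nodes), and
all serializations by round trip (write→read, load→dump, export→re-parse),
with equality taken modulo the documented normalizations (column order,
empty-vs-absent fields, value stringification). These sizes keep the full
suite under ten seconds while covering every code path; the engines
themselves have no size-dependent branches, so scaling them up changes
runtime, not behavior.

## Known limitations

* No OWL reasoning, equivalent-class handling, or live ontology endpoints.
* No batch-effect *correction*; flagged samples are removed.
* Material matching in SQL summaries is exact and case-sensitive by design;
  ontology-aware widening lives in the query engine.
* Subject↔Experiment and Subject↔Group are modeled 1:N, not M:N.
* The single-cell path consumes observation metadata only, not count
  matrices.
* Figures for the published external resources (study and sample counts of
  registration-gated or versioned repositories) are documented but not
  recomputed here, since reproducing them requires downloading those
  resources: the two-file-layout source reports 28 studies with 4,859
  experimental samples, a Fluarix day-7 stimulated-gene count of 35 in
  prose against 36 in the corresponding table (the discrepancy is in the
  source itself), a four-vaccine union of 590 genes, 228 of 1,263
  influenza-related studies in the immune-study repository, and 111 author
  variables across five single-cell datasets. Likewise the prose/table
  swap of biosample vs expsample counts in that source is resolved here by
  following the summary query's column order (biosamples, studies,
  expsamples).
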