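# Default mapping for per-table relational dumps.
#
# PROVISIONAL: the column-to-attribute assignments below are defaults for the
# synthetic fixture layout; real dumps carry many more tables and columns, and
# their assignments should be reviewed before use.  Unmapped columns are
# routed to the extended-attribute side table, never dropped.
source: immport
id_prefix: "IMMPORT:"
options:
  # three intervention-like source tables merged into one Intervention table,
  # with the originating table recorded per row
  intervention_tables: [intervention, immune_exposure, treatment]
  # sample-like source tables merged into Sample; value = the `type` flag
  sample_tables:
    biosample: biosample
    control_sample: control
    expsample: expsample
  # any table named assay_<something>.csv becomes one Assay row plus one
  # Result row per record
  assay_table_prefix: "assay_"
  assay_types:
    assay_gene_expression: transcription profiling assay
  # tables that map one-to-one onto model classes
  passthrough_tables:
    study: Study
    experiment: Experiment
    subject: Subject
    group: Group
    material: Material
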