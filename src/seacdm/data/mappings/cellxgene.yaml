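# Default mapping for flattened single-cell observation tables (or the obs
# frame of an H5ad file).  The 10 common variables map to fixed targets; the
# 2 metadata columns key the generated records; every other column is an
# author variable routed to the extended-attribute side table.
source: cellxgene
id_prefix: "CXG:"
common_variables:
  organism: [Subject, organism]
  species: [Subject, species]
  developmental_stage: [Subject, developmental_stage]
  sex: [Subject, sex]
  disease: [Occurrence, disease]
  tissue: [Sample, biosample_source]
  tissue_type: [Sample, tissue_type]
  suspension: [Sample, suspension]
  assay: [Assay, assay_type]
  cell_type: [Result, cell_type]
metadata: [sample_id, observation_join_id]
ontology_suffix: "_ontology_id"
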