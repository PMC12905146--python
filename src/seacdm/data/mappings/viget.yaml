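# Default mapping for the two-file study layout (study/sample metadata table
# + normalized log2 expression matrix).  `roles` maps semantic roles the
# connector needs onto metadata column names; adjust to match your export.
source: viget
id_prefix: "VIGET:"
roles:
  study_id: study_id
  study_name: study_name
  subject_id: subject_id
  species: species
  sex: sex
  age: age
  material: vaccine
  material_ontology_id: vaccine_vo_id
  day: day
  expsample_reference_name: expsample_reference_name
  biosample_reference_name: biosample_reference_name
  batch: batch
constants:
  Assay:
    assay_type: transcription profiling assay
  Result:
    datatype: normalized log2 expression
    filetype: csv
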