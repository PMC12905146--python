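"""ETL connectors: convert three heterogeneous source layouts into bundles.

Three connectors are provided, each driven by a :class:`MappingConfig` whose
defaults ship with the package (``data/mappings/*.yaml``):

* :func:`viget_to_bundle` — a study/sample metadata table plus a normalized
  log2 expression matrix (the two-file layout used by vaccine
  gene-expression portals);
* :func:`immport_to_bundle` — a directory of per-table relational CSV dumps,
  consolidating intervention-like tables into Intervention, sample-like
  tables into Sample (with a ``type`` flag), and assay-specific tables into
  one Assay row plus per-record Results;
* :func:`cellxgene_to_bundle` — a flattened single-cell observation table or
  an H5ad file, mapping the 10 common variables to fixed targets and routing
  author variables to extended attributes.

Connectors prefix primary keys (``VIGET:``, ``IMMPORT:``, ``CXG:``) so
bundles from different sources merge into one store without collisions, and
they conserve rows: every source row maps to exactly one record in its
destination class.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .bundle import RecordBundle
from .expression import ExpressionMatrix
from .schema import SchemaRegistry, build_default_registry

__all__ = [
    "MappingConfig",
    "load_mapping",
    "viget_to_bundle",
    "immport_to_bundle",
    "cellxgene_to_bundle",
]


@dataclass
class MappingConfig:
    """Declarative source-to-model mapping.

    ``roles`` (two-file layout) maps semantic roles to source columns;
    ``common_variables`` (observation-table layout) maps the shared variable
    names to (class, attribute) targets; ``options`` carries per-source
    settings such as table groupings.  Unmapped source fields are never
    dropped — they travel as extended attributes.
    """

    source: str
    id_prefix: str = ""
    roles: dict[str, str] = field(default_factory=dict)
    constants: dict[str, dict[str, str]] = field(default_factory=dict)
    options: dict[str, Any] = field(default_factory=dict)
    common_variables: dict[str, tuple[str, str]] = field(default_factory=dict)
    metadata: list[str] = field(default_factory=list)
    ontology_suffix: str = "_ontology_id"

    def validate(self, registry: SchemaRegistry) -> None:
        for var, (class_name, attr) in self.common_variables.items():
            if class_name not in registry:
                raise ValueError(f"mapping {var!r}: unknown class {class_name!r}")
            if registry[class_name].attribute(attr) is None:
                raise ValueError(f"mapping {var!r}: unknown attribute {class_name}.{attr}")
        for class_name in self.constants:
            if class_name not in registry:
                raise ValueError(f"constants: unknown class {class_name!r}")

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "MappingConfig":
        return cls(
            source=raw.get("source", "unknown"),
            id_prefix=raw.get("id_prefix", ""),
            roles=dict(raw.get("roles", {})),
            constants={k: dict(v) for k, v in raw.get("constants", {}).items()},
            options=dict(raw.get("options", {})),
            common_variables={
                k: (v[0], v[1]) for k, v in raw.get("common_variables", {}).items()
            },
            metadata=list(raw.get("metadata", [])),
            ontology_suffix=raw.get("ontology_suffix", "_ontology_id"),
        )


def load_mapping(source: str | Path) -> MappingConfig:
    """Load a mapping config: a built-in name (viget / immport / cellxgene)
    or a path to a YAML file."""
    if isinstance(source, str) and source in ("viget", "immport", "cellxgene"):
        text = resources.files("seacdm.data.mappings").joinpath(f"{source}.yaml").read_text()
    else:
        text = Path(source).read_text()
    return MappingConfig.from_dict(yaml.safe_load(text))


def _truthy(value: Any) -> bool:
    return str(value).strip().lower() in ("1", "true", "yes", "y")


# --- two-file study layout ------------------------------------------------


def viget_to_bundle(
    metadata_path: str | Path,
    expression_path: str | Path,
    config: MappingConfig | None = None,
    registry: SchemaRegistry | None = None,
) -> tuple[RecordBundle, ExpressionMatrix]:
    """Convert the two-file layout: one metadata row per experimental sample,
    plus a genes × samples normalized log2 expression matrix.

    Builds Study / Experiment / Subject / Intervention / Material / Sample /
    Assay / Result records, records the expression file path in a
    Documentation row, and indexes the matrix by the expsample reference
    names.  Samples present in only one of the two files produce warnings,
    not failures.
    """
    config = config or load_mapping("viget")
    registry = registry or build_default_registry()
    P = config.id_prefix
    role = config.roles.get

    bundle = RecordBundle()
    src = str(metadata_path)
    with Path(metadata_path).open(newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        warnings.warn(f"{src}: metadata file has no rows; empty bundle", stacklevel=2)

    seen: dict[str, set[str]] = {k: set() for k in ("study", "subject", "material", "intervention", "bio")}
    batch_flags: dict[str, bool] = {}
    n_int = 0
    for i, row in enumerate(rows):
        study = row.get(role("study_id", "study_id"), "") or f"study_{i}"
        subject = row.get(role("subject_id", "subject_id"), "") or f"subject_{i}"
        material = row.get(role("material", "material"), "")
        material_oid = row.get(role("material_ontology_id", "material_ontology_id"), "")
        day = row.get(role("day", "day"), "")
        exp_ref = row.get(role("expsample_reference_name", "expsample_reference_name"), "")
        bio_ref = row.get(role("biosample_reference_name", "biosample_reference_name"), "")
        batch = _truthy(row.get(role("batch", "batch"), ""))

        if study not in seen["study"]:
            seen["study"].add(study)
            bundle.add("Study", {
                "study_id": f"{P}{study}",
                "name": row.get(role("study_name", "study_name"), ""),
                "reference_name": study,
            }, src)
            bundle.add("Experiment", {
                "experiment_id": f"{P}exp_{study}",
                "study_id": f"{P}{study}",
            }, src)
        if material and material not in seen["material"]:
            seen["material"].add(material)
            bundle.add("Material", {
                "material_id": f"{P}mat_{material}",
                "name": material,
                "name_ontology_id": material_oid,
                "material_type": "vaccine",
            }, src)
        if subject not in seen["subject"]:
            seen["subject"].add(subject)
            bundle.add("Subject", {
                "subject_id": f"{P}{subject}",
                "experiment_id": f"{P}exp_{study}",
                "age": row.get(role("age", "age"), ""),
                "sex": row.get(role("sex", "sex"), ""),
                "species": row.get(role("species", "species"), ""),
            }, src)
        int_key = f"{subject}|{material}"
        if material and int_key not in seen["intervention"]:
            seen["intervention"].add(int_key)
            n_int += 1
            bundle.add("Intervention", {
                "intervention_id": f"{P}int_{n_int}",
                "subject_id": f"{P}{subject}",
                "material_id": f"{P}mat_{material}",
                "intervention_type": "vaccination",
                "material": material,
                "material_ontology_id": material_oid,
                "intervention_time": 0,
            }, src)
        if bio_ref and bio_ref not in seen["bio"]:
            seen["bio"].add(bio_ref)
            bundle.add("Sample", {
                "sample_id": f"{P}sam_b_{bio_ref}",
                "subject_id": f"{P}{subject}",
                "type": "biosample",
                "collection": "blood draw",
                "collection_time": day,
                "biosample_source": "blood",
                "biosample_reference_name": bio_ref,
            }, src)
        sample_rec = {
            "sample_id": f"{P}sam_e_{exp_ref or i}",
            "subject_id": f"{P}{subject}",
            "type": "expsample",
            "collection_time": day,
            "expsample_type": "PBMC",
            "expsample_reference_name": exp_ref,
        }
        if batch:
            sample_rec["batch"] = "true"
        if exp_ref:
            batch_flags[exp_ref] = batch
        bundle.add("Sample", sample_rec, src)
        bundle.add("Assay", {
            "assay_id": f"{P}asy_{exp_ref or i}",
            "experiment_id": f"{P}exp_{study}",
            "sample_id": f"{P}sam_e_{exp_ref or i}",
            **config.constants.get("Assay", {}),
        }, src)
        bundle.add("Result", {
            "result_id": f"{P}res_{exp_ref or i}",
            "assay_id": f"{P}asy_{exp_ref or i}",
            "reference_name": exp_ref,
            **config.constants.get("Result", {}),
        }, src)

    bundle.add("Documentation", {
        "documentation_id": f"{P}doc_expression",
        "name": "normalized gene expression data file",
        "path": str(expression_path),
        "doc_type": "expression data file",
        "linked_class": "Study",
    }, src)

    matrix = ExpressionMatrix.from_csv(expression_path, batch_flag=batch_flags)
    meta_refs = {r for r in batch_flags}
    matrix_refs = set(matrix.samples)
    for ref in sorted(meta_refs - matrix_refs):
        warnings.warn(f"metadata sample {ref} absent from expression matrix", stacklevel=2)
    for ref in sorted(matrix_refs - meta_refs):
        warnings.warn(f"expression matrix sample {ref} absent from metadata", stacklevel=2)
    return bundle, matrix


# --- per-table relational dump layout ------------------------------------


def _read_table(path: Path) -> list[dict[str, str]]:
    with path.open(newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def immport_to_bundle(
    table_dir: str | Path,
    config: MappingConfig | None = None,
    registry: SchemaRegistry | None = None,
) -> RecordBundle:
    """Consolidate a directory of per-table CSV dumps.

    Merge rules: the intervention-like tables concatenate into Intervention
    (each row keeps its source table name); the sample-like tables
    concatenate into Sample with ``type`` set per source table; each
    assay-specific table becomes one Assay row plus one Result row per
    record.  Primary-key collisions across merged source tables are errors
    naming the offending tables.
    """
    config = config or load_mapping("immport")
    registry = registry or build_default_registry()
    P = config.id_prefix
    opts = config.options
    src_dir = Path(table_dir)
    bundle = RecordBundle()

    def prefixed(class_name: str, rec: dict[str, str]) -> dict[str, str]:
        cdef = registry[class_name]
        out = {k: v for k, v in rec.items() if v != ""}
        id_cols = {cdef.primary_key} | {fk.column for fk in cdef.foreign_keys}
        for col in id_cols:
            if out.get(col):
                out[col] = f"{P}{out[col]}"
        return out

    for table, class_name in opts.get("passthrough_tables", {}).items():
        path = src_dir / f"{table}.csv"
        if path.exists():
            for rec in _read_table(path):
                bundle.add(class_name, prefixed(class_name, rec), str(path))

    seen_keys: dict[str, str] = {}
    for table in opts.get("intervention_tables", []):
        path = src_dir / f"{table}.csv"
        if not path.exists():
            continue
        for rec in _read_table(path):
            key = rec.get("intervention_id", "")
            if key in seen_keys:
                raise ValueError(
                    f"intervention key {key!r} appears in both "
                    f"{seen_keys[key]!r} and {table!r}"
                )
            seen_keys[key] = table
            out = prefixed("Intervention", rec)
            out["source_table"] = table
            bundle.add("Intervention", out, str(path))

    seen_samples: dict[str, str] = {}
    for table, type_flag in opts.get("sample_tables", {}).items():
        path = src_dir / f"{table}.csv"
        if not path.exists():
            continue
        for rec in _read_table(path):
            key = rec.get("sample_id", "")
            if key in seen_samples:
                raise ValueError(
                    f"sample key {key!r} appears in both {seen_samples[key]!r} and {table!r}"
                )
            seen_samples[key] = table
            out = prefixed("Sample", rec)
            out["type"] = type_flag
            bundle.add("Sample", out, str(path))

    prefix = opts.get("assay_table_prefix", "assay_")
    assay_types = opts.get("assay_types", {})
    for path in sorted(src_dir.glob(f"{prefix}*.csv")):
        table = path.stem
        records = _read_table(path)
        if not records:
            continue
        assay_id = f"{P}assay_{table}"
        bundle.add("Assay", {
            "assay_id": assay_id,
            "assay_type": assay_types.get(table, table.removeprefix(prefix)),
        }, str(path))
        for rec in records:
            out = prefixed("Result", rec)
            out["assay_id"] = assay_id
            bundle.add("Result", out, str(path))
    return bundle


# --- flattened observation-table layout -----------------------------------


def cellxgene_to_bundle(
    source: str | Path | pd.DataFrame,
    config: MappingConfig | None = None,
    registry: SchemaRegistry | None = None,
) -> RecordBundle:
    """Convert a single-cell observation table (flattened CSV, an H5ad file,
    or a DataFrame) into a bundle.

    Each observation row yields one Subject, one Sample, one Assay, one
    Result, and — when a disease value is present — one Occurrence.  The 10
    common variables land on their fixed targets with their companion
    ontology ids in the paired columns; a missing common variable warns and
    stays null; every other column is an author variable attached to the
    Sample record (hence the extended-attribute table).
    """
    config = config or load_mapping("cellxgene")
    registry = registry or build_default_registry()
    config.validate(registry)
    P = config.id_prefix
    suffix = config.ontology_suffix

    if isinstance(source, pd.DataFrame):
        obs, src = source, "dataframe"
    elif str(source).endswith(".h5ad"):
        import anndata

        obs = anndata.read_h5ad(str(source)).obs.reset_index(names="observation_join_id")
        src = str(source)
    else:
        obs = pd.read_csv(source, dtype=str, keep_default_na=False)
        src = str(source)

    if "sample_id" not in obs.columns:
        raise ValueError("observation table must carry a sample_id column")

    missing = [v for v in config.common_variables if v not in obs.columns]
    for var in missing:
        warnings.warn(f"common variable {var!r} missing from observation table", stacklevel=2)

    known = set(config.common_variables) | set(config.metadata)
    companion = {f"{v}{suffix}" for v in config.common_variables}
    author_vars = [c for c in obs.columns if c not in known and c not in companion]

    bundle = RecordBundle()
    bundle.add("Study", {"study_id": f"{P}study_1", "name": "observation table import"}, src)
    bundle.add("Experiment", {"experiment_id": f"{P}exp_1", "study_id": f"{P}study_1"}, src)

    for i, row in enumerate(obs.to_dict("records")):
        join_id = str(row.get("observation_join_id") or f"row{i + 1}")
        sample_id = str(row["sample_id"])
        records: dict[str, dict[str, Any]] = {
            "Subject": {"subject_id": f"{P}sub_{join_id}", "experiment_id": f"{P}exp_1"},
            "Sample": {
                "sample_id": f"{P}sam_{join_id}",
                "subject_id": f"{P}sub_{join_id}",
                "type": "expsample",
                "expsample_reference_name": sample_id,
            },
            "Assay": {"assay_id": f"{P}asy_{join_id}", "sample_id": f"{P}sam_{join_id}",
                      "experiment_id": f"{P}exp_1"},
            "Result": {"result_id": f"{P}res_{join_id}", "assay_id": f"{P}asy_{join_id}"},
        }
        occurrence: dict[str, Any] = {
            "occurrence_id": f"{P}occ_{join_id}",
            "subject_id": f"{P}sub_{join_id}",
            "occurrence_type": "disease history",
        }
        has_disease = False
        for var, (class_name, attr) in config.common_variables.items():
            value = row.get(var)
            if value is None or value == "":
                continue
            oid = row.get(f"{var}{suffix}", "")
            target = occurrence if class_name == "Occurrence" else records[class_name]
            target[attr] = value
            if oid:
                target[f"{attr}{suffix}"] = oid
            if class_name == "Occurrence":
                has_disease = True
        for var in author_vars:
            value = row.get(var)
            if value is not None and value != "":
                records["Sample"][var] = value
        for class_name, rec in records.items():
            bundle.add(class_name, rec, src)
        if has_disease:
            bundle.add("Occurrence", occurrence, src)
    return bundle
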