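"""Seeded synthetic vaccine-study generator.

Emulates the canonical vaccine immune-response study pattern: each study runs
one experiment in which human subjects receive an influenza vaccine at day 0;
at each visit day a blood biosample is drawn and processed into a PBMC
expsample that is assayed by transcription profiling, producing one
normalized-log2 expression column per expsample (GEO GSM-style reference
names).  A configurable subset of genes is planted with a fixed log2 gain at
post-baseline days in responder subjects, and a configurable fraction of
expsamples is flagged as carrying a batch factor.

The same simulated cohort can be written out in all three supported source
layouts (study-metadata + expression files, per-table relational dumps, and
flat single-cell observation tables), so every connector is testable without
downloads.

The noise model is independent Gaussian on the log2 scale — a deliberate
stand-in for real transcriptome data, which is correlated and heteroskedastic;
see the methods note for what this does and does not exercise.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bundle import RecordBundle
from .expression import ExpressionMatrix

__all__ = [
    "VaccineSpec",
    "SimConfig",
    "SimTruth",
    "simulate_study",
    "simulate_viget_files",
    "simulate_immport_tables",
    "simulate_cellxgene_obs",
]

#: The four influenza vaccines of the canonical use case.  Only the
#: 'trivalent influenza vaccine' and Fluzone CURIEs are real Vaccine Ontology
#: ids; the rest are synthetic placeholders matching the bundled
#: mini-ontology fixture.
DEFAULT_VACCINES = (
    ("Fluarix", "VO_9000010", "TIV"),
    ("Fluvirin", "VO_9000011", "TIV"),
    ("Fluzone", "VO_0000047", "TIV"),
    ("FluMist", "VO_9000012", "LAIV"),
)


@dataclass(frozen=True)
class VaccineSpec:
    name: str
    vo_id: str
    vaccine_class: str  # "TIV" | "LAIV"


@dataclass
class SimConfig:
    """Study-generator knobs; defaults are the canonical test conditions.

    ``planted_delta`` is the log2 gain planted genes receive at post-baseline
    days in responders (2.0 ≈ a 4-fold change, comfortably above the 1.0
    stimulation threshold); ``noise_sd`` is the per-measurement Gaussian sd
    on the log2 scale.
    """

    n_studies: int = 4
    subjects_per_study: int = 10
    sex_ratio: float = 0.5  # fraction female
    vaccines: tuple[tuple[str, str, str], ...] = DEFAULT_VACCINES
    days: tuple[int, ...] = (0, 7, 14, 28)
    n_genes: int = 200
    planted_genes: int = 20
    planted_delta: float = 2.0
    noise_sd: float = 0.1
    batch_fraction: float = 0.1
    responder_fraction: float = 1.0
    baseline_mean: float = 5.0
    n_cells: int = 50  # observation rows for the single-cell layout
    extra_vars: int = 0  # author-specific variables in the single-cell layout
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.batch_fraction <= 1:
            raise ValueError("batch_fraction must be in [0, 1]")
        if self.planted_genes > self.n_genes:
            raise ValueError("planted_genes cannot exceed n_genes")
        if self.planted_delta < 0:
            raise ValueError("planted_delta must be >= 0")
        if 0 not in self.days:
            raise ValueError("days must include the baseline day 0")

    @property
    def vaccine_specs(self) -> list[VaccineSpec]:
        return [VaccineSpec(*v) for v in self.vaccines]


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated cohort."""

    planted_genes: list[str]
    responders: dict[str, bool]  # subject id -> responds to the vaccine
    batch_samples: set[str] = field(default_factory=set)  # expsample reference names

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "planted_genes": self.planted_genes,
            "responders": self.responders,
            "batch_samples": sorted(self.batch_samples),
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


def simulate_study(config: SimConfig) -> tuple[RecordBundle, ExpressionMatrix, SimTruth]:
    """Generate a referentially closed bundle, its expression matrix, and truth.

    Deterministic given ``config.seed``: the same config yields byte-identical
    serializations.  Studies are assigned vaccines round-robin; every subject
    receives one intervention at day 0 and contributes one biosample plus one
    derived PBMC expsample per visit day.
    """
    rng = np.random.default_rng(config.seed)
    vaccines = config.vaccine_specs
    bundle = RecordBundle()

    genes = [f"G{g + 1:05d}" for g in range(config.n_genes)]
    planted = genes[: config.planted_genes]
    truth = SimTruth(planted_genes=list(planted), responders={})

    for vac in {v.name: v for v in vaccines}.values():
        bundle.add(
            "Material",
            {
                "material_id": f"Mat_{vac.name}",
                "name": vac.name,
                "name_ontology_id": vac.vo_id,
                "material_type": "vaccine",
            },
        )
    bundle.add(
        "Ontology",
        {
            "ontology_id": "Ont_1",
            "name": "mini vaccine ontology (synthetic subset)",
            "linked_class": "Material",
        },
    )
    bundle.add(
        "Documentation",
        {
            "documentation_id": "Doc_1",
            "name": "normalized log2 expression matrix",
            "path": "expression_matrix.csv",
            "doc_type": "expression data file",
            "linked_class": "Study",
        },
    )

    columns: dict[str, np.ndarray] = {}
    gsm_counter = 0
    sample_meta: list[dict] = []  # per-expsample metadata, reused by layout writers

    for s in range(1, config.n_studies + 1):
        vac = vaccines[(s - 1) % len(vaccines)]
        study_id = f"Stu_{s}"
        experiment_id = f"Exp_{s}"
        group_id = f"Grp_{s}"
        bundle.add(
            "Study",
            {
                "study_id": study_id,
                "name": f"{vac.name} immune response study {s}",
                "study_type": "interventional vaccine study",
            },
        )
        bundle.add(
            "Experiment",
            {
                "experiment_id": experiment_id,
                "study_id": study_id,
                "name": f"{vac.name} vaccination experiment",
            },
        )
        bundle.add("Group", {"group_id": group_id, "name": f"{vac.name} vaccinated group"})

        for j in range(1, config.subjects_per_study + 1):
            subject_id = f"Sub_{s}_{j}"
            sex = "female" if rng.random() < config.sex_ratio else "male"
            responder = bool(rng.random() < config.responder_fraction)
            truth.responders[subject_id] = responder
            bundle.add(
                "Subject",
                {
                    "subject_id": subject_id,
                    "experiment_id": experiment_id,
                    "group_id": group_id,
                    "age": int(rng.integers(18, 66)),
                    "sex": sex,
                    "species": "Homo sapiens",
                    "species_ontology_id": "NCBITaxon_9606",
                },
            )
            bundle.add(
                "Intervention",
                {
                    "intervention_id": f"Int_{s}_{j}",
                    "subject_id": subject_id,
                    "material_id": f"Mat_{vac.name}",
                    "intervention_type": "vaccination",
                    "material": vac.name,
                    "material_ontology_id": vac.vo_id,
                    "intervention_time": 0,
                    "dose": "1 dose",
                    "route": "intranasal" if vac.vaccine_class == "LAIV" else "intramuscular",
                },
            )
            if j == 1:  # sprinkle post-vaccination occurrences for coverage
                bundle.add(
                    "Occurrence",
                    {
                        "occurrence_id": f"Occ_{s}_{j}",
                        "subject_id": subject_id,
                        "occurrence_type": "adverse event",
                        "occurrence_time": 1,
                        "description": "transient injection-site reaction",
                    },
                )

            for day in config.days:
                gsm_counter += 1
                bio_id = f"Sam_b_{s}_{j}_{day}"
                exp_id = f"Sam_e_{s}_{j}_{day}"
                bio_ref = f"BIO{gsm_counter:06d}"
                gsm_ref = f"GSM{700000 + gsm_counter}"
                bundle.add(
                    "Sample",
                    {
                        "sample_id": bio_id,
                        "subject_id": subject_id,
                        "type": "biosample",
                        "collection": "blood draw",
                        "collection_time": day,
                        "biosample_source": "blood",
                        "biosample_reference_name": bio_ref,
                    },
                )
                batch = bool(rng.random() < config.batch_fraction)
                exp_rec = {
                    "sample_id": exp_id,
                    "subject_id": subject_id,
                    "type": "expsample",
                    "collection": "blood draw",
                    "collection_time": day,
                    "biosample_source": "blood",
                    "expsample_type": "PBMC",
                    "expsample_reference_name": gsm_ref,
                }
                if batch:
                    exp_rec["batch"] = "true"  # extended attribute, mirrors source batch flags
                    truth.batch_samples.add(gsm_ref)
                bundle.add("Sample", exp_rec)
                assay_id = f"Asy_{s}_{j}_{day}"
                bundle.add(
                    "Assay",
                    {
                        "assay_id": assay_id,
                        "experiment_id": experiment_id,
                        "sample_id": exp_id,
                        "assay_type": "transcription profiling assay",
                        "organism_inclusion": "yes",
                        "platform": "expression microarray",
                    },
                )
                bundle.add(
                    "Result",
                    {
                        "result_id": f"Res_{s}_{j}_{day}",
                        "assay_id": assay_id,
                        "datatype": "normalized log2 expression",
                        "original_assay_type": "transcription profiling assay",
                        "filetype": "csv",
                        "reference_name": gsm_ref,
                    },
                )

                expr = config.baseline_mean + (
                    rng.normal(0.0, config.noise_sd, size=config.n_genes)
                    if config.noise_sd > 0
                    else np.zeros(config.n_genes)
                )
                if day > 0 and responder:
                    expr[: config.planted_genes] += config.planted_delta
                columns[gsm_ref] = expr
                sample_meta.append(
                    {
                        "study_id": study_id,
                        "study_name": f"{vac.name} immune response study {s}",
                        "subject_id": subject_id,
                        "species": "Homo sapiens",
                        "sex": sex,
                        "age": bundle.tables["Subject"][-1]["age"],
                        "vaccine": vac.name,
                        "vaccine_vo_id": vac.vo_id,
                        "day": day,
                        "expsample_reference_name": gsm_ref,
                        "biosample_reference_name": bio_ref,
                        "batch": "Yes" if batch else "",
                    }
                )

    matrix = ExpressionMatrix(
        values=pd.DataFrame(columns, index=pd.Index(genes, name="gene_symbol")),
        batch_flag={ref: ref in truth.batch_samples for ref in columns},
    )
    bundle._sample_meta = sample_meta  # type: ignore[attr-defined]  # reused by layout writers
    return bundle, matrix, truth


def simulate_viget_files(config: SimConfig, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the two-file study layout: a per-expsample metadata table and the
    normalized log2 expression matrix, as a converter-ready fixture."""
    bundle, matrix, _ = simulate_study(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_path = out / "study_metadata.csv"
    expr_path = out / "expression_matrix.csv"
    meta: list[dict] = bundle._sample_meta  # type: ignore[attr-defined]
    fieldnames = list(meta[0].keys()) if meta else [
        "study_id", "study_name", "subject_id", "species", "sex", "age",
        "vaccine", "vaccine_vo_id", "day",
        "expsample_reference_name", "biosample_reference_name", "batch",
    ]
    with meta_path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        writer.writerows(meta)
    matrix.to_csv(expr_path)
    return meta_path, expr_path


def _write_table(path: Path, fieldnames: list[str], rows: list[dict]) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames, extrasaction="ignore")
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row.get(k, "") for k in fieldnames})


def simulate_immport_tables(config: SimConfig, out_dir: str | Path) -> Path:
    """Write the per-table relational dump layout.

    The intervention rows are spread across three source tables
    (intervention / immune_exposure / treatment), the sample rows across
    biosample / control_sample / expsample tables, and the assay results into
    one assay-specific table, so that consolidation by the connector
    reproduces the merge rules (concatenation with a ``type`` column for
    samples and one Assay row per assay-specific table).
    """
    bundle, _, _ = simulate_study(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    interventions = bundle.tables.get("Intervention", [])
    int_cols = [
        "intervention_id", "subject_id", "material_id", "intervention_type",
        "material", "material_ontology_id", "intervention_time", "dose", "route",
    ]
    # round-robin split across the three intervention-like source tables
    splits: dict[str, list[dict]] = {"intervention": [], "immune_exposure": [], "treatment": []}
    names = list(splits)
    for i, row in enumerate(interventions):
        splits[names[i % 3]].append(row)
    for name, rows in splits.items():
        _write_table(out / f"{name}.csv", int_cols, rows)

    samples = bundle.tables.get("Sample", [])
    samp_cols = [
        "sample_id", "subject_id", "collection", "collection_time", "biosample_source",
        "expsample_type", "biosample_reference_name", "expsample_reference_name", "batch",
    ]
    by_type = {"biosample": [], "control": [], "expsample": []}
    for row in samples:
        by_type[row.get("type", "biosample")].append(row)
    _write_table(out / "biosample.csv", samp_cols, by_type["biosample"])
    _write_table(out / "control_sample.csv", samp_cols, by_type["control"])
    _write_table(out / "expsample.csv", samp_cols, by_type["expsample"])

    # one assay-specific table: transcription profiling results
    results = bundle.tables.get("Result", [])
    assays = {a["assay_id"]: a for a in bundle.tables.get("Assay", [])}
    res_cols = ["result_id", "sample_id", "datatype", "filetype", "reference_name"]
    res_rows = []
    for res in results:
        assay = assays.get(res.get("assay_id"), {})
        res_rows.append({**res, "sample_id": assay.get("sample_id", "")})
    _write_table(out / "assay_gene_expression.csv", res_cols, res_rows)

    used_materials = {r.get("material_id") for r in interventions}
    for name, cols in (
        ("study", ["study_id", "name", "study_type"]),
        ("experiment", ["experiment_id", "study_id", "name"]),
        ("subject", ["subject_id", "experiment_id", "group_id", "age", "sex",
                     "species", "species_ontology_id"]),
        ("group", ["group_id", "name"]),
        ("material", ["material_id", "name", "name_ontology_id", "material_type"]),
    ):
        rows = bundle.tables.get(name.capitalize(), [])
        if name == "material":  # only materials actually administered
            rows = [r for r in rows if r["material_id"] in used_materials]
        _write_table(out / f"{name}.csv", cols, rows)
    return out


CELLXGENE_COMMON_VARS = (
    "organism",
    "species",
    "developmental_stage",
    "disease",
    "sex",
    "tissue",
    "cell_type",
    "suspension",
    "assay",
    "tissue_type",
)

_CXG_VALUES = {
    "organism": ("Homo sapiens", "NCBITaxon_9606"),
    "species": ("Homo sapiens", "NCBITaxon_9606"),
    "developmental_stage": ("human adult stage", "HsapDv_0000087"),
    "disease": ("influenza", "MONDO_0005812"),
    "tissue": ("blood", "UBERON_0000178"),
    "suspension": ("cell", "EFO_0030080"),
    "assay": ("10x 3' v3", "EFO_0009922"),
    "tissue_type": ("tissue", "CURIE_tissue"),
}
_CXG_CELL_TYPES = (
    ("T cell", "CL_0000084"),
    ("B cell", "CL_0000236"),
    ("monocyte", "CL_0000576"),
    ("natural killer cell", "CL_0000623"),
)


def simulate_cellxgene_obs(config: SimConfig) -> pd.DataFrame:
    """Generate a flattened single-cell observation table: the 2 metadata
    columns (sample_id, observation_join_id), the 10 common variables each
    paired with its ontology-id column, and ``config.extra_vars`` author
    variables — 22 columns plus extras."""
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for i in range(config.n_cells):
        sex = ("female", "PATO_0000383") if rng.random() < config.sex_ratio else ("male", "PATO_0000384")
        cell_type = _CXG_CELL_TYPES[int(rng.integers(len(_CXG_CELL_TYPES)))]
        row: dict[str, object] = {
            "sample_id": f"cxg_sample_{i + 1:04d}",
            "observation_join_id": f"obs_{i + 1:06d}",
        }
        for var in CELLXGENE_COMMON_VARS:
            if var == "sex":
                value, oid = sex
            elif var == "cell_type":
                value, oid = cell_type
            else:
                value, oid = _CXG_VALUES[var]
            row[var] = value
            row[f"{var}_ontology_id"] = oid
        for k in range(config.extra_vars):
            row[f"author_var_{k + 1}"] = round(float(rng.normal(0, 1)), 4)
        rows.append(row)
    columns = ["sample_id", "observation_join_id"]
    for var in CELLXGENE_COMMON_VARS:
        columns += [var, f"{var}_ontology_id"]
    columns += [f"author_var_{k + 1}" for k in range(config.extra_vars)]
    return pd.DataFrame(rows, columns=columns)
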