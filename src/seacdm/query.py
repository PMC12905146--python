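"""Paired-sample selection and the stimulated-gene statistic.

The central analysis answers questions of the form *"which genes are
stimulated by vaccine X in species Y at day D after vaccination?"*:

1. :func:`select_pairs` retrieves, from a loaded store, one
   (baseline, follow-up) expsample pair per subject matching the metadata
   query — optionally expanding an ontology term id to all descendant
   materials;
2. :func:`stimulated_genes` applies the gene restriction criteria to the
   expression matrix: a gene passes for a subject when its log2 change from
   baseline is at least ``min_log2_fc`` (default 1.0, i.e. 2-fold) and its
   expression on either day is at least ``expr_floor_log2`` (default 0.2);
   a gene is *stimulated* when at least ``min_subjects`` (default 3)
   subjects pass, after removing batch-flagged samples.

All thresholds are inclusive.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .expression import ExpressionMatrix
from .ontology import OntologyGraph, descendants, label_to_id
from .store import StoreHandle

__all__ = [
    "SampleQuery",
    "GeneFilterCriteria",
    "SubjectPair",
    "StimulationResult",
    "select_pairs",
    "stimulated_genes",
    "group_by_vaccine_class",
    "overlap_counts",
    "export_results",
    "read_results",
    "check_result_json",
]


@dataclass(frozen=True)
class SampleQuery:
    """Metadata criteria selecting paired samples.

    ``material`` is either an exact material name or an ontology term id;
    term ids are expanded to all descendant materials when an ontology graph
    is supplied to :func:`select_pairs`.
    """

    material: str
    species: str | None = "Homo sapiens"
    sex: str | None = None
    day: int = 7
    baseline_day: int = 0

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError("day must be >= 0")
        if self.baseline_day >= self.day:
            raise ValueError("baseline_day must precede day")


@dataclass(frozen=True)
class GeneFilterCriteria:
    """The gene restriction thresholds (all inclusive, log2 scale)."""

    min_log2_fc: float = 1.0
    expr_floor_log2: float = 0.2
    min_subjects: int = 3
    exclude_batch: bool = True

    def __post_init__(self) -> None:
        if self.min_log2_fc < 0:
            raise ValueError("min_log2_fc must be non-negative")
        if self.min_subjects < 1:
            raise ValueError("min_subjects must be >= 1")


@dataclass(frozen=True)
class SubjectPair:
    subject_id: str
    baseline_ref: str
    followup_ref: str


@dataclass
class GeneStats:
    deltas: list[float]  # per-subject Δlog2 for passing pairs only
    n_passing: int
    mean_delta: float | None


@dataclass
class StimulationResult:
    genes: dict[str, GeneStats]
    stimulated: list[str]
    criteria: GeneFilterCriteria
    n_pairs_used: int = 0

    @property
    def stimulated_set(self) -> set[str]:
        return set(self.stimulated)


def _expand_materials(
    material: str, ontology: OntologyGraph | None
) -> tuple[list[str], list[str]]:
    """Return (material names, ontology ids) to match against interventions."""
    if ontology is not None and material in ontology:
        ids = sorted(descendants(ontology, material, include_self=True))
        labels = sorted(ontology.terms[t].label for t in ids)
        return labels, ids
    return [material], []


def select_pairs(
    handle: StoreHandle,
    query: SampleQuery,
    ontology: OntologyGraph | None = None,
) -> list[SubjectPair]:
    """Select one (baseline, follow-up) expsample pair per subject.

    A subject contributes a pair only when it has expsamples at both
    ``baseline_day`` and ``day`` and received an intervention with a
    matching material.  When several expsamples exist for one subject-day,
    the lexicographically first reference name is used, with a warning.
    """
    names, term_ids = _expand_materials(query.material, ontology)
    conds = ["sa.type = 'expsample'", "sa.expsample_reference_name IS NOT NULL"]
    params: list[object] = []
    mat = f"i.material IN ({','.join('?' for _ in names)})"
    params.extend(names)
    if term_ids:
        mat = f"({mat} OR i.material_ontology_id IN ({','.join('?' for _ in term_ids)}))"
        params.extend(term_ids)
    conds.append(mat)
    if query.species is not None:
        conds.append("su.species = ?")
        params.append(query.species)
    if query.sex is not None:
        conds.append("su.sex = ?")
        params.append(query.sex)
    conds.append("CAST(sa.collection_time AS REAL) IN (?, ?)")
    params.extend([float(query.baseline_day), float(query.day)])

    sql = f"""
        SELECT su.subject_id, CAST(sa.collection_time AS REAL), sa.expsample_reference_name
        FROM Sample sa
        JOIN Subject su ON sa.subject_id = su.subject_id
        JOIN Intervention i ON i.subject_id = su.subject_id
        WHERE {' AND '.join(conds)}
        ORDER BY su.subject_id, sa.expsample_reference_name
    """
    by_subject: dict[str, dict[float, list[str]]] = {}
    for subject, day, ref in handle.execute(sql, params).fetchall():
        by_subject.setdefault(subject, {}).setdefault(day, []).append(ref)

    pairs: list[SubjectPair] = []
    for subject in sorted(by_subject):
        days = by_subject[subject]
        base = sorted(set(days.get(float(query.baseline_day), [])))
        follow = sorted(set(days.get(float(query.day), [])))
        if not base or not follow:
            continue
        if len(base) > 1 or len(follow) > 1:
            warnings.warn(
                f"subject {subject}: multiple samples at one day; "
                "using lexicographically first reference",
                stacklevel=2,
            )
        pairs.append(SubjectPair(subject, base[0], follow[0]))
    return pairs


def stimulated_genes(
    matrix: ExpressionMatrix,
    pairs: list[SubjectPair],
    criteria: GeneFilterCriteria = GeneFilterCriteria(),
) -> StimulationResult:
    """Apply the gene restriction criteria over subject pairs.

    Batch-flagged samples are removed first (a pair is dropped when either
    member is flagged).  Per gene and pair the pass rule is::

        (x_day - x_base >= min_log2_fc) and
        (x_day >= expr_floor_log2 or x_base >= expr_floor_log2)

    and a gene is stimulated when passing pairs >= min_subjects.
    """
    usable = [
        p
        for p in pairs
        if not criteria.exclude_batch
        or not (matrix.is_batch(p.baseline_ref) or matrix.is_batch(p.followup_ref))
    ]
    genes = matrix.genes
    if not usable:
        stats = {g: GeneStats([], 0, None) for g in genes}
        return StimulationResult(stats, [], criteria, 0)

    base = np.column_stack([matrix.column(p.baseline_ref) for p in usable])
    follow = np.column_stack([matrix.column(p.followup_ref) for p in usable])
    delta = follow - base
    passing = (delta >= criteria.min_log2_fc) & (
        (follow >= criteria.expr_floor_log2) | (base >= criteria.expr_floor_log2)
    )
    n_passing = passing.sum(axis=1)

    stats: dict[str, GeneStats] = {}
    stimulated: list[str] = []
    for gi, gene in enumerate(genes):
        deltas = [float(d) for d in delta[gi, passing[gi]]]
        mean = float(np.mean(deltas)) if deltas else None
        stats[gene] = GeneStats(deltas, int(n_passing[gi]), mean)
        if n_passing[gi] >= criteria.min_subjects:
            stimulated.append(gene)
    return StimulationResult(stats, stimulated, criteria, len(usable))


def group_by_vaccine_class(
    gene_lists: dict[str, set[str]],
    ontology: OntologyGraph,
    classes: list[str],
) -> dict[str, set[str]]:
    """Union per-vaccine gene sets into ontology-defined vaccine classes.

    A vaccine belongs to a class when its term (resolved by label, or used
    directly if already a term id) lies in the class's subClassOf closure
    (self included).  Vaccines belonging to no class are reported with a
    warning; classes may overlap, so a gene can appear in several unions.
    """
    closures = {c: descendants(ontology, c, include_self=True) for c in classes}
    out: dict[str, set[str]] = {c: set() for c in classes}
    unassigned: list[str] = []
    for vaccine, genes in gene_lists.items():
        term = vaccine if vaccine in ontology else label_to_id(ontology, vaccine)
        hit = False
        for cls, closure in closures.items():
            if term is not None and term in closure:
                out[cls] |= genes
                hit = True
        if not hit:
            unassigned.append(vaccine)
    if unassigned:
        warnings.warn(f"vaccines with no class membership: {sorted(unassigned)}", stacklevel=2)
    return out


def overlap_counts(sets: dict[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Counts for every non-empty membership region of the named sets
    (the Venn-diagram numbers).  Region keys are sorted name tuples; the
    counts sum to the size of the union."""
    names = sorted(sets)
    counts: dict[tuple[str, ...], int] = {}
    from itertools import combinations

    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(sets[n] for n in combo)) if combo else set()
            outside = set.union(*(sets[n] for n in names if n not in combo), set())
            counts[combo] = len(inside - outside)
    return counts


# --- result export --------------------------------------------------------

RESULT_COLUMNS = ("gene", "n_passing", "mean_delta_log2")


def export_results(result: StimulationResult, fmt: str, path: str | Path) -> Path:
    """Write the stimulated-gene table as CSV or JSON: one row per
    stimulated gene with its passing-subject count and mean Δlog2."""
    path = Path(path)
    rows = [
        {
            "gene": g,
            "n_passing": result.genes[g].n_passing,
            "mean_delta_log2": result.genes[g].mean_delta,
        }
        for g in result.stimulated
    ]
    if fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=RESULT_COLUMNS)
            writer.writeheader()
            writer.writerows(rows)
    elif fmt == "json":
        payload = {
            "criteria": {
                "min_log2_fc": result.criteria.min_log2_fc,
                "expr_floor_log2": result.criteria.expr_floor_log2,
                "min_subjects": result.criteria.min_subjects,
                "exclude_batch": result.criteria.exclude_batch,
            },
            "n_pairs_used": result.n_pairs_used,
            "stimulated_genes": rows,
        }
        path.write_text(json.dumps(payload, indent=2))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_results(path: str | Path) -> list[dict[str, object]]:
    """Read back an exported result table (CSV or JSON) as a list of
    {gene, n_passing, mean_delta_log2} rows."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        check_result_json(payload)
        return [dict(r) for r in payload["stimulated_genes"]]
    with path.open(newline="", encoding="utf-8") as fh:
        rows = []
        for rec in csv.DictReader(fh):
            rows.append(
                {
                    "gene": rec["gene"],
                    "n_passing": int(rec["n_passing"]),
                    "mean_delta_log2": float(rec["mean_delta_log2"]),
                }
            )
        return rows


def check_result_json(payload: object) -> None:
    """Structural check of an exported JSON result against the shipped
    schema (``data/stimulation_result.schema.json``)."""
    if not isinstance(payload, dict):
        raise ValueError("result JSON must be an object")
    for key in ("criteria", "n_pairs_used", "stimulated_genes"):
        if key not in payload:
            raise ValueError(f"result JSON missing key {key!r}")
    for row in payload["stimulated_genes"]:
        if not isinstance(row, dict) or set(row) != set(RESULT_COLUMNS):
            raise ValueError(f"malformed stimulated gene row: {row!r}")
        if not isinstance(row["gene"], str) or not isinstance(row["n_passing"], int):
            raise ValueError(f"malformed stimulated gene row types: {row!r}")
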