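import numpy as np
import pandas as pd
import pytest

import seacdm as sc
from seacdm.expression import ExpressionMatrix
from seacdm.query import SubjectPair


@pytest.fixture(scope="session")
def registry():
    return sc.build_default_registry()


@pytest.fixture(scope="session")
def mini_ontology():
    from importlib import resources

    path = resources.files("seacdm.data").joinpath("mini_vo_synthetic.csv")
    return sc.load_ontology(str(path))


@pytest.fixture(scope="session")
def sim():
    """Default simulated cohort: 4 studies, one per vaccine."""
    return sc.simulate_study(sc.SimConfig(seed=11))


@pytest.fixture()
def loaded_store(registry, sim):
    bundle, _, _ = sim
    handle = sc.init_store(registry)
    sc.load_bundle(handle, bundle)
    yield handle
    handle.close()


def random_matrix_and_pairs(seed, n_genes=100, n_pairs=12, batch_fraction=0.15):
    """A random expression matrix with paired baseline/follow-up samples,
    spanning values around the filter boundaries."""
    rng = np.random.default_rng(seed)
    refs = [f"S{i:03d}_{t}" for i in range(n_pairs) for t in ("base", "day")]
    values = rng.uniform(-1.0, 6.0, size=(n_genes, len(refs)))
    genes = [f"G{g:04d}" for g in range(n_genes)]
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=refs),
        batch_flag={r: bool(rng.random() < batch_fraction) for r in refs},
    )
    pairs = [SubjectPair(f"sub{i}", f"S{i:03d}_base", f"S{i:03d}_day") for i in range(n_pairs)]
    return matrix, pairs


def random_dag(seed, n_nodes):
    """Random ontology DAG as an in-memory term table (child -> parents)."""
    rng = np.random.default_rng(seed)
    terms = {}
    for i in range(n_nodes):
        n_parents = int(rng.integers(0, min(i, 3) + 1)) if i else 0
        parents = sorted(rng.choice(i, size=n_parents, replace=False)) if n_parents else []
        terms[f"T{i:04d}"] = [f"T{int(p):04d}" for p in parents]
    return terms


def dag_to_graph(terms):
    import networkx as nx

    from seacdm.ontology import OntologyGraph, OntologyTerm, _finalize

    graph = OntologyGraph()
    for tid, parents in terms.items():
        graph.terms[tid] = OntologyTerm(id=tid, label=f"label {tid}", parents=tuple(parents))
    return _finalize(graph)


def bfs_descendants(terms, root, include_self=False):
    """Independent breadth-first closure oracle over child->parent edges."""
    children = {}
    for child, parents in terms.items():
        for p in parents:
            children.setdefault(p, set()).add(child)
    out, frontier = set(), [root]
    while frontier:
        node = frontier.pop()
        for child in children.get(node, ()):
            if child not in out:
                out.add(child)
                frontier.append(child)
    if include_self:
        out.add(root)
    return out


def oracle_stimulated(matrix, pairs, criteria):
    """Exhaustive per-gene, per-pair reference implementation of the
    stimulated-gene filter (pure python loops, no vectorization)."""
    usable = []
    for p in pairs:
        if criteria.exclude_batch and (matrix.is_batch(p.baseline_ref) or matrix.is_batch(p.followup_ref)):
            continue
        usable.append(p)
    stimulated = set()
    for gene in matrix.genes:
        n = 0
        for p in usable:
            xb = float(matrix.values.at[gene, p.baseline_ref])
            xd = float(matrix.values.at[gene, p.followup_ref])
            if (xd - xb) >= criteria.min_log2_fc and (
                xd >= criteria.expr_floor_log2 or xb >= criteria.expr_floor_log2
            ):
                n += 1
        if n >= criteria.min_subjects:
            stimulated.add(gene)
    return stimulated


def oracle_material_summary(bundle, materials):
    """Brute-force join + distinct over the bundle's record lists."""
    materials = set(materials)
    subj_exp = {
        r["subject_id"]: r["experiment_id"]
        for r in bundle.tables.get("Subject", [])
        if r.get("experiment_id")
    }
    exp_study = {
        r["experiment_id"]: r.get("study_id")
        for r in bundle.tables.get("Experiment", [])
    }
    hit_subjects = {
        r.get("subject_id")
        for r in bundle.tables.get("Intervention", [])
        if r.get("material") in materials
    }
    bio, studies, exps = set(), set(), set()
    for r in bundle.tables.get("Sample", []):
        subj = r.get("subject_id")
        if subj not in hit_subjects or subj not in subj_exp:
            continue
        if subj_exp[subj] not in exp_study:  # inner join on Experiment
            continue
        study = exp_study[subj_exp[subj]]
        if study:
            studies.add(str(study))
        if r.get("biosample_reference_name"):
            bio.add(str(r["biosample_reference_name"]))
        if r.get("expsample_reference_name"):
            exps.add(str(r["expsample_reference_name"]))
    return len(bio), len(studies), len(exps)
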