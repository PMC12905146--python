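# seacdm

A working implementation of the **Study-Experiment-Assay (SEA) common data
model**: an ontology-aware schema for integrating heterogeneous biomedical
experimental studies, together with the tooling needed to actually use it —
CSV templates, an embedded relational store, ETL connectors for three source
layouts, a paired-sample gene-expression query engine, and a property-graph
export.

It is aimed at data engineers and computational immunologists who need to
pull study metadata from resources with incompatible schemas (immune-study
repositories, single-cell atlases, expression portals) into one queryable
store without losing source-specific fields.

## The model

Thirteen classes, ten of them core and linked by foreign keys:

```
Study ← Experiment ← Subject ← {Sample, Intervention, Occurrence}
                     Subject ↔ Group
Experiment ← Assay → Sample;  Assay ← Result;  Analysis → {Group, Result}
```

plus three accessory classes: **Material** (agents administered, e.g. a
vaccine), **Ontology**, and **Documentation**. A study contains experiments;
experiments produce samples from subjects; assays consume samples and
produce results. Sample distinguishes `biosample` (collected from a subject,
e.g. blood) from `expsample` (a processed derivative used in an assay, e.g.
PBMC) via a `type` column. Every controlled attribute is paired with a
`<name>_ontology_id` column carrying a CURIE (e.g. `VO_0000047` for the
Fluzone vaccine in the Vaccine Ontology), so queries can be widened through
the ontology's subClassOf hierarchy instead of string matching. Fields
outside the fixed schema are never dropped: they travel in a long-format
`extended_attribute` side table.

## The stimulated-gene statistic

Given per-subject expression at a baseline day $d_0$ and a follow-up day
$d$, on the normalized $\log_2$ scale, a gene $g$ *passes* for subject $i$
when

$$x_{g,i}(d) - x_{g,i}(d_0) \ge \Delta_{\min} \quad\text{and}\quad
\max\big(x_{g,i}(d),\, x_{g,i}(d_0)\big) \ge f$$

with defaults $\Delta_{\min} = 1$ (a 2-fold change) and floor $f = 0.2$,
both inclusive. Samples flagged with a batch factor are removed first
(removed, not adjusted), and $g$ is **stimulated** when at least
$k_{\min} = 3$ subjects pass. Gene sets per vaccine can then be unioned
into ontology-defined classes (e.g. inactivated vs live attenuated
influenza vaccines) and compared via Venn-region counts; gene lists export
as CSV/JSON for external enrichment services.

## Worked example

```python
import seacdm as sc
from importlib import resources

registry = sc.build_default_registry()
bundle, matrix, truth = sc.simulate_study(sc.SimConfig(seed=42))
store = sc.init_store(registry)
sc.load_bundle(store, bundle)

summary = sc.material_summary(store, ["Fluarix"])
print(f"Fluarix: {summary.n_studies} studies, {summary.n_biosamples} biosamples, "
      f"{summary.n_expsamples} expsamples")

pairs = sc.select_pairs(store, sc.SampleQuery(material="Fluarix", day=7))
result = sc.stimulated_genes(matrix, pairs)
print(f"{result.n_pairs_used} usable subject pairs, "
      f"{len(result.stimulated)} stimulated genes")

vo = sc.load_ontology(str(resources.files("seacdm.data") / "mini_vo_synthetic.csv"))
expanded = sc.select_pairs(store, sc.SampleQuery(material="VO_0001236", day=7), vo)
print(f"trivalent influenza vaccine (VO_0001236) expands to {len(expanded)} pairs")

kg = sc.build_graph(bundle, vo, registry)
print(f"knowledge graph: {kg.number_of_nodes()} nodes, {kg.number_of_edges()} edges")
```

prints

```
Fluarix: 1 studies, 40 biosamples, 40 expsamples
10 usable subject pairs, 20 stimulated genes
trivalent influenza vaccine (VO_0001236) expands to 40 pairs
knowledge graph: 751 nodes, 1024 edges
```

The default synthetic cohort is four studies (one per influenza vaccine),
10 subjects each, sampled at days 0/7/14/28. The Fluarix study alone
supplies 10 subject pairs at day 7 vs day 0; its 40 biosamples are the
blood draws and the 40 expsamples the derived PBMC samples. The 20
stimulated genes are exactly the generator's planted responders
(`truth.planted_genes`). Querying by the ontology term *trivalent influenza
vaccine* instead of a vaccine name widens the selection to all four
vaccines' subjects (40 pairs), because every vaccine in the bundled
mini-ontology sits below that term.

The same workflow is available from the shell via the `seacdm` CLI
(`seacdm simulate`, `seacdm load`, `seacdm summarize`,
`seacdm stimulated-genes`, `seacdm export-kg`, ...).

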