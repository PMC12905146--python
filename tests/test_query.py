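import json

import numpy as np
import pandas as pd
import pytest

import seacdm as sc
from seacdm.expression import ExpressionMatrix
from seacdm.query import GeneFilterCriteria, SubjectPair, check_result_json, read_results

from .conftest import oracle_stimulated, random_matrix_and_pairs


def _matrix(rows, batch=None):
    """rows: gene -> {sample: value}"""
    df = pd.DataFrame(rows).T
    return ExpressionMatrix(values=df, batch_flag=batch or {})


class TestSelectPairs:
    def test_one_pair_per_complete_subject(self, loaded_store):
        pairs = sc.select_pairs(loaded_store, sc.SampleQuery(material="Fluarix", day=7))
        assert len(pairs) == 10  # subjects_per_study in the default cohort
        assert len({p.subject_id for p in pairs}) == len(pairs)

    def test_subject_without_baseline_excluded(self, registry):
        bundle, _, _ = sc.simulate_study(sc.SimConfig(seed=31, n_studies=1, subjects_per_study=2, days=(0, 7)))
        # strip one subject's day-0 expsample (and its assay/result, to stay closed)
        dropped = "Sam_e_1_1_0"
        bundle.tables["Sample"] = [r for r in bundle.tables["Sample"] if r["sample_id"] != dropped]
        gone_assays = {r["assay_id"] for r in bundle.tables["Assay"] if r.get("sample_id") == dropped}
        bundle.tables["Assay"] = [r for r in bundle.tables["Assay"] if r["assay_id"] not in gone_assays]
        bundle.tables["Result"] = [r for r in bundle.tables["Result"] if r.get("assay_id") not in gone_assays]
        handle = sc.init_store(registry)
        sc.load_bundle(handle, bundle)
        pairs = sc.select_pairs(handle, sc.SampleQuery(material="Fluarix", day=7))
        assert {p.subject_id for p in pairs} == {"Sub_1_2"}
        handle.close()

    def test_sex_filter(self, loaded_store, sim):
        bundle, _, _ = sim
        females = {r["subject_id"] for r in bundle.tables["Subject"] if r["sex"] == "female"}
        pairs = sc.select_pairs(loaded_store, sc.SampleQuery(material="Fluzone", day=7, sex="female"))
        assert pairs and all(p.subject_id in females for p in pairs)

    def test_term_id_query_equals_union_of_string_queries(self, loaded_store, mini_ontology):
        by_term = sc.select_pairs(
            loaded_store, sc.SampleQuery(material="VO_0001236", day=7), mini_ontology
        )
        union = set()
        for vaccine in ("Fluarix", "Fluvirin", "Fluzone", "FluMist"):
            union |= set(sc.select_pairs(loaded_store, sc.SampleQuery(material=vaccine, day=7)))
        assert set(by_term) == union

    def test_duplicate_samples_pick_lexicographic_first(self, registry):
        bundle, _, _ = sc.simulate_study(sc.SimConfig(seed=32, n_studies=1, subjects_per_study=1, days=(0, 7)))
        dup = dict(bundle.tables["Sample"][1])  # the day-0 expsample
        assert dup["type"] == "expsample"
        dup["sample_id"] = "Sam_dup"
        dup["expsample_reference_name"] = "GSM000001"  # sorts first
        bundle.add("Sample", dup)
        handle = sc.init_store(registry)
        sc.load_bundle(handle, bundle)
        with pytest.warns(UserWarning, match="multiple samples"):
            pairs = sc.select_pairs(handle, sc.SampleQuery(material="Fluarix", day=7))
        assert pairs[0].baseline_ref == "GSM000001"
        handle.close()

    def test_invalid_query_rejected(self):
        with pytest.raises(ValueError):
            sc.SampleQuery(material="Fluarix", day=0)


class TestStimulatedGenes:
    def test_inclusive_boundaries_stimulate(self):
        # Δ exactly 1.0 and follow-up exactly at the 0.2 floor, 3 subjects
        samples = {}
        for i in range(3):
            samples[f"b{i}"] = -0.8
            samples[f"d{i}"] = 0.2
        matrix = _matrix({"GENE": samples})
        pairs = [SubjectPair(f"s{i}", f"b{i}", f"d{i}") for i in range(3)]
        result = sc.stimulated_genes(matrix, pairs, GeneFilterCriteria())
        assert result.stimulated == ["GENE"]
        assert result.genes["GENE"].n_passing == 3

    def test_floor_fails_on_both_days(self):
        matrix = _matrix({"GENE": {f"b{i}": -1.95 for i in range(3)} | {f"d{i}": 0.05 for i in range(3)}})
        pairs = [SubjectPair(f"s{i}", f"b{i}", f"d{i}") for i in range(3)]
        result = sc.stimulated_genes(matrix, pairs, GeneFilterCriteria())
        # Δ = 2.0 but both days below the 0.2 expression floor
        assert result.stimulated == []

    def test_min_subjects_boundary(self):
        vals = {}
        for i in range(3):
            vals[f"b{i}"] = 1.0
            vals[f"d{i}"] = 3.0 if i < 2 else 1.5  # only 2 of 3 pass
        matrix = _matrix({"GENE": vals})
        pairs = [SubjectPair(f"s{i}", f"b{i}", f"d{i}") for i in range(3)]
        assert sc.stimulated_genes(matrix, pairs).stimulated == []
        assert sc.stimulated_genes(matrix, pairs, GeneFilterCriteria(min_subjects=2)).stimulated == ["GENE"]

    def test_batch_flagged_pairs_removed_first(self):
        vals = {}
        for i in range(4):
            vals[f"b{i}"] = 1.0
            vals[f"d{i}"] = 3.0
        matrix = _matrix({"GENE": vals}, batch={"d3": True})
        pairs = [SubjectPair(f"s{i}", f"b{i}", f"d{i}") for i in range(4)]
        result = sc.stimulated_genes(matrix, pairs)
        assert result.n_pairs_used == 3
        keep = sc.stimulated_genes(matrix, pairs, GeneFilterCriteria(exclude_batch=False))
        assert keep.n_pairs_used == 4

    def test_missing_reference_named_in_error(self):
        matrix = _matrix({"GENE": {"b0": 1.0, "d0": 3.0}})
        with pytest.raises(KeyError, match="ghost"):
            sc.stimulated_genes(matrix, [SubjectPair("s", "b0", "ghost")])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle(self, seed):
        matrix, pairs = random_matrix_and_pairs(seed)
        criteria = GeneFilterCriteria()
        result = sc.stimulated_genes(matrix, pairs, criteria)
        assert result.stimulated_set == oracle_stimulated(matrix, pairs, criteria)

    @pytest.mark.parametrize("seed", range(4))
    def test_monotone_in_thresholds(self, seed):
        matrix, pairs = random_matrix_and_pairs(seed, n_genes=60)
        base = sc.stimulated_genes(matrix, pairs, GeneFilterCriteria()).stimulated_set
        for tighter in (
            GeneFilterCriteria(min_log2_fc=1.5),
            GeneFilterCriteria(expr_floor_log2=1.0),
            GeneFilterCriteria(min_subjects=5),
        ):
            assert sc.stimulated_genes(matrix, pairs, tighter).stimulated_set <= base

    def test_fully_relaxed_criteria_closed_form(self):
        matrix, pairs = random_matrix_and_pairs(3, n_genes=50, batch_fraction=0.3)
        relaxed = GeneFilterCriteria(
            min_log2_fc=0.0, expr_floor_log2=-np.inf, min_subjects=1, exclude_batch=False
        )
        got = sc.stimulated_genes(matrix, pairs, relaxed).stimulated_set
        expected = set()
        for gene in matrix.genes:
            for p in pairs:
                if matrix.values.at[gene, p.followup_ref] - matrix.values.at[gene, p.baseline_ref] >= 0:
                    expected.add(gene)
        assert got == expected
        positive = {
            g
            for g in matrix.genes
            if any(
                matrix.values.at[g, p.followup_ref] - matrix.values.at[g, p.baseline_ref] > 0
                for p in pairs
            )
        }
        assert positive <= got


class TestPlantedRecovery:
    def test_noise_free_exact_recovery(self, registry):
        config = sc.SimConfig(seed=41, n_studies=1, subjects_per_study=6, days=(0, 7), noise_sd=0.0, batch_fraction=0.0)
        bundle, matrix, truth = sc.simulate_study(config)
        handle = sc.init_store(registry)
        sc.load_bundle(handle, bundle)
        pairs = sc.select_pairs(handle, sc.SampleQuery(material="Fluarix", day=7))
        result = sc.stimulated_genes(matrix, pairs)
        assert result.stimulated_set == set(truth.planted_genes)
        handle.close()

    def test_nonresponders_respect_min_subjects(self, registry):
        # 2 responders of 6 < min_subjects=3: nothing is stimulated
        config = sc.SimConfig(
            seed=42, n_studies=1, subjects_per_study=6, days=(0, 7),
            noise_sd=0.0, batch_fraction=0.0, responder_fraction=0.34,
        )
        bundle, matrix, truth = sc.simulate_study(config)
        n_resp = sum(truth.responders.values())
        handle = sc.init_store(registry)
        sc.load_bundle(handle, bundle)
        pairs = sc.select_pairs(handle, sc.SampleQuery(material="Fluarix", day=7))
        result = sc.stimulated_genes(matrix, pairs)
        if n_resp >= 3:
            assert result.stimulated_set == set(truth.planted_genes)
        else:
            assert result.stimulated == []
        handle.close()


class TestGroupingAndOverlap:
    def test_vaccine_class_unions(self, mini_ontology):
        gene_lists = {
            "Fluarix": {"A", "B"},
            "Fluzone": {"B", "C"},
            "Fluvirin": {"D"},
            "FluMist": {"E"},
        }
        grouped = sc.group_by_vaccine_class(
            gene_lists, mini_ontology, ["VO_9000004", "VO_9000003"]
        )
        assert grouped["VO_9000004"] == {"A", "B", "C", "D"}  # inactivated = TIV trio
        assert grouped["VO_9000003"] == {"E"}  # live attenuated = FluMist only

    def test_single_vaccine_identity(self, mini_ontology):
        grouped = sc.group_by_vaccine_class({"Fluzone": {"X"}}, mini_ontology, ["VO_9000004"])
        assert grouped == {"VO_9000004": {"X"}}

    def test_overlapping_classes_share_genes(self, mini_ontology):
        # FluMist is both trivalent and live attenuated
        grouped = sc.group_by_vaccine_class(
            {"FluMist": {"E"}}, mini_ontology, ["VO_0001236", "VO_9000003"]
        )
        assert grouped["VO_0001236"] == {"E"} and grouped["VO_9000003"] == {"E"}

    def test_unassigned_vaccine_warns(self, mini_ontology):
        with pytest.warns(UserWarning, match="Shingrix"):
            sc.group_by_vaccine_class({"Shingrix": {"Z"}}, mini_ontology, ["VO_9000003"])

    def test_overlap_counts_identical_sets(self):
        counts = sc.overlap_counts({"a": {1, 2}, "b": {1, 2}})
        assert counts[("a", "b")] == 2 and counts[("a",)] == 0 and counts[("b",)] == 0

    def test_overlap_counts_disjoint(self):
        counts = sc.overlap_counts({"a": {1}, "b": {2, 3}})
        assert counts[("a",)] == 1 and counts[("b",)] == 2 and counts[("a", "b")] == 0

    @pytest.mark.parametrize("seed", range(3))
    def test_overlap_counts_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        sets = {name: set(rng.choice(40, size=rng.integers(0, 25), replace=False)) for name in "abc"}
        counts = sc.overlap_counts(sets)
        assert len(counts) == 7
        assert sum(counts.values()) == len(sets["a"] | sets["b"] | sets["c"])
        for region, n in counts.items():
            members = set.intersection(*(sets[r] for r in region))
            for other in sets:
                if other not in region:
                    members -= sets[other]
            assert len(members) == n


class TestExport:
    def _result(self):
        matrix, pairs = random_matrix_and_pairs(7, n_genes=30)
        return sc.stimulated_genes(matrix, pairs, GeneFilterCriteria(min_subjects=2))

    def test_empty_result_header_only_csv(self, tmp_path):
        matrix, pairs = random_matrix_and_pairs(8, n_genes=5)
        result = sc.stimulated_genes(matrix, pairs, GeneFilterCriteria(min_log2_fc=50.0))
        path = sc.export_results(result, "csv", tmp_path / "out.csv")
        assert path.read_text().strip() == "gene,n_passing,mean_delta_log2"

    def test_csv_round_trip(self, tmp_path):
        result = self._result()
        path = sc.export_results(result, "csv", tmp_path / "out.csv")
        rows = read_results(path)
        assert [r["gene"] for r in rows] == result.stimulated
        for r in rows:
            assert r["n_passing"] == result.genes[r["gene"]].n_passing
            assert r["mean_delta_log2"] == pytest.approx(result.genes[r["gene"]].mean_delta)

    def test_json_matches_shipped_schema(self, tmp_path):
        result = self._result()
        path = sc.export_results(result, "json", tmp_path / "out.json")
        payload = json.loads(path.read_text())
        check_result_json(payload)  # structural check mirroring the shipped schema
        assert len(payload["stimulated_genes"]) == len(result.stimulated)
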