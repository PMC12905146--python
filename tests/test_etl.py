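import csv

import pytest

import seacdm as sc


@pytest.fixture(scope="module")
def viget_fixture(tmp_path_factory):
    out = tmp_path_factory.mktemp("viget")
    config = sc.SimConfig(seed=21, n_studies=3, subjects_per_study=5, days=(0, 7))
    meta, expr = sc.simulate_viget_files(config, out)
    return config, meta, expr


@pytest.fixture(scope="module")
def immport_fixture(tmp_path_factory):
    out = tmp_path_factory.mktemp("immport")
    config = sc.SimConfig(seed=22, n_studies=2, subjects_per_study=4, days=(0, 7))
    sc.simulate_immport_tables(config, out)
    return config, out


class TestVigetConnector:
    def test_study_and_sample_counts(self, registry, viget_fixture):
        config, meta, expr = viget_fixture
        bundle, matrix = sc.viget_to_bundle(meta, expr)
        assert bundle.n_records("Study") == config.n_studies
        n_expsamples = config.n_studies * config.subjects_per_study * len(config.days)
        exps = [r for r in bundle.tables["Sample"] if r["type"] == "expsample"]
        assert len(exps) == n_expsamples
        assert set(matrix.samples) == {r["expsample_reference_name"] for r in exps}

    def test_bundle_validates_and_documents_expression_file(self, registry, viget_fixture):
        _, meta, expr = viget_fixture
        bundle, _ = sc.viget_to_bundle(meta, expr)
        assert sc.validate_bundle(registry, bundle).ok
        docs = bundle.tables["Documentation"]
        assert any(str(expr) == d.get("path") for d in docs)

    def test_batch_flags_carried_into_matrix(self, viget_fixture):
        _, meta, expr = viget_fixture
        with open(meta, newline="") as fh:
            flagged = {
                r["expsample_reference_name"] for r in csv.DictReader(fh) if r["batch"] == "Yes"
            }
        _, matrix = sc.viget_to_bundle(meta, expr)
        assert {s for s in matrix.samples if matrix.is_batch(s)} == flagged

    def test_empty_metadata_warns(self, tmp_path, viget_fixture):
        _, _, expr = viget_fixture
        empty = tmp_path / "empty.csv"
        empty.write_text("study_id,subject_id,vaccine,day,expsample_reference_name,batch\n")
        with pytest.warns(UserWarning):
            bundle, _ = sc.viget_to_bundle(empty, expr)
        assert bundle.n_records("Study") == 0

    def test_ids_are_namespaced(self, viget_fixture):
        _, meta, expr = viget_fixture
        bundle, _ = sc.viget_to_bundle(meta, expr)
        assert all(r["study_id"].startswith("VIGET:") for r in bundle.tables["Study"])


class TestImmportConnector:
    def test_intervention_tables_concatenate(self, registry, tmp_path):
        # hand-built 2/3/4-row intervention-like tables
        cols = "intervention_id,subject_id,material\n"
        (tmp_path / "intervention.csv").write_text(cols + "i1,s1,flu\ni2,s1,flu\n")
        (tmp_path / "immune_exposure.csv").write_text(cols + "i3,s1,flu\ni4,s1,flu\ni5,s1,flu\n")
        (tmp_path / "treatment.csv").write_text(cols + "i6,s1,flu\ni7,s1,flu\ni8,s1,flu\ni9,s1,flu\n")
        (tmp_path / "subject.csv").write_text("subject_id\ns1\n")
        bundle = sc.immport_to_bundle(tmp_path)
        assert bundle.n_records("Intervention") == 9
        sources = {r["source_table"] for r in bundle.tables["Intervention"]}
        assert sources == {"intervention", "immune_exposure", "treatment"}

    def test_sample_type_flags(self, registry, immport_fixture):
        _, table_dir = immport_fixture
        bundle = sc.immport_to_bundle(table_dir)
        types = {r["type"] for r in bundle.tables["Sample"]}
        assert types <= {"biosample", "control", "expsample"}
        with open(table_dir / "expsample.csv", newline="") as fh:
            n_exp = len(list(csv.DictReader(fh)))
        assert sum(1 for r in bundle.tables["Sample"] if r["type"] == "expsample") == n_exp

    def test_assay_table_yields_one_assay_many_results(self, tmp_path):
        (tmp_path / "assay_elisa.csv").write_text(
            "result_id,datatype\n" + "".join(f"r{i},od\n" for i in range(5))
        )
        bundle = sc.immport_to_bundle(tmp_path)
        assert bundle.n_records("Assay") == 1
        assert bundle.n_records("Result") == 5
        assert len({r["assay_id"] for r in bundle.tables["Result"]}) == 1

    def test_key_collision_across_merged_tables(self, tmp_path):
        cols = "intervention_id,subject_id\n"
        (tmp_path / "intervention.csv").write_text(cols + "i1,s1\n")
        (tmp_path / "treatment.csv").write_text(cols + "i1,s1\n")
        with pytest.raises(ValueError, match="intervention.*treatment"):
            sc.immport_to_bundle(tmp_path)

    def test_row_conservation_and_validity(self, registry, immport_fixture):
        config, table_dir = immport_fixture
        bundle = sc.immport_to_bundle(table_dir)
        assert sc.validate_bundle(registry, bundle).ok
        n_int = 0
        for name in ("intervention", "immune_exposure", "treatment"):
            with open(table_dir / f"{name}.csv", newline="") as fh:
                n_int += len(list(csv.DictReader(fh)))
        assert bundle.n_records("Intervention") == n_int

    def test_zero_subjects_header_only(self, registry, tmp_path):
        sc.simulate_immport_tables(sc.SimConfig(seed=9, n_studies=0), tmp_path)
        assert (tmp_path / "intervention.csv").exists()
        bundle = sc.immport_to_bundle(tmp_path)
        assert bundle.n_records() == 0


class TestCellxgeneConnector:
    def test_exactly_common_variables_no_extended_rows(self, registry, tmp_path):
        obs = sc.simulate_cellxgene_obs(sc.SimConfig(seed=23, n_cells=8, extra_vars=0))
        bundle = sc.cellxgene_to_bundle(obs)
        sc.write_bundle(registry, bundle, tmp_path)
        with open(tmp_path / "extended_attribute.csv", newline="") as fh:
            assert len(list(csv.DictReader(fh))) == 0

    def test_author_variables_routed_to_extended(self, registry, tmp_path):
        n_cells, extra = 8, 7
        obs = sc.simulate_cellxgene_obs(sc.SimConfig(seed=23, n_cells=n_cells, extra_vars=extra))
        bundle = sc.cellxgene_to_bundle(obs)
        sc.write_bundle(registry, bundle, tmp_path)
        with open(tmp_path / "extended_attribute.csv", newline="") as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == n_cells * extra

    def test_common_variable_targets(self, registry):
        obs = sc.simulate_cellxgene_obs(sc.SimConfig(seed=24, n_cells=3))
        bundle = sc.cellxgene_to_bundle(obs)
        subj = bundle.tables["Subject"][0]
        assert subj["species"] == "Homo sapiens"
        assert subj["species_ontology_id"] == "NCBITaxon_9606"
        assert bundle.tables["Occurrence"][0]["disease"] == "influenza"
        assert bundle.tables["Result"][0]["cell_type"]
        assert sc.validate_bundle(registry, bundle).ok

    def test_missing_common_variable_warns_not_fails(self):
        obs = sc.simulate_cellxgene_obs(sc.SimConfig(seed=25, n_cells=3))
        obs = obs.drop(columns=["tissue", "tissue_ontology_id"])
        with pytest.warns(UserWarning, match="tissue"):
            bundle = sc.cellxgene_to_bundle(obs)
        assert all("biosample_source" not in r for r in bundle.tables["Sample"])

    def test_h5ad_path(self, registry, tmp_path):
        anndata = pytest.importorskip("anndata")
        import numpy as np

        obs = sc.simulate_cellxgene_obs(sc.SimConfig(seed=26, n_cells=5)).set_index(
            "observation_join_id"
        )
        adata = anndata.AnnData(X=np.zeros((5, 2)), obs=obs)
        path = tmp_path / "mini.h5ad"
        adata.write_h5ad(path)
        bundle = sc.cellxgene_to_bundle(str(path))
        assert bundle.n_records("Subject") == 5
        assert sc.validate_bundle(registry, bundle).ok


class TestMergedStores:
    def test_disjoint_namespaces_merge_into_one_store(self, registry, viget_fixture, immport_fixture):
        _, meta, expr = viget_fixture
        vb, _ = sc.viget_to_bundle(meta, expr)
        ib = sc.immport_to_bundle(immport_fixture[1])
        cb = sc.cellxgene_to_bundle(sc.simulate_cellxgene_obs(sc.SimConfig(seed=27, n_cells=5)))
        merged = sc.merge_bundles([vb, ib, cb])
        handle = sc.init_store(registry)
        counts = sc.load_bundle(handle, merged)
        assert counts["Sample"] == merged.n_records("Sample")
        handle.close()
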