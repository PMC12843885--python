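"""Synthetic-data generators: determinism, planted structure, round trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from teametab.binning import build_feature_matrix
from teametab.errors import InvalidDesignError
from teametab.formulas import consensus_classification
from teametab.synthetic import (
    BLACK_STAGES,
    SimulationConfig,
    black_config,
    green_config,
    simulate_compound_library,
    simulate_design,
    simulate_feature_matrix,
    simulate_knowledge_graph,
    simulate_spectra,
    write_dataset,
)


class TestDesign:
    def test_stage_replicate_counting(self):
        design = simulate_design(green_config(1, n_features=10, n_informative=0))
        assert (~design["is_qc"]).sum() == 18  # 6 stages x 3 reps

    def test_seed_determinism(self):
        a = simulate_design(green_config(5, n_features=10, n_informative=0))
        b = simulate_design(green_config(5, n_features=10, n_informative=0))
        pd.testing.assert_frame_equal(a, b)

    def test_black_template_stages_and_arms(self):
        design = simulate_design(black_config(1, n_features=10, n_informative=0))
        non_qc = design[~design["is_qc"]]
        assert set(non_qc["stage"]) == set(BLACK_STAGES)
        armed = non_qc[non_qc["arm"].notna()]
        assert set(armed["stage"]) == {"oxidation", "roasting"}
        assert set(armed["arm"]) == {"4h", "overnight"}
        # 5 shared stages x 3 + 2 stages x 2 arms x 3
        assert len(non_qc) == 5 * 3 + 2 * 2 * 3

    def test_too_few_replicates_error(self):
        with pytest.raises(InvalidDesignError):
            SimulationConfig(seed=1, replicates_per_stage=1)

    def test_weights_positive_and_dry_below_fresh(self):
        design = simulate_design(green_config(2, n_features=10, n_informative=0))
        non_qc = design[~design["is_qc"]]
        assert (non_qc["fresh_weight"] > 0).all()
        measured = non_qc[non_qc["dry_weight"].notna()]
        assert (measured["dry_weight"] <= measured["fresh_weight"]).all()


class TestFeatureMatrix:
    def test_zero_noise_stage_means_equal_template(self):
        cfg = green_config(
            3, n_features=40, n_informative=12, n_trend_clusters=3,
            noise_sigma=0.0, weight_effect=False, n_compounds=30,
        )
        design = simulate_design(cfg)
        matrix, truth = simulate_feature_matrix(cfg, design)
        stages = list(cfg.stages)
        for fid in truth.informative_feature_ids:
            cluster = truth.cluster_membership[fid]
            template = truth.trend_templates[cluster]
            sample_cols = {
                s: [f"{s}_r{r}" for r in range(1, 4)] for s in stages
            }
            means = np.array(
                [matrix.values.loc[fid, sample_cols[s]].mean() for s in stages]
            )
            assert np.allclose(means / means.sum(),
                               template / template.sum(), rtol=1e-9)

    def test_null_anova_calibration(self):
        """With no planted stage effect the per-feature ANOVA is uniform."""
        cfg = green_config(
            4, n_features=1000, n_informative=0, n_compounds=30,
            weight_effect=False, mapped_fraction=0.0,
        )
        design = simulate_design(cfg)
        matrix, _ = simulate_feature_matrix(cfg, design)
        non_qc = design[~design["is_qc"]]
        groups = [
            list(non_qc.loc[non_qc["stage"] == s, "sample_id"]) for s in cfg.stages
        ]
        log_values = np.log(matrix.values)
        pvals = np.array([
            stats.f_oneway(*[row[g].to_numpy() for g in groups]).pvalue
            for _, row in log_values.iterrows()
        ])
        frac = (pvals < 0.05).mean()
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / 1000)
        assert abs(frac - 0.05) <= half_width

    def test_more_clusters_than_informative_error(self):
        with pytest.raises(InvalidDesignError):
            SimulationConfig(seed=1, n_features=50, n_informative=2, n_trend_clusters=3)

    def test_values_positive(self):
        cfg = green_config(5, n_features=60, n_informative=10, n_compounds=30)
        matrix, _ = simulate_feature_matrix(cfg)
        assert (matrix.values.to_numpy() > 0).all()

    def test_determinism(self):
        cfg = green_config(6, n_features=60, n_informative=10, n_compounds=30)
        a, _ = simulate_feature_matrix(cfg)
        b, _ = simulate_feature_matrix(cfg)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestSpectra:
    def test_zero_jitter_roundtrip_exact(self):
        cfg = green_config(
            7, n_features=80, n_informative=10, ppm_jitter=0.0, n_compounds=30,
        )
        matrix, _ = simulate_feature_matrix(cfg)
        spectra = simulate_spectra(matrix, cfg)
        rebinned = build_feature_matrix(spectra)
        common = rebinned.values.reindex(
            index=matrix.values.index, columns=matrix.values.columns
        )
        assert rebinned.values.shape == matrix.values.shape
        rel = ((common - matrix.values).abs() / matrix.values).max().max()
        assert rel < 1e-9

    def test_jitter_scale_at_289(self):
        """3 ppm at m/z 289.07 is ~0.00087 Da of 1-sigma mass error."""
        cfg = green_config(8, n_features=5, n_informative=0, ppm_jitter=3.0,
                           n_scans=300, n_compounds=10, mapped_fraction=0.0)
        matrix, _ = simulate_feature_matrix(cfg)
        fid = matrix.feature_info.index[0]
        true_mz = matrix.feature_info.loc[fid, "accurate_mz"]
        with pytest.warns(UserWarning, match="bin boundaries"):
            spectra = simulate_spectra(matrix, cfg)
        sample = matrix.samples[0]
        polarity = matrix.feature_info.loc[fid, "polarity"]
        deltas = []
        for scan in spectra[sample]:
            if scan.polarity != polarity:
                continue
            i = int(np.argmin(np.abs(scan.mz - true_mz)))
            deltas.append(scan.mz[i] - true_mz)
        sigma_da = 3e-6 * true_mz
        observed = np.std(deltas)
        assert 0.6 * sigma_da < observed < 1.5 * sigma_da
        assert np.max(np.abs(deltas)) < 5 * sigma_da

    def test_polarity_partition(self):
        cfg = green_config(9, n_features=60, n_informative=0, ppm_jitter=0.0,
                           n_compounds=20)
        matrix, _ = simulate_feature_matrix(cfg)
        spectra = simulate_spectra(matrix, cfg)
        info = matrix.feature_info
        neg_mzs = set(np.round(info.loc[info["polarity"] == "negative", "accurate_mz"], 6))
        for scan in spectra[matrix.samples[0]]:
            if scan.polarity == "positive":
                assert not neg_mzs & set(np.round(scan.mz, 6))


class TestCompoundLibrary:
    def test_counts_and_tiers(self):
        cfg = green_config(10, n_features=50, n_informative=10, n_compounds=120)
        lib = simulate_compound_library(cfg)
        assert len(lib) == 120
        assert set(lib["tier"]) <= {"primary", "fallback"}
        assert (lib["tier"] == "primary").sum() + (lib["tier"] == "fallback").sum() == 120

    def test_depth_two_consensus_fixture(self):
        cfg = green_config(10, n_features=50, n_informative=10, n_compounds=120)
        lib = simulate_compound_library(cfg)
        counts = lib.groupby("formula").size()
        found = False
        for formula in counts[counts >= 3].index:
            paths = list(lib.loc[lib["formula"] == formula, "taxonomy_path"])
            if len(paths) == 3:
                _, depth = consensus_classification(paths, 0.66)
                if depth == 2:
                    found = True
        assert found

    def test_taxonomy_depth(self):
        cfg = green_config(10, n_features=50, n_informative=10, n_compounds=60)
        lib = simulate_compound_library(cfg)
        assert (lib["taxonomy_path"].str.count("/") >= 2).all()

    def test_seeded_regeneration_identical(self):
        cfg = green_config(12, n_features=50, n_informative=10, n_compounds=60)
        pd.testing.assert_frame_equal(
            simulate_compound_library(cfg), simulate_compound_library(cfg)
        )


class TestKnowledgeGraph:
    def test_node_type_counts(self):
        cfg = green_config(13, n_features=50, n_informative=10,
                           n_compounds=60, n_pathways=5)
        graph, planted = simulate_knowledge_graph(cfg)
        types = pd.Series([d["type"] for _, d in graph.nodes(data=True)])
        assert (types == "compound").sum() == 60
        assert (types == "pathway").sum() == 5
        assert planted == "PATH001"

    def test_planted_pathway_reachable(self):
        import networkx as nx

        cfg = green_config(13, n_features=50, n_informative=10,
                           n_compounds=60, n_pathways=5)
        graph, planted = simulate_knowledge_graph(cfg)
        lib = simulate_compound_library(cfg)
        planted_compounds = list(lib.loc[lib["planted"], "compound_id"])
        reachable = sum(
            nx.has_path(graph, c, planted) for c in planted_compounds
        )
        assert reachable / len(planted_compounds) >= 0.8

    def test_min_pathways(self):
        with pytest.raises(InvalidDesignError):
            simulate_knowledge_graph(
                green_config(1, n_features=10, n_informative=0, n_pathways=1)
            )


def test_write_dataset_files(tmp_path, small_dataset):
    write_dataset(small_dataset, tmp_path)
    for name in ("samples.tsv", "feature_matrix.tsv", "compounds.tsv",
                 "graph.tsv", "ground_truth.tsv", "config.yaml"):
        assert (tmp_path / name).exists()
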