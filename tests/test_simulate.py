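import networkx as nx
import numpy as np
import pandas as pd
import pytest

from blastnet import netsig, simulate
from blastnet.simulate import (
    BELOW_LOD,
    FlowMarkerModel,
    InvalidConfigError,
    MrdModel,
    PlantedNetwork,
    SimulationConfig,
)


class TestPpiGraph:
    def test_complete_graph_edge_count(self):
        cfg = SimulationConfig(n_proteins=10, edge_model="erdos_renyi", edge_density=1.0)
        graph = simulate.generate_ppi_graph(cfg)
        assert graph.number_of_edges() == 45

    def test_seed_determinism(self):
        cfgs = [SimulationConfig(seed=7), SimulationConfig(seed=7)]
        g1, g2 = (simulate.generate_ppi_graph(c) for c in cfgs)
        e1 = sorted((u, v, d["confidence"]) for u, v, d in g1.edges(data=True))
        e2 = sorted((u, v, d["confidence"]) for u, v, d in g2.edges(data=True))
        assert e1 == e2

    def test_point_mass_confidence_below_threshold_filters_everything(self):
        cfg = SimulationConfig(n_proteins=20, confidence_distribution=("point", 0.05))
        graph = simulate.generate_ppi_graph(cfg)
        assert graph.number_of_edges() > 0
        assert netsig.filter_graph(graph, 0.119).number_of_edges() == 0

    def test_confidences_in_unit_interval(self):
        graph = simulate.generate_ppi_graph(SimulationConfig(seed=3))
        conf = [d["confidence"] for _, _, d in graph.edges(data=True)]
        assert all(0.0 <= c <= 1.0 for c in conf)

    def test_invalid_size_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(n_proteins=1)


class TestExpression:
    def test_shape_contract(self):
        cfg = SimulationConfig(seed=1, n_genes=500, n_samples_a=10, n_samples_b=10)
        graph = simulate.generate_ppi_graph(cfg)
        matrix, labels, _ = simulate.generate_expression(cfg, graph)
        assert matrix.shape == (500, 20)
        assert len(labels) == 20
        assert labels.value_counts().to_dict() == {"A": 10, "B": 10}

    def test_planted_members_are_shifted_and_flagged(self, small_config):
        graph = simulate.generate_ppi_graph(small_config)
        seed_node = max(graph.degree, key=lambda kv: kv[1])[0]
        small_config.planted_networks = [PlantedNetwork(seed=seed_node, effect_log2=2.0)]
        matrix, labels, truth = simulate.generate_expression(small_config, graph)
        members = truth.planted_network_members[seed_node]
        assert truth.de_gene_flags[members].all()
        assert truth.de_gene_flags.sum() == len(members)
        diff = (
            matrix.loc[members, labels == "A"].mean(axis=1)
            - matrix.loc[members, labels == "B"].mean(axis=1)
        )
        assert (diff > 1.0).all()

    def test_absent_seed_raises_with_name(self, small_config):
        graph = simulate.generate_ppi_graph(small_config)
        small_config.planted_networks = [PlantedNetwork(seed="NOPE", effect_log2=1.0)]
        with pytest.raises(InvalidConfigError, match="NOPE"):
            simulate.generate_expression(small_config, graph)

    def test_bitwise_determinism(self, small_config):
        graph = simulate.generate_ppi_graph(small_config)
        m1, l1, _ = simulate.generate_expression(small_config, graph)
        m2, l2, _ = simulate.generate_expression(small_config, graph)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_series_equal(l1, l2)

    def test_probe_map_contains_duplicate_probe_gene(self, small_config):
        graph = simulate.generate_ppi_graph(small_config)
        _, _, truth = simulate.generate_expression(small_config, graph)
        counts = truth.probe_map.groupby("gene").size()
        assert (counts == 2).sum() == small_config.n_duplicate_probe_genes


class TestFlowCohort:
    def test_event_count_and_truth_passthrough(self):
        cfg = SimulationConfig(
            seed=2,
            n_events=50_000,
            n_flow_patients=1,
            flow_markers={
                "CD34": FlowMarkerModel(
                    means=(0.5, 2.5), sds=(0.15, 0.15), weights=(0.6, 0.4)
                )
            },
        )
        tables, truth = simulate.generate_flow_cohort(cfg)
        (table,) = tables.values()
        assert len(table) == 50_000
        rec = truth.flow_truth.iloc[0]
        assert rec["modality"] == "bimodal"
        assert rec["weights"] == "0.6000/0.4000"
        assert rec["overall_score"] == "-"  # dominant component is negative

    def test_sub_percent_component_marked_unimodal_in_truth(self):
        cfg = SimulationConfig(
            seed=2,
            n_flow_patients=1,
            n_events=1000,
            flow_markers={
                "CD34": FlowMarkerModel(
                    means=(0.5, 2.5), sds=(0.15, 0.15), weights=(0.995, 0.005)
                )
            },
        )
        _, truth = simulate.generate_flow_cohort(cfg)
        assert truth.flow_truth.iloc[0]["modality"] == "unimodal"

    def test_invalid_weights_rejected(self):
        with pytest.raises(InvalidConfigError, match="sum to 1"):
            FlowMarkerModel(means=(0.5, 2.5), sds=(0.2, 0.2), weights=(0.6, 0.3))


class TestPhlikeReference:
    def test_zero_positives_all_negative(self):
        cfg = SimulationConfig(seed=3, n_genes=300, phlike_signature_size=40)
        _, labels, _ = simulate.generate_phlike_reference(cfg, n_samples=30, n_positive=0)
        assert not labels.any()

    def test_label_determinism(self):
        cfg = SimulationConfig(seed=3, n_genes=300, phlike_signature_size=40)
        _, l1, _ = simulate.generate_phlike_reference(cfg, n_samples=30, n_positive=5)
        _, l2, _ = simulate.generate_phlike_reference(cfg, n_samples=30, n_positive=5)
        pd.testing.assert_series_equal(l1, l2)

    def test_too_many_positives_rejected(self):
        cfg = SimulationConfig(seed=3)
        with pytest.raises(InvalidConfigError):
            simulate.generate_phlike_reference(cfg, n_samples=10, n_positive=11)

    def test_signature_shift_follows_factor_sign(self):
        cfg = SimulationConfig(seed=4, n_genes=300, phlike_signature_size=40,
                               phlike_effect=2.0)
        sig = simulate.make_phlike_signature(cfg)
        matrix, labels, _ = simulate.generate_phlike_reference(
            cfg, sig, n_samples=60, n_positive=30
        )
        per_gene = sig.groupby("gene")["factor"].mean()
        diff = (
            matrix.loc[per_gene.index, labels].mean(axis=1)
            - matrix.loc[per_gene.index, ~labels].mean(axis=1)
        )
        assert (np.sign(diff) == np.sign(per_gene)).mean() > 0.95


class TestOutcomeCohort:
    def test_below_lod_sentinel_is_a_string_token(self):
        cfg = SimulationConfig(
            seed=5, n_patients=300,
            mrd_model=MrdModel(intercept_log10=-5.2, fold_effects={}, noise_sd_log10=0.5),
        )
        table, _ = simulate.generate_outcome_cohort(cfg)
        sentinels = table["mrd"].apply(lambda v: isinstance(v, str))
        assert sentinels.any()
        assert set(table.loc[sentinels, "mrd"]) == {BELOW_LOD}
        numeric = table.loc[~sentinels, "mrd"].astype(float)
        assert (numeric >= cfg.mrd_model.lod).all() and (numeric <= 1.0).all()

    def test_null_fold_effects_give_flat_groups(self):
        cfg = SimulationConfig(
            seed=6, n_patients=400,
            mrd_model=MrdModel(fold_effects={}, noise_sd_log10=0.5),
        )
        table, truth = simulate.generate_outcome_cohort(cfg)
        assert truth.mrd_fold_effects == {}
        from blastnet.outcome import censor_mrd

        y = np.log10(censor_mrd(list(table["mrd"])))
        means = pd.Series(y).groupby(table["CD34"].values).mean()
        assert means.max() - means.min() < 0.3

    def test_truth_records_configured_folds(self):
        cfg = SimulationConfig(seed=7)
        _, truth = simulate.generate_outcome_cohort(cfg)
        assert truth.mrd_fold_effects[("CD34", "++")] == pytest.approx(6.47)
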