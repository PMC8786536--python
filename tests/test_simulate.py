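"""Tests of the synthetic-data generator: determinism, bounds, planted
structure, and degenerate configurations."""

import numpy as np
import pytest

from epidriver import (
    SimulationConfig,
    plant_gene_labels,
    simulate_cohort,
    simulate_network,
    simulate_omics,
)
from epidriver.clinical import logrank_test


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_pairs": 0},
            {"n_ei": 1500, "n_es": 600},
            {"expr_effect": -1.0},
            {"meth_effect": -0.1},
            {"driver_wiring": 1.5},
            {"coupling": 2.0},
            {"meth_effect": 0.45},  # would push planted betas outside [0, 1]
            {"cohort_n": 2, "censor_horizon_months": -5},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_cohort_needs_two_patients(self):
        with pytest.raises(ValueError):
            simulate_cohort(SimulationConfig(cohort_n=1))


class TestDeterminism:
    def test_same_seed_reproduces_identical_outputs(self):
        cfg = SimulationConfig(seed=5, n_genes=80, n_ei=6, n_es=4,
                               network_nodes=200, cohort_n=40)
        a = simulate_omics(cfg)
        b = simulate_omics(cfg)
        assert a[0].values.equals(b[0].values)
        assert a[1].values.equals(b[1].values)
        assert a[4].gene_class == b[4].gene_class
        net_a = simulate_network(cfg, a[4])
        net_b = simulate_network(cfg, b[4])
        assert sorted(net_a.edges()) == sorted(net_b.edges())
        assert simulate_cohort(cfg).equals(simulate_cohort(cfg))

    def test_different_seeds_differ(self):
        a = simulate_omics(SimulationConfig(seed=1, n_genes=50, n_ei=5, n_es=5))
        b = simulate_omics(SimulationConfig(seed=2, n_genes=50, n_ei=5, n_es=5))
        assert not a[0].values.equals(b[0].values)


class TestOmicsStructure:
    def test_bounds_and_planted_effects(self, omics_bundle, default_config):
        expr, beta = omics_bundle["expr"], omics_bundle["beta"]
        labels = omics_bundle["labels"]
        arr = beta.values.to_numpy()
        assert arr.min() >= 0 and arr.max() <= 1
        assert (expr.values.to_numpy() > 0).all()

        log2 = np.log2(expr.values)
        shift = log2[expr.group_columns("tumor")].mean(axis=1) - log2[
            expr.group_columns("normal")
        ].mean(axis=1)
        ei, es = labels.ei_genes, labels.es_genes
        nulls = [g for g, c in labels.gene_class.items() if c == "null"]
        assert shift.loc[ei].mean() == pytest.approx(default_config.expr_effect, abs=0.2)
        assert shift.loc[es].mean() == pytest.approx(-default_config.expr_effect, abs=0.2)
        assert abs(shift.loc[nulls].mean()) < 0.05

    def test_probes_lie_inside_promoter_windows(self, omics_bundle):
        from epidriver.preprocess import map_probes_to_promoters

        mapping = map_probes_to_promoters(
            omics_bundle["annotations"], omics_bundle["genes"]
        )
        mapped = {p for probes in mapping.values() for p in probes}
        assert mapped == set(omics_bundle["annotations"])

    def test_planted_promoter_beta_shift(self, omics_bundle, default_config):
        from epidriver.preprocess import (
            aggregate_promoter_methylation,
            map_probes_to_promoters,
        )

        mapping = map_probes_to_promoters(
            omics_bundle["annotations"], omics_bundle["genes"]
        )
        meth = aggregate_promoter_methylation(omics_bundle["beta"], mapping)
        delta = meth.values[meth.group_columns("tumor")].mean(axis=1) - meth.values[
            meth.group_columns("normal")
        ].mean(axis=1)
        labels = omics_bundle["labels"]
        assert delta.loc[labels.ei_genes].mean() == pytest.approx(
            -default_config.meth_effect, abs=0.05
        )
        assert delta.loc[labels.es_genes].mean() == pytest.approx(
            default_config.meth_effect, abs=0.05
        )

    def test_zero_effect_null_keeps_false_calls_below_fdr(self):
        from epidriver.differential import (
            call_differential_expression,
            call_differential_methylation,
            classify_ei_es,
        )
        from epidriver.preprocess import (
            aggregate_promoter_methylation,
            map_probes_to_promoters,
        )

        cfg = SimulationConfig(seed=21, expr_effect=0.0, meth_effect=0.0, coupling=0.0)
        expr, beta, annotations, genes, _ = simulate_omics(cfg)
        de = call_differential_expression(expr)
        meth = aggregate_promoter_methylation(
            beta, map_probes_to_promoters(annotations, genes)
        )
        dm = call_differential_methylation(meth)
        calls = classify_ei_es(de, dm)
        frac = np.mean([c.epigenetic_class != "none" for c in calls.values()])
        assert frac <= 0.05

    def test_recall_monotone_in_effect_size(self):
        from epidriver.differential import (
            call_differential_expression,
            call_differential_methylation,
            classify_ei_es,
        )
        from epidriver.preprocess import (
            aggregate_promoter_methylation,
            map_probes_to_promoters,
        )

        recalls = []
        for effect in (0.0, 1.0, 2.0):
            cfg = SimulationConfig(
                seed=31, n_genes=400, n_ei=30, n_es=15,
                expr_effect=effect, meth_effect=0.15 * effect,
            )
            expr, beta, annotations, genes, labels = simulate_omics(cfg)
            de = call_differential_expression(expr)
            meth = aggregate_promoter_methylation(
                beta, map_probes_to_promoters(annotations, genes)
            )
            dm = call_differential_methylation(meth)
            calls = classify_ei_es(de, dm)
            planted = set(labels.ei_genes) | set(labels.es_genes)
            hit = sum(
                calls[g].epigenetic_class == labels.gene_class[g] for g in planted
            )
            recalls.append(hit / len(planted))
        assert recalls[0] <= recalls[1] <= recalls[2]


class TestNetworkStructure:
    def test_simple_graph_and_handshake(self, network_bundle):
        net = network_bundle["net"]
        assert nx_selfloops(net) == 0
        assert sum(d for _, d in net.degree()) == 2 * net.number_of_edges()

    def test_driver_neighborhoods_reach_wiring_fraction(
        self, network_bundle, default_config
    ):
        net, labels = network_bundle["net"], network_bundle["labels"]
        eies = set(labels.ei_genes) | set(labels.es_genes)
        for d in labels.driver_genes:
            nb = set(net.neighbors(d))
            frac = len(nb & eies) / len(nb)
            assert frac == pytest.approx(default_config.driver_wiring, abs=0.1)

    def test_null_wiring_matches_global_fraction(self):
        cfg = SimulationConfig(seed=9, driver_wiring=0.0)
        labels = plant_gene_labels(cfg)
        net = simulate_network(cfg, labels)
        eies = set(labels.ei_genes) | set(labels.es_genes)
        global_frac = len(eies) / net.number_of_nodes()
        fracs = []
        for d in labels.driver_genes:
            nb = set(net.neighbors(d))
            fracs.append(len(nb & eies) / len(nb))
        assert np.mean(fracs) == pytest.approx(global_frac, abs=0.08)

    def test_network_nodes_must_cover_planted_genes(self):
        cfg = SimulationConfig(seed=1, n_genes=100, n_ei=10, n_es=5, network_nodes=50)
        labels = plant_gene_labels(cfg)
        net = simulate_network(cfg, labels)  # 50 >= 15 planted: all present
        assert all(net.has_node(g) for g in labels.ei_genes + labels.es_genes)
        too_small = SimulationConfig(seed=1, n_genes=100, n_ei=10, n_es=5, network_nodes=10)
        with pytest.raises(ValueError):
            simulate_network(too_small, labels)


class TestCohort:
    def test_scores_and_labels_consistent(self, cohort):
        assert cohort["staining_score"].isin([1, 2, 3, 4]).all()
        low = cohort["staining_score"] <= 2
        assert (cohort.loc[low, "marker_level"] == "low").all()
        assert (cohort.loc[~low, "marker_level"] == "high").all()
        assert (cohort["time"] >= 0).all()
        assert cohort["event"].isin([0, 1]).all()

    def test_planted_hazard_separates_survival(self, cohort):
        res = logrank_test(cohort["time"], cohort["event"], cohort["marker_level"])
        assert res.p_value < 0.01

    def test_stage_association_with_marker(self, cohort):
        late_high = cohort.loc[cohort.marker_true == 1, "tnm_late"].mean()
        late_low = cohort.loc[cohort.marker_true == 0, "tnm_late"].mean()
        assert late_high > late_low

    def test_all_marker_low_degenerate_group_refused_downstream(self):
        cfg = SimulationConfig(seed=3, marker_prevalence=0.0, cohort_n=30)
        coh = simulate_cohort(cfg)
        assert (coh["marker_level"] == "low").all()
        with pytest.raises(ValueError):
            logrank_test(coh["time"], coh["event"], coh["marker_level"])


def nx_selfloops(net):
    import networkx as nx

    return nx.number_of_selfloops(net)
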