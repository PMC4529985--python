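"""Generator determinism, planted effect sizes, and ground-truth structure."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from proteoscreen import (
    SimulationConfig,
    generate_annotations,
    generate_expression,
    generate_network,
    generate_proteomics,
    min_hypergeom,
    partners,
)


class TestSimulationConfig:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_genes", 0),
            ("n_replicates", 0),
            ("n_specific", -1),
            ("specific_fc", 0.5),
            ("shared_fc", 0.0),
            ("noise_sd", 0.0),
            ("proteome_coverage", 1.5),
            ("peptide_count_range", (0, 5)),
        ],
    )
    def test_invalid_fields_named_in_error(self, field, value):
        with pytest.raises(ValueError, match=field.split("_")[0]):
            SimulationConfig(**{field: value})

    def test_planted_counts_bounded_by_universe(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=10, n_specific=6, n_shared=5)


class TestGenerateExpression:
    def test_determinism_field_for_field(self):
        cfg = SimulationConfig(n_genes=50, seed=7)
        e1, t1 = generate_expression(cfg)
        e2, t2 = generate_expression(cfg)
        pd.testing.assert_frame_equal(e1.values, e2.values)
        assert t1.specific_genes == t2.specific_genes
        pd.testing.assert_frame_equal(t1.true_fc, t2.true_fc)

    def test_truth_partitions_universe(self):
        _, truth = generate_expression(SimulationConfig(n_genes=40, n_specific=5, n_shared=7))
        parts = [set(truth.specific_genes), set(truth.shared_genes), set(truth.null_genes)]
        assert sum(len(p) for p in parts) == 40
        assert set.union(*parts) == set(truth.all_genes)
        assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])

    def test_null_design_has_equal_condition_means(self):
        cfg = SimulationConfig(n_genes=30, n_specific=0, n_shared=0, noise_sd=1e-9, seed=1)
        expr, truth = generate_expression(cfg)
        assert (truth.true_fc == 1.0).all().all()
        means = expr.values.T.groupby(expr.conditions).mean().T
        assert np.allclose(means.to_numpy(), means.to_numpy()[:, [0]], rtol=1e-6)

    def test_intensities_positive_and_lognormal(self):
        cfg = SimulationConfig(n_genes=2000, n_specific=0, n_shared=0, seed=3)
        expr, _ = generate_expression(cfg)
        vals = expr.values.to_numpy()
        assert (vals > 0).all()
        # Log-intensities of null genes pass a normality sanity check.
        logs = np.log(vals[:, 0])
        assert stats.normaltest(logs).pvalue > 0.01

    def test_monte_carlo_specific_fold_change(self):
        # Empirical treatment/control fold change of specific genes within
        # 10% of the planted 2.2 over replicated draws.
        fcs = []
        for seed in range(10):
            cfg = SimulationConfig(
                n_genes=500, n_specific=10, n_shared=0, specific_fc=2.2,
                noise_sd=0.1, seed=seed,
            )
            expr, truth = generate_expression(cfg)
            t = expr.values.loc[truth.specific_genes, expr.samples_of("LPON")].mean(axis=1)
            c = expr.values.loc[truth.specific_genes, expr.samples_of("control")].mean(axis=1)
            fcs.extend((t / c).tolist())
        assert abs(np.mean(fcs) - 2.2) / 2.2 < 0.10


class TestGenerateProteomics:
    def test_coverage_extremes(self):
        cfg1 = SimulationConfig(n_genes=30, proteome_coverage=1.0, seed=2)
        _, truth = generate_expression(cfg1)
        table = generate_proteomics(cfg1, truth)
        assert len(table) == 30 and set(table["gene_symbol"]) == set(truth.all_genes)
        cfg0 = SimulationConfig(n_genes=30, proteome_coverage=0.0, seed=2)
        assert generate_proteomics(cfg0, truth).empty

    def test_determinism_and_peptide_range(self):
        cfg = SimulationConfig(n_genes=40, peptide_count_range=(2, 6), seed=9)
        _, truth = generate_expression(cfg)
        t1 = generate_proteomics(cfg, truth)
        t2 = generate_proteomics(cfg, truth)
        pd.testing.assert_frame_equal(t1, t2)
        assert t1["unique_peptides"].between(2, 6).all()

    def test_monte_carlo_protein_ratio(self):
        ratios = []
        for seed in range(10):
            cfg = SimulationConfig(n_genes=200, n_specific=10, n_shared=0, noise_sd=0.1, seed=seed)
            expr, truth = generate_expression(cfg)
            table = generate_proteomics(cfg, truth).set_index("gene_symbol")
            t_cols = expr.samples_of("LPON")
            c_cols = expr.samples_of("control")
            sub = table.loc[truth.specific_genes]
            ratios.extend((sub[t_cols].mean(axis=1) / sub[c_cols].mean(axis=1)).tolist())
        assert abs(np.mean(ratios) - 2.2) / 2.2 < 0.10


class TestGenerateNetwork:
    def test_partner_counts_and_decoy_invisibility(self):
        cfg = SimulationConfig(n_genes=200, n_specific=2, n_shared=0, seed=4)
        _, truth = generate_expression(cfg)
        net = generate_network(truth, partners_per_candidate=32, decoy_edges=0, seed=4)
        noisy = generate_network(truth, partners_per_candidate=32, decoy_edges=100, seed=4)
        for cand in truth.specific_genes:
            assert len(partners(net, cand)) == 32
            assert partners(noisy, cand) == partners(net, cand)
        assert noisy.n_edges == net.n_edges + 100

    def test_isolated_candidate_and_validation(self):
        cfg = SimulationConfig(n_genes=50, n_specific=1, n_shared=0, seed=5)
        _, truth = generate_expression(cfg)
        net = generate_network(truth, partners_per_candidate=0, decoy_edges=0, seed=5)
        assert partners(net, truth.specific_genes[0]) == set()
        with pytest.raises(ValueError):
            generate_network(truth, partners_per_candidate=-1)

    def test_determinism(self):
        cfg = SimulationConfig(n_genes=100, n_specific=3, n_shared=0, seed=6)
        _, truth = generate_expression(cfg)
        n1 = generate_network(truth, seed=6)
        n2 = generate_network(truth, seed=6)
        assert set(n1.graph.edges(data="score")) == set(n2.graph.edges(data="score"))


class TestGenerateAnnotations:
    def test_empty_and_planted_term(self):
        genes = [f"g{i}" for i in range(33)]
        assert generate_annotations(genes, n_terms=0, seed=1) == {}
        ann = generate_annotations(genes, n_terms=5, seed=1, enriched_genes=genes[:3])
        assert ann["TERM_ENRICHED"] == set(genes[:3])

    def test_planted_tuple_closed_form_p(self):
        # A term covering exactly the top 3 of a 33-gene ranked list gives
        # the closed-form minimum tail 1/C(33,3).
        genes = [f"g{i:02d}" for i in range(33)]
        ann = generate_annotations(genes, n_terms=0, seed=2, enriched_genes=genes[:3])
        flags = [g in ann["TERM_ENRICHED"] for g in genes]
        n, b, p = min_hypergeom(flags)
        assert (n, b) == (3, 3)
        assert p == pytest.approx(1 / comb(33, 3), rel=1e-12)

    def test_term_sizes_validated(self):
        with pytest.raises(ValueError):
            generate_annotations(["a", "b"], n_terms=2, term_size_range=(3, 5), seed=0)
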