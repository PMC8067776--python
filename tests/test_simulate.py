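import math

import numpy as np
import pytest

from cerna.expression import coexpression_filter, filter_expressed, spearman
from cerna.interactions import mirna_universe
from cerna.screen import screen_pairs
from cerna.simulate import (
    SimConfig,
    evaluate_recovery,
    read_truth,
    rho_spearman_to_pearson,
    simulate_expression,
    simulate_interactions,
    study_scale_config,
    write_simulation,
    write_truth,
)


class TestSimulateInteractions:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(seed=42, n_mirna=60, n_lnc=10, n_mrna=30, n_planted=5)
        a = simulate_interactions(cfg)
        b = simulate_interactions(cfg)
        assert a[0].entries == b[0].entries
        assert a[1].entries == b[1].entries
        assert a[2] == b[2]

    def test_planted_pairs_share_at_least_planted_shared(self):
        cfg = SimConfig(n_mirna=80, n_lnc=12, n_mrna=40, n_planted=8, planted_shared=6)
        lnc, mrna, truth = simulate_interactions(cfg)
        assert len(truth.planted_pairs) == 8
        for pair in truth.planted_pairs:
            overlap = lnc.entries[pair.lnc_id] & mrna.entries[pair.mrna_id]
            assert pair.shared_mirna_ids <= overlap
            assert len(overlap) >= 6

    def test_no_planting_gives_empty_truth(self):
        cfg = SimConfig(n_planted=0)
        _, _, truth = simulate_interactions(cfg)
        assert truth.planted_pairs == ()

    def test_target_set_sizes_within_law_bounds(self):
        cfg = SimConfig(n_mirna=100, n_lnc=20, n_mrna=50, n_planted=0,
                        target_min=5)
        lnc, mrna, _ = simulate_interactions(cfg)
        for tmap in (lnc, mrna):
            for targets in tmap.entries.values():
                assert 5 <= len(targets) <= 50

    def test_hub_planting_concentrates_pairs_on_one_lncrna(self):
        cfg = SimConfig(n_planted=20, hub_lnc_pairs=15)
        _, _, truth = simulate_interactions(cfg)
        assert len(truth.hub_ids) == 1
        hub = truth.hub_ids[0]
        assert sum(p.lnc_id == hub for p in truth.planted_pairs) >= 15

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_mirna=4, planted_shared=6)


class TestCopula:
    def test_conversion_is_odd_and_increasing(self):
        assert rho_spearman_to_pearson(0.0) == 0.0
        assert rho_spearman_to_pearson(-0.5) == -rho_spearman_to_pearson(0.5)
        grid = [rho_spearman_to_pearson(r) for r in np.linspace(-0.95, 0.95, 20)]
        assert all(a < b for a, b in zip(grid, grid[1:]))

    def test_worked_value(self):
        assert rho_spearman_to_pearson(0.85) == pytest.approx(
            2 * math.sin(math.pi * 0.85 / 6), abs=1e-15
        )
        assert rho_spearman_to_pearson(0.85) == pytest.approx(0.861, abs=5e-4)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            rho_spearman_to_pearson(1.0)

    @pytest.mark.parametrize("rho_target", [0.3, 0.6, 0.85])
    def test_empirical_spearman_matches_target_at_large_n(self, rho_target):
        cfg = SimConfig(
            n_mirna=30, n_lnc=2, n_mrna=5, n_planted=1, planted_shared=3,
            planted_rho=rho_target, groups=(("g", 2000),), seed=7,
        )
        _, _, truth = simulate_interactions(cfg)
        matrix, _ = simulate_expression(cfg, truth)
        pair = truth.planted_pairs[0]
        rho = spearman(
            matrix.values.loc[pair.lnc_id], matrix.values.loc[pair.mrna_id]
        ).rho
        assert rho == pytest.approx(rho_target, abs=0.04)


class TestSimulateExpression:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_mirna=40, n_lnc=5, n_mrna=10, n_planted=2, planted_shared=3,
                        groups=(("a", 6), ("b", 5)))
        _, _, truth = simulate_interactions(cfg)
        m1, l1 = simulate_expression(cfg, truth)
        m2, l2 = simulate_expression(cfg, truth)
        assert m1.values.equals(m2.values) and l1 == l2

    def test_group_labels_cover_all_samples(self):
        cfg = SimConfig(n_mirna=40, n_lnc=5, n_mrna=10, n_planted=0,
                        groups=(("ALS", 7), ("control", 4)))
        _, _, truth = simulate_interactions(cfg)
        matrix, labels = simulate_expression(cfg, truth)
        assert set(labels) == set(matrix.sample_ids)
        assert sorted(set(labels.values())) == ["ALS", "control"]
        assert sum(g == "ALS" for g in labels.values()) == 7

    def test_unplanted_pair_uncorrelated_at_large_n(self):
        cfg = SimConfig(n_mirna=30, n_lnc=3, n_mrna=6, n_planted=0,
                        groups=(("g", 1000),), seed=7)
        _, _, truth = simulate_interactions(cfg)
        matrix, _ = simulate_expression(cfg, truth)
        rho = spearman(matrix.values.iloc[0], matrix.values.iloc[3]).rho
        assert abs(rho) < 0.1

    def test_dropout_fails_expression_filter_for_some_genes(self):
        cfg = SimConfig(n_mirna=40, n_lnc=10, n_mrna=30, n_planted=0,
                        dropout_rate=0.6, groups=(("g", 11),))
        _, _, truth = simulate_interactions(cfg)
        matrix, _ = simulate_expression(cfg, truth)
        # independent count of genes nonzero in more than half the samples
        nonzero = (matrix.values.to_numpy() > 0).sum(axis=1)
        expected_kept = int((nonzero > 5.5).sum())
        kept = filter_expressed(matrix)
        assert len(kept.gene_ids) == expected_kept
        assert expected_kept < len(matrix.gene_ids)

    def test_marginal_transform_preserves_spearman(self):
        rng = np.random.default_rng(11)
        x, y = rng.standard_normal(200), rng.standard_normal(200)
        base = spearman(x, y).rho
        lifted = spearman(np.exp(3 + x), np.exp(3 + y)).rho
        assert lifted == pytest.approx(base, abs=1e-12)


class TestEvaluateRecovery:
    def _edges_for(self, pairs, group="g"):
        from cerna.expression import CoexpressionResult

        return [
            CoexpressionResult(
                lnc_id=l, mrna_id=m, group=group, rho=0.9, p_value=0.001,
                n_samples=10, method="asymptotic_t",
            )
            for l, m in pairs
        ]

    def _truth_for(self, pairs):
        from cerna.simulate import PlantedPair, SyntheticTruth

        return SyntheticTruth(
            planted_pairs=tuple(
                PlantedPair(l, m, frozenset({"m1"}), 0.85) for l, m in pairs
            )
        )

    def test_perfect_recovery(self):
        pairs = [("L1", "G1"), ("L2", "G2")]
        rec = evaluate_recovery(self._edges_for(pairs), self._truth_for(pairs))
        assert rec.sensitivity == 1.0 and rec.precision == 1.0

    def test_empty_retained_has_na_precision(self):
        rec = evaluate_recovery([], self._truth_for([("L1", "G1")]))
        assert rec.sensitivity == 0.0 and rec.precision is None

    def test_half_recovered_no_false_positives(self):
        planted = [(f"L{i}", f"G{i}") for i in range(10)]
        rec = evaluate_recovery(self._edges_for(planted[:5]), self._truth_for(planted))
        assert rec.sensitivity == 0.5 and rec.precision == 1.0
        assert rec.table["recovered"].sum() == 5

    def test_false_positives_lower_precision(self):
        planted = [("L1", "G1")]
        retained = [("L1", "G1"), ("L9", "G9")]
        rec = evaluate_recovery(self._edges_for(retained), self._truth_for(planted))
        assert rec.precision == 0.5 and rec.n_false_positive == 1


class TestSimulationIO:
    def test_truth_roundtrip(self, tmp_path):
        cfg = SimConfig(n_mirna=50, n_lnc=8, n_mrna=20, n_planted=4, planted_shared=3)
        _, _, truth = simulate_interactions(cfg)
        path = tmp_path / "truth.tsv"
        write_truth(truth, path)
        back = read_truth(path)
        assert back.pair_set() == truth.pair_set()
        assert {p.shared_mirna_ids for p in back.planted_pairs} == {
            p.shared_mirna_ids for p in truth.planted_pairs
        }

    def test_written_dataset_flows_through_pipeline_stages(self, tmp_path):
        from cerna.expression import read_expression, read_group_labels
        from cerna.interactions import read_interactions

        cfg = SimConfig(n_mirna=60, n_lnc=8, n_mrna=25, n_planted=4,
                        groups=(("a", 12), ("b", 12)))
        paths = write_simulation(cfg, tmp_path)
        lnc = read_interactions(paths["lnc_mirna"], "lncRNA")
        mrna = read_interactions(paths["mrna_mirna"], "mRNA")
        uni = mirna_universe(lnc, mrna)
        pairs, _ = screen_pairs(lnc, mrna, uni)
        matrix = read_expression(paths["expression"])
        labels = read_group_labels(paths["labels"])
        edges = coexpression_filter(pairs, filter_expressed(matrix), labels)
        rec = evaluate_recovery(edges, read_truth(paths["truth"]))
        assert rec.n_planted == 4
        assert rec.sensitivity > 0

    def test_study_scale_config_group_sizes(self):
        cfg = study_scale_config()
        assert cfg.groups == (("ALS", 7), ("control", 4))
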