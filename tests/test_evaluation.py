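import numpy as np
import pandas as pd
import pytest

from bowtie_grn.core_model import EvaluationCounts, GoldStandard, ScoredNetwork, ValidationError
from bowtie_grn.evaluation import (
    aufe,
    double_edge_swap,
    naive_expected_precision,
    per_regulator_pfe,
    pfe,
    pfe_survival_curve,
    precision_accuracy_aupr,
    zscore_vs_random,
)
from bowtie_grn.synthetic_data import PRESETS, make_bowtie_grn, sample_gold_standard


class TestPfe:
    def test_arithmetic(self):
        assert pfe(EvaluationCounts(p=5, n=10, k=20, K=200)) == pytest.approx(5.0)

    def test_random_level_is_one(self):
        assert pfe(EvaluationCounts(p=1, n=10, k=10, K=100)) == pytest.approx(1.0)

    def test_saturated_gold_standard_is_one(self):
        assert pfe(EvaluationCounts(p=7, n=7, k=50, K=50)) == pytest.approx(1.0)

    def test_no_predictions_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="predicted nothing"):
            assert pfe(EvaluationCounts(p=0, n=0, k=5, K=50)) == 0.0

    def test_random_prediction_concentrates_at_one(self):
        rng = np.random.default_rng(0)
        R, T, n_pred = 50, 100, 1000
        K = R * T
        slots = [(f"r{i}", f"t{j}") for i in range(R) for j in range(T)]
        positives = {slots[i] for i in rng.choice(K, size=500, replace=False)}
        gs = GoldStandard(positives, {f"r{i}" for i in range(R)}, {f"t{j}" for j in range(T)})
        values = []
        for _ in range(100):
            pred = {slots[i] for i in rng.choice(K, size=n_pred, replace=False)}
            p = len(pred & positives)
            values.append(pfe(EvaluationCounts(p=p, n=n_pred, k=500, K=K)))
        assert abs(np.mean(values) - 1.0) < 0.1


class TestNaivePrecision:
    def test_boundaries(self):
        assert naive_expected_precision(0, 10, 10) == 0.0
        assert naive_expected_precision(100, 10, 10) == 1.0

    def test_overfull_network_rejected(self):
        with pytest.raises(ValidationError):
            naive_expected_precision(101, 10, 10)


class TestPerRegulatorPfe:
    def _gs(self):
        return GoldStandard(
            positives={("r", "t1"), ("r", "t2")},
            regulator_universe={"r"},
            target_universe={f"t{i}" for i in range(1, 11)},
        )

    def test_perfect_prediction_hits_maximum(self):
        net = ScoredNetwork.from_edges([("r", "t1"), ("r", "t2")])
        result = per_regulator_pfe(net, self._gs())
        assert result["r"] == pytest.approx(10 / 2)  # K_r / k_r

    def test_predicting_everything_gives_one(self):
        net = ScoredNetwork.from_edges([("r", f"t{i}") for i in range(1, 11)])
        assert per_regulator_pfe(net, self._gs())["r"] == pytest.approx(1.0)

    def test_absent_regulator_scores_zero(self):
        net = ScoredNetwork.from_edges([("other", "t1")])
        assert per_regulator_pfe(net, self._gs())["r"] == 0.0


class TestAufe:
    def test_two_regulator_survival_case(self):
        pfe_max = 7.3
        assert aufe([0.0, pfe_max]) == pytest.approx(pfe_max / 2)

    def test_all_equal_case(self):
        assert aufe([2.5, 2.5, 2.5]) == pytest.approx(2.5)

    def test_mean_oracle(self):
        assert aufe([1, 2, 3]) == pytest.approx(2.0)

    def test_equals_survival_integral(self):
        rng = np.random.default_rng(9)
        values = rng.exponential(2.0, size=50)
        curve = pfe_survival_curve(values)
        assert curve["fraction_ge"].iloc[0] == 1.0
        # dense-grid integral of the survival function equals the mean
        grid = np.linspace(0, values.max(), 20001)
        surv = [(values >= x).mean() for x in grid]
        assert np.trapezoid(surv, grid) == pytest.approx(aufe(values), rel=1e-3)


class TestPrecisionAccuracyAupr:
    def _table(self):
        return pd.DataFrame(
            {
                "regulator": ["r"] * 4,
                "target": ["t1", "t2", "t3", "t4"],
                "pcc": [0.9, 0.8, 0.3, -0.9],
            }
        )

    def test_hand_confusion_matrix(self):
        nets = [ScoredNetwork.from_edges([("r", "t1"), ("r", "t4")])]
        precision, accuracy, _ = precision_accuracy_aupr(nets, self._table(), cutoff=0.75)
        assert precision == pytest.approx(1.0)
        assert accuracy == pytest.approx(0.75)  # t2 positive but unpredicted

    def test_no_predicted_pairs(self):
        nets = [ScoredNetwork.from_edges([("x", "y")])]
        with pytest.warns(UserWarning, match="precision"):
            precision, accuracy, _ = precision_accuracy_aupr(nets, self._table(), 0.75)
        assert precision == 0.0
        assert accuracy == pytest.approx(0.25)  # only t3 is a true negative

    def test_cutoff_zero_all_positive(self):
        nets = [ScoredNetwork.from_edges([("r", "t3")])]
        precision, _, _ = precision_accuracy_aupr(nets, self._table(), cutoff=0.0)
        assert precision == 1.0

    def test_cutoff_out_of_range(self):
        with pytest.raises(ValidationError):
            precision_accuracy_aupr([], self._table(), cutoff=1.5)


class TestDoubleEdgeSwap:
    def test_degree_sequences_preserved(self):
        rng = np.random.default_rng(1)
        pairs = sorted({(f"r{rng.integers(10)}", f"t{rng.integers(20)}") for _ in range(60)})
        net = ScoredNetwork.from_edges(pairs)
        for seed in range(5):
            swapped = double_edge_swap(net, n_swaps=120, seed=seed)
            for axis in ("regulator", "target"):
                assert sorted(net.edges[axis].value_counts()) == sorted(
                    swapped.edges[axis].value_counts()
                )

    def test_single_edge_unchanged(self):
        net = ScoredNetwork.from_edges([("a", "b")])
        assert double_edge_swap(net, 10, seed=0).edge_set() == {("a", "b")}

    def test_two_edge_forced_swap(self):
        net = ScoredNetwork.from_edges([("a", "b"), ("c", "d")])
        swapped = double_edge_swap(net, n_swaps=1, seed=3)
        assert swapped.edge_set() == {("a", "d"), ("c", "b")}

    def test_rewiring_degrades_planted_network_pfe(self):
        from bowtie_grn.evaluation import network_counts

        world = make_bowtie_grn(**PRESETS["bowtie-small"], seed=5)
        gs = sample_gold_standard(world, n_regulators=20, seed=5)
        truth_pfe = pfe(network_counts(world.truth, gs))
        for seed in range(1, 6):
            swapped = double_edge_swap(world.truth, n_swaps=10 * world.truth.n_edges, seed=seed)
            assert truth_pfe >= pfe(network_counts(swapped, gs))


class TestZscore:
    def test_reference_points(self):
        assert zscore_vs_random(0.2, [0.1, 0.2, 0.3]) == pytest.approx(0.0)
        assert zscore_vs_random(0.3, [0.1, 0.2, 0.3]) == pytest.approx(1.0)
        assert zscore_vs_random(0.5, [0.1, 0.2, 0.3]) == pytest.approx(3.0)

    def test_zero_spread_sentinel(self):
        with pytest.warns(UserWarning, match="zero spread"):
            assert zscore_vs_random(1.0, [0.5, 0.5]) == np.inf


class TestRewiringZscores:
    def test_accuracy_signal_and_precision_null(self):
        """A planted-truth network beats rewired replicas on accuracy; a
        density-matched random network's precision is at chance level."""
        rng = np.random.default_rng(21)
        world = make_bowtie_grn(**PRESETS["bowtie-small"], seed=21)
        truth = world.truth
        genes = world.genes
        true_set = truth.edge_set()
        # knockdown-style test table: strong PCC on true edges, weak otherwise
        tested = list(true_set)[:60]
        non_edges = []
        while len(non_edges) < 60:
            r, t = rng.choice(genes, 2, replace=False)
            if (r, t) not in true_set:
                non_edges.append((r, t))
        table = pd.DataFrame(
            {
                "regulator": [p[0] for p in tested + non_edges],
                "target": [p[1] for p in tested + non_edges],
                "pcc": np.concatenate(
                    [rng.uniform(0.8, 1.0, len(tested)), rng.uniform(0.0, 0.5, len(non_edges))]
                ),
            }
        )
        _, acc_obs, _ = precision_accuracy_aupr([truth], table)
        acc_null = []
        for s in range(30):
            rewired = double_edge_swap(truth, n_swaps=5 * truth.n_edges, seed=s)
            _, a, _ = precision_accuracy_aupr([rewired], table)
            acc_null.append(a)
        assert zscore_vs_random(acc_obs, acc_null) > 3.0

        # density-matched random network: precision Z ~ 0 vs its own rewirings
        n_rand = len(true_set)
        all_pairs = [(r, t) for r in genes for t in genes if r != t]
        rand_idx = rng.choice(len(all_pairs), size=n_rand, replace=False)
        rand_net = ScoredNetwork.from_edges([all_pairs[i] for i in rand_idx])
        prec_obs, _, _ = precision_accuracy_aupr([rand_net], table)
        prec_null = []
        for s in range(30):
            rewired = double_edge_swap(rand_net, n_swaps=5 * n_rand, seed=100 + s)
            p, _, _ = precision_accuracy_aupr([rewired], table)
            prec_null.append(p)
        assert abs(zscore_vs_random(prec_obs, prec_null)) < 3.0
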