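import numpy as np
import pandas as pd
import pytest

from bowtie_grn.core_model import DETable, ModulePartition, ScoredNetwork, ValidationError
from bowtie_grn.structure import (
    LayerAssignment,
    aggregate_module_graph,
    ami_zscore,
    assign_empirical_modules,
    classify_layers,
    fit_partition_baseline,
    jaccard_recovery,
    pattern_compliance,
    robust_z,
    _dl,
    _group_edge_counts,
)


class TestAggregateModuleGraph:
    def test_single_module_totals(self):
        net = ScoredNetwork.from_edges([("a", "b"), ("b", "c")])
        part = ModulePartition({"a": 0, "b": 0, "c": 0})
        W = aggregate_module_graph(net, part)
        assert W.shape == (1, 1) and W[0, 0] == 2

    def test_cross_module_direction(self):
        net = ScoredNetwork.from_edges([("a1", "b1"), ("a2", "b2")])
        part = ModulePartition({"a1": 0, "a2": 0, "b1": 1, "b2": 1})
        W = aggregate_module_graph(net, part)
        assert W[0, 1] == 2 and W[1, 0] == 0

    def test_edge_count_conserved(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(20)]
        pairs = sorted({tuple(rng.choice(genes, 2, replace=False)) for _ in range(70)})[:50]
        net = ScoredNetwork.from_edges(pairs)
        part = ModulePartition({g: i % 4 for i, g in enumerate(genes)})
        assert aggregate_module_graph(net, part).sum() == 50

    def test_unassigned_gene_rejected(self):
        net = ScoredNetwork.from_edges([("a", "b")])
        with pytest.raises(ValidationError, match="without a module"):
            aggregate_module_graph(net, ModulePartition({"a": 0}))


class TestClassifyLayers:
    def test_chain_labels(self):
        W = np.array([[0.0, 10, 0], [0, 0, 10], [0, 0, 0]])
        layers = classify_layers(W)
        assert [layers.layer[m] for m in range(3)] == ["input", "core", "output"]

    def test_tolerance_absorbs_small_upward_weight(self):
        W = np.array([[0.0, 100, 0], [0.5, 0, 100], [0, 0, 0]])
        layers = classify_layers(W, tol=0.01)
        assert [layers.layer[m] for m in range(3)] == ["input", "core", "output"]

    def test_within_only_modules_flagged_core(self):
        W = np.diag([5.0, 3.0])
        with pytest.warns(UserWarning, match="both input and output"):
            layers = classify_layers(W)
        assert set(layers.layer.values()) == {"core"}

    def test_isolated_module(self):
        W = np.array([[0.0, 4, 0], [0, 0, 0], [0, 0, 0]])
        layers = classify_layers(W)
        assert layers.layer[2] == "isolated"


class TestPatternCompliance:
    def _layers(self, W, labels):
        return LayerAssignment({i: lab for i, lab in enumerate(labels)}, W)

    def test_perfect_chain_has_no_upward(self):
        W = np.array([[0.0, 10, 0], [0, 0, 10], [0, 0, 0]])
        down, within, up = pattern_compliance(W, self._layers(W, ["input", "core", "output"]))
        assert up == 0.0 and down == 1.0

    def test_worked_percentages(self):
        W = np.array([[9.0, 90, 0], [2, 9, 90], [0, 0, 0]])
        down, within, up = pattern_compliance(W, self._layers(W, ["input", "core", "output"]))
        assert up == pytest.approx(2 / 200)
        assert down == pytest.approx(180 / 200)
        assert down + within + up == pytest.approx(1.0)

    def test_single_layer_all_within(self):
        W = np.array([[3.0, 2], [1, 4]])
        _, within, _ = pattern_compliance(W, self._layers(W, ["core", "core"]))
        assert within == 1.0


class TestEmpiricalModules:
    @pytest.mark.parametrize(
        "log2fc,padj,expected",
        [
            (2.0, 0.01, 0),  # strongly up -> class 1 (compact id 0)
            (0.5, 0.01, 1),  # weakly up -> class 2
            (-2.0, 0.01, 2),  # strongly down -> class 3
            (-0.5, 0.01, 3),  # weakly down -> class 4
            (3.0, 0.2, 4),  # not significant -> class 5
            (0.0, 0.01, 4),  # zero change -> class 5
        ],
    )
    def test_class_rules(self, log2fc, padj, expected):
        frame = pd.DataFrame(
            {
                "gene": ["g", "u1", "u2", "d1", "d2", "ns"],
                "log2fc": [log2fc, 2, 0.5, -2, -0.5, 0.1],
                "padj": [padj, 0.01, 0.01, 0.01, 0.01, 0.9],
            }
        )
        part = assign_empirical_modules(DETable(frame))
        assert part.assignment["g"] == expected


class TestRobustZ:
    def test_reference_values(self):
        assert robust_z(3, [1, 2, 3, 4, 5]) == 0.0
        assert robust_z(6, [1, 2, 3, 4, 5]) == pytest.approx((6 - 3) / 1.4826, rel=1e-6)

    def test_translation_invariance(self):
        sample = [1.0, 2, 3, 4, 10]
        assert robust_z(5, sample) == pytest.approx(robust_z(105, [s + 100 for s in sample]))

    def test_zero_mad_sentinel(self):
        with pytest.warns(UserWarning, match="MAD"):
            assert robust_z(2, [1, 1, 1]) == np.inf


class TestJaccardRecovery:
    def _balanced(self, n_modules=5, size=200):
        genes = [f"g{i}" for i in range(n_modules * size)]
        labels = np.repeat(np.arange(n_modules), size)
        return genes, labels

    def test_identical_partitions_all_recovered(self):
        genes, labels = self._balanced()
        a = ModulePartition(dict(zip(genes, labels)))
        b = ModulePartition(dict(zip(genes, labels)))
        result = jaccard_recovery(a, b, n_shuffles=500, seed=1)
        assert result.n_recovered == 5
        assert np.allclose(result.per_module["jaccard"], 1.0)

    def test_random_relabeling_recovers_at_most_one_on_average(self):
        genes, labels = self._balanced()
        a = ModulePartition(dict(zip(genes, labels)))
        total = 0
        for seed in range(20):
            shuffled = np.random.default_rng(seed).permutation(labels)
            b = ModulePartition(dict(zip(genes, shuffled)))
            total += jaccard_recovery(a, b, n_shuffles=300, seed=seed).n_recovered
        assert total / 20 <= 1.0

    def test_jaccard_value_feeds_score(self):
        genes = list("abcdx")
        a = ModulePartition({"a": 0, "b": 0, "c": 0, "d": 1, "x": 1})
        b = ModulePartition({"b": 0, "c": 0, "d": 0, "a": 1, "x": 1})
        result = jaccard_recovery(a, b, n_shuffles=50, seed=0)
        row = result.per_module.set_index("empirical_module").loc[0]
        assert row.jaccard == pytest.approx(0.5)  # {b,c,d} vs {a,b,c}

    def test_mismatched_universe_rejected(self):
        a = ModulePartition({"a": 0, "b": 1})
        b = ModulePartition({"a": 0, "c": 1})
        with pytest.raises(ValidationError, match="universe"):
            jaccard_recovery(a, b, n_shuffles=10, seed=0)


class TestAmiZscore:
    def _parts(self, agreement, seed, n=500):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n)]
        a = rng.integers(0, 5, size=n)
        b = a.copy()
        flip = rng.random(n) > agreement
        b[flip] = rng.integers(0, 5, size=flip.sum())
        return (
            ModulePartition(dict(zip(genes, a))),
            ModulePartition(dict(zip(genes, b))),
        )

    def test_identical_partitions_have_unit_ami(self):
        a, _ = self._parts(1.0, 0)
        ami, z, z_adj = ami_zscore(a, a, n_rand=200, seed=1)
        assert ami == pytest.approx(1.0)
        assert z > 1.96 and z_adj > 1.96

    def test_planted_agreement_is_significant(self):
        for seed in range(1, 6):
            a, b = self._parts(0.8, seed)
            _, z, _ = ami_zscore(a, b, n_rand=300, seed=seed)
            assert z > 1.96

    def test_independent_partitions_calibrated(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            genes = [f"g{i}" for i in range(500)]
            a = ModulePartition(dict(zip(genes, rng.integers(0, 5, 500))))
            b = ModulePartition(dict(zip(genes, rng.integers(0, 4, 500))))
            _, z, _ = ami_zscore(a, b, n_rand=300, seed=seed)
            hits += abs(z) <= 3
        assert hits >= 19

    def test_single_module_partition_rejected(self):
        genes = ["a", "b", "c"]
        one = ModulePartition({g: 0 for g in genes})
        two = ModulePartition({"a": 0, "b": 1, "c": 1})
        with pytest.raises(ValidationError, match="single-module"):
            ami_zscore(one, two, n_rand=10, seed=0)


class TestPartitionBaseline:
    def _planted(self, seed=2, n=80, p_in=0.3, p_out=0.01):
        rng = np.random.default_rng(seed)
        block = np.repeat([0, 1], n // 2)
        prob = np.where(block[:, None] == block[None, :], p_in, p_out)
        np.fill_diagonal(prob, 0)
        mask = rng.random((n, n)) < prob
        genes = [f"g{i:02d}" for i in range(n)]
        edges = [(genes[i], genes[j]) for i, j in zip(*np.nonzero(mask))]
        return ScoredNetwork.from_edges(edges), block, genes

    def test_planted_two_block_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        net, block, genes = self._planted(seed=2)
        part = fit_partition_baseline(net, seed=2, n_restarts=5)
        assert part.n_modules == 2
        assert adjusted_rand_score(block, part.labels_for(genes)) == 1.0

    def test_near_edgeless_network(self):
        net = ScoredNetwork.from_edges([("a", "b")])
        part = fit_partition_baseline(net, seed=0, n_restarts=3)
        assert part.genes == {"a", "b"}
        assert part.n_modules <= 2

    def test_merges_never_increase_description_length(self):
        from bowtie_grn.structure import _compact, _merge_phase

        net, block, genes = self._planted(seed=4)
        index = {g: i for i, g in enumerate(genes)}
        src = np.array([index[r] for r, _ in net.edge_set()])
        dst = np.array([index[t] for _, t in net.edge_set()])
        rng = np.random.default_rng(0)
        labels = _compact(rng.integers(0, 10, size=len(genes)))
        before = _dl(_group_edge_counts(src, dst, labels, labels.max() + 1), len(genes))
        merged = _merge_phase(src, dst, labels, len(genes))
        after = _dl(_group_edge_counts(src, dst, merged, merged.max() + 1), len(genes))
        assert after <= before + 1e-9

    def test_deterministic_given_seed(self):
        net, _, _ = self._planted(seed=6)
        p1 = fit_partition_baseline(net, seed=3, n_restarts=3)
        p2 = fit_partition_baseline(net, seed=3, n_restarts=3)
        assert p1.assignment == p2.assignment
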