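"""End-to-end orchestration of the inference workflow.

Wires the stages together: inference on real and randomized data, null
filtering, grouping, consensus building and gold-standard evaluation.
Used by the command-line interface and by the synthetic end-to-end
studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .consensus import consensus_union, edge_overlap_similarity, group_networks
from .core_model import GoldStandard, LassoConfig, PriorSet, ScoredNetwork
from .evaluation import aufe, network_counts, per_regulator_pfe, pfe
from .inference import (
    NullDistribution,
    filter_edges_by_null,
    lagged_lasso_infer,
    randomize_timeseries,
)
from .synthetic_data import (
    PRESETS,
    degrade_to_priors,
    make_bowtie_grn,
    sample_gold_standard,
    simulate_timeseries,
)

__all__ = ["infer_filtered_network", "EndToEndResult", "run_small_study"]


def infer_filtered_network(
    ts,
    regulators,
    priors: PriorSet | None,
    config: LassoConfig,
    alpha: float = 0.05,
    seed: int = 0,
    name: str = "",
) -> ScoredNetwork:
    """Infer a network and filter it against its own randomized-data null.

    The null distribution pools the edge scores of one inference run on
    time/gene-shuffled data; edges of the real run survive when their
    score exceeds the null's (1 - alpha) quantile.
    """
    net = lagged_lasso_infer(ts, regulators, priors, config)
    null_net = lagged_lasso_infer(randomize_timeseries(ts, seed), regulators, priors, config)
    null_scores = (
        null_net.edges["score"].to_numpy() if null_net.n_edges else np.array([0.0])
    )
    null = NullDistribution(null_scores, alpha=alpha)
    filtered = filter_edges_by_null(net, null)
    filtered.name = name or net.name
    return filtered


@dataclass
class EndToEndResult:
    consensus: ScoredNetwork
    gold_standard: GoldStandard
    pfe: float
    aufe: float
    n_edges_raw: list
    n_edges_filtered: list


def run_small_study(
    seed: int,
    preset: str = "bowtie-small",
    n_noise_replicas: int = 3,
    n_timepoints: int = 20,
    n_replicates: int = 3,
    noise_sd: float = 0.2,
    prior_recall: float = 0.5,
    prior_false_rate: float = 0.2,
    n_gs_regulators: int = 20,
    alpha: float = 0.05,
    config: LassoConfig = LassoConfig(),
) -> EndToEndResult:
    """Simulate -> infer -> filter -> consensus -> evaluate on one world.

    Three (by default) independently noised time series of the same
    planted world play the role of input-combination variants; their
    null-filtered networks are unioned into a consensus and scored
    against a sampled gold standard.
    """
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731
    world = make_bowtie_grn(**PRESETS[preset], seed=sub())
    priors = degrade_to_priors(world, prior_recall, prior_false_rate, seed=sub())
    raw_counts, nets = [], []
    for i in range(n_noise_replicas):
        ts = simulate_timeseries(world, n_timepoints, n_replicates, noise_sd, seed=sub())
        net = lagged_lasso_infer(ts, world.genes, priors, config)
        raw_counts.append(net.n_edges)
        null_net = lagged_lasso_infer(
            randomize_timeseries(ts, sub()), world.genes, priors, config
        )
        null_scores = (
            null_net.edges["score"].to_numpy() if null_net.n_edges else np.array([0.0])
        )
        filtered = filter_edges_by_null(net, NullDistribution(null_scores, alpha=alpha))
        filtered.name = f"replica{i}"
        nets.append(filtered)
    if len(nets) > 1:
        similarity = edge_overlap_similarity(nets)
        group_networks(similarity, 1)  # single consensus group by construction
    consensus = consensus_union(nets, name=f"consensus_seed{seed}")
    gs = sample_gold_standard(world, n_regulators=n_gs_regulators, seed=sub())
    counts = network_counts(consensus, gs)
    return EndToEndResult(
        consensus=consensus,
        gold_standard=gs,
        pfe=pfe(counts),
        aufe=aufe(list(per_regulator_pfe(consensus, gs).values())),
        n_edges_raw=raw_counts,
        n_edges_filtered=[n.n_edges for n in nets],
    )
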