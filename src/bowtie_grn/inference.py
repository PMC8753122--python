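"""Network inference: prior-weighted time-lagged lasso and null filtering.

The scoring model regresses each target's expression at time t on
regulator expression at lags 1..l_max, with a smaller L1 penalty on
coefficients of regulator->target pairs present in the prior set.  The
edge score is the sum of |beta| across lags (the signed sum supplies the
edge sign).  Spurious edges are removed by comparing scores against the
empirical distribution of scores obtained from a time/gene-shuffled run
of the same inference.

Per-coefficient penalties are realized through the standard
reparameterization: scaling column j by 1/w_j under a uniform L1 penalty
is equivalent to penalizing |beta_j| by w_j.  Predictors and responses
are standardized per regression, so lambda values act on the
standardized scale; replicates contribute independent lagged samples and
lags never cross replicate boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso

from .core_model import (
    ExpressionTimeSeries,
    LassoConfig,
    PriorSet,
    ScoredNetwork,
    ValidationError,
    flag_warning,
)

__all__ = [
    "NullDistribution",
    "select_variable_genes",
    "normalize_stable_genes",
    "lagged_lasso_infer",
    "randomize_timeseries",
    "filter_edges_by_null",
]


@dataclass
class NullDistribution:
    """Edge scores from a randomized-data inference run, plus the
    significance level used when filtering against it."""

    scores: np.ndarray
    alpha: float = 0.05

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size == 0:
            raise ValidationError("null distribution is empty")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")

    def threshold(self) -> float:
        """Type-7 empirical (1 - alpha) quantile of the null scores."""
        return float(np.quantile(self.scores, 1.0 - self.alpha, method="linear"))


def select_variable_genes(ts: ExpressionTimeSeries, min_log2_range: float = 1.0) -> set:
    """Genes whose max - min log2 expression across all samples >= threshold."""
    rng_ = ts.values.max(axis=1) - ts.values.min(axis=1)
    return set(rng_.index[rng_ >= min_log2_range])


def normalize_stable_genes(ts: ExpressionTimeSeries, stable_genes) -> ExpressionTimeSeries:
    """Rescale each sample so its stable-gene mean equals the grand mean.

    The multiplicative factor per sample is grand_mean / sample_mean over
    the stable genes; after normalization all samples share the same
    stable-gene mean.
    """
    stable = sorted(set(stable_genes))
    if not stable:
        raise ValueError("stable gene set is empty")
    missing = set(stable) - set(ts.gene_ids)
    if missing:
        raise ValueError(f"stable genes absent from the series: {sorted(missing)}")
    sample_means = ts.values.loc[stable].mean(axis=0)
    if (sample_means == 0).any():
        raise ValueError("a sample has zero stable-gene mean; cannot rescale")
    factors = sample_means.mean() / sample_means
    return ExpressionTimeSeries(ts.values * factors, ts.samples.copy())


def _lagged_design(ts: ExpressionTimeSeries, regulators: list, l_max: int):
    """Stack (X, Y) across (condition, replicate) segments.

    Returns (X, Y, columns) where X rows are samples with full lag
    history, Y is the genes x rows response matrix, and columns lists the
    (regulator, lag) identity of each X column.
    """
    values = ts.values
    X_blocks, Y_blocks = [], []
    for (_, _), meta in ts.samples.groupby(["condition", "replicate"], sort=True):
        meta = meta.sort_values("timepoint", kind="stable")
        cols = meta.index
        if len(cols) <= l_max:
            continue
        block = values.loc[:, cols].to_numpy()  # genes x T
        reg_block = values.loc[regulators, cols].to_numpy()
        T = block.shape[1]
        xs = [reg_block[:, l_max - l : T - l] for l in range(1, l_max + 1)]
        X_blocks.append(np.vstack(xs).T)  # rows x (n_reg * l_max)
        Y_blocks.append(block[:, l_max:])
    if not X_blocks:
        raise ValidationError(f"no segment has more than l_max={l_max} timepoints")
    X = np.vstack(X_blocks)
    Y = np.hstack(Y_blocks)
    columns = [(r, l) for l in range(1, l_max + 1) for r in regulators]
    return X, Y, columns


def lagged_lasso_infer(
    ts: ExpressionTimeSeries,
    regulators,
    priors: PriorSet | None = None,
    config: LassoConfig = LassoConfig(),
    include_self: bool = False,
) -> ScoredNetwork:
    """Score regulator->target edges with the prior-weighted lagged lasso.

    For each target the lasso solves, on standardized data,

        min ||y_t - sum_{r,l} beta_{r,l} x_r(t - l)||^2
            + alpha * sum_{r,l} lambda_{r,target} |beta_{r,l}|

    with lambda = lambda_prior for pairs in ``priors`` and lambda_nonprior
    otherwise.  Edge score = sum_l |beta_{r,l}|; zero-score edges are
    omitted.  A target's own lags are excluded from its design unless
    ``include_self`` is set (self-edges would otherwise reflect plain
    autocorrelation).
    """
    if config.monotone_lags:
        raise NotImplementedError(
            "monotone lag constraint is not implemented; the unconstrained "
            "per-coefficient-penalty lasso is the reference scoring model"
        )
    regulators = sorted(set(regulators))
    missing = set(regulators) - set(ts.gene_ids)
    if missing:
        raise ValidationError(f"regulators absent from the series: {sorted(missing)}")
    min_len = ts.samples.groupby(["condition", "replicate"])["timepoint"].nunique().min()
    if min_len <= config.l_max:
        raise ValidationError(
            f"l_max={config.l_max} requires more than {config.l_max} timepoints per replicate"
        )
    prior_pairs = priors.pairs() if priors is not None else frozenset()

    X, Y, columns = _lagged_design(ts, regulators, config.l_max)
    col_regs = np.array([r for r, _ in columns])
    X_mean = X.mean(axis=0)
    X_sd = X.std(axis=0)
    live = X_sd > 0
    Xs = np.zeros_like(X)
    Xs[:, live] = (X[:, live] - X_mean[live]) / X_sd[live]

    rows = []
    genes = ts.gene_ids
    for gi, gene in enumerate(genes):
        y = Y[gi]
        sd = y.std()
        if sd == 0:
            continue  # constant target: no incoming edges
        ys = (y - y.mean()) / sd
        usable = live.copy()
        if not include_self:
            usable &= col_regs != gene
        if not usable.any():
            continue
        weights = np.where(
            [(r, gene) in prior_pairs for r in col_regs[usable]],
            config.lambda_prior,
            config.lambda_nonprior,
        )
        Xw = Xs[:, usable] / weights
        model = Lasso(alpha=config.alpha, fit_intercept=False, max_iter=5000)
        with np.errstate(all="ignore"):
            model.fit(Xw, ys)
        beta = model.coef_ / weights
        if not np.isfinite(beta).all():
            flag_warning(f"degenerate design for target {gene!r}; skipped")
            continue
        sub_regs = col_regs[usable]
        for r in np.unique(sub_regs):
            b = beta[sub_regs == r]
            score = float(np.abs(b).sum())
            if score == 0.0:
                continue
            signed = float(b.sum())
            sign = "+" if signed > 0 else ("-" if signed < 0 else "unknown")
            rows.append({"regulator": r, "target": gene, "score": score, "sign": sign})
    frame = pd.DataFrame(rows, columns=["regulator", "target", "score", "sign"])
    return ScoredNetwork(frame, name="lagged_lasso")


def randomize_timeseries(ts: ExpressionTimeSeries, seed: int) -> ExpressionTimeSeries:
    """Shuffle both the time and gene dimensions with a seeded generator.

    The sample axis is permuted (each row's value multiset is preserved)
    and gene labels are independently permuted across rows.
    """
    rng = np.random.default_rng(seed)
    values = ts.values
    col_perm = rng.permutation(values.shape[1])
    gene_perm = rng.permutation(values.shape[0])
    shuffled = pd.DataFrame(
        values.to_numpy()[:, col_perm],
        index=values.index.to_numpy()[gene_perm],
        columns=values.columns,
    )
    shuffled = shuffled.loc[values.index]
    return ExpressionTimeSeries(shuffled, ts.samples.copy())


def filter_edges_by_null(net: ScoredNetwork, null: NullDistribution) -> ScoredNetwork:
    """Keep edges whose score strictly exceeds the null's (1 - alpha) quantile."""
    scores = net.scores()  # raises on unscored networks
    cut = null.threshold()
    kept = net.edges[scores.to_numpy() > cut]
    return ScoredNetwork(kept.reset_index(drop=True), name=net.name)
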