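"""Gold-standard performance metrics and randomization baselines.

Because curated gold standards cover a tiny fraction of the possible
regulator-target space, raw precision is hard to interpret; the central
metrics here measure signal relative to random expectation:

* PFE (precision fold enrichment): (p/n) / (k/K), precision divided by
  the gold-standard density.  PFE > 1 means better than random.
* AUFE: area under the survival curve of per-regulator PFE values, i.e.
  the fraction of measurable regulators with PFE_r >= x integrated over
  x.  For a piecewise-constant survival curve this equals the arithmetic
  mean of the PFE_r values.
* Precision/accuracy/AUPR against knockdown correlation experiments,
  with degree-preserving double-edge-swap replicas supplying the random
  expectation for Z-scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_model import (
    EvaluationCounts,
    GoldStandard,
    ScoredNetwork,
    ValidationError,
    flag_warning,
)

__all__ = [
    "pfe",
    "naive_expected_precision",
    "network_counts",
    "per_regulator_pfe",
    "aufe",
    "pfe_survival_curve",
    "precision_accuracy_aupr",
    "double_edge_swap",
    "zscore_vs_random",
]


def pfe(counts: EvaluationCounts) -> float:
    """Precision fold enrichment (p/n)/(k/K); 0 (with warning) when n = 0."""
    if counts.K <= 0 or counts.k <= 0:
        raise ValidationError("PFE needs k > 0 and K > 0")
    if counts.n == 0:
        flag_warning("regulator predicted nothing; PFE defined as 0")
        return 0.0
    return (counts.p / counts.n) / (counts.k / counts.K)


def naive_expected_precision(E: int, R: int, T: int) -> float:
    """Expected precision of a random network: its density E/(R*T)."""
    if R <= 0 or T <= 0:
        raise ValidationError("need R > 0 and T > 0")
    if E > R * T:
        raise ValidationError(f"E={E} exceeds the {R * T} possible edges")
    return E / (R * T)


def network_counts(net: ScoredNetwork, gs: GoldStandard) -> EvaluationCounts:
    """Whole-network PFE counts against a gold standard.

    The universe is the gold standard's regulator x target universe
    restricted to genes present in the network; predictions outside it do
    not count toward n.
    """
    nodes = net.nodes
    regs = gs.regulator_universe & nodes
    tgts = gs.target_universe & nodes
    K = len(regs) * len(tgts)
    if K == 0:
        raise ValidationError("no gold-standard universe genes present in the network")
    edges = {(r, t) for r, t in net.edge_set() if r in regs and t in tgts}
    positives = {(r, t) for r, t in gs.positives if r in regs and t in tgts}
    n = len(edges)
    p = len(edges & positives)
    k = len(positives)
    return EvaluationCounts(p=p, n=n, k=k, K=K)


def per_regulator_pfe(net: ScoredNetwork, gs: GoldStandard) -> dict:
    """PFE_r for every measurable regulator of the gold standard.

    For regulator r: n_r = predicted edges of r into the target universe,
    p_r = those in the positives, k_r = positives of r, K_r = size of the
    target universe.  PFE_r = 0 when r predicts nothing (or is absent
    from the network).
    """
    measurable = gs.measurable_regulators
    if not measurable:
        raise ValidationError("gold standard has no measurable regulators")
    K_r = len(gs.target_universe)
    by_reg: dict = {r: set() for r in measurable}
    for r, t in net.edge_set():
        if r in by_reg and t in gs.target_universe:
            by_reg[r].add(t)
    pos_by_reg: dict = {r: set() for r in measurable}
    for r, t in gs.positives:
        pos_by_reg[r].add(t)
    out = {}
    for r in sorted(measurable):
        n_r = len(by_reg[r])
        if n_r == 0:
            out[r] = 0.0
            continue
        p_r = len(by_reg[r] & pos_by_reg[r])
        k_r = len(pos_by_reg[r])
        out[r] = (p_r / n_r) / (k_r / K_r)
    return out


def aufe(pfe_values) -> float:
    """Area under the fold-enrichment survival curve = mean of the values."""
    values = np.asarray(list(pfe_values), dtype=float)
    if values.size == 0:
        raise ValidationError("aufe needs at least one PFE value")
    if (values < 0).any():
        raise ValidationError("PFE values must be >= 0")
    return float(values.mean())


def pfe_survival_curve(pfe_values) -> pd.DataFrame:
    """Survival-curve form of AUFE for plotting: fraction of regulators
    with PFE_r >= x at each distinct x (0 included)."""
    values = np.sort(np.asarray(list(pfe_values), dtype=float))
    xs = np.unique(np.concatenate([[0.0], values]))
    frac = [(values >= x).mean() for x in xs]
    return pd.DataFrame({"pfe": xs, "fraction_ge": frac})


def precision_accuracy_aupr(
    nets: list[ScoredNetwork],
    pcc_table: pd.DataFrame,
    cutoff: float = 0.75,
) -> tuple[float, float, float]:
    """Score predictions against knockdown-correlation experiments.

    ``pcc_table`` has columns regulator, target, pcc; a tested pair is
    *positive* when |pcc| >= cutoff and *predicted* when its edge appears
    in at least one network.  Returns (precision, accuracy, AUPR), where
    AUPR integrates, step-wise, precision over recall as the cutoff
    sweeps across all observed |pcc| values (positives vary with the
    cutoff while the prediction set stays fixed).
    """
    if not 0 <= cutoff <= 1:
        raise ValidationError("cutoff must lie in [0, 1]")
    predicted_edges = set().union(*(net.edge_set() for net in nets)) if nets else set()
    pairs = list(zip(pcc_table["regulator"], pcc_table["target"]))
    abs_pcc = np.abs(pcc_table["pcc"].to_numpy(dtype=float))
    predicted = np.array([pair in predicted_edges for pair in pairs])
    positive = abs_pcc >= cutoff

    tp = int((predicted & positive).sum())
    fp = int((predicted & ~positive).sum())
    tn = int((~predicted & ~positive).sum())
    if predicted.sum() == 0:
        flag_warning("no tested pair is predicted; precision defined as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    accuracy = (tp + tn) / len(pairs)

    # sweep cutoffs descending; step-integrate precision d(recall)
    curve = []
    for c in np.unique(abs_pcc)[::-1]:
        pos_c = abs_pcc >= c
        n_pos = int(pos_c.sum())
        tp_c = int((predicted & pos_c).sum())
        prec_c = tp_c / predicted.sum() if predicted.sum() else 0.0
        rec_c = tp_c / n_pos if n_pos else 0.0
        curve.append((rec_c, prec_c))
    curve.sort()
    aupr = 0.0
    prev_r = 0.0
    for rec_c, prec_c in curve:
        aupr += (rec_c - prev_r) * prec_c
        prev_r = rec_c
    return precision, accuracy, float(aupr)


def double_edge_swap(net: ScoredNetwork, n_swaps: int, seed: int) -> ScoredNetwork:
    """Degree-preserving rewiring: n_swaps accepted target swaps.

    Each move picks two edges (u -> v), (s -> t) and proposes (u -> t),
    (s -> v); proposals creating a duplicate edge or a self-loop are
    rejected.  In- and out-degree sequences are preserved exactly.  If no
    legal swap is found within 100 * n_swaps attempts, the partially
    rewired network is returned with a warning.
    """
    edges = [tuple(e) for e in net.edges[["regulator", "target"]].itertuples(index=False)]
    if len(edges) < 2:
        return ScoredNetwork.from_edges(edges, name=f"{net.name}|rewired")
    rng = np.random.default_rng(seed)
    edge_set = set(edges)
    accepted = 0
    attempts = 0
    max_attempts = 100 * n_swaps
    m = len(edges)
    while accepted < n_swaps and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        u, v = edges[i]
        s, t = edges[j]
        if v == t:
            continue  # no-op swap
        if u == t or s == v:
            continue  # would create a self-loop
        if (u, t) in edge_set or (s, v) in edge_set:
            continue  # would duplicate an existing edge
        edge_set.discard((u, v))
        edge_set.discard((s, t))
        edge_set.add((u, t))
        edge_set.add((s, v))
        edges[i] = (u, t)
        edges[j] = (s, v)
        accepted += 1
    if accepted < n_swaps:
        flag_warning(
            f"only {accepted}/{n_swaps} swaps accepted after {attempts} attempts"
        )
    return ScoredNetwork.from_edges(edges, name=f"{net.name}|rewired")


def zscore_vs_random(observed: float, randomized) -> float:
    """(observed - mean) / sample sd of the randomized ensemble."""
    values = np.asarray(list(randomized), dtype=float)
    if values.size < 2:
        raise ValidationError("need >= 2 randomized values")
    sd = values.std(ddof=1)
    if sd == 0:
        flag_warning("zero spread in randomized ensemble; returning signed infinity")
        diff = observed - values.mean()
        return float(np.sign(diff) * np.inf) if diff != 0 else 0.0
    return float((observed - values.mean()) / sd)
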