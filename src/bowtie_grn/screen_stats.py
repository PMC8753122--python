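"""Statistics for the experimental layers of the pipeline.

Covers the knockdown validation and lifespan-screen arithmetic: a
max-|PCC| resampling null that yields family-wise-adjusted p-values for
regulator-target correlations across qPCR replicates, survival
percentages and their normalization against empty-vector controls,
two-group logrank tests combined across replicates with Fisher's method
and Bonferroni correction, and a resampling test for label enrichment in
gene subsets.

All resampling p-values carry an add-one pseudo-count,
p = (1 + #extreme) / (1 + iterations), so a finite null never reports
exactly zero.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .core_model import EnrichmentProblem, KDExperiment, flag_warning

__all__ = [
    "resampling_max_pcc_pvalues",
    "survival_percentage",
    "normalize_survival",
    "logrank_test",
    "fisher_combine",
    "bonferroni",
    "resampling_enrichment",
]


def resampling_max_pcc_pvalues(
    exp: KDExperiment, n_iter: int = 1000, seed: int = 0
) -> dict:
    """Per-target (PCC, p) for a knockdown experiment via a max-|PCC| null.

    The observed statistic is the Pearson correlation between the
    regulator's replicate ddCT vector and each target's.  Each null
    iteration shuffles every target's vector independently and records
    the maximum |PCC| across targets; because the null is built from the
    maximum over all targets, the p-values are family-wise adjusted by
    construction.  Zero-variance targets are skipped with a warning.
    """
    reg = exp.ddct[exp.regulator].to_numpy(dtype=float)
    if reg.std() == 0:
        raise ValueError("regulator ddCT vector has zero variance")
    n_rep = exp.n_replicates
    zr = (reg - reg.mean()) / reg.std()

    targets, cols = [], []
    for t in exp.targets:
        v = exp.ddct[t].to_numpy(dtype=float)
        if v.std() == 0:
            flag_warning(f"target {t!r} has zero variance; skipped")
            continue
        targets.append(t)
        cols.append((v - v.mean()) / v.std())
    if not targets:
        return {}
    Z = np.column_stack(cols)  # replicates x targets, standardized
    obs = zr @ Z / n_rep

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_iter)
    for i in range(n_iter):
        perm = np.argsort(rng.random(Z.shape), axis=0)
        shuffled = np.take_along_axis(Z, perm, axis=0)
        null_max[i] = np.abs(zr @ shuffled / n_rep).max()

    out = {}
    for j, t in enumerate(targets):
        extreme = int((null_max >= abs(obs[j])).sum())
        out[t] = (float(obs[j]), (1 + extreme) / (1 + n_iter))
    return out


def survival_percentage(dead: int, mean_total: float, mode: str = "dead") -> float:
    """100 * dead / mean(dead + alive), or the complementary ``alive`` mode.

    The screen's printed formula puts the dead count in the numerator of
    its "percentage of survival"; the ``alive`` mode computes the literal
    survivor fraction instead.
    """
    if mean_total <= 0:
        raise ValueError("mean_total must be > 0")
    if dead > mean_total:
        raise ValueError(f"dead={dead} exceeds mean_total={mean_total}")
    if mode == "dead":
        return 100.0 * dead / mean_total
    if mode == "alive":
        return 100.0 * (mean_total - dead) / mean_total
    raise ValueError(f"unknown mode {mode!r}")


def normalize_survival(test_pct: float, control_pcts, mode: str) -> float:
    """Normalize a test survival percentage against same-round controls.

    ``center50`` returns 50 * (test / control mean), so a test equal to
    its controls maps to 50; ``ratio50`` returns test/control + 50, the
    literal "add 50 to this ratio" reading.  The mode is mandatory
    because the two readings disagree.
    """
    controls = np.asarray(list(control_pcts), dtype=float)
    if controls.size == 0:
        raise ValueError("no control percentages supplied")
    mean_ctrl = controls.mean()
    if mean_ctrl <= 0:
        raise ValueError("control mean must be > 0")
    ratio = test_pct / mean_ctrl
    if mode == "center50":
        return 50.0 * ratio
    if mode == "ratio50":
        return ratio + 50.0
    raise ValueError(f"unknown mode {mode!r}")


def logrank_test(group_a, group_b) -> tuple[float, float]:
    """Two-group logrank test on (time, event) records.

    Returns the chi-squared statistic (1 df) and its p-value.  Raises if
    the pooled sample has no events.
    """
    from lifelines.statistics import logrank_test as _ll_logrank

    ta, ea = zip(*group_a)
    tb, eb = zip(*group_b)
    if not any(ea) and not any(eb):
        raise ValueError("no events in either group")
    res = _ll_logrank(list(ta), list(tb), event_observed_A=list(ea), event_observed_B=list(eb))
    return float(res.test_statistic), float(res.p_value)


def fisher_combine(pvalues) -> tuple[float, int, float]:
    """Fisher's method: chi2 = -2 sum(ln p), df = 2m, upper-tail p."""
    ps = np.asarray(list(pvalues), dtype=float)
    if ps.size == 0:
        raise ValueError("no p-values supplied")
    if (ps > 1).any() or (ps < 0).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (ps == 0).any():
        flag_warning("p-value of 0 clamped to machine minimum")
        ps = np.clip(ps, np.finfo(float).tiny, 1.0)
    chi2 = float(-2.0 * np.log(ps).sum())
    df = 2 * ps.size
    return chi2, df, float(stats.chi2.sf(chi2, df))


def bonferroni(pvalues, n_conditions: int | None = None) -> np.ndarray:
    """Bonferroni correction across screen conditions (capped at 1)."""
    ps = np.asarray(list(pvalues), dtype=float)
    m = n_conditions if n_conditions is not None else ps.size
    return np.minimum(ps * m, 1.0)


def resampling_enrichment(
    problem: EnrichmentProblem,
    n_samples: int = 10000,
    seed: int = 0,
    mode: str = "enrichment",
) -> float:
    """Resampling p-value for label enrichment (or depletion) in a subset.

    Draws ``n_samples`` random subsets of Nt genes from the Ng-gene
    background carrying Mg labels and compares each sample's label count
    with the observed Mt: enrichment counts samples with >= Mt labels,
    depletion counts <= Mt.
    """
    if mode not in ("enrichment", "depletion"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    labels = np.zeros(problem.Ng, dtype=bool)
    labels[: problem.Mg] = True
    hits = 0
    for _ in range(n_samples):
        draw = rng.choice(problem.Ng, size=problem.Nt, replace=False)
        count = int(labels[draw].sum())
        if mode == "enrichment" and count >= problem.Mt:
            hits += 1
        elif mode == "depletion" and count <= problem.Mt:
            hits += 1
    return (1 + hits) / (1 + n_samples)
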