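"""Synthetic worlds: layered ground-truth networks with linear dynamics.

The generator plants a bow-tie (input -> core -> output) module
architecture, draws a stable first-order vector-autoregressive
coefficient matrix on its edges, and derives from it everything the
pipeline consumes: expression time series with replicate noise, degraded
prior sets, sampled gold standards and knockdown response tables.  Every
stage of the pipeline therefore has a known-answer test without any
external download.

Two presets capture the two study regimes: ``bowtie-small`` (60 genes,
sparse) sized for end-to-end inference, and ``bowtie-layers`` (150
genes, dense downward flow) sized for structural layer analysis — see
docs/methods.md for the power analysis behind the densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_model import (
    DETable,
    ExpressionTimeSeries,
    GoldStandard,
    KDExperiment,
    ModulePartition,
    PriorSet,
    ScoredNetwork,
    ValidationError,
    flag_warning,
)

__all__ = [
    "SyntheticWorld",
    "PRESETS",
    "make_bowtie_grn",
    "simulate_timeseries",
    "degrade_to_priors",
    "sample_gold_standard",
    "simulate_kd_response",
]

PRESETS = {
    # sparse regime: inference can separate signal from noise at 60 genes
    "bowtie-small": dict(
        n_modules=(2, 3, 1),
        genes_per_module=10,
        p_forward=0.15,
        p_within=0.10,
        violation_rate=0.005,
    ),
    # dense downward flow: per-module violation fraction stays below the
    # layer-classification tolerance
    "bowtie-layers": dict(
        n_modules=(2, 3, 1),
        genes_per_module=25,
        p_forward=0.8,
        p_within=0.3,
        violation_rate=0.005,
    ),
}


@dataclass
class SyntheticWorld:
    """Ground truth for one synthetic study.

    ``dynamics`` is the VAR(1) coefficient matrix A with A[target,
    regulator] convention; ``truth`` holds exactly its nonzero entries as
    regulator -> target edges scored by |coefficient|.
    """

    truth: ScoredNetwork
    layers: dict  # module id -> layer label
    partition: ModulePartition
    dynamics: np.ndarray
    genes: list
    seed: int

    def __post_init__(self):
        self.dynamics = np.asarray(self.dynamics, dtype=float)
        n = len(self.genes)
        if self.dynamics.shape != (n, n):
            raise ValidationError("dynamics matrix shape must match the gene list")
        radius = np.max(np.abs(np.linalg.eigvals(self.dynamics))) if n else 0.0
        if radius >= 1.0:
            raise ValidationError(f"unstable dynamics (spectral radius {radius:.3f})")
        idx = {g: i for i, g in enumerate(self.genes)}
        nz = {
            (self.genes[j], self.genes[i])
            for i, j in zip(*np.nonzero(self.dynamics))
        }
        if nz != self.truth.edge_set():
            raise ValidationError("truth edges must coincide with nonzero coefficients")
        del idx

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def make_bowtie_grn(
    n_modules: tuple[int, int, int] = (2, 3, 1),
    genes_per_module: int = 10,
    p_forward: float = 0.15,
    p_within: float = 0.10,
    violation_rate: float = 0.005,
    seed: int = 0,
    spectral_radius: float = 0.9,
) -> SyntheticWorld:
    """Plant a layered module network with stable VAR(1) dynamics.

    Ordered module pairs receive edges independently: downward-layer
    pairs at ``p_forward``, within-module gene pairs at ``p_within``,
    upward pairs at ``violation_rate``; same-layer cross-module pairs get
    none.  Coefficients are drawn from +-Uniform(0.3, 0.9) and the matrix
    is rescaled to ``spectral_radius`` (skipped with a warning for
    near-nilpotent draws, which are already stable).
    """
    n_in, n_core, n_out = n_modules
    if min(n_in, n_core, n_out) < 1:
        raise ValueError("each layer needs at least one module")
    if genes_per_module < 1:
        raise ValueError("genes_per_module must be >= 1")
    rng = np.random.default_rng(seed)
    B = n_in + n_core + n_out
    layer_of = {}
    for m in range(B):
        layer_of[m] = "input" if m < n_in else ("core" if m < n_in + n_core else "output")
    genes = [f"g{m:02d}_{i:03d}" for m in range(B) for i in range(genes_per_module)]
    module = np.repeat(np.arange(B), genes_per_module)
    n = len(genes)

    rank = {"input": 0, "core": 1, "output": 2}
    prob = np.zeros((n, n))  # prob[i, j]: edge gene j -> gene i
    for a in range(B):
        for b in range(B):
            ra, rb = rank[layer_of[a]], rank[layer_of[b]]
            if a == b:
                p = p_within
            elif ra < rb:
                p = p_forward
            elif ra > rb:
                p = violation_rate
            else:
                p = 0.0
            if p:
                rows = np.flatnonzero(module == b)  # targets
                cols = np.flatnonzero(module == a)  # regulators
                prob[np.ix_(rows, cols)] = p
    np.fill_diagonal(prob, 0.0)

    mask = rng.random((n, n)) < prob
    coeff = rng.uniform(0.3, 0.9, size=(n, n)) * rng.choice([-1.0, 1.0], size=(n, n))
    A = np.where(mask, coeff, 0.0)
    radius = np.max(np.abs(np.linalg.eigvals(A))) if mask.any() else 0.0
    if radius >= 1e-3:
        A *= spectral_radius / radius
    elif mask.any():
        flag_warning("near-nilpotent coefficient matrix; spectral rescaling skipped")

    rows = []
    for i, j in zip(*np.nonzero(A)):
        rows.append(
            {
                "regulator": genes[j],
                "target": genes[i],
                "score": abs(A[i, j]),
                "sign": "+" if A[i, j] > 0 else "-",
            }
        )
    truth = ScoredNetwork(
        pd.DataFrame(rows, columns=["regulator", "target", "score", "sign"]),
        name="truth",
    )
    partition = ModulePartition({g: int(m) for g, m in zip(genes, module)}, level="planted")
    return SyntheticWorld(
        truth=truth,
        layers=layer_of,
        partition=partition,
        dynamics=A,
        genes=genes,
        seed=seed,
    )


def simulate_timeseries(
    world: SyntheticWorld,
    n_timepoints: int = 20,
    n_replicates: int = 3,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> ExpressionTimeSeries:
    """First-order autoregression x_t = A x_{t-1} + eps on the planted dynamics.

    Each replicate starts from an independent standard-normal state (zero
    when ``noise_sd`` is 0, pinning the fixed point); values are log2-scale
    by construction.
    """
    if n_timepoints < 2:
        raise ValueError("need at least two timepoints")
    rng = np.random.default_rng(seed)
    A = world.dynamics
    n = world.n_genes
    columns, data, meta = [], [], []
    for rep in range(1, n_replicates + 1):
        x = rng.standard_normal(n) if noise_sd > 0 else np.zeros(n)
        for t in range(n_timepoints):
            if t > 0:
                x = A @ x + rng.normal(0.0, noise_sd, size=n)
            name = f"r{rep}_t{t:02d}"
            columns.append(name)
            data.append(x.copy())
            meta.append({"sample": name, "timepoint": t, "replicate": f"r{rep}", "condition": "sim"})
    values = pd.DataFrame(np.column_stack(data), index=world.genes, columns=columns)
    samples = pd.DataFrame(meta).set_index("sample")
    return ExpressionTimeSeries(values, samples)


def degrade_to_priors(
    world: SyntheticWorld, recall: float = 0.5, false_rate: float = 0.2, seed: int = 0
) -> PriorSet:
    """Thin the truth to an imperfect prior set.

    Each true edge is kept with probability ``recall``; false pairs are
    added so the expected false fraction of the prior set is
    ``false_rate``.  All priors carry the functional-evidence weight.
    """
    if not (0 <= recall <= 1 and 0 <= false_rate < 1):
        raise ValueError("recall in [0,1], false_rate in [0,1) required")
    rng = np.random.default_rng(seed)
    true_edges = sorted(world.truth.edge_set())
    kept = [e for e in true_edges if rng.random() < recall]
    n_false = int(round(len(kept) * false_rate / (1.0 - false_rate))) if kept else 0
    truth_set = set(true_edges)
    false_pairs: set = set()
    genes = world.genes
    while len(false_pairs) < n_false:
        r, t = rng.choice(len(genes), size=2, replace=False)
        pair = (genes[r], genes[t])
        if pair not in truth_set:
            false_pairs.add(pair)
    records = [(r, t, "functional") for r, t in kept + sorted(false_pairs)]
    if not records:
        return PriorSet(
            pd.DataFrame(columns=["regulator", "target", "weight", "evidence"]).astype(
                {"weight": float}
            )
        )
    return PriorSet.from_records(records)


def sample_gold_standard(
    world: SyntheticWorld, n_regulators: int, seed: int = 0
) -> GoldStandard:
    """Sample measurable regulators and expose their true edges as positives.

    The regulator universe is the sampled set; the target universe is all
    genes, mirroring a functional gold standard that covers few
    regulators but any target.
    """
    measurable = sorted(world.truth.regulators)
    if n_regulators > len(measurable):
        raise ValueError(f"only {len(measurable)} regulators have outgoing true edges")
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(measurable, size=n_regulators, replace=False))
    positives = {(r, t) for r, t in world.truth.edge_set() if r in chosen}
    return GoldStandard(
        positives=positives,
        regulator_universe=chosen,
        target_universe=set(world.genes),
    )


def simulate_kd_response(
    world: SyntheticWorld,
    regulator: str,
    effect: float = 1.0,
    noise_sd: float = 0.1,
    n_replicates: int = 6,
    seed: int = 0,
) -> tuple[DETable, KDExperiment]:
    """Propagate a sustained knockdown through the linear dynamics.

    A persistent -``effect`` input at the regulator shifts the steady
    state by (I - A)^{-1} (-effect e_r); genes unreachable from the
    regulator shift exactly zero.  The DE table reports the shift as
    log2fc with a BH-adjusted one-sample t-test over replicate-noised
    shifts; the ddCT table holds those replicate values.
    """
    if regulator not in world.genes:
        raise ValueError(f"unknown gene {regulator!r}")
    idx = world.genes.index(regulator)
    if not (world.dynamics[:, idx] != 0).any():
        raise ValueError(f"regulator {regulator!r} has no outgoing edges")
    n = world.n_genes
    shift = np.linalg.solve(np.eye(n) - world.dynamics, -effect * np.eye(n)[:, idx])
    rng = np.random.default_rng(seed)
    reps = shift[None, :] + rng.normal(0.0, noise_sd, size=(n_replicates, n))

    if noise_sd > 0:
        res = stats.ttest_1samp(reps, popmean=0.0, axis=0)
        pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    else:
        pvals = np.where(shift == 0.0, 1.0, 0.0)
    padj = multipletests(pvals, method="fdr_bh")[1]
    de = DETable(
        pd.DataFrame({"gene": world.genes, "log2fc": shift, "padj": padj})
    )
    ddct = pd.DataFrame(reps, columns=world.genes)
    return de, KDExperiment(regulator=regulator, ddct=ddct)
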