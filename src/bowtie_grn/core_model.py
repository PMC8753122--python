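"""Domain types and file input/output for the network-inference pipeline.

Every object the pipeline passes between stages lives here: expression
time series, scored edge lists, prior interaction sets, gold standards,
module partitions, genomic interval sets, differential-expression tables
and knockdown experiments.  Invariants are enforced at construction; all
on-disk formats are plain tab-separated text (header required, UTF-8,
``#`` comment lines ignored) or BED3/BED6 for intervals.

Gene identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ParseError",
    "ExpressionTimeSeries",
    "ScoredNetwork",
    "PriorSet",
    "GoldStandard",
    "ModulePartition",
    "GenomicIntervalSet",
    "DETable",
    "KDExperiment",
    "EvaluationCounts",
    "LassoConfig",
    "EnrichmentProblem",
    "load_network",
    "write_network",
    "load_timeseries",
    "write_timeseries",
    "load_priors",
    "write_priors",
    "load_gold_standard",
    "write_gold_standard",
    "load_partition",
    "write_partition",
    "load_bed",
    "write_bed",
    "load_de_table",
    "write_de_table",
]

EVIDENCE_TYPES = ("chip", "motif", "ey1h", "functional")
#: default prior weight per evidence type
EVIDENCE_WEIGHTS = {"chip": 0.8, "motif": 0.6, "ey1h": 0.6, "functional": 0.6}


class ValidationError(ValueError):
    """An object violates a domain invariant."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


# ---------------------------------------------------------------------------
# TSV plumbing


def _read_tsv(path, required_cols):
    """Read a TSV with header, skipping '#' comments; return (frame, line_numbers).

    ``line_numbers`` maps frame row position -> 1-based line number in the
    file, so validation errors can point at the source.
    """
    with open(path, encoding="utf-8") as fh:
        raw = fh.readlines()
    kept, numbers = [], []
    for i, line in enumerate(raw, start=1):
        if line.lstrip().startswith("#") or not line.strip():
            continue
        kept.append(line)
        numbers.append(i)
    if not kept:
        raise ParseError(f"{path}: empty file (no header)")
    try:
        frame = pd.read_csv(io.StringIO("".join(kept)), sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required_cols if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}; header line {numbers[0]}")
    return frame, numbers[1:]


def _write_tsv(frame, path):
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression time series


@dataclass
class ExpressionTimeSeries:
    """A genes x samples matrix of log2 expression with sample metadata.

    ``values`` is indexed by gene id; its columns are sample ids matching
    the index of ``samples``, which carries ``timepoint`` (ordinal int),
    ``replicate`` and ``condition`` labels.  Samples are kept in canonical
    (condition, replicate, timepoint) order.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        unmatched = set(self.values.columns) ^ set(self.samples.index)
        if unmatched:
            raise ValidationError(f"expression/metadata sample mismatch: {sorted(unmatched)}")
        if self.samples["timepoint"].isna().any():
            bad = self.samples.index[self.samples["timepoint"].isna()].tolist()
            raise ValidationError(f"samples without a timepoint: {bad}")
        if self.values.isna().any().any():
            raise ValidationError(
                "missing expression values; impute before construction or load with impute=True"
            )
        self.samples = self.samples.copy()
        self.samples["timepoint"] = self.samples["timepoint"].astype(int)
        order = self.samples.sort_values(
            ["condition", "replicate", "timepoint"], kind="stable"
        ).index
        self.samples = self.samples.loc[order]
        self.values = self.values.loc[:, order].astype(float)
        for cond, meta in self.samples.groupby("condition"):
            if meta["timepoint"].nunique() < 2:
                raise ValidationError(f"condition {cond!r} has <2 distinct timepoints")

    @property
    def gene_ids(self):
        return list(self.values.index)

    @property
    def n_samples(self):
        return self.values.shape[1]

    def copy(self) -> "ExpressionTimeSeries":
        return ExpressionTimeSeries(self.values.copy(), self.samples.copy())

    def equals(self, other: "ExpressionTimeSeries") -> bool:
        return self.values.equals(other.values) and self.samples.equals(other.samples)


def load_timeseries(path, meta_path, impute: bool = False) -> ExpressionTimeSeries:
    """Load an expression table (gene x sample TSV) plus a sample-metadata TSV.

    The metadata table needs columns ``sample``, ``timepoint``, ``replicate``,
    ``condition``.  With ``impute=True`` missing cells are filled by per-gene
    linear interpolation along the canonical sample order; otherwise they are
    a load error.
    """
    expr, _ = _read_tsv(path, [])
    gene_col = expr.columns[0]
    expr = expr.set_index(gene_col)
    expr = expr.apply(pd.to_numeric)
    meta, _ = _read_tsv(meta_path, ["sample", "timepoint", "replicate", "condition"])
    meta = meta.set_index("sample")
    meta["timepoint"] = pd.to_numeric(meta["timepoint"])
    unmatched = set(expr.columns) ^ set(meta.index)
    if unmatched:
        raise ValidationError(
            f"samples present in only one of {path}/{meta_path}: {sorted(unmatched)}"
        )
    if impute and expr.isna().any().any():
        order = meta.sort_values(["condition", "replicate", "timepoint"], kind="stable").index
        expr = expr.loc[:, order].interpolate(axis=1, limit_direction="both")
    return ExpressionTimeSeries(expr, meta)


def write_timeseries(ts: ExpressionTimeSeries, path, meta_path) -> None:
    out = ts.values.copy()
    out.insert(0, "gene", out.index)
    _write_tsv(out, path)
    meta = ts.samples.copy()
    meta.insert(0, "sample", meta.index)
    _write_tsv(meta, meta_path)


# ---------------------------------------------------------------------------
# Scored network


@dataclass
class ScoredNetwork:
    """A directed regulator -> target edge set with optional scores and signs.

    ``edges`` columns: ``regulator``, ``target``, optional ``score`` (>= 0)
    and ``sign`` (one of ``+ - unknown``).  Self-edges are permitted but
    flagged in :attr:`self_edges`.
    """

    edges: pd.DataFrame
    name: str = ""
    #: optional per-edge consensus support counts (set by consensus_union)
    support: pd.Series | None = None

    def __post_init__(self):
        req = {"regulator", "target"}
        if not req.issubset(self.edges.columns):
            raise ValidationError(f"edge frame needs columns {sorted(req)}")
        self.edges = self.edges.reset_index(drop=True)
        dup = self.edges.duplicated(subset=["regulator", "target"], keep=False)
        if dup.any():
            pairs = self.edges.loc[dup, ["regulator", "target"]].apply(tuple, axis=1).unique()
            raise ValidationError(f"duplicate edges: {list(pairs)[:10]}")
        if "score" in self.edges.columns:
            self.edges["score"] = self.edges["score"].astype(float)
            if (self.edges["score"] < 0).any():
                raise ValidationError("negative edge scores")
        self.self_edges = frozenset(
            self.edges.loc[self.edges.regulator == self.edges.target, "regulator"]
        )

    @property
    def regulators(self) -> frozenset:
        return frozenset(self.edges["regulator"])

    @property
    def targets(self) -> frozenset:
        return frozenset(self.edges["target"])

    @property
    def nodes(self) -> frozenset:
        return self.regulators | self.targets

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def scored(self) -> bool:
        return "score" in self.edges.columns

    def edge_set(self) -> frozenset:
        return frozenset(zip(self.edges["regulator"], self.edges["target"]))

    def scores(self) -> pd.Series:
        if not self.scored:
            raise ValidationError(f"network {self.name!r} has no scores")
        return self.edges.set_index(["regulator", "target"])["score"]

    @classmethod
    def from_edges(cls, pairs, name: str = "", scores=None) -> "ScoredNetwork":
        pairs = list(pairs)
        frame = pd.DataFrame(pairs, columns=["regulator", "target"])
        if scores is not None:
            frame["score"] = list(scores)
        return cls(frame, name=name)


def load_network(path, score_column: str | None = "score") -> ScoredNetwork:
    """Load a TSV edge list (regulator, target[, score][, sign]).

    Duplicate (regulator, target) pairs are rejected with the offending
    1-based line numbers in the message.
    """
    frame, numbers = _read_tsv(path, ["regulator", "target"])
    bad = frame["regulator"].isna() | frame["target"].isna()
    if bad.any():
        pos = int(np.flatnonzero(bad)[0])
        raise ParseError(f"{path}: malformed line {numbers[pos]}")
    dup = frame.duplicated(subset=["regulator", "target"], keep=False)
    if dup.any():
        lines = [numbers[i] for i in np.flatnonzero(dup)]
        raise ValidationError(f"{path}: duplicate edges on lines {lines}")
    keep = ["regulator", "target"]
    if score_column and score_column in frame.columns:
        frame[score_column] = pd.to_numeric(frame[score_column])
        keep.append(score_column)
        frame = frame.rename(columns={score_column: "score"})
        keep[-1] = "score"
    if "sign" in frame.columns:
        keep.append("sign")
    return ScoredNetwork(frame[keep], name=str(path))


def write_network(net: ScoredNetwork, path) -> None:
    _write_tsv(net.edges, path)


# ---------------------------------------------------------------------------
# Priors


@dataclass
class PriorSet:
    """Weighted prior regulator->target interactions with evidence labels.

    One record per (regulator, target); a pair supported by several
    evidence types keeps the maximum weight and the union of labels.
    """

    edges: pd.DataFrame  # columns: regulator, target, weight, evidence

    def __post_init__(self):
        req = {"regulator", "target", "weight", "evidence"}
        if not req.issubset(self.edges.columns):
            raise ValidationError(f"prior frame needs columns {sorted(req)}")
        self.edges = self.edges.reset_index(drop=True)
        self.edges["weight"] = self.edges["weight"].astype(float)
        if ((self.edges["weight"] <= 0) | (self.edges["weight"] > 1)).any():
            raise ValidationError("prior weights must lie in (0, 1]")
        for ev in self.edges["evidence"]:
            for label in str(ev).split(","):
                if label not in EVIDENCE_TYPES:
                    raise ValidationError(f"unknown evidence type {label!r}")
        if self.edges.duplicated(subset=["regulator", "target"]).any():
            raise ValidationError("duplicate prior pairs; collapse before construction")

    def pairs(self) -> frozenset:
        return frozenset(zip(self.edges["regulator"], self.edges["target"]))

    def __len__(self):
        return len(self.edges)

    @classmethod
    def from_records(cls, records) -> "PriorSet":
        """Build from (regulator, target, evidence[, weight]) records,
        collapsing duplicates by max weight and merging evidence labels."""
        best: dict = {}
        for rec in records:
            reg, tgt, ev = rec[0], rec[1], rec[2]
            w = rec[3] if len(rec) > 3 else EVIDENCE_WEIGHTS[ev]
            key = (reg, tgt)
            if key in best:
                w0, evs = best[key]
                best[key] = (max(w0, w), evs | {ev})
            else:
                best[key] = (w, {ev})
        rows = [
            {"regulator": r, "target": t, "weight": w, "evidence": ",".join(sorted(evs))}
            for (r, t), (w, evs) in sorted(best.items())
        ]
        return cls(pd.DataFrame(rows, columns=["regulator", "target", "weight", "evidence"]))


def load_priors(path) -> PriorSet:
    frame, _ = _read_tsv(path, ["regulator", "target", "evidence"])
    records = []
    for row in frame.itertuples(index=False):
        w = float(row.weight) if hasattr(row, "weight") else EVIDENCE_WEIGHTS[row.evidence]
        records.append((row.regulator, row.target, row.evidence, w))
    return PriorSet.from_records(records)


def write_priors(priors: PriorSet, path) -> None:
    _write_tsv(priors.edges, path)


# ---------------------------------------------------------------------------
# Gold standard


@dataclass
class GoldStandard:
    """Known functional interactions within a declared regulator/target universe."""

    positives: frozenset
    regulator_universe: frozenset
    target_universe: frozenset

    def __post_init__(self):
        self.positives = frozenset(self.positives)
        self.regulator_universe = frozenset(self.regulator_universe)
        self.target_universe = frozenset(self.target_universe)
        stray = [
            (r, t)
            for r, t in self.positives
            if r not in self.regulator_universe or t not in self.target_universe
        ]
        if stray:
            raise ValidationError(f"positives outside the declared universe: {stray[:10]}")

    @property
    def measurable_regulators(self) -> frozenset:
        """Regulators with at least one positive interaction."""
        return frozenset(r for r, _ in self.positives)


def load_gold_standard(path, regulator_universe=None, target_universe=None) -> GoldStandard:
    frame, _ = _read_tsv(path, ["regulator", "target"])
    pos = frozenset(zip(frame["regulator"], frame["target"]))
    regs = frozenset(regulator_universe) if regulator_universe else frozenset(frame["regulator"])
    tgts = frozenset(target_universe) if target_universe else frozenset(frame["target"])
    return GoldStandard(pos, regs, tgts)


def write_gold_standard(gs: GoldStandard, path) -> None:
    frame = pd.DataFrame(sorted(gs.positives), columns=["regulator", "target"])
    _write_tsv(frame, path)


# ---------------------------------------------------------------------------
# Module partitions


@dataclass
class ModulePartition:
    """A gene -> module-id mapping at one hierarchy level.

    Module ids are compacted to contiguous integers 0..B-1 (stable order of
    first appearance is not preserved; ids sort by original label).
    """

    assignment: dict
    level: str = "level1"

    def __post_init__(self):
        labels = sorted(set(self.assignment.values()), key=lambda x: str(x))
        remap = {lab: i for i, lab in enumerate(labels)}
        self.assignment = {g: remap[m] for g, m in self.assignment.items()}

    @property
    def genes(self) -> frozenset:
        return frozenset(self.assignment)

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values())) if self.assignment else 0

    def members(self, module: int) -> frozenset:
        return frozenset(g for g, m in self.assignment.items() if m == module)

    def labels_for(self, genes) -> np.ndarray:
        return np.array([self.assignment[g] for g in genes], dtype=int)


def load_partition(path, level: str = "level1") -> ModulePartition:
    frame, _ = _read_tsv(path, ["gene", "module"])
    if frame["gene"].duplicated().any():
        dups = frame.loc[frame["gene"].duplicated(), "gene"].tolist()
        raise ValidationError(f"{path}: genes in more than one module: {dups[:10]}")
    return ModulePartition(dict(zip(frame["gene"], frame["module"])), level=level)


def write_partition(partition: ModulePartition, path) -> None:
    frame = pd.DataFrame(
        sorted(partition.assignment.items()), columns=["gene", "module"]
    )
    _write_tsv(frame, path)


# ---------------------------------------------------------------------------
# Genomic intervals (BED convention: 0-based half-open)


@dataclass
class GenomicIntervalSet:
    """Intervals in 0-based half-open coordinates (BED convention).

    ``records`` columns: chrom, start, end, and optional name, strand.
    Strand is carried but ignored by all overlap operations.
    """

    records: pd.DataFrame

    def __post_init__(self):
        req = {"chrom", "start", "end"}
        if not req.issubset(self.records.columns):
            raise ValidationError(f"interval frame needs columns {sorted(req)}")
        self.records = self.records.reset_index(drop=True)
        self.records["start"] = self.records["start"].astype(int)
        self.records["end"] = self.records["end"].astype(int)
        bad = self.records["start"] >= self.records["end"]
        if bad.any():
            rows = self.records.loc[bad, ["chrom", "start", "end"]].values.tolist()
            raise ValidationError(f"empty/inverted intervals: {rows[:10]}")
        if "name" not in self.records.columns:
            self.records["name"] = "."

    def __len__(self):
        return len(self.records)

    def sorted(self) -> "GenomicIntervalSet":
        frame = self.records.sort_values(["chrom", "start", "end"], kind="stable")
        return GenomicIntervalSet(frame.reset_index(drop=True))

    def chromosomes(self) -> list:
        return sorted(set(self.records["chrom"]))

    def by_chrom(self, chrom) -> pd.DataFrame:
        return self.records[self.records["chrom"] == chrom]

    @classmethod
    def from_tuples(cls, tuples) -> "GenomicIntervalSet":
        cols = ["chrom", "start", "end", "name", "strand"]
        rows = [dict(zip(cols, t)) for t in tuples]
        frame = pd.DataFrame(rows)
        return cls(frame)


def load_bed(path) -> GenomicIntervalSet:
    """Read BED3/BED6; track/browser and '#' lines are skipped."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            parts = s.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: malformed BED line {i}")
            row = {"chrom": parts[0], "start": int(parts[1]), "end": int(parts[2])}
            if len(parts) > 3:
                row["name"] = parts[3]
            if len(parts) > 5:
                row["strand"] = parts[5]
            rows.append(row)
    if not rows:
        return GenomicIntervalSet(pd.DataFrame(columns=["chrom", "start", "end", "name"]))
    return GenomicIntervalSet(pd.DataFrame(rows))


def write_bed(ivs: GenomicIntervalSet, path) -> None:
    cols = ["chrom", "start", "end", "name"]
    frame = ivs.records.copy()
    if "strand" in frame.columns:
        frame["score"] = 0
        cols += ["score", "strand"]
    frame[cols].to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# Differential expression and knockdown tables


@dataclass
class DETable:
    """One row per gene: log2 fold change and BH-adjusted p-value."""

    rows: pd.DataFrame  # columns: gene, log2fc, padj

    def __post_init__(self):
        req = {"gene", "log2fc", "padj"}
        if not req.issubset(self.rows.columns):
            raise ValidationError(f"DE table needs columns {sorted(req)}")
        self.rows = self.rows.reset_index(drop=True)
        if self.rows["gene"].duplicated().any():
            raise ValidationError("duplicate genes in DE table")
        self.rows["log2fc"] = self.rows["log2fc"].astype(float)
        self.rows["padj"] = self.rows["padj"].astype(float)
        if self.rows["padj"].isna().any():
            raise ValidationError("padj missing for some genes")
        if ((self.rows["padj"] < 0) | (self.rows["padj"] > 1)).any():
            raise ValidationError("padj outside [0, 1]")


def load_de_table(path) -> DETable:
    frame, _ = _read_tsv(path, ["gene", "log2fc", "padj"])
    frame["log2fc"] = pd.to_numeric(frame["log2fc"])
    frame["padj"] = pd.to_numeric(frame["padj"])
    return DETable(frame[["gene", "log2fc", "padj"]])


def write_de_table(de: DETable, path) -> None:
    _write_tsv(de.rows, path)


@dataclass
class KDExperiment:
    """Replicate ddCT responses to one regulator knockdown.

    ``ddct`` is replicates x genes; the regulator's own column must be
    present (its knockdown response is the correlation anchor).
    """

    regulator: str
    ddct: pd.DataFrame

    def __post_init__(self):
        if self.regulator not in self.ddct.columns:
            raise ValidationError(f"regulator {self.regulator!r} missing from ddct columns")
        if self.n_replicates < 6:
            raise ValidationError(
                f"need >=6 replicates, got {self.n_replicates}"
            )

    @property
    def n_replicates(self) -> int:
        return self.ddct.shape[0]

    @property
    def targets(self) -> list:
        return [c for c in self.ddct.columns if c != self.regulator]


# ---------------------------------------------------------------------------
# Evaluation bookkeeping


@dataclass(frozen=True)
class EvaluationCounts:
    """Counts underlying precision fold enrichment.

    p: correct predictions; n: predicted edges; k: gold-standard edges;
    K: possible edges (#regulators x #targets).
    """

    p: int
    n: int
    k: int
    K: int

    def __post_init__(self):
        for name in ("p", "n", "k", "K"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.p > min(self.n, self.k):
            raise ValidationError("p cannot exceed min(n, k)")
        if self.n > self.K or self.k > self.K:
            raise ValidationError("n and k cannot exceed K")


@dataclass(frozen=True)
class LassoConfig:
    """Time-lagged lasso settings.

    Penalties are per-coefficient multipliers on the standardized scale:
    coefficients of prior edges are penalized by ``lambda_prior`` and all
    others by ``lambda_nonprior`` (0 < lambda_prior <= lambda_nonprior).
    ``alpha`` is the overall regularization strength the multipliers scale.
    """

    l_max: int = 5
    lambda_prior: float = 0.5
    lambda_nonprior: float = 1.0
    monotone_lags: bool = False
    alpha: float = 0.01

    def __post_init__(self):
        if self.l_max < 1:
            raise ValidationError("l_max must be >= 1")
        if not 0 < self.lambda_prior <= self.lambda_nonprior:
            raise ValidationError("need 0 < lambda_prior <= lambda_nonprior")
        if self.alpha <= 0:
            raise ValidationError("alpha must be > 0")


@dataclass(frozen=True)
class EnrichmentProblem:
    """Label-enrichment counts: Mt labeled among Nt drawn from Ng with Mg labeled."""

    Ng: int
    Mg: int
    Nt: int
    Mt: int

    def __post_init__(self):
        if not (0 <= self.Mt <= self.Mg <= self.Ng):
            raise ValidationError("need 0 <= Mt <= Mg <= Ng")
        if not (self.Mt <= self.Nt <= self.Ng):
            raise ValidationError("need Mt <= Nt <= Ng")


def flag_warning(message: str) -> None:
    """Uniform channel for contract-level warnings."""
    warnings.warn(message, UserWarning, stacklevel=3)
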