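"""Construction of the weighted TF->gene physical prior set.

Binding-site intervals (ChIP peaks, motif hits, eY1H promoter baits) are
filtered against ATAC open-chromatin regions, mapped to genes through TSS
windows, and merged into a single weighted prior set.  All coordinates are
0-based half-open (BED convention) and strand is ignored throughout.

Interval arithmetic follows bedtools semantics: overlap requires at least
one shared base, merging joins overlapping *or* bookended (gap 0)
intervals, and consensus across replicates is defined by per-base support
counting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_model import (
    EVIDENCE_WEIGHTS,
    GenomicIntervalSet,
    PriorSet,
    flag_warning,
)

__all__ = [
    "intersect_filter",
    "merge_intervals",
    "consensus_open_regions",
    "map_sites_to_genes",
    "filter_ey1h",
    "build_prior_set",
]


def _merged_arrays(ivs: GenomicIntervalSet, chrom) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint sorted (starts, ends) covering chrom with bookended merging."""
    sub = ivs.by_chrom(chrom)
    if sub.empty:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:  # overlapping or bookended
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s), np.array(out_e)


def merge_intervals(ivs: GenomicIntervalSet) -> GenomicIntervalSet:
    """Merge overlapping or bookended intervals per chromosome; output sorted."""
    rows = []
    for chrom in ivs.chromosomes():
        s, e = _merged_arrays(ivs, chrom)
        for a, b in zip(s, e):
            rows.append({"chrom": chrom, "start": int(a), "end": int(b), "name": "."})
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return GenomicIntervalSet(frame)


def _overlaps_any(starts, ends, q_start, q_end) -> np.ndarray:
    """For each query [q_start, q_end), does it share >=1 bp with the
    disjoint sorted intervals (starts, ends)?"""
    if len(starts) == 0:
        return np.zeros(len(q_start), dtype=bool)
    idx = np.searchsorted(starts, q_end, side="left") - 1
    hit = idx >= 0
    hit[hit] = ends[idx[hit]] > q_start[hit]
    return hit


def intersect_filter(
    sites: GenomicIntervalSet, open_regions: GenomicIntervalSet
) -> GenomicIntervalSet:
    """Keep sites with >=1 bp overlap with any open region (no clipping).

    Sites on chromosomes absent from the open-region set are dropped with a
    warning rather than raising.
    """
    open_chroms = set(open_regions.chromosomes())
    keep_masks = []
    missing = sorted(set(sites.chromosomes()) - open_chroms)
    if missing:
        flag_warning(f"chromosome(s) {missing} absent from open regions; their sites dropped")
    mask = np.zeros(len(sites.records), dtype=bool)
    for chrom in sites.chromosomes():
        rows = sites.records["chrom"] == chrom
        if chrom not in open_chroms:
            continue
        starts, ends = _merged_arrays(open_regions, chrom)
        sub = sites.records[rows]
        mask[np.flatnonzero(rows)] = _overlaps_any(
            starts, ends, sub["start"].to_numpy(), sub["end"].to_numpy()
        )
    del keep_masks
    return GenomicIntervalSet(sites.records[mask].reset_index(drop=True))


def consensus_open_regions(
    replicates: list[GenomicIntervalSet], min_support: int = 2
) -> GenomicIntervalSet:
    """Positions covered by >= min_support replicate sets, as maximal intervals.

    Each replicate contributes at most one unit of coverage per base (its
    intervals are merged first), so the result is order-independent.
    """
    if min_support > len(replicates):
        raise ValueError(
            f"min_support={min_support} exceeds the {len(replicates)} replicate sets"
        )
    chroms = sorted({c for rep in replicates for c in rep.chromosomes()})
    rows = []
    for chrom in chroms:
        events = []  # (position, delta)
        for rep in replicates:
            s, e = _merged_arrays(rep, chrom)
            events.extend((int(p), +1) for p in s)
            events.extend((int(p), -1) for p in e)
        events.sort()
        depth, cur_start = 0, None
        for pos, delta in events:
            new_depth = depth + delta
            if depth < min_support <= new_depth and cur_start is None:
                cur_start = pos
            elif cur_start is not None and new_depth < min_support:
                if pos > cur_start:
                    rows.append({"chrom": chrom, "start": cur_start, "end": pos, "name": "."})
                cur_start = None
            depth = new_depth
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    # adjacent segments can be bookended when depth dips and recovers at a point
    return merge_intervals(GenomicIntervalSet(frame)) if rows else GenomicIntervalSet(frame)


def map_sites_to_genes(
    sites: GenomicIntervalSet, tss: GenomicIntervalSet, window: int = 1000
) -> list[tuple[str, str]]:
    """Emit (TF, gene) pairs for every TSS within ``window`` bp of a site.

    Sites carry the TF in their ``name`` field; TSS records are 1 bp and
    named by gene.  The site is extended by ``window`` on both ends and a
    pair is emitted on >=1 bp overlap; duplicates are collapsed.  With
    window 0 this reduces to TSS-in-site containment.
    """
    bad = tss.records["end"] - tss.records["start"] != 1
    if bad.any():
        raise ValueError("TSS records must be exactly 1 bp")
    pairs = set()
    for chrom in sites.chromosomes():
        t_sub = tss.by_chrom(chrom)
        if t_sub.empty:
            continue
        positions = t_sub["start"].to_numpy()
        order = np.argsort(positions, kind="stable")
        positions = positions[order]
        genes = t_sub["name"].to_numpy()[order]
        for row in sites.by_chrom(chrom).itertuples(index=False):
            lo = row.start - window
            hi = row.end + window  # TSS position t qualifies iff lo <= t < hi
            i = np.searchsorted(positions, lo, side="left")
            j = np.searchsorted(positions, hi, side="left")
            for g in genes[i:j]:
                pairs.add((row.name, g))
    return sorted(pairs)


def filter_ey1h(
    pairs: list[tuple[str, str]],
    tss: GenomicIntervalSet,
    open_regions: GenomicIntervalSet,
) -> list[tuple[str, str]]:
    """Keep (TF, gene) pairs whose target-gene TSS overlaps an open region.

    Genes without a TSS record are dropped with a warning.
    """
    tss_map = {}
    for row in tss.records.itertuples(index=False):
        tss_map[row.name] = (row.chrom, int(row.start))
    merged = {c: _merged_arrays(open_regions, c) for c in open_regions.chromosomes()}
    kept, missing = [], set()
    for tf, gene in pairs:
        if gene not in tss_map:
            missing.add(gene)
            continue
        chrom, pos = tss_map[gene]
        starts, ends = merged.get(chrom, (np.empty(0, dtype=int), np.empty(0, dtype=int)))
        if _overlaps_any(starts, ends, np.array([pos]), np.array([pos + 1]))[0]:
            kept.append((tf, gene))
    if missing:
        flag_warning(f"{len(missing)} gene(s) without TSS dropped from eY1H pairs")
    return sorted(set(kept))


def build_prior_set(chip=(), motif=(), ey1h=()) -> PriorSet:
    """Union the evidence streams into one weighted prior set.

    Weights by data type: ChIP 0.8; motif and eY1H 0.6.  A pair present in
    several sources keeps the maximum weight and all evidence labels.
    """
    records = []
    for source, label in ((chip, "chip"), (motif, "motif"), (ey1h, "ey1h")):
        for tf, gene in set(source):
            records.append((tf, gene, label, EVIDENCE_WEIGHTS[label]))
    return PriorSet.from_records(records)
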