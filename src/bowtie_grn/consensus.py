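"""Consensus building: group candidate networks by edge overlap and
union them.

Networks inferred from different input combinations are compared by the
Jaccard similarity of their edge sets, grouped by complete-linkage
hierarchical clustering on 1 - similarity, and each group is collapsed
into a binary union network (per-edge support counts retained).  All
non-empty combinations of the resulting consensus networks can then be
ranked against a gold standard by PFE and AUFE.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core_model import GoldStandard, ScoredNetwork, ValidationError, flag_warning
from .evaluation import aufe, network_counts, per_regulator_pfe, pfe

__all__ = [
    "edge_overlap_similarity",
    "group_networks",
    "consensus_union",
    "evaluate_combinations",
]


def edge_overlap_similarity(
    nets: list[ScoredNetwork], asymmetric: bool = False
) -> np.ndarray:
    """Pairwise fraction of overlapping edges.

    Default is the Jaccard index |Ei & Ej| / |Ei | Ej|; with
    ``asymmetric`` entry (i, j) is |Ei & Ej| / |Ei| instead.  Empty
    networks get zero rows/columns (diagonal stays 1) with a warning.
    """
    if len(nets) < 2:
        raise ValueError("need at least two networks")
    sets = [net.edge_set() for net in nets]
    empty = [i for i, s in enumerate(sets) if not s]
    if empty:
        flag_warning(f"empty network(s) at positions {empty}; similarity set to 0")
    n = len(sets)
    sim = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j or not sets[i] or not sets[j]:
                continue
            inter = len(sets[i] & sets[j])
            denom = len(sets[i]) if asymmetric else len(sets[i] | sets[j])
            sim[i, j] = inter / denom
    return sim


def group_networks(similarity: np.ndarray, n_groups: int) -> np.ndarray:
    """Complete-linkage clustering on distance 1 - similarity.

    Returns 0-based group labels; groups are renumbered deterministically
    by the lowest network index they contain.
    """
    similarity = np.asarray(similarity, dtype=float)
    n = similarity.shape[0]
    if not 1 <= n_groups <= n:
        raise ValueError(f"n_groups must lie in [1, {n}]")
    if n_groups == n:
        return np.arange(n)
    dist = 1.0 - (similarity + similarity.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="complete")
    raw = fcluster(Z, t=n_groups, criterion="maxclust")
    order: dict = {}
    for idx, lab in enumerate(raw):
        order.setdefault(lab, idx)
    remap = {lab: rank for rank, (lab, _) in enumerate(sorted(order.items(), key=lambda kv: kv[1]))}
    return np.array([remap[lab] for lab in raw])


def consensus_union(group: list[ScoredNetwork], name: str = "consensus") -> ScoredNetwork:
    """Binary union of the group's edge sets, with per-edge support counts."""
    if not group:
        raise ValueError("empty group")
    support: dict = {}
    for net in group:
        for edge in net.edge_set():
            support[edge] = support.get(edge, 0) + 1
    edges = sorted(support)
    out = ScoredNetwork.from_edges(edges, name=name)
    out.support = pd.Series(
        [support[e] for e in edges],
        index=pd.MultiIndex.from_tuples(edges, names=["regulator", "target"]),
        name="support",
    )
    return out


def evaluate_combinations(
    consensus_nets: list[ScoredNetwork], gs: GoldStandard
) -> pd.DataFrame:
    """Score every non-empty subset union of consensus networks.

    Returns one row per subset with PFE, AUFE, edge and regulator counts,
    sorted by AUFE then PFE (both descending).  Capped at 16 networks
    (2^16 subsets).
    """
    if len(consensus_nets) > 16:
        raise ValueError("more than 16 networks; pre-group before enumerating subsets")
    rows = []
    indices = range(len(consensus_nets))
    for size in range(1, len(consensus_nets) + 1):
        for subset in combinations(indices, size):
            union = consensus_union(
                [consensus_nets[i] for i in subset],
                name="+".join(consensus_nets[i].name or str(i) for i in subset),
            )
            try:
                pfe_val = pfe(network_counts(union, gs))
                aufe_val = aufe(list(per_regulator_pfe(union, gs).values()))
            except ValidationError:
                # subset shares no measurable gold-standard content
                pfe_val = aufe_val = 0.0
            rows.append(
                {
                    "subset": subset,
                    "pfe": pfe_val,
                    "aufe": aufe_val,
                    "n_edges": union.n_edges,
                    "n_regulators": len(union.regulators),
                }
            )
    table = pd.DataFrame(rows)
    return table.sort_values(["aufe", "pfe"], ascending=False, kind="stable").reset_index(
        drop=True
    )
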