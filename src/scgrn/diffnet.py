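"""Differential comparison of two per-class consensus networks.

Weighted degree of a gene is the sum of its pair weights over all partners,
where the undirected pair weight is the larger of the two directed
confidences.  Differential hub genes (DHGs) are genes with a large absolute
degree difference between the class networks; differential edges are pairs
whose confidence differs by more than a threshold between classes (strictly
greater, default 0.75).  Degrees are computed on the full unthresholded
consensus; the confidence cut applies only to subnetwork export and
differential-edge calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus import ConsensusNetwork

__all__ = ["weighted_degree", "degree_difference", "high_confidence_subnetwork",
           "differential_edges", "run_diffnet", "DiffnetResult"]


def weighted_degree(net: ConsensusNetwork) -> pd.Series:
    """Per-gene sum of undirected pair weights (max over the two directions)."""
    w = net.pair_weight()
    np.fill_diagonal(w, 0.0)
    return pd.Series(w.sum(axis=1), index=net.genes, name="degree")


def degree_difference(a: pd.Series, b: pd.Series) -> pd.DataFrame:
    """Degree table plus DHG ranking by |degree_a − degree_b| descending.

    Ties break lexicographically by gene id.  Returns one row per gene with
    columns degree_class_a, degree_class_b, degree_difference, rank.
    """
    if set(a.index) != set(b.index):
        raise ValueError("degree tables cover different gene sets")
    b = b.loc[a.index]
    diff = (a - b).abs()
    table = pd.DataFrame({
        "degree_class_a": a,
        "degree_class_b": b,
        "degree_difference": diff,
    })
    table = table.iloc[np.lexsort((table.index.to_numpy(),
                                   -table["degree_difference"].to_numpy()))]
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def high_confidence_subnetwork(net: ConsensusNetwork,
                               threshold: float = 0.75) -> pd.DataFrame:
    """Undirected pairs with confidence strictly above the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    w = net.pair_weight()
    rows = []
    for i in range(net.n):
        for j in range(i + 1, net.n):
            if w[i, j] > threshold:
                rows.append((net.genes[i], net.genes[j], w[i, j]))
    return pd.DataFrame(rows, columns=["regulator", "target", "confidence"])


def differential_edges(a: ConsensusNetwork, b: ConsensusNetwork,
                       threshold: float = 0.75) -> pd.DataFrame:
    """Pairs whose class confidences differ by strictly more than threshold.

    direction_of_activation is class_b_only when conf_b − conf_a > threshold
    and class_a_only for the symmetric case.
    """
    if a.genes != b.genes:
        raise ValueError("networks cover different gene sets")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    wa, wb = a.pair_weight(), b.pair_weight()
    rows = []
    for i in range(a.n):
        for j in range(i + 1, a.n):
            delta = wb[i, j] - wa[i, j]
            if delta > threshold:
                rows.append((a.genes[i], a.genes[j], wa[i, j], wb[i, j],
                             delta, "class_b_only"))
            elif -delta > threshold:
                rows.append((a.genes[i], a.genes[j], wa[i, j], wb[i, j],
                             delta, "class_a_only"))
    return pd.DataFrame(rows, columns=["regulator", "target", "conf_class_a",
                                       "conf_class_b", "delta",
                                       "direction_of_activation"])


@dataclass
class DiffnetResult:
    degree_table: pd.DataFrame
    subnetwork_a: pd.DataFrame
    subnetwork_b: pd.DataFrame
    differential: pd.DataFrame


def run_diffnet(a: ConsensusNetwork, b: ConsensusNetwork,
                confidence_threshold: float = 0.75,
                differential_threshold: float = 0.75) -> DiffnetResult:
    """Degree table + DHG ranking, per-class subnetworks, differential edges."""
    if a.genes != b.genes:
        raise ValueError("networks cover different gene sets")
    deg_a = weighted_degree(a)
    deg_b = weighted_degree(b)
    return DiffnetResult(
        degree_table=degree_difference(deg_a, deg_b),
        subnetwork_a=high_confidence_subnetwork(a, confidence_threshold),
        subnetwork_b=high_confidence_subnetwork(b, confidence_threshold),
        differential=differential_edges(a, b, differential_threshold),
    )
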