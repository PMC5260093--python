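"""Top1net integration of per-algorithm score matrices.

Three steps per the integration framework:

1. Within each algorithm, rank all N(N−1) ordered gene pairs by confidence
   (rank 1 = most confident; ties get the average of covered ranks).
2. Map ranks to normalized ranked scores:
       NRS(i, j) = (N(N−1) + 1 − g(i, j)) / (N(N−1))  ∈ (0, 1]
   so the top pair maps to exactly 1 and the worst to 1/(N(N−1)).
3. The consensus confidence of a pair is the *maximum* NRS over all
   algorithms: one confident algorithm suffices to call an interaction.

Ranking is over ordered (directed) pairs — the N(N−1) denominator counts
ordered pairs — so symmetric algorithms simply yield mirrored ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .netinfer import ScoreMatrix

__all__ = ["RankedPairList", "ConsensusNetwork", "rank_pairs", "nrs_transform",
           "integrate_top1", "consensus_from_scores"]


@dataclass
class RankedPairList:
    """Per-ordered-pair rank values for one algorithm (best = 1)."""

    algorithm: str
    genes: list[str]
    ranks: np.ndarray  # N×N, diagonal nan

    @property
    def n(self) -> int:
        return len(self.genes)


@dataclass
class ConsensusNetwork:
    """Integrated per-pair confidences in (0, 1] with winning algorithm."""

    genes: list[str]
    confidence: np.ndarray  # N×N, diagonal 0
    provenance: np.ndarray  # N×N object array of algorithm ids
    class_label: str | None = None

    @property
    def n(self) -> int:
        return len(self.genes)

    def pair_weight(self) -> np.ndarray:
        """Undirected pair weight: max of the two directed confidences."""
        return np.maximum(self.confidence, self.confidence.T)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, gi in enumerate(self.genes):
            for j, gj in enumerate(self.genes):
                if i == j:
                    continue
                rows.append((gi, gj, self.confidence[i, j], self.provenance[i, j]))
        return pd.DataFrame(rows, columns=["regulator", "target", "confidence",
                                           "winning_algorithm"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_graphml(self, path, threshold: float = 0.0) -> None:
        import networkx as nx
        g = nx.DiGraph()
        g.add_nodes_from(self.genes)
        for i, gi in enumerate(self.genes):
            for j, gj in enumerate(self.genes):
                if i != j and self.confidence[i, j] > threshold:
                    g.add_edge(gi, gj, confidence=float(self.confidence[i, j]),
                               algorithm=str(self.provenance[i, j]))
        nx.write_graphml(g, path)


def rank_pairs(s: ScoreMatrix) -> RankedPairList:
    """Descending-score average ranks over all N(N−1) ordered pairs."""
    if s.n < 2:
        raise ValueError("ranking needs at least 2 genes")
    if not np.isfinite(s.scores[s.offdiag_mask()]).all():
        raise ValueError("non-finite scores cannot be ranked")
    mask = s.offdiag_mask()
    flat = s.scores[mask]
    ranks_flat = stats.rankdata(-flat, method="average")
    ranks = np.full((s.n, s.n), np.nan)
    ranks[mask] = ranks_flat
    return RankedPairList(s.algorithm, list(s.genes), ranks)


def nrs_transform(ranks: RankedPairList) -> ScoreMatrix:
    """Normalized ranked scores: (N(N−1) + 1 − g) / (N(N−1))."""
    n = ranks.n
    m = n * (n - 1)
    mask = ~np.eye(n, dtype=bool)
    g = ranks.ranks[mask]
    if np.any((g < 1) | (g > m)):
        raise ValueError(f"rank outside [1, {m}]")
    nrs = np.zeros((n, n))
    nrs[mask] = (m + 1 - g) / m
    return ScoreMatrix(ranks.algorithm, list(ranks.genes), nrs, {"transform": "nrs"})


def integrate_top1(nrs_list: list[ScoreMatrix],
                   class_label: str | None = None) -> ConsensusNetwork:
    """Per-pair maximum NRS across algorithms; ties keep the first algorithm."""
    if not nrs_list:
        raise ValueError("empty NRS list")
    genes = nrs_list[0].genes
    for sm in nrs_list[1:]:
        if sm.genes != genes:
            raise ValueError("NRS matrices have mismatched gene sets")
    stacked = np.stack([sm.scores for sm in nrs_list])
    conf = stacked.max(axis=0)
    win = stacked.argmax(axis=0)
    names = np.array([sm.algorithm for sm in nrs_list], dtype=object)
    provenance = names[win]
    np.fill_diagonal(conf, 0.0)
    return ConsensusNetwork(list(genes), conf, provenance, class_label)


def consensus_from_scores(score_list: list[ScoreMatrix],
                          class_label: str | None = None) -> ConsensusNetwork:
    """Full Step 1–3 pipeline: rank, NRS-transform, integrate by max."""
    nrs = [nrs_transform(rank_pairs(s)) for s in score_list]
    return integrate_top1(nrs, class_label)
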