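"""Seeded two-class single-cell expression datasets with planted ground truth.

The generator emulates the shape of a small Fluidigm-style FPKM dataset:
two cell classes of unequal size (default 15 vs 50), a handful of
class-discriminating marker genes, a subset of genes wired into
class-specific regulatory structure, and a large background of null genes
with dropout zeros.

Model: each gene has a baseline log2 mean; marker genes are up-regulated in
class_b by ``marker_effect`` on the log scale; network genes follow a
linear-Gaussian structural equation model per class over a random DAG, so
each class has its own true edge set; everything is exponentiated back to
the FPKM scale and dropout zeroes entries independently.  Differential hubs
are planted by giving a hub gene out-edges in exactly one class.

This is deliberately not a count-level scRNA-seq simulator: no library
sizes, no UMIs, no zero-inflated negative binomial.  It exists so that every
downstream stage (filtering, feature selection, classification, network
inference, differential-hub ranking) has a recovery-testable input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CLASS_A, CLASS_B, ExpressionMatrix

__all__ = ["SyntheticConfig", "GroundTruth", "generate_dataset", "generate_genesets",
           "GeneSetCollection", "write_gmt"]

#: out-edges given to each planted differential hub: a hub regulates a large
#: share of its module (half the non-hub genes of the default 20-gene
#: configuration)
HUB_OUT_DEGREE = 10


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic two-class dataset.

    Defaults mirror the study conditions: 15 progenitor-like (class_a) and
    50 neuronal-like (class_b) cells, 10 markers with a 3 log2-unit shift,
    20 network genes, 2 differential hubs, 10% dropout.
    """

    n_genes: int = 2000
    n_cells_class_a: int = 15
    n_cells_class_b: int = 50
    n_markers: int = 10
    marker_effect: float = 3.0
    n_network_genes: int = 20
    edge_density: float = 0.1
    n_diff_hubs: int = 2
    dropout_rate: float = 0.1
    noise_sd: float = 0.5
    baseline_mean: float = 4.0
    baseline_sd: float = 1.0
    low_expression_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_genes, self.n_cells_class_a, self.n_cells_class_b,
                  self.n_markers, self.n_network_genes, self.n_diff_hubs)
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.n_markers + self.n_network_genes > self.n_genes:
            raise ValueError("n_markers + n_network_genes must be <= n_genes")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.n_diff_hubs > self.n_network_genes:
            raise ValueError("n_diff_hubs must be <= n_network_genes")
        if self.noise_sd < 0 or self.edge_density < 0 or self.edge_density > 1:
            raise ValueError("noise_sd >= 0 and edge_density in [0,1] required")
        if not 0.0 <= self.low_expression_fraction <= 1.0:
            raise ValueError("low_expression_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted structure of a generated dataset."""

    marker_genes: set[str]
    edges_class_a: dict[tuple[str, str], float]
    edges_class_b: dict[tuple[str, str], float]
    diff_hub_genes: list[str]
    network_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for edges in (self.edges_class_a, self.edges_class_b):
            for (src, dst) in edges:
                if src == dst:
                    raise ValueError("self-loop in planted edge set")
        net = set(self.network_genes)
        if not set(self.diff_hub_genes) <= net:
            raise ValueError("diff_hub_genes must be network genes")

    def to_json(self) -> str:
        return json.dumps({
            "marker_genes": sorted(self.marker_genes),
            "edges_class_a": [[s, t, w] for (s, t), w in sorted(self.edges_class_a.items())],
            "edges_class_b": [[s, t, w] for (s, t), w in sorted(self.edges_class_b.items())],
            "diff_hub_genes": self.diff_hub_genes,
            "network_genes": self.network_genes,
        }, indent=1)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


@dataclass
class GeneSetCollection:
    """Named genesets (GMT-compatible)."""

    sets: dict[str, list[str]]
    source: str = "synthetic"

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"empty geneset: {name!r}")


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def _sample_class_edges(rng: np.random.Generator, net_genes: list[str],
                        cfg: SyntheticConfig) -> tuple[dict, dict, list[str]]:
    """Random DAG edges per class plus hub edges active in one class only.

    Network genes are ordered topologically by index; shared backbone edges
    (present in both classes) are drawn at ``edge_density`` over forward
    pairs among non-hub genes; each differential hub gets HUB_OUT_DEGREE
    strong out-edges in exactly one class.
    """
    n = len(net_genes)
    hubs = net_genes[:cfg.n_diff_hubs]
    edges_a: dict[tuple[str, str], float] = {}
    edges_b: dict[tuple[str, str], float] = {}
    non_hub = net_genes[cfg.n_diff_hubs:]
    # differential hubs: strong out-edges in exactly one class (alternating)
    hub_targets: set[str] = set()
    for h_idx, hub in enumerate(hubs):
        targets = rng.choice(len(non_hub), size=min(HUB_OUT_DEGREE, len(non_hub)),
                             replace=False)
        active = edges_b if h_idx % 2 == 0 else edges_a
        for t in targets:
            active[(hub, non_hub[t])] = rng.uniform(0.8, 1.2) * rng.choice([-1.0, 1.0])
            hub_targets.add(non_hub[t])
    # shared backbone among non-hub genes (same weights both classes); hub
    # targets act as sinks so indirect paths cannot cancel a planted hub edge
    for i in range(len(non_hub)):
        if non_hub[i] in hub_targets:
            continue
        for j in range(i + 1, len(non_hub)):
            if rng.random() < cfg.edge_density:
                w = rng.uniform(0.6, 1.2) * rng.choice([-1.0, 1.0])
                edges_a[(non_hub[i], non_hub[j])] = w
                edges_b[(non_hub[i], non_hub[j])] = w
    return edges_a, edges_b, hubs


def _sem_sample(rng: np.random.Generator, net_genes: list[str],
                edges: dict[tuple[str, str], float], baselines: np.ndarray,
                n_cells: int, noise_sd: float) -> np.ndarray:
    """Sample log-scale values from the linear-Gaussian SEM (genes × cells)."""
    idx = {g: i for i, g in enumerate(net_genes)}
    out = np.empty((len(net_genes), n_cells))
    parents: list[list[tuple[int, float]]] = [[] for _ in net_genes]
    for (src, dst), w in edges.items():
        parents[idx[dst]].append((idx[src], w))
    # net_genes are in topological order by construction
    for i, g in enumerate(net_genes):
        val = baselines[i] + rng.normal(0.0, noise_sd, size=n_cells)
        for p, w in parents[i]:
            val = val + w * (out[p] - baselines[p])
        out[i] = val
    return out


def generate_dataset(config: SyntheticConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate a labelled FPKM-scale matrix plus its planted ground truth.

    Identical config (including seed) gives bit-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)
    n_cells = cfg.n_cells_class_a + cfg.n_cells_class_b
    cells = [f"A{i:03d}" for i in range(cfg.n_cells_class_a)] + \
            [f"B{i:03d}" for i in range(cfg.n_cells_class_b)]
    labels = pd.Series([CLASS_A] * cfg.n_cells_class_a + [CLASS_B] * cfg.n_cells_class_b,
                       index=cells, name="class")

    markers = genes[:cfg.n_markers]
    net_genes = genes[cfg.n_markers:cfg.n_markers + cfg.n_network_genes]

    baselines = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    # a tail of barely-expressed genes so the expression filter has work to do
    n_planted = cfg.n_markers + cfg.n_network_genes
    n_low = int(round(cfg.low_expression_fraction * (cfg.n_genes - n_planted)))
    if n_low > 0:
        baselines[cfg.n_genes - n_low:] = rng.normal(0.2, 0.2, size=n_low)
    log_vals = baselines[:, None] + rng.normal(0.0, cfg.noise_sd,
                                               size=(cfg.n_genes, n_cells))

    # markers are up-regulated in class_b by marker_effect on the log scale
    a_cols = np.arange(cfg.n_cells_class_a)
    b_cols = np.arange(cfg.n_cells_class_a, n_cells)
    log_vals[:cfg.n_markers, :][:, b_cols] += cfg.marker_effect

    # network genes: overwrite with SEM samples per class
    edges_a, edges_b, hubs = _sample_class_edges(rng, net_genes, cfg)
    if net_genes:
        net_idx = np.arange(cfg.n_markers, cfg.n_markers + cfg.n_network_genes)
        net_base = baselines[net_idx]
        vals_a = _sem_sample(rng, net_genes, edges_a, net_base,
                             cfg.n_cells_class_a, cfg.noise_sd)
        vals_b = _sem_sample(rng, net_genes, edges_b, net_base,
                             cfg.n_cells_class_b, cfg.noise_sd)
        log_vals[net_idx[:, None], a_cols[None, :]] = vals_a
        log_vals[net_idx[:, None], b_cols[None, :]] = vals_b

    fpkm = np.maximum(np.exp2(log_vals) - 1.0, 0.0)
    if cfg.dropout_rate > 0:
        drop = rng.random(size=fpkm.shape) < cfg.dropout_rate
        fpkm = np.where(drop, 0.0, fpkm)

    matrix = ExpressionMatrix(pd.DataFrame(fpkm, index=genes, columns=cells), labels)
    truth = GroundTruth(
        marker_genes=set(markers),
        edges_class_a=edges_a,
        edges_class_b=edges_b,
        diff_hub_genes=hubs,
        network_genes=net_genes,
    )
    return matrix, truth


def generate_genesets(truth: GroundTruth, n_sets: int, set_size: int, seed: int,
                      universe: list[str] | None = None) -> GeneSetCollection:
    """Random genesets over the gene universe, one enriched for the markers.

    When the truth has markers, the first set packs in as many markers as
    fit (at least half its members when set_size <= 2 × n_markers) and fills
    the rest uniformly; all other sets are uniform draws without replacement.
    """
    if set_size < 2:
        raise ValueError("set_size must be >= 2")
    if universe is None:
        universe = sorted(
            set(truth.marker_genes)
            | set(truth.network_genes)
            | {s for (s, _t) in truth.edges_class_a}
        )
    if set_size > len(universe):
        raise ValueError("set_size exceeds the gene universe")
    rng = np.random.default_rng(seed)
    markers = sorted(truth.marker_genes)
    sets: dict[str, list[str]] = {}
    start = 0
    if markers:
        take = min(len(markers), set_size)
        members = markers[:take]
        rest = [g for g in universe if g not in set(members)]
        fill = rng.choice(len(rest), size=set_size - take, replace=False)
        sets["SET_MARKER_ENRICHED"] = members + [rest[i] for i in sorted(fill)]
        start = 1
    for k in range(start, n_sets):
        pick = rng.choice(len(universe), size=set_size, replace=False)
        sets[f"SET_{k:03d}"] = [universe[i] for i in sorted(pick)]
    return GeneSetCollection(sets, source="synthetic")


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = [
        "\t".join([name, collection.source] + members)
        for name, members in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
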