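"""Twelve gene-pair scorers for regulatory-network inference.

Each scorer maps a (one-class) expression matrix to a :class:`ScoreMatrix`
of per-ordered-pair confidences (higher = more confident):

mutual-information family (shared discretized-MI estimate):
  relnet  — the MI matrix itself (relevance network)
  clr     — per-gene background z-scores, score = sqrt(z_i² + z_j²)
  aracne  — data-processing-inequality pruning of MI triangles (eps slack)
  mrnet   — greedy max-relevance min-redundancy forward selection per target
  c3net   — each gene keeps only its single maximum-MI partner
  bc3net  — bootstrap ensemble of significance-filtered C3NET runs

correlation family:
  pearson / spearman — |correlation coefficient|

regression family (directed):
  genie3 (K=all / K=sqrt)  — per-target random-forest variable importance
  tigress (area / max)     — stability selection over LARS paths

Symmetric scorers fill both ordered directions with the same value so the
consensus layer can treat every algorithm uniformly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import lars_path

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreMatrix", "MIEstimatorConfig", "mi_matrix", "score_correlation",
    "score_relnet", "score_clr", "score_aracne", "score_mrnet", "score_c3net",
    "score_bc3net", "score_genie3", "score_tigress", "run_battery",
    "default_registry",
]


@dataclass
class ScoreMatrix:
    """Per-ordered-pair confidence scores for one algorithm.

    ``scores`` is an N×N array with zero diagonal (self-pairs carry no
    score); symmetric-family algorithms satisfy scores[i, j] == scores[j, i].
    """

    algorithm: str
    genes: list[str]
    scores: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.genes)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (n, n):
            raise ValueError("scores must be N×N for N genes")
        if not np.isfinite(self.scores).all():
            raise ValueError("non-finite scores")
        np.fill_diagonal(self.scores, 0.0)

    @property
    def n(self) -> int:
        return len(self.genes)

    def offdiag_mask(self) -> np.ndarray:
        return ~np.eye(self.n, dtype=bool)


@dataclass(frozen=True)
class MIEstimatorConfig:
    """Discretization and estimator settings for mutual information."""

    binning: str = "equal_frequency"
    n_bins: int | None = None  # default floor(sqrt(n_cells))
    estimator: str = "maximum_likelihood"

    def __post_init__(self) -> None:
        if self.n_bins is not None and self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.binning not in ("equal_frequency", "equal_width"):
            raise ValueError(f"unknown binning: {self.binning!r}")
        if self.estimator not in ("maximum_likelihood", "miller_madow"):
            raise ValueError(f"unknown estimator: {self.estimator!r}")


def _values(m: ExpressionMatrix) -> np.ndarray:
    return m.values.to_numpy()


def discretize(vals: np.ndarray, cfg: MIEstimatorConfig) -> np.ndarray:
    """Per-gene bin indices; constant genes collapse to a single bin."""
    n_genes, n_cells = vals.shape
    n_bins = cfg.n_bins or max(2, int(math.floor(math.sqrt(n_cells))))
    out = np.zeros_like(vals, dtype=int)
    for g in range(n_genes):
        row = vals[g]
        if np.ptp(row) == 0:
            continue
        if cfg.binning == "equal_frequency":
            ranks = stats.rankdata(row, method="average") - 0.5
            out[g] = np.minimum((ranks * n_bins / n_cells).astype(int), n_bins - 1)
        else:
            edges = np.linspace(row.min(), row.max(), n_bins + 1)
            out[g] = np.minimum(np.digitize(row, edges[1:-1]), n_bins - 1)
    return out


def _entropy_counts(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _pair_mi(bi: np.ndarray, bj: np.ndarray, estimator: str) -> float:
    """Plug-in MI (nats) from bin indices via a bincount contingency table."""
    n = bi.size
    ky = int(bj.max()) + 1
    kx = int(bi.max()) + 1
    joint = np.bincount(bi * ky + bj, minlength=kx * ky).astype(float)
    joint = joint[joint > 0] / n
    px = np.bincount(bi).astype(float)
    py = np.bincount(bj).astype(float)
    px = px[px > 0] / n
    py = py[py > 0] / n
    hx = -(px * np.log(px)).sum()
    hy = -(py * np.log(py)).sum()
    hxy = -(joint * np.log(joint)).sum()
    mi = max(0.0, float(hx + hy - hxy))
    if estimator == "miller_madow":
        mi += (len(px) + len(py) - len(joint) - 1) / (2.0 * n)
        mi = max(mi, 0.0)
    return mi


def mi_matrix(m: ExpressionMatrix, cfg: MIEstimatorConfig | None = None) -> ScoreMatrix:
    """Pairwise mutual information (nats) of discretized expression."""
    cfg = cfg or MIEstimatorConfig()
    vals = _values(m)
    if vals.shape[1] < 3:
        raise ValueError("mutual information needs at least 3 cells")
    bins = discretize(vals, cfg)
    n = vals.shape[0]
    mi = np.zeros((n, n))
    constant = np.ptp(vals, axis=1) == 0
    for i in range(n):
        if constant[i]:
            continue
        for j in range(i + 1, n):
            if constant[j]:
                continue
            mi[i, j] = mi[j, i] = _pair_mi(bins[i], bins[j], cfg.estimator)
    return ScoreMatrix("mi", m.gene_ids, mi,
                       {"binning": cfg.binning, "n_bins": cfg.n_bins,
                        "estimator": cfg.estimator})


def score_correlation(m: ExpressionMatrix, method: str = "pearson") -> ScoreMatrix:
    """|Pearson| or |Spearman| correlation; constant genes score 0."""
    vals = _values(m)
    if vals.shape[1] < 3:
        raise ValueError("correlation needs at least 3 cells")
    if method == "spearman":
        vals = stats.rankdata(vals, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method: {method!r}")
    sd = vals.std(axis=1)
    ok = sd > 0
    corr = np.zeros((vals.shape[0], vals.shape[0]))
    if ok.sum() >= 2:
        sub = np.corrcoef(vals[ok])
        corr[np.ix_(ok, ok)] = np.abs(sub)
    return ScoreMatrix(method, m.gene_ids, corr, {"method": method})


def score_relnet(mi: ScoreMatrix) -> ScoreMatrix:
    """Relevance network: MI passed through unchanged."""
    return ScoreMatrix("relnet", mi.genes, mi.scores.copy(), dict(mi.params))


def score_clr(mi: ScoreMatrix) -> ScoreMatrix:
    """Context-likelihood-of-relatedness: background-corrected MI z-scores."""
    if mi.n < 3:
        raise ValueError("CLR needs at least 3 genes")
    s = mi.scores
    n = mi.n
    mask = mi.offdiag_mask()
    z = np.zeros_like(s)
    for i in range(n):
        row = s[i][mask[i]]
        mu, sd = row.mean(), row.std()
        if sd > 0:
            zi = np.maximum(0.0, (s[i] - mu) / sd)
            zi[i] = 0.0
            z[i] = zi
    out = np.sqrt(z ** 2 + z.T ** 2)
    np.fill_diagonal(out, 0.0)
    return ScoreMatrix("clr", mi.genes, out, dict(mi.params))


def score_aracne(mi: ScoreMatrix, eps: float = 0.1) -> ScoreMatrix:
    """Data-processing-inequality pruning with subtractive tolerance eps.

    For every triangle (i, j, k), the (i, j) edge is zeroed when
    MI(i, j) < min(MI(i, k), MI(j, k)) - eps, evaluated on the input MI.
    """
    s = mi.scores
    n = mi.n
    keep = s.copy()
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(n):
                if k == i or k == j:
                    continue
                if s[i, j] < min(s[i, k], s[j, k]) - eps:
                    keep[i, j] = keep[j, i] = 0.0
                    break
    return ScoreMatrix("aracne", mi.genes, keep, {**mi.params, "eps": eps})


def mrnet_selection(mi_row_fn, n: int, target: int) -> list[tuple[int, float]]:
    """Greedy MRMR ordering for one target: (candidate, score-at-selection).

    Score of candidate i = MI(i, target) − mean MI(i, already-selected);
    the first pick is pure relevance (argmax MI).
    """
    candidates = [i for i in range(n) if i != target]
    selected: list[int] = []
    out: list[tuple[int, float]] = []
    while candidates:
        best_i, best_s = None, -np.inf
        for i in candidates:
            rel = mi_row_fn(i, target)
            red = np.mean([mi_row_fn(i, k) for k in selected]) if selected else 0.0
            sc = rel - red
            if sc > best_s:
                best_i, best_s = i, sc
        out.append((best_i, best_s))
        selected.append(best_i)
        candidates.remove(best_i)
    return out


def score_mrnet(mi: ScoreMatrix) -> ScoreMatrix:
    """Max-relevance min-redundancy network from the MI matrix."""
    if mi.n < 3:
        raise ValueError("MRNET needs at least 3 genes")
    s = mi.scores
    n = mi.n
    pair = np.full((n, n), -np.inf)
    for j in range(n):
        for i, sc in mrnet_selection(lambda a, b: s[a, b], n, j):
            pair[i, j] = sc
    out = np.maximum(0.0, np.maximum(pair, pair.T))
    np.fill_diagonal(out, 0.0)
    return ScoreMatrix("mrnet", mi.genes, out, dict(mi.params))


def c3net_edges(s: np.ndarray, eligible: np.ndarray | None = None) -> set[tuple[int, int]]:
    """Undirected C3NET edge set: each gene's single maximum-score partner.

    ``eligible`` optionally masks which pairs may be linked (significance
    filter).  Genes whose eligible row is all ≤ 0 contribute no edge.
    """
    n = s.shape[0]
    edges: set[tuple[int, int]] = set()
    for i in range(n):
        row = s[i].copy()
        row[i] = -np.inf
        if eligible is not None:
            row[~eligible[i]] = -np.inf
        j = int(np.argmax(row))
        if row[j] > 0:
            edges.add((min(i, j), max(i, j)))
    return edges


def score_c3net(mi: ScoreMatrix, significance: str = "none",
                null_quantile: np.ndarray | None = None) -> ScoreMatrix:
    """Conservative causal-core network: per-gene argmax-MI partner only."""
    if mi.n < 2:
        raise ValueError("C3NET needs at least 2 genes")
    eligible = None
    if significance == "permutation":
        if null_quantile is None:
            raise ValueError("permutation significance requires a null threshold")
        eligible = mi.scores > null_quantile
    elif significance != "none":
        raise ValueError(f"unknown significance mode: {significance!r}")
    out = np.zeros_like(mi.scores)
    for i, j in c3net_edges(mi.scores, eligible):
        out[i, j] = out[j, i] = mi.scores[i, j]
    return ScoreMatrix("c3net", mi.genes, out, dict(mi.params))


def _null_mi_threshold(bins: np.ndarray, estimator: str, level: float,
                       rng: np.random.Generator, n_null: int = 200) -> float:
    """Quantile of a pooled null-MI distribution from gene-wise permutations."""
    n_genes, n_cells = bins.shape
    null = np.empty(n_null)
    for t in range(n_null):
        i, j = rng.integers(0, n_genes, size=2)
        perm = rng.permutation(n_cells)
        null[t] = _pair_mi(bins[i], bins[j][perm], estimator)
    return float(np.quantile(null, level))


def score_bc3net(m: ExpressionMatrix, cfg: MIEstimatorConfig | None = None,
                 boot: int = 10, alpha1: float = 0.99, alpha2: float = 0.99,
                 seed: int = 0) -> ScoreMatrix:
    """Bootstrap ensemble of significance-filtered C3NET runs.

    ``boot`` bootstrap resamples of cells each yield a C3NET edge set whose
    MI values must clear a permutation-null test at significance level
    ``alpha1``; edges are kept when their ensemble frequency is binomially
    significant at level ``alpha2`` (BH-corrected); the score is the
    selection frequency.  Large alpha values are permissive (0.99 keeps
    nearly every candidate), small values are strict.
    """
    if boot < 1:
        raise ValueError("boot must be >= 1")
    cfg = cfg or MIEstimatorConfig()
    vals = _values(m)
    n_genes, n_cells = vals.shape
    rng = np.random.default_rng(seed)
    freq = np.zeros((n_genes, n_genes))
    for _b in range(boot):
        take = rng.integers(0, n_cells, size=n_cells)
        bins = discretize(vals[:, take], cfg)
        mi = np.zeros((n_genes, n_genes))
        constant = np.array([len(np.unique(bins[g])) < 2 for g in range(n_genes)])
        for i in range(n_genes):
            if constant[i]:
                continue
            for j in range(i + 1, n_genes):
                if not constant[j]:
                    mi[i, j] = mi[j, i] = _pair_mi(bins[i], bins[j], cfg.estimator)
        thr = _null_mi_threshold(bins, cfg.estimator, 1.0 - alpha1, rng)
        for i, j in c3net_edges(mi, eligible=mi > thr):
            freq[i, j] += 1
            freq[j, i] += 1
    freq /= boot
    # ensemble-level binomial test: edge frequency vs uniform selection rate
    n_pairs = n_genes * (n_genes - 1) // 2
    iu = np.triu_indices(n_genes, 1)
    total_selected = freq[iu].sum() * boot
    p0 = min(1.0, total_selected / (boot * n_pairs)) if n_pairs else 0.0
    pvals = stats.binom.sf(np.round(freq[iu] * boot) - 1, boot, p0)
    from statsmodels.stats.multitest import multipletests
    keep_flat = np.zeros(len(pvals), dtype=bool)
    nonzero = freq[iu] > 0
    if nonzero.any():
        keep_flat[nonzero] = multipletests(pvals[nonzero], method="fdr_bh")[1] < alpha2
    out = np.zeros_like(freq)
    out[iu] = np.where(keep_flat, freq[iu], 0.0)
    out = out + out.T
    return ScoreMatrix("bc3net", m.gene_ids, out,
                       {"boot": boot, "alpha1": alpha1, "alpha2": alpha2})


def score_genie3(m: ExpressionMatrix, K: str = "all", n_trees: int = 1000,
                 seed: int = 0) -> ScoreMatrix:
    """Tree-ensemble variable importance per target gene (directed).

    Each gene is regressed on all others with a random forest (``K``
    candidate features per split: "all" or "sqrt"); score(i→j) is predictor
    i's total importance for target j, normalized per target to sum to 1.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if K not in ("all", "sqrt"):
        raise ValueError(f"K must be 'all' or 'sqrt', got {K!r}")
    vals = _values(m)
    n = vals.shape[0]
    if n < 2:
        raise ValueError("GENIE3 needs at least 2 genes")
    max_features = 1.0 if K == "all" else "sqrt"
    out = np.zeros((n, n))
    for j in range(n):
        preds = [i for i in range(n) if i != j]
        x = vals[preds].T
        y = vals[j]
        if np.ptp(y) == 0:
            continue
        rf = RandomForestRegressor(n_estimators=n_trees, max_features=max_features,
                                   random_state=seed + j, n_jobs=1)
        rf.fit(x, y)
        imp = rf.feature_importances_
        tot = imp.sum()
        if tot > 0:
            imp = imp / tot
        for pos, i in enumerate(preds):
            out[i, j] = imp[pos]
    return ScoreMatrix(f"genie3_{K}", m.gene_ids, out,
                       {"K": K, "n_trees": n_trees, "seed": seed})


def score_tigress(m: ExpressionMatrix, scoring: str = "area", n_resample: int = 200,
                  L: int = 5, alpha: float = 0.2, seed: int = 0) -> ScoreMatrix:
    """Stability selection over least-angle-regression paths (directed).

    Per target, ``n_resample`` half-samples with random predictor
    reweighting (uniform in [alpha, 1]) are fed to LARS for ``L`` steps.
    ``max`` scoring is the frequency a predictor enters within L steps;
    ``area`` scoring averages the selection frequency over steps 1..L.
    """
    if scoring not in ("area", "max"):
        raise ValueError(f"scoring must be 'area' or 'max', got {scoring!r}")
    vals = _values(m)
    n, n_cells = vals.shape
    if L >= n:
        raise ValueError("L must be < number of genes")
    rng = np.random.default_rng(seed)
    out = np.zeros((n, n))
    half = max(2, n_cells // 2)
    for j in range(n):
        preds = [i for i in range(n) if i != j]
        x_full = vals[preds].T
        y_full = vals[j]
        if np.ptp(y_full) == 0:
            continue
        # sel_count[p, l] = times predictor p selected within first l+1 steps
        sel_count = np.zeros((len(preds), L))
        for _r in range(n_resample):
            take = rng.choice(n_cells, size=half, replace=False)
            w = rng.uniform(alpha, 1.0, size=len(preds))
            x = x_full[take] * w
            y = y_full[take]
            x = x - x.mean(axis=0)
            y = y - y.mean()
            try:
                _alphas, active, _coefs = lars_path(x, y, max_iter=L, method="lar")
            except Exception:  # degenerate resample
                continue
            for step, p_idx in enumerate(active[:L]):
                sel_count[p_idx, step:] += 1
        freq = sel_count / n_resample  # column l: P(selected within l+1 steps)
        score = freq[:, -1] if scoring == "max" else freq.mean(axis=1)
        for pos, i in enumerate(preds):
            out[i, j] = score[pos]
    return ScoreMatrix(f"tigress_{scoring}", m.gene_ids, out,
                       {"scoring": scoring, "n_resample": n_resample,
                        "L": L, "alpha": alpha, "seed": seed})


def default_registry(profile: str = "desk", seed: int = 0) -> list[dict]:
    """The 12-algorithm battery configuration.

    ``desk`` profile scales the stochastic ensemble sizes down for a single
    CPU; ``paper`` uses the study-scale settings (GENIE3 10,000 trees,
    TIGRESS defaults).
    """
    genie_trees = 10_000 if profile == "paper" else 50
    tig_resample = 200 if profile == "paper" else 50
    return [
        {"name": "relnet", "kind": "relnet", "params": {}},
        {"name": "clr", "kind": "clr", "params": {}},
        {"name": "aracne", "kind": "aracne", "params": {"eps": 0.1}},
        {"name": "mrnet", "kind": "mrnet", "params": {}},
        {"name": "c3net", "kind": "c3net", "params": {}},
        {"name": "bc3net", "kind": "bc3net",
         "params": {"boot": 10, "alpha1": 0.99, "alpha2": 0.99, "seed": seed}},
        {"name": "pearson", "kind": "correlation", "params": {"method": "pearson"}},
        {"name": "spearman", "kind": "correlation", "params": {"method": "spearman"}},
        {"name": "genie3_all", "kind": "genie3",
         "params": {"K": "all", "n_trees": genie_trees, "seed": seed}},
        {"name": "genie3_sqrt", "kind": "genie3",
         "params": {"K": "sqrt", "n_trees": genie_trees, "seed": seed}},
        {"name": "tigress_area", "kind": "tigress",
         "params": {"scoring": "area", "n_resample": tig_resample, "seed": seed}},
        {"name": "tigress_max", "kind": "tigress",
         "params": {"scoring": "max", "n_resample": tig_resample, "seed": seed}},
    ]


def run_battery(m: ExpressionMatrix, registry: list[dict] | None = None,
                class_label: str | None = None,
                mi_cfg: MIEstimatorConfig | None = None) -> list[ScoreMatrix]:
    """Run every registry entry on one class's cells; skip (log) failures.

    The MI matrix is computed once and shared by the MI-family scorers.
    All outputs share the input's gene order.
    """
    if registry is None:
        registry = default_registry()
    if not registry:
        raise ValueError("empty algorithm registry")
    if class_label is not None:
        m = m.subset_cells(m.class_cells(class_label))
    mi_cfg = mi_cfg or MIEstimatorConfig()
    mi = None
    results: list[ScoreMatrix] = []
    for entry in registry:
        name, kind, params = entry["name"], entry["kind"], dict(entry.get("params", {}))
        try:
            if kind in ("relnet", "clr", "aracne", "mrnet", "c3net"):
                if mi is None:
                    mi = mi_matrix(m, mi_cfg)
                fn = {"relnet": score_relnet, "clr": score_clr,
                      "aracne": score_aracne, "mrnet": score_mrnet,
                      "c3net": score_c3net}[kind]
                sm = fn(mi, **params)
            elif kind == "bc3net":
                sm = score_bc3net(m, mi_cfg, **params)
            elif kind == "correlation":
                sm = score_correlation(m, **params)
            elif kind == "genie3":
                sm = score_genie3(m, **params)
            elif kind == "tigress":
                sm = score_tigress(m, **params)
            else:
                raise ValueError(f"unknown algorithm kind: {kind!r}")
            sm.algorithm = name
            results.append(sm)
        except Exception as exc:
            logger.warning("algorithm %s failed and was skipped: %s", name, exc)
    if not results:
        raise RuntimeError("every algorithm in the battery failed")
    return results
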