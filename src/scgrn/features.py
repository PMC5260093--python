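"""Five feature-selection strategies for two-class expression data.

Given a filtered, labelled log-expression matrix, each selector returns a
:class:`FeatureSet` — the surviving gene list plus per-gene scores:

* ``ttest``      — two-tailed Welch test per gene (BH-adjustable).
* ``srap_de``    — pooled-variance linear-model test + BH + |log-FC| gate,
                   a documented stand-in for a simplified RNA-seq DE pipeline.
* ``gsva``       — single-sample rank-walk enrichment per geneset, pathway
                   level two-sample test, union of significant sets' members.
                   This is an unweighted Kolmogorov–Smirnov random-walk
                   statistic (ssGSEA-like), not the kernel-CDF variant.
* ``svm_rfe``    — recursive feature elimination by the squared weights of a
                   linear soft-margin SVM, final size picked by inner CV.
* ``rf_mda``     — bagged decision trees with out-of-bag permutation
                   importance (mean decrease in accuracy); keep MDA > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multitest import multipletests

from .datagen import GeneSetCollection
from .io import CLASS_A, CLASS_B, ExpressionMatrix

__all__ = [
    "FeatureSet", "read_gmt",
    "select_ttest", "select_srap_de",
    "score_geneset_per_sample", "select_gsva",
    "select_svm_rfe", "select_rf_mda",
]


@dataclass
class FeatureSet:
    """A named selection method's surviving genes with per-gene scores."""

    method: str
    genes: list[str]
    scores: list[float]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("duplicate genes in FeatureSet")
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores length mismatch")

    def __len__(self) -> int:
        return len(self.genes)

    def write_tsv(self, path) -> None:
        pd.DataFrame({
            "gene": self.genes,
            "score": self.scores,
            "rank": np.arange(1, len(self.genes) + 1),
        }).to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name <tab> description <tab> member genes...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
        sets[parts[0]] = parts[2:]
    return GeneSetCollection(sets, source=str(path))


def _split_classes(m: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    if m.labels is None:
        raise ValueError("labelled matrix required")
    a = m.values[m.class_cells(CLASS_A)].to_numpy()
    b = m.values[m.class_cells(CLASS_B)].to_numpy()
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each class needs at least 2 cells")
    return a, b


def _two_sample_p(a: np.ndarray, b: np.ndarray, equal_var: bool) -> np.ndarray:
    """Row-wise two-tailed two-sample p-values; degenerate rows get p = 1."""
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    p[~np.isfinite(p)] = 1.0
    return p


def select_ttest(m: ExpressionMatrix, alpha: float = 0.05, adjust: str = "bh",
                 equal_var: bool = False) -> FeatureSet:
    """Genes with two-tailed two-sample test p (BH-adjusted by default) < alpha."""
    a, b = _split_classes(m)
    p = _two_sample_p(a, b, equal_var=equal_var)
    if adjust == "bh":
        p_used = multipletests(p, method="fdr_bh")[1]
    elif adjust == "none":
        p_used = p
    else:
        raise ValueError(f"unknown adjustment: {adjust!r}")
    keep = p_used < alpha
    order = np.argsort(p_used[keep], kind="stable")
    genes = np.asarray(m.gene_ids)[keep][order]
    return FeatureSet("ttest", list(genes), list(p_used[keep][order]),
                      {"alpha": alpha, "adjust": adjust, "equal_var": equal_var})


def select_srap_de(m: ExpressionMatrix, fdr: float = 0.05,
                   min_abs_lfc: float = 0.58) -> FeatureSet:
    """Pooled-variance two-group test with BH plus |mean log-FC| gate."""
    a, b = _split_classes(m)
    p = _two_sample_p(a, b, equal_var=True)
    q = multipletests(p, method="fdr_bh")[1]
    lfc = b.mean(axis=1) - a.mean(axis=1)
    keep = (q < fdr) & (np.abs(lfc) >= min_abs_lfc)
    order = np.argsort(q[keep], kind="stable")
    genes = np.asarray(m.gene_ids)[keep][order]
    return FeatureSet("srap_de", list(genes), list(q[keep][order]),
                      {"fdr": fdr, "min_abs_lfc": min_abs_lfc})


def _ks_walk_score(order: np.ndarray, in_set: np.ndarray) -> float:
    """Signed maximum deviation of the unweighted KS random walk.

    ``order`` ranks genes from highest to lowest expression in one cell;
    ``in_set`` flags set membership per gene.  Steps are +1/n_in for member
    genes and -1/n_out otherwise; the score is the deviation of largest
    magnitude (keeping its sign).
    """
    hits = in_set[order]
    n_in = int(hits.sum())
    n_out = hits.size - n_in
    if n_in == 0 or n_out == 0:
        return 0.0
    steps = np.where(hits, 1.0 / n_in, -1.0 / n_out)
    walk = np.cumsum(steps)
    i = int(np.argmax(np.abs(walk)))
    return float(walk[i])


def score_geneset_per_sample(m: ExpressionMatrix,
                             genesets: GeneSetCollection) -> pd.DataFrame:
    """Pathway × cell table of single-sample rank-walk enrichment scores.

    Genesets overlapping the matrix by fewer than 2 genes are dropped (and
    reported via the returned frame's attrs['dropped']).
    """
    gene_index = {g: i for i, g in enumerate(m.gene_ids)}
    usable: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for name, members in genesets.sets.items():
        mask = np.zeros(m.n_genes, dtype=bool)
        for g in members:
            if g in gene_index:
                mask[gene_index[g]] = True
        if mask.sum() >= 2:
            usable[name] = mask
        else:
            dropped.append(name)
    if not usable:
        raise ValueError("no geneset overlaps the matrix by >= 2 genes")
    vals = m.values.to_numpy()
    scores = np.zeros((len(usable), m.n_cells))
    for c in range(m.n_cells):
        order = np.argsort(-vals[:, c], kind="stable")
        for s, mask in enumerate(usable.values()):
            scores[s, c] = _ks_walk_score(order, mask)
    out = pd.DataFrame(scores, index=list(usable), columns=m.cell_ids)
    out.attrs["dropped"] = dropped
    return out


def select_gsva(m: ExpressionMatrix, genesets: GeneSetCollection,
                alpha: float = 0.005, adjust: str = "none") -> FeatureSet:
    """Union of member genes of pathways whose per-sample scores separate classes.

    Per pathway, a two-tailed Welch test compares enrichment scores between
    the two classes; pathways with p < alpha are pooled and their members
    (intersected with the matrix) form the returned FeatureSet.  No
    significant pathway yields an empty (not failed) selection.
    """
    table = score_geneset_per_sample(m, genesets)
    a_cells = m.class_cells(CLASS_A)
    b_cells = m.class_cells(CLASS_B)
    p = _two_sample_p(table[a_cells].to_numpy(), table[b_cells].to_numpy(),
                      equal_var=False)
    if adjust == "bh":
        p = multipletests(p, method="fdr_bh")[1]
    sig = np.asarray(table.index)[p < alpha]
    present = set(m.gene_ids)
    pooled: dict[str, float] = {}
    for name, pval in zip(table.index, p):
        if pval >= alpha:
            continue
        for g in genesets.sets[name]:
            if g in present:
                pooled[g] = min(pooled.get(g, 1.0), float(pval))
    genes = sorted(pooled, key=lambda g: (pooled[g], g))
    return FeatureSet("gsva", genes, [pooled[g] for g in genes],
                      {"alpha": alpha, "adjust": adjust,
                       "significant_pathways": list(sig)})


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def svm_rfe_ranking(x: np.ndarray, y: np.ndarray, drop_fraction: float = 0.1,
                    C: float = 1.0) -> list[int]:
    """Elimination order of feature indices, least informative first.

    Repeatedly fits a linear soft-margin SVM on the surviving features and
    removes the ceil(drop_fraction × current) features with the smallest
    squared weight.  The returned list ends with the longest-surviving
    feature.
    """
    surviving = list(range(x.shape[1]))
    eliminated: list[int] = []
    while len(surviving) > 1:
        clf = SVC(kernel="linear", C=C)
        clf.fit(x[:, surviving], y)
        w2 = np.square(np.asarray(clf.coef_).ravel())
        k = max(1, math.ceil(drop_fraction * len(surviving)))
        k = min(k, len(surviving) - 1)
        drop_pos = np.argsort(w2, kind="stable")[:k]
        for pos in sorted(drop_pos, reverse=True):
            eliminated.append(surviving.pop(pos))
    eliminated.extend(surviving)
    return eliminated


def _default_size_grid(n_features: int) -> list[int]:
    grid = [s for s in (2, 5, 10, 20, 38, 50, 100, 200) if s <= n_features]
    return grid or [n_features]


def select_svm_rfe(m: ExpressionMatrix, drop_fraction: float = 0.1,
                   inner_folds: int = 5, size_grid: list[int] | None = None,
                   C: float = 1.0, seed: int = 0) -> FeatureSet:
    """SVM recursive feature elimination with inner-CV choice of set size.

    Genes are standardized internally; the nested elimination order is
    computed once on the full data, candidate sizes are scored by
    ``inner_folds``-fold cross-validated accuracy of a linear SVM on the
    top-ranked genes, and ties prefer the smaller size.
    """
    if m.labels is None:
        raise ValueError("labelled matrix required")
    x = _standardize(m.values.to_numpy().T)
    y = (np.asarray(m.labels) == CLASS_B).astype(int)
    if size_grid is None:
        size_grid = _default_size_grid(m.n_genes)
    if max(size_grid) > m.n_genes:
        raise ValueError("size_grid exceeds gene count")
    if m.n_genes == 1:
        clf = SVC(kernel="linear", C=C).fit(x, y)
        return FeatureSet("svm_rfe", [m.gene_ids[0]],
                          [float(np.square(clf.coef_).ravel()[0])],
                          {"size": 1, "size_grid": size_grid})
    order = svm_rfe_ranking(x, y, drop_fraction=drop_fraction, C=C)
    ranked = order[::-1]  # best first
    best_size, best_acc = None, -1.0
    cv = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    for size in sorted(size_grid):
        cols = ranked[:size]
        accs = []
        for tr, te in cv.split(x, y):
            clf = SVC(kernel="linear", C=C)
            clf.fit(x[np.ix_(tr, cols)], y[tr])
            accs.append(float((clf.predict(x[np.ix_(te, cols)]) == y[te]).mean()))
        acc = float(np.mean(accs))
        if acc > best_acc + 1e-12:
            best_acc, best_size = acc, size
    cols = ranked[:best_size]
    final = SVC(kernel="linear", C=C).fit(x[:, cols], y)
    w2 = np.square(np.asarray(final.coef_).ravel())
    sel = np.argsort(-w2, kind="stable")
    genes = [m.gene_ids[cols[i]] for i in sel]
    return FeatureSet("svm_rfe", genes, [float(w2[i]) for i in sel],
                      {"size": int(best_size), "inner_cv_accuracy": best_acc,
                       "drop_fraction": drop_fraction, "C": C,
                       "size_grid": sorted(size_grid),
                       "elimination_order": [m.gene_ids[i] for i in order]})


def rf_oob_mda(x: np.ndarray, y: np.ndarray, n_trees: int, seed: int,
               max_features: str | float = "sqrt") -> np.ndarray:
    """Out-of-bag permutation importance from an explicit bagging loop.

    For each bootstrap tree, accuracy on its out-of-bag cells is compared
    with accuracy after permuting one feature at a time; only features the
    tree actually split on are permuted (others change nothing).  MDA per
    feature is the average accuracy drop over trees with OOB samples.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rng = np.random.default_rng(seed)
    n, p = x.shape
    drops = np.zeros(p)
    counts = np.zeros(p)
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0 or len(np.unique(y[boot])) < 2:
            continue
        tree = DecisionTreeClassifier(max_features=max_features,
                                      random_state=int(rng.integers(2**31)))
        tree.fit(x[boot], y[boot])
        base = (tree.predict(x[oob]) == y[oob]).mean()
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        counts[used] += 1
        for f in used:
            xp = x[oob].copy()
            xp[:, f] = xp[rng.permutation(oob.size), f]
            drops[f] += base - (tree.predict(xp) == y[oob]).mean()
    counts[counts == 0] = 1.0
    return drops / counts


def select_rf_mda(m: ExpressionMatrix, n_trees: int = 2000,
                  seed: int = 0) -> FeatureSet:
    """Genes with positive out-of-bag mean decrease in accuracy."""
    if m.labels is None:
        raise ValueError("labelled matrix required")
    x = m.values.to_numpy().T
    y = (np.asarray(m.labels) == CLASS_B).astype(int)
    mda = rf_oob_mda(x, y, n_trees=n_trees, seed=seed)
    keep = mda > 0
    order = np.argsort(-mda[keep], kind="stable")
    genes = np.asarray(m.gene_ids)[keep][order]
    return FeatureSet("rf_mda", list(genes), list(mda[keep][order]),
                      {"n_trees": n_trees, "seed": seed})
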