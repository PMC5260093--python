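"""Reading, log-transforming and expression-filtering of gene × cell matrices.

The pipeline's universal input is an :class:`ExpressionMatrix`: a genes ×
cells table of non-negative FPKM-scale values plus an optional two-class
cell label map.  Filtering follows the study design for Fluidigm-style
single-cell FPKM data: log-transform first, then drop genes that are not
expressed above a threshold in enough cells.  Two printed variants of the
filter exist in the source protocol and both are implemented (``main_text``
and ``footnote``); they genuinely differ and the choice is explicit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

CLASS_A = "class_a"
CLASS_B = "class_b"

__all__ = [
    "ExpressionMatrix",
    "FilterReport",
    "read_expression",
    "read_labels",
    "log_transform",
    "filter_genes",
]


@dataclass
class ExpressionMatrix:
    """Genes × cells expression values with optional two-class labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are genes, columns are cells.  Non-negative, FPKM scale unless
        ``log_transformed`` is set.
    labels : pandas.Series or None
        Maps cell id → class label.  When present it must cover every cell.
    log_transformed : bool
        Whether ``values`` are already on the log scale.
    transform : dict
        Metadata of the applied transform (base, pseudocount).
    """

    values: pd.DataFrame
    labels: pd.Series | None = None
    log_transformed: bool = False
    transform: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate cell id: {dup!r}")
        arr = self.values.to_numpy()
        if np.isnan(arr).any():
            gene = idx[np.isnan(arr).any(axis=1)][0]
            raise ValueError(f"missing value in gene {gene!r} (ragged input?)")
        if not self.log_transformed and (arr < 0).any():
            gene = idx[(arr < 0).any(axis=1)][0]
            raise ValueError(f"negative expression value in gene {gene!r}")
        if self.labels is not None:
            missing = cols.difference(self.labels.index)
            if len(missing):
                raise ValueError(f"cells without labels: {list(missing)[:5]}")
            self.labels = self.labels.loc[cols]

    # -- convenience accessors -------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def class_cells(self, label: str) -> list[str]:
        if self.labels is None:
            raise ValueError("matrix has no labels")
        return list(self.labels.index[self.labels == label])

    def subset_cells(self, cells) -> "ExpressionMatrix":
        labels = self.labels.loc[cells] if self.labels is not None else None
        return ExpressionMatrix(
            self.values[list(cells)], labels, self.log_transformed, dict(self.transform)
        )

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(genes)], self.labels, self.log_transformed, dict(self.transform)
        )

    def write_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")

    def write_labels(self, path) -> None:
        if self.labels is None:
            raise ValueError("matrix has no labels")
        self.labels.rename("class").to_csv(path, sep="\t", index_label="cell_id")


@dataclass
class FilterReport:
    """Outcome of an expression filter: per-gene pass flags plus counts."""

    n_input_genes: int
    n_retained: int
    rule: str
    passed: pd.Series  # gene id -> bool

    def __post_init__(self) -> None:
        if self.n_retained != int(self.passed.sum()):
            raise ValueError("n_retained inconsistent with pass flags")
        if self.n_retained > self.n_input_genes:
            raise ValueError("n_retained exceeds n_input_genes")

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input_genes": self.n_input_genes,
                "n_retained": self.n_retained,
                "rule": self.rule,
            }
        )

    def write(self, tsv_path, json_path=None) -> None:
        self.passed.rename("passed").to_csv(tsv_path, sep="\t", index_label="gene")
        if json_path is not None:
            Path(json_path).write_text(self.to_json() + "\n")


def read_expression(path, format: str = "tsv", genes_path=None, cells_path=None,
                    labels_path=None) -> ExpressionMatrix:
    """Read an expression matrix from TSV, CSV, or MTX-triplet files.

    ``mtx-triplet`` requires companion ``genes_path`` / ``cells_path`` index
    files (one id per line).  Row and column order are preserved.
    """
    path = Path(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    elif format == "mtx-triplet":
        if genes_path is None or cells_path is None:
            raise ValueError("mtx-triplet format requires genes_path and cells_path")
        mat = scipy.io.mmread(path)
        genes = Path(genes_path).read_text().split()
        cells = Path(cells_path).read_text().split()
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        if dense.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix shape {dense.shape} does not match index files "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
        df = pd.DataFrame(dense, index=genes, columns=cells)
    else:
        raise ValueError(f"unknown format: {format!r}")
    labels = read_labels(labels_path) if labels_path is not None else None
    return ExpressionMatrix(df, labels)


def read_labels(path) -> pd.Series:
    """Read a two-column (cell_id, class) TSV into a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError("label file must have exactly two columns (cell_id, class)")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="class")


_LOG_FUNCS = {2: np.log2, 10: np.log10, "e": np.log}


def log_transform(m: ExpressionMatrix, base=2, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Return a log-scale copy: values become log_base(value + pseudocount)."""
    if base not in _LOG_FUNCS:
        raise ValueError(f"unsupported base {base!r}; use 2, 10 or 'e'")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (m.values.to_numpy() == 0).any():
        raise ValueError("zeros present: pseudocount must be > 0")
    vals = _LOG_FUNCS[base](m.values + pseudocount)
    return ExpressionMatrix(
        vals, m.labels, log_transformed=True,
        transform={"base": base, "pseudocount": pseudocount},
    )


def filter_genes(m: ExpressionMatrix, rule: str = "main_text", threshold: float = 1.0,
                 min_cells: int = 6) -> tuple[ExpressionMatrix, FilterReport]:
    """Apply an expression filter to a log-transformed matrix.

    ``main_text`` retains a gene iff it has value > ``threshold`` in strictly
    more than ``min_cells`` cells.  ``footnote`` removes a gene iff its total
    expression is zero or it has value < ``threshold`` in strictly more than
    ``min_cells`` cells.  The threshold is compared on the matrix's own
    (log) scale in both variants.
    """
    if not m.log_transformed:
        raise ValueError("filter_genes expects a log-transformed matrix")
    vals = m.values
    if rule == "main_text":
        passed = (vals > threshold).sum(axis=1) > min_cells
    elif rule == "footnote":
        removed = (vals.sum(axis=1) == 0) | ((vals < threshold).sum(axis=1) > min_cells)
        passed = ~removed
    else:
        raise ValueError(f"unknown filter rule: {rule!r}")
    report = FilterReport(
        n_input_genes=m.n_genes,
        n_retained=int(passed.sum()),
        rule=rule,
        passed=passed,
    )
    filtered = ExpressionMatrix(
        vals.loc[passed], m.labels, m.log_transformed, dict(m.transform)
    )
    return filtered, report
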