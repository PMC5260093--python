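"""Evaluate SVM (RBF, leave-one-out) and random-forest (out-of-bag)
classifiers on every feature set plus the all-genes baseline — the
Table-2-style accuracy/MCC grid.

Writes classification_table.tsv under results/.
"""

from pathlib import Path

import pandas as pd

from scgrn.classify import ClassifierSpec, run_table2
from scgrn.features import FeatureSet
from scgrn.io import read_expression

ROOT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"
METHODS = ("gsva", "srap_de", "svm_rfe", "rf_mda", "ttest")


def _load_feature_set(name: str) -> FeatureSet | None:
    df = pd.read_csv(ROOT / f"features_{name}.tsv", sep="\t")
    if df.empty:
        return None
    return FeatureSet(name, list(df["gene"]), list(df["score"]))


def main() -> None:
    m = read_expression(SCRATCH / "expression_filtered.tsv",
                        labels_path=SCRATCH / "data" / "labels.tsv")
    m.log_transformed = True
    feature_sets: dict = {"all_genes": None}
    for name in METHODS:
        fs = _load_feature_set(name)
        if fs is not None:
            feature_sets[name] = fs
    spec = ClassifierSpec(c_grid=[2.0 ** k for k in (-3, 1, 5, 9)],
                          gamma_grid=[2.0 ** k for k in (-13, -9, -5, -1)],
                          n_trees=2000, seed=20160104)
    table = run_table2(m, feature_sets, spec)
    cols = ["n_features", "svm_accuracy", "svm_mcc", "rf_accuracy", "rf_mcc"]
    print(table[cols].to_string())
    table.to_csv(ROOT / "classification_table.tsv", sep="\t")


if __name__ == "__main__":
    main()
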