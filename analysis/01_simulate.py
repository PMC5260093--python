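"""Generate the synthetic two-class single-cell dataset used by every
downstream step: 600 genes (10 planted markers, 20 network genes with two
differential hubs, a low-expression tail), 15 + 50 cells, 10% dropout.

Writes expression/labels/genesets/ground-truth under scratch/data/
(regenerable raw data is kept out of the versioned results).
"""

from pathlib import Path

from scgrn.datagen import (SyntheticConfig, generate_dataset, generate_genesets,
                           write_gmt)

OUT = Path(__file__).resolve().parents[1] / "scratch" / "data"
SEED = 20160101


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig(n_genes=600, seed=SEED)
    matrix, truth = generate_dataset(cfg)
    genesets = generate_genesets(truth, n_sets=10, set_size=20, seed=SEED + 1,
                                 universe=matrix.gene_ids)
    matrix.write_tsv(OUT / "expression.tsv")
    matrix.write_labels(OUT / "labels.tsv")
    write_gmt(genesets, OUT / "genesets.gmt")
    truth.write(OUT / "ground_truth.json")
    n_zero = (matrix.values.to_numpy() == 0).mean()
    print(f"wrote {matrix.n_genes} genes x {matrix.n_cells} cells "
          f"({n_zero:.1%} zeros) to {OUT}")
    print(f"planted: {len(truth.marker_genes)} markers, "
          f"{len(truth.network_genes)} network genes, "
          f"hubs {truth.diff_hub_genes}")


if __name__ == "__main__":
    main()
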