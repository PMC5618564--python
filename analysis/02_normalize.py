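"""Normalize the Ct matrix to clipped, median-centered log2 expression.

Each gene is centered on its pooled median Ct (all cells, both groups,
all chips), one cycle = one log2 unit, clipped to +/-5 (32-fold), with
non-expressers floored at -5. Writes the expression matrix, the
expressed-entry mask, per-gene pooled medians, and per-group failed
fractions under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from scqpcr import failed_fraction, normalize, read_ct_table, write_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data/ct_matrix.csv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--bound", type=float, default=5.0)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = read_ct_table(args.data)
    matrix = normalize(table, bound=args.bound)

    expr = matrix.to_frame().reset_index(names="cell_id")
    expr.insert(1, "group", matrix.group)
    expr.insert(2, "chip", matrix.chip)
    write_table(expr, args.out / "expression_matrix.csv")
    write_table(
        matrix.expressed_frame().reset_index(names="cell_id"),
        args.out / "expressed_mask.csv",
    )
    write_table(
        pd.DataFrame({"gene": matrix.gene_ids, "median_ct": matrix.gene_median_ct}),
        args.out / "gene_medians.csv",
    )
    failed = failed_fraction(matrix, matrix.group)
    write_table(failed.reset_index(names="gene"), args.out / "failed_fractions.csv")

    print(f"normalized {matrix.n_cells} cells x {matrix.n_genes} genes "
          f"(dropped {len(matrix.dropped_genes)} all-dropout gene(s))")
    print(f"expression range: [{matrix.values.min():+.2f}, {matrix.values.max():+.2f}] "
          f"log2 (bound +/-{matrix.bound:g} = {2**matrix.bound:g}-fold)")
    print("mean failed fraction by group:")
    print(failed.mean(axis=0).round(3).to_string())


if __name__ == "__main__":
    main()
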