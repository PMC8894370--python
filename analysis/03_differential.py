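#!/usr/bin/env python
"""Per-peptide differential phosphorylation for both study contrasts.

Runs unpaired t-tests for rd1 vs WT and CN03-treated rd1 vs untreated rd1,
reports the up/down fractions and significant-peptide counts, and writes
contrast tables, volcano data, the violin long table, and the clustered
heatmap matrix.
"""

import argparse
from pathlib import Path

from kinomeprofiler.array_io import read_design, read_layout, read_signal_table
from kinomeprofiler.differential import (
    contrast,
    export_heatmap,
    export_violin,
    export_volcano,
    fraction_changed,
)
from kinomeprofiler.preprocess import preprocess

CONTRASTS = [("rd1", "WT"), ("rd1_CN03", "rd1")]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    layout = read_layout(args.data / "layout.tsv")
    design = read_design(args.data / "design.tsv")
    matrix = preprocess(read_signal_table(args.data / "signals.tsv", layout, design))

    export_violin(matrix, args.out / "violin_long.tsv")
    export_heatmap(matrix, args.out / "heatmap_matrix.tsv")

    for ga, gb in CONTRASTS:
        res = contrast(matrix, ga, gb)
        name = res.contrast_name
        res.to_frame().to_csv(args.out / f"contrast_{name}.tsv", sep="\t", index=False)
        export_volcano(res, args.out / f"volcano_{name}.tsv",
                       plot_path=args.out / f"volcano_{name}.png")
        print(
            f"{name}: {100 * fraction_changed(res, 'up'):.0f}% peptides up, "
            f"{100 * fraction_changed(res, 'down'):.0f}% down, "
            f"{int(res.significant.sum())} significant at p < {res.alpha}"
        )


if __name__ == "__main__":
    main()
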