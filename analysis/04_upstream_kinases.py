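#!/usr/bin/env python
"""Rank candidate upstream kinases by permutation-based Kinase Scores.

For each contrast, computes per-kinase statistic, significance score (500
sample-label permutations) and specificity score (500 target-peptide
permutations), ranks by their sum, and writes the full ranking, the
score > 1.5 report, and a kinome-tree (Coral) export.
"""

import argparse
from pathlib import Path

from kinomeprofiler.array_io import read_design, read_layout, read_signal_table
from kinomeprofiler.preprocess import preprocess
from kinomeprofiler.upstream import (
    export_coral,
    rank_kinases,
    read_substrate_map,
    results_frame,
)

CONTRASTS = [("rd1", "WT"), ("rd1_CN03", "rd1")]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--permutations", type=int, default=500)
    args = ap.parse_args()

    layout = read_layout(args.data / "layout.tsv")
    design = read_design(args.data / "design.tsv")
    matrix = preprocess(read_signal_table(args.data / "signals.tsv", layout, design))
    smap = read_substrate_map(args.data / "substrate_map.tsv")

    for ga, gb in CONTRASTS:
        name = f"{ga}_vs_{gb}"
        full, reported = rank_kinases(
            matrix, smap, ga, gb,
            b_labels=args.permutations, b_peptides=args.permutations, seed=args.seed,
        )
        results_frame(full).to_csv(args.out / f"kinases_full_{name}.tsv", sep="\t", index=False)
        results_frame(reported).to_csv(
            args.out / f"kinases_reported_{name}.tsv", sep="\t", index=False
        )
        export_coral(reported, args.out / f"coral_{name}.tsv")
        top = ", ".join(
            f"{r.kinase} (score {r.score:.2f}, stat {r.statistic:+.2f})" for r in full[:3]
        )
        print(f"{name}: {len(reported)} kinases with score > 1.5; top: {top}")


if __name__ == "__main__":
    main()
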