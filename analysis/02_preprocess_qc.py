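#!/usr/bin/env python
"""Collapse exposures to one log2 value per spot and check sample quality.

Reads the simulated signals, fits the through-origin exposure line per
(sample, peptide), evaluates it at 100 ms, log2-transforms with floor 1,
and writes the analysis matrix plus a per-sample QC table.
"""

import argparse
from pathlib import Path

from kinomeprofiler.array_io import read_design, read_layout, read_signal_table, write_matrix
from kinomeprofiler.preprocess import preprocess, qc_summary


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    layout = read_layout(args.data / "layout.tsv")
    design = read_design(args.data / "design.tsv")
    stack = read_signal_table(args.data / "signals.tsv", layout, design)
    matrix = preprocess(stack)
    write_matrix(matrix, args.out / "log2_matrix.tsv")
    qc = qc_summary(matrix)
    qc.to_csv(args.out / "qc_summary.tsv", sep="\t", index=False)

    print(f"matrix: {len(matrix.samples)} samples x {len(matrix.peptides)} peptides")
    print(f"flagged samples: {int(qc['flagged'].sum())} of {len(qc)}")


if __name__ == "__main__":
    main()
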