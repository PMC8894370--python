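#!/usr/bin/env python
"""Over-representation analysis of the reported kinases.

Maps the reported kinase names to gene symbols through the packaged alias
table and tests them against the packaged toy pathway collection with the
hypergeometric test, BH q-values, and gene ratios.
"""

import argparse
from pathlib import Path

import pandas as pd

from kinomeprofiler.enrichment import load_toy_pathways, map_kinases_to_genes, run_ora


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    collection = load_toy_pathways()
    for name in ("rd1_vs_WT", "rd1_CN03_vs_rd1"):
        path = args.out / f"kinases_reported_{name}.tsv"
        if not path.exists():
            print(f"{name}: kinase list missing; run 04_upstream_kinases.py first")
            continue
        kinases = pd.read_csv(path, sep="\t")["kinase"].tolist()
        if not kinases:
            print(f"{name}: no reported kinases to test")
            continue
        genes = map_kinases_to_genes(kinases)
        try:
            ora = run_ora(genes, collection)
        except ValueError as exc:
            print(f"{name}: ORA not possible ({exc})")
            continue
        ora.to_csv(args.out / f"ora_{name}.tsv", sep="\t", index=False)
        top = ora.iloc[0]
        print(
            f"{name}: top pathway {top['pathway']!r} "
            f"(p={top['p']:.3g}, q={top['q']:.3g}, gene ratio {top['gene_ratio']:.0f}%)"
        )


if __name__ == "__main__":
    main()
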