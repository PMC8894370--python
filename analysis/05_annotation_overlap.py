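#!/usr/bin/env python
"""Substrate-specificity annotation and overlap of the two kinase lists.

Reproduces the reference-table counts (peptides at p < 0.1 / p < 0.05,
dual PKG1+PKG2 substrates, PKG1-only substrates) and computes the Venn
overlap between the kinases reported for rd1 vs WT and for CN03-treated
rd1 vs rd1.
"""

import argparse
from pathlib import Path

import pandas as pd

from kinomeprofiler.annotation import (
    classify_substrate,
    contrast_overlap,
    count_by_filter,
    load_reference_substrates,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    records = load_reference_substrates()
    print(f"reference table: {len(records)} peptides at p < 0.1")
    print(f"  p < 0.05: {count_by_filter(records, p_max=0.05)}")
    print(f"  dual PKG1/PKG2 substrates (both >= 4): "
          f"{count_by_filter(records, pkg1_min=4, pkg2_min=4)}")
    print(f"  PKG1-only substrates (pkg2 in 1-3): "
          f"{count_by_filter(records, pkg1_min=4, pkg2_min=1, pkg2_max=3)}")

    annotated = pd.DataFrame(
        {
            "peptide": [r.peptide.raw_id for r in records],
            "p_value": [r.p_value for r in records],
            "pkg1_class": [classify_substrate(r.pkg1_score) for r in records],
            "pkg2_class": [classify_substrate(r.pkg2_score) for r in records],
        }
    )
    annotated.to_csv(args.out / "substrate_classes.tsv", sep="\t", index=False)

    lists = {}
    for name in ("rd1_vs_WT", "rd1_CN03_vs_rd1"):
        path = args.out / f"kinases_reported_{name}.tsv"
        if path.exists():
            lists[name] = pd.read_csv(path, sep="\t")["kinase"].tolist()
    if len(lists) == 2 and all(lists.values()):
        (a, la), (b, lb) = lists.items()
        shared, pct_a, pct_b = contrast_overlap(la, lb)
        pd.DataFrame({"shared_kinase": sorted(shared)}).to_csv(
            args.out / "overlap_shared.tsv", sep="\t", index=False
        )
        print(f"overlap: {len(shared)} shared kinases "
              f"({pct_a:.1f}% of {a}, {pct_b:.1f}% of {b})")
    else:
        print("kinase lists not found; run 04_upstream_kinases.py first")


if __name__ == "__main__":
    main()
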