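"""Substrate-specificity classification, filter counts, and contrast overlap.

The packaged reference table lists the 22 peptides whose phosphorylation
dropped at p < 0.1 when rd1 retinal explants were treated with the PKG
inhibitor CN03, together with each peptide's integer PKG1/PKG2 substrate
specificity score (0–10). The score bands are: 8–10 good substrate, 4–7
intermediate, 1–3 poor, 0 not a substrate. "Substrate of both PKGs" is
operationalised as intermediate-or-better (score ≥ 4) for both isoforms;
"PKG1 only" as pkg1 ≥ 4 with pkg2 in 1–3.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .array_io import PeptideID, parse_peptide_id

__all__ = [
    "SubstrateRecord",
    "classify_substrate",
    "load_reference_substrates",
    "count_by_filter",
    "contrast_overlap",
]

_CLASS_BANDS = {
    "good": range(8, 11),
    "intermediate": range(4, 8),
    "poor": range(1, 4),
    "non_substrate": range(0, 1),
}


@dataclass(frozen=True)
class SubstrateRecord:
    """One differentially phosphorylated peptide with its PKG substrate scores."""

    peptide: PeptideID
    protein_name: str
    uniprot_id: str
    p_value: float
    pkg1_score: int
    pkg2_score: int
    localisation: str = ""

    def __post_init__(self) -> None:
        for score in (self.pkg1_score, self.pkg2_score):
            if not 0 <= score <= 10:
                raise ValueError(f"substrate score {score} outside 0..10")


def classify_substrate(score: int) -> str:
    """Map an integer specificity score 0–10 onto its substrate-quality band."""
    if not isinstance(score, (int,)) or isinstance(score, bool):
        score = int(score)
    if not 0 <= score <= 10:
        raise ValueError(f"substrate score must be in 0..10, got {score}")
    for label, band in _CLASS_BANDS.items():
        if score in band:
            return label
    raise AssertionError("unreachable: bands partition 0..10")


def load_reference_substrates(path=None) -> list[SubstrateRecord]:
    """Load the packaged 22-peptide reference table (or a file of the same shape)."""
    if path is None:
        with resources.as_file(
            resources.files("kinomeprofiler.data") / "pkg_substrate_reference.tsv"
        ) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    df["localisation"] = df.get("localisation", "").fillna("")
    return [
        SubstrateRecord(
            peptide=parse_peptide_id(str(row.peptide_id)),
            protein_name=str(row.protein_name),
            uniprot_id=str(row.uniprot_id),
            p_value=float(row.p_value),
            pkg1_score=int(row.pkg1_score),
            pkg2_score=int(row.pkg2_score),
            localisation=str(row.localisation),
        )
        for row in df.itertuples(index=False)
    ]


def count_by_filter(
    records: list[SubstrateRecord],
    p_max: float | None = None,
    pkg1_min: int | None = None,
    pkg1_max: int | None = None,
    pkg2_min: int | None = None,
    pkg2_max: int | None = None,
) -> int:
    """Count records passing a p-value cut and optional PKG score bounds.

    All bounds are optional; p is a strict upper bound (p_value < p_max),
    score bounds are inclusive.
    """
    if not records:
        raise ValueError("no records to filter")
    n = 0
    for r in records:
        if p_max is not None and not r.p_value < p_max:
            continue
        if pkg1_min is not None and r.pkg1_score < pkg1_min:
            continue
        if pkg1_max is not None and r.pkg1_score > pkg1_max:
            continue
        if pkg2_min is not None and r.pkg2_score < pkg2_min:
            continue
        if pkg2_max is not None and r.pkg2_score > pkg2_max:
            continue
        n += 1
    return n


def contrast_overlap(
    list_a: list[str], list_b: list[str]
) -> tuple[set[str], float, float]:
    """Venn-style overlap of two kinase name lists (case-normalised).

    Returns (shared names in their original case from list A,
    100·|A∩B|/|A|, 100·|A∩B|/|B|).
    """
    if not list_a or not list_b:
        raise ValueError("both lists must be non-empty")
    norm_a = {k.casefold(): k for k in list_a}
    norm_b = {k.casefold(): k for k in list_b}
    shared_keys = set(norm_a) & set(norm_b)
    shared = {norm_a[k] for k in shared_keys}
    return (
        shared,
        100.0 * len(shared_keys) / len(norm_a),
        100.0 * len(shared_keys) / len(norm_b),
    )
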