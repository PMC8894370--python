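"""Upstream kinase ranking from substrate-set changes.

Each candidate kinase is represented by a fingerprint: the set of array
peptides it is known or predicted to phosphorylate, each with an integer
specificity weight 0–10 (0 = not a substrate, dropped at load time). Three
quantities are computed per kinase for a given two-group contrast:

* **Kinase Statistic** — the (optionally weight-proportional) mean log2
  fold change over the kinase's measured substrates. Positive values mean
  higher inferred activity in the contrast's first-named group.
* **Significance Score** — evidence that the statistic is nonzero, from
  permutations of the sample labels: the empirical two-sided p-value
  (r+1)/(B+1), where r counts permuted |statistic| ≥ observed |statistic|,
  reported as −log10 p.
* **Specificity Score** — evidence that the signal is specific to the
  kinase's substrates rather than an array-wide shift, from random peptide
  sets of the same size drawn (without replacement within a draw) from all
  measured peptides; same p-value estimator and −log10 transform.

The **Kinase Score** is the sum of the two scores; kinases are ranked by
it, and the report conventionally includes only scores > 1.5. With B
permutations each score is capped at log10(B+1), so the score itself is
capped at 2·log10(B+1) (≈ 5.40 at B = 500).

The two permutation analyses draw from independent, seed-derived streams,
so enabling or reordering one never perturbs the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from ._rng import substream
from .array_io import parse_peptide_id
from .differential import ContrastResult, contrast
from .preprocess import PhosphoMatrix

__all__ = [
    "KinaseSubstrateMap",
    "KinaseResult",
    "read_substrate_map",
    "kinase_statistic",
    "significance_score",
    "specificity_score",
    "rank_kinases",
    "export_coral",
]

logger = logging.getLogger(__name__)


@dataclass
class KinaseSubstrateMap:
    """Kinase → {(peptide, weight 1–10)} fingerprints.

    Weight-0 entries are excluded at construction; every peptide ID must
    parse under the array ID grammar.
    """

    substrates_of: dict[str, dict[str, int]]

    def __post_init__(self) -> None:
        cleaned: dict[str, dict[str, int]] = {}
        for kinase, subs in self.substrates_of.items():
            kept: dict[str, int] = {}
            for pep, w in subs.items():
                w = int(w)
                if not 0 <= w <= 10:
                    raise ValueError(
                        f"substrate weight {w} for {kinase}/{pep} outside 0..10"
                    )
                parse_peptide_id(pep)  # raises on malformed IDs
                if w > 0:
                    kept[pep] = w
            cleaned[kinase] = kept
        self.substrates_of = cleaned

    @property
    def kinases(self) -> list[str]:
        return list(self.substrates_of)

    def measured_substrates(
        self, kinase: str, measured: list[str]
    ) -> tuple[list[str], np.ndarray]:
        """Substrates of ``kinase`` present on the array, with their weights."""
        subs = self.substrates_of[kinase]
        present = [p for p in measured if p in subs]
        return present, np.array([subs[p] for p in present], dtype=float)


@dataclass
class KinaseResult:
    kinase: str
    n_peptides: int
    statistic: float
    significance_score: float
    specificity_score: float
    rank: int = 0

    @property
    def score(self) -> float:
        return self.significance_score + self.specificity_score


def read_substrate_map(path) -> KinaseSubstrateMap:
    """Read a kinase/peptide_id/weight TSV into a :class:`KinaseSubstrateMap`."""
    df = pd.read_csv(path, sep="\t")
    required = {"kinase", "peptide_id", "weight"}
    if not required.issubset(df.columns):
        raise ValueError(f"substrate map missing columns {sorted(required - set(df.columns))}")
    substrates: dict[str, dict[str, int]] = {}
    for row in df.itertuples(index=False):
        substrates.setdefault(str(row.kinase), {})[str(row.peptide_id)] = int(row.weight)
    return KinaseSubstrateMap(substrates)


def write_substrate_map(smap: KinaseSubstrateMap, path) -> None:
    rows = [
        (k, p, w)
        for k, subs in smap.substrates_of.items()
        for p, w in subs.items()
    ]
    pd.DataFrame(rows, columns=["kinase", "peptide_id", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def _set_statistic(lfc: np.ndarray, weights: np.ndarray | None) -> float:
    if weights is None:
        return float(np.mean(lfc))
    return float(np.sum(weights * lfc) / np.sum(weights))


def kinase_statistic(
    result: ContrastResult,
    smap: KinaseSubstrateMap,
    kinase: str,
    weighted: bool = False,
    min_set_size: int = 3,
) -> float:
    """Mean (or weight-proportional mean) LFC over the kinase's measured substrates."""
    present, weights = smap.measured_substrates(kinase, result.peptides)
    if len(present) < min_set_size:
        raise ValueError(
            f"kinase {kinase!r}: only {len(present)} substrates measured "
            f"(min_set_size={min_set_size})"
        )
    idx = {p: i for i, p in enumerate(result.peptides)}
    lfc = result.lfc[[idx[p] for p in present]]
    return _set_statistic(lfc, weights if weighted else None)


def _group_lfc(values: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    return values[idx_a].mean(axis=0) - values[idx_b].mean(axis=0)


def _perm_pvalue(observed: float, perm_stats: np.ndarray) -> float:
    r = int(np.sum(np.abs(perm_stats) >= abs(observed)))
    return (r + 1) / (perm_stats.size + 1)


def significance_score(
    matrix: PhosphoMatrix,
    smap: KinaseSubstrateMap,
    kinase: str,
    group_a: str,
    group_b: str,
    b_labels: int = 500,
    seed: int = 0,
    weighted: bool = False,
    min_set_size: int = 3,
) -> float:
    """−log10 of the two-sided label-permutation p-value of the kinase statistic.

    Group labels of the contrast's samples are shuffled ``b_labels`` times
    (sampling permutations with replacement; a note is logged when fewer
    distinct relabellings exist than permutations requested).
    """
    res = contrast(matrix, group_a, group_b)
    observed = kinase_statistic(res, smap, kinase, weighted=weighted, min_set_size=min_set_size)

    present, weights = smap.measured_substrates(kinase, matrix.peptides)
    col = {p: i for i, p in enumerate(matrix.peptides)}
    sub_values = matrix.values[:, [col[p] for p in present]]
    # canonicalise the orientation so the null (and hence the score) is
    # identical however the caller orders the two groups
    first, second = sorted([group_a, group_b])
    idx_a = matrix.rows_for_group(first)
    idx_b = matrix.rows_for_group(second)
    n_a, n = idx_a.size, idx_a.size + idx_b.size
    if comb(n, n_a) < b_labels:
        logger.info(
            "kinase %s: only %d distinct relabellings < %d permutations; sampling with replacement",
            kinase, comb(n, n_a), b_labels,
        )
    pool = np.concatenate([idx_a, idx_b])
    rng = substream(seed, "labels-permutation", kinase)
    perm_stats = np.empty(b_labels)
    w = weights if weighted else None
    for i in range(b_labels):
        perm = rng.permutation(pool)
        lfc = _group_lfc(sub_values, perm[:n_a], perm[n_a:])
        perm_stats[i] = _set_statistic(lfc, w)
    return -np.log10(_perm_pvalue(observed, perm_stats))


def specificity_score(
    result: ContrastResult,
    smap: KinaseSubstrateMap,
    kinase: str,
    b_peptides: int = 500,
    seed: int = 0,
    weighted: bool = False,
    min_set_size: int = 3,
) -> float:
    """−log10 of the two-sided peptide-permutation p-value of the kinase statistic.

    Random peptide sets of the fingerprint's measured size are drawn
    uniformly without replacement from all measured peptides; the observed
    weights are carried over to each random set in the weighted variant.
    """
    present, weights = smap.measured_substrates(kinase, result.peptides)
    m, n_measured = len(present), len(result.peptides)
    if m < min_set_size:
        raise ValueError(
            f"kinase {kinase!r}: only {m} substrates measured (min_set_size={min_set_size})"
        )
    if m >= n_measured:
        raise ValueError(
            f"kinase {kinase!r}: substrate set size {m} must be smaller than the "
            f"number of measured peptides ({n_measured})"
        )
    idx = {p: i for i, p in enumerate(result.peptides)}
    observed = _set_statistic(
        result.lfc[[idx[p] for p in present]], weights if weighted else None
    )
    rng = substream(seed, "peptide-permutation", kinase)
    w = weights if weighted else None
    perm_stats = np.empty(b_peptides)
    for i in range(b_peptides):
        cols = rng.choice(n_measured, size=m, replace=False)
        perm_stats[i] = _set_statistic(result.lfc[cols], w)
    return -np.log10(_perm_pvalue(observed, perm_stats))


def rank_kinases(
    matrix: PhosphoMatrix,
    smap: KinaseSubstrateMap,
    group_a: str,
    group_b: str,
    b_labels: int = 500,
    b_peptides: int = 500,
    seed: int = 0,
    weighted: bool = False,
    min_set_size: int = 3,
    report_threshold: float = 1.5,
) -> tuple[list[KinaseResult], list[KinaseResult]]:
    """Score and rank every eligible kinase for one contrast.

    Returns ``(full, reported)``: the full ranking (ranks 1..K by
    descending Kinase Score, ties broken by |statistic| descending then
    name), and the subset with score > ``report_threshold``. Kinases whose
    fingerprints intersect the array in fewer than ``min_set_size``
    peptides are skipped with a logged reason.
    """
    if not smap.kinases:
        raise ValueError("empty substrate map")
    res = contrast(matrix, group_a, group_b)
    results: list[KinaseResult] = []
    for kinase in smap.kinases:
        present, _ = smap.measured_substrates(kinase, matrix.peptides)
        if len(present) < min_set_size:
            logger.info(
                "skipping kinase %s: %d measured substrates < min_set_size %d",
                kinase, len(present), min_set_size,
            )
            continue
        stat = kinase_statistic(res, smap, kinase, weighted=weighted, min_set_size=min_set_size)
        sig = significance_score(
            matrix, smap, kinase, group_a, group_b,
            b_labels=b_labels, seed=seed, weighted=weighted, min_set_size=min_set_size,
        )
        spec = specificity_score(
            res, smap, kinase,
            b_peptides=b_peptides, seed=seed, weighted=weighted, min_set_size=min_set_size,
        )
        results.append(
            KinaseResult(
                kinase=kinase,
                n_peptides=len(present),
                statistic=stat,
                significance_score=sig,
                specificity_score=spec,
            )
        )
    if not results:
        logger.warning("no eligible kinase for contrast %s vs %s", group_a, group_b)
        return [], []
    results.sort(key=lambda r: (-r.score, -abs(r.statistic), r.kinase))
    for i, r in enumerate(results, start=1):
        r.rank = i
    reported = [r for r in results if r.score > report_threshold]
    return results, reported


def results_frame(results: list[KinaseResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank": [r.rank for r in results],
            "kinase": [r.kinase for r in results],
            "n_peptides": [r.n_peptides for r in results],
            "statistic": [r.statistic for r in results],
            "significance_score": [r.significance_score for r in results],
            "specificity_score": [r.specificity_score for r in results],
            "score": [r.score for r in results],
        }
    )


def export_coral(results: list[KinaseResult], path) -> pd.DataFrame:
    """Kinome-tree export: kinase, statistic (colour), score (node size).

    The TSV columns map onto the Coral web application's branch/node colour
    (signed statistic) and node size (non-negative score) inputs.
    """
    df = pd.DataFrame(
        {
            "kinase": [r.kinase for r in results],
            "statistic": [r.statistic for r in results],
            "score": [r.score for r in results],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return df
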