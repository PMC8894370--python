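"""Per-peptide two-group statistics and clustering for heatmap reporting.

The comparison between two sample groups is an unpaired t-test per peptide
on the log2 matrix (pooled-variance Student's t by default, Welch by flag)
with the log2 fold change defined as mean(first-named group) − mean(second
group); contrast names encode this orientation ("rd1_vs_WT" means
rd1 − WT). Peptide p-values are reported raw, without multiple-testing
correction, matching the convention of reporting peptides at p < 0.05 and
p < 0.1; Benjamini–Hochberg q-values can be attached on request.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .preprocess import PhosphoMatrix

__all__ = [
    "ContrastResult",
    "contrast",
    "fraction_changed",
    "cluster_peptides",
    "export_volcano",
    "export_violin",
    "export_heatmap",
]

_TINY_P = np.nextafter(0.0, 1.0)


@dataclass
class ContrastResult:
    """Per-peptide statistics for one two-group comparison.

    ``lfc`` is mean(groupA) − mean(groupB) on log2 values; ``p`` is the
    two-sided t-test p-value in (0, 1]; ``degenerate`` marks peptides where
    both groups had zero variance but unequal means (p floored at the
    smallest positive float).
    """

    contrast_name: str
    group_a: str
    group_b: str
    peptides: list[str]
    lfc: np.ndarray = field(repr=False)
    t: np.ndarray = field(repr=False)
    p: np.ndarray = field(repr=False)
    alpha: float = 0.05
    degenerate: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.degenerate is None:
            self.degenerate = np.zeros(len(self.peptides), dtype=bool)
        if np.any(self.p <= 0) or np.any(self.p > 1):
            raise ValueError("p-values must lie in (0, 1]")

    @property
    def significant(self) -> np.ndarray:
        return self.p < self.alpha

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peptide": self.peptides,
                "lfc": self.lfc,
                "t": self.t,
                "p": self.p,
                "significant": self.significant,
                "degenerate": self.degenerate,
            }
        )


def contrast(
    matrix: PhosphoMatrix,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    variance: str = "pooled",
    name: str | None = None,
) -> ContrastResult:
    """Unpaired two-sided t-test per peptide between ``group_a`` and ``group_b``.

    ``variance='pooled'`` gives the classical Student's t; ``'welch'`` drops
    the equal-variance assumption. Each group needs at least two samples.
    Degenerate peptides (zero variance in both groups) get p = 1, t = 0 when
    the means agree, else the smallest positive p with the ``degenerate``
    flag set.
    """
    if variance not in {"pooled", "welch"}:
        raise ValueError(f"variance must be 'pooled' or 'welch', got {variance!r}")
    a = matrix.values[matrix.rows_for_group(group_a)]
    b = matrix.values[matrix.rows_for_group(group_b)]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError(
            f"each group needs >= 2 samples (got {a.shape[0]} in {group_a!r}, "
            f"{b.shape[0]} in {group_b!r})"
        )
    lfc = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # scipy near-constant data
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=(variance == "pooled"))

    zero_var = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    degenerate = zero_var & (lfc != 0)
    t = np.where(zero_var & (lfc == 0), 0.0, t)
    p = np.where(zero_var & (lfc == 0), 1.0, p)
    t = np.where(degenerate, np.where(lfc > 0, np.inf, -np.inf), t)
    p = np.where(degenerate, _TINY_P, p)
    # scipy may still return p = 0 at extreme t; keep p strictly positive.
    p = np.maximum(p, _TINY_P)

    return ContrastResult(
        contrast_name=name or f"{group_a}_vs_{group_b}",
        group_a=group_a,
        group_b=group_b,
        peptides=list(matrix.peptides),
        lfc=lfc,
        t=np.asarray(t, dtype=float),
        p=np.asarray(p, dtype=float),
        alpha=alpha,
        degenerate=degenerate,
    )


def fraction_changed(result: ContrastResult, direction: str) -> float:
    """Fraction of peptides with lfc > 0 ('up') or < 0 ('down'); zeros count to neither."""
    if direction == "up":
        return float((result.lfc > 0).mean())
    if direction == "down":
        return float((result.lfc < 0).mean())
    raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")


def cluster_peptides(
    matrix: PhosphoMatrix, metric: str = "euclidean"
) -> tuple[list[str], np.ndarray]:
    """Average-linkage (UPGMA) hierarchical clustering of peptide profiles.

    Returns the dendrogram leaf order (a permutation of the peptides) and
    the scipy linkage matrix.
    """
    if len(matrix.peptides) < 2:
        raise ValueError("clustering needs >= 2 peptides")
    profiles = matrix.values.T  # peptides × samples
    if not np.all(np.isfinite(profiles)):
        raise ValueError("non-finite values in matrix")
    linkage = hierarchy.linkage(pdist(profiles, metric=metric), method="average")
    order = hierarchy.leaves_list(linkage)
    return [matrix.peptides[i] for i in order], linkage


def cluster_samples(
    matrix: PhosphoMatrix, metric: str = "euclidean"
) -> tuple[list[str], np.ndarray]:
    """Same linkage applied to sample profiles, for the heatmap's other axis."""
    if len(matrix.samples) < 2:
        raise ValueError("clustering needs >= 2 samples")
    linkage = hierarchy.linkage(pdist(matrix.values, metric=metric), method="average")
    order = hierarchy.leaves_list(linkage)
    return [matrix.samples[i] for i in order], linkage


def export_volcano(result: ContrastResult, path, plot_path=None) -> pd.DataFrame:
    """Write volcano-plot data: peptide, lfc, −log10(p), significance flag.

    Optionally renders a PNG/SVG scatter when ``plot_path`` is given.
    """
    df = pd.DataFrame(
        {
            "peptide": result.peptides,
            "lfc": result.lfc,
            "neg_log10_p": -np.log10(result.p),
            "significant": result.significant,
        }
    )
    df.to_csv(path, sep="\t", index=False)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        col = np.where(result.significant, "red", "black")
        ax.scatter(df["lfc"], df["neg_log10_p"], s=12, c=col)
        ax.axhline(-np.log10(result.alpha), ls="--", lw=0.8, c="grey")
        ax.set_xlabel("log2 fold change")
        ax.set_ylabel("-log10 p")
        ax.set_title(result.contrast_name)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return df


def export_violin(matrix: PhosphoMatrix, path) -> pd.DataFrame:
    """Long-format sample/peptide/value/group table for violin-style plots."""
    df = matrix.to_frame().reset_index(names="sample").melt(
        id_vars="sample", var_name="peptide", value_name="log2_signal"
    )
    df["group"] = df["sample"].map(matrix.group_of)
    df.to_csv(path, sep="\t", index=False)
    return df


def export_heatmap(matrix: PhosphoMatrix, path, metric: str = "euclidean") -> pd.DataFrame:
    """Matrix TSV reordered by UPGMA leaf order on both axes."""
    pep_order, _ = cluster_peptides(matrix, metric=metric)
    samp_order, _ = cluster_samples(matrix, metric=metric)
    df = matrix.to_frame().loc[samp_order, pep_order]
    df.to_csv(path, sep="\t", index_label="sample")
    return df
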