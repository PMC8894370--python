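"""Exposure-time scaling and log2 transformation.

A spot imaged at several camera exposure times yields several intensities
that, in the camera's linear range, are proportional to exposure. The stack
is collapsed to one value per (sample, peptide) by fitting
``intensity = slope × exposure`` by least squares through the origin and
evaluating the fit at a reference exposure (default 100 ms). A zero-exposure
image carries no signal, which is why the fit is constrained through the
origin; an unconstrained intercept is available for robustness checks.

The combined values are floored (default 1.0) and log2-transformed into the
analysis matrix. Flooring keeps negative fitted slopes — possible when spot
signals sit below background — finite and retains the peptide for
clustering and permutation analysis instead of dropping it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .array_io import ExposureStack

__all__ = ["PhosphoMatrix", "combine_exposures", "log2_with_floor", "qc_summary"]


@dataclass
class PhosphoMatrix:
    """Samples × peptides matrix of log2 exposure-scaled signals with design."""

    samples: list[str]
    peptides: list[str]
    values: np.ndarray = field(repr=False)
    group_of: dict[str, str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.peptides)):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.samples)}, {len(self.peptides)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix values must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.peptides)

    def rows_for_group(self, group: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if self.group_of[s] == group]
        if not idx:
            raise KeyError(f"no samples in group {group!r}")
        return np.asarray(idx)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.group_of[s], None)
        return list(seen)


def combine_exposures(
    stack: ExposureStack,
    reference_ms: float = 100.0,
    fit_intercept: bool = False,
) -> np.ndarray:
    """Collapse multi-exposure intensities to the predicted signal at ``reference_ms``.

    Per (sample, peptide) a least-squares line through the origin is fitted
    over exposure times (slope = Σ t·y / Σ t²) and evaluated at the reference
    exposure. The operation is linear in the intensities; negative fitted
    slopes pass through unchanged (they are floored downstream). With
    ``fit_intercept`` an ordinary simple regression is used instead and only
    its slope term is rescaled.

    Returns an (n_samples, n_peptides) array.
    """
    t = stack.exposure_times_ms
    y = stack.intensity
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite intensities in exposure stack")
    if fit_intercept:
        tc = t - t.mean()
        slope = (y * tc).sum(axis=-1) / (tc**2).sum()
    else:
        slope = (y * t).sum(axis=-1) / (t**2).sum()
    return slope * reference_ms


def log2_with_floor(
    combined: np.ndarray,
    stack: ExposureStack,
    floor: float = 1.0,
    reference_ms: float = 100.0,
) -> PhosphoMatrix:
    """log2-transform combined signals, clipping below at ``floor``.

    ``floor`` must be positive; the default 1.0 maps non-positive combined
    signals to log2 value 0.
    """
    if floor <= 0:
        raise ValueError(f"floor must be > 0, got {floor}")
    values = np.log2(np.maximum(np.asarray(combined, dtype=float), floor))
    return PhosphoMatrix(
        samples=list(stack.samples),
        peptides=list(stack.peptide_ids),
        values=values,
        group_of=dict(stack.group_of),
        provenance={"reference_ms": reference_ms, "floor": floor},
    )


def preprocess(
    stack: ExposureStack,
    reference_ms: float = 100.0,
    floor: float = 1.0,
    fit_intercept: bool = False,
    normalize: str = "none",
) -> PhosphoMatrix:
    """Full preprocessing: exposure-time scaling then log2 with floor.

    ``normalize='median'`` optionally centres each sample at the cohort-wide
    median (off by default; no between-sample normalisation is assumed).
    """
    combined = combine_exposures(stack, reference_ms=reference_ms, fit_intercept=fit_intercept)
    matrix = log2_with_floor(combined, stack, floor=floor, reference_ms=reference_ms)
    if normalize == "median":
        med = np.median(matrix.values, axis=1, keepdims=True)
        matrix.values = matrix.values - med + np.median(matrix.values)
        matrix.provenance["normalize"] = "median"
    elif normalize != "none":
        raise ValueError(f"unknown normalize mode {normalize!r}")
    matrix.provenance.setdefault("normalize", normalize)
    matrix.provenance["fit_intercept"] = fit_intercept
    return matrix


def qc_summary(matrix: PhosphoMatrix, iqr_multiple: float = 3.0) -> pd.DataFrame:
    """Per-sample QC table: median, IQR, floored fraction, outlier flag.

    A sample is flagged when its median deviates from the cohort median of
    sample medians by strictly more than ``iqr_multiple`` × the cohort IQR of
    sample medians. The strict inequality means identical samples (IQR 0,
    deviation 0) are never flagged, while a gross outlier in an otherwise
    tight cohort is.
    """
    floor = matrix.provenance.get("floor", 1.0)
    floored_value = np.log2(floor)
    med = np.median(matrix.values, axis=1)
    q75, q25 = np.percentile(matrix.values, [75, 25], axis=1)
    frac_floored = (matrix.values <= floored_value).mean(axis=1)
    cohort_median = np.median(med)
    cohort_iqr = np.subtract(*np.percentile(med, [75, 25]))
    flagged = np.abs(med - cohort_median) > iqr_multiple * cohort_iqr
    return pd.DataFrame(
        {
            "sample": matrix.samples,
            "group": [matrix.group_of[s] for s in matrix.samples],
            "median": med,
            "iqr": q75 - q25,
            "fraction_floored": frac_floored,
            "flagged": flagged,
        }
    )
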