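"""Array layouts, peptide identifiers, and spot-level signal tables.

Peptides on a serine/threonine kinase array are named after the protein
they derive from plus the first and last amino-acid positions of the
peptide, joined by underscores (``KCNA6_504_516``). Protein tags may
themselves contain underscores (``SRC8_CHICK_423_435``), so the ID grammar
is: everything up to the final two integer tokens is the protein tag.

Spot signals are read from long-format tables with one row per
(sample, peptide, exposure time) and collected into an :class:`ExposureStack`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MalformedPeptideIDError",
    "LayoutMismatchError",
    "IncompleteStackError",
    "PeptideID",
    "ArrayLayout",
    "ExposureStack",
    "parse_peptide_id",
    "read_layout",
    "read_design",
    "read_signal_table",
    "write_signal_table",
    "write_matrix",
    "read_matrix",
]


class MalformedPeptideIDError(ValueError):
    """A peptide identifier does not follow the <tag>_<start>_<end> grammar."""


class LayoutMismatchError(ValueError):
    """A signal table refers to peptides absent from the array layout."""


class IncompleteStackError(ValueError):
    """A signal table is missing (sample, peptide, exposure) combinations."""


@dataclass(frozen=True)
class PeptideID:
    """A parsed array-peptide identifier.

    ``start`` and ``end`` are 1-based inclusive amino-acid positions in the
    source protein.
    """

    raw_id: str
    protein_tag: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise MalformedPeptideIDError(
                f"peptide ID {self.raw_id!r}: start {self.start} > end {self.end}"
            )
        expect = f"{self.protein_tag}_{self.start}_{self.end}"
        if self.raw_id != expect:
            raise MalformedPeptideIDError(
                f"peptide ID {self.raw_id!r} does not reconstruct from its parts ({expect!r})"
            )


def parse_peptide_id(raw: str) -> PeptideID:
    """Parse ``raw`` into a :class:`PeptideID`.

    The final two underscore-separated tokens are the integer start/end
    positions; all preceding tokens (re-joined with ``_``) form the protein
    tag. Raises :class:`MalformedPeptideIDError` on fewer than three tokens,
    non-integer positions, or start > end.
    """
    if not raw:
        raise MalformedPeptideIDError("empty peptide ID")
    tokens = raw.split("_")
    if len(tokens) < 3:
        raise MalformedPeptideIDError(
            f"peptide ID {raw!r}: expected <protein>_<start>_<end>"
        )
    try:
        start, end = int(tokens[-2]), int(tokens[-1])
    except ValueError:
        raise MalformedPeptideIDError(
            f"peptide ID {raw!r}: last two tokens must be integer positions"
        ) from None
    if start <= 0 or end <= 0:
        raise MalformedPeptideIDError(f"peptide ID {raw!r}: positions must be positive")
    return PeptideID(raw_id=raw, protein_tag="_".join(tokens[:-2]), start=start, end=end)


@dataclass(frozen=True)
class ArrayLayout:
    """An ordered, duplicate-free list of peptides printed on one array."""

    peptides: tuple[PeptideID, ...]
    array_name: str = "STK"

    def __post_init__(self) -> None:
        ids = [p.raw_id for p in self.peptides]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate peptide IDs in layout: {dupes}")

    @property
    def peptide_ids(self) -> list[str]:
        return [p.raw_id for p in self.peptides]

    def __len__(self) -> int:
        return len(self.peptides)


@dataclass
class ExposureStack:
    """Background-subtracted spot signals indexed by (sample, peptide, exposure).

    ``intensity`` has shape (n_samples, n_peptides, n_exposures) in arbitrary
    fluorescence units; ``exposure_times_ms`` is strictly increasing with at
    least two entries, matching multi-exposure camera readout.
    """

    samples: list[str]
    group_of: dict[str, str]
    peptide_ids: list[str]
    exposure_times_ms: np.ndarray
    intensity: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.exposure_times_ms = np.asarray(self.exposure_times_ms, dtype=float)
        t = self.exposure_times_ms
        if t.size < 2 or np.any(np.diff(t) <= 0) or np.any(t <= 0):
            raise ValueError("exposure times must be >= 2 strictly increasing positives")
        self.intensity = np.asarray(self.intensity, dtype=float)
        expect = (len(self.samples), len(self.peptide_ids), t.size)
        if self.intensity.shape != expect:
            raise ValueError(
                f"intensity shape {self.intensity.shape} != expected {expect}"
            )
        missing = set(self.samples) - set(self.group_of)
        if missing:
            raise ValueError(f"samples without group assignment: {sorted(missing)}")

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.group_of[s], None)
        return list(seen)


def _read_table(path) -> pd.DataFrame:
    """Read a delimited text table, sniffing tab vs comma."""
    with open(path, "r", encoding="utf-8") as fh:
        head = fh.readline()
        rest = fh.read()
    sep = "\t" if head.count("\t") >= head.count(",") else ","
    return pd.read_csv(io.StringIO(head + rest), sep=sep)


def read_layout(path, array_name: str = "STK") -> ArrayLayout:
    """Read an array layout: one peptide ID per line (optionally headed 'peptide_id')."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if lines and lines[0].lower() in {"peptide_id", "peptide"}:
        lines = lines[1:]
    return ArrayLayout(tuple(parse_peptide_id(ln) for ln in lines), array_name=array_name)


def read_design(path) -> dict[str, str]:
    """Read a sample→group design table with columns sample, group."""
    df = _read_table(path)
    for col in ("sample", "group"):
        if col not in df.columns:
            raise ValueError(f"design table missing column {col!r}")
    return dict(zip(df["sample"].astype(str), df["group"].astype(str)))


def read_signal_table(path, layout: ArrayLayout, design: dict[str, str]) -> ExposureStack:
    """Read a long-format signal table into a complete :class:`ExposureStack`.

    Expects columns sample, peptide, exposure_ms, signal (TSV or CSV). Every
    (sample, peptide, exposure) combination must be present exactly once and
    every peptide must belong to ``layout``.
    """
    df = _read_table(path)
    required = {"sample", "peptide", "exposure_ms", "signal"}
    if not required.issubset(df.columns):
        raise ValueError(f"signal table missing columns {sorted(required - set(df.columns))}")

    known = set(layout.peptide_ids)
    unknown = sorted(set(df["peptide"].astype(str)) - known)
    if unknown:
        raise LayoutMismatchError(
            f"peptides not in layout {layout.array_name!r}: {unknown[:10]}"
        )

    samples = sorted(df["sample"].astype(str).unique())
    exposures = np.sort(df["exposure_ms"].astype(float).unique())
    wide = df.pivot_table(
        index=["sample", "peptide"], columns="exposure_ms", values="signal",
        aggfunc="first", dropna=False,
    )
    full_index = pd.MultiIndex.from_product(
        [samples, layout.peptide_ids], names=["sample", "peptide"]
    )
    wide = wide.reindex(full_index)
    if wide.isna().any().any():
        gaps = [
            (s, p, float(e))
            for (s, p), row in wide.iterrows()
            for e, v in row.items()
            if pd.isna(v)
        ]
        raise IncompleteStackError(
            f"{len(gaps)} missing (sample, peptide, exposure) entries, e.g. {gaps[:5]}"
        )

    missing_design = sorted(set(samples) - set(design))
    if missing_design:
        raise ValueError(f"samples absent from design: {missing_design}")
    intensity = wide.to_numpy().reshape(len(samples), len(layout), exposures.size)
    return ExposureStack(
        samples=samples,
        group_of={s: design[s] for s in samples},
        peptide_ids=list(layout.peptide_ids),
        exposure_times_ms=exposures,
        intensity=intensity,
    )


def write_signal_table(stack: ExposureStack, path) -> None:
    """Write a stack back to the long-format TSV that :func:`read_signal_table` reads."""
    rows = []
    for i, s in enumerate(stack.samples):
        for j, p in enumerate(stack.peptide_ids):
            for k, e in enumerate(stack.exposure_times_ms):
                rows.append((s, p, e, stack.intensity[i, j, k]))
    pd.DataFrame(rows, columns=["sample", "peptide", "exposure_ms", "signal"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def write_matrix(matrix, path) -> None:
    """Write a samples × peptides matrix as TSV at full float precision."""
    df = matrix.to_frame()
    if df.size == 0:
        raise ValueError("refusing to write an empty matrix")
    if not np.all(np.isfinite(df.to_numpy())):
        raise ValueError("matrix contains non-finite values")
    df.to_csv(path, sep="\t", index=True, index_label="sample", float_format="%.17g")


def read_matrix(path, group_of: dict[str, str] | None = None):
    """Read a matrix written by :func:`write_matrix` back into a PhosphoMatrix."""
    from .preprocess import PhosphoMatrix  # local import avoids a cycle

    df = pd.read_csv(path, sep="\t", index_col="sample")
    if group_of is None:
        group_of = {s: "unknown" for s in df.index}
    return PhosphoMatrix(
        samples=list(df.index.astype(str)),
        peptides=list(df.columns.astype(str)),
        values=df.to_numpy(dtype=float),
        group_of=group_of,
    )
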