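"""Retinal-layer statistics from immunofluorescence intensity traces.

An intensity trace is a 1-D profile along a retinal cross-section (position
in arbitrary units, intensity per position) for one antibody in one animal,
with a matching trace for the negative control (secondary antibody only).
Layer annotations assign half-open position intervals [start, end) to the
anatomical layers (OS/IS, ONL, OPL, INL, IPL, GCL, NFL). The analysis
reports the mean intensity per layer and the antibody/negative-control
ratio per layer, summarised across animals as mean ± sample SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RETINAL_LAYERS",
    "IntensityTrace",
    "LayerAnnotation",
    "layer_means",
    "layer_ratio",
    "summarize_animals",
    "read_traces",
    "read_layer_annotation",
]

RETINAL_LAYERS = ("OS/IS", "ONL", "OPL", "INL", "IPL", "GCL", "NFL")


@dataclass
class IntensityTrace:
    animal_id: str
    antibody: str  # antigen name, or "neg_ctrl"
    position: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.position.shape != self.intensity.shape:
            raise ValueError("position and intensity must have the same length")
        if np.any(np.diff(self.position) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")


@dataclass
class LayerAnnotation:
    """Ordered, non-overlapping half-open [start, end) layer intervals."""

    layers: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for name, start, end in self.layers:
            if start >= end:
                raise ValueError(f"layer {name!r}: start {start} >= end {end}")
            if start < prev_end:
                raise ValueError(f"layer {name!r} overlaps the preceding layer")
            prev_end = end

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.layers]


def layer_means(trace: IntensityTrace, ann: LayerAnnotation) -> dict[str, float]:
    """Mean intensity per layer; a position exactly on a boundary belongs to
    the following layer (half-open intervals). Raises for layers with no
    sampled positions."""
    out: dict[str, float] = {}
    for name, start, end in ann.layers:
        mask = (trace.position >= start) & (trace.position < end)
        if not mask.any():
            raise ValueError(f"layer {name!r} contains no trace positions")
        out[name] = float(trace.intensity[mask].mean())
    return out


def layer_ratio(
    antibody_means: dict[str, float], control_means: dict[str, float]
) -> dict[str, float]:
    """Per-layer antibody / negative-control ratio.

    The negative control carries autofluorescence and must be positive in
    every layer; a non-positive control mean is an error rather than an
    epsilon-padded division.
    """
    out: dict[str, float] = {}
    for layer, ab in antibody_means.items():
        ctrl = control_means.get(layer)
        if ctrl is None:
            raise KeyError(f"no control mean for layer {layer!r}")
        if ctrl <= 0:
            raise ValueError(f"non-positive control mean in layer {layer!r}: {ctrl}")
        out[layer] = ab / ctrl
    return out


def summarize_animals(
    ratios_per_animal: list[dict[str, float]], n_expected: int = 3
) -> pd.DataFrame:
    """Across-animal mean and sample SD (n−1) per layer.

    Requires at least two animals; a count differing from ``n_expected`` is
    allowed (small studies lose sections) but the caller sees the actual n.
    """
    if len(ratios_per_animal) < 2:
        raise ValueError("need >= 2 animals to summarise")
    layers = list(ratios_per_animal[0])
    for r in ratios_per_animal[1:]:
        if list(r) != layers:
            raise ValueError("animals report different layer sets")
    data = np.array([[r[l] for l in layers] for r in ratios_per_animal])
    return pd.DataFrame(
        {
            "layer": layers,
            "mean": data.mean(axis=0),
            "sd": data.std(axis=0, ddof=1),
            "n": len(ratios_per_animal),
        }
    )


def read_traces(path) -> list[IntensityTrace]:
    """Read traces from CSV/TSV with columns position, intensity, animal, antibody."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"position", "intensity", "animal", "antibody"}
    if not required.issubset(df.columns):
        raise ValueError(f"trace table missing columns {sorted(required - set(df.columns))}")
    traces = []
    for (animal, antibody), grp in df.groupby(["animal", "antibody"], sort=True):
        grp = grp.sort_values("position")
        traces.append(
            IntensityTrace(
                animal_id=str(animal),
                antibody=str(antibody),
                position=grp["position"].to_numpy(),
                intensity=grp["intensity"].to_numpy(),
            )
        )
    return traces


def read_layer_annotation(path) -> LayerAnnotation:
    """Read layer annotation CSV/TSV with columns layer, start, end."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    return LayerAnnotation(
        [(str(r.layer), float(r.start), float(r.end)) for r in df.itertuples(index=False)]
    )


def profile_study(
    traces: list[IntensityTrace], ann: LayerAnnotation, antibody: str
) -> pd.DataFrame:
    """End-to-end per-antibody summary: layer ratios per animal, then mean ± SD.

    Each animal must contribute both the antibody trace and a "neg_ctrl"
    trace.
    """
    by_animal: dict[str, dict[str, IntensityTrace]] = {}
    for t in traces:
        by_animal.setdefault(t.animal_id, {})[t.antibody] = t
    ratios = []
    for animal, tr in sorted(by_animal.items()):
        if antibody not in tr or "neg_ctrl" not in tr:
            continue
        ratios.append(
            layer_ratio(layer_means(tr[antibody], ann), layer_means(tr["neg_ctrl"], ann))
        )
    summary = summarize_animals(ratios)
    summary.insert(0, "antibody", antibody)
    return summary
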