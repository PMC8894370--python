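"""Synthetic multi-exposure array experiments with planted kinase activities.

The generator emulates the measurement model of a serine/threonine peptide
microarray read at several camera exposure times: each peptide has a
baseline log2 phosphorylation level; a kinase made more active in one group
(activity multiplier > 1 on the linear scale) raises its substrates' levels
in proportion to substrate weight (full effect at weight 10, log2-additive
contribution log2(multiplier)·weight/10); biological noise is Gaussian on
the log2 scale per sample; each exposure reads the linear signal scaled by
exposure/100 ms with small multiplicative camera noise, truncated at zero.

Defaults mirror the study conditions: three groups (WT n=5, rd1 n=8,
rd1_CN03 n=10), a 142-peptide array, exposures 10–200 ms. The CN03-treated
group models pharmacological PKG inhibition purely as resetting the PKG
activity multipliers toward 1.

A :class:`GroundTruthLedger` carries the planted per-peptide expected
levels and per-kinase expected statistic signs, so recovery tests can
compare pipeline output against the construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .array_io import ArrayLayout, ExposureStack, parse_peptide_id
from .annotation import load_reference_substrates
from .upstream import KinaseSubstrateMap

__all__ = [
    "SyntheticTruth",
    "GroundTruthLedger",
    "default_fixture_layout",
    "default_substrate_map",
    "simulate_experiment",
]

#: Peptides named individually in the study besides the reference table.
RESULTS_PEPTIDES = (
    "SRC8_CHICK_423_435",
    "RBL2_959_971",
    "CDN1B_151_163",
    "RADI_559_569",
)


@dataclass
class SyntheticTruth:
    """Parameters of one simulated experiment; the ground-truth record.

    ``active_kinases`` maps (kinase, group) to a linear-scale activity
    multiplier; groups not listed for a kinase have multiplier 1.
    """

    seed: int = 0
    groups: dict[str, int] = field(
        default_factory=lambda: {"WT": 5, "rd1": 8, "rd1_CN03": 10}
    )
    active_kinases: dict[tuple[str, str], float] = field(default_factory=dict)
    baseline_log2: float = 8.0
    noise_sd_log2: float = 0.35
    exposure_times_ms: tuple[float, ...] = (10.0, 20.0, 50.0, 100.0, 200.0)
    exposure_noise_cv: float = 0.05
    saturation_ceiling: float | None = None

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.groups.values()):
            raise ValueError("every group needs >= 2 samples")
        if any(m <= 0 for m in self.active_kinases.values()):
            raise ValueError("activity multipliers must be > 0")
        if self.noise_sd_log2 < 0 or self.exposure_noise_cv < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class GroundTruthLedger:
    """Deterministic consequences of a :class:`SyntheticTruth`.

    ``expected_log2`` is a groups × peptides frame of noise-free log2
    levels; ``expected_sign`` maps (kinase, contrast "A_vs_B") to the sign
    of the planted kinase statistic.
    """

    truth: SyntheticTruth
    expected_log2: pd.DataFrame
    expected_sign: dict[tuple[str, str], int]

    def to_frame(self) -> pd.DataFrame:
        return self.expected_log2.reset_index(names="group").melt(
            id_vars="group", var_name="peptide", value_name="expected_log2"
        )


def default_fixture_layout() -> ArrayLayout:
    """The packaged 142-peptide array layout.

    Contains the 22 reference-table peptides, the 4 individually named
    peptides, and 116 synthetic filler IDs of valid format (named
    SYNPEP001_1_13 ...), for a total of 142.
    """
    named = [r.peptide.raw_id for r in load_reference_substrates()] + list(RESULTS_PEPTIDES)
    fillers = [f"SYNPEP{i:03d}_{i}_{i + 12}" for i in range(1, 142 - len(named) + 1)]
    return ArrayLayout(
        tuple(parse_peptide_id(p) for p in named + fillers), array_name="STK-142"
    )


def default_substrate_map(
    n_decoys: int = 9,
    peptides_per_decoy: int = 8,
    decoy_seed: int = 20220303,
    layout: ArrayLayout | None = None,
) -> KinaseSubstrateMap:
    """PKG1/PKG2 fingerprints from the reference table plus synthetic decoys.

    PKG1 and PKG2 substrate weights are the table's printed specificity
    scores (weight-0 rows drop out). Decoy kinases (DECOY1..) get disjoint
    substrate sets drawn deterministically from the synthetic filler
    peptides with weights cycling 4..10 — synthetic stand-ins providing a
    null background for the permutation analyses, not a curated database.
    """
    if layout is None:
        layout = default_fixture_layout()
    records = load_reference_substrates()
    substrates: dict[str, dict[str, int]] = {
        "PKG1": {r.peptide.raw_id: r.pkg1_score for r in records},
        "PKG2": {r.peptide.raw_id: r.pkg2_score for r in records},
    }
    named = {p for sub in substrates.values() for p in sub}
    pool = [p for p in layout.peptide_ids if p not in named and p not in RESULTS_PEPTIDES]
    need = n_decoys * peptides_per_decoy
    if need > len(pool):
        raise ValueError(f"not enough filler peptides for {n_decoys} disjoint decoys")
    rng = substream(decoy_seed, "decoy-substrates")
    chosen = rng.choice(len(pool), size=need, replace=False)
    weights = [4 + (i % 7) for i in range(peptides_per_decoy)]
    for d in range(n_decoys):
        picks = chosen[d * peptides_per_decoy : (d + 1) * peptides_per_decoy]
        substrates[f"DECOY{d + 1}"] = {
            pool[j]: w for j, w in zip(picks, weights)
        }
    return KinaseSubstrateMap(substrates)


def expected_levels(
    truth: SyntheticTruth, layout: ArrayLayout, smap: KinaseSubstrateMap
) -> pd.DataFrame:
    """Noise-free expected log2 level per (group, peptide)."""
    peptides = layout.peptide_ids
    levels = pd.DataFrame(
        truth.baseline_log2, index=list(truth.groups), columns=peptides, dtype=float
    )
    for (kinase, group), mult in truth.active_kinases.items():
        if kinase not in smap.substrates_of:
            raise ValueError(f"active kinase {kinase!r} not in substrate map")
        if group not in truth.groups:
            raise ValueError(f"active-kinase group {group!r} not a simulated group")
        for pep, w in smap.substrates_of[kinase].items():
            if pep in levels.columns:
                levels.loc[group, pep] += np.log2(mult) * (w / 10.0)
    return levels


def simulate_experiment(
    truth: SyntheticTruth,
    layout: ArrayLayout | None = None,
    smap: KinaseSubstrateMap | None = None,
) -> tuple[ExposureStack, GroundTruthLedger]:
    """Simulate one multi-exposure experiment under ``truth``.

    Per sample, log2 value = expected level + N(0, noise_sd_log2); per
    exposure e, intensity = 2^value · (e/100) · (1 + N(0, exposure_noise_cv)),
    truncated at 0 (and optionally capped at ``saturation_ceiling``). The
    same seed always produces the same stack bit-for-bit.
    """
    if layout is None:
        layout = default_fixture_layout()
    if smap is None:
        smap = default_substrate_map()
    levels = expected_levels(truth, layout, smap)
    exposures = np.asarray(truth.exposure_times_ms, dtype=float)

    rng = substream(truth.seed, "simulation")
    samples: list[str] = []
    group_of: dict[str, str] = {}
    rows = []
    for group, n in truth.groups.items():
        for i in range(1, n + 1):
            s = f"{group}_{i:02d}"
            samples.append(s)
            group_of[s] = group
            value = levels.loc[group].to_numpy() + rng.normal(
                0.0, truth.noise_sd_log2, size=len(layout)
            )
            linear = 2.0**value
            noise = rng.normal(0.0, truth.exposure_noise_cv, size=(len(layout), exposures.size))
            inten = linear[:, None] * (exposures[None, :] / 100.0) * (1.0 + noise)
            inten = np.maximum(inten, 0.0)
            if truth.saturation_ceiling is not None:
                inten = np.minimum(inten, truth.saturation_ceiling)
            rows.append(inten)

    stack = ExposureStack(
        samples=samples,
        group_of=group_of,
        peptide_ids=list(layout.peptide_ids),
        exposure_times_ms=exposures,
        intensity=np.stack(rows),
    )

    signs: dict[tuple[str, str], int] = {}
    groups = list(truth.groups)
    for kinase in smap.kinases:
        present = [p for p in layout.peptide_ids if p in smap.substrates_of[kinase]]
        if not present:
            continue
        for ga in groups:
            for gb in groups:
                if ga == gb:
                    continue
                delta = (levels.loc[ga, present] - levels.loc[gb, present]).mean()
                signs[(kinase, f"{ga}_vs_{gb}")] = int(np.sign(delta))
    ledger = GroundTruthLedger(truth=truth, expected_log2=levels, expected_sign=signs)
    return stack, ledger
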