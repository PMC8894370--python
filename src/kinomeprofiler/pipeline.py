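"""End-to-end orchestration: read → preprocess → contrasts → kinases → ORA.

A run is driven by a :class:`RunConfig` (usually a YAML file) and writes
all exports plus a JSON manifest (package version, config hash, seed, and
the files produced) into one output directory. Outputs are written to a
temporary staging directory and moved into place only when every stage has
succeeded, so a failed run leaves no partial outputs behind. Identical
config + seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import contrast_overlap
from .array_io import read_design, read_layout, read_signal_table, write_matrix
from .differential import contrast, export_heatmap, export_violin, export_volcano, fraction_changed
from .enrichment import load_toy_pathways, map_kinases_to_genes, read_gmt, run_ora
from .preprocess import preprocess, qc_summary
from .upstream import export_coral, rank_kinases, read_substrate_map, results_frame

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    signals: str
    layout: str
    design: str
    substrate_map: str
    out_dir: str
    gene_sets: str | None = None
    contrasts: list[tuple[str, str]] = field(default_factory=list)
    reference_ms: float = 100.0
    floor: float = 1.0
    fit_intercept: bool = False
    normalize: str = "none"
    alpha: float = 0.05
    variance: str = "pooled"
    b_labels: int = 500
    b_peptides: int = 500
    min_set_size: int = 3
    weighted: bool = False
    report_threshold: float = 1.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        raw["contrasts"] = [tuple(c) for c in raw.get("contrasts", [])]
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in sorted(self.__dict__.items())}, default=str, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def validate(self, groups: set[str]) -> None:
        for path in (self.signals, self.layout, self.design, self.substrate_map):
            if not Path(path).exists():
                raise FileNotFoundError(path)
        for a, b in self.contrasts:
            if a not in groups or b not in groups:
                raise ValueError(f"contrast ({a}, {b}) references undeclared groups {sorted(groups)}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dict.

    Stages: read signals → preprocess + QC → per-contrast differential
    exports → upstream kinase ranking + kinome-tree export → kinase-list
    overlap (when ≥ 2 contrasts) → ORA of each contrast's reported kinases.
    """
    out_dir = Path(config.out_dir)
    staging = Path(tempfile.mkdtemp(prefix="kinomeprofiler_run_"))
    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "contrasts": [],
        "files": [],
    }

    def _emit(name: str) -> Path:
        manifest["files"].append(name)
        return staging / name

    stage = "validate"
    try:
        design = read_design(config.design)
        config.validate(set(design.values()))

        stage = "read"
        layout = read_layout(config.layout)
        stack = read_signal_table(config.signals, layout, design)

        stage = "preprocess"
        matrix = preprocess(
            stack,
            reference_ms=config.reference_ms,
            floor=config.floor,
            fit_intercept=config.fit_intercept,
            normalize=config.normalize,
        )
        write_matrix(matrix, _emit("log2_matrix.tsv"))
        qc_summary(matrix).to_csv(_emit("qc_summary.tsv"), sep="\t", index=False)
        export_violin(matrix, _emit("violin_long.tsv"))
        export_heatmap(matrix, _emit("heatmap_matrix.tsv"))

        smap = read_substrate_map(config.substrate_map)
        reported_by_contrast: dict[str, list[str]] = {}
        for group_a, group_b in config.contrasts:
            cname = f"{group_a}_vs_{group_b}"
            stage = f"differential:{cname}"
            res = contrast(
                matrix, group_a, group_b, alpha=config.alpha, variance=config.variance
            )
            res.to_frame().to_csv(_emit(f"contrast_{cname}.tsv"), sep="\t", index=False)
            export_volcano(res, _emit(f"volcano_{cname}.tsv"))

            stage = f"upstream:{cname}"
            full, reported = rank_kinases(
                matrix, smap, group_a, group_b,
                b_labels=config.b_labels, b_peptides=config.b_peptides,
                seed=config.seed, weighted=config.weighted,
                min_set_size=config.min_set_size,
                report_threshold=config.report_threshold,
            )
            results_frame(full).to_csv(_emit(f"kinases_full_{cname}.tsv"), sep="\t", index=False)
            results_frame(reported).to_csv(
                _emit(f"kinases_reported_{cname}.tsv"), sep="\t", index=False
            )
            export_coral(reported, _emit(f"coral_{cname}.tsv"))
            reported_by_contrast[cname] = [r.kinase for r in reported]
            manifest["contrasts"].append(
                {
                    "name": cname,
                    "fraction_up": fraction_changed(res, "up"),
                    "fraction_down": fraction_changed(res, "down"),
                    "n_significant": int(res.significant.sum()),
                    "n_reported_kinases": len(reported),
                }
            )

        names = list(reported_by_contrast)
        if len(names) >= 2:
            stage = "overlap"
            a, b = names[0], names[1]
            if reported_by_contrast[a] and reported_by_contrast[b]:
                shared, pct_a, pct_b = contrast_overlap(
                    reported_by_contrast[a], reported_by_contrast[b]
                )
                pd.DataFrame(
                    {"shared_kinase": sorted(shared)}
                ).to_csv(_emit("overlap_shared.tsv"), sep="\t", index=False)
                manifest["overlap"] = {
                    "contrasts": [a, b],
                    "shared": sorted(shared),
                    "pct_of_first": pct_a,
                    "pct_of_second": pct_b,
                }

        stage = "ora"
        collection = read_gmt(config.gene_sets) if config.gene_sets else load_toy_pathways()
        for cname, kinases in reported_by_contrast.items():
            if not kinases:
                continue
            genes = map_kinases_to_genes(kinases)
            try:
                ora = run_ora(genes, collection)
            except ValueError as exc:
                logger.warning("ORA skipped for %s: %s", cname, exc)
                continue
            ora.to_csv(_emit(f"ora_{cname}.tsv"), sep="\t", index=False)

        stage = "manifest"
        with open(staging / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        manifest["files"].append("manifest.json")
    except Exception as exc:
        shutil.rmtree(staging, ignore_errors=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc

    out_dir.mkdir(parents=True, exist_ok=True)
    for name in manifest["files"]:
        shutil.move(str(staging / name), str(out_dir / name))
    shutil.rmtree(staging, ignore_errors=True)
    return manifest
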