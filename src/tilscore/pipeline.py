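"""End-to-end orchestration: slide -> tile -> filter -> normalize ->
classify -> score -> map.

Batch-robust by design: a slide that fails to read or process is
recorded and skipped, the run continues, and the failure list is part of
the result.  With the rule-based backend the whole pipeline is
deterministic: re-running with identical config and inputs reproduces
byte-identical TSV outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .classify import (
    DetectorParams,
    PatchLabel,
    Prediction,
    RuleBasedBackend,
    classify_patch,
)
from .evalmetrics import evaluate
from .scoring import build_til_map, score_cohort
from .slideio import BlankFilterParams, TileManifest, filter_patches, read_slide, tile_slide
from .stainnorm import MacenkoParams, StainProfile, default_target_profile, normalize_patch

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_patient_map"]

logger = logging.getLogger("tilscore")

FLOAT_FORMAT = "%.6f"


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    Values stated by the patch-labeling protocol (patch size 150, blank
    mean > 230 / sd < 15) are the defaults; Macenko hyperparameters and
    detector geometry are package defaults, configurable here or via
    YAML.
    """

    patch_size: int = 150
    blank: BlankFilterParams = field(default_factory=BlankFilterParams)
    macenko: MacenkoParams = field(default_factory=MacenkoParams)
    target_profile_path: str | None = None
    normalize: bool = True
    backend: str = "rule"
    detector: DetectorParams = field(default_factory=DetectorParams)
    out_dir: str = "tilscore_out"
    map_scale: int = 8
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.patch_size <= 0:
            raise ValueError("patch_size must be positive")
        if self.backend not in ("rule",):
            raise ValueError(f"unknown backend '{self.backend}'")
        if self.target_profile_path and not Path(self.target_profile_path).exists():
            raise ValueError(f"target profile not found: {self.target_profile_path}")

    def target_profile(self) -> StainProfile:
        if self.target_profile_path:
            return StainProfile.from_json(self.target_profile_path)
        return default_target_profile()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_to_plain(dataclasses.asdict(self))))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, klass in (
            ("blank", BlankFilterParams),
            ("macenko", MacenkoParams),
            ("detector", DetectorParams),
        ):
            if key in raw and isinstance(raw[key], dict):
                params = raw[key]
                # YAML round-trips tuples as lists
                params = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in params.items()
                }
                raw[key] = klass(**params)
        return cls(**raw)


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class PipelineResult:
    predictions: pd.DataFrame
    scores: pd.DataFrame
    manifests: dict[str, TileManifest]
    failures: dict[str, str]
    out_dir: Path


def load_patient_map(path: str | Path) -> dict[str, str]:
    """Read a slide -> patient grouping TSV (columns slide_id, patient_id)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(table["slide_id"], table["patient_id"]))


def _process_slide(path: Path, config: PipelineConfig, backend) -> tuple[TileManifest, list[dict]]:
    raster = read_slide(path)
    slide_id = path.stem
    manifest, patches = tile_slide(raster, slide_id=slide_id, patch_size=config.patch_size)
    retained = filter_patches(manifest, patches, config.blank)
    target = config.target_profile()
    rows = []
    for patch in retained:
        pixels = patch.pixels
        if config.normalize:
            pixels = normalize_patch(patch, target=target, params=config.macenko).pixels
        prediction = classify_patch(pixels, backend)
        rows.append(
            {
                "slide_id": slide_id,
                "grid_row": patch.grid_row,
                "grid_col": patch.grid_col,
                "label": int(prediction.label),
                "p0": prediction.probabilities[0],
                "p1": prediction.probabilities[1],
                "p2": prediction.probabilities[2],
            }
        )
    return manifest, rows


def run_pipeline(
    slide_paths: Sequence[str | Path],
    patient_map: Mapping[str, str] | None = None,
    config: PipelineConfig | None = None,
    truth: Mapping[str, pd.DataFrame] | None = None,
) -> PipelineResult:
    """Run the full scoring pipeline over a batch of slide rasters.

    Writes, under ``config.out_dir``: per-slide manifest TSVs, a pooled
    predictions TSV, the slide/patient scores TSV, per-slide TIL-map PNG
    + grid TSV, a ``run.log`` echoing the config, and — when ground-truth
    label tables are supplied via ``truth`` — a metrics JSON.

    Slides that fail to read or process are recorded in
    ``result.failures`` and the run continues.
    """
    config = config or PipelineConfig()
    slide_paths = [Path(p) for p in slide_paths]
    if not slide_paths:
        raise ValueError("no slides given: aborting before any processing")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    if config.backend == "rule":
        backend = RuleBasedBackend(
            stain_profile=config.target_profile(), params=config.detector
        )

    manifests: dict[str, TileManifest] = {}
    failures: dict[str, str] = {}
    all_rows: list[dict] = []
    for path in sorted(slide_paths):
        try:
            manifest, rows = _process_slide(path, config, backend)
        except Exception as exc:  # noqa: BLE001 — per-slide isolation is the contract
            logger.warning("slide %s failed: %s", path, exc)
            failures[path.stem] = str(exc)
            continue
        manifests[manifest.slide_id] = manifest
        all_rows.extend(rows)
        manifest.to_tsv(out_dir / f"{manifest.slide_id}.manifest.tsv")

    columns = ["slide_id", "grid_row", "grid_col", "label", "p0", "p1", "p2"]
    predictions = pd.DataFrame(all_rows, columns=columns)
    predictions.to_csv(
        out_dir / "predictions.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # undefined scores become NaN rows
        scores = score_cohort(predictions, patient_map)
    scores.to_csv(out_dir / "scores.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)

    for slide_id, manifest in manifests.items():
        slide_preds = predictions[predictions["slide_id"] == slide_id]
        til_map = build_til_map(manifest, slide_preds)
        til_map.scale_px_per_patch = config.map_scale
        til_map.save_png(out_dir / f"{slide_id}.map.png")
        til_map.to_tsv(out_dir / f"{slide_id}.map.tsv")

    if truth:
        merged_true: list[int] = []
        merged_pred: list[Prediction] = []
        for slide_id, truth_table in truth.items():
            slide_preds = predictions[predictions["slide_id"] == slide_id]
            lookup = {
                (int(r), int(c)): Prediction.from_probabilities([p0, p1, p2])
                for r, c, p0, p1, p2 in zip(
                    slide_preds["grid_row"],
                    slide_preds["grid_col"],
                    slide_preds["p0"],
                    slide_preds["p1"],
                    slide_preds["p2"],
                )
            }
            for _, row in truth_table.iterrows():
                pos = (int(row["grid_row"]), int(row["grid_col"]))
                if pos in lookup:
                    merged_true.append(int(row["label"]))
                    merged_pred.append(lookup[pos])
        if merged_true:
            report = evaluate(merged_true, merged_pred)
            report.to_json(out_dir / "metrics.json")

    log_lines = [
        "tilscore run",
        f"seed: {config.seed}",
        f"config: {_to_plain(dataclasses.asdict(config))}",
        f"slides processed: {len(manifests)}",
        f"slides failed: {len(failures)} {sorted(failures)}",
        f"patches predicted: {len(predictions)}",
    ]
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")

    return PipelineResult(
        predictions=predictions,
        scores=scores,
        manifests=manifests,
        failures=failures,
        out_dir=out_dir,
    )
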