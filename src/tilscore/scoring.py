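"""TIL scores, cohort density summaries, and patch-level TIL maps.

The TIL score of a slide is the fraction of predicted TIL-positive
patches among tumor-containing patches:

    TIL score = sum_i N_pos^i / sum_i (N_pos^i + N_neg^i)

where the sum runs over a patient's slides (m = 1 for a single slide).
Pooling is by summed counts, *not* by averaging per-slide scores — a
patient with slides (2 pos, 2 neg) and (0 pos, 6 neg) scores 2/10 = 0.2,
not 0.25.  Other/necrotic and blank patches enter neither numerator nor
denominator.  A zero denominator leaves the score undefined: it is an
explicit error (or missing value at cohort level), never silently 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .classify import PatchLabel
from .slideio import TileManifest

__all__ = [
    "TILScoreRecord",
    "TILMap",
    "UndefinedScoreError",
    "til_score",
    "score_cohort",
    "score_density",
    "build_til_map",
    "DEFAULT_PALETTE",
]


class UndefinedScoreError(ValueError):
    """No tumor-containing patches: the TIL score has a zero denominator."""


@dataclass(frozen=True)
class TILScoreRecord:
    """Pooled patch counts and the resulting TIL score for one unit
    (a slide, or a patient pooling m slides)."""

    unit_id: str
    m: int  # number of WSIs pooled
    n_positive: int
    n_negative: int
    n_other: int
    score: float

    def __post_init__(self) -> None:
        if min(self.n_positive, self.n_negative, self.n_other) < 0 or self.m < 1:
            raise ValueError("counts must be non-negative and m >= 1")
        denom = self.n_positive + self.n_negative
        if denom > 0 and abs(self.score - self.n_positive / denom) > 1e-9:
            raise ValueError("score inconsistent with counts")


def til_score(
    per_slide_counts: Sequence[tuple[int, int]],
    unit_id: str = "unit",
    n_other: int = 0,
) -> TILScoreRecord:
    """Pooled TIL score over one or more slides' (n_pos, n_neg) counts."""
    if len(per_slide_counts) == 0:
        raise UndefinedScoreError(f"{unit_id}: no slides to score")
    n_pos = sum(int(c[0]) for c in per_slide_counts)
    n_neg = sum(int(c[1]) for c in per_slide_counts)
    if n_pos < 0 or n_neg < 0:
        raise ValueError("patch counts must be non-negative")
    if n_pos + n_neg == 0:
        raise UndefinedScoreError(
            f"{unit_id}: no TIL-positive or TIL-negative patches; score undefined"
        )
    return TILScoreRecord(
        unit_id=unit_id,
        m=len(per_slide_counts),
        n_positive=n_pos,
        n_negative=n_neg,
        n_other=n_other,
        score=n_pos / (n_pos + n_neg),
    )


def _label_counts(labels: Sequence[int]) -> tuple[int, int, int]:
    labels = np.asarray(labels, dtype=int)
    return (
        int((labels == PatchLabel.TIL_POSITIVE).sum()),
        int((labels == PatchLabel.TIL_NEGATIVE).sum()),
        int((labels == PatchLabel.OTHER_NECROTIC).sum()),
    )


def score_cohort(
    predictions: pd.DataFrame,
    patient_map: Mapping[str, str] | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-slide and per-patient TIL scores from a prediction table.

    ``predictions`` needs columns ``slide_id`` and ``label`` (one row per
    non-blank patch).  ``patient_map`` maps slide_id -> patient_id (dict,
    or a DataFrame with those two columns); slides without a mapping are
    scored at slide level only, with a warning.  Units whose score is
    undefined (no tumor-containing patches) get score = NaN, with a
    warning — the run completes.

    Returns a table with columns
    ``unit_id, level, m, n_positive, n_negative, n_other, score``.
    """
    if isinstance(patient_map, pd.DataFrame):
        patient_map = dict(zip(patient_map["slide_id"], patient_map["patient_id"]))
    patient_map = patient_map or {}

    records = []
    slide_counts: dict[str, tuple[int, int, int]] = {}
    for slide_id, group in predictions.groupby("slide_id", sort=True):
        counts = _label_counts(group["label"])
        slide_counts[str(slide_id)] = counts
        records.append(_record_row(str(slide_id), "slide", 1, counts))

    by_patient: dict[str, list[str]] = {}
    for slide_id in slide_counts:
        if slide_id in patient_map:
            by_patient.setdefault(str(patient_map[slide_id]), []).append(slide_id)
        elif patient_map:
            warnings.warn(
                f"slide {slide_id} missing from patient map; scored at slide level only"
            )
    for patient_id in sorted(by_patient):
        slides = by_patient[patient_id]
        pooled = tuple(
            sum(slide_counts[s][k] for s in slides) for k in range(3)
        )
        records.append(_record_row(patient_id, "patient", len(slides), pooled))
    return pd.DataFrame.from_records(records)


def _record_row(unit_id: str, level: str, m: int, counts: tuple[int, int, int]) -> dict:
    n_pos, n_neg, n_other = counts
    if n_pos + n_neg == 0:
        warnings.warn(f"{level} {unit_id}: TIL score undefined (no tumor patches)")
        score = float("nan")
    else:
        score = n_pos / (n_pos + n_neg)
    return {
        "unit_id": unit_id,
        "level": level,
        "m": m,
        "n_positive": n_pos,
        "n_negative": n_neg,
        "n_other": n_other,
        "score": score,
    }


def score_density(
    scores: Sequence[float], grid_points: int = 512, bandwidth: str | float = "scott"
) -> tuple[np.ndarray, np.ndarray, float]:
    """Gaussian KDE of a cohort's TIL scores on a fixed [0, 1] grid.

    Returns ``(grid, density, mode)`` where mode is the grid point of
    highest density.  Uses Scott's-rule bandwidth by default; no boundary
    correction is applied at 0/1.
    """
    scores = np.asarray(scores, dtype=float)
    scores = scores[np.isfinite(scores)]
    if scores.size < 2:
        raise ValueError("need at least 2 finite scores for a density estimate")
    kde = gaussian_kde(scores, bw_method=bandwidth)
    grid = np.linspace(0.0, 1.0, grid_points)
    density = kde(grid)
    return grid, density, float(grid[int(np.argmax(density))])


# ---------------------------------------------------------------------------
# TIL maps

#: state codes used in the map grid
STATE_POSITIVE, STATE_NEGATIVE, STATE_OTHER, STATE_BLANK = 0, 1, 2, 3

DEFAULT_PALETTE: dict[int, tuple[int, int, int]] = {
    STATE_POSITIVE: (200, 30, 30),  # red
    STATE_NEGATIVE: (40, 60, 200),  # blue
    STATE_OTHER: (40, 160, 60),  # green
    STATE_BLANK: (255, 255, 255),  # white
}


@dataclass
class TILMap:
    """Patch-level class map of one slide.

    ``grid`` holds one state code per patch position (positive /
    negative / other / blank); rendering scales each cell to
    ``scale_px_per_patch`` pixels of its palette color.
    """

    slide_id: str
    grid: np.ndarray  # (rows, cols) int state codes
    palette: dict[int, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_PALETTE)
    )
    scale_px_per_patch: int = 8

    def render(self) -> np.ndarray:
        image = np.zeros((*self.grid.shape, 3), dtype=np.uint8)
        for state, color in self.palette.items():
            image[self.grid == state] = color
        return np.kron(image, np.ones((self.scale_px_per_patch, self.scale_px_per_patch, 1))).astype(
            np.uint8
        )

    def save_png(self, path: str | Path) -> None:
        iio.imwrite(Path(path), self.render())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# slide_id={self.slide_id} scale={self.scale_px_per_patch}\n")
            np.savetxt(fh, self.grid, fmt="%d", delimiter="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TILMap":
        with open(path) as fh:
            meta_line = fh.readline().strip().lstrip("# ")
            meta = dict(item.split("=", 1) for item in meta_line.split())
            grid = np.loadtxt(fh, dtype=int, delimiter="\t", ndmin=2)
        return cls(slide_id=meta["slide_id"], grid=grid, scale_px_per_patch=int(meta["scale"]))


def build_til_map(manifest: TileManifest, predictions: pd.DataFrame) -> TILMap:
    """Place per-patch predictions onto the slide grid.

    ``predictions`` needs columns ``grid_row, grid_col, label``; lookup
    is position-keyed, so row order is irrelevant.  Every non-blank
    manifest patch must have a prediction — missing ones raise an error
    listing their coordinates.
    """
    n_rows, n_cols = manifest.grid_shape
    grid = np.full((n_rows, n_cols), STATE_BLANK, dtype=int)
    pred_at = {
        (int(r), int(c)): int(l)
        for r, c, l in zip(
            predictions["grid_row"], predictions["grid_col"], predictions["label"]
        )
    }
    missing = []
    for _, row in manifest.rows.iterrows():
        pos = (int(row["grid_row"]), int(row["grid_col"]))
        if bool(row["is_blank"]):
            continue
        if pos not in pred_at:
            missing.append(pos)
            continue
        grid[pos] = pred_at[pos]
    if missing:
        raise ValueError(f"missing predictions for non-blank patches at {sorted(missing)}")
    return TILMap(slide_id=manifest.slide_id, grid=grid)
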