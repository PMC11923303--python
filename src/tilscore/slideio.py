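"""Slide reading, non-overlapping tiling and the blank-patch filter.

A slide raster is cut into non-overlapping ``patch_size`` x ``patch_size``
tiles (default 150 px, assumed x20 magnification); partial tiles at the
right/bottom edges are dropped.  A tile is *blank* — and excluded from all
downstream classification and scoring — when its per-pixel gray values
``(R+G+B)/3`` have mean > 230 and standard deviation < 15.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "Patch",
    "BlankFilterParams",
    "TileManifest",
    "read_slide",
    "write_slide",
    "tile_slide",
    "is_blank",
    "filter_patches",
]

PATCH_SIZE = 150

MANIFEST_COLUMNS = ["grid_row", "grid_col", "is_blank", "label"]


@dataclass(frozen=True)
class Patch:
    """One RGB tile with its grid coordinates and slide identity."""

    pixels: np.ndarray  # (patch_size, patch_size, 3) uint8
    slide_id: str = "patch"
    grid_row: int = 0
    grid_col: int = 0

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels)
        if pixels.ndim != 3 or pixels.shape[2] != 3 or pixels.shape[0] != pixels.shape[1]:
            raise ValueError(f"patch must be square HxWx3, got shape {pixels.shape}")
        if pixels.dtype != np.uint8:
            if pixels.min() < 0 or pixels.max() > 255:
                raise ValueError("patch values must lie in [0, 255]")
            object.__setattr__(self, "pixels", pixels.astype(np.uint8))

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass
class BlankFilterParams:
    """Thresholds of the blank filter.

    With ``per_channel=False`` (default) the statistics are computed on
    the per-pixel gray ``(R+G+B)/3``; with ``True`` on the pooled raw
    channel values.  Both inequalities are strict.
    """

    mean_threshold: float = 230.0
    sd_threshold: float = 15.0
    per_channel: bool = False

    def __post_init__(self) -> None:
        for name in ("mean_threshold", "sd_threshold"):
            value = getattr(self, name)
            if not 0 < value < 255:
                raise ValueError(f"{name} must be in (0, 255), got {value}")


@dataclass
class TileManifest:
    """The tiling grid of one slide: per-patch blank flags and labels.

    ``rows`` is a DataFrame with one row per grid cell, columns
    ``grid_row, grid_col, is_blank, label`` plus any ground-truth columns
    a synthetic generator attaches (``n_lymph``, ``n_tumor``, ...).
    """

    slide_id: str
    slide_height_px: int
    slide_width_px: int
    patch_size: int = PATCH_SIZE
    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.rows is None or len(self.rows) == 0:
            self.rows = pd.DataFrame(columns=MANIFEST_COLUMNS)
        n_rows = self.slide_height_px // self.patch_size
        n_cols = self.slide_width_px // self.patch_size
        if len(self.rows):
            if self.rows["grid_row"].max() >= n_rows or self.rows["grid_col"].max() >= n_cols:
                raise ValueError("manifest grid coordinates exceed the slide grid")
            if self.rows.duplicated(subset=["grid_row", "grid_col"]).any():
                raise ValueError("duplicate (grid_row, grid_col) in manifest")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (self.slide_height_px // self.patch_size, self.slide_width_px // self.patch_size)

    def set_blank(self, grid_row: int, grid_col: int, blank: bool) -> None:
        mask = (self.rows["grid_row"] == grid_row) & (self.rows["grid_col"] == grid_col)
        self.rows.loc[mask, "is_blank"] = bool(blank)

    def to_tsv(self, path: str | Path) -> None:
        out = self.rows.copy()
        out.insert(0, "slide_id", self.slide_id)
        out.attrs = {}
        header = (
            f"# slide_id={self.slide_id} height={self.slide_height_px} "
            f"width={self.slide_width_px} patch_size={self.patch_size}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            out.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TileManifest":
        with open(path) as fh:
            meta_line = fh.readline().strip().lstrip("# ")
            meta = dict(item.split("=", 1) for item in meta_line.split())
            rows = pd.read_csv(fh, sep="\t")
        rows = rows.drop(columns=["slide_id"])
        return cls(
            slide_id=meta["slide_id"],
            slide_height_px=int(meta["height"]),
            slide_width_px=int(meta["width"]),
            patch_size=int(meta["patch_size"]),
            rows=rows,
        )


def read_slide(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF slide raster as an HxWx3 uint8 array.

    Grayscale inputs are broadcast to 3 channels; an alpha channel is
    dropped.  Pyramidal WSI formats are out of scope for this reader —
    export level 0 to TIFF first.
    """
    raster = np.asarray(iio.imread(Path(path)))
    if raster.ndim == 2:
        raster = np.stack([raster] * 3, axis=-1)
    if raster.shape[2] == 4:
        raster = raster[:, :, :3]
    return raster.astype(np.uint8)


def write_slide(path: str | Path, raster: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(raster, dtype=np.uint8))


def tile_slide(
    raster: np.ndarray, slide_id: str = "slide", patch_size: int = PATCH_SIZE
) -> tuple[TileManifest, list[Patch]]:
    """Cut a slide raster into non-overlapping patches.

    Patch (i, j) covers pixel rows ``[i*p, (i+1)*p)`` and columns
    ``[j*p, (j+1)*p)``; partial tiles at the right/bottom edges are
    dropped, so the count is ``floor(H/p) * floor(W/p)``.
    """
    raster = np.asarray(raster)
    if raster.ndim != 3 or raster.shape[2] != 3:
        raise ValueError(f"slide raster must be HxWx3, got shape {raster.shape}")
    height, width = raster.shape[:2]
    if height < patch_size or width < patch_size:
        raise ValueError(
            f"slide {slide_id} is {height}x{width} px, smaller than one "
            f"{patch_size}x{patch_size} patch"
        )
    n_rows, n_cols = height // patch_size, width // patch_size
    patches: list[Patch] = []
    records = []
    for i in range(n_rows):
        for j in range(n_cols):
            block = raster[
                i * patch_size : (i + 1) * patch_size,
                j * patch_size : (j + 1) * patch_size,
            ]
            patches.append(Patch(pixels=block, slide_id=slide_id, grid_row=i, grid_col=j))
            records.append({"grid_row": i, "grid_col": j, "is_blank": False, "label": pd.NA})
    manifest = TileManifest(
        slide_id=slide_id,
        slide_height_px=height,
        slide_width_px=width,
        patch_size=patch_size,
        rows=pd.DataFrame.from_records(records),
    )
    return manifest, patches


def is_blank(patch: Patch | np.ndarray, params: BlankFilterParams | None = None) -> bool:
    """True iff the patch fails the tissue-content check.

    Per-pixel gray g = (R+G+B)/3; blank iff mean(g) > mean_threshold and
    population sd(g) < sd_threshold (both strict).
    """
    params = params or BlankFilterParams()
    pixels = np.asarray(getattr(patch, "pixels", patch), dtype=float)
    values = pixels.ravel() if params.per_channel else pixels.mean(axis=2)
    return bool(values.mean() > params.mean_threshold and values.std() < params.sd_threshold)


def filter_patches(
    manifest: TileManifest,
    patches: Iterable[Patch],
    params: BlankFilterParams | None = None,
) -> list[Patch]:
    """Flag blank patches in the manifest and return the retained ones."""
    params = params or BlankFilterParams()
    retained: list[Patch] = []
    flags = []
    for patch in patches:
        blank = is_blank(patch, params)
        flags.append({"grid_row": patch.grid_row, "grid_col": patch.grid_col, "is_blank": blank})
        if not blank:
            retained.append(patch)
    flag_df = pd.DataFrame.from_records(flags)
    merged = manifest.rows.drop(columns=["is_blank"]).merge(
        flag_df, on=["grid_row", "grid_col"], how="left"
    )
    merged["is_blank"] = merged["is_blank"].astype("boolean").fillna(False).astype(bool)
    manifest.rows = merged[
        ["grid_row", "grid_col", "is_blank"]
        + [c for c in merged.columns if c not in ("grid_row", "grid_col", "is_blank")]
    ]
    return retained
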