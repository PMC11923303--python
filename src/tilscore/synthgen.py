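"""Seeded synthetic H&E patch, slide and dataset generator.

Patches are rendered through a Beer–Lambert stain model: per-pixel
hematoxylin/eosin concentration fields are built from simple nucleus
geometry, converted to optical density with a configurable 3x2 stain
matrix, and exponentiated to RGB intensities (``I = Io * exp(-S @ c)``),
optionally with additive Gaussian intensity noise.

Cell morphology follows the standard H&E reading: lymphocytes are small
round disks with strong hematoxylin uptake; tumor nuclei are larger,
radially perturbed ellipses with weaker hematoxylin and an eosin
cytoplasm halo.  Tissue background is an eosin-stained stroma field;
non-tissue background is near-white.  Every generated patch carries its
exact cell list and the ground-truth label obtained by applying the
counting rule to the true counts, so the whole downstream pipeline can
be verified against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .classify import CellInstance, PatchLabel, rule_label
from .slideio import PATCH_SIZE, Patch, TileManifest, write_slide
from .stainnorm import StainProfile, default_target_profile

__all__ = [
    "PatchSpec",
    "PatchSampler",
    "SlideSpec",
    "CapacityError",
    "generate_patch",
    "generate_slide",
    "generate_labeled_dataset",
    "apportion_counts",
]


class CapacityError(RuntimeError):
    """Raised when the requested cells cannot be placed without overlap."""


@dataclass
class PatchSpec:
    """Everything needed to render one synthetic patch deterministically.

    Radii are in pixels at the assumed ~0.5 um/px (x20) scale: lymphocyte
    nuclei 5–7 px (~5–7 um), tumor nuclei 12–20 px.  Hematoxylin
    concentrations put lymphocytes (0.8–1.2) well above tumor nuclei
    (0.4–0.8); stroma is a strongly eosin-stained field, which keeps its
    pixels above the Macenko OD floor so the stain geometry of a patch is
    recoverable.  ``noise_sd`` is the sd of additive Gaussian noise on
    the 0–255 intensity scale.
    """

    n_lymphocytes: int = 0
    n_tumor_cells: int = 0
    lymph_radius_px: tuple[float, float] = (5.0, 7.0)
    tumor_radius_px: tuple[float, float] = (12.0, 20.0)
    stain_profile: StainProfile = field(default_factory=default_target_profile)
    noise_sd: float = 0.0
    background: str = "stroma"  # "white" | "stroma"
    seed: int = 0
    patch_size: int = PATCH_SIZE
    lymph_h_range: tuple[float, float] = (0.8, 1.2)
    tumor_h_range: tuple[float, float] = (0.4, 0.8)
    halo_e_range: tuple[float, float] = (0.1, 0.3)
    halo_width_px: float = 4.0
    stroma_e_range: tuple[float, float] = (1.2, 2.2)
    tumor_perturbation: float = 0.25  # radial jitter amplitude of tumor nuclei
    min_gap_px: float = 5.0
    max_attempts_per_cell: int = 1000

    def __post_init__(self) -> None:
        if self.n_lymphocytes < 0 or self.n_tumor_cells < 0:
            raise ValueError("cell counts must be non-negative")
        for name in ("lymph_radius_px", "tumor_radius_px"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be a positive increasing range")
        if self.lymph_radius_px[1] >= self.tumor_radius_px[0]:
            raise ValueError("lymphocyte radii must stay below tumor radii (area separability)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.background not in ("white", "stroma"):
            raise ValueError("background must be 'white' or 'stroma'")


@dataclass(frozen=True)
class _PlacedCell:
    center: tuple[float, float]  # (row, col)
    effective_radius: float
    cell_class: str
    # geometry payload
    rx: float = 0.0
    ry: float = 0.0
    angle: float = 0.0
    perturb_amp: float = 0.0
    perturb_freq: int = 0
    perturb_phase: float = 0.0
    h_conc: float = 0.0
    halo_e: float = 0.0


def _place_cells(spec: PatchSpec, rng: np.random.Generator) -> list[_PlacedCell]:
    """Rejection-sample non-overlapping nucleus positions (tumors first).

    Spacing uses the nucleus envelope only — eosin halos may overlap and
    are overwritten wherever a nucleus is painted.  A handful of full
    layout restarts precede the capacity error.
    """
    size = spec.patch_size
    last_error = "no cells requested"
    for _ in range(5):  # full-layout restarts
        placed: list[_PlacedCell] = []
        try:
            _fill_layout(spec, rng, placed, size)
            return placed
        except CapacityError as exc:
            last_error = str(exc)
    raise CapacityError(last_error)


def _fill_layout(
    spec: PatchSpec, rng: np.random.Generator, placed: list[_PlacedCell], size: int
) -> None:
    def try_place(effective_radius: float, **payload) -> None:
        margin = effective_radius + 2.0
        if 2 * margin >= size:
            raise CapacityError(
                f"cell of effective radius {effective_radius:.1f} px cannot fit a "
                f"{size}x{size} patch"
            )
        for _ in range(spec.max_attempts_per_cell):
            center = (rng.uniform(margin, size - margin), rng.uniform(margin, size - margin))
            ok = all(
                math.hypot(center[0] - other.center[0], center[1] - other.center[1])
                > effective_radius + other.effective_radius + spec.min_gap_px
                for other in placed
            )
            if ok:
                placed.append(
                    _PlacedCell(center=center, effective_radius=effective_radius, **payload)
                )
                return
        raise CapacityError(
            f"could not place cell {len(placed) + 1} after "
            f"{spec.max_attempts_per_cell} attempts (too many / too large cells)"
        )

    for _ in range(spec.n_tumor_cells):
        rx = rng.uniform(*spec.tumor_radius_px)
        ry = rng.uniform(*spec.tumor_radius_px)
        amp = spec.tumor_perturbation * rng.uniform(0.5, 1.0)
        try_place(
            max(rx, ry) * (1.0 + amp),
            cell_class="tumor",
            rx=rx,
            ry=ry,
            angle=rng.uniform(0, np.pi),
            perturb_amp=amp,
            perturb_freq=int(rng.integers(3, 6)),
            perturb_phase=rng.uniform(0, 2 * np.pi),
            h_conc=rng.uniform(*spec.tumor_h_range),
            halo_e=rng.uniform(*spec.halo_e_range),
        )
    for _ in range(spec.n_lymphocytes):
        radius = rng.uniform(*spec.lymph_radius_px)
        try_place(
            radius,
            cell_class="lymphocyte",
            rx=radius,
            ry=radius,
            h_conc=rng.uniform(*spec.lymph_h_range),
        )


def _stroma_field(
    size: int, conc_range: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Eosin stroma background: a smooth concentration gradient spanning
    ``conc_range`` along a random direction, with a gentle sinusoidal
    fiber texture.  The spatial spread matters: it is what anchors the
    eosin axis of the OD covariance eigenplane under pixel noise."""
    lo, hi = conc_range
    rows, cols = np.mgrid[0:size, 0:size].astype(float) / max(size - 1, 1)
    theta = rng.uniform(0, 2 * np.pi)
    t = rows * np.cos(theta) + cols * np.sin(theta)
    t = (t - t.min()) / max(t.max() - t.min(), 1e-9)
    texture = 0.5 + 0.5 * np.sin(2 * np.pi * (rng.uniform(2, 4) * t + rng.uniform()))
    ramp = np.clip(0.85 * t + 0.15 * texture, 0.0, 1.0)
    return lo + (hi - lo) * ramp


def _cell_masks(cell: _PlacedCell, size: int, halo_width: float):
    """Boolean nucleus mask (and halo ring mask for tumor cells)."""
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    dr, dc = rows - cell.center[0], cols - cell.center[1]
    if cell.cell_class == "lymphocyte":
        nucleus = dr**2 + dc**2 <= cell.rx**2
        return nucleus, None
    # tumor: radially perturbed rotated ellipse
    cos_a, sin_a = math.cos(cell.angle), math.sin(cell.angle)
    u = (dr * cos_a + dc * sin_a) / cell.rx
    v = (-dr * sin_a + dc * cos_a) / cell.ry
    rho = np.hypot(u, v)
    phi = np.arctan2(v, u)
    boundary = 1.0 + cell.perturb_amp * np.sin(cell.perturb_freq * phi + cell.perturb_phase)
    nucleus = rho <= boundary
    halo_scale = 1.0 + halo_width / min(cell.rx, cell.ry)
    halo = (rho <= boundary * halo_scale) & ~nucleus
    return nucleus, halo


def _mask_shape_stats(mask: np.ndarray) -> tuple[tuple[float, float], float, float]:
    """Centroid, area and circularity of a single-blob boolean mask."""
    region = regionprops(cc_label(mask))[0]
    perimeter = max(region.perimeter, 1.0)
    circularity = min(4.0 * np.pi * region.area / perimeter**2, 1.3)
    return tuple(region.centroid), float(region.area), float(circularity)


def generate_patch(
    spec: PatchSpec, slide_id: str = "synthetic", grid_row: int = 0, grid_col: int = 0
) -> tuple[Patch, list[CellInstance], PatchLabel]:
    """Render one synthetic patch with its exact cell list and true label.

    Deterministic for a fixed spec (including seed).  Raises
    :class:`CapacityError` when the requested cells cannot be placed
    without overlap inside the patch.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    size = spec.patch_size
    placed = _place_cells(spec, rng)

    h_field = np.zeros((size, size))
    if spec.background == "stroma":
        e_field = _stroma_field(size, spec.stroma_e_range, rng)
    else:
        e_field = np.zeros((size, size))

    cells: list[CellInstance] = []
    nucleus_masks = []
    for cell in placed:
        nucleus, halo = _cell_masks(cell, size, spec.halo_width_px)
        if halo is not None:
            e_field[halo] = cell.halo_e
        nucleus_masks.append((cell, nucleus))
    # nuclei painted last: pure hematoxylin, eosin excluded
    for cell, nucleus in nucleus_masks:
        h_field[nucleus] = cell.h_conc
        e_field[nucleus] = 0.0
        centroid, area, circularity = _mask_shape_stats(nucleus)
        cells.append(
            CellInstance(
                centroid=centroid,
                area=area,
                circularity=circularity,
                mean_h_od=cell.h_conc,
                cell_class=cell.cell_class,
            )
        )

    stain = spec.stain_profile
    od = h_field[..., None] * stain.hematoxylin + e_field[..., None] * stain.eosin
    intensity = stain.io * np.exp(-od)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, intensity.shape)
    pixels = np.clip(np.round(intensity), 0, 255).astype(np.uint8)

    label = rule_label(spec.n_lymphocytes, spec.n_tumor_cells)
    patch = Patch(pixels=pixels, slide_id=slide_id, grid_row=grid_row, grid_col=grid_col)
    return patch, cells, label


def generate_stain_phantom(
    seed: int = 0,
    noise_sd: float = 0.0,
    stain_profile: StainProfile | None = None,
    h_max: float = 1.3,
    e_max: float = 1.8,
    size: int = PATCH_SIZE,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthetic stain-calibration target with known per-pixel concentrations.

    Unlike a tissue patch — whose optical densities cluster around pure
    hematoxylin (nuclei) and pure eosin (stroma) — the phantom samples
    both concentrations independently and uniformly per pixel, so the OD
    cloud fills the whole cone between the stain vectors.  That dense
    interior is what makes stain-vector estimation well-conditioned, and
    the known concentration fields make Beer–Lambert round trips exactly
    checkable.

    Returns ``(pixels, h_concentration, e_concentration)``.
    """
    profile = stain_profile or default_target_profile()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    c_h = rng.uniform(0.0, h_max, (size, size))
    c_e = rng.uniform(0.0, e_max, (size, size))
    od = c_h[..., None] * profile.hematoxylin + c_e[..., None] * profile.eosin
    intensity = profile.io * np.exp(-od)
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, intensity.shape)
    return np.clip(np.round(intensity), 0, 255).astype(np.uint8), c_h, c_e


# ---------------------------------------------------------------------------
# Slides


@dataclass
class PatchSampler:
    """Samples per-patch cell counts given a target class mix.

    ``class_probs`` defaults to the 1 : 1.5 : 1.5 mix of
    TIL-positive : TIL-negative : other patches.  Count ranges are
    inclusive and respect the counting rule by construction.
    """

    class_probs: tuple[float, float, float] = (0.25, 0.375, 0.375)
    pos_lymph: tuple[int, int] = (3, 8)
    pos_tumor: tuple[int, int] = (1, 3)
    neg_lymph: tuple[int, int] = (0, 2)
    neg_tumor: tuple[int, int] = (1, 3)
    other_lymph: tuple[int, int] = (0, 5)

    def __post_init__(self) -> None:
        probs = np.asarray(self.class_probs, dtype=float)
        if probs.shape != (3,) or np.any(probs < 0) or probs.sum() <= 0:
            raise ValueError("class_probs must be 3 non-negative weights")
        self.class_probs = tuple(probs / probs.sum())

    def sample_label(self, rng: np.random.Generator) -> PatchLabel:
        return PatchLabel(int(rng.choice(3, p=self.class_probs)))

    def sample_counts(self, label: PatchLabel, rng: np.random.Generator) -> tuple[int, int]:
        if label == PatchLabel.TIL_POSITIVE:
            ranges = (self.pos_lymph, self.pos_tumor)
        elif label == PatchLabel.TIL_NEGATIVE:
            ranges = (self.neg_lymph, self.neg_tumor)
        else:
            ranges = (self.other_lymph, (0, 0))
        (l_lo, l_hi), (t_lo, t_hi) = ranges
        return int(rng.integers(l_lo, l_hi + 1)), int(rng.integers(t_lo, t_hi + 1))


@dataclass
class SlideSpec:
    """A synthetic slide: a grid of patches, a fraction of which is tissue.

    ``label_schedule`` optionally fixes the label of each tissue patch
    (row-major over tissue cells, cycled if shorter), e.g. to program an
    exact TIL-positive fraction; otherwise labels are drawn from the
    sampler's class mix.
    """

    grid_rows: int = 10
    grid_cols: int = 10
    tissue_fraction: float = 0.7
    sampler: PatchSampler = field(default_factory=PatchSampler)
    patch_template: PatchSpec = field(default_factory=PatchSpec)
    label_schedule: Sequence[int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if not 0.0 <= self.tissue_fraction <= 1.0:
            raise ValueError("tissue_fraction must be in [0, 1]")


def patch_seed_for(slide_seed: int, grid_row: int, grid_col: int) -> int:
    """Counter-based per-patch seed: SeedSequence((slide_seed, row, col)).

    Stable across runs and independent of generation order, so any patch
    of a slide can be re-rendered in isolation.
    """
    return int(np.random.SeedSequence((slide_seed, grid_row, grid_col)).generate_state(1)[0])


def generate_slide(
    spec: SlideSpec, slide_id: str = "synthetic_slide"
) -> tuple[np.ndarray, TileManifest]:
    """Assemble a slide raster and its ground-truth manifest.

    Non-tissue grid cells are rendered near-white (they pass the blank
    filter); tissue cells are stroma-backed patches whose label, blank
    flag and true cell counts are recorded in the manifest.
    """
    size = spec.patch_template.patch_size
    n_cells = spec.grid_rows * spec.grid_cols
    layout_rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0)))
    n_tissue = int(round(spec.tissue_fraction * n_cells))
    tissue_cells = set(
        map(int, layout_rng.choice(n_cells, size=n_tissue, replace=False))
    )

    raster = np.zeros((spec.grid_rows * size, spec.grid_cols * size, 3), dtype=np.uint8)
    records = []
    tissue_counter = 0
    for i in range(spec.grid_rows):
        for j in range(spec.grid_cols):
            seed = patch_seed_for(spec.seed, i, j)
            rng = np.random.default_rng(np.random.SeedSequence(seed))
            if (i * spec.grid_cols + j) in tissue_cells:
                if spec.label_schedule is not None:
                    label = PatchLabel(
                        int(spec.label_schedule[tissue_counter % len(spec.label_schedule)])
                    )
                else:
                    label = spec.sampler.sample_label(rng)
                tissue_counter += 1
                n_lymph, n_tumor = spec.sampler.sample_counts(label, rng)
                patch_spec = replace(
                    spec.patch_template,
                    n_lymphocytes=n_lymph,
                    n_tumor_cells=n_tumor,
                    background="stroma",
                    seed=seed,
                )
                blank = False
            else:
                n_lymph = n_tumor = 0
                patch_spec = replace(
                    spec.patch_template,
                    n_lymphocytes=0,
                    n_tumor_cells=0,
                    background="white",
                    seed=seed,
                )
                blank = True
            patch, _, true_label = generate_patch(patch_spec, slide_id, i, j)
            raster[i * size : (i + 1) * size, j * size : (j + 1) * size] = patch.pixels
            records.append(
                {
                    "grid_row": i,
                    "grid_col": j,
                    "is_blank": blank,
                    "label": int(true_label),
                    "n_lymph": n_lymph,
                    "n_tumor": n_tumor,
                    "seed": seed,
                }
            )
    manifest = TileManifest(
        slide_id=slide_id,
        slide_height_px=spec.grid_rows * size,
        slide_width_px=spec.grid_cols * size,
        patch_size=size,
        rows=pd.DataFrame.from_records(records),
    )
    return raster, manifest


# ---------------------------------------------------------------------------
# Labeled datasets


def apportion_counts(n_total: int, ratio: Sequence[float]) -> list[int]:
    """Integer class counts matching a ratio (largest-remainder rounding;
    ties break toward the lowest class code)."""
    weights = np.asarray(ratio, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("ratio components must be positive")
    shares = n_total * weights / weights.sum()
    counts = np.floor(shares).astype(int)
    remainders = shares - counts
    for idx in sorted(range(len(counts)), key=lambda k: (-remainders[k], k))[
        : n_total - counts.sum()
    ]:
        counts[idx] += 1
    return counts.tolist()


def generate_labeled_dataset(
    n_total: int,
    label_ratio: Sequence[float] = (1.0, 1.5, 1.5),
    seed: int = 0,
    sampler: PatchSampler | None = None,
    patch_template: PatchSpec | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[Patch], list[PatchLabel], pd.DataFrame]:
    """Generate a labeled patch dataset at the requested class mix.

    The default 1 : 1.5 : 1.5 positive : negative : other mix mirrors the
    labeling-set composition used for classifier training.  Label counts
    match the ratio within rounding; patches are generated independently
    with counter-based per-item seeds.  Optionally writes patches as PNG
    plus a ``labels.tsv`` manifest.
    """
    if n_total < 3:
        raise ValueError("n_total must be >= 3 (one patch per class)")
    sampler = sampler or PatchSampler()
    template = patch_template or PatchSpec()
    counts = apportion_counts(n_total, label_ratio)
    schedule = [PatchLabel(code) for code, n in enumerate(counts) for _ in range(n)]
    order_rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    order_rng.shuffle(schedule)

    patches: list[Patch] = []
    labels: list[PatchLabel] = []
    records = []
    for idx, label in enumerate(schedule):
        item_seed = int(np.random.SeedSequence((seed, 2, idx)).generate_state(1)[0])
        count_rng = np.random.default_rng(np.random.SeedSequence(item_seed))
        n_lymph, n_tumor = sampler.sample_counts(label, count_rng)
        spec = replace(
            template,
            n_lymphocytes=n_lymph,
            n_tumor_cells=n_tumor,
            background="stroma",
            seed=item_seed,
        )
        patch, _, true_label = generate_patch(spec, slide_id=f"dataset_{idx:05d}")
        assert true_label == label  # counts are sampled inside the label's region
        patches.append(patch)
        labels.append(true_label)
        records.append(
            {
                "item": idx,
                "label": int(true_label),
                "n_lymph": n_lymph,
                "n_tumor": n_tumor,
                "seed": item_seed,
            }
        )
    table = pd.DataFrame.from_records(records)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for idx, patch in enumerate(patches):
            write_slide(out_dir / f"patch_{idx:05d}.png", patch.pixels)
        table.to_csv(out_dir / "labels.tsv", sep="\t", index=False)
    return patches, labels, table
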