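"""Macenko stain normalization for H&E patches.

H&E color variation between slides is dominated by differences in stain
intensity and hue.  Under the Beer–Lambert law a pixel's optical density
``OD = -ln(I / Io)`` is linear in the per-stain concentrations:
``OD = S @ c`` with ``S`` the 3x2 matrix of unit stain vectors
(hematoxylin, eosin).  The Macenko procedure estimates ``S`` from the
image itself: tissue OD pixels are projected onto the plane spanned by
the top two eigenvectors of their covariance, and the extreme angle
percentiles of that projection are taken as the two stain directions.
Concentrations are then rescaled so that their 99th percentiles match a
reference profile, and the image is re-rendered with the reference
stain matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import nnls as _nnls
from skimage.restoration import estimate_sigma

__all__ = [
    "StainProfile",
    "MacenkoParams",
    "DegenerateStainError",
    "rgb_to_od",
    "od_to_rgb",
    "unmix_concentrations",
    "estimate_stain_profile",
    "normalize_patch",
    "default_target_profile",
]

#: Widely used reference H&E stain matrix (columns: hematoxylin, eosin)
#: and 99th-percentile concentration scales.
REFERENCE_STAIN_MATRIX = np.array(
    [
        [0.5626, 0.2159],
        [0.7201, 0.8012],
        [0.4062, 0.5581],
    ]
)
REFERENCE_MAX_CONCENTRATION = np.array([1.9705, 1.0308])
DEFAULT_IO = 240.0


class DegenerateStainError(ValueError):
    """Raised when a patch has too little tissue, or effectively a single
    stain, so that no two-stain profile can be estimated from it."""


@dataclass
class StainProfile:
    """A 3x2 optical-density stain matrix plus concentration scales.

    Column 0 is hematoxylin, column 1 eosin; columns are unit-norm.
    ``max_concentration`` holds the 99th-percentile concentration of each
    stain, used to match stain intensity between images.  ``io`` is the
    background (unstained) transmitted intensity.
    """

    stain_matrix: np.ndarray
    max_concentration: np.ndarray
    io: float = DEFAULT_IO

    def __post_init__(self) -> None:
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=float)
        self.max_concentration = np.asarray(self.max_concentration, dtype=float)
        if self.stain_matrix.shape != (3, 2):
            raise ValueError(f"stain_matrix must be 3x2, got {self.stain_matrix.shape}")
        norms = np.linalg.norm(self.stain_matrix, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-3):
            raise ValueError(f"stain_matrix columns must be unit-norm, got norms {norms}")
        if np.any(self.stain_matrix < -1e-6):
            raise ValueError("stain_matrix entries must be non-negative")
        if self.max_concentration.shape != (2,) or np.any(self.max_concentration <= 0):
            raise ValueError("max_concentration must be a positive 2-vector")
        if self.io <= 0:
            raise ValueError("io must be positive")

    @property
    def hematoxylin(self) -> np.ndarray:
        return self.stain_matrix[:, 0]

    @property
    def eosin(self) -> np.ndarray:
        return self.stain_matrix[:, 1]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "stain_matrix": self.stain_matrix.tolist(),
            "max_concentration": self.max_concentration.tolist(),
            "io": self.io,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StainProfile":
        payload = json.loads(Path(path).read_text())
        return cls(
            stain_matrix=np.array(payload["stain_matrix"]),
            max_concentration=np.array(payload["max_concentration"]),
            io=float(payload["io"]),
        )


def default_target_profile() -> StainProfile:
    """The canonical reference profile used as normalization target."""
    return StainProfile(
        stain_matrix=REFERENCE_STAIN_MATRIX.copy(),
        max_concentration=REFERENCE_MAX_CONCENTRATION.copy(),
        io=DEFAULT_IO,
    )


@dataclass
class MacenkoParams:
    """Hyperparameters of the stain-vector estimation.

    beta — OD threshold: a pixel enters the estimation only if *every*
    OD channel exceeds it (removes background / weakly stained pixels).
    alpha — robust angle percentile; the stain directions are the alpha
    and (100 - alpha) percentiles of the projected angle.
    min_tissue_pixels — fewer retained pixels than this raises
    :class:`DegenerateStainError`.
    min_stain_separation_deg — if the two recovered directions are closer
    than this the patch is effectively single-stain and is flagged
    degenerate.
    max_noise_sd — pixel-noise ceiling for per-patch estimation inside
    :func:`normalize_patch`.  The eigenplane of the OD covariance is
    pinned by stain variance of order sin^2(22 deg) of the concentration
    spread; on sparsely cellular patches that is a few 1e-3 in OD^2,
    which anisotropic sensor noise overwhelms once its sd exceeds ~3
    intensity units.  Patches whose wavelet-estimated noise exceeds this
    ceiling pass through unnormalized (flagged) rather than being
    re-rendered with an unreliable profile.
    use_nnls — solve concentrations by non-negative least squares instead
    of plain least squares with negative clipping.
    """

    beta: float = 0.15
    alpha: float = 1.0
    io: float = DEFAULT_IO
    min_tissue_pixels: int = 100
    min_stain_separation_deg: float = 10.0
    max_noise_sd: float = 2.5
    use_nnls: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 50:
            raise ValueError("alpha must be in (0, 50)")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


def rgb_to_od(pixels: np.ndarray, io: float = DEFAULT_IO) -> np.ndarray:
    """Convert RGB intensities (0–255) to optical density.

    ``OD_c = -ln((I_c + 1) / io)``, clipped below at 0.  The +1 guards
    against log(0) and makes intensity io-1 map to exactly zero OD.
    """
    if io <= 0:
        raise ValueError("io must be positive")
    od = -np.log((np.asarray(pixels, dtype=float) + 1.0) / io)
    return np.clip(od, 0.0, None)


def od_to_rgb(od: np.ndarray, io: float = DEFAULT_IO) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`; returns uint8 in [0, 255]."""
    intensity = io * np.exp(-np.asarray(od, dtype=float)) - 1.0
    return np.clip(np.round(intensity), 0, 255).astype(np.uint8)


def unmix_concentrations(
    od: np.ndarray, stain_matrix: np.ndarray, use_nnls: bool = False
) -> np.ndarray:
    """Solve ``OD = S @ c`` for per-pixel stain concentrations.

    Parameters
    ----------
    od : (n, 3) optical-density pixels.
    stain_matrix : 3x2 stain matrix.
    use_nnls : exact non-negative least squares per pixel (slow) instead
        of unconstrained least squares with negatives clipped to 0.

    Returns
    -------
    (2, n) concentration array, non-negative.
    """
    od = np.asarray(od, dtype=float).reshape(-1, 3)
    if use_nnls:
        conc = np.empty((2, od.shape[0]))
        for i, pixel in enumerate(od):
            conc[:, i] = _nnls(stain_matrix, pixel)[0]
        return conc
    conc, *_ = np.linalg.lstsq(stain_matrix, od.T, rcond=None)
    return np.clip(conc, 0.0, None)


def _patch_pixels(patch) -> np.ndarray:
    """Accept either a raw HxWx3 array or an object with a .pixels array."""
    pixels = getattr(patch, "pixels", patch)
    return np.asarray(pixels)


def estimate_stain_profile(patch, params: MacenkoParams | None = None) -> StainProfile:
    """Estimate the H&E stain profile of a patch (Macenko procedure).

    Raises
    ------
    DegenerateStainError
        If fewer than ``min_tissue_pixels`` pixels survive the OD
        threshold, or the recovered stain directions nearly coincide
        (single-stain image).
    """
    params = params or MacenkoParams()
    pixels = _patch_pixels(patch)
    od = rgb_to_od(pixels, params.io).reshape(-1, 3)
    tissue = od[np.all(od > params.beta, axis=1)]
    if tissue.shape[0] < params.min_tissue_pixels:
        raise DegenerateStainError(
            f"only {tissue.shape[0]} tissue pixels above OD {params.beta} "
            f"(need {params.min_tissue_pixels})"
        )

    # Top-2 eigenplane of the OD covariance.
    cov = np.cov(tissue, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    plane = eigvecs[:, [2, 1]]  # descending order of variance
    # Orient basis vectors so projections land in a consistent half-space.
    for k in range(2):
        if plane[:, k].sum() < 0:
            plane[:, k] = -plane[:, k]

    proj = tissue @ plane
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    phi_lo = np.percentile(phi, params.alpha)
    phi_hi = np.percentile(phi, 100.0 - params.alpha)

    v_lo = plane @ np.array([np.cos(phi_lo), np.sin(phi_lo)])
    v_hi = plane @ np.array([np.cos(phi_hi), np.sin(phi_hi)])
    for v in (v_lo, v_hi):
        if v.sum() < 0:
            v *= -1.0
    v_lo = np.clip(v_lo, 0.0, None)
    v_hi = np.clip(v_hi, 0.0, None)
    v_lo /= np.linalg.norm(v_lo)
    v_hi /= np.linalg.norm(v_hi)

    separation = np.degrees(np.arccos(np.clip(v_lo @ v_hi, -1.0, 1.0)))
    if separation < params.min_stain_separation_deg:
        raise DegenerateStainError(
            f"stain directions separated by only {separation:.2f} deg; "
            "patch is effectively single-stain"
        )

    # Hematoxylin has the larger red-channel OD component.
    if v_lo[0] > v_hi[0]:
        stain_matrix = np.column_stack([v_lo, v_hi])
    else:
        stain_matrix = np.column_stack([v_hi, v_lo])

    conc = unmix_concentrations(od, stain_matrix, use_nnls=params.use_nnls)
    max_c = np.percentile(conc, 99.0, axis=1)
    max_c = np.maximum(max_c, 1e-6)
    return StainProfile(stain_matrix=stain_matrix, max_concentration=max_c, io=params.io)


@dataclass
class NormalizationResult:
    """Normalized pixels plus a flag recording pass-through on degenerate
    input (blank or single-stain patches are returned unchanged)."""

    pixels: np.ndarray
    passthrough: bool = False
    reason: str = ""


def normalize_patch(
    patch,
    target: StainProfile | None = None,
    params: MacenkoParams | None = None,
    source: StainProfile | None = None,
) -> NormalizationResult:
    """Macenko-normalize a patch to a target stain profile.

    The source profile is estimated from the patch itself unless given.
    Concentrations are rescaled stain-wise by
    ``target.max_concentration / source 99th percentile`` and re-rendered
    with the target stain matrix and background intensity.  Degenerate
    input (too little tissue, single stain) passes through unchanged with
    ``passthrough=True``.
    """
    target = target or default_target_profile()
    params = params or MacenkoParams()
    pixels = _patch_pixels(patch)
    if source is None:
        noise_sd = float(
            estimate_sigma(pixels.astype(float), channel_axis=-1, average_sigmas=True)
        )
        if noise_sd > params.max_noise_sd:
            return NormalizationResult(
                pixels=pixels.copy(),
                passthrough=True,
                reason=(
                    f"estimated pixel noise sd {noise_sd:.1f} exceeds "
                    f"{params.max_noise_sd}; per-patch stain estimation unreliable"
                ),
            )
        try:
            source = estimate_stain_profile(pixels, params)
        except DegenerateStainError as exc:
            return NormalizationResult(pixels=pixels.copy(), passthrough=True, reason=str(exc))

    od = rgb_to_od(pixels, source.io)
    conc = unmix_concentrations(od, source.stain_matrix, use_nnls=params.use_nnls)
    scale = target.max_concentration / source.max_concentration
    conc = conc * scale[:, None]
    od_new = (target.stain_matrix @ conc).T.reshape(pixels.shape)
    return NormalizationResult(pixels=od_to_rgb(od_new, target.io), passthrough=False)
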