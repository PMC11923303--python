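"""Three-class patch labeling: TIL-positive / TIL-negative / other-necrotic.

The labeling rule counts detected cells in a patch:

* TIL-positive (code 0): >= 3 lymphocytes and >= 1 tumor cell;
* TIL-negative (code 1): >= 1 tumor cell and < 3 lymphocytes;
* other/necrotic (code 2): no tumor cells, regardless of lymphocytes.

Lymphocytes present in H&E as small round darkly hematoxylin-stained
nuclei; tumor cells as larger, irregularly shaped nuclei.  The reference
backend makes the rule executable: it unmixes the hematoxylin channel,
segments nuclei by thresholding and connected components, classifies each
nucleus by area and circularity (4*pi*A/P^2), and applies the rule to the
counts.  Any backend exposing ``predict(patch) -> Prediction`` can stand
in for it (e.g. a trained network).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.transform import resize
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .stainnorm import (
    StainProfile,
    default_target_profile,
    rgb_to_od,
    unmix_concentrations,
)

__all__ = [
    "PatchLabel",
    "Prediction",
    "CellInstance",
    "DetectorParams",
    "detect_nuclei",
    "rule_label",
    "classify_patch",
    "RuleBasedBackend",
    "PixelClassifierBackend",
    "train_small_classifier",
    "split_dataset",
    "train_val_split",
    "stratified_folds",
]


class PatchLabel(IntEnum):
    """Patch classes, with the label encoding used throughout."""

    TIL_POSITIVE = 0
    TIL_NEGATIVE = 1
    OTHER_NECROTIC = 2


@dataclass(frozen=True)
class Prediction:
    """A class label plus the 3-vector of class probabilities.

    The label is the argmax of the probabilities; ties break toward the
    lowest class code.
    """

    label: PatchLabel
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probabilities, dtype=float)
        if probs.shape != (3,):
            raise ValueError("probabilities must be a 3-vector")
        if np.any(probs < -1e-9) or abs(probs.sum() - 1.0) > 1e-6:
            raise ValueError(f"probabilities must be a simplex point, got {probs}")
        object.__setattr__(self, "probabilities", probs)

    @classmethod
    def from_probabilities(cls, probs: Sequence[float]) -> "Prediction":
        probs = np.asarray(probs, dtype=float)
        return cls(label=PatchLabel(int(np.argmax(probs))), probabilities=probs)

    @classmethod
    def one_hot(cls, label: PatchLabel) -> "Prediction":
        probs = np.zeros(3)
        probs[int(label)] = 1.0
        return cls(label=PatchLabel(label), probabilities=probs)


@dataclass(frozen=True)
class CellInstance:
    """A detected (or simulated) nucleus."""

    centroid: tuple[float, float]  # (row, col) px
    area: float  # px^2
    circularity: float  # 4*pi*A/P^2, 1 for a perfect disk
    mean_h_od: float  # mean hematoxylin signal over the nucleus
    cell_class: str  # "lymphocyte" | "tumor" | "other"

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("area must be positive")
        if self.circularity > 1.0 + 0.35:
            # digital perimeter estimates overshoot slightly for tiny blobs
            raise ValueError(f"implausible circularity {self.circularity}")


@dataclass
class DetectorParams:
    """Parameters of the rule-based nucleus detector.

    The hematoxylin concentration map is Gaussian-smoothed and
    thresholded (fixed value, or Otsu over tissue pixels); connected
    components are classified by area and circularity.  Defaults are
    calibrated to the synthetic generator's nucleus geometry
    (lymphocyte radius 5–7 px, tumor radius 12–20 px at ~0.5 um/px).
    """

    h_threshold_mode: str = "fixed"  # "fixed" | "otsu"
    fixed_threshold: float = 0.25
    tissue_floor: float = 0.1  # Otsu computed over pixels above this
    min_area_px: int = 30
    lymph_area_range: tuple[float, float] = (30.0, 250.0)
    tumor_min_area_px: float = 300.0
    circularity_min: float = 0.7
    smoothing_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.h_threshold_mode not in ("fixed", "otsu"):
            raise ValueError("h_threshold_mode must be 'fixed' or 'otsu'")
        lo, hi = self.lymph_area_range
        if not 0 < lo < hi:
            raise ValueError("lymph_area_range must be increasing and positive")
        if hi >= self.tumor_min_area_px:
            raise ValueError("lymph_area_range max must be below tumor_min_area_px")
        if self.min_area_px <= 0:
            raise ValueError("min_area_px must be positive")


def rule_label(n_lymphocytes: int, n_tumor_cells: int) -> PatchLabel:
    """Apply the counting rule to ground-truth or detected cell counts."""
    if n_lymphocytes < 0 or n_tumor_cells < 0:
        raise ValueError("cell counts must be non-negative")
    if n_tumor_cells == 0:
        return PatchLabel.OTHER_NECROTIC
    if n_lymphocytes >= 3:
        return PatchLabel.TIL_POSITIVE
    return PatchLabel.TIL_NEGATIVE


def detect_nuclei(
    patch,
    stain_profile: StainProfile | None = None,
    params: DetectorParams | None = None,
) -> list[CellInstance]:
    """Segment and classify nuclei in a patch via the hematoxylin channel.

    Deterministic.  Returns an empty list when no pixel clears the
    tissue floor (blank or unstained input).
    """
    profile = stain_profile or default_target_profile()
    params = params or DetectorParams()
    pixels = np.asarray(getattr(patch, "pixels", patch))
    od = rgb_to_od(pixels, profile.io)
    conc = unmix_concentrations(od, profile.stain_matrix)
    h_map = conc[0].reshape(pixels.shape[:2])
    h_smooth = gaussian_filter(h_map, sigma=params.smoothing_sigma)

    tissue = h_smooth > params.tissue_floor
    if tissue.sum() < params.min_area_px:
        return []
    if params.h_threshold_mode == "otsu":
        threshold = max(threshold_otsu(h_smooth[tissue]), params.tissue_floor)
    else:
        threshold = params.fixed_threshold

    mask = h_smooth > threshold
    components = cc_label(mask, connectivity=2)
    cells: list[CellInstance] = []
    for region in regionprops(components, intensity_image=h_map):
        if region.area < params.min_area_px:
            continue
        perimeter = max(region.perimeter, 1.0)
        circularity = min(4.0 * np.pi * region.area / perimeter**2, 1.3)
        lo, hi = params.lymph_area_range
        if region.area >= params.tumor_min_area_px:
            cell_class = "tumor"
        elif lo <= region.area <= hi and circularity >= params.circularity_min:
            cell_class = "lymphocyte"
        else:
            cell_class = "other"
        cells.append(
            CellInstance(
                centroid=tuple(region.centroid),
                area=float(region.area),
                circularity=float(circularity),
                mean_h_od=float(region.intensity_mean),
                cell_class=cell_class,
            )
        )
    return cells


class Backend(Protocol):
    def predict(self, patch) -> Prediction: ...


@dataclass
class RuleBasedBackend:
    """Reference classifier: nucleus detection + counting rule.

    Emits degenerate one-hot probabilities; fully deterministic.
    """

    stain_profile: StainProfile = field(default_factory=default_target_profile)
    params: DetectorParams = field(default_factory=DetectorParams)

    def predict(self, patch) -> Prediction:
        cells = detect_nuclei(patch, self.stain_profile, self.params)
        n_lymph = sum(1 for c in cells if c.cell_class == "lymphocyte")
        n_tumor = sum(1 for c in cells if c.cell_class == "tumor")
        return Prediction.one_hot(rule_label(n_lymph, n_tumor))


def classify_patch(patch, backend: Backend) -> Prediction:
    """Run a backend on one patch; validates the Prediction contract."""
    if backend is None or not hasattr(backend, "predict"):
        raise ValueError("backend is not initialized or lacks a predict method")
    prediction = backend.predict(patch)
    if not isinstance(prediction, Prediction):
        prediction = Prediction.from_probabilities(np.asarray(prediction))
    return prediction


# ---------------------------------------------------------------------------
# Dataset splitting


def train_val_split(
    labels: Sequence[int],
    train_frac: float = 0.8,
    seed: int = 0,
    strata: Sequence | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/validation split (default 8:2).

    Stratification is per label within each stratum key (e.g. cancer
    type); the train fraction per group is honoured within one item.
    """
    labels = np.asarray(labels)
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    keys = (
        np.array([f"{s}|{l}" for s, l in zip(strata, labels)])
        if strata is not None
        else labels.astype(str)
    )
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    for key in np.unique(keys):
        members = np.flatnonzero(keys == key)
        rng.shuffle(members)
        n_train = int(round(train_frac * len(members)))
        train_idx.extend(members[:n_train])
        val_idx.extend(members[n_train:])
    return np.sort(np.array(train_idx, dtype=int)), np.sort(np.array(val_idx, dtype=int))


def stratified_folds(
    labels: Sequence[int],
    n_folds: int,
    seed: int = 0,
    strata: Sequence | None = None,
) -> np.ndarray:
    """Disjoint, exhaustive, label-stratified fold assignment (0..n_folds-1)."""
    labels = np.asarray(labels)
    keys = (
        np.array([f"{s}|{l}" for s, l in zip(strata, labels)])
        if strata is not None
        else labels
    )
    values, counts = np.unique(keys, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"cannot build {n_folds} stratified folds: smallest label group has "
            f"{counts.min()} items"
        )
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(labels)), keys)):
        assignment[test_idx] = fold
    return assignment


def split_dataset(
    labels: Sequence[int],
    train_frac: float = 0.8,
    n_folds: int | None = None,
    seed: int = 0,
    strata: Sequence | None = None,
):
    """Seeded stratified split: 8:2 train/val, or k disjoint folds.

    Returns ``(train_idx, val_idx)`` when ``n_folds`` is None, else a
    per-item fold-id array.
    """
    if n_folds is not None:
        return stratified_folds(labels, n_folds, seed=seed, strata=strata)
    return train_val_split(labels, train_frac=train_frac, seed=seed, strata=strata)


# ---------------------------------------------------------------------------
# Optional trainable backend (non-reference)

PIXEL_INPUT_SIZE = 24


@dataclass
class PixelClassifierBackend:
    """Small trainable pixel classifier honouring the Prediction contract.

    Patches are resized to the network input size
    (``PIXEL_INPUT_SIZE`` square) and fed, flattened and scaled to
    [0, 1], to a multilayer perceptron.  Useful as a learned stand-in on
    synthetic data; not the reference backend.
    """

    model: MLPClassifier

    def _features(self, patch) -> np.ndarray:
        pixels = np.asarray(getattr(patch, "pixels", patch), dtype=float) / 255.0
        small = resize(pixels, (PIXEL_INPUT_SIZE, PIXEL_INPUT_SIZE, 3), anti_aliasing=True)
        return small.ravel()[None, :]

    def predict(self, patch) -> Prediction:
        probs = np.zeros(3)
        raw = self.model.predict_proba(self._features(patch))[0]
        for cls, p in zip(self.model.classes_, raw):
            probs[int(cls)] = p
        probs /= probs.sum()
        return Prediction.from_probabilities(probs)


def train_small_classifier(
    patches: Sequence,
    labels: Sequence[int],
    seed: int = 0,
    hidden_layer_sizes: tuple[int, ...] = (64,),
    max_iter: int = 300,
) -> PixelClassifierBackend:
    """Train the small pixel classifier on a labeled patch set.

    Requires all three classes in ``labels``.  Seeded but (like any
    SGD-trained model) not bit-reproducible across library versions.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 3:
        raise ValueError("training set must contain all three classes")
    backend = PixelClassifierBackend(
        model=MLPClassifier(
            hidden_layer_sizes=hidden_layer_sizes,
            max_iter=max_iter,
            random_state=seed,
        )
    )
    features = np.vstack([backend._features(p) for p in patches])
    backend.model.fit(features, labels)
    return backend
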