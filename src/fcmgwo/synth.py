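"""Synthetic cytology-like images with exact ground truth.

Real stained smears have no pixel-level ground truth, which blocks any
accuracy-style evaluation of a segmenter.  This module emulates their
three-population intensity structure -- dark hematoxylin-stained nuclei
inside mid-intensity cytoplasm halos on a bright background -- as disks in
disks with additive Gaussian noise, and records the exact class of every
pixel.  Defaults: 400x300 pixels, 10 cells, class mean intensities
40 / 130 / 220 (nucleus / cytoplasm / background), noise sigma 8, nucleus
radii 8-12 px inside cytoplasm radii 16-24 px.

What it deliberately does not model: chromatin texture, H&E color physics,
stain variation, or out-of-focus blur; see the methods note for what that
implies about transferring test results to real slides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from skimage.draw import disk as draw_disk

__all__ = [
    "PlacementError",
    "SyntheticSpec",
    "GroundTruth",
    "CLASS_NAMES",
    "generate_cell_image",
    "segmentation_accuracy",
]

# mask encoding, also used by the CLI when writing mask PNGs
CLASS_NAMES = {0: "background", 1: "cytoplasm", 2: "nucleus"}

_MAX_TRIES = 100


class PlacementError(RuntimeError):
    """A cell could not be placed inside the canvas after bounded retries."""


@dataclass(frozen=True)
class SyntheticSpec:
    width: int = 400
    height: int = 300
    n_cells: int = 10
    nucleus_level: float = 40.0
    cytoplasm_level: float = 130.0
    background_level: float = 220.0
    noise_sigma: float = 8.0
    nucleus_radius_range: tuple[int, int] = (8, 12)
    cytoplasm_radius_range: tuple[int, int] = (16, 24)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.background_level > self.cytoplasm_level > self.nucleus_level):
            raise ValueError("expected background > cytoplasm > nucleus intensity")
        for name in ("nucleus_radius_range", "cytoplasm_radius_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid {name}: {(lo, hi)}")
        if self.width < 1 or self.height < 1 or self.n_cells < 0:
            raise ValueError("non-positive image dimensions or negative cell count")
        if self.noise_sigma < 0:
            raise ValueError(f"noise sigma must be >= 0, got {self.noise_sigma}")


@dataclass
class GroundTruth:
    mask: np.ndarray                    # (H, W) uint8 in {0, 1, 2}
    class_proportions: dict[str, float]


def generate_cell_image(spec: SyntheticSpec) -> tuple[np.ndarray, GroundTruth]:
    """Paint disk-in-disk cells on a bright background and add clipped noise.

    Cells may overlap; later cells are painted on top.  Each cytoplasm disk
    must fit entirely inside the canvas; radii/positions are re-drawn up to a
    bounded number of times before a :class:`PlacementError` is raised.
    Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    img = np.full((h, w), spec.background_level, dtype=float)
    mask = np.zeros((h, w), dtype=np.uint8)

    for _ in range(spec.n_cells):
        for attempt in range(_MAX_TRIES):
            r_cyt = int(rng.integers(*spec.cytoplasm_radius_range, endpoint=True))
            r_nuc = int(rng.integers(*spec.nucleus_radius_range, endpoint=True))
            if r_nuc >= r_cyt:
                continue
            if 2 * r_cyt + 1 > min(h, w):
                continue
            cy = int(rng.integers(r_cyt, h - r_cyt))
            cx = int(rng.integers(r_cyt, w - r_cyt))
            break
        else:
            raise PlacementError(
                f"could not place a cell on a {w}x{h} canvas after {_MAX_TRIES} tries"
            )
        rr, cc = draw_disk((cy, cx), r_cyt, shape=(h, w))
        img[rr, cc] = spec.cytoplasm_level
        mask[rr, cc] = 1
        rr, cc = draw_disk((cy, cx), r_nuc, shape=(h, w))
        img[rr, cc] = spec.nucleus_level
        mask[rr, cc] = 2

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    counts = np.bincount(mask.ravel(), minlength=3)
    proportions = {CLASS_NAMES[k]: counts[k] / mask.size for k in CLASS_NAMES}
    return img, GroundTruth(mask=mask, class_proportions=proportions)


def segmentation_accuracy(predicted: np.ndarray, truth: GroundTruth | np.ndarray) -> float:
    """Best-matching pixel accuracy, invariant to predicted label permutation.

    Builds the predicted-vs-true contingency table and maximizes total
    agreement over bijective label assignments (Hungarian algorithm), so any
    relabeling of the predicted clusters scores identically.
    """
    truth_mask = truth.mask if isinstance(truth, GroundTruth) else np.asarray(truth)
    predicted = np.asarray(predicted)
    if predicted.shape != truth_mask.shape:
        raise ValueError(
            f"prediction {predicted.shape} and truth {truth_mask.shape} differ in shape"
        )
    p = predicted.ravel().astype(np.int64)
    t = truth_mask.ravel().astype(np.int64)
    n_p, n_t = p.max() + 1, t.max() + 1
    size = max(n_p, n_t)
    contingency = np.zeros((size, size), dtype=np.int64)
    np.add.at(contingency, (p, t), 1)
    rows, cols = linear_sum_assignment(-contingency)
    return float(contingency[rows, cols].sum() / p.size)
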