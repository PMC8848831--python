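"""The hybrid segmentation pipeline: FCM seeds a grey-wolf refinement of J_m.

FCM alone is sensitive to initialization and can stall in local optima of
its objective.  The hybrid runs FCM to convergence (or its iteration cap),
places one wolf exactly at the FCM cluster centers, fills the rest of the
pack uniformly at random inside the search box, and lets GWO minimize the
same dissimilarity J_m -- evaluated with memberships re-derived optimally
from each candidate center set.  Because the FCM solution is in the initial
pack and leaders are elitist, the hybrid objective can never exceed the
FCM-only objective on the same data.

For three-cluster intensity segmentation the clusters are mapped to tissue
classes by brightness rank: hematoxylin-stained nuclei are darkest,
cytoplasm intermediate, background brightest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .fcm import (
    FcmConfig,
    FcmResult,
    as_feature_matrix,
    fcm_objective,
    run_fcm,
    update_memberships,
)
from .gwo import GwoConfig, GwoResult, run_gwo
from .imaging import PreprocessSettings, preprocess

__all__ = [
    "UnsupportedTissueMapError",
    "SegmentationConfig",
    "HybridResult",
    "SegmentationResult",
    "center_fitness",
    "seed_pack_from_centers",
    "run_fcmgwo",
    "labels_from_memberships",
    "assign_tissue_classes",
    "segment_image",
    "render_overlay",
]

TISSUE_CLASSES = ("nucleus", "cytoplasm", "background")  # darkest to brightest

# Fig-style overlay colors: nucleus red, cytoplasm yellow
_OVERLAY_COLORS = {"nucleus": (255, 0, 0), "cytoplasm": (255, 255, 0)}


class UnsupportedTissueMapError(ValueError):
    """Tissue-class mapping is defined only for 3 single-feature clusters."""


@dataclass(frozen=True)
class SegmentationConfig:
    """Bundled configuration for one segmentation run.

    ``method`` selects plain ``"fcm"`` or the hybrid ``"fcmgwo"``.
    """

    fcm: FcmConfig = field(default_factory=FcmConfig)
    gwo: GwoConfig = field(default_factory=GwoConfig)
    preprocess: PreprocessSettings = field(default_factory=PreprocessSettings)
    method: str = "fcmgwo"

    def __post_init__(self) -> None:
        if self.method not in ("fcm", "fcmgwo"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class HybridResult:
    centers: np.ndarray
    memberships: np.ndarray
    objective: float
    fcm_result: FcmResult
    gwo_result: GwoResult | None = None


@dataclass
class SegmentationResult:
    labels: np.ndarray                  # (H, W) int cluster indices
    centers: np.ndarray                 # (c, 1)
    memberships: np.ndarray             # (n, c)
    objective: float
    tissue_map: dict[int, str]
    provenance: dict


def center_fitness(data: np.ndarray, flat_centers: np.ndarray, c: int, m: float) -> float:
    """J_m of a candidate center set with memberships re-derived optimally.

    This is the fitness GWO minimizes; the position vector encodes all ``c``
    centers concatenated feature-block by feature-block.
    """
    X = as_feature_matrix(data)
    flat = np.asarray(flat_centers, dtype=float).ravel()
    f = X.shape[1]
    if flat.size != c * f:
        raise ValueError(f"position of length {flat.size} cannot encode {c} centers of dim {f}")
    if not np.all(np.isfinite(flat)):
        raise ValueError("candidate centers contain non-finite values")
    centers = flat.reshape(c, f)
    u = update_memberships(X, centers, m)
    return fcm_objective(X, centers, u, m)


def seed_pack_from_centers(
    fcm_centers: np.ndarray,
    cfg: GwoConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Initial wolf pack: agent 0 is the flattened FCM centers, rest uniform."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    flat = np.clip(np.asarray(fcm_centers, dtype=float).ravel(),
                   cfg.lower_bound, cfg.upper_bound)
    rest = rng.uniform(cfg.lower_bound, cfg.upper_bound, (cfg.n_agents - 1, flat.size))
    return np.vstack([flat[None, :], rest])


def run_fcmgwo(data: np.ndarray, cfg: SegmentationConfig) -> HybridResult:
    """FCM, then GWO refinement of the cluster centers under the same J_m."""
    X = as_feature_matrix(data)
    c, m = cfg.fcm.c, cfg.fcm.m
    fcm_res = run_fcm(X, cfg.fcm)

    rng = np.random.default_rng(cfg.gwo.seed)
    pack = seed_pack_from_centers(fcm_res.centers, cfg.gwo, rng)
    gwo_res = run_gwo(
        lambda p: center_fitness(X, p, c, m),
        dim=c * X.shape[1],
        cfg=cfg.gwo,
        init_positions=pack,
        rng=rng,
    )
    centers = gwo_res.best_position.reshape(c, X.shape[1])
    u = update_memberships(X, centers, m)
    objective = fcm_objective(X, centers, u, m)
    return HybridResult(centers=centers, memberships=u, objective=objective,
                        fcm_result=fcm_res, gwo_result=gwo_res)


def labels_from_memberships(u: np.ndarray) -> np.ndarray:
    """Hard labels by per-row argmax; ties go to the lowest cluster index."""
    u = np.asarray(u, dtype=float)
    if u.ndim != 2:
        raise ValueError(f"membership matrix must be 2-D, got shape {u.shape}")
    return np.argmax(u, axis=1)


def assign_tissue_classes(centers: np.ndarray) -> dict[int, str]:
    """Map 3 intensity clusters to tissue classes by brightness rank.

    Darkest center -> nucleus, middle -> cytoplasm, brightest -> background;
    ties resolve toward the lower cluster index (stable sort).
    """
    C = np.asarray(centers, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape != (3, 1):
        raise UnsupportedTissueMapError(
            f"tissue mapping needs 3 single-feature centers, got shape {C.shape}"
        )
    order = np.argsort(C.ravel(), kind="stable")
    return {int(cluster): TISSUE_CLASSES[rank] for rank, cluster in enumerate(order)}


def segment_image(img: np.ndarray, cfg: SegmentationConfig | None = None) -> SegmentationResult:
    """Preprocess, cluster pixel intensities, and label each pixel.

    Provenance records the configuration, objective traces and the FCM-only
    objective so hybrid runs can be audited against their FCM baseline.
    """
    if cfg is None:
        cfg = SegmentationConfig()
    pre = preprocess(img, cfg.preprocess)
    if pre.ndim != 2:
        raise ValueError("segmentation expects a single-channel preprocessed image")
    X = pre.reshape(-1, 1).astype(float)

    if cfg.method == "fcm":
        fcm_res = run_fcm(X, cfg.fcm)
        centers, u, objective = fcm_res.centers, fcm_res.memberships, fcm_res.objective
        traces = {"fcm_objective_trace": list(fcm_res.objective_trace)}
    else:
        hyb = run_fcmgwo(X, cfg)
        centers, u, objective = hyb.centers, hyb.memberships, hyb.objective
        traces = {
            "fcm_objective_trace": list(hyb.fcm_result.objective_trace),
            "gwo_best_fitness_trace": list(hyb.gwo_result.trace),
            "fcm_objective": hyb.fcm_result.objective,
        }

    labels = labels_from_memberships(u).reshape(pre.shape)
    try:
        tissue_map = assign_tissue_classes(centers)
    except UnsupportedTissueMapError:
        tissue_map = {j: f"cluster_{j}" for j in range(cfg.fcm.c)}

    distinct = np.unique(np.round(centers.ravel(), 6)).size
    provenance = {
        "method": cfg.method,
        "fcm_config": vars(cfg.fcm).copy(),
        "gwo_config": vars(cfg.gwo).copy(),
        "preprocess": vars(cfg.preprocess).copy(),
        "n_effective_clusters": int(distinct),
        **traces,
    }
    return SegmentationResult(labels=labels, centers=centers, memberships=u,
                              objective=objective, tissue_map=tissue_map,
                              provenance=provenance)


def render_overlay(gray: np.ndarray, labels: np.ndarray, tissue_map: dict[int, str]) -> np.ndarray:
    """RGB overlay: nucleus painted red, cytoplasm yellow, background left gray."""
    gray = np.asarray(gray)
    if gray.shape != labels.shape:
        raise ValueError(f"image {gray.shape} and labels {labels.shape} differ in shape")
    rgb = np.stack([gray] * 3, axis=-1).astype(np.uint8)
    for cluster, tissue in tissue_map.items():
        color = _OVERLAY_COLORS.get(tissue)
        if color is not None:
            rgb[labels == cluster] = color
    return rgb


def per_cluster_pixel_counts(labels: np.ndarray, c: int) -> dict[int, int]:
    counts = np.bincount(np.asarray(labels).ravel(), minlength=c)
    return {j: int(counts[j]) for j in range(c)}
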