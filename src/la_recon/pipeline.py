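"""End-to-end orchestration: from (geometry, cloud) pairs to network inputs.

One simulated case runs the full data-generation chain: the cloud is
misaligned by a random similarity transform (standing in for the catheter
coordinate frame), registered back via the PV landmarks, spherically
projected onto the segmentation surface, densified with the iterative
alpha-concave hull, and discretized into a partial-shell volume cropped
identically to the label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .projection import project_to_surface
from .registration import apply_transform, register_landmarks
from .shell import DEFAULT_CROP_SHAPE, densify, discretize
from .synthetic import DESK_PROFILE, SyntheticConfig, make_cohort, perturb_cloud, random_similarity
from .types import LAGeometry, PartialShell, PointCloud

__all__ = ["PipelineConfig", "build_training_pair", "simulate_dataset", "SimulatedCase"]


@dataclass(frozen=True)
class PipelineConfig:
    """Shell-construction parameters."""

    alpha_mm: float = 5.0
    iterations: int = 3
    points_per_edge: int = 1
    crop_shape: tuple[int, int, int] = DEFAULT_CROP_SHAPE


#: Desk-scale shell settings paired with the coarser synthetic profile:
#: two densification iterations already close the shell at 1 mm spacing.
DESK_PIPELINE = PipelineConfig(iterations=2, crop_shape=(64, 64, 48))


def _crop_about(mask: np.ndarray, crop_origin: np.ndarray, crop_shape: tuple[int, int, int]) -> np.ndarray:
    out = np.zeros(tuple(crop_shape), dtype=bool)
    lo = np.asarray(crop_origin)
    hi = lo + np.asarray(crop_shape)
    src_lo = np.maximum(lo, 0)
    src_hi = np.minimum(hi, mask.shape)
    dst_lo = src_lo - lo
    dst_hi = dst_lo + (src_hi - src_lo)
    if np.any(src_hi <= src_lo):
        return out
    out[tuple(slice(a, b) for a, b in zip(dst_lo, dst_hi))] = mask[
        tuple(slice(a, b) for a, b in zip(src_lo, src_hi))
    ]
    return out


def build_training_pair(
    la: LAGeometry,
    cloud: PointCloud,
    config: PipelineConfig = PipelineConfig(),
    registered: bool = True,
) -> tuple[PartialShell, LAGeometry]:
    """Project + densify + discretize a (registered) cloud; crop shell and
    label identically about the label's bounding-box center.

    Raises if the label bounding box exceeds ``config.crop_shape``.
    """
    if not registered:
        transform = register_landmarks(cloud, la)
        cloud = apply_transform(cloud, transform)
    projected = project_to_surface(cloud, la).cloud
    dense = densify(projected.points, config.alpha_mm, config.iterations, config.points_per_edge)

    # the crop is centered on the label so input and label stay aligned
    fg = np.argwhere(la.mask)
    lo, hi = fg.min(axis=0), fg.max(axis=0)
    crop = np.asarray(config.crop_shape, dtype=int)
    if np.any(hi - lo + 1 > crop):
        raise ValueError(
            f"label bounding box {tuple(hi - lo + 1)} exceeds crop shape {tuple(crop)}"
        )
    center = (lo + hi) / 2.0
    crop_origin = np.round(center - (crop - 1) / 2.0).astype(np.int64)

    idx = np.floor((dense - la.origin) / la.spacing_mm).astype(np.int64) - crop_origin
    keep = np.all((idx >= 0) & (idx < crop), axis=1)
    volume = np.zeros(tuple(crop), dtype=bool)
    volume[tuple(idx[keep].T)] = True
    shell = PartialShell(volume=volume, spacing_mm=la.spacing_mm, crop_origin=crop_origin)

    label_mask = _crop_about(la.mask, crop_origin, tuple(crop))
    label = LAGeometry(
        mask=label_mask,
        spacing_mm=la.spacing_mm,
        pv_landmarks={k: v - crop_origin for k, v in (la.pv_landmarks or {}).items()} or None,
        origin=la.origin + crop_origin * la.spacing_mm,
    )
    return shell, label


@dataclass
class SimulatedCase:
    la: LAGeometry  # full (uncropped) ground truth
    cloud: PointCloud  # image-frame cloud (pre-perturbation)
    shell: PartialShell
    label: LAGeometry  # cropped ground truth aligned with the shell
    config: SyntheticConfig


def simulate_dataset(
    n_cases: int,
    seed: int = 0,
    base: SyntheticConfig = DESK_PROFILE,
    pipeline: PipelineConfig = DESK_PIPELINE,
    coverage_range: tuple[float, float] = (0.25, 0.40),
    misalign: bool = True,
) -> list[SimulatedCase]:
    """Simulate paired cases end-to-end through the full pipeline."""
    cohort = make_cohort(n_cases, base=base, seed=seed, coverage_range=coverage_range)
    rng = np.random.default_rng([int(seed) % (2**31), 13])
    cases = []
    for la, cloud, cfg in cohort:
        if misalign:
            t = random_similarity(rng)
            misaligned = perturb_cloud(cloud, t)
            shell, label = build_training_pair(la, misaligned, pipeline, registered=False)
        else:
            shell, label = build_training_pair(la, cloud, pipeline, registered=True)
        cases.append(SimulatedCase(la=la, cloud=cloud, shell=shell, label=label, config=cfg))
    return cases
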