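"""Spherical (radial) projection of a registered point cloud onto the LA wall.

After landmark registration the cloud only approximately matches the target
anatomy.  Each point is therefore moved along the ray from the chamber's
center of mass through the point onto the segmentation's outer surface,
yielding an exact surface match.  Rays are marched at half-voxel steps with
trilinear interpolation of the mask and the *outermost* 0.5 iso-crossing is
taken, so points land on the endocardial shell even when a ray crosses a
pulmonary vein twice.  Points whose ray never enters the foreground cannot be
projected and are dropped (their count is reported).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import LAGeometry, PointCloud

__all__ = ["center_of_mass", "project_to_surface", "ProjectionResult"]


def center_of_mass(la: LAGeometry) -> np.ndarray:
    """World-space (mm) centroid of the foreground voxels."""
    if not la.mask.any():
        raise ValueError("cannot take the center of mass of an empty mask")
    com_vox = np.asarray(ndimage.center_of_mass(la.mask))
    return la.voxel_to_world(com_vox)


@dataclass
class ProjectionResult:
    cloud: PointCloud
    n_dropped: int
    dropped_indices: np.ndarray


def _project_points(
    points: np.ndarray,
    com: np.ndarray,
    la: LAGeometry,
    step_mm: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Project points radially from com; returns (projected, ok_mask)."""
    mask_f = la.mask.astype(np.float32)
    shape = np.asarray(la.mask.shape)

    vec = points - com
    norm = np.linalg.norm(vec, axis=1, keepdims=True)
    # a point exactly at the COM has no direction; give it an arbitrary one
    degenerate = norm[:, 0] < 1e-12
    norm[degenerate] = 1.0
    dirs = vec / norm
    dirs[degenerate] = np.array([1.0, 0.0, 0.0])

    t_max = float(np.linalg.norm(shape * la.spacing_mm)) + 2 * la.spacing_mm
    ts = np.arange(0.0, t_max, step_mm, dtype=np.float64)
    # sample positions in continuous voxel coordinates, rays x steps
    sample_world = com[None, None, :] + ts[None, :, None] * dirs[:, None, :]
    sample_vox = (sample_world - la.origin) / la.spacing_mm - 0.5
    values = ndimage.map_coordinates(
        mask_f,
        sample_vox.reshape(-1, 3).T,
        order=1,
        mode="constant",
        cval=0.0,
    ).reshape(len(points), len(ts))

    inside = values >= 0.5
    ok = inside.any(axis=1)
    # outermost foreground sample; the iso-crossing lies in the next interval
    last = np.where(ok, inside.shape[1] - 1 - np.argmax(inside[:, ::-1], axis=1), 0)
    # the final sample is beyond the grid (value 0), so last+1 is always valid
    v0 = values[np.arange(len(points)), last]
    v1 = values[np.arange(len(points)), np.minimum(last + 1, len(ts) - 1)]
    frac = np.where(v0 > v1, (v0 - 0.5) / np.maximum(v0 - v1, 1e-9), 0.0)
    t_star = ts[last] + frac * step_mm
    projected = com + t_star[:, None] * dirs
    return projected, ok


def project_to_surface(pc: PointCloud, la: LAGeometry, step_factor: float = 0.5) -> ProjectionResult:
    """Move every point of the cloud onto the outer surface of the LA mask.

    Parameters
    ----------
    pc
        Registered point cloud (world mm, same frame as ``la``).
    la
        Target segmentation; its center of mass must lie inside the mask.
    step_factor
        Ray-marching step as a fraction of the voxel spacing (default 0.5).

    Returns
    -------
    ProjectionResult
        The projected cloud, the number of dropped points (rays that never
        intersect the foreground), and their indices in the input cloud.
    """
    com = center_of_mass(la)
    com_vox = np.floor(la.world_to_voxel(com) + 0.5).astype(int)
    if not la.mask[tuple(np.clip(com_vox, 0, np.asarray(la.mask.shape) - 1))]:
        raise ValueError("center of mass lies outside the mask; projection is ill-posed")

    step = step_factor * la.spacing_mm
    projected, ok = _project_points(pc.points, com, la, step)
    landmarks = {}
    for label, lm in pc.pv_landmarks.items():
        proj, lm_ok = _project_points(lm[None, :], com, la, step)
        # landmark rays are through the PV ostia and essentially always hit;
        # if one does not, keep the registered position rather than lose it
        landmarks[label] = proj[0] if lm_ok[0] else lm

    dropped = np.flatnonzero(~ok)
    cloud = PointCloud(points=projected[ok], pv_landmarks=landmarks)
    return ProjectionResult(cloud=cloud, n_dropped=len(dropped), dropped_indices=dropped)
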