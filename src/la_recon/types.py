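"""Core domain containers for the LA reconstruction pipeline.

Coordinate conventions
----------------------
Volumes are indexed ``(i, j, k)`` with isotropic voxel spacing.  A voxel's
*world* position (mm) is the position of its center::

    world = origin + (index + 0.5) * spacing_mm

so a world point maps back to the voxel ``floor((world - origin) / spacing_mm)``.
Point clouds and landmark tables are always stored in world millimetres;
``LAGeometry.pv_landmarks`` is stored in (floating-point) voxel indices to
match how landmarks are annotated on images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

#: Canonical ordering of the four pulmonary-vein landmark labels:
#: left/right superior/inferior PV.
PV_LABELS: tuple[str, ...] = ("LSPV", "LIPV", "RSPV", "RIPV")


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Binary mask of surface voxels: foreground with >=1 background 6-neighbor."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError(f"expected a 3D mask, got shape {mask.shape}")
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~interior


def _check_landmark_labels(landmarks: dict) -> None:
    if tuple(landmarks.keys()) != PV_LABELS:
        raise ValueError(
            f"PV landmarks must be exactly {PV_LABELS} in order, "
            f"got {tuple(landmarks.keys())}"
        )


@dataclass
class LAGeometry:
    """A left-atrium segmentation: binary voxel mask plus PV landmarks.

    Parameters
    ----------
    mask
        3D boolean array; foreground is the LA blood pool including the
        proximal pulmonary veins.
    spacing_mm
        Isotropic voxel edge length in millimetres.
    pv_landmarks
        Ordered mapping of the four PV labels to voxel coordinates
        (floating point, ``(i, j, k)``).  ``None`` for geometries that carry
        no landmarks (e.g. network predictions).
    origin
        World-space offset (mm) of the corner of voxel (0,0,0).
    """

    mask: np.ndarray
    spacing_mm: float
    pv_landmarks: dict[str, np.ndarray] | None = None
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.pv_landmarks is not None:
            self.pv_landmarks = {
                k: np.asarray(v, dtype=float) for k, v in self.pv_landmarks.items()
            }
            _check_landmark_labels(self.pv_landmarks)
        if self.spacing_mm <= 0:
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")

    # -- coordinate transforms -------------------------------------------------
    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + (np.asarray(idx, dtype=float) + 0.5) * self.spacing_mm

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinate of a world point (no rounding)."""
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing_mm - 0.5

    @property
    def landmarks_world(self) -> dict[str, np.ndarray]:
        if self.pv_landmarks is None:
            raise ValueError("geometry carries no PV landmarks")
        return {k: self.voxel_to_world(v) for k, v in self.pv_landmarks.items()}

    @property
    def surface(self) -> np.ndarray:
        return surface_voxels(self.mask)

    def validate(self) -> None:
        """Check the structural invariants of a usable ground-truth geometry."""
        if not self.mask.any():
            raise ValueError("mask is empty")
        structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
        _, n_components = ndimage.label(self.mask, structure=structure)
        if n_components != 1:
            raise ValueError(f"mask has {n_components} 26-connected components, expected 1")
        surf = np.argwhere(self.surface)
        for label, lm in (self.pv_landmarks or {}).items():
            d = np.min(np.linalg.norm(surf - lm, axis=1))
            if d > 2.0:
                raise ValueError(f"landmark {label} is {d:.2f} voxels from the surface (limit 2)")

    # -- I/O -------------------------------------------------------------------
    def save(self, volume_path: str | Path, landmarks_path: str | Path) -> None:
        import nibabel as nib

        affine = np.diag([self.spacing_mm] * 3 + [1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), affine), str(volume_path))
        rows = [
            {"label": k, **dict(zip("xyz", self.voxel_to_world(v)))}
            for k, v in (self.pv_landmarks or {}).items()
        ]
        pd.DataFrame(rows, columns=["label", "x", "y", "z"]).to_csv(landmarks_path, index=False)

    @classmethod
    def load(cls, volume_path: str | Path, landmarks_path: str | Path) -> "LAGeometry":
        import nibabel as nib

        img = nib.load(str(volume_path))
        zooms = img.header.get_zooms()[:3]
        if not np.allclose(zooms, zooms[0], atol=1e-6):
            raise ValueError(f"anisotropic spacing {zooms} not supported")
        origin = np.asarray(img.affine[:3, 3], dtype=float)
        spacing = float(zooms[0])
        mask = np.asarray(img.dataobj) > 0
        table = pd.read_csv(landmarks_path)
        landmarks = {}
        for label in PV_LABELS:
            row = table[table["label"] == label]
            if len(row) != 1:
                raise ValueError(f"landmark {label} missing or duplicated in {landmarks_path}")
            world = row[["x", "y", "z"]].to_numpy(dtype=float)[0]
            landmarks[label] = (world - origin) / spacing - 0.5
        return cls(mask=mask, spacing_mm=spacing, pv_landmarks=landmarks, origin=origin)


@dataclass
class PointCloud:
    """An endocardial point-cloud recording with labelled PV landmarks (mm)."""

    points: np.ndarray
    pv_landmarks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.pv_landmarks = {k: np.asarray(v, dtype=float) for k, v in self.pv_landmarks.items()}
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be N x 3, got shape {self.points.shape}")
        if len(self.points) < 4:
            raise ValueError(f"need at least 4 points, got {len(self.points)}")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points contain non-finite coordinates")
        _check_landmark_labels(self.pv_landmarks)

    @property
    def landmark_array(self) -> np.ndarray:
        """4 x 3 array of landmark coordinates in canonical PV order."""
        return np.stack([self.pv_landmarks[k] for k in PV_LABELS])

    def save(self, points_path: str | Path, landmarks_path: str | Path) -> None:
        pd.DataFrame(self.points, columns=["x", "y", "z"]).to_csv(points_path, index=False)
        rows = [{"label": k, **dict(zip("xyz", v))} for k, v in self.pv_landmarks.items()]
        pd.DataFrame(rows).to_csv(landmarks_path, index=False)

    @classmethod
    def load(cls, points_path: str | Path, landmarks_path: str | Path) -> "PointCloud":
        points = pd.read_csv(points_path)[["x", "y", "z"]].to_numpy(dtype=float)
        table = pd.read_csv(landmarks_path)
        landmarks = {
            label: table.loc[table["label"] == label, ["x", "y", "z"]].to_numpy(dtype=float)[0]
            for label in PV_LABELS
        }
        return cls(points=points, pv_landmarks=landmarks)


@dataclass
class PartialShell:
    """Thin voxelized partial LA surface — the network input volume."""

    volume: np.ndarray
    spacing_mm: float
    crop_origin: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=int))

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=bool)
        self.crop_origin = np.asarray(self.crop_origin, dtype=int)
        if self.spacing_mm <= 0:
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")

    def validate(self) -> None:
        frac = self.volume.mean()
        if frac >= 0.10:
            raise ValueError(f"foreground fraction {frac:.3f} is not shell-like (>= 0.10)")

    def save(self, path: str | Path) -> None:
        import nibabel as nib

        affine = np.diag([self.spacing_mm] * 3 + [1.0])
        affine[:3, 3] = self.crop_origin * self.spacing_mm
        nib.save(nib.Nifti1Image(self.volume.astype(np.uint8), affine), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "PartialShell":
        import nibabel as nib

        img = nib.load(str(path))
        spacing = float(img.header.get_zooms()[0])
        crop_origin = np.round(img.affine[:3, 3] / spacing).astype(int)
        return cls(volume=np.asarray(img.dataobj) > 0, spacing_mm=spacing, crop_origin=crop_origin)


@dataclass
class SurfaceMesh:
    """Triangle surface mesh (vertices in mm)."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges (E x 2, sorted vertex indices)."""
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [0, 2]]])
        return np.unique(np.sort(e, axis=1), axis=0)

    @property
    def area(self) -> float:
        v = self.vertices
        a = v[self.faces[:, 1]] - v[self.faces[:, 0]]
        b = v[self.faces[:, 2]] - v[self.faces[:, 0]]
        return float(0.5 * np.linalg.norm(np.cross(a, b), axis=1).sum())

    def save_ply(self, path: str | Path) -> None:
        import trimesh

        trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False).export(str(path))
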