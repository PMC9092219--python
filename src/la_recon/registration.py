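"""Landmark-based similarity registration of point clouds to image space.

A mapping-system point cloud lives in catheter coordinates; the target LA
segmentation lives in image (world, mm) coordinates.  Both carry the same
four labelled pulmonary-vein landmarks, which are matched *by label* and used
to estimate the least-squares similarity transform (rotation + translation +
one isotropic scale) taking cloud coordinates into image coordinates.

The estimator is the closed-form SVD solution for the orthogonal Procrustes
problem with scaling: center both landmark sets, take the SVD of their
cross-covariance to obtain the rotation (with a sign correction so that
det(R) = +1, i.e. reflections are never returned), and recover the scale from
the variance ratio.  This is the global optimum of the summed squared
landmark residuals for the similarity family.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .types import LAGeometry, PointCloud

__all__ = ["SimilarityTransform", "register_landmarks", "apply_transform"]


@dataclass
class SimilarityTransform:
    """x -> scale * R @ x + translation with R a proper rotation."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation has det -1 (reflection not allowed)")

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return self.scale * xyz @ self.rotation.T + self.translation

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return SimilarityTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.scale * self.rotation @ other.translation + self.translation,
            scale=self.scale * other.scale,
        )

    def inverse(self) -> "SimilarityTransform":
        r_inv = self.rotation.T
        return SimilarityTransform(
            rotation=r_inv,
            translation=-r_inv @ self.translation / self.scale,
            scale=1.0 / self.scale,
        )

    # -- serialization ---------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "rotation": [float(v) for v in self.rotation.ravel()],
                "translation": [float(v) for v in self.translation],
                "scale": float(self.scale),
            }
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "SimilarityTransform":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            rotation=np.asarray(d["rotation"], dtype=float).reshape(3, 3),
            translation=np.asarray(d["translation"], dtype=float),
            scale=float(d["scale"]),
        )


def estimate_similarity(source: np.ndarray, target: np.ndarray) -> SimilarityTransform:
    """Least-squares similarity transform mapping paired points source -> target.

    Closed-form solution (centering, SVD of the cross-covariance, scale from
    the variance ratio).  Raises if the source points are coincident or
    collinear, in which case the rotation is under-determined.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape or source.ndim != 2 or source.shape[1] != 3:
        raise ValueError(f"paired N x 3 arrays required, got {source.shape} and {target.shape}")
    n = len(source)
    if n < 3:
        raise ValueError("at least 3 correspondences required")

    mu_s = source.mean(axis=0)
    mu_t = target.mean(axis=0)
    xs = source - mu_s
    xt = target - mu_t

    var_s = (xs**2).sum() / n
    if var_s < 1e-12:
        raise ValueError("source landmarks are coincident; transform under-determined")

    cov = xt.T @ xs / n
    u, d, vt = np.linalg.svd(cov)
    # Collinear points: cross-covariance rank < 2 leaves a free rotation axis.
    if d[1] < 1e-9 * max(d[0], 1.0):
        raise ValueError("landmarks are collinear or coincident; rotation under-determined")

    s = np.eye(3)
    if np.linalg.det(u) * np.linalg.det(vt) < 0:
        s[2, 2] = -1.0
    rotation = u @ s @ vt
    scale = float(np.trace(np.diag(d) @ s) / var_s)
    if scale <= 0:
        raise ValueError("degenerate configuration produced non-positive scale")
    translation = mu_t - scale * rotation @ mu_s
    return SimilarityTransform(rotation=rotation, translation=translation, scale=scale)


def register_landmarks(source: PointCloud, target: LAGeometry) -> SimilarityTransform:
    """Similarity transform aligning the cloud's 4 PV landmarks to the image's.

    Correspondence is by PV label, never nearest-neighbour; the target
    landmarks are taken in world millimetres.
    """
    src = source.landmark_array
    tgt = np.stack([target.landmarks_world[k] for k in source.pv_landmarks])
    return estimate_similarity(src, tgt)


def apply_transform(pc: PointCloud, t: SimilarityTransform) -> PointCloud:
    """Apply a similarity transform to all points and landmarks of a cloud."""
    return PointCloud(
        points=t.apply(pc.points),
        pv_landmarks={k: t.apply(v) for k, v in pc.pv_landmarks.items()},
    )


def landmark_rms(source: PointCloud, target: LAGeometry, t: SimilarityTransform) -> float:
    """Root-mean-square residual of the transformed landmarks (mm)."""
    src = t.apply(source.landmark_array)
    tgt = np.stack([target.landmarks_world[k] for k in source.pv_landmarks])
    return float(np.sqrt(np.mean(np.sum((src - tgt) ** 2, axis=1))))
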