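"""Planar rigid transforms (rotation + translation + optional mirror flip).

Serial sections land on the array in an arbitrary orientation: each section may
be rotated, shifted and — if the tissue was flipped onto the array — mirrored
relative to its neighbours.  A :class:`RigidTransform2D` captures exactly these
degrees of freedom.  The mirror is taken about the vertical axis through the
pivot, applied *before* the rotation, so the linear part is ``R(theta) @ F``
with ``F = diag(-1, 1)`` when ``flip`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["RigidTransform2D"]

_FLIP = np.diag([-1.0, 1.0])


def _rotation_matrix(theta_deg: float) -> np.ndarray:
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class RigidTransform2D:
    """A planar rigid motion, optionally improper (mirrored).

    Parameters
    ----------
    theta : float
        Counter-clockwise rotation angle in degrees.
    tx, ty : float
        Translation in µm, applied after rotation about the pivot.
    flip : bool
        Mirror about the vertical axis through the pivot, before rotating.
    pivot : tuple of float
        Point (µm) the rotation (and mirror) is taken about.
    """

    theta: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    flip: bool = False
    pivot: tuple[float, float] = (0.0, 0.0)

    # -- matrix form ------------------------------------------------------

    @property
    def linear(self) -> np.ndarray:
        """The 2x2 linear part ``R(theta) @ F``; orthogonal, det = ±1."""
        rot = _rotation_matrix(self.theta)
        return rot @ _FLIP if self.flip else rot

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix mapping source to target coordinates."""
        lin = self.linear
        p = np.asarray(self.pivot, dtype=float)
        const = p + np.array([self.tx, self.ty]) - lin @ p
        out = np.eye(3)
        out[:2, :2] = lin
        out[:2, 2] = const
        return out

    @classmethod
    def from_matrix(
        cls, matrix: np.ndarray, pivot: tuple[float, float] = (0.0, 0.0)
    ) -> "RigidTransform2D":
        matrix = np.asarray(matrix, dtype=float)
        lin = matrix[:2, :2]
        det = np.linalg.det(lin)
        if not np.isclose(abs(det), 1.0, atol=1e-6):
            raise ValueError(f"linear part is not orthogonal (|det|={abs(det):.6f})")
        flip = det < 0
        rot = lin @ _FLIP if flip else lin
        theta = float(np.rad2deg(np.arctan2(rot[1, 0], rot[0, 0])))
        p = np.asarray(pivot, dtype=float)
        t = matrix[:2, 2] - p + lin @ p
        return cls(theta=theta, tx=float(t[0]), ty=float(t[1]), flip=bool(flip), pivot=tuple(p))

    # -- action -----------------------------------------------------------

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (n, 2) array of points (µm)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        m = self.matrix
        return pts @ m[:2, :2].T + m[:2, 2]

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Return the transform equivalent to applying *other* first, then self."""
        return RigidTransform2D.from_matrix(self.matrix @ other.matrix, pivot=self.pivot)

    def inverse(self) -> "RigidTransform2D":
        return RigidTransform2D.from_matrix(np.linalg.inv(self.matrix), pivot=self.pivot)

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.matrix, np.eye(3), atol=1e-9)

    @classmethod
    def identity(cls) -> "RigidTransform2D":
        return cls()

    def with_pivot(self, pivot: tuple[float, float]) -> "RigidTransform2D":
        """Re-express the same motion about a different pivot point."""
        return RigidTransform2D.from_matrix(self.matrix, pivot=pivot)

    # -- comparison helpers ------------------------------------------------

    def angle_error(self, other: "RigidTransform2D") -> float:
        """Rotation-angle difference in degrees, in [0, 180].

        Compares the proper-rotation parts; a flip mismatch is reported
        separately (see :func:`embryo3d.registration.registration_report`).
        """
        rel = self.linear @ np.linalg.inv(other.linear)
        if np.linalg.det(rel) < 0:  # flip mismatch: compare rotation magnitude only
            rel = rel @ _FLIP
        ang = abs(np.rad2deg(np.arctan2(rel[1, 0], rel[0, 0])))
        return float(min(ang % 360.0, 360.0 - ang % 360.0))

    def point_error(self, other: "RigidTransform2D", point: np.ndarray) -> float:
        """Displacement (µm) between the two images of *point*."""
        return float(np.linalg.norm(self.apply(point)[0] - other.apply(point)[0]))
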