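"""Rigid-body poses and superposition helpers shared across the package."""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["Pose", "kabsch", "rotation_about_axis", "screw_decompose"]


@dataclasses.dataclass(frozen=True)
class Pose:
    """A proper rigid transform ``x -> R x + t`` (rotation then translation, Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float).reshape(3, 3)
        t = np.asarray(self.translation, float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation matrix is not proper (det != +1)")

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def compose(self, other: "Pose") -> "Pose":
        """Return the pose equivalent to applying ``other`` first, then ``self``."""
        return Pose(self.rotation @ other.rotation,
                    self.rotation @ other.translation + self.translation)

    def inverse(self) -> "Pose":
        return Pose(self.rotation.T, -self.rotation.T @ self.translation)

    def as_flat(self) -> np.ndarray:
        """Row-major 3x4 matrix flattened to 12 floats (R | t)."""
        return np.hstack([self.rotation, self.translation[:, None]]).ravel()

    @classmethod
    def from_flat(cls, values: np.ndarray) -> "Pose":
        m = np.asarray(values, float).reshape(3, 4)
        return cls(m[:, :3], m[:, 3])


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about a unit axis.

    Positive angles rotate counter-clockwise when viewed down the +axis
    (looking from the axis tip toward the origin).
    """
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def kabsch(mobile: np.ndarray, target: np.ndarray,
           ) -> tuple[Pose, float]:
    """Least-squares superposition of ``mobile`` onto ``target``.

    Returns the proper rigid pose minimising RMSD and the residual RMSD (Å).
    Point correspondence is positional (row i to row i).
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return Pose(R, t), rmsd


def screw_decompose(pose: Pose) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Decompose a rigid transform into its screw parameters.

    Returns ``(axis, point_on_axis, angle_deg, rise)`` where ``axis`` is the
    unit rotation axis oriented so the rotation angle is in (0, 180], the
    signed ``rise`` is the translation component along the axis, and
    ``point_on_axis`` is the axis point closest to the origin. For a (near-)
    pure translation the axis is taken along the translation and the angle
    is 0.
    """
    R, t = pose.rotation, pose.translation
    cos_a = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = np.arccos(cos_a)
    if angle < 1e-9:  # pure translation
        norm = np.linalg.norm(t)
        axis = t / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
        return axis, np.zeros(3), 0.0, float(norm)
    if np.pi - angle < 1e-7:
        # 180 degrees: axis from the symmetric part of R
        M = (R + np.eye(3)) / 2.0
        axis = np.sqrt(np.clip(np.diag(M), 0, None))
        # fix signs from the largest component
        k = int(np.argmax(axis))
        signs = np.sign(M[k])
        signs[signs == 0] = 1.0
        axis = axis * signs * np.sign(axis[k] if axis[k] else 1.0)
    else:
        axis = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        axis = axis / (2.0 * np.sin(angle))
    axis = axis / np.linalg.norm(axis)
    rise = float(t @ axis)
    t_perp = t - rise * axis
    # solve (I - R) p = t_perp for the axis point (p orthogonal to axis)
    A = np.eye(3) - R
    p, *_ = np.linalg.lstsq(A, t_perp, rcond=None)
    p = p - (p @ axis) * axis
    return axis, p, float(np.rad2deg(angle)), rise
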