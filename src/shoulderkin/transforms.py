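"""Elementary rotations, homogeneous transforms, and Euler-sequence conversions.

All angles are radians inside the library; degrees appear only at file and
CLI boundaries.  Rotations are proper orthonormal 3x3 ``numpy`` arrays whose
columns are direction cosines of the rotated frame's axes; homogeneous
transforms are 4x4 arrays with last row (0, 0, 0, 1) and translations in mm.

Euler sequences are interpreted *intrinsically* (body-fixed axes), i.e. the
matrix is the left-to-right product of the elementary rotations as written:
``euler_to_matrix("YXZ", (a, b, c)) == rot_axis("y", a) @ rot_axis("x", b)
@ rot_axis("z", c)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation as _ScipyRotation

__all__ = [
    "EulerAngles",
    "GimbalLockError",
    "rot_axis",
    "trans_axis",
    "make_transform",
    "rotation_of",
    "translation_of",
    "invert_transform",
    "euler_to_matrix",
    "matrix_to_euler",
    "is_rotation",
    "assert_rotation",
]

_AXES = ("x", "y", "z")

#: Sequences with repeated first/last axis (middle angle singular at 0 and pi).
_SYMMETRIC = frozenset({"XYX", "XZX", "YXY", "YZY", "ZXZ", "ZYZ"})

#: Tolerance below which the middle angle counts as gimbal-locked (rad).
GIMBAL_TOL = 1e-8


class GimbalLockError(ValueError):
    """Raised only when a locked decomposition is explicitly disallowed."""


@dataclass(frozen=True)
class EulerAngles:
    """Three intrinsic Euler angles (radians) plus their sequence.

    ``gimbal_lock`` is set by :func:`matrix_to_euler` when the middle angle
    sits within :data:`GIMBAL_TOL` of a singular value, in which case the
    first and third angles are not individually determined (their sum or
    difference is).
    """

    sequence: str
    angles: tuple[float, float, float]
    gimbal_lock: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) != 3 or any(a not in "XYZ" for a in seq) or seq[0] == seq[1] or seq[1] == seq[2]:
            raise ValueError(f"unsupported Euler sequence {self.sequence!r}")
        object.__setattr__(self, "sequence", seq)
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("Euler angles must be finite")

    @property
    def degrees(self) -> tuple[float, float, float]:
        return tuple(np.degrees(self.angles))


def rot_axis(axis: str, angle: float) -> np.ndarray:
    """Proper rotation about a principal axis, right-hand rule."""
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {_AXES}, got {axis!r}")
    c, s = np.cos(angle), np.sin(angle)
    if axis == "x":
        return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
    if axis == "y":
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def trans_axis(axis: str, distance: float) -> np.ndarray:
    """Pure translation along a principal axis as a homogeneous transform."""
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {_AXES}, got {axis!r}")
    T = np.eye(4)
    T[_AXES.index(axis), 3] = distance
    return T


def make_transform(rotation: np.ndarray, translation) -> np.ndarray:
    T = np.eye(4)
    T[:3, :3] = rotation
    T[:3, 3] = np.asarray(translation, dtype=float)
    return T


def rotation_of(T: np.ndarray) -> np.ndarray:
    return np.asarray(T)[:3, :3]


def translation_of(T: np.ndarray) -> np.ndarray:
    return np.asarray(T)[:3, 3]


def invert_transform(T: np.ndarray) -> np.ndarray:
    """Closed-form inverse of a rigid transform (R^T, -R^T t)."""
    R = rotation_of(T)
    return make_transform(R.T, -R.T @ translation_of(T))


def euler_to_matrix(e: EulerAngles | tuple, sequence: str | None = None) -> np.ndarray:
    """Intrinsic Euler angles to a rotation matrix.

    Accepts either an :class:`EulerAngles` or ``(angles, sequence)``.
    The result is the literal product of elementary rotations in the
    written order.
    """
    if not isinstance(e, EulerAngles):
        if sequence is None:
            raise TypeError("sequence required when angles are given as a tuple")
        e = EulerAngles(sequence, tuple(float(a) for a in e))
    a, b, c = e.angles
    s = e.sequence.lower()
    return rot_axis(s[0], a) @ rot_axis(s[1], b) @ rot_axis(s[2], c)


def matrix_to_euler(
    R: np.ndarray,
    sequence: str,
    prev: EulerAngles | None = None,
    tol: float = 1e-6,
) -> EulerAngles:
    """Decompose a proper rotation into intrinsic Euler angles.

    Principal branch: middle angle in [0, pi] for symmetric sequences
    (e.g. YXY, ZXZ) and [-pi/2, pi/2] for asymmetric ones (e.g. YXZ).
    When ``prev`` is given, each returned angle is shifted by multiples of
    2*pi toward the previous sample so that frame-by-frame decomposition of
    a trajectory stays continuous.

    At gimbal lock the first angle is set so the product still reproduces
    ``R`` and ``gimbal_lock`` is flagged.
    """
    seq = sequence.upper()
    assert_rotation(R, tol=tol)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns at lock; we flag instead
        angles = _ScipyRotation.from_matrix(R).as_euler(seq)
    mid = angles[1]
    if seq in _SYMMETRIC:
        locked = min(abs(mid), abs(mid - np.pi)) < GIMBAL_TOL
    else:
        locked = abs(abs(mid) - np.pi / 2) < GIMBAL_TOL
    if prev is not None:
        if prev.sequence != seq:
            raise ValueError("prev must use the same sequence")
        angles = [
            a + 2 * np.pi * np.round((p - a) / (2 * np.pi))
            for a, p in zip(angles, prev.angles)
        ]
    return EulerAngles(seq, tuple(float(a) for a in angles), gimbal_lock=bool(locked))


def is_rotation(R: np.ndarray, tol: float = 1e-12) -> bool:
    R = np.asarray(R)
    if R.shape != (3, 3):
        return False
    return (
        np.allclose(R.T @ R, np.eye(3), atol=tol)
        and abs(np.linalg.det(R) - 1.0) < max(tol, 1e-12) * 10
    )


def assert_rotation(R: np.ndarray, tol: float = 1e-9) -> None:
    if not is_rotation(R, tol=tol):
        raise ValueError("matrix is not a proper rotation (R^T R = I, det = +1)")
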