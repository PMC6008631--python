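"""Turn measured (or synthetic) posture data into the solver's three inputs.

Two independent measurements drive the girdle solve:

* the ISB clavicle posture (YXZ Euler angles ClavY, ClavX, ClavZ of the
  clavicle relative to the thorax), which yields the SC-joint angles
  (theta1, theta2); and
* the thorax-frame positions of the SC and AI bony landmarks, which yield
  the azimuth psi_d of the scapula's inferior contact point: AI generally
  floats just off the rib cage, so it is projected through the ellipsoid
  centre onto the surface and the azimuth of that central projection is
  read off.

Singular rows (clavicle along the global z-axis, AI at the centre) are
flagged, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .girdle_kinematics import GirdleInputs
from .model_geometry import FrameAlignment, ThoraxEllipsoid, alignment_matrices
from .transforms import euler_to_matrix, invert_transform, make_transform

__all__ = [
    "ClavPosture",
    "ThoraxAnchors",
    "ExtractedInputs",
    "clav_angles",
    "build_T0t",
    "build_T3t",
    "ai_to_ellipsoid_frame",
    "project_ai",
    "extract_inputs",
    "extract_table",
]

#: |sin(theta2)| below which theta1 is undetermined.
DEGENERATE_TOL = 1e-8


@dataclass(frozen=True)
class ClavPosture:
    """ISB clavicle-vs-thorax YXZ Euler angles, degrees."""

    clav_y: float
    clav_x: float
    clav_z: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.clav_y, self.clav_x, self.clav_z])):
            raise ValueError("clavicle angles must be finite")

    def rotation(self) -> np.ndarray:
        return euler_to_matrix(
            np.radians([self.clav_y, self.clav_x, self.clav_z]), "YXZ"
        )


@dataclass(frozen=True)
class ThoraxAnchors:
    """SC and AI landmark positions, thorax-ISB frame, mm."""

    p_sc: np.ndarray
    p_ai: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "p_sc", np.asarray(self.p_sc, dtype=float))
        object.__setattr__(self, "p_ai", np.asarray(self.p_ai, dtype=float))
        if not (np.all(np.isfinite(self.p_sc)) and np.all(np.isfinite(self.p_ai))):
            raise ValueError("anchor positions must be finite")


def clav_angles(
    cp: ClavPosture, alignment: FrameAlignment | None = None
) -> tuple[float, float, bool]:
    """SC-joint angles (theta1, theta2) from the ISB clavicle posture.

    Builds Rct (YXZ product), maps it into the computation frames as
    R10 = R0t^T Rct R1c, and reads the third column, whose rows correspond
    to (wz, wx, wy).  With the clavicle chain R10 = Rz(t1) Rx(t2) Rz(0),
    that column is (sin t1 sin t2, -cos t1 sin t2, cos t2), so

        theta2 = atan2(hypot(wz, wx), wy)   in [0, pi]
        theta1 = atan2(wz, -wx)

    which satisfies all three scalar relations simultaneously (the
    quadrant-aware resolution of the single-argument arctangent forms).
    Returns ``(theta1, theta2, degenerate)``; when sin(theta2) ~ 0 the
    clavicle lies along the global z-axis, theta1 is undetermined and is
    returned as 0 with the flag set.
    """
    al = alignment or alignment_matrices(warn=False)
    R10 = al.R0t.T @ cp.rotation() @ al.R1c
    w = R10[:, 2]
    wz, wx, wy = w[0], w[1], w[2]
    s2 = float(np.hypot(wz, wx))
    theta2 = float(np.arctan2(s2, wy))
    if s2 < DEGENERATE_TOL:
        return 0.0, theta2, True
    theta1 = float(np.arctan2(wz, -wx))
    return theta1, theta2, False


def build_T0t(p_sc, alignment: FrameAlignment | None = None) -> np.ndarray:
    """Homogeneous S0 -> thorax transform: rotation R0t, translation p_sc."""
    al = alignment or alignment_matrices(warn=False)
    return make_transform(al.R0t, p_sc)


def build_T3t(
    p_sc,
    ellipsoid_center_thorax,
    alignment: FrameAlignment | None = None,
) -> np.ndarray:
    """Homogeneous S3 (ellipsoid) -> thorax transform.

    Composed as T0t @ T30 where T30 is the pure translation to the
    ellipsoid centre in S0; the result has rotation R0t and translation
    equal to the ellipsoid centre in thorax coordinates.
    """
    al = alignment or alignment_matrices(warn=False)
    T0t = build_T0t(p_sc, al)
    center_thorax = np.asarray(ellipsoid_center_thorax, dtype=float)
    center_s0 = al.R0t.T @ (center_thorax - np.asarray(p_sc, dtype=float))
    T30 = make_transform(np.eye(3), center_s0)
    return T0t @ T30


def ai_to_ellipsoid_frame(p_ai, T3t: np.ndarray) -> np.ndarray:
    """AI landmark expressed in the ellipsoid frame S3: T3t^-1 @ p_AI."""
    return (invert_transform(T3t) @ np.append(np.asarray(p_ai, dtype=float), 1.0))[:3]


def project_ai(p_ai3, e: ThoraxEllipsoid) -> tuple[np.ndarray, float]:
    """Central projection of AI onto the ellipsoid and its azimuth psi_d.

    The ray from the ellipsoid centre through AI meets the surface at the
    equivalent contact point d.  The azimuth is quadrant-aware:
    psi_d = atan2(m * y_AI, n * x_AI), invariant to radial scaling of AI.
    """
    q = np.asarray(p_ai3, dtype=float)
    r = float(np.linalg.norm(q / e.semi_axes))
    if r == 0.0:
        raise ValueError("AI coincides with the ellipsoid centre; no projection")
    d_point = q / r
    psi_d = float(np.arctan2(e.m * q[1], e.n * q[0]))
    return d_point, psi_d


@dataclass(frozen=True)
class ExtractedInputs:
    """Solver inputs for one frame, with degeneracy flags."""

    inputs: GirdleInputs
    degenerate_clavicle: bool = False
    d_point: np.ndarray | None = None  # equivalent contact point, S3 frame


def extract_inputs(
    cp: ClavPosture,
    anchors: ThoraxAnchors,
    e: ThoraxEllipsoid,
    alignment: FrameAlignment | None = None,
) -> ExtractedInputs:
    """One frame of posture data -> (theta1, theta2, psi_d).

    The ellipsoid centre must be known in thorax coordinates; if ``e``
    stores it in S0 it is converted through the SC anchor.
    """
    al = alignment or alignment_matrices(warn=False)
    theta1, theta2, degenerate = clav_angles(cp, al)
    if e.center_frame == "thorax":
        center_thorax = e.center
    else:
        center_thorax = al.R0t @ e.center + anchors.p_sc
    T3t = build_T3t(anchors.p_sc, center_thorax, al)
    p_ai3 = ai_to_ellipsoid_frame(anchors.p_ai, T3t)
    d_point, psi_d = project_ai(p_ai3, e)
    return ExtractedInputs(
        inputs=GirdleInputs(theta1=theta1, theta2=theta2, psi_d=psi_d),
        degenerate_clavicle=degenerate,
        d_point=d_point,
    )


def extract_table(df, e: ThoraxEllipsoid, alignment: FrameAlignment | None = None):
    """Batch extraction over a trajectory table.

    ``df`` follows the shared trajectory CSV schema (columns ``t_s``,
    ``ClavY_deg`` .. ``AI_z_mm``).  Returns a ``pandas.DataFrame`` with
    columns ``t_s, theta1_deg, theta2_deg, psi_d_deg, degenerate`` in row
    order; degenerate rows are flagged, not dropped.
    """
    import pandas as pd

    al = alignment or alignment_matrices(warn=False)
    out = {"t_s": [], "theta1_deg": [], "theta2_deg": [], "psi_d_deg": [], "degenerate": []}
    for row in df.itertuples(index=False):
        cp = ClavPosture(row.ClavY_deg, row.ClavX_deg, row.ClavZ_deg)
        anchors = ThoraxAnchors(
            p_sc=(row.SC_x_mm, row.SC_y_mm, row.SC_z_mm),
            p_ai=(row.AI_x_mm, row.AI_y_mm, row.AI_z_mm),
        )
        ext = extract_inputs(cp, anchors, e, al)
        out["t_s"].append(row.t_s)
        out["theta1_deg"].append(np.degrees(ext.inputs.theta1))
        out["theta2_deg"].append(np.degrees(ext.inputs.theta2))
        out["psi_d_deg"].append(np.degrees(ext.inputs.psi_d))
        out["degenerate"].append(ext.degenerate_clavicle)
    return pd.DataFrame(out)
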