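"""Constant geometry of the shoulder-girdle skeleton model.

The girdle is a closed chain thorax -> clavicle -> scapula -> thorax.  The
computation frames are

* ``S0`` — global frame at the sternoclavicular (SC) joint, axes parallel to
  the intersections of the anatomical planes (x lateral, y anterior,
  z superior);
* ``S1`` — clavicle frame (z1 along the clavicle axis);
* ``S2`` — scapula frame at the acromioclavicular (AC) joint;
* ``S3`` — ellipsoid frame, axes parallel to ``S0``, origin at the centre of
  the ellipsoid approximating the rib cage;
* ``S4`` — humerus frame at the glenohumeral (GH) centre.

Constant alignment rotations map these onto the ISB-recommended bone frames
St (thorax), Sc (clavicle), Ss (scapula), Sh (humerus).

Link lengths, the thorax-ellipsoid semi-axes, and the bony-landmark tables
for the generic (cadaver-derived) skeleton and the test subject are stored
here; lengths in mm, angles in degrees in the tables and radians in code.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .transforms import is_rotation

__all__ = [
    "GirdleGeometry",
    "ThoraxEllipsoid",
    "FrameAlignment",
    "LandmarkSet",
    "default_geometry",
    "ellipsoid_point",
    "scapula_points",
    "alignment_matrices",
    "load_geometry_config",
    "save_geometry_config",
]


@dataclass(frozen=True)
class GirdleGeometry:
    """Link lengths (mm) and the scapula edge angle gamma (radians).

    ``l1``: SC->AC clavicle length; ``l2``: AC->c and ``l3``: AC->d scapula
    edges (c, d are the two points gliding on the thorax ellipsoid);
    ``l4``: humerus length GH->elbow midpoint; ``gamma``: angle between
    AC->c and AC->d.  ``l22`` is carried from the source size table; it
    equals the c-d chord implied by (l2, l3, gamma) and is used only as a
    consistency check.
    """

    l1: float
    l2: float
    l3: float
    l4: float
    gamma: float
    l22: float | None = None

    def __post_init__(self) -> None:
        for name in ("l1", "l2", "l3", "l4"):
            if not getattr(self, name) > 0:
                raise ValueError(f"link length {name} must be positive")
        if not 0 < self.gamma < np.pi:
            raise ValueError("gamma must lie strictly between 0 and 180 degrees")

    @property
    def cd_chord(self) -> float:
        """Distance |c - d| from the law of cosines on (l2, l3, gamma)."""
        return float(
            np.sqrt(self.l2**2 + self.l3**2 - 2 * self.l2 * self.l3 * np.cos(self.gamma))
        )


@dataclass(frozen=True)
class ThoraxEllipsoid:
    """Thorax ellipsoid: semi-axes m, n, p (mm) along S3 x, y, z.

    ``center`` is the ellipsoid centre, tagged with the frame it is
    expressed in (``"S0"`` or ``"thorax"`` for the ISB thorax frame).
    """

    m: float
    n: float
    p: float
    center: np.ndarray
    center_frame: str = "S0"

    def __post_init__(self) -> None:
        if not (self.m > 0 and self.n > 0 and self.p > 0):
            raise ValueError("ellipsoid semi-axes must be positive")
        if self.center_frame not in ("S0", "thorax"):
            raise ValueError(f"unknown center frame {self.center_frame!r}")
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))

    @property
    def semi_axes(self) -> np.ndarray:
        return np.array([self.m, self.n, self.p])

    def center_in_s0(self, p_sc: np.ndarray | None = None) -> np.ndarray:
        """Ellipsoid centre in S0.

        If the centre is stored in thorax-ISB coordinates the SC landmark
        position ``p_sc`` (thorax frame) is required:
        c_0 = R0t^T (c_t - p_sc).
        """
        if self.center_frame == "S0":
            return self.center.copy()
        if p_sc is None:
            raise ValueError("p_sc required to convert a thorax-frame centre to S0")
        return R0T.T @ (self.center - np.asarray(p_sc, dtype=float))

    def implicit(self, point: np.ndarray) -> float:
        """(x/m)^2 + (y/n)^2 + (z/p)^2 - 1 for a point in S3 coordinates."""
        q = np.asarray(point, dtype=float) / self.semi_axes
        return float(q @ q - 1.0)


# Frame-alignment constants: R0t maps S0 coordinates to thorax-ISB
# coordinates (p_t = R0t p_0), and likewise R1c, R2s, R4h for the clavicle,
# scapula and humerus bone frames.
R0T = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
R1C = np.eye(3)
R2S = np.array(
    [
        [0.9599, 0.0373, -0.2778],
        [-0.0131, -0.9841, -0.1773],
        [-0.2800, -0.1738, -0.9441],
    ]
)
R4H = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])


@dataclass(frozen=True)
class FrameAlignment:
    """Constant rotations aligning computation frames with ISB bone frames."""

    R0t: np.ndarray = field(default_factory=lambda: R0T.copy())
    R1c: np.ndarray = field(default_factory=lambda: R1C.copy())
    R2s: np.ndarray = field(default_factory=lambda: R2S.copy())
    R4h: np.ndarray = field(default_factory=lambda: R4H.copy())


_LANDMARK_NAMES = ("IJ", "PX", "C7", "T8", "AA", "TS", "AI", "AC", "SC")


@dataclass(frozen=True)
class LandmarkSet:
    """Bony-landmark positions in the thorax-ISB frame (mm)."""

    points: dict

    def __post_init__(self) -> None:
        pts = {k: np.asarray(v, dtype=float) for k, v in self.points.items()}
        if "SC" not in pts:
            raise ValueError("LandmarkSet requires the SC landmark")
        for name, v in pts.items():
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"landmark {name} must be a finite 3-vector")
        object.__setattr__(self, "points", pts)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]


# Generic skeleton: link sizes and thorax ellipsoid (centre in S0).
_GARNER_LINKS = GirdleGeometry(
    l1=154.17, l2=120.71, l3=187.21, l4=301.56, gamma=np.radians(33.8), l22=109.83
)
_GARNER_ELLIPSOID = ThoraxEllipsoid(
    m=76.85, n=97.17, p=217.44, center=(28.12, -43.90, -164.51), center_frame="S0"
)

# Landmark tables (thorax-ISB frame, mm): generic cadaver-derived skeleton
# and the test subject.
_LANDMARKS_COMMON = {
    "IJ": (0.0, 0.0, 0.0),
    "PX": (31.9, -132.7, -9.8),
    "C7": (-124.2, 54.1, 0.0),
    "T8": (-156.61, -171.5, 0.0),
    "AA": (-105.6, 7.5, 182.6),
    "TS": (-156.0, -11.7, 75.0),
    "AI": (-156.7, -126.2, 101.9),
    "AC": (-71.8, 26.6, 165.1),
    "SC": (-2.8, -15.2, 1.4),
}
_LANDMARKS_SUBJECT = {
    "IJ": (0.0, 0.0, 0.0),
    "PX": (56.0, -163.0, -2.4),
    "C7": (-123.1, 80.7, -4.7),
    "T8": (-179.1, -133.2, 11.2),
    "AA": (-73.5, 9.3, 205.1),
    "TS": (-136.3, 5.1, 121.8),
    "AI": (-141.6, -126.5, 116.2),
    "AC": (-37.0, 40.4, 167.2),
    "SC": (15.3, -31.0, -6.6),
}

# Subject ellipsoid: the size table lists centre and semi-axes in
# thorax-frame axis order (x_t, y_t, z_t); semi-axes map to the ellipsoid
# frame (S3, parallel to S0) through R0t as (m, n, p) = (a_zt, a_xt, a_yt).
_SUBJECT_SEMIAXES_THORAX = (114.4, 222.7, 164.8)
_SUBJECT_ELLIPSOID = ThoraxEllipsoid(
    m=_SUBJECT_SEMIAXES_THORAX[2],
    n=_SUBJECT_SEMIAXES_THORAX[0],
    p=_SUBJECT_SEMIAXES_THORAX[1],
    center=(-61.6, -148.1, 0.0),
    center_frame="thorax",
)

#: Subject "zoom factor" row from the size table; metadata only, unused.
SUBJECT_ZOOM_FACTOR = (1.20, 1.05, 1.14)

#: GH-joint centre in the scapula frame S2 as printed; source does not state
#: its units (inconsistent with mm elsewhere), so it is stored untouched.
GH_CENTER_S2_UNIT_UNKNOWN = np.array([-0.294, 3.713, 3.41])


def default_geometry(source: str = "garner"):
    """Built-in geometry sets.

    ``"garner"`` — generic skeleton link sizes + generic thorax ellipsoid
    (centre in S0) + generic landmark table.  ``"subject_s1"`` — the same
    link sizes with the test subject's ellipsoid (centre in thorax frame)
    and landmark table.

    Returns ``(GirdleGeometry, ThoraxEllipsoid, LandmarkSet)``.
    """
    if source == "garner":
        return _GARNER_LINKS, _GARNER_ELLIPSOID, LandmarkSet(dict(_LANDMARKS_COMMON))
    if source == "subject_s1":
        return _GARNER_LINKS, _SUBJECT_ELLIPSOID, LandmarkSet(dict(_LANDMARKS_SUBJECT))
    raise ValueError(f"unknown geometry source {source!r}; use 'garner' or 'subject_s1'")


def ellipsoid_point(phi: float, psi: float, e: ThoraxEllipsoid) -> np.ndarray:
    """Surface point of the ellipsoid in S3 coordinates.

    ``phi`` is the polar angle from the +z axis, ``psi`` the azimuth in the
    x-y plane: (m sin(phi) cos(psi), n sin(phi) sin(psi), p cos(phi)).
    """
    sphi = np.sin(phi)
    return np.array([e.m * sphi * np.cos(psi), e.n * sphi * np.sin(psi), e.p * np.cos(phi)])


def surface_params(point_s3: np.ndarray, e: ThoraxEllipsoid) -> tuple[float, float]:
    """Inverse of :func:`ellipsoid_point` for a point on (or off) the surface.

    Returns (phi, psi) of the central projection of ``point_s3`` onto the
    surface; phi in [0, pi].
    """
    q = np.asarray(point_s3, dtype=float)
    r = np.linalg.norm(q / e.semi_axes)
    if r == 0:
        raise ValueError("point at the ellipsoid centre has no surface parameters")
    s = q / r  # central projection onto the surface
    phi = float(np.arccos(np.clip(s[2] / e.p, -1.0, 1.0)))
    psi = float(np.arctan2(e.m * s[1], e.n * s[0]))
    return phi, psi


def scapula_points(g: GirdleGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Contact points c and d in the scapula frame S2.

    c lies on the z2 axis at distance l2 from the AC joint; d lies in the
    y2-z2 plane at distance l3, separated from c by the angle gamma.
    """
    pc2 = np.array([0.0, 0.0, g.l2])
    pd2 = np.array([0.0, g.l3 * np.sin(g.gamma), g.l3 * np.cos(g.gamma)])
    return pc2, pd2


def alignment_matrices(orthonormalize_r2s: bool = False, warn: bool = True) -> FrameAlignment:
    """The four constant computation-frame -> ISB-frame rotations.

    The scapula alignment R2s is published in a visibly non-orthogonal form
    (det ~ 0.94; one pair of rows is ~20 degrees from orthogonal, most
    plausibly a sign misprint).  By default it is used as printed (with a
    warning); ``orthonormalize_r2s=True`` replaces it with the nearest
    proper rotation (SVD projection).
    """
    r2s = R2S.copy()
    if orthonormalize_r2s:
        U, _, Vt = np.linalg.svd(r2s)
        r2s = U @ Vt
        if np.linalg.det(r2s) < 0:
            U[:, -1] *= -1
            r2s = U @ Vt
    elif warn and not is_rotation(r2s, tol=1e-6):
        warnings.warn(
            "R2s used as printed; orthonormal only to ~1e-3 "
            "(pass orthonormalize_r2s=True for the nearest rotation)",
            stacklevel=2,
        )
    return FrameAlignment(R2s=r2s)


# ---------------------------------------------------------------------------
# Geometry configuration files (YAML or JSON)

def _geometry_to_dict(g: GirdleGeometry, e: ThoraxEllipsoid, lm: LandmarkSet) -> dict:
    return {
        "links": {
            "l1": g.l1,
            "l2": g.l2,
            "l3": g.l3,
            "l4": g.l4,
            "l22": g.l22,
            "gamma_deg": float(np.degrees(g.gamma)),
        },
        "ellipsoid": {
            "m": e.m,
            "n": e.n,
            "p": e.p,
            "center": [float(x) for x in e.center],
            "center_frame": e.center_frame,
        },
        "landmarks": {k: [float(x) for x in v] for k, v in lm.points.items()},
    }


def save_geometry_config(path, g: GirdleGeometry, e: ThoraxEllipsoid, lm: LandmarkSet) -> None:
    path = Path(path)
    payload = _geometry_to_dict(g, e, lm)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def load_geometry_config(path):
    """Load and validate a geometry config; errors name the offending key."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    for section in ("links", "ellipsoid", "landmarks"):
        if section not in raw:
            raise ValueError(f"geometry config missing section {section!r}")
    links = raw["links"]
    for key in ("l1", "l2", "l3", "l4", "gamma_deg"):
        if key not in links:
            raise ValueError(f"geometry config missing key links.{key}")
        if not np.isfinite(links[key]):
            raise ValueError(f"geometry config key links.{key} is not finite")
    try:
        g = GirdleGeometry(
            l1=links["l1"],
            l2=links["l2"],
            l3=links["l3"],
            l4=links["l4"],
            gamma=np.radians(links["gamma_deg"]),
            l22=links.get("l22"),
        )
    except ValueError as err:
        raise ValueError(f"geometry config links: {err}") from err
    ell = raw["ellipsoid"]
    for key in ("m", "n", "p", "center"):
        if key not in ell:
            raise ValueError(f"geometry config missing key ellipsoid.{key}")
    try:
        e = ThoraxEllipsoid(
            m=ell["m"],
            n=ell["n"],
            p=ell["p"],
            center=ell["center"],
            center_frame=ell.get("center_frame", "S0"),
        )
    except ValueError as err:
        raise ValueError(f"geometry config ellipsoid: {err}") from err
    try:
        lm = LandmarkSet(raw["landmarks"])
    except ValueError as err:
        raise ValueError(f"geometry config landmarks: {err}") from err
    return g, e, lm
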