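"""Shared fixtures and the independent feasible-state constructor.

The constructor in :func:`make_feasible_state` builds closed-loop girdle
configurations *geometrically* — place the contact point d on the ellipsoid,
intersect spheres for the AC joint b and the second contact point c, and
read the joint angles off the resulting frames — using only numpy/scipy
primitives (scipy's Euler machinery, not the package's).  It serves as a
forward-construction oracle: states it returns must close the loop, and the
package's inverse solver must recover them from their three inputs.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation as ScipyRotation

from shoulderkin.girdle_kinematics import JointState
from shoulderkin.model_geometry import default_geometry


@pytest.fixture(scope="session")
def garner_geometry():
    return default_geometry("garner")


@pytest.fixture(scope="session")
def subject_geometry():
    return default_geometry("subject_s1")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240817)


def _ellipsoid_surface(phi, psi, axes):
    m, n, p = axes
    return np.array([m * np.sin(phi) * np.cos(psi), n * np.sin(phi) * np.sin(psi), p * np.cos(phi)])


def make_feasible_state(g, e, rng, max_tries: int = 200):
    """Construct a random closed-loop girdle state by pure geometry.

    Returns ``(JointState, dict)`` where the dict carries the constructed
    b, c, d positions in S0 for independent checks.  Sampling is confined
    to the anatomical neighbourhood (d inferolateral on the thorax, scapula
    below the clavicle); draws that do not assemble are rejected.
    """
    axes = e.semi_axes
    center = e.center_in_s0() if e.center_frame == "S0" else None
    assert center is not None, "use a geometry whose ellipsoid centre is in S0"
    for _ in range(max_tries):
        phi_d = rng.uniform(np.radians(70.0), np.radians(100.0))
        psi_d = rng.uniform(np.radians(-60.0), np.radians(-20.0))
        d = center + _ellipsoid_surface(phi_d, psi_d, axes)
        # AC joint b: |b| = l1 (SC at the origin), |b - d| = l3.
        L = np.linalg.norm(d)
        a = (g.l1**2 - g.l3**2 + L**2) / (2.0 * L)
        if g.l1**2 - a**2 <= 1.0:
            continue
        rho = np.sqrt(g.l1**2 - a**2)
        u = d / L
        v = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(v) < 1e-9:
            continue
        v /= np.linalg.norm(v)
        w = np.cross(u, v)
        alpha = np.arctan2(w[2], v[2])  # superior-most point of the circle
        b = a * u + rho * (np.cos(alpha) * v + np.sin(alpha) * w)
        sin_theta2 = np.hypot(b[0], b[1]) / g.l1
        if sin_theta2 < 0.2:
            continue
        # c: on the circle |c-b| = l2, angle(c-b, d-b) = gamma, and on the
        # ellipsoid surface.
        ubd = (d - b) / np.linalg.norm(d - b)
        v2 = np.cross(ubd, [0.0, 0.0, 1.0])
        if np.linalg.norm(v2) < 1e-9:
            continue
        v2 /= np.linalg.norm(v2)
        w2 = np.cross(ubd, v2)
        cc = b + g.l2 * np.cos(g.gamma) * ubd
        r2 = g.l2 * np.sin(g.gamma)

        def implicit(t):
            c = cc + r2 * (np.cos(t) * v2 + np.sin(t) * w2)
            q = (c - center) / axes
            return q @ q - 1.0

        ts = np.linspace(0.0, 2.0 * np.pi, 181)
        vals = np.array([implicit(t) for t in ts])
        crossings = np.nonzero(vals[:-1] * vals[1:] < 0.0)[0]
        if crossings.size == 0:
            continue
        # Prefer the superior root (c sits above d on the scapula).
        best = None
        for i in crossings:
            t_root = brentq(implicit, ts[i], ts[i + 1], xtol=1e-15)
            c = cc + r2 * (np.cos(t_root) * v2 + np.sin(t_root) * w2)
            if best is None or c[2] > best[2]:
                best = c
        c = best

        theta2 = float(np.arccos(np.clip(b[2] / g.l1, -1.0, 1.0)))
        theta1 = float(np.arctan2(b[0], -b[1]))
        R10 = ScipyRotation.from_euler("ZXZ", [theta1, theta2, 0.0]).as_matrix()
        z2 = (c - b) / np.linalg.norm(c - b)
        y2 = (d - b) - ((d - b) @ z2) * z2
        y2 /= np.linalg.norm(y2)
        x2 = np.cross(y2, z2)
        R20 = np.column_stack([x2, y2, z2])
        t4, t5, t6 = ScipyRotation.from_matrix(R10.T @ R20).as_euler("YXY")
        cs = c - center
        phi_c = float(np.arccos(np.clip(cs[2] / axes[2], -1.0, 1.0)))
        psi_c = float(np.arctan2(axes[0] * cs[1], axes[1] * cs[0]))
        state = JointState(
            theta1=theta1,
            theta2=theta2,
            theta4=float(t4),
            theta5=float(t5),
            theta6=float(t6),
            phi_c=phi_c,
            psi_c=psi_c,
            phi_d=phi_d,
            psi_d=psi_d,
        )
        return state, {"b": b, "c": c, "d": d, "center": center}
    raise RuntimeError("could not construct a feasible girdle state")


@pytest.fixture()
def feasible_state(garner_geometry, rng):
    g, e, _ = garner_geometry
    return make_feasible_state(g, e, rng)
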