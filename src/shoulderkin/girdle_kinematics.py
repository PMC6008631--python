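"""Closed-chain kinematics of the shoulder girdle.

The girdle (thorax - clavicle - scapula) forms a closed loop: the clavicle
rotates about the SC joint (spherical, angles theta1..theta3), the scapula
about the AC joint (spherical, theta4..theta6), and two scapular points c
and d glide on the thorax ellipsoid (scapulothoracic contact, a 4-DoF
cylinder-plane pair).  Requiring c and d to lie on the ellipsoid yields six
scalar constraints in ten joint variables (theta1..theta6 plus the surface
parameters phi_c, psi_c, phi_d, psi_d); with the clavicle axial rotation
theta3 fixed at zero, three independent inputs determine the assembly.

The inverse position problem — given (theta1, theta2, psi_d), find
(theta4, theta5, theta6, phi_c, psi_c, phi_d) — is solved by a damped
Newton iteration with a finite-difference Jacobian and a Levenberg-style
fallback, warm-started frame to frame along trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_geometry import (
    FrameAlignment,
    GirdleGeometry,
    ThoraxEllipsoid,
    alignment_matrices,
    ellipsoid_point,
    scapula_points,
    surface_params,
)
from .transforms import (
    EulerAngles,
    make_transform,
    matrix_to_euler,
    rot_axis,
    rotation_of,
    trans_axis,
)

__all__ = [
    "JointState",
    "GirdleInputs",
    "HumerusPose",
    "SolverSettings",
    "SolvedFrame",
    "ConvergenceError",
    "mobility",
    "forward_chain",
    "constraint_residual",
    "solve_girdle",
    "solve_trajectory",
    "humerus_transform",
    "scapula_isb_posture",
]


def mobility(n_links: int, joint_dofs) -> int:
    """Kutzbach-Grubler mobility M = 6(n - g - 1) + sum(f_i).

    ``n_links`` counts the mechanism components (the ground/thorax
    included), ``joint_dofs`` lists the relative freedom of each joint
    (1..5; the scapulothoracic two-point contact counts as a single 4-DoF
    cylinder-plane pair).
    """
    if n_links < 1:
        raise ValueError("n_links must be >= 1")
    dofs = list(joint_dofs)
    if any(not 1 <= f <= 5 for f in dofs):
        raise ValueError("each joint freedom must be between 1 and 5")
    g = len(dofs)
    return 6 * (n_links - g - 1) + sum(dofs)


@dataclass(frozen=True)
class JointState:
    """The ten girdle joint variables (radians).

    theta1..theta3: clavicle vs thorax (Z-X-Z); theta4..theta6: scapula vs
    clavicle (Y-X-Y); (phi_c, psi_c) and (phi_d, psi_d): ellipsoid surface
    parameters of the contact points c and d.
    """

    theta1: float
    theta2: float
    theta4: float
    theta5: float
    theta6: float
    phi_c: float
    psi_c: float
    phi_d: float
    psi_d: float
    theta3: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError("joint variables must be finite")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.theta1,
                self.theta2,
                self.theta3,
                self.theta4,
                self.theta5,
                self.theta6,
                self.phi_c,
                self.psi_c,
                self.phi_d,
                self.psi_d,
            ]
        )


@dataclass(frozen=True)
class GirdleInputs:
    """The three independent inputs of the inverse solve (radians)."""

    theta1: float
    theta2: float
    psi_d: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.theta1, self.theta2, self.psi_d])):
            raise ValueError("girdle inputs must be finite")


@dataclass(frozen=True)
class SolverSettings:
    tolerance: float = 1e-8  # residual norm, mm
    max_iterations: int = 100
    initial_guess_strategy: str = "neutral"  # neutral | previous_frame | user
    finite_difference_step: float = 1e-7  # rad

    def __post_init__(self) -> None:
        if not self.tolerance > 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.initial_guess_strategy not in ("neutral", "previous_frame", "user"):
            raise ValueError(f"unknown guess strategy {self.initial_guess_strategy!r}")


class ConvergenceError(RuntimeError):
    """Inverse solve failed; carries the final residual norm (mm)."""

    def __init__(self, message: str, residual: float, condition: float | None = None):
        super().__init__(message)
        self.residual = residual
        self.condition = condition


def _t10_rotation(theta1: float, theta2: float, theta3: float) -> np.ndarray:
    return rot_axis("z", theta1) @ rot_axis("x", theta2) @ rot_axis("z", theta3)


def _t21(g: GirdleGeometry, theta4: float, theta5: float, theta6: float) -> np.ndarray:
    R = rot_axis("y", theta4) @ rot_axis("x", theta5) @ rot_axis("y", theta6)
    return trans_axis("z", g.l1) @ make_transform(R, (0.0, 0.0, 0.0))


def forward_chain(state: JointState, g: GirdleGeometry):
    """Chain-side transforms and contact-point positions.

    Returns ``(T10, T21, pc0, pd0)``: the clavicle and scapula transforms
    and the scapular points c, d expressed in the global frame S0 through
    T10 @ T21.
    """
    T10 = make_transform(_t10_rotation(state.theta1, state.theta2, state.theta3), (0, 0, 0))
    T21 = _t21(g, state.theta4, state.theta5, state.theta6)
    T20 = T10 @ T21
    pc2, pd2 = scapula_points(g)
    pc0 = (T20 @ np.append(pc2, 1.0))[:3]
    pd0 = (T20 @ np.append(pd2, 1.0))[:3]
    return T10, T21, pc0, pd0


def _center_s0(e: ThoraxEllipsoid, p_sc) -> np.ndarray:
    return e.center_in_s0(p_sc)


def constraint_residual(
    state: JointState,
    g: GirdleGeometry,
    e: ThoraxEllipsoid,
    p_sc=None,
) -> np.ndarray:
    """Six-component closure gap (mm).

    Concatenates the 3-vector differences between the chain-side positions
    of c and d (through the clavicle and scapula) and their ellipsoid-side
    positions (centre + surface point); zero iff the loop closes.
    ``p_sc`` (SC landmark, thorax frame) is needed only when the ellipsoid
    centre is stored in thorax coordinates.
    """
    _, _, pc0, pd0 = forward_chain(state, g)
    c0 = _center_s0(e, p_sc)
    gap_c = pc0 - (c0 + ellipsoid_point(state.phi_c, state.psi_c, e))
    gap_d = pd0 - (c0 + ellipsoid_point(state.phi_d, state.psi_d, e))
    return np.concatenate([gap_c, gap_d])


def _projection_guess(
    inputs: GirdleInputs, g: GirdleGeometry, e: ThoraxEllipsoid, center0: np.ndarray
) -> np.ndarray:
    """Fallback seed: straight chain, contact parameters by central projection."""
    state = JointState(
        theta1=inputs.theta1,
        theta2=inputs.theta2,
        theta4=0.0,
        theta5=0.0,
        theta6=0.0,
        phi_c=0.0,
        psi_c=0.0,
        phi_d=0.0,
        psi_d=inputs.psi_d,
    )
    _, _, pc0, pd0 = forward_chain(state, g)
    phi_c, psi_c = surface_params(pc0 - center0, e)
    phi_d, _ = surface_params(pd0 - center0, e)
    return np.array([0.0, 0.0, 0.0, phi_c, psi_c, phi_d])


def _neutral_guess(
    inputs: GirdleInputs, g: GirdleGeometry, e: ThoraxEllipsoid, center0: np.ndarray
) -> np.ndarray:
    """Geometric assembly seed on the anatomical branch.

    With (theta1, theta2) fixed, the AC joint b is known.  The contact
    point d must lie on the psi_d meridian of the ellipsoid at distance l3
    from b; of the (up to two) such points the inferior one (largest polar
    angle) is taken — the scapula hangs below the AC joint.  c then lies on
    the circle |c - b| = l2, angle(c-b, d-b) = gamma; the point of that
    circle nearest the ellipsoid surface seeds (phi_c, psi_c), and the
    scapula frame built from (b, c, d) seeds (theta4, theta5, theta6).
    Falls back to a straight-chain projection seed if the meridian carries
    no distance-l3 point.
    """
    from scipy.optimize import brentq

    R10 = _t10_rotation(inputs.theta1, inputs.theta2, 0.0)
    b = R10 @ np.array([0.0, 0.0, g.l1]) - center0  # AC joint in S3

    def gap(phi: float) -> float:
        return float(np.linalg.norm(b - ellipsoid_point(phi, inputs.psi_d, e)) - g.l3)

    phis = np.linspace(1e-6, np.pi - 1e-6, 121)
    vals = np.array([gap(p) for p in phis])
    roots = [
        brentq(gap, phis[i], phis[i + 1])
        for i in range(len(phis) - 1)
        if vals[i] == 0.0 or vals[i] * vals[i + 1] < 0.0
    ]
    if not roots:
        return _projection_guess(inputs, g, e, center0)
    phi_d = max(roots)  # inferior intersection
    d = ellipsoid_point(phi_d, inputs.psi_d, e)

    # Circle of candidate c points: centre b + l2 cos(gamma) u, radius
    # l2 sin(gamma), in the plane normal to u = (d - b)/l3.
    u = (d - b) / np.linalg.norm(d - b)
    v = np.cross(u, np.array([0.0, 0.0, 1.0]))
    if np.linalg.norm(v) < 1e-9:
        v = np.cross(u, np.array([1.0, 0.0, 0.0]))
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    cc = b + g.l2 * np.cos(g.gamma) * u
    rho = g.l2 * np.sin(g.gamma)
    alphas = np.linspace(0.0, 2.0 * np.pi, 73)
    cands = cc[None, :] + rho * (np.cos(alphas)[:, None] * v + np.sin(alphas)[:, None] * w)
    impl = np.array([e.implicit(c) for c in cands])
    c = cands[int(np.argmin(np.abs(impl)))]
    sign_change = np.nonzero(impl[:-1] * impl[1:] < 0.0)[0]
    if sign_change.size:
        # Of the on-surface roots take the superior one: c sits above d on
        # the scapula's medial border.
        roots_c = []
        for i in sign_change:
            alpha = brentq(
                lambda a: e.implicit(cc + rho * (np.cos(a) * v + np.sin(a) * w)),
                alphas[i],
                alphas[i + 1],
            )
            roots_c.append(cc + rho * (np.cos(alpha) * v + np.sin(alpha) * w))
        c = max(roots_c, key=lambda pt: pt[2])
    phi_c, psi_c = surface_params(c, e)

    # Scapula frame from (b, c, d): z2 along b->c, d-b in the y2-z2 plane
    # with positive y2 component.
    z2 = (c - b) / np.linalg.norm(c - b)
    y2 = (d - b) - ((d - b) @ z2) * z2
    y2 /= np.linalg.norm(y2)
    x2 = np.cross(y2, z2)
    R20 = np.column_stack([x2, y2, z2])
    eul = matrix_to_euler(R10.T @ R20, "YXY", tol=1e-6)
    return np.array([eul.angles[0], eul.angles[1], eul.angles[2], phi_c, psi_c, phi_d])


def _state_from_unknowns(inputs: GirdleInputs, x: np.ndarray) -> JointState:
    return JointState(
        theta1=inputs.theta1,
        theta2=inputs.theta2,
        theta4=x[0],
        theta5=x[1],
        theta6=x[2],
        phi_c=x[3],
        psi_c=x[4],
        phi_d=x[5],
        psi_d=inputs.psi_d,
    )


def solve_girdle(
    inputs: GirdleInputs,
    g: GirdleGeometry,
    e: ThoraxEllipsoid,
    settings: SolverSettings | None = None,
    guess: JointState | None = None,
    p_sc=None,
) -> JointState:
    """Inverse position solve of the closed girdle loop.

    Fixes (theta1, theta2, psi_d) from ``inputs`` (theta3 = 0) and finds
    (theta4, theta5, theta6, phi_c, psi_c, phi_d) such that both contact
    points lie on the thorax ellipsoid (residual norm < tolerance).
    A ``guess`` selects the assembly branch; without one, the neutral
    scapula posture is used as the starting point.

    Raises :class:`ConvergenceError` on failure, reporting the final
    residual and, for a singular Jacobian, its condition estimate.
    """
    settings = settings or SolverSettings()
    center0 = _center_s0(e, p_sc)
    pc2, pd2 = scapula_points(g)
    T10 = make_transform(_t10_rotation(inputs.theta1, inputs.theta2, 0.0), (0, 0, 0))
    R10 = rotation_of(T10)
    b0 = R10 @ np.array([0.0, 0.0, g.l1])  # AC-joint position in S0

    def residual(x: np.ndarray) -> np.ndarray:
        R21 = rot_axis("y", x[0]) @ rot_axis("x", x[1]) @ rot_axis("y", x[2])
        R20 = R10 @ R21
        pc0 = b0 + R20 @ pc2
        pd0 = b0 + R20 @ pd2
        gap_c = pc0 - (center0 + ellipsoid_point(x[3], x[4], e))
        gap_d = pd0 - (center0 + ellipsoid_point(x[5], inputs.psi_d, e))
        return np.concatenate([gap_c, gap_d])

    if guess is not None:
        x = np.array(
            [guess.theta4, guess.theta5, guess.theta6, guess.phi_c, guess.psi_c, guess.phi_d]
        )
    else:
        x = _neutral_guess(inputs, g, e, center0)

    x, res_norm, cond = _damped_newton(
        residual,
        x,
        tol=settings.tolerance,
        max_iterations=settings.max_iterations,
        fd_step=settings.finite_difference_step,
    )
    if res_norm >= settings.tolerance:
        raise ConvergenceError(
            f"girdle solve did not converge: residual {res_norm:.3e} mm "
            f"after {settings.max_iterations} iterations",
            residual=res_norm,
            condition=cond,
        )
    return _state_from_unknowns(inputs, x)


def _fd_jacobian(fun, x: np.ndarray, f: np.ndarray, step: float) -> np.ndarray:
    J = np.empty((f.size, x.size))
    for j in range(x.size):
        xp = x.copy()
        xp[j] += step
        J[:, j] = (fun(xp) - f) / step
    return J


def _damped_newton(fun, x0, tol, max_iterations, fd_step):
    """Newton iteration with backtracking, falling back to Levenberg steps.

    Returns ``(x, residual_norm, condition_estimate)``.
    """
    x = np.asarray(x0, dtype=float).copy()
    f = fun(x)
    nf = np.linalg.norm(f)
    cond = None
    for _ in range(max_iterations):
        if nf < tol:
            break
        J = _fd_jacobian(fun, x, f, fd_step)
        cond = np.linalg.cond(J)
        dx = None
        if np.isfinite(cond) and cond < 1e12:
            dx = np.linalg.solve(J, -f)
        improved = False
        if dx is not None:
            t = 1.0
            while t >= 1.0 / 64.0:
                xt = x + t * dx
                ft = fun(xt)
                nft = np.linalg.norm(ft)
                if nft < nf:
                    x, f, nf = xt, ft, nft
                    improved = True
                    break
                t /= 2.0
        if not improved:
            # Levenberg fallback: (J^T J + lam I) dx = -J^T f
            JtJ = J.T @ J
            Jtf = J.T @ f
            lam = 1e-6 * max(1.0, np.trace(JtJ) / JtJ.shape[0])
            for _ in range(25):
                try:
                    dx = np.linalg.solve(JtJ + lam * np.eye(JtJ.shape[0]), -Jtf)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                xt = x + dx
                ft = fun(xt)
                nft = np.linalg.norm(ft)
                if nft < nf:
                    x, f, nf = xt, ft, nft
                    improved = True
                    break
                lam *= 10.0
            if not improved:
                break  # stagnated
    return x, nf, cond


@dataclass(frozen=True)
class SolvedFrame:
    """Per-frame result of a trajectory solve."""

    state: JointState | None
    residual_norm: float
    converged: bool
    message: str = ""


def solve_trajectory(
    inputs_series,
    g: GirdleGeometry,
    e: ThoraxEllipsoid,
    settings: SolverSettings | None = None,
    guess: JointState | None = None,
    p_sc=None,
) -> list[SolvedFrame]:
    """Frame-by-frame inverse solve with previous-frame warm starts.

    Non-converged frames are flagged (``converged=False``) rather than
    aborting the batch; subsequent frames fall back to the last good state
    as their warm start.
    """
    settings = settings or SolverSettings()
    frames: list[SolvedFrame] = []
    warm = guess
    for inputs in inputs_series:
        try:
            state = solve_girdle(inputs, g, e, settings=settings, guess=warm, p_sc=p_sc)
            res = float(np.linalg.norm(constraint_residual(state, g, e, p_sc=p_sc)))
            frames.append(SolvedFrame(state=state, residual_norm=res, converged=True))
            warm = state
        except ConvergenceError as err:
            frames.append(
                SolvedFrame(state=None, residual_norm=err.residual, converged=False, message=str(err))
            )
    return frames


@dataclass(frozen=True)
class HumerusPose:
    """Humerus orientation (computation-frame Y-X-Z angles, radians) and the
    GH-centre position ``pe`` (mm, global frame S0)."""

    theta7: float
    theta8: float
    theta9: float
    pe: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "pe", np.asarray(self.pe, dtype=float))
        if not (
            np.all(np.isfinite([self.theta7, self.theta8, self.theta9]))
            and np.all(np.isfinite(self.pe))
        ):
            raise ValueError("humerus pose must be finite")

    def rotation(self) -> np.ndarray:
        return rot_axis("y", self.theta7) @ rot_axis("x", self.theta8) @ rot_axis("z", self.theta9)

    def isb_degrees(self, alignment: FrameAlignment | None = None) -> tuple[float, float, float]:
        """ISB humerus-vs-thorax angles (HumY1, HumX, HumY2), degrees (YXY).

        Raises no error at the YXY singularity; the gimbal flag of the
        decomposition is propagated as a warning there.
        """
        al = alignment or alignment_matrices(warn=False)
        R_ht = al.R0t @ self.rotation() @ al.R4h.T
        eul = matrix_to_euler(R_ht, "YXY")
        return eul.degrees

    @classmethod
    def from_isb_degrees(
        cls,
        hum_y1: float,
        hum_x: float,
        hum_y2: float,
        pe=(0.0, 0.0, 0.0),
        alignment: FrameAlignment | None = None,
    ) -> "HumerusPose":
        """Build the pose from ISB YXY angles (degrees)."""
        al = alignment or alignment_matrices(warn=False)
        R_ht = (
            rot_axis("y", np.radians(hum_y1))
            @ rot_axis("x", np.radians(hum_x))
            @ rot_axis("y", np.radians(hum_y2))
        )
        R40 = al.R0t.T @ R_ht @ al.R4h
        eul = matrix_to_euler(R40, "YXZ")
        return cls(theta7=eul.angles[0], theta8=eul.angles[1], theta9=eul.angles[2], pe=pe)


def humerus_transform(pose: HumerusPose) -> np.ndarray:
    """Homogeneous S4 -> S0 transform of the humerus."""
    return make_transform(pose.rotation(), pose.pe)


def scapula_isb_posture(
    state: JointState,
    g: GirdleGeometry,
    alignment: FrameAlignment | None = None,
    prev: EulerAngles | None = None,
) -> EulerAngles:
    """Scapula-vs-thorax (ST joint) posture as ISB YXZ Euler angles.

    Composes R_st = R0t R10 R21 R2s^T and decomposes Y-X-Z.  The published
    R2s is far from orthonormal as printed (det ~ 0.94, likely a sign
    misprint), so the composed matrix is projected onto the nearest proper
    rotation (SVD) before decomposition.
    """
    al = alignment or alignment_matrices(warn=False)
    T10, T21, _, _ = forward_chain(state, g)
    R_st = al.R0t @ rotation_of(T10) @ rotation_of(T21) @ al.R2s.T
    U, _, Vt = np.linalg.svd(R_st)
    if np.linalg.det(U @ Vt) < 0:
        U[:, -1] *= -1
    return matrix_to_euler(U @ Vt, "YXZ", prev=prev)
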