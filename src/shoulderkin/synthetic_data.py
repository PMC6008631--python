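"""Synthetic range-of-motion trajectories for testing the whole pipeline.

Real validation data for this model comes from marker-based motion capture
of ABD / SCAP / FLEX range-of-motion tasks sampled at 100 Hz.  This module
emulates those recordings by *inverting* the analysis direction: the rhythm
model prescribes the girdle inputs as functions of humeral elevation, the
closed-chain solver produces a fully consistent girdle state per frame, and
the observable quantities (ISB clavicle and humerus Euler angles, SC and AI
landmark positions in the thorax frame) are synthesized from that state,
optionally corrupted with independent Gaussian angle noise.

Ground-truth columns (prefix ``gt_``) are written alongside the observables
and are never touched by noise, so every downstream stage (input
extraction, inverse solve, rhythm fitting) can be checked against the
quantities that generated the data.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .girdle_kinematics import (
    ConvergenceError,
    GirdleInputs,
    JointState,
    SolverSettings,
    forward_chain,
    solve_girdle,
)
from .input_extraction import build_T3t
from .model_geometry import (
    FrameAlignment,
    alignment_matrices,
    default_geometry,
    ellipsoid_point,
)
from .rhythm import RhythmModel, builtin_rhythm, dispatch_task, rhythm_eval
from .transforms import matrix_to_euler, rotation_of

__all__ = [
    "SimConfig",
    "Trajectory",
    "elevation_profile",
    "generate_trajectory",
    "write_trajectory",
    "read_trajectory",
    "REQUIRED_COLUMNS",
]

#: Observable schema shared with the extraction stage.
REQUIRED_COLUMNS = (
    "t_s",
    "ClavY_deg",
    "ClavX_deg",
    "ClavZ_deg",
    "HumY1_deg",
    "HumX_deg",
    "HumY2_deg",
    "SC_x_mm",
    "SC_y_mm",
    "SC_z_mm",
    "AI_x_mm",
    "AI_y_mm",
    "AI_z_mm",
)

GROUND_TRUTH_COLUMNS = (
    "gt_theta1_deg",
    "gt_theta2_deg",
    "gt_theta4_deg",
    "gt_theta5_deg",
    "gt_theta6_deg",
    "gt_phi_c_deg",
    "gt_psi_c_deg",
    "gt_phi_d_deg",
    "gt_psi_d_deg",
    "gt_HumY1_deg",
    "gt_HumX_deg",
    "gt_HumY2_deg",
)

#: Lift-and-drop cycles per task in the emulated protocol.
DEFAULT_CYCLES = {"ABD": 5, "SCAP": 4, "FLEX": 4}


@dataclass(frozen=True)
class SimConfig:
    """Conditions of one simulated range-of-motion trial.

    ``peak_elevation`` (degrees) is the humeral elevation reached at the
    top of each lift; the default 90 keeps the rhythm cubics inside the
    regime where they describe physiological girdle postures (extrapolated
    far beyond it they drive the contact azimuth out of the assemblable
    region).  ``cycle_duration`` is the lift+drop period in seconds;
    ``noise_sd`` the angle-noise standard deviation in degrees;
    ``ai_offset`` the radial factor placing the AI landmark outside its
    equivalent contact point on the ellipsoid.
    """

    task: str = "ABD"
    n_cycles: int | None = None
    peak_elevation: float = 90.0
    sample_rate: float = 100.0
    cycle_duration: float = 4.0
    noise_sd: float = 0.0
    seed: int = 0
    geometry_source: str = "subject_s1"
    ai_offset: float = 1.1

    def __post_init__(self) -> None:
        if self.task not in DEFAULT_CYCLES:
            raise ValueError(f"unknown task {self.task!r}")
        if self.n_cycles is not None and self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not 0 < self.peak_elevation <= 165.0:
            raise ValueError("peak_elevation must be in (0, 165] degrees")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if not self.cycle_duration > 0:
            raise ValueError("cycle_duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.ai_offset <= 0:
            raise ValueError("ai_offset must be positive")

    @property
    def cycles(self) -> int:
        return self.n_cycles if self.n_cycles is not None else DEFAULT_CYCLES[self.task]


@dataclass(frozen=True)
class Trajectory:
    """A time series of observables, plus ground truth when synthetic."""

    data: pd.DataFrame
    config: dict | None = None

    @property
    def has_ground_truth(self) -> bool:
        return all(c in self.data.columns for c in GROUND_TRUTH_COLUMNS)

    def __len__(self) -> int:
        return len(self.data)


def elevation_profile(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Time base and humerus (HumY1, HumX) series for one trial (degrees).

    HumX follows raised-cosine lift/drop cycles from 0 to the peak; HumY1
    wanders slowly inside the task's plane-of-elevation band as the sum of
    two incommensurate random-phase sinusoids (amplitude 80% of the band's
    half-width), emulating how subjects drift about the nominal plane.
    """
    if rng is None:
        rng = np.random.default_rng([int(cfg.seed), 0])
    n = int(round(cfg.cycles * cfg.cycle_duration * cfg.sample_rate)) + 1
    t = np.arange(n) / cfg.sample_rate
    hum_x = cfg.peak_elevation * 0.5 * (1.0 - np.cos(2.0 * np.pi * t / cfg.cycle_duration))
    lo, hi = builtin_rhythm().ranges[cfg.task]
    mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=2)
    total = cfg.cycles * cfg.cycle_duration
    hum_y1 = mid + 0.8 * half * (
        0.6 * np.sin(2.0 * np.pi * 1.7 * t / total + phases[0])
        + 0.4 * np.sin(2.0 * np.pi * 2.9 * t / total + phases[1])
    )
    return t, hum_y1, hum_x


def generate_trajectory(
    cfg: SimConfig,
    model: RhythmModel | None = None,
    geometry=None,
    settings: SolverSettings | None = None,
    alignment: FrameAlignment | None = None,
) -> Trajectory:
    """Simulate one range-of-motion trial.

    Per frame the rhythm model yields (theta1, theta2, psi_d, HumY2) from
    (HumY1, HumX); the inverse solve closes the girdle loop; the ISB
    clavicle angles are re-synthesized from the SC rotation through
    Rct = R0t R10 R1c^-1; and the AI landmark is placed radially outside
    the contact point d by ``cfg.ai_offset``.  Noise (zero-mean Gaussian,
    sd ``cfg.noise_sd`` degrees, independent per angle and frame) enters
    every observed output angle: the six Euler-angle columns directly, and
    the AI landmark through its angular placement on the ellipsoid (both
    surface angles of the placement direction are perturbed).  Noise is
    drawn from a stream separate from the ground-truth draws, so ground
    truth is identical across noise settings at a fixed seed.
    """
    model = model or builtin_rhythm()
    if geometry is None:
        geometry = default_geometry(cfg.geometry_source)
    g, e, landmarks = geometry
    al = alignment or alignment_matrices(warn=False)
    settings = settings or SolverSettings()
    p_sc = landmarks["SC"]
    if e.center_frame == "thorax":
        center_thorax = e.center
    else:
        center_thorax = al.R0t @ e.center + p_sc
    T3t = build_T3t(p_sc, center_thorax, al)

    gt_rng = np.random.default_rng([int(cfg.seed), 0])
    noise_rng = np.random.default_rng([int(cfg.seed), 1])
    t, hum_y1, hum_x = elevation_profile(cfg, rng=gt_rng)

    n = t.size
    rows = np.empty((n, 9))  # girdle state (deg): th1 th2 th4 th5 th6 phi_c psi_c phi_d psi_d
    clav = np.empty((n, 3))
    ai_t = np.empty((n, 3))
    hum_y2 = np.empty(n)
    warm: JointState | None = None
    prev_clav = None
    for i in range(n):
        r = rhythm_eval(model.tables[dispatch_task(model, hum_y1[i])], hum_x[i])
        inputs = GirdleInputs(
            theta1=np.radians(r["theta1"]),
            theta2=np.radians(r["theta2"]),
            psi_d=np.radians(r["psi_d"]),
        )
        hum_y2[i] = r["HumY2"]
        try:
            state = solve_girdle(inputs, g, e, settings=settings, guess=warm, p_sc=p_sc)
        except ConvergenceError as err:
            raise ConvergenceError(
                f"frame {i} (t = {t[i]:.2f} s, HumX = {hum_x[i]:.1f} deg): {err}",
                residual=err.residual,
                condition=err.condition,
            ) from err
        warm = state
        T10, _, _, _ = forward_chain(state, g)
        rct = al.R0t @ rotation_of(T10) @ al.R1c.T
        eul = matrix_to_euler(rct, "YXZ", prev=prev_clav)
        prev_clav = eul
        clav[i] = eul.degrees
        if cfg.noise_sd > 0:
            dphi, dpsi = np.radians(noise_rng.normal(0.0, cfg.noise_sd, size=2))
        else:
            dphi = dpsi = 0.0
        d3 = ellipsoid_point(state.phi_d + dphi, state.psi_d + dpsi, e)
        ai_t[i] = (T3t @ np.append(cfg.ai_offset * d3, 1.0))[:3]
        rows[i] = [
            state.theta1,
            state.theta2,
            state.theta4,
            state.theta5,
            state.theta6,
            state.phi_c,
            state.psi_c,
            state.phi_d,
            state.psi_d,
        ]

    deg = np.degrees(rows)
    df = pd.DataFrame({"t_s": t})
    noisy = lambda x: x + noise_rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else x
    df["ClavY_deg"] = noisy(clav[:, 0])
    df["ClavX_deg"] = noisy(clav[:, 1])
    df["ClavZ_deg"] = noisy(clav[:, 2])
    df["HumY1_deg"] = noisy(hum_y1)
    df["HumX_deg"] = noisy(hum_x)
    df["HumY2_deg"] = noisy(hum_y2)
    df["SC_x_mm"], df["SC_y_mm"], df["SC_z_mm"] = p_sc
    df["AI_x_mm"] = ai_t[:, 0]
    df["AI_y_mm"] = ai_t[:, 1]
    df["AI_z_mm"] = ai_t[:, 2]
    for j, col in enumerate(GROUND_TRUTH_COLUMNS[:9]):
        df[col] = deg[:, j]
    df["gt_HumY1_deg"] = hum_y1
    df["gt_HumX_deg"] = hum_x
    df["gt_HumY2_deg"] = hum_y2
    return Trajectory(data=df, config=asdict(cfg))


def write_trajectory(path, traj: Trajectory) -> None:
    """Write the trajectory as CSV at full float precision (lossless)."""
    df = traj.data
    with open(path, "w") as fh:
        if traj.config is not None:
            import json

            fh.write(f"# config: {json.dumps(traj.config)}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_trajectory(path) -> Trajectory:
    """Read a trajectory CSV, validating the observable schema.

    A missing required column raises a ``ValueError`` naming it.
    """
    path = Path(path)
    config = None
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("# config:"):
        import json

        config = json.loads(first[len("# config:") :])
        skip = 1
    df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"trajectory file {path.name} missing required column {col!r}")
    # integer-looking values (e.g. a constant landmark coordinate) must stay floats
    df = df.astype({c: float for c in df.columns if df[c].dtype.kind in "iu"})
    return Trajectory(data=df, config=config)
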