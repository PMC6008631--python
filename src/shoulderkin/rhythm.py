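"""Shoulder-rhythm model: per-task cubic regressions in humeral elevation.

During natural arm raising the shoulder girdle follows the humerus in a
highly repeatable pattern (the shoulder rhythm).  Here that pattern is a
cubic polynomial in the humeral elevation angle HumX for each of four
dependent variables — the SC-joint angles theta1 and theta2, the contact
azimuth psi_d, and the humeral axial rotation HumY2 — fitted separately for
three range-of-motion tasks (ABD: frontal-plane abduction, SCAP: scaption,
FLEX: sagittal-plane flexion) and assembled piecewise over the plane of
elevation HumY1.

All rhythm quantities are in degrees (the coefficient tables are printed in
degrees); conversion to radians happens where the solver consumes them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TASKS",
    "VARIABLES",
    "RhythmCoefficients",
    "RhythmModel",
    "FitReport",
    "rhythm_eval",
    "rhythm_piecewise",
    "fit_rhythm",
    "builtin_rhythm",
    "save_rhythm_model",
    "load_rhythm_model",
]

TASKS = ("ABD", "SCAP", "FLEX")
VARIABLES = ("theta1", "theta2", "psi_d", "HumY2")

#: Elevation domain (degrees) shared by all tasks.
ELEVATION_DOMAIN = (0.0, 165.0)


@dataclass(frozen=True)
class FitDiagnostics:
    """Goodness of fit for one dependent variable.

    ``rmse`` is the population form sqrt(SSres/n); ``rmse_dof`` the
    degrees-of-freedom corrected sqrt(SSres/(n-4)).  ``stderr`` holds the
    four coefficient standard errors when the fit produced them.
    """

    r2: float
    rmse: float
    rmse_dof: float | None = None
    stderr: tuple | None = None


@dataclass(frozen=True)
class RhythmCoefficients:
    """Cubic coefficients per dependent variable for one task.

    ``coeffs[v] = (p1, p2, p3, p4)`` with
    v(HumX) = p1 HumX^3 + p2 HumX^2 + p3 HumX + p4 (degrees).
    """

    task: str
    coeffs: dict
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        for v in VARIABLES:
            if v not in self.coeffs:
                raise ValueError(f"missing coefficients for variable {v!r}")
            if len(self.coeffs[v]) != 4:
                raise ValueError(f"variable {v!r} needs exactly four coefficients")
        for v, diag in self.diagnostics.items():
            if diag.r2 > 1.0 + 1e-12:
                raise ValueError(f"R^2 for {v!r} exceeds 1")


@dataclass(frozen=True)
class RhythmModel:
    """Piecewise rhythm: one coefficient set per task plus the HumY1 ranges.

    Ranges are half-open at the upper boundary except the last, covering
    the plane-of-elevation domain [-10, 90] degrees without gaps.
    """

    tables: dict
    ranges: dict = field(
        default_factory=lambda: {
            "ABD": (-10.0, 20.0),
            "SCAP": (20.0, 50.0),
            "FLEX": (50.0, 90.0),
        }
    )

    def __post_init__(self) -> None:
        for task in TASKS:
            if task not in self.tables:
                raise ValueError(f"rhythm model missing task {task!r}")
            if task not in self.ranges:
                raise ValueError(f"rhythm model missing range for task {task!r}")
        edges = sorted(self.ranges.values())
        for (lo0, hi0), (lo1, _) in zip(edges, edges[1:]):
            if hi0 != lo1:
                raise ValueError("plane-of-elevation ranges must tile without gaps")


def _warn_domain(name: str, value: float, lo: float, hi: float) -> None:
    if not lo <= value <= hi:
        warnings.warn(
            f"{name} = {value:.1f} deg outside [{lo:.0f}, {hi:.0f}]; evaluating anyway",
            stacklevel=3,
        )


def rhythm_eval(c: RhythmCoefficients, hum_x: float) -> dict:
    """Evaluate the four cubics at elevation ``hum_x`` (degrees in and out)."""
    _warn_domain("HumX", hum_x, *ELEVATION_DOMAIN)
    out = {}
    for v in VARIABLES:
        p1, p2, p3, p4 = c.coeffs[v]
        out[v] = ((p1 * hum_x + p2) * hum_x + p3) * hum_x + p4
    return out


def rhythm_piecewise(model: RhythmModel, hum_y1: float, hum_x: float) -> dict:
    """Dispatch on the plane of elevation, then evaluate that task's cubics.

    Intervals are half-open at the top except the last; values outside
    [-10, 90] degrees are clamped to the nearest branch with a warning.
    """
    _warn_domain("HumY1", hum_y1, -10.0, 90.0)
    task = dispatch_task(model, hum_y1)
    return rhythm_eval(model.tables[task], hum_x)


def dispatch_task(model: RhythmModel, hum_y1: float) -> str:
    """Task whose plane-of-elevation range contains ``hum_y1`` (degrees)."""
    items = sorted(model.ranges.items(), key=lambda kv: kv[1][0])
    if hum_y1 < items[0][1][0]:
        return items[0][0]
    for task, (lo, hi) in items[:-1]:
        if lo <= hum_y1 < hi:
            return task
    return items[-1][0]


@dataclass(frozen=True)
class FitReport:
    """Result of :func:`fit_rhythm`: coefficients + per-variable diagnostics."""

    coefficients: RhythmCoefficients
    n_samples: int


def fit_rhythm(samples, task: str = "ABD") -> FitReport:
    """Least-squares cubic fit of the four rhythm variables on HumX.

    ``samples`` is a table (``pandas.DataFrame`` or dict of arrays) with
    columns ``HumX`` plus the four dependent variables, all in degrees.
    The cubic is fitted in a centred/scaled basis for conditioning and the
    coefficients are mapped back to raw powers of HumX exactly.

    Diagnostics per variable: R^2 = 1 - SSres/SStot, RMSE in both the
    population (sqrt(SSres/n)) and dof-corrected (sqrt(SSres/(n-4)))
    conventions, and analytic coefficient standard errors from
    (X^T X)^{-1} * SSres/(n-4).
    """
    x = np.asarray(samples["HumX"], dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("need at least four samples to fit a cubic")
    if np.unique(x).size < 4:
        raise ValueError("need at least four distinct HumX values (rank-deficient design)")
    n = x.size
    mu, sd = x.mean(), x.std()
    if sd == 0:
        raise ValueError("HumX has zero spread")
    z = (x - mu) / sd
    Z = np.vander(z, 4)  # columns z^3, z^2, z, 1
    # Exact basis change from powers of z = (x - mu)/sd to powers of x.
    A = _basis_change(mu, sd)
    ZtZ_inv = np.linalg.inv(Z.T @ Z)
    coeffs = {}
    diagnostics = {}
    for v in VARIABLES:
        y = np.asarray(samples[v], dtype=float)
        beta_z, *_ = np.linalg.lstsq(Z, y, rcond=None)
        beta = A @ beta_z
        resid = y - Z @ beta_z
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        rmse = float(np.sqrt(ss_res / n))
        rmse_dof = float(np.sqrt(ss_res / (n - 4))) if n > 4 else None
        if n > 4:
            sigma2 = ss_res / (n - 4)
            cov_raw = A @ (ZtZ_inv * sigma2) @ A.T
            stderr = tuple(np.sqrt(np.maximum(np.diag(cov_raw), 0.0)))
        else:
            stderr = None
        coeffs[v] = tuple(float(b) for b in beta)
        diagnostics[v] = FitDiagnostics(
            r2=min(r2, 1.0), rmse=rmse, rmse_dof=rmse_dof, stderr=stderr
        )
    return FitReport(
        coefficients=RhythmCoefficients(task=task, coeffs=coeffs, diagnostics=diagnostics),
        n_samples=n,
    )


def _basis_change(mu: float, sd: float) -> np.ndarray:
    """Matrix A with p_raw = A p_z for cubic coefficients in Vander order.

    If y = sum_k beta_k z^(3-k) with z = (x - mu)/sd, expand each power of
    z in powers of x; both coefficient vectors are ordered (x^3 .. 1).
    """
    A = np.zeros((4, 4))
    for col, power in enumerate((3, 2, 1, 0)):
        # z^power = (x - mu)^power / sd^power
        poly = np.polynomial.polynomial.polypow((-mu, 1.0), power) / sd**power
        for deg, coef in enumerate(poly):
            A[3 - deg, col] = coef
    return A


# Built-in coefficient tables (degrees), one row per dependent variable:
# (p1, p2, p3, p4), plus the published fit diagnostics (R^2, RMSE).
_BUILTIN = {
    "ABD": {
        "theta1": ((2.483e-06, 0.0009501, 0.2419, 74.07), (0.9581, 1.811)),
        "theta2": ((-6.441e-06, -0.001558, -0.06742, 81.4), (0.6004, 1.271)),
        "psi_d": ((2.822e-05, 0.006688, 0.3163, -50.89), (0.5203, 4.848)),
        "HumY2": ((2.443e-05, 0.01201, 1.833, 32.07), (0.8376, 13.76)),
    },
    "SCAP": {
        "theta1": ((-6.283e-06, -0.001732, 0.03207, 76.14), (0.9574, 1.922)),
        "theta2": ((-2.328e-07, -3.272e-06, 0.01831, 80.13), (0.9161, 0.6043)),
        "psi_d": ((4.478e-06, 0.0008388, -0.002783, -44.38), (0.3585, 2.969)),
        "HumY2": ((-1.417e-05, 8.118e-05, 0.6336, 4.591), (0.6418, 12.61)),
    },
    "FLEX": {
        "theta1": ((3.587e-06, -0.000406, -0.01044, 79.29), (0.9963, 0.475)),
        "theta2": ((-1.058e-05, -0.002583, -0.1365, 77.43), (0.3921, 2.833)),
        "psi_d": ((6.167e-06, 0.0002202, -0.179, -48.39), (0.5784, 3.951)),
        "HumY2": ((3.011e-05, 0.01069, 1.412, 25.64), (0.7932, 12.75)),
    },
}


def builtin_rhythm() -> RhythmModel:
    """The built-in per-task coefficient tables and plane-of-elevation ranges."""
    tables = {}
    for task, rows in _BUILTIN.items():
        coeffs = {v: rows[v][0] for v in VARIABLES}
        diagnostics = {
            v: FitDiagnostics(r2=rows[v][1][0], rmse=rows[v][1][1]) for v in VARIABLES
        }
        tables[task] = RhythmCoefficients(task=task, coeffs=coeffs, diagnostics=diagnostics)
    return RhythmModel(tables=tables)


def save_rhythm_model(path, model: RhythmModel) -> None:
    payload = {
        "ranges": {t: list(r) for t, r in model.ranges.items()},
        "tasks": {
            task: {
                v: {
                    "p": list(table.coeffs[v]),
                    **(
                        {
                            "r2": table.diagnostics[v].r2,
                            "rmse": table.diagnostics[v].rmse,
                        }
                        if v in table.diagnostics
                        else {}
                    ),
                }
                for v in VARIABLES
            }
            for task, table in model.tables.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_rhythm_model(path) -> RhythmModel:
    raw = json.loads(Path(path).read_text())
    tables = {}
    for task, rows in raw["tasks"].items():
        coeffs = {v: tuple(rows[v]["p"]) for v in rows}
        diagnostics = {
            v: FitDiagnostics(r2=rows[v]["r2"], rmse=rows[v]["rmse"])
            for v in rows
            if "r2" in rows[v]
        }
        tables[task] = RhythmCoefficients(task=task, coeffs=coeffs, diagnostics=diagnostics)
    ranges = {t: tuple(r) for t, r in raw["ranges"].items()}
    return RhythmModel(tables=tables, ranges=ranges)
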