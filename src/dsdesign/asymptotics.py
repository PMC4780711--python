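"""Asymptotic variance of the distance-sampling abundance estimator.

Under the model where object distances are independent uniform and detections
are independent Bernoulli, the count of detections is n ~ bin(N, P*gbar) and
the abundance MLE with known detection parameters has variance

    var(N_hat | theta known) = N * P^-1 * gbar^-1 * (1 - P*gbar).

When theta must be estimated by conditional maximum likelihood, the limiting
variance is inflated by the penalty factor

    F = 1 + hbar' Delta^-1 hbar / (gbar^2 * (1 - P*gbar))  >=  1,

where Delta = var_D[h(D)/g(D)] and D is a distance drawn from the
detection-conditional density.  This module computes Delta by quadrature,
assembles the Fisher information of (N, theta) and its blockwise inverse,
and exposes the coefficient of variation and sample-size formulas that
follow, plus generators for penalty tables over grids of coverage P, mean
detection gbar and shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, NumericError
from .families import DetectionFamily, _quad, calibrate_scale, gbar, hbar

__all__ = [
    "SurveyDesign",
    "AsymptoticSummary",
    "delta_matrix",
    "var_known_theta",
    "penalty_F",
    "fisher_blocks",
    "variance_blocks",
    "cv_cds",
    "sample_size",
    "penalty_table",
    "table_hazard_rate",
    "table_half_normal",
    "round_half_away",
]

_COND_LIMIT = 1e12  # refuse to invert Delta beyond this condition number


@dataclass(frozen=True)
class SurveyDesign:
    """Survey geometry: coverage P, truncation w, and optionally N or E[n].

    P is the proportion of the study area lying within distance w of a
    transect line; in the simulation geometry P = w/M with M the maximum
    possible distance.
    """

    P: float
    w: float = 1.0
    M: float | None = None
    N: int | None = None
    E_n: float | None = None

    def __post_init__(self):
        if not 0.0 < self.P <= 1.0:
            raise ConfigError(f"coverage P must be in (0, 1], got {self.P}")
        if not self.w > 0:
            raise ConfigError(f"truncation w must be > 0, got {self.w}")
        if self.M is not None:
            if self.w > self.M:
                raise ConfigError(f"w={self.w} exceeds maximum distance M={self.M}")
            if abs(self.P - self.w / self.M) > 1e-9:
                raise ConfigError(
                    f"P={self.P} inconsistent with w/M={self.w / self.M}"
                )
        if self.N is not None and self.N <= 0:
            raise ConfigError(f"abundance N must be positive, got {self.N}")
        if self.E_n is not None and self.E_n <= 0:
            raise ConfigError(f"expected detections E_n must be positive, got {self.E_n}")


@dataclass
class AsymptoticSummary:
    """Fisher-information and variance blocks for (N, theta)."""

    N: float
    P: float
    gbar: float
    hbar: np.ndarray
    Delta: np.ndarray
    I_NN: float = 0.0
    I_Ntheta: np.ndarray = field(default_factory=lambda: np.empty(0))
    I_thetatheta: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    V11: float = float("nan")
    V21: np.ndarray = field(default_factory=lambda: np.empty(0))
    V22: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    var_known: float = float("nan")
    F: float = float("nan")
    cv: float = float("nan")

    def fisher_matrix(self) -> np.ndarray:
        """Assemble the full (1+p) x (1+p) information matrix."""
        p = len(self.I_Ntheta)
        out = np.empty((1 + p, 1 + p))
        out[0, 0] = self.I_NN
        out[0, 1:] = self.I_Ntheta
        out[1:, 0] = self.I_Ntheta
        out[1:, 1:] = self.I_thetatheta
        return out

    def covariance_matrix(self) -> np.ndarray:
        p = len(self.V21)
        out = np.empty((1 + p, 1 + p))
        out[0, 0] = self.V11
        out[0, 1:] = self.V21
        out[1:, 0] = self.V21
        out[1:, 1:] = self.V22
        return out


def _solve_delta(Delta: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Symmetric solve Delta x = rhs, guarding near-singular matrices."""
    Delta = np.atleast_2d(Delta)
    cond = np.linalg.cond(Delta)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise NumericError(
            f"Delta is numerically singular (condition number {cond:.3g})"
        )
    return np.linalg.solve(Delta, rhs)


def delta_matrix(family: DetectionFamily, theta) -> np.ndarray:
    """Delta = var_D[h(D)/g(D)], the p x p core of the penalty.

    Computed entrywise by adaptive quadrature of the moment form
    [w^-1 int_0^w h h' / g du] / gbar - hbar hbar' / gbar^2.
    """
    theta = family.validate_theta(theta)
    p = family.n_params
    gb = gbar(family, theta)
    hb = hbar(family, theta)
    w = family.w
    moment = np.empty((p, p))
    for i in range(p):
        for j in range(i + 1):
            def integrand(u, i=i, j=j):
                h = family.grad(u, theta)
                return float(h[i] * h[j] / family.g(u, theta))

            moment[i, j] = moment[j, i] = _quad(integrand, 0.0, w) / w
    Delta = moment / gb - np.outer(hb, hb) / gb**2
    return 0.5 * (Delta + Delta.T)


def var_known_theta(design: SurveyDesign, family: DetectionFamily, theta) -> float:
    """Variance of the abundance estimator when theta is known:
    N * P^-1 * gbar^-1 * (1 - P*gbar)."""
    if design.N is None:
        raise ConfigError("var_known_theta requires a known abundance N in the design")
    gb = gbar(family, theta)
    return design.N / (design.P * gb) * (1.0 - design.P * gb)


def penalty_F(family: DetectionFamily, theta, P: float, *, _parts=None) -> float:
    """Asymptotic variance penalty for unknown detection parameters.

    F = 1 + hbar' Delta^-1 hbar / (gbar^2 (1 - P gbar)); F >= 1 because
    Delta is a covariance matrix.  When the gradient mean is identically
    zero (parameter-free detection) F = 1 by limit.
    """
    if not 0.0 < P <= 1.0:
        raise ConfigError(f"coverage P must be in (0, 1], got {P}")
    if _parts is not None:
        gb, hb, Delta = _parts
    else:
        gb = gbar(family, theta)
        hb = hbar(family, theta)
        Delta = delta_matrix(family, theta)
    if np.allclose(hb, 0.0, atol=1e-12):
        return 1.0
    quad_form = float(hb @ _solve_delta(Delta, hb))
    return 1.0 + quad_form / (gb**2 * (1.0 - P * gb))


def fisher_blocks(design: SurveyDesign, family: DetectionFamily, theta) -> AsymptoticSummary:
    """Populate the Fisher-information blocks of (N, theta).

    I_NN   = N^-1 (1 - P gbar)^-1 P gbar
    I_Nth  = (1 - P gbar)^-1 P hbar
    I_thth = N P gbar Delta + N P hbar hbar' gbar^-1 (1 - P gbar)^-1
    """
    if design.N is None:
        raise ConfigError("fisher_blocks requires a known abundance N in the design")
    N, P = float(design.N), design.P
    gb = gbar(family, theta)
    hb = hbar(family, theta)
    Delta = delta_matrix(family, theta)
    q = 1.0 - P * gb
    summary = AsymptoticSummary(N=N, P=P, gbar=gb, hbar=hb, Delta=Delta)
    summary.I_NN = P * gb / (N * q)
    summary.I_Ntheta = P * hb / q
    summary.I_thetatheta = N * P * gb * Delta + N * P * np.outer(hb, hb) / (gb * q)
    summary.var_known = N * q / (P * gb)
    return summary


def variance_blocks(summary: AsymptoticSummary) -> AsymptoticSummary:
    """Fill the inverse (variance) blocks from their closed forms.

    V22 = N^-1 P^-1 Delta^-1 gbar^-1
    V11 = N (1 - P gbar) P^-1 gbar^-1 + N P^-1 gbar^-3 hbar' Delta^-1 hbar
    V21 = -gbar^-2 P^-1 Delta^-1 hbar
    """
    N, P, gb, hb = summary.N, summary.P, summary.gbar, summary.hbar
    p = len(hb)
    if np.allclose(hb, 0.0, atol=1e-12) and np.allclose(summary.Delta, 0.0, atol=1e-12):
        # parameter-free detection: theta carries no information (V22
        # unbounded) and abundance suffers no penalty
        summary.V22 = np.full((p, p), np.inf)
        summary.V11 = summary.var_known
        summary.V21 = np.zeros(p)
        summary.F = 1.0
        return summary
    Dinv_h = _solve_delta(summary.Delta, hb)
    summary.V22 = np.linalg.inv(np.atleast_2d(summary.Delta)) / (N * P * gb)
    summary.V11 = N * (1.0 - P * gb) / (P * gb) + N * float(hb @ Dinv_h) / (P * gb**3)
    summary.V21 = -Dinv_h / (P * gb**2)
    summary.F = summary.V11 / summary.var_known
    return summary


def cv_cds(F: float, E_n: float, N: float) -> float:
    """Coefficient of variation of the CDS estimator:
    sqrt(F * (1 - E[n]/N) / E[n])."""
    if F < 1.0:
        raise ConfigError(f"penalty F must be >= 1, got {F}")
    if not 0.0 < E_n < N:
        raise ConfigError(f"need 0 < E[n] < N, got E[n]={E_n}, N={N}")
    return math.sqrt(F * (1.0 - E_n / N) / E_n)


def sample_size(cv_target: float, F: float, N: float | None = None) -> float:
    """Expected detections needed to reach a target CV.

    With finite N: E[n] = (N^-1 + CV^2 / F)^-1; when n << N this
    simplifies to E[n] = F / CV^2.
    """
    if cv_target <= 0:
        raise ConfigError(f"target CV must be > 0, got {cv_target}")
    if F < 1.0:
        raise ConfigError(f"penalty F must be >= 1, got {F}")
    if N is None:
        return F / cv_target**2
    if N <= 0:
        raise ConfigError(f"abundance N must be positive, got {N}")
    return 1.0 / (1.0 / N + cv_target**2 / F)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention used in printed tables)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def penalty_table(
    family: DetectionFamily,
    P_list,
    gbar_list,
    shape_list=None,
    ndigits: int = 2,
) -> pd.DataFrame:
    """Grid of penalty factors F over coverage, mean detection and shape.

    Returns a tidy frame with columns P, gbar, shape (NaN for one-parameter
    families) and F rounded to ``ndigits`` decimals.  Cells whose scale
    calibration fails are recorded with F = NaN rather than aborting the
    whole grid.
    """
    shapes = [None] if shape_list is None else list(shape_list)
    rows = []
    for gb_target in gbar_list:
        for P in P_list:
            for shape in shapes:
                rec = {"P": P, "gbar": gb_target, "shape": np.nan if shape is None else shape}
                try:
                    scale = calibrate_scale(
                        family, gb_target, None if shape is None else [shape]
                    )
                    theta = [scale] if shape is None else [scale, shape]
                    rec["F"] = round_half_away(penalty_F(family, theta, P), ndigits)
                except Exception:
                    rec["F"] = np.nan
                rows.append(rec)
    return pd.DataFrame(rows, columns=["P", "gbar", "shape", "F"])


# Published grid layouts (w = 1): hazard-rate shapes by coverage and mean
# detection, and the matching half-normal grid.
_P_GRID = (0.1, 0.3, 0.6, 0.9)
_GBAR_GRID = (0.3, 0.6, 0.9)
_SHAPE_GRID = (1.1, 1.25, 1.5, 2.0, 2.5, 3.0)


def table_hazard_rate(w: float = 1.0) -> pd.DataFrame:
    """72-cell hazard-rate penalty grid (P x gbar x shape)."""
    from .families import hazard_rate

    return penalty_table(hazard_rate(w), _P_GRID, _GBAR_GRID, _SHAPE_GRID)


def table_half_normal(w: float = 1.0) -> pd.DataFrame:
    """12-cell half-normal penalty grid (P x gbar)."""
    from .families import half_normal

    return penalty_table(half_normal(w), _P_GRID, _GBAR_GRID)
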