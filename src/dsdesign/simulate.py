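"""Replicate simulation of line-transect surveys with overdispersion.

The generator places N object distances on (0, M).  Without overdispersion
they are independent uniforms, so the count n(v) falling in any interval of
length v*w is binomial bin(N, vP) with P = w/M.  Overdispersed distances are
drawn from a K-point discrete approximation to a Dirichlet process centred
on the uniform: category weights phi ~ Dirichlet(alpha/K, ..., alpha/K) over
K evenly spaced support points (bin midpoints), redrawn for every replicate,
then N categorical draws.  Interval counts are then beta-binomial with
variance c * N v P (1 - vP), where c = (alpha + N)/(alpha + 1) is the
overdispersion factor; alpha = (N - c)/(c - 1) inverts this.

Detection thinning keeps each object with distance d <= w independently
with probability g(d; theta_true).  Per replicate the harness computes the
known-theta estimator, conditional-ML CDS estimators for each requested
family, and the strip-transect curve over a width grid, then aggregates
bias, variance, MSE and relative RMSE, the empirical variance penalty, the
MSE-optimal strip width, and the width range over which the strip estimator
beats CDS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .estimation import (
    N_MIN_FIT,
    DistanceSample,
    estimate_cds,
    estimate_known_theta,
    fit_cml,
    strip_curve,
)
from .families import DetectionFamily, gbar, get_family

__all__ = [
    "SimulationConfig",
    "PopulationDraw",
    "SimulationResult",
    "draw_uniform_distances",
    "overdispersion_alpha",
    "draw_overdispersed_distances",
    "thin_by_detection",
    "run_simulation",
    "empirical_penalty",
    "optimal_strip_width",
    "crossing_range",
]


def _default_grid() -> np.ndarray:
    return np.round(np.arange(1, 101) * 0.01, 10)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulation cell.

    Defaults follow the standard design: truncation w = 1, maximum distance
    M = 10 (so coverage P = 0.1), K = 1000 discrete support points, strip
    widths 0.01, 0.02, ..., 1, and 10,000 replicates.
    """

    family: str
    theta_true: tuple
    E_n: float
    P: float = 0.1
    w: float = 1.0
    M: float = 10.0
    c: float = 1.0
    K: int = 1000
    reps: int = 10_000
    strip_grid: np.ndarray = field(default_factory=_default_grid)
    fit_families: tuple = ()
    master_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "strip_grid", np.asarray(self.strip_grid, dtype=float))
        object.__setattr__(self, "theta_true", tuple(float(t) for t in np.atleast_1d(self.theta_true)))
        object.__setattr__(self, "fit_families", tuple(self.fit_families))
        if self.E_n <= 0:
            raise ConfigError(f"E_n must be positive, got {self.E_n}")
        if self.c < 1.0:
            raise ConfigError(f"overdispersion factor c must be >= 1, got {self.c}")
        if self.K < 2:
            raise ConfigError(f"need at least 2 support points, got K={self.K}")
        if self.reps < 1:
            raise ConfigError(f"need at least 1 replicate, got {self.reps}")
        if abs(self.P - self.w / self.M) > 1e-9:
            raise ConfigError(f"P={self.P} inconsistent with w/M={self.w / self.M}")

    def detection_family(self) -> DetectionFamily:
        return get_family(self.family, self.w)

    def abundance(self) -> int:
        """N = round(E[n] / (P * gbar(theta_true)))."""
        fam = self.detection_family()
        N = int(round(self.E_n / (self.P * gbar(fam, self.theta_true))))
        if N < 1:
            raise ConfigError("target E_n implies an abundance below 1")
        return N


@dataclass(frozen=True)
class PopulationDraw:
    """All N object distances, plus the category weights if overdispersed."""

    distances_all: np.ndarray
    phi: np.ndarray | None = None


def draw_uniform_distances(N: int, M: float, rng: np.random.Generator) -> PopulationDraw:
    """N independent U(0, M) distances (the non-overdispersed case)."""
    if N < 1 or M <= 0:
        raise ConfigError(f"need N >= 1 and M > 0, got N={N}, M={M}")
    return PopulationDraw(rng.uniform(0.0, M, size=N))


def overdispersion_alpha(N: int, c: float) -> float:
    """Dirichlet total concentration alpha = (N - c)/(c - 1) giving interval
    counts with variance inflated by c = (alpha + N)/(alpha + 1)."""
    if c <= 1.0:
        raise ConfigError("c <= 1 has no finite alpha; use the uniform generator")
    if c >= N:
        raise ConfigError(f"overdispersion c must be < N, got c={c}, N={N}")
    return (N - c) / (c - 1.0)


def support_points(K: int, M: float) -> np.ndarray:
    """K evenly spaced support values on (0, M): bin midpoints
    (2k - 1) M / (2K), k = 1..K."""
    return (2.0 * np.arange(1, K + 1) - 1.0) * M / (2.0 * K)


def draw_overdispersed_distances(
    N: int, M: float, c: float, K: int, rng: np.random.Generator
) -> PopulationDraw:
    """Dirichlet-process-style overdispersed distances.

    phi ~ Dirichlet(alpha/K * 1_K) is redrawn per call; the N distances are
    then independent categorical draws over the K midpoint support values.
    """
    alpha = overdispersion_alpha(N, c)
    conc = np.full(K, alpha / K)
    phi = rng.dirichlet(conc)
    for _ in range(5):
        if phi.sum() > 0 and np.all(np.isfinite(phi)):
            break
        warnings.warn("degenerate Dirichlet draw; resampling", RuntimeWarning)
        phi = rng.dirichlet(conc)
    values = support_points(K, M)
    idx = rng.choice(K, size=N, p=phi)
    return PopulationDraw(values[idx], phi=phi)


def thin_by_detection(
    population: PopulationDraw,
    family: DetectionFamily,
    theta_true,
    rng: np.random.Generator,
) -> DistanceSample:
    """Apply the detection process: keep d <= w with probability g(d)."""
    d = population.distances_all
    inside = d[d <= family.w]
    if inside.size == 0:
        return DistanceSample(np.empty(0), w=family.w)
    detected = rng.random(inside.size) < family.g(inside, theta_true)
    return DistanceSample(inside[detected], w=family.w)


@dataclass
class SimulationResult:
    """Per-replicate estimates plus summary machinery."""

    config: SimulationConfig
    N: int
    n_detections: np.ndarray
    known_theta: np.ndarray
    cds: dict  # family name -> (reps,) array, NaN where the fit failed
    converged: dict  # family name -> bool array
    strip: np.ndarray  # (reps, len(strip_grid))

    def failure_counts(self) -> dict:
        return {k: int((~v).sum()) for k, v in self.converged.items()}

    @staticmethod
    def _moments(x: np.ndarray, N: int) -> dict:
        """Mean/variance/bias/MSE/RRMSE with the exact decomposition
        MSE = var + bias^2 (population variance)."""
        mean = float(np.mean(x))
        var = float(np.var(x))
        bias = mean - N
        mse = var + bias**2
        return {
            "mean": mean,
            "var": var,
            "bias": bias,
            "mse": mse,
            "rrmse_pct": 100.0 * np.sqrt(mse) / N,
        }

    def cds_values(self, fit_family: str | None = None) -> np.ndarray:
        """Converged CDS estimates for one fitted family."""
        if fit_family is None:
            if len(self.cds) != 1:
                raise ConfigError(
                    f"specify fit_family; result holds {sorted(self.cds)}"
                )
            fit_family = next(iter(self.cds))
        mask = self.converged[fit_family]
        return self.cds[fit_family][mask]

    def cds_mask(self, fit_family: str | None = None) -> np.ndarray:
        if fit_family is None:
            fit_family = next(iter(self.cds))
        return self.converged[fit_family]

    def strip_mse(self) -> np.ndarray:
        """Empirical MSE of the strip estimator at each grid width."""
        dev = self.strip - self.N
        return np.mean(dev * dev, axis=0)

    def summary(self) -> pd.DataFrame:
        """Tidy per-estimator summary (one row per estimator/statistic)."""
        rows = []

        def add(name, values, extra=None):
            rec = {"estimator": name, "n_reps_used": len(values)}
            rec.update(self._moments(np.asarray(values), self.N))
            if extra:
                rec.update(extra)
            rows.append(rec)

        add("known_theta", self.known_theta)
        for fam, vals in self.cds.items():
            add(
                f"cds_{fam}",
                vals[self.converged[fam]],
                {"n_failures": self.failure_counts()[fam]},
            )
        for j, wp in enumerate(self.config.strip_grid):
            add(f"strip_{wp:.2f}", self.strip[:, j])
        return pd.DataFrame(rows)

    def rrmse_curve(self) -> pd.DataFrame:
        """Strip RRMSE (%) by width, for plotting or CSV export."""
        mse = self.strip_mse()
        return pd.DataFrame(
            {
                "w_prime": self.config.strip_grid,
                "c": self.config.c,
                "rrmse_pct": 100.0 * np.sqrt(mse) / self.N,
            }
        )


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Run the replicate harness for one simulation cell.

    Each replicate draws a fresh population (fresh Dirichlet weights when
    c > 1), thins it by the detection process, fits each requested family by
    conditional ML, and evaluates all estimators.  Replicates get
    independent RNG substreams spawned from the master seed, so the whole
    result is reproducible and any single replicate can be replayed.
    """
    fam_true = config.detection_family()
    gb_true = gbar(fam_true, config.theta_true)
    N = config.abundance()
    fit_fams = {name: get_family(name, config.w) for name in config.fit_families}

    reps = config.reps
    n_det = np.zeros(reps, dtype=int)
    known = np.empty(reps)
    cds = {name: np.full(reps, np.nan) for name in fit_fams}
    conv = {name: np.zeros(reps, dtype=bool) for name in fit_fams}
    strip = np.empty((reps, config.strip_grid.size))

    streams = np.random.SeedSequence(config.master_seed).spawn(reps)
    for r in range(reps):
        rng = np.random.default_rng(streams[r])
        if config.c > 1.0:
            pop = draw_overdispersed_distances(N, config.M, config.c, config.K, rng)
        else:
            pop = draw_uniform_distances(N, config.M, rng)
        sample = thin_by_detection(pop, fam_true, config.theta_true, rng)
        n_det[r] = sample.n
        known[r] = sample.n / (config.P * gb_true)
        for name, fam in fit_fams.items():
            if sample.n < N_MIN_FIT:
                continue
            fit = fit_cml(sample, fam)
            if fit.converged:
                conv[name][r] = True
                cds[name][r] = estimate_cds(sample.n, fit.theta_hat, fam, config.P)
        strip[r] = strip_curve(sample, config.P, config.strip_grid)

    result = SimulationResult(config, N, n_det, known, cds, conv, strip)
    for name, count in result.failure_counts().items():
        if count > 0.05 * reps:
            warnings.warn(
                f"{count}/{reps} replicates failed to converge for {name}",
                RuntimeWarning,
            )
    return result


def empirical_penalty(result: SimulationResult, fit_family: str | None = None) -> float:
    """Empirical variance ratio var(N_CDS) / var(N_known-theta).

    Uses variances (not MSEs), restricted to replicates whose fit converged
    so both estimator streams come from the same populations.
    """
    if fit_family is None:
        if len(result.cds) != 1:
            raise ConfigError(f"specify fit_family; result holds {sorted(result.cds)}")
        fit_family = next(iter(result.cds))
    mask = result.converged[fit_family]
    var_known = float(np.var(result.known_theta[mask]))
    if var_known == 0.0:
        raise ConfigError("known-theta estimator has zero variance; ratio undefined")
    return float(np.var(result.cds[fit_family][mask])) / var_known


def optimal_strip_width(result: SimulationResult) -> float:
    """Grid width minimizing the empirical strip MSE (ties -> smaller width)."""
    return float(result.config.strip_grid[int(np.argmin(result.strip_mse()))])


def crossing_range(
    result: SimulationResult, fit_family: str | None = None
) -> tuple[float, float] | None:
    """Smallest and largest widths where strip MSE beats CDS MSE.

    Returns None when the strip estimator never has lower MSE.
    """
    cds_vals = result.cds_values(fit_family)
    if cds_vals.size == 0:
        raise ConfigError("no converged CDS replicates")
    dev = cds_vals - result.N
    cds_mse = float(np.mean(dev * dev))
    below = result.strip_mse() < cds_mse
    if not below.any():
        return None
    idx = np.flatnonzero(below)
    grid = result.config.strip_grid
    return float(grid[idx[0]]), float(grid[idx[-1]])
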