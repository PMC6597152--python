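"""ABC rejection fitting of the spreading model to kinematic data.

The discrepancy between a simulation and an experiment combines an edge term
(per-frame RMS of minimum distances from computational edge points to the
experimental edge polyline, summed over frames) and a density-ratio term
(per-frame-pair RMS difference between computational and experimental density
ratios over the whole grid, summed over pairs), weighted

    z = z_d + w * z_p,   w = 1000 by default.

A candidate whose simulated tissue leaves the computational domain, or whose
centre density rises between frames, receives the NaN sentinel and can never
be accepted.  Rejection sampling draws parameters from uniform priors,
simulates, and keeps candidates with z at or below a tolerance threshold
(1500 by default); the accepted sets approximate the posterior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.stats import gaussian_kde

from .kinematics import DensityRatioMap, computational_density_ratio, interpolate_ratio_to_grid
from .model import PARAM_NAMES, ModelConfig, ParameterSet, PriorSpec, sample_prior
from .simulator import (BoundaryContour, FrameSeries, Grid, NumericalFailure,
                        Schedule, simulate)

__all__ = [
    "ExperimentDataset",
    "ErrorBreakdown",
    "Posterior",
    "NoAcceptanceError",
    "edge_distance_error",
    "distances_error",
    "density_ratio_error_frame",
    "density_error",
    "total_error",
    "evaluate_candidate",
    "calibrate_threshold",
    "abc_rejection",
    "posterior_summaries",
    "pairwise_correlations",
    "credible_intervals",
]

DEFAULT_WEIGHT = 1000.0
DEFAULT_THRESHOLD = 1500.0
CENTER_RISE_RTOL = 1e-6


class NoAcceptanceError(RuntimeError):
    """The candidate budget was exhausted with no acceptance."""


@dataclass
class ExperimentDataset:
    """Observed (or synthetic) kinematics of one spreading explant.

    contours[j] is the tissue edge at frame j (5-minute spacing by default);
    ratio_maps[j] is the density-ratio map for the frame pair (j, j+delta),
    defined for j = 1 .. t_end - delta on a pixel grid.
    """

    times: np.ndarray
    contours: list[BoundaryContour]
    ratio_maps: dict[int, DensityRatioMap]
    delta: int = 5
    pixel_size_um: float | None = None
    init_contour: BoundaryContour | None = None
    _grid_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.contours) != len(self.times):
            raise ValueError("one contour per frame time required")
        if len(self.times) < self.delta + 1:
            raise ValueError("dataset must span at least delta+1 frames")

    @property
    def initial_contour(self) -> BoundaryContour:
        """Simulation initial condition: a dedicated simple contour if one is
        stored (frame-0 segmentations can be too noisy to seed a level set),
        otherwise the frame-0 edge."""
        return self.init_contour if self.init_contour is not None else self.contours[0]

    @property
    def t_end_index(self) -> int:
        return len(self.times) - 1

    def ratio_maps_on_grid(self, grid: Grid) -> dict[int, DensityRatioMap]:
        """Experimental ratio maps bilinearly interpolated onto `grid` (cached)."""
        key = (grid.x0, grid.y0, grid.h, grid.nx, grid.ny)
        if key not in self._grid_cache:
            self._grid_cache[key] = {
                j: interpolate_ratio_to_grid(m, grid)
                for j, m in self.ratio_maps.items()
            }
        return self._grid_cache[key]


@dataclass
class ErrorBreakdown:
    """Per-frame error terms and rejection flags for one candidate."""

    D: np.ndarray
    P: np.ndarray
    z_d: float
    z_p: float
    w: float
    z: float
    rejected_reason: str = "none"   # none | escaped_domain | center_density_increased | numerical_failure


@dataclass
class Posterior:
    """Accepted parameter sets with their errors."""

    samples: pd.DataFrame      # columns: F_over_k, k_over_b, alpha, rho_unstressed, z
    n_attempted: int
    threshold: float
    priors: PriorSpec
    seed: int | None = None

    @property
    def n_accepted(self) -> int:
        return len(self.samples)

    def to_csv(self, path) -> None:
        self.samples.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# error function


def edge_distance_error(comp: BoundaryContour, exp: BoundaryContour) -> float:
    """RMS over computational edge points of the minimum distance to the
    experimental edge polyline (point-to-segment, closed)."""
    if len(comp.points) == 0 or len(exp.points) == 0:
        raise ValueError("contours must be nonempty")
    ring = shapely.LinearRing(exp.points)
    shapely.prepare(ring)
    pts = shapely.points(comp.points[:, 0], comp.points[:, 1])
    d = shapely.distance(ring, pts)
    return float(np.sqrt(np.mean(d * d)))


def distances_error(series: FrameSeries, data: ExperimentDataset) -> float:
    """Edge error summed over frames j = 1 .. t_end (t=0 excluded)."""
    if series.n_frames != len(data.contours):
        raise ValueError("simulation and dataset frame counts differ")
    if not np.allclose(series.times, data.times):
        raise ValueError("simulation and dataset frame times differ")
    return float(sum(edge_distance_error(series.contours[j], data.contours[j])
                     for j in range(1, series.n_frames)))


def density_ratio_error_frame(xi_comp: DensityRatioMap, xi_exp: DensityRatioMap) -> float:
    """RMS of (xi_comp - xi_exp) over every grid node (0 sentinels included)."""
    if xi_comp.xi.shape != xi_exp.xi.shape:
        raise ValueError("ratio maps must share the grid shape")
    diff = xi_comp.xi - xi_exp.xi
    return float(np.sqrt(np.mean(diff * diff)))


def density_error(series: FrameSeries, data: ExperimentDataset) -> float:
    """Density-ratio error summed over frame pairs j = 1 .. t_end - delta."""
    delta = data.delta
    if series.n_frames <= delta + 1:
        raise ValueError("series too short for the pairing increment delta")
    exp_maps = data.ratio_maps_on_grid(series.grid)
    z_p = 0.0
    for j in range(1, series.n_frames - delta):
        if j not in exp_maps:
            raise ValueError(f"dataset lacks a ratio map for frame pair ({j}, {j + delta})")
        xi_comp = computational_density_ratio(series, j, delta)
        z_p += density_ratio_error_frame(xi_comp, exp_maps[j])
    return float(z_p)


def total_error(z_d: float, z_p: float, flags: str = "none",
                w: float = DEFAULT_WEIGHT) -> float:
    """z = z_d + w z_p, or the NaN sentinel when a rejection flag is set."""
    if flags != "none":
        return float("nan")
    return float(z_d + w * z_p)


def _center_density_increased(series: FrameSeries) -> bool:
    c = series.center_density
    if len(c) < 3:
        return False
    prev, nxt = c[1:-1], c[2:]
    return bool(np.any(nxt > prev * (1.0 + CENTER_RISE_RTOL) + 1e-300))


def evaluate_candidate(theta: ParameterSet, data: ExperimentDataset, grid: Grid,
                       schedule: Schedule | None = None,
                       config: ModelConfig | None = None,
                       w: float = DEFAULT_WEIGHT) -> ErrorBreakdown:
    """Simulate one candidate from the dataset's initial contour and score it."""
    if schedule is None:
        schedule = Schedule(frame_interval_h=float(data.times[1] - data.times[0]),
                            t_end_h=float(data.times[-1]))
    nan = float("nan")
    try:
        series = simulate(data.initial_contour, theta, grid, schedule, config)
    except NumericalFailure:
        return ErrorBreakdown(D=np.array([]), P=np.array([]), z_d=nan, z_p=nan,
                              w=w, z=nan, rejected_reason="numerical_failure")
    if series.escaped:
        return ErrorBreakdown(D=np.array([]), P=np.array([]), z_d=nan, z_p=nan,
                              w=w, z=nan, rejected_reason="escaped_domain")
    if _center_density_increased(series):
        return ErrorBreakdown(D=np.array([]), P=np.array([]), z_d=nan, z_p=nan,
                              w=w, z=nan, rejected_reason="center_density_increased")

    D = np.array([edge_distance_error(series.contours[j], data.contours[j])
                  for j in range(1, series.n_frames)])
    exp_maps = data.ratio_maps_on_grid(grid)
    P = np.array([density_ratio_error_frame(
        computational_density_ratio(series, j, data.delta), exp_maps[j])
        for j in range(1, series.n_frames - data.delta)])
    z_d = float(D.sum())
    z_p = float(P.sum())
    return ErrorBreakdown(D=D, P=P, z_d=z_d, z_p=z_p, w=w,
                          z=total_error(z_d, z_p, "none", w))


# ---------------------------------------------------------------------------
# rejection sampling


def abc_rejection(data: ExperimentDataset, priors: PriorSpec,
                  grid: Grid,
                  threshold: float = DEFAULT_THRESHOLD,
                  n_accept: int = 200,
                  rng: np.random.Generator | int | None = None,
                  budget: int | None = None,
                  schedule: Schedule | None = None,
                  config: ModelConfig | None = None,
                  w: float = DEFAULT_WEIGHT,
                  progress: bool = False) -> Posterior:
    """Collect n_accept parameter sets with z <= threshold (NaN never accepted).

    Stops when the acceptance quota or the candidate budget (default
    50 * n_accept) is reached; raises NoAcceptanceError if the budget runs
    out with nothing accepted.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if n_accept < 1:
        raise ValueError("n_accept must be >= 1")
    seed = rng if isinstance(rng, int) else None
    rng = np.random.default_rng(rng)
    if budget is None:
        budget = 50 * n_accept
    rows: list[dict] = []
    n_attempted = 0
    while len(rows) < n_accept and n_attempted < budget:
        theta = sample_prior(priors, rng)
        n_attempted += 1
        bd = evaluate_candidate(theta, data, grid, schedule, config, w)
        if math.isfinite(bd.z) and bd.z <= threshold:
            rows.append({**theta.to_dict(), "z": bd.z})
        if progress and n_attempted % 25 == 0:
            print(f"  attempted {n_attempted}, accepted {len(rows)}", flush=True)
    if not rows:
        raise NoAcceptanceError(
            f"no candidate of {n_attempted} reached z <= {threshold}; "
            "consider raising the threshold")
    samples = pd.DataFrame(rows, columns=list(PARAM_NAMES) + ["z"])
    return Posterior(samples=samples, n_attempted=n_attempted,
                     threshold=threshold, priors=priors, seed=seed)


def calibrate_threshold(data: ExperimentDataset, priors: PriorSpec, grid: Grid,
                        rng: np.random.Generator | int | None = None,
                        n_pilot: int = 100,
                        accept_quantile: float = 0.15,
                        schedule: Schedule | None = None,
                        config: ModelConfig | None = None,
                        w: float = DEFAULT_WEIGHT) -> float:
    """Pilot-run threshold: the given quantile of finite candidate errors.

    Gives a target acceptance rate of roughly `accept_quantile` among
    candidates that do not trip a rejection flag.
    """
    rng = np.random.default_rng(rng)
    zs = []
    for _ in range(n_pilot):
        theta = sample_prior(priors, rng)
        bd = evaluate_candidate(theta, data, grid, schedule, config, w)
        if math.isfinite(bd.z):
            zs.append(bd.z)
    if not zs:
        raise NoAcceptanceError("every pilot candidate tripped a rejection flag")
    return float(np.quantile(zs, accept_quantile))


# ---------------------------------------------------------------------------
# posterior summaries


def posterior_summaries(post: Posterior, bins: int = 30) -> dict:
    """1D histograms with kernel-smoothed curves and modes, 2D histograms for
    all parameter pairs, the posterior mean, and the 3 smallest-error sets."""
    if post.n_accepted < 1:
        raise ValueError("empty posterior")
    df = post.samples
    out: dict = {"mean": {}, "mode": {}, "hist1d": {}, "kde": {}, "hist2d": {}}
    for name in PARAM_NAMES:
        x = df[name].to_numpy()
        lo, hi = post.priors.bounds(name)
        counts, edges = np.histogram(x, bins=bins, range=(lo, hi))
        out["hist1d"][name] = (counts, edges)
        out["mean"][name] = float(x.mean())
        xs = np.linspace(lo, hi, 512)
        if len(x) > 1 and np.std(x) > 0:
            dens = gaussian_kde(x, bw_method="silverman")(xs)
        else:  # degenerate sample: spike at the value
            dens = np.zeros_like(xs)
            dens[np.argmin(np.abs(xs - x[0]))] = 1.0
        out["kde"][name] = (xs, dens)
        out["mode"][name] = float(xs[np.argmax(dens)])
    for i, a in enumerate(PARAM_NAMES):
        for b in PARAM_NAMES[i + 1:]:
            H, xe, ye = np.histogram2d(df[a], df[b], bins=bins,
                                       range=[post.priors.bounds(a),
                                              post.priors.bounds(b)])
            out["hist2d"][(a, b)] = (H, xe, ye)
    best = df.nsmallest(3, "z").reset_index(drop=True)
    out["best"] = best
    return out


def pairwise_correlations(post: Posterior, fraction: float = 0.2) -> pd.DataFrame:
    """Pearson correlations over the smallest-z `fraction` of the samples.

    Zero-variance parameters yield NaN entries (flagged, not silently 0).
    """
    k = max(3, int(round(fraction * post.n_accepted)))
    if post.n_accepted < 3:
        raise ValueError("need at least 3 accepted samples")
    sub = post.samples.nsmallest(k, "z")[list(PARAM_NAMES)]
    vals = sub.to_numpy()
    std = vals.std(axis=0)
    corr = np.full((4, 4), np.nan)
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(vals, rowvar=False)
    for i in range(4):
        for j in range(4):
            if i == j:
                corr[i, j] = 1.0
            elif std[i] > 0 and std[j] > 0:
                corr[i, j] = c[i, j]
    return pd.DataFrame(corr, index=PARAM_NAMES, columns=PARAM_NAMES)


def credible_intervals(post: Posterior, level: float = 0.95) -> dict[str, tuple[float, float]]:
    """Central percentile intervals of each parameter's accepted values."""
    if post.n_accepted < 2:
        raise ValueError("need at least 2 accepted samples")
    lo_q, hi_q = (1 - level) / 2, (1 + level) / 2
    return {name: (float(np.quantile(post.samples[name], lo_q)),
                   float(np.quantile(post.samples[name], hi_q)))
            for name in PARAM_NAMES}
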