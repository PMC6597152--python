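"""Moving-boundary solver for the spreading-tissue model on a fixed grid.

The tissue occupies the region where a level-set field phi is negative; the
zero contour of phi is the free edge.  Density diffuses inside the tissue
with diffusivity k/b and a mass-limited logistic source, the edge carries a
Dirichlet density rho_unstressed * exp(-F/k), and the edge advances with the
normal speed -(k/b) exp(F/k) (grad rho . n) / rho_unstressed.

Numerics: explicit finite differences on a square grid.  The Dirichlet
condition at the (generally off-grid) interface is imposed through ghost
values obtained by linear extrapolation across the cut point (cut fraction
clamped to [theta_min, 1]); the diffusion update is sub-stepped so that every
update is a convex combination of old values and the boundary value, which
guarantees a discrete maximum principle.  The front speed is evaluated near
the interface, extended to a narrow band by nearest-interface-node copy, and
phi is advected with first-order Godunov upwinding.  phi is reinitialised to
a signed distance every `reinit_every` steps from the marching-squares zero
contour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage
from scipy.stats import linregress
from skimage import measure

from .model import ModelConfig, ParameterSet, boundary_density

__all__ = [
    "Grid",
    "BoundaryContour",
    "TissueState",
    "FrameSeries",
    "Schedule",
    "NumericalFailure",
    "EmptyTissueError",
    "initialize_state",
    "compute_dt",
    "step",
    "simulate",
    "extract_contour",
    "total_mass",
    "area_spreading_rate",
    "signed_distance",
]

UM2_PER_MM2 = 1.0e6


class NumericalFailure(RuntimeError):
    """The solver produced non-finite fields; carries the offending state."""

    def __init__(self, message: str, state: "TissueState | None" = None):
        super().__init__(message)
        self.state = state


class EmptyTissueError(ValueError):
    """No zero contour: the level-set field has one sign everywhere."""


@dataclass(frozen=True)
class Grid:
    """Square-cell computational grid.

    Arrays over the grid are indexed [iy, ix]; x runs along columns
    (x = x0 + ix*h), y along rows (y = y0 + iy*h).  The outermost nodes form
    the domain edge, on which the density satisfies a zero-flux condition.
    """

    x0: float
    y0: float
    h: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("grid spacing h must be > 0")
        if self.nx < 16 or self.ny < 16:
            raise ValueError("grid must be at least 16x16 nodes")

    @classmethod
    def square(cls, extent_um: float, h: float, x0: float = 0.0, y0: float = 0.0) -> "Grid":
        n = int(round(extent_um / h)) + 1
        return cls(x0=x0, y0=y0, h=h, nx=n, ny=n)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def cell_area_mm2(self) -> float:
        return self.h * self.h / UM2_PER_MM2

    def xs(self) -> np.ndarray:
        return self.x0 + self.h * np.arange(self.nx)

    def ys(self) -> np.ndarray:
        return self.y0 + self.h * np.arange(self.ny)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.xs(), self.ys())

    def node_near(self, x: float, y: float) -> tuple[int, int]:
        """(iy, ix) of the node nearest a physical point."""
        ix = int(np.clip(round((x - self.x0) / self.h), 0, self.nx - 1))
        iy = int(np.clip(round((y - self.y0) / self.h), 0, self.ny - 1))
        return iy, ix


@dataclass(frozen=True)
class BoundaryContour:
    """Closed simple polyline of the tissue edge, in um, counter-clockwise.

    The polygon is implicitly closed (last point joins the first).
    """

    points: np.ndarray  # (N, 2) columns x, y

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("contour points must be an (N, 2) array")
        # drop an explicit closing point
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 8:
            raise ValueError(f"contour needs >= 8 points, got {len(pts)}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("contour contains non-finite coordinates")
        # canonical counter-clockwise orientation
        if _shoelace(pts) < 0:
            pts = pts[::-1]
        object.__setattr__(self, "points", pts)

    def validate_simple(self) -> None:
        ring = shapely.LinearRing(self.points)
        if not ring.is_simple:
            raise ValueError("contour is self-intersecting")

    def area_um2(self) -> float:
        return abs(_shoelace(self.points))

    def area_mm2(self) -> float:
        return self.area_um2() / UM2_PER_MM2

    def centroid(self) -> tuple[float, float]:
        c = shapely.Polygon(self.points).centroid
        return c.x, c.y

    def resample(self, n: int) -> "BoundaryContour":
        """Resample to n points equally spaced in arc length."""
        pts = np.vstack([self.points, self.points[:1]])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        targets = np.linspace(0.0, s[-1], n, endpoint=False)
        x = np.interp(targets, s, pts[:, 0])
        y = np.interp(targets, s, pts[:, 1])
        return BoundaryContour(np.column_stack([x, y]))


def _shoelace(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class TissueState:
    """Level-set field, density field and mass bookkeeping at one time.

    phi < 0 marks tissue; rho (cells/mm^2) is meaningful where phi < 0 and
    holds extrapolated edge values elsewhere.  m is the cumulative mass added
    by the growth term since t=0 (cells); m0 the initial mass.
    """

    grid: Grid
    phi: np.ndarray
    rho: np.ndarray
    m: float
    m0: float
    t: float
    escaped: bool = False

    @property
    def inside(self) -> np.ndarray:
        return self.phi < 0


@dataclass(frozen=True)
class Schedule:
    """Frame sampling: 5-minute frames over 10 hours by default."""

    frame_interval_h: float = 5.0 / 60.0
    t_end_h: float = 10.0

    def times(self) -> np.ndarray:
        n = int(round(self.t_end_h / self.frame_interval_h))
        return self.frame_interval_h * np.arange(n + 1)


@dataclass
class FrameSeries:
    """Simulation output sampled at frame times."""

    grid: Grid
    times: np.ndarray
    contours: list[BoundaryContour]
    densities: list[np.ndarray]
    inside_masks: list[np.ndarray]
    center_density: np.ndarray
    escaped: bool
    center_node: tuple[int, int]

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def areas_mm2(self) -> np.ndarray:
        return np.array([c.area_mm2() for c in self.contours])


# ---------------------------------------------------------------------------
# geometry helpers


def signed_distance(contour: BoundaryContour, grid: Grid) -> np.ndarray:
    """Signed distance to the contour on grid nodes; negative inside."""
    ring = shapely.LinearRing(contour.points)
    poly = shapely.Polygon(contour.points)
    shapely.prepare(ring)
    shapely.prepare(poly)
    X, Y = grid.meshgrid()
    pts = shapely.points(X.ravel(), Y.ravel())
    dist = shapely.distance(ring, pts).reshape(grid.shape)
    inside = shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(grid.shape)
    return np.where(inside, -dist, dist)


def extract_contour(phi: np.ndarray, grid: Grid) -> BoundaryContour:
    """Zero contour of phi as a closed polyline in um (largest component)."""
    contours = measure.find_contours(phi, 0.0)
    contours = [c for c in contours if len(c) >= 8]
    if not contours:
        raise EmptyTissueError("no zero contour in the level-set field")
    best = max(contours, key=lambda c: abs(_shoelace(c[:, ::-1])))
    xy = np.column_stack([grid.x0 + best[:, 1] * grid.h,
                          grid.y0 + best[:, 0] * grid.h])
    return BoundaryContour(xy)


def total_mass(state: TissueState) -> float:
    """Tissue mass in cells: sum of rho * cell area, with a subcell weight.

    Cells cut by the interface contribute with weight 1/2 at phi = 0,
    ramping linearly to full weight at phi = -h/2 and zero at phi = +h/2.
    """
    w = np.clip(0.5 - state.phi / state.grid.h, 0.0, 1.0)
    return float(np.sum(state.rho * w)) * state.grid.cell_area_mm2


# ---------------------------------------------------------------------------
# initialisation


def initialize_state(contour: BoundaryContour, grid: Grid,
                     params: ParameterSet, config: ModelConfig | None = None,
                     margin_cells: int = 3) -> TissueState:
    """Initial state: signed-distance phi, uniform interior density, m = 0."""
    if config is None:
        config = ModelConfig()
    contour.validate_simple()
    xmin, ymin = contour.points.min(axis=0)
    xmax, ymax = contour.points.max(axis=0)
    if (xmin < grid.x0 + margin_cells * grid.h
            or ymin < grid.y0 + margin_cells * grid.h
            or xmax > grid.x0 + (grid.nx - 1 - margin_cells) * grid.h
            or ymax > grid.y0 + (grid.ny - 1 - margin_cells) * grid.h):
        raise ValueError("initial contour too close to the domain edge")
    phi = signed_distance(contour, grid)
    rho_b = boundary_density(params) * config.density_unit_scale
    rho = np.where(phi < 0, config.rho_init, rho_b)
    state = TissueState(grid=grid, phi=phi, rho=rho, m=0.0, m0=0.0, t=0.0)
    state.m0 = total_mass(state)
    return state


# ---------------------------------------------------------------------------
# stepping


def compute_dt(grid: Grid, params: ParameterSet, vmax: float,
               safety: float = 0.9) -> float:
    """Stable step from diffusion, advection and growth limits."""
    if vmax < 0:
        raise ValueError("vmax must be >= 0")
    h = grid.h
    dt = h * h / (4.0 * params.k_over_b)
    if vmax > 0:
        dt = min(dt, h / (2.0 * vmax))
    if params.alpha > 0:
        dt = min(dt, 1.0 / (4.0 * params.alpha))
    return safety * dt


def _shift(a: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Array of neighbour values: out[i, j] = a[i+dy, j+dx], edges replicated.

    Edge replication realises the zero-flux condition on the domain edge.
    """
    p = np.pad(a, 1, mode="edge")
    ny, nx = a.shape
    return p[1 + dy:1 + dy + ny, 1 + dx:1 + dx + nx]


_DIRS = ((1, 0), (-1, 0), (0, 1), (0, -1))
_THETA_MIN = 0.25


def _cut_geometry(phi: np.ndarray, inside: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-node stencil geometry for the ghost-value Laplacian.

    Returns (n_reg, sum_inv_theta): the number of inside 4-neighbours of each
    inside node, and the sum over its cut directions of 1/theta, where
    theta = phi_i/(phi_i - phi_nb) is the cut fraction clamped to
    [theta_min, 1].  Both are zero outside the tissue.
    """
    n_reg = np.zeros(phi.shape)
    sum_inv_theta = np.zeros(phi.shape)
    for dy, dx in _DIRS:
        phi_nb = _shift(phi, dy, dx)
        nb_inside = phi_nb < 0
        n_reg += inside & nb_inside
        denom = phi - phi_nb
        with np.errstate(divide="ignore", invalid="ignore"):
            theta = np.where(denom != 0, phi / denom, 1.0)
        theta = np.clip(theta, _THETA_MIN, 1.0)
        sum_inv_theta += np.where(inside & ~nb_inside, 1.0 / theta, 0.0)
    return n_reg, sum_inv_theta


def _diffusion_increment(phi: np.ndarray, rho: np.ndarray, rho_b: float,
                         h: float, inside: np.ndarray,
                         geometry: tuple[np.ndarray, np.ndarray] | None = None,
                         ) -> np.ndarray:
    """Ghost-value five-point Laplacian of rho on interior nodes (0 elsewhere).

    Directions whose neighbour lies outside the tissue contribute
    (rho_b - rho_i)/theta at the cut fraction theta (see _cut_geometry).
    With the sub-step bound used in step() every update is a convex
    combination of old values and rho_b.
    """
    if geometry is None:
        geometry = _cut_geometry(phi, inside)
    n_reg, sum_inv_theta = geometry
    rho_in = np.where(inside, rho, 0.0)
    p = np.pad(rho_in, 1, mode="edge")  # edge replication = zero-flux domain edge
    nb_sum = p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:]
    inc = nb_sum - n_reg * rho + (rho_b - rho) * sum_inv_theta
    return np.where(inside, inc, 0.0) / (h * h)


def _ghost_fill(phi: np.ndarray, rho: np.ndarray, rho_b: float) -> np.ndarray:
    """Density field extended past the interface for gradients/engulfment.

    Outside nodes adjacent to the tissue carry the linear extrapolation of
    the interior profile through the interface Dirichlet value (averaged over
    crossing directions); other outside nodes carry the boundary value.
    """
    inside = phi < 0
    fill = np.where(inside, rho, rho_b)
    acc = np.zeros_like(rho)
    cnt = np.zeros(rho.shape, dtype=np.int32)
    for dy, dx in _DIRS:
        phi_n = _shift(phi, dy, dx)
        rho_n = _shift(rho, dy, dx)
        pair = (~inside) & (phi_n < 0)
        denom = phi_n - phi
        with np.errstate(divide="ignore", invalid="ignore"):
            theta = np.where(denom != 0, phi_n / denom, 1.0)
        theta = np.clip(theta, _THETA_MIN, 1.0)
        ghost = rho_n + (rho_b - rho_n) / theta
        acc[pair] += ghost[pair]
        cnt[pair] += 1
    edge = cnt > 0
    fill[edge] = acc[edge] / cnt[edge]
    return fill


def _growth(rho: np.ndarray, m: float, m0: float, params: ParameterSet,
            config: ModelConfig) -> np.ndarray:
    if m >= config.mass_cap_fraction * m0:
        return np.zeros_like(rho)
    rho_tilde = params.rho_unstressed * config.density_unit_scale * math.exp(params.F_over_k)
    return params.alpha * rho * (1.0 - rho / rho_tilde)


def _front_velocity(phi: np.ndarray, rho: np.ndarray, rho_b: float, grid: Grid,
                    params: ParameterSet, config: ModelConfig,
                    band_halfwidth: float = 6.0) -> tuple[np.ndarray, float]:
    """Extended normal front speed on the grid (um/h) and its band maximum.

    At each interior node near the front the interface point is located along
    the normal (x_I = x - phi n), the density is sampled (bilinearly) one grid
    spacing inside the interface along -n, and the normal density gradient is
    the two-point form (rho_b - rho_1)/h — the same form as the interface
    diffusion flux, which keeps the discrete front law mass-conservative
    (analytically v = -D grad rho . n / rho_b).  The speed is then extended
    to a narrow band by nearest-source copy.
    """
    h = grid.h
    py, px = np.gradient(phi, h)
    norm = np.hypot(px, py)
    norm[norm == 0] = 1.0
    nx_, ny_ = px / norm, py / norm

    source = (phi < 0) & (phi >= -1.5 * h)
    if not source.any():
        return np.zeros_like(phi), 0.0
    iy_s, ix_s = np.nonzero(source)
    x = grid.x0 + ix_s * h
    y = grid.y0 + iy_s * h
    n_x, n_y = nx_[iy_s, ix_s], ny_[iy_s, ix_s]
    d = phi[iy_s, ix_s]
    xi_x, xi_y = x - d * n_x, y - d * n_y       # interface point
    sx = (xi_x - h * n_x - grid.x0) / h          # column coordinate
    sy = (xi_y - h * n_y - grid.y0) / h          # row coordinate
    rho_1 = ndimage.map_coordinates(rho, [sy, sx], order=1, mode="nearest")
    grad_n = (rho_b - rho_1) / h
    rho_u = params.rho_unstressed * config.density_unit_scale
    v_src = -(params.k_over_b * math.exp(params.F_over_k) / rho_u) * grad_n

    v = np.zeros_like(phi)
    v[iy_s, ix_s] = v_src
    _, (iy, ix) = ndimage.distance_transform_edt(~source, return_indices=True)
    v_ext = v[iy, ix]
    band = np.abs(phi) <= band_halfwidth * h
    v_ext = np.where(band, v_ext, 0.0)
    return v_ext, float(np.max(np.abs(v_ext[band])))


def _advect_upwind(phi: np.ndarray, v: np.ndarray, h: float, dt: float) -> np.ndarray:
    """First-order Godunov update of phi_t + v |grad phi| = 0."""
    dxm = (phi - _shift(phi, 0, 1)) / h
    dxp = (_shift(phi, 0, -1) - phi) / h
    dym = (phi - _shift(phi, 1, 0)) / h
    dyp = (_shift(phi, -1, 0) - phi) / h
    gp = np.sqrt(np.maximum(dxm, 0.0) ** 2 + np.minimum(dxp, 0.0) ** 2
                 + np.maximum(dym, 0.0) ** 2 + np.minimum(dyp, 0.0) ** 2)
    gm = np.sqrt(np.minimum(dxm, 0.0) ** 2 + np.maximum(dxp, 0.0) ** 2
                 + np.minimum(dym, 0.0) ** 2 + np.maximum(dyp, 0.0) ** 2)
    return phi - dt * (np.maximum(v, 0.0) * gp + np.minimum(v, 0.0) * gm)


def step(state: TissueState, params: ParameterSet, dt: float,
         config: ModelConfig | None = None,
         freeze_front: bool = False) -> tuple[TissueState, float]:
    """Advance the state by dt.  Returns (new state, max front speed seen).

    The diffusion+growth update is internally sub-stepped so each substep is
    monotone even at cut cells; the front is advected once per call.
    `freeze_front=True` disables boundary motion (used in conservation
    checks).
    """
    if config is None:
        config = ModelConfig()
    grid, h = state.grid, state.grid.h
    D = params.k_over_b
    rho_b = boundary_density(params) * config.density_unit_scale
    inside = state.phi < 0

    # worst-case cut-cell stencil (four directions at theta_min) needs
    # dt_sub <= 0.9 h^2 / (4 D / theta_min) for a convex (monotone) update
    n_sub = max(1, int(math.ceil(dt / (0.9 * h * h * _THETA_MIN / (4.0 * D)))))
    dt_sub = dt / n_sub
    rho = state.rho.copy()
    m = state.m
    geometry = _cut_geometry(state.phi, inside)
    for _ in range(n_sub):
        inc = _diffusion_increment(state.phi, rho, rho_b, h, inside, geometry)
        q = _growth(rho, m, state.m0, params, config)
        rho = np.where(inside, rho + dt_sub * (D * inc + q), rho)
        m += dt_sub * float(np.sum(q[inside])) * grid.cell_area_mm2

    if freeze_front:
        vmax = 0.0
        phi = state.phi
    else:
        fill = _ghost_fill(state.phi, rho, rho_b)
        v, vmax = _front_velocity(state.phi, fill, rho_b, grid, params, config)
        phi = _advect_upwind(state.phi, v, h, dt)
        # newly engulfed nodes take the extrapolated edge density
        engulfed = (phi < 0) & ~inside
        rho = np.where(engulfed, fill, rho)

    if not (np.all(np.isfinite(rho)) and np.all(np.isfinite(phi)) and math.isfinite(m)):
        bad = TissueState(grid=grid, phi=phi, rho=rho, m=m, m0=state.m0,
                          t=state.t + dt, escaped=state.escaped)
        raise NumericalFailure("non-finite fields after step", bad)

    new = TissueState(grid=grid, phi=phi, rho=rho, m=m, m0=state.m0,
                      t=state.t + dt, escaped=state.escaped)
    return new, vmax


def _reinitialize(state: TissueState) -> None:
    """Rebuild phi as a signed distance to the current zero contour."""
    contour = extract_contour(state.phi, state.grid)
    ring = shapely.LinearRing(contour.points)
    X, Y = state.grid.meshgrid()
    dist = shapely.distance(ring, shapely.points(X.ravel(), Y.ravel()))
    dist = dist.reshape(state.grid.shape)
    state.phi = np.where(state.phi < 0, -dist, dist)


def _touches_border(phi: np.ndarray) -> bool:
    return bool((phi[0, :] < 0).any() or (phi[-1, :] < 0).any()
                or (phi[:, 0] < 0).any() or (phi[:, -1] < 0).any())


def simulate(contour: BoundaryContour, params: ParameterSet, grid: Grid,
             schedule: Schedule | None = None,
             config: ModelConfig | None = None,
             reinit_every: int = 20) -> FrameSeries:
    """Run the moving-boundary problem and sample frames.

    Emits one boundary contour and one density snapshot per frame time, a
    density trace at the node nearest the initial centroid, and an `escaped`
    flag set as soon as the tissue touches the domain edge (the run then
    stops; frames recorded so far are kept).
    """
    if schedule is None:
        schedule = Schedule()
    if config is None:
        config = ModelConfig()

    state = initialize_state(contour, grid, params, config)
    cx, cy = contour.centroid()
    center = grid.node_near(cx, cy)

    times = schedule.times()
    contours: list[BoundaryContour] = [extract_contour(state.phi, grid)]
    densities: list[np.ndarray] = [np.where(state.inside, state.rho, 0.0)]
    masks: list[np.ndarray] = [state.inside.copy()]
    center_trace = [float(state.rho[center])]
    escaped = False

    # conservative first CFL guess: full density drop across one cell
    rho_b = boundary_density(params) * config.density_unit_scale
    vmax = (params.k_over_b * math.exp(params.F_over_k)
            * abs(config.rho_init - rho_b)
            / (grid.h * params.rho_unstressed * config.density_unit_scale))
    n_steps = 0
    for t_next in times[1:]:
        while state.t < t_next - 1e-12:
            dt = min(compute_dt(grid, params, vmax), t_next - state.t)
            state, v_seen = step(state, params, dt, config)
            vmax = max(v_seen, 1e-12)
            n_steps += 1
            if n_steps % reinit_every == 0:
                _reinitialize(state)
            if _touches_border(state.phi):
                escaped = True
                break
        if escaped:
            break
        contours.append(extract_contour(state.phi, grid))
        densities.append(np.where(state.inside, state.rho, 0.0))
        masks.append(state.inside.copy())
        center_trace.append(float(state.rho[center]))

    n = len(contours)
    return FrameSeries(grid=grid, times=times[:n], contours=contours,
                       densities=densities, inside_masks=masks,
                       center_density=np.array(center_trace),
                       escaped=escaped, center_node=center)


def area_spreading_rate(series: FrameSeries) -> float:
    """Least-squares slope of contour area (mm^2) against time (h)."""
    if series.n_frames < 2:
        raise ValueError("need at least two frames for a spreading rate")
    areas = series.areas_mm2()
    if np.allclose(areas, areas[0]):
        return 0.0
    return float(linregress(series.times, areas).slope)
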