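"""Synthetic spreading datasets with known ground-truth parameters.

The raw time-lapse images behind published explant datasets are rarely
deposited, so tests and recovery studies here run against pseudo-experiments:
the model is simulated at a known parameter set theta*, and the simulated
edges and density ratios are degraded with the statistical structure of
image-derived data — denser, jittered edge points (segmentation error is
bounded by ~5 px ≈ 40 um; the default jitter sigma is 13 um ≈ 5 px at
2.6 um/px) and multiplicative log-normal noise on the density ratios.

Also provides analytic displacement fields (translation, dilation, shear,
radial) with closed-form Jacobians for kinematics tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .inference import ExperimentDataset
from .kinematics import DensityRatioMap, DisplacementField, computational_density_ratio, \
    interpolate_ratio_to_grid
from .model import ModelConfig, ParameterSet
from .simulator import BoundaryContour, FrameSeries, Grid, Schedule, simulate

__all__ = [
    "SyntheticProtocol",
    "make_initial_contour",
    "generate_dataset",
    "make_displacement_field",
]


@dataclass(frozen=True)
class SyntheticProtocol:
    """Recipe for one pseudo-experiment.

    Initial areas span the observed explant range (~0.14-2.23 mm^2).  Noise
    magnitudes are protocol fields, never hidden constants: edge_jitter_um is
    the i.i.d. Gaussian jitter per coordinate of the experimental edge points,
    ratio_noise_sigma the log-sd of the multiplicative noise on on-mask
    density ratios.  The experimental edge carries point_multiplier times as
    many points as the computational edge.
    """

    theta_star: ParameterSet
    shape: str = "circle"            # circle | ellipse | blob
    area_mm2: float = 0.3
    frame_interval_h: float = 5.0 / 60.0
    t_end_h: float = 10.0
    delta: int = 5
    edge_jitter_um: float = 13.0
    ratio_noise_sigma: float = 0.02
    point_multiplier: int = 3
    pixel_size_um: float = 2.6
    ratio_pixel_size_um: float | None = None   # default: the simulation grid spacing
    axis_ratio: float = 2.0
    blob_amplitude: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.edge_jitter_um < 0 or self.ratio_noise_sigma < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if self.point_multiplier <= 1:
            raise ValueError("point_multiplier must exceed 1")
        if self.area_mm2 <= 0:
            raise ValueError("area must be positive")


def make_initial_contour(shape: str, area_mm2: float, n_points: int = 64,
                         rng: np.random.Generator | int | None = None,
                         center: tuple[float, float] = (0.0, 0.0),
                         axis_ratio: float = 2.0,
                         blob_amplitude: float = 0.08) -> BoundaryContour:
    """Closed simple contour of the requested area (polygon area exact).

    `blob` is a circle with a low-order Fourier perturbation of the radius;
    zero amplitude reduces it to the circle.
    """
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    rng = np.random.default_rng(rng)
    area_um2 = area_mm2 * 1e6
    R = math.sqrt(area_um2 / math.pi)
    t = np.linspace(0.0, 2.0 * math.pi, n_points, endpoint=False)
    if shape == "circle":
        x, y = R * np.cos(t), R * np.sin(t)
    elif shape == "ellipse":
        a, b = R * math.sqrt(axis_ratio), R / math.sqrt(axis_ratio)
        x, y = a * np.cos(t), b * np.sin(t)
    elif shape == "blob":
        r = np.full_like(t, R)
        for k in (2, 3, 4):
            amp = blob_amplitude * R * rng.uniform(0.3, 1.0) if blob_amplitude > 0 else 0.0
            phase = rng.uniform(0.0, 2.0 * math.pi)
            r = r + amp * np.cos(k * t + phase)
        x, y = r * np.cos(t), r * np.sin(t)
    else:
        raise ValueError(f"unknown shape {shape!r}")
    pts = np.column_stack([x, y])
    # rescale so the polygon (shoelace) area hits the target exactly
    poly_area = 0.5 * abs(np.sum(pts[:, 0] * np.roll(pts[:, 1], -1)
                                 - np.roll(pts[:, 0], -1) * pts[:, 1]))
    pts *= math.sqrt(area_um2 / poly_area)
    pts += np.asarray(center)
    return BoundaryContour(pts)


def _jitter_contour(contour: BoundaryContour, multiplier: int, sigma: float,
                    rng: np.random.Generator) -> BoundaryContour:
    dense = contour.resample(multiplier * len(contour.points))
    pts = dense.points + rng.normal(0.0, sigma, size=dense.points.shape)
    return BoundaryContour(pts)


def generate_dataset(protocol: SyntheticProtocol, grid: Grid,
                     config: ModelConfig | None = None,
                     center: tuple[float, float] | None = None,
                     ) -> tuple[ExperimentDataset, dict]:
    """Simulate at theta* and emit a noisy pseudo-experimental dataset.

    Returns (dataset, ground_truth) where ground_truth records theta*, the
    seed, the protocol and the noiseless FrameSeries.  The dataset's
    designated initial contour is the noise-free initial shape: i.i.d. point
    jitter at the dense experimental spacing does not yield a simple polygon,
    so the jittered frame-0 edge cannot seed a level set.
    """
    if config is None:
        config = ModelConfig()
    if center is None:
        center = (grid.x0 + (grid.nx - 1) * grid.h / 2.0,
                  grid.y0 + (grid.ny - 1) * grid.h / 2.0)
    rng = np.random.default_rng(protocol.seed)
    contour0 = make_initial_contour(protocol.shape, protocol.area_mm2,
                                    rng=rng, center=center,
                                    axis_ratio=protocol.axis_ratio,
                                    blob_amplitude=protocol.blob_amplitude)
    schedule = Schedule(frame_interval_h=protocol.frame_interval_h,
                        t_end_h=protocol.t_end_h)
    series = simulate(contour0, protocol.theta_star, grid, schedule, config)
    if series.escaped:
        raise RuntimeError("ground-truth simulation escaped the domain; "
                           "enlarge the grid or shrink the explant")

    exp_contours = [_jitter_contour(c, protocol.point_multiplier,
                                    protocol.edge_jitter_um, rng)
                    for c in series.contours]

    pix = protocol.ratio_pixel_size_um or grid.h
    if pix == grid.h:
        pixel_grid = grid
    else:
        ext_x, ext_y = (grid.nx - 1) * grid.h, (grid.ny - 1) * grid.h
        pixel_grid = Grid(x0=grid.x0, y0=grid.y0, h=pix,
                          nx=int(math.floor(ext_x / pix)) + 1,
                          ny=int(math.floor(ext_y / pix)) + 1)
    ratio_maps: dict[int, DensityRatioMap] = {}
    for j in range(1, series.n_frames - protocol.delta):
        xi_c = computational_density_ratio(series, j, protocol.delta)
        if pixel_grid is not grid:
            xi_c = interpolate_ratio_to_grid(xi_c, pixel_grid)
        noise = np.exp(rng.normal(0.0, protocol.ratio_noise_sigma, size=xi_c.xi.shape)) \
            if protocol.ratio_noise_sigma > 0 else 1.0
        xi = np.where(xi_c.mask, xi_c.xi * noise, 0.0)
        ratio_maps[j] = DensityRatioMap(xi=xi, mask=xi_c.mask, frame_j=j,
                                        delta=protocol.delta,
                                        pixel_size_um=pixel_grid.h,
                                        origin=(pixel_grid.x0, pixel_grid.y0))

    dataset = ExperimentDataset(times=series.times, contours=exp_contours,
                                ratio_maps=ratio_maps, delta=protocol.delta,
                                pixel_size_um=protocol.pixel_size_um,
                                init_contour=contour0)
    ground_truth = {"theta_star": protocol.theta_star, "seed": protocol.seed,
                    "protocol": protocol, "series": series}
    return dataset, ground_truth


def make_displacement_field(kind: str, shape: tuple[int, int],
                            pixel_size_um: float = 2.6,
                            amplitude: float = 0.1,
                            frame_j: int = 0, delta: int = 5,
                            ) -> tuple[DisplacementField, np.ndarray]:
    """Analytic displacement field plus its closed-form det F per pixel.

    kinds: 'zero'; 'translation' (uniform shift by amplitude um, det 1);
    'dilation' (u = s X, det (1+s)^2); 'shear' (u_x = gamma Y, det 1);
    'radial' (u = a r rhat: det (1+2ar)(1+ar)), all about the grid centre.
    """
    ny, nx = shape
    X, Y = np.meshgrid(pixel_size_um * np.arange(nx), pixel_size_um * np.arange(ny))
    Xc = X - X.mean()
    Yc = Y - Y.mean()
    ones = np.ones(shape)
    if kind == "zero":
        ux, uy, det = 0.0 * X, 0.0 * Y, ones
    elif kind == "translation":
        ux, uy, det = amplitude * ones, amplitude * ones, ones
    elif kind == "dilation":
        s = amplitude
        ux, uy, det = s * Xc, s * Yc, (1.0 + s) ** 2 * ones
    elif kind == "shear":
        g = amplitude
        ux, uy, det = g * Yc, 0.0 * Y, ones
    elif kind == "radial":
        a = amplitude
        r = np.hypot(Xc, Yc)
        ux, uy = a * r * Xc, a * r * Yc
        det = (1.0 + 2.0 * a * r) * (1.0 + a * r)
    else:
        raise ValueError(f"unknown displacement kind {kind!r}")
    u = DisplacementField(u_x=ux, u_y=uy, pixel_size_um=pixel_size_um,
                          frame_j=frame_j, delta=delta)
    return u, det
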