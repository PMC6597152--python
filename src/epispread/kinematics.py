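"""Strain and density-ratio maps from displacement fields.

Elastic registration of an image pair (frames j and j+delta) yields a
displacement field u(X).  Its gradient gives the deformation gradient
F = grad(u) + I, and under local conservation of mass det F equals the ratio
of the earlier to the later tissue density.  These per-pixel density ratios
are the kinematic observable the inference compares against the model's own
frame-to-frame density ratios.

Coordinate convention: arrays are indexed [row, col]; pixel (0, 0) maps to
the grid origin, x runs along columns and y along rows, and all positions are
in um after pixel-size scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .simulator import FrameSeries, Grid

__all__ = [
    "DisplacementField",
    "DeformationField",
    "DensityRatioMap",
    "displacement_gradient",
    "deformation_gradient",
    "strain_tensor",
    "density_ratio_from_displacement",
    "computational_density_ratio",
    "interpolate_ratio_to_grid",
]


@dataclass
class DisplacementField:
    """Registration output u = (u_x, u_y) on a pixel grid, in um."""

    u_x: np.ndarray
    u_y: np.ndarray
    pixel_size_um: float
    frame_j: int = 0
    delta: int = 5

    def __post_init__(self) -> None:
        self.u_x = np.asarray(self.u_x, dtype=float)
        self.u_y = np.asarray(self.u_y, dtype=float)
        if self.u_x.shape != self.u_y.shape:
            raise ValueError("u_x and u_y must have the same shape")
        if not (np.all(np.isfinite(self.u_x)) and np.all(np.isfinite(self.u_y))):
            raise ValueError("displacement field contains non-finite values")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u_x.shape


@dataclass
class DeformationField:
    """Per-pixel deformation gradient F = grad(u) + I and its Jacobian."""

    F: np.ndarray      # (ny, nx, 2, 2)
    det: np.ndarray    # (ny, nx)


@dataclass
class DensityRatioMap:
    """Per-node ratio of earlier to later density, with a validity mask.

    Off-mask nodes carry the 0 sentinel, matching the error-function
    convention in which absent tissue contributes a zero ratio.
    """

    xi: np.ndarray
    mask: np.ndarray
    frame_j: int = 0
    delta: int = 5
    pixel_size_um: float | None = None
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.xi.shape != self.mask.shape:
            raise ValueError("xi and mask must have the same shape")
        if np.any(self.xi[self.mask] <= 0):
            raise ValueError("density ratio must be positive on the mask")
        self.xi = np.where(self.mask, self.xi, 0.0)


def displacement_gradient(u: DisplacementField) -> np.ndarray:
    """Per-pixel 2x2 gradient of u: out[..., m, n] = d(u_m)/d(X_n).

    Central differences in the interior, one-sided at the borders; exact for
    affine displacement fields.  Axis order is (x, y): out[..., 0, 1] is
    d(u_x)/dY.
    """
    if u.shape[0] < 3 or u.shape[1] < 3:
        raise ValueError("need at least a 3x3 pixel grid")
    s = u.pixel_size_um
    dux_dy, dux_dx = np.gradient(u.u_x, s)
    duy_dy, duy_dx = np.gradient(u.u_y, s)
    out = np.empty(u.shape + (2, 2))
    out[..., 0, 0] = dux_dx
    out[..., 0, 1] = dux_dy
    out[..., 1, 0] = duy_dx
    out[..., 1, 1] = duy_dy
    return out


def deformation_gradient(grad_u: np.ndarray) -> DeformationField:
    """F = grad(u) + I at each pixel, with its determinant."""
    F = grad_u + np.eye(2)
    det = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
    return DeformationField(F=F, det=det)


def strain_tensor(grad_u: np.ndarray) -> dict[str, np.ndarray]:
    """Small-strain tensor eps = (grad u + grad u^T)/2 as named components."""
    return {
        "eps_xx": grad_u[..., 0, 0],
        "eps_yy": grad_u[..., 1, 1],
        "eps_xy": 0.5 * (grad_u[..., 0, 1] + grad_u[..., 1, 0]),
    }


def density_ratio_from_displacement(u: DisplacementField,
                                    mask: np.ndarray | None = None) -> DensityRatioMap:
    """Experimental density ratio xi = det F per pixel.

    `mask` marks pixels inside the tissue in both frames (all-true when not
    given); off-mask pixels carry the 0 sentinel.
    """
    det = deformation_gradient(displacement_gradient(u)).det
    if mask is None:
        mask = np.ones(det.shape, dtype=bool)
    mask = mask & (det > 0)
    return DensityRatioMap(xi=np.where(mask, det, 0.0), mask=mask,
                           frame_j=u.frame_j, delta=u.delta,
                           pixel_size_um=u.pixel_size_um)


def computational_density_ratio(series: FrameSeries, j: int, delta: int) -> DensityRatioMap:
    """Model-side ratio of the frame-j density to the frame-(j+delta) density.

    Valid only at nodes inside the tissue at both frames; 0 elsewhere.
    """
    if j < 0 or j + delta >= series.n_frames:
        raise IndexError(f"frame pair ({j}, {j + delta}) outside the series")
    rho_r = series.densities[j]
    rho_s = series.densities[j + delta]
    mask = series.inside_masks[j] & series.inside_masks[j + delta] & (rho_s > 0) & (rho_r > 0)
    xi = np.zeros_like(rho_r)
    xi[mask] = rho_r[mask] / rho_s[mask]
    return DensityRatioMap(xi=xi, mask=mask, frame_j=j, delta=delta,
                           pixel_size_um=series.grid.h,
                           origin=(series.grid.x0, series.grid.y0))


def interpolate_ratio_to_grid(ratio: DensityRatioMap, grid: Grid) -> DensityRatioMap:
    """Bilinear interpolation of a pixel-grid ratio map onto grid nodes.

    A node is on-mask only when all four surrounding pixels are on-mask.
    Raises if the pixel grid does not cover the computational grid extent.
    """
    if ratio.pixel_size_um is None:
        raise ValueError("ratio map needs a pixel size for interpolation")
    s = ratio.pixel_size_um
    oy, ox = ratio.origin[1], ratio.origin[0]
    ny, nx = ratio.xi.shape
    ys = oy + s * np.arange(ny)
    xs = ox + s * np.arange(nx)
    gx, gy = grid.xs(), grid.ys()
    eps = 1e-9 * s
    if (gx[0] < xs[0] - eps or gx[-1] > xs[-1] + eps
            or gy[0] < ys[0] - eps or gy[-1] > ys[-1] + eps):
        raise ValueError("pixel grid does not cover the computational grid")
    xi_interp = RegularGridInterpolator((ys, xs), ratio.xi, method="linear",
                                        bounds_error=False, fill_value=0.0)
    mk_interp = RegularGridInterpolator((ys, xs), ratio.mask.astype(float),
                                        method="linear", bounds_error=False,
                                        fill_value=0.0)
    X, Y = grid.meshgrid()
    pts = np.column_stack([Y.ravel(), X.ravel()])
    xi = xi_interp(pts).reshape(grid.shape)
    mask = mk_interp(pts).reshape(grid.shape) >= 1.0 - 1e-9
    return DensityRatioMap(xi=np.where(mask, xi, 0.0), mask=mask,
                           frame_j=ratio.frame_j, delta=ratio.delta,
                           pixel_size_um=grid.h, origin=(grid.x0, grid.y0))
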