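"""Constitutive relations and parameters of the spreading-tissue continuum model.

The tissue is a 2D compressible continuum in an Eulerian frame.  Its density
rho(x, t) obeys a diffusion equation with effective diffusivity k/b (residual
stretching modulus over substrate adhesion), plus a mass-limited logistic
source that represents visible material added by radial intercalation and
active cell shape change.  The free edge carries a Dirichlet density set by
the lamellipodial edge force F, and moves with a speed proportional to the
normal density gradient.

Units used throughout the package: lengths in micrometres, time in hours,
densities in cells/mm^2, mass in cells.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "ParameterSet",
    "PriorSpec",
    "ModelConfig",
    "boundary_density",
    "limiting_density",
    "growth_rate",
    "boundary_normal_velocity",
    "sample_prior",
]


@dataclass(frozen=True)
class ParameterSet:
    """Mechanical parameters of the spreading model.

    The edge force F, stiffness k and adhesion b enter the equations only as
    the ratios F/k and k/b, so only the ratios are carried.

    Attributes
    ----------
    F_over_k : float
        Dimensionless edge force over tissue stiffness; sets the density drop
        at the free edge.
    k_over_b : float
        Effective diffusivity, um^2/h.
    alpha : float
        Visible material growth rate, 1/h.
    rho_unstressed : float
        Density of relaxed (unstressed) tissue, cells/mm^2.
    """

    F_over_k: float
    k_over_b: float
    alpha: float
    rho_unstressed: float

    def __post_init__(self) -> None:
        vals = (self.F_over_k, self.k_over_b, self.alpha, self.rho_unstressed)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite parameter in {vals}")
        if self.F_over_k < 0:
            raise ValueError("F_over_k must be >= 0")
        if self.k_over_b <= 0:
            raise ValueError("k_over_b must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.rho_unstressed <= 0:
            raise ValueError("rho_unstressed must be > 0")

    # -- flat key/value serialisation -------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(
            F_over_k=float(d["F_over_k"]),
            k_over_b=float(d["k_over_b"]),
            alpha=float(d["alpha"]),
            rho_unstressed=float(d["rho_unstressed"]),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ParameterSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


PARAM_NAMES = ("F_over_k", "k_over_b", "alpha", "rho_unstressed")


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors U(a, b) for each model parameter.

    Defaults are the broad bounds used for the epiboly fits:
    F/k ~ U(0, 1.5), k/b ~ U(500, 5000) um^2/h, alpha ~ U(0, 1) 1/h,
    rho_unstressed ~ U(1000, 2000).
    """

    F_over_k: tuple[float, float] = (0.0, 1.5)
    k_over_b: tuple[float, float] = (500.0, 5000.0)
    alpha: tuple[float, float] = (0.0, 1.0)
    rho_unstressed: tuple[float, float] = (1000.0, 2000.0)

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            a, b = getattr(self, name)
            if not (a < b):
                raise ValueError(f"prior for {name}: need a < b, got ({a}, {b})")

    def bounds(self, name: str) -> tuple[float, float]:
        return getattr(self, name)

    def to_dict(self) -> dict:
        return {name: list(getattr(self, name)) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        kwargs = {name: tuple(map(float, d[name])) for name in d}
        return cls(**kwargs)


@dataclass(frozen=True)
class ModelConfig:
    """Non-inferred model settings.

    rho_init is the uniform initial interior density: 0.0047 cells/um^2,
    carried here as 4700 cells/mm^2 (the package's canonical density unit).
    mass_cap_fraction is the growth shutoff: visible material addition stops
    once cumulative added mass reaches this fraction of the initial mass
    (the tissue holds at most ~50% more cells than it started with).
    density_unit_scale multiplies prior rho_unstressed values on their way
    into a simulation, for users who want a different unit convention.
    """

    rho_init: float = 4700.0
    mass_cap_fraction: float = 0.5
    density_unit_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.rho_init <= 0:
            raise ValueError("rho_init must be > 0")
        if not (0 < self.mass_cap_fraction <= 1):
            raise ValueError("mass_cap_fraction must be in (0, 1]")
        if self.density_unit_scale <= 0:
            raise ValueError("density_unit_scale must be > 0")

    def scaled_rho_unstressed(self, params: ParameterSet) -> float:
        return params.rho_unstressed * self.density_unit_scale


def boundary_density(params: ParameterSet) -> float:
    """Dirichlet density at the free edge: rho_unstressed * exp(-F/k).

    The outward edge force stretches the boundary tissue below its relaxed
    density; F/k = 0 leaves the edge at rho_unstressed.
    """
    return params.rho_unstressed * math.exp(-params.F_over_k)


def limiting_density(params: ParameterSet) -> float:
    """Carrying density of the logistic source: rho_unstressed * exp(F/k).

    Interpreted as the density of maximally compressed tissue.
    """
    return params.rho_unstressed * math.exp(params.F_over_k)


def growth_rate(rho, m: float, m0: float, params: ParameterSet,
                config: ModelConfig | None = None):
    """Mass-limited logistic source q(rho, m), cells/mm^2/h.

    q = alpha * rho * (1 - rho/rho_tilde) while cumulative added mass m is
    below mass_cap_fraction * m0; once the cap is reached (inclusively),
    q = 0 and stays 0 for as long as m remains at or above the cap.
    The logistic expression is applied literally: it is negative where
    rho exceeds the limiting density rho_tilde.

    Accepts scalar or array rho.
    """
    if config is None:
        config = ModelConfig()
    if m0 <= 0:
        raise ValueError("m0 must be > 0")
    if m >= config.mass_cap_fraction * m0:
        return np.zeros_like(np.asarray(rho, dtype=float)) if np.ndim(rho) else 0.0
    rho_tilde = limiting_density(params) * config.density_unit_scale
    return params.alpha * np.asarray(rho, dtype=float) * (1.0 - np.asarray(rho, dtype=float) / rho_tilde) \
        if np.ndim(rho) else params.alpha * rho * (1.0 - rho / rho_tilde)


def boundary_normal_velocity(grad_rho_normal, params: ParameterSet):
    """Normal speed of the free edge, um/h.

    v . n = -(k/b) * (1/rho_unstressed) * exp(F/k) * (grad rho . n).
    A density that decreases outward (grad rho . n < 0) drives outward
    spreading (v > 0).  Accepts scalar or array gradients in
    cells/mm^2/um; rho_unstressed is in cells/mm^2, so the result is um/h.
    """
    factor = -params.k_over_b * math.exp(params.F_over_k) / params.rho_unstressed
    return factor * grad_rho_normal


def sample_prior(priors: PriorSpec, rng: np.random.Generator) -> ParameterSet:
    """Draw one parameter set, each field independently uniform on its bounds."""
    vals = {}
    for name in PARAM_NAMES:
        a, b = priors.bounds(name)
        vals[name] = float(rng.uniform(a, b))
    return ParameterSet(**vals)
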