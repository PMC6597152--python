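"""Shared fixtures: small, fast scenarios reused across the suite."""

import numpy as np
import pytest

import epispread as ep


@pytest.fixture(scope="session")
def theta_star() -> ep.ParameterSet:
    return ep.ParameterSet(F_over_k=0.8, k_over_b=1000.0, alpha=0.5,
                           rho_unstressed=1500.0)


@pytest.fixture(scope="session")
def coarse_grid() -> ep.Grid:
    return ep.Grid.square(1200.0, 20.0, x0=-600.0, y0=-600.0)


@pytest.fixture(scope="session")
def short_schedule() -> ep.Schedule:
    """Two hours of 5-minute frames: long enough for delta=5 pairings."""
    return ep.Schedule(frame_interval_h=5.0 / 60.0, t_end_h=2.0)


@pytest.fixture(scope="session")
def small_series(theta_star, coarse_grid, short_schedule) -> ep.FrameSeries:
    contour = ep.make_initial_contour("circle", 0.125, center=(0.0, 0.0))
    return ep.simulate(contour, theta_star, coarse_grid, short_schedule)


def _make_dataset(theta, grid, seed, jitter, ratio_noise, t_end=2.0, area=0.125):
    proto = ep.SyntheticProtocol(theta_star=theta, area_mm2=area,
                                 t_end_h=t_end, edge_jitter_um=jitter,
                                 ratio_noise_sigma=ratio_noise, seed=seed)
    return ep.generate_dataset(proto, grid)


@pytest.fixture(scope="session")
def noiseless_dataset(theta_star, coarse_grid):
    return _make_dataset(theta_star, coarse_grid, seed=3, jitter=0.0,
                         ratio_noise=0.0)


@pytest.fixture(scope="session")
def noisy_dataset(theta_star, coarse_grid):
    return _make_dataset(theta_star, coarse_grid, seed=3, jitter=13.0,
                         ratio_noise=0.02)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
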