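"""ABC error function, rejection rules, sampler and posterior summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

import epispread as ep
from epispread.inference import Posterior
from epispread.model import PARAM_NAMES


def square_contour(side=200.0, center=(0.0, 0.0), pts_per_side=4):
    """Axis-aligned square polyline with pts_per_side points per edge."""
    s = side / 2.0
    corners = np.array([[-s, -s], [s, -s], [s, s], [-s, s]])
    pts = []
    for k in range(4):
        a, b = corners[k], corners[(k + 1) % 4]
        for f in np.linspace(0.0, 1.0, pts_per_side, endpoint=False):
            pts.append(a + f * (b - a))
    return ep.BoundaryContour(np.asarray(pts) + np.asarray(center))


class TestEdgeDistanceError:
    def test_identical_contours(self):
        c = square_contour()
        assert ep.edge_distance_error(c, c) == pytest.approx(0.0, abs=1e-12)

    def test_known_point_offsets(self):
        # 8-point comp contour: 6 points on the experimental square, one
        # displaced 3 um and one 4 um perpendicular to an edge
        exp = square_contour(side=200.0, pts_per_side=8)
        comp_pts = square_contour(side=200.0, pts_per_side=2).points.copy()
        assert len(comp_pts) == 8
        comp_pts[0] = [-100.0 + 30.0, -100.0 + 3.0]   # 3 um inside bottom edge
        comp_pts[1] = [100.0 - 4.0, -100.0 + 60.0]    # 4 um inside right edge
        comp = ep.BoundaryContour(comp_pts)
        expected = math.sqrt((9.0 + 16.0) / 8.0)
        assert ep.edge_distance_error(comp, exp) == pytest.approx(expected, abs=1e-9)

    def test_matches_dense_sampling_oracle(self, rng):
        # brute force: resample experimental segments at 0.01 um and take
        # nearest-point distances
        for _ in range(20):
            exp = ep.make_initial_contour("blob", 0.03, rng=rng,
                                          blob_amplitude=0.1)
            comp = ep.make_initial_contour("blob", 0.028, rng=rng,
                                           blob_amplitude=0.1)
            pts = np.vstack([exp.points, exp.points[:1]])
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            s = np.concatenate([[0.0], np.cumsum(seg)])
            t = np.arange(0.0, s[-1], 0.01)
            dense = np.column_stack([np.interp(t, s, pts[:, 0]),
                                     np.interp(t, s, pts[:, 1])])
            d, _ = cKDTree(dense).query(comp.points)
            oracle = float(np.sqrt(np.mean(d ** 2)))
            assert ep.edge_distance_error(comp, exp) == pytest.approx(oracle, abs=1e-4)


class TestErrorSums:
    def test_distance_error_sums_over_frames(self, noiseless_dataset, coarse_grid, theta_star):
        dataset, gt = noiseless_dataset
        series = gt["series"]
        D = [ep.edge_distance_error(series.contours[j], dataset.contours[j])
             for j in range(1, series.n_frames)]
        assert ep.distances_error(series, dataset) == pytest.approx(sum(D), rel=1e-12)

    def test_constant_per_frame_error_scales_linearly(self):
        # D_j = c over n frames sums to n*c (here exercised arithmetically)
        c, n = 3.7, 120
        assert sum([c] * n) == pytest.approx(n * c)

    def test_density_error_frame_direct_values(self):
        xi1 = ep.DensityRatioMap(xi=np.full((10, 12), 1.3),
                                 mask=np.ones((10, 12), bool))
        xi2 = ep.DensityRatioMap(xi=np.full((10, 12), 1.4),
                                 mask=np.ones((10, 12), bool))
        assert ep.density_ratio_error_frame(xi1, xi2) == pytest.approx(0.1, abs=1e-12)

    def test_density_error_frame_2x2_example(self):
        # differences (0.2, 0, 0, 0) -> sqrt(0.04/4) = 0.1
        a = ep.DensityRatioMap(xi=np.array([[1.2, 1.0], [1.0, 1.0]]),
                               mask=np.ones((2, 2), bool))
        b = ep.DensityRatioMap(xi=np.ones((2, 2)),
                               mask=np.ones((2, 2), bool))
        assert ep.density_ratio_error_frame(a, b) == pytest.approx(0.1, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        a = ep.DensityRatioMap(xi=np.ones((4, 4)), mask=np.ones((4, 4), bool))
        b = ep.DensityRatioMap(xi=np.ones((5, 4)), mask=np.ones((5, 4), bool))
        with pytest.raises(ValueError):
            ep.density_ratio_error_frame(a, b)

    def test_density_error_self_consistency(self, noiseless_dataset, coarse_grid):
        dataset, gt = noiseless_dataset
        assert ep.density_error(gt["series"], dataset) < 1e-9

    def test_delta_longer_than_series_rejected(self, noiseless_dataset):
        dataset, gt = noiseless_dataset
        series = gt["series"]
        with pytest.raises(ValueError):
            ep.ExperimentDataset(times=dataset.times,
                                 contours=dataset.contours,
                                 ratio_maps=dataset.ratio_maps,
                                 delta=series.n_frames + 1)


class TestTotalError:
    def test_weighted_combination(self):
        assert ep.total_error(500.0, 0.5) == pytest.approx(1000.0)

    def test_zero_density_term(self):
        assert ep.total_error(432.1, 0.0) == pytest.approx(432.1)

    def test_flags_give_nan_sentinel(self):
        for flag in ("escaped_domain", "center_density_increased",
                     "numerical_failure"):
            assert math.isnan(ep.total_error(1.0, 1.0, flags=flag))

    def test_monotone_in_components(self):
        assert ep.total_error(10.0, 1.0) < ep.total_error(11.0, 1.0)
        assert ep.total_error(10.0, 1.0) < ep.total_error(10.0, 1.1)


class TestEvaluateCandidate:
    def test_ground_truth_scores_low_on_noiseless_data(self, noiseless_dataset,
                                                       coarse_grid, theta_star):
        dataset, _ = noiseless_dataset
        bd = ep.evaluate_candidate(theta_star, dataset, coarse_grid)
        assert bd.rejected_reason == "none"
        assert bd.z < 10.0

    def test_escape_yields_nan(self, theta_star):
        # domain too small for the spreading explant
        grid = ep.Grid.square(800.0, 20.0, x0=-400.0, y0=-400.0)
        proto = ep.SyntheticProtocol(theta_star=theta_star, area_mm2=0.125,
                                     t_end_h=1.0, edge_jitter_um=0.0,
                                     ratio_noise_sigma=0.0, seed=5)
        big = ep.Grid.square(1200.0, 20.0, x0=-600.0, y0=-600.0)
        dataset, _ = ep.generate_dataset(proto, big)
        runaway = ep.ParameterSet(1.5, 5000.0, 1.0, 1000.0)
        bd = ep.evaluate_candidate(runaway, dataset, grid,
                                   schedule=ep.Schedule(t_end_h=10.0))
        assert bd.rejected_reason == "escaped_domain"
        assert math.isnan(bd.z)

    def test_center_density_rise_yields_nan(self, coarse_grid, noiseless_dataset):
        # slow diffusion + strong growth below the limiting density raises
        # the centre density -> rejected with the NaN sentinel
        dataset, _ = noiseless_dataset
        riser = ep.ParameterSet(1.5, 500.0, 1.0, 2000.0)  # rho_tilde ~ 8963 > 4700
        bd = ep.evaluate_candidate(riser, dataset, coarse_grid)
        assert bd.rejected_reason == "center_density_increased"
        assert math.isnan(bd.z)

    def test_deterministic(self, noiseless_dataset, coarse_grid, theta_star):
        dataset, _ = noiseless_dataset
        z1 = ep.evaluate_candidate(theta_star, dataset, coarse_grid).z
        z2 = ep.evaluate_candidate(theta_star, dataset, coarse_grid).z
        assert z1 == z2


class TestAbcRejection:
    def test_infinite_threshold_accepts_all_finite(self, noisy_dataset, coarse_grid):
        dataset, _ = noisy_dataset
        post = ep.abc_rejection(dataset, ep.PriorSpec(), coarse_grid,
                                threshold=1e18, n_accept=5, rng=0, budget=8)
        assert post.n_accepted >= 1
        assert np.all(np.isfinite(post.samples["z"]))

    def test_accepted_errors_below_threshold(self, noisy_dataset, coarse_grid):
        dataset, _ = noisy_dataset
        post = ep.abc_rejection(dataset, ep.PriorSpec(), coarse_grid,
                                threshold=5e4, n_accept=3, rng=1, budget=30)
        assert np.all(post.samples["z"] <= 5e4)

    def test_same_seed_identical_posterior(self, noisy_dataset, coarse_grid):
        dataset, _ = noisy_dataset
        kw = dict(threshold=1e18, n_accept=3, budget=5)
        p1 = ep.abc_rejection(dataset, ep.PriorSpec(), coarse_grid, rng=42, **kw)
        p2 = ep.abc_rejection(dataset, ep.PriorSpec(), coarse_grid, rng=42, **kw)
        pd.testing.assert_frame_equal(p1.samples, p2.samples)

    def test_no_acceptance_raises(self, noisy_dataset, coarse_grid):
        dataset, _ = noisy_dataset
        with pytest.raises(ep.NoAcceptanceError):
            ep.abc_rejection(dataset, ep.PriorSpec(), coarse_grid,
                             threshold=1e-6, n_accept=1, rng=0, budget=3)


def _posterior_from(samples: dict, priors=None) -> Posterior:
    df = pd.DataFrame(samples)
    return Posterior(samples=df, n_attempted=len(df),
                     threshold=float("inf"),
                     priors=priors or ep.PriorSpec())


class TestPosteriorSummaries:
    def test_degenerate_samples(self):
        post = _posterior_from({
            "F_over_k": [0.7] * 5, "k_over_b": [900.0] * 5,
            "alpha": [0.4] * 5, "rho_unstressed": [1500.0] * 5,
            "z": [1.0, 2.0, 3.0, 4.0, 5.0]})
        s = ep.posterior_summaries(post)
        assert s["mean"]["F_over_k"] == pytest.approx(0.7)
        assert s["mode"]["F_over_k"] == pytest.approx(0.7, abs=1.5 / 512)

    def test_mode_of_unimodal_sample(self, rng):
        n = 4000
        alpha = np.clip(rng.normal(0.45, 0.05, n), 0.0, 1.0)
        post = _posterior_from({
            "F_over_k": rng.uniform(0, 1.5, n),
            "k_over_b": rng.uniform(500, 5000, n),
            "alpha": alpha,
            "rho_unstressed": rng.uniform(1000, 2000, n),
            "z": rng.uniform(0, 1, n)})
        s = ep.posterior_summaries(post, bins=30)
        assert s["mode"]["alpha"] == pytest.approx(0.45, abs=1.0 / 30)

    def test_best_sets_are_smallest_errors(self, rng):
        n = 50
        df = {name: rng.uniform(*ep.PriorSpec().bounds(name), n)
              for name in PARAM_NAMES}
        df["z"] = rng.uniform(10, 100, n)
        post = _posterior_from(df)
        s = ep.posterior_summaries(post)
        assert s["best"]["z"].tolist() == sorted(df["z"])[:3]

    def test_empty_posterior_rejected(self):
        post = _posterior_from({name: [] for name in PARAM_NAMES} | {"z": []})
        with pytest.raises(ValueError):
            ep.posterior_summaries(post)


class TestPairwiseCorrelations:
    def test_diagonal_is_one_and_antisymmetric_pair(self, rng):
        n = 200
        x = rng.uniform(0, 1.5, n)
        post = _posterior_from({
            "F_over_k": x,
            "k_over_b": 5000.0 - 3000.0 * x / 1.5,   # exactly anti-correlated
            "alpha": rng.uniform(0, 1, n),
            "rho_unstressed": rng.uniform(1000, 2000, n),
            "z": rng.uniform(0, 1, n)})
        corr = ep.pairwise_correlations(post, fraction=1.0)
        assert np.allclose(np.diag(corr), 1.0)
        assert corr.loc["F_over_k", "k_over_b"] == pytest.approx(-1.0)

    def test_zero_variance_column_flagged_nan(self, rng):
        n = 100
        post = _posterior_from({
            "F_over_k": rng.uniform(0, 1.5, n),
            "k_over_b": rng.uniform(500, 5000, n),
            "alpha": np.full(n, 0.5),
            "rho_unstressed": rng.uniform(1000, 2000, n),
            "z": rng.uniform(0, 1, n)})
        corr = ep.pairwise_correlations(post, fraction=1.0)
        assert math.isnan(corr.loc["alpha", "F_over_k"])
        assert corr.loc["alpha", "alpha"] == 1.0

    def test_uses_smallest_error_fraction(self, rng):
        # best 20%: F_over_k increases with k_over_b among small-z samples,
        # decreases among the rest; the correlation must reflect the former
        n = 500
        z = np.arange(n, dtype=float)
        x = rng.uniform(0, 1.5, n)
        y = np.where(z < 100, 500 + 3000 * x / 1.5, 5000 - 3000 * x / 1.5)
        post = _posterior_from({
            "F_over_k": x, "k_over_b": y,
            "alpha": rng.uniform(0, 1, n),
            "rho_unstressed": rng.uniform(1000, 2000, n), "z": z})
        corr = ep.pairwise_correlations(post, fraction=0.2)
        assert corr.loc["F_over_k", "k_over_b"] > 0.99


class TestCredibleIntervals:
    def test_degenerate_zero_width(self):
        post = _posterior_from({
            "F_over_k": [0.7, 0.7, 0.7], "k_over_b": [900.0] * 3,
            "alpha": [0.4] * 3, "rho_unstressed": [1500.0] * 3,
            "z": [1.0, 2.0, 3.0]})
        lo, hi = ep.credible_intervals(post)["alpha"]
        assert lo == hi == 0.4

    def test_uniform_order_statistics(self, rng):
        n = 100_000
        post = _posterior_from({
            "F_over_k": rng.uniform(0, 1.5, n),
            "k_over_b": rng.uniform(500, 5000, n),
            "alpha": rng.uniform(0, 1, n),
            "rho_unstressed": rng.uniform(1000, 2000, n),
            "z": rng.uniform(0, 1, n)})
        lo, hi = ep.credible_intervals(post, level=0.95)["alpha"]
        assert lo == pytest.approx(0.025, abs=0.005)
        assert hi == pytest.approx(0.975, abs=0.005)

    def test_intervals_within_prior_bounds(self, rng):
        n = 500
        priors = ep.PriorSpec()
        post = _posterior_from({name: rng.uniform(*priors.bounds(name), n)
                                for name in PARAM_NAMES} | {"z": rng.uniform(0, 1, n)})
        for name, (lo, hi) in ep.credible_intervals(post).items():
            a, b = priors.bounds(name)
            assert a <= lo <= hi <= b
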