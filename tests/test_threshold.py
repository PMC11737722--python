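import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import f as f_dist

from vethresh import synth, threshold
from vethresh.threshold import (DoseResponseRecord, GridSpec, build_design,
                                contour_surface, eq1_mean, fit_cell,
                                grid_scan, select_thresholds,
                                variance_change_test)


def recs_from(theta, phi, y, timepoint="D0"):
    return [DoseResponseRecord(subject_id=f"r{i}", theta=t, phi=p,
                               dy_amplitude=v, timepoint=timepoint)
            for i, (t, p, v) in enumerate(zip(theta, phi, y))]


class TestEq1Mean:
    def test_both_sub_threshold(self):
        assert eq1_mean(10.0, 500.0, theta0=20.5, phi0=1475.0,
                        c1=-0.0221, c2=1.0) == 0.0

    def test_theta_branch_hand_arithmetic(self):
        # -0.0221 * (38.1 - 20.5) = -0.38896
        assert eq1_mean(38.1, 500.0, theta0=20.5, phi0=1475.0,
                        c1=-0.0221) == pytest.approx(-0.38896, abs=1e-12)

    def test_boundary_zero_excess(self):
        assert eq1_mean(20.5, 1475.0, theta0=20.5, phi0=1475.0,
                        c1=5.0, c2=7.0) == 0.0

    def test_phi_branch(self):
        assert eq1_mean(10.0, 2000.0, theta0=20.5, phi0=1475.0,
                        c1=1.0, c2=2e-3) == pytest.approx(2e-3 * 525.0)

    def test_continuity_near_thresholds(self):
        eps = 1e-9
        lo = eq1_mean(20.5 - eps, 100.0, theta0=20.5, phi0=1475.0, c1=3.0)
        hi = eq1_mean(20.5 + eps, 100.0, theta0=20.5, phi0=1475.0, c1=3.0)
        assert abs(hi - lo) < 1e-6

    def test_vectorized(self):
        out = eq1_mean(np.array([10.0, 38.1]), np.array([500.0, 500.0]),
                       theta0=20.5, phi0=1475.0, c1=-0.0221)
        np.testing.assert_allclose(out, [0.0, -0.38896])


class TestBuildDesign:
    def test_all_sub_threshold_gives_empty_design(self):
        info = build_design(np.array([1.0, 2.0]), np.array([3.0, 4.0]),
                            10.0, 10.0)
        assert info.X.shape == (2, 0)
        assert info.n_supra_theta == 0 and info.n_supra_phi == 0

    def test_single_record_hinge_value(self):
        info = build_design(np.array([25.0]), np.array([100.0]), 20.0, 500.0)
        assert info.columns == ["theta"]
        np.testing.assert_allclose(info.X[:, 0], [5.0])

    def test_proportional_design_collapses(self):
        theta = np.linspace(0.0, 45.0, 12)
        phi = 73.8 * theta
        info = build_design(theta, phi, 5.0, 369.0)
        # exact proportional coupling -> hinge columns collinear
        x1 = np.clip(theta - 5.0, 0, None)
        x2 = np.clip(phi - 369.0, 0, None)
        assert abs(np.corrcoef(x1, x2)[0, 1]) > 0.99  # condition verified
        assert info.collapsed
        assert not info.identifiable
        assert info.columns == ["theta"]


class TestFitCell:
    def test_noise_free_recovery_at_truth(self):
        # orthogonal design: theta and phi vary independently
        rng = np.random.default_rng(0)
        theta = rng.uniform(0, 45, 30)
        phi = rng.uniform(0, 3500, 30)
        y = eq1_mean(theta, phi, theta0=20.0, phi0=1500.0, c1=-0.02,
                     c2=3e-4)
        fit = fit_cell(recs_from(theta, phi, y), 20.0, 1500.0)
        assert fit.c1 == pytest.approx(-0.02, abs=1e-10)
        assert fit.c2 == pytest.approx(3e-4, abs=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        assert fit.p_value == 0.0

    def test_all_zero_response(self):
        theta = np.array([0.0, 10.0, 30.0, 40.0])
        fit = fit_cell(recs_from(theta, np.zeros(4), np.zeros(4)), 5.0, 0.0)
        assert fit.p_value == 1.0
        assert fit.c1 == pytest.approx(0.0)

    def test_hand_computed_single_hinge_oracle(self):
        theta = np.array([0.0, 5.0, 22.0, 25.0, 30.0, 40.0])
        y = np.array([0.1, -0.2, 0.5, 1.0, 2.2, 4.1])
        theta0 = 20.0
        fit = fit_cell(recs_from(theta, np.zeros(6), y), theta0, 0.0)
        # independent closed-form oracle: slope through origin on the hinge
        x = np.clip(theta - theta0, 0, None)
        slope = float(x @ y) / float(x @ x)
        rss = float(np.sum((y - slope * x) ** 2))
        f = ((float(y @ y) - rss) / 1) / (rss / 5)
        assert fit.c1 == pytest.approx(slope, rel=1e-12)
        assert fit.rss == pytest.approx(rss, rel=1e-12)
        assert fit.f_stat == pytest.approx(f, rel=1e-12)
        assert fit.p_value == pytest.approx(float(f_dist.sf(f, 1, 5)),
                                            rel=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=100_000))
    def test_single_hinge_matches_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 11)
        theta = rng.uniform(0, 45, n)
        y = rng.normal(0, 1, n)
        theta0 = rng.uniform(0, np.max(theta) - 1e-6)
        x = np.clip(theta - theta0, 0, None)
        if not np.any(x > 0):
            return
        fit = fit_cell(recs_from(theta, np.zeros(n), y), theta0, 0.0)
        slope = float(x @ y) / float(x @ x)
        assert fit.c1 == pytest.approx(slope, rel=1e-9, abs=1e-12)
        assert fit.rss == pytest.approx(
            float(np.sum((y - slope * x) ** 2)), rel=1e-9, abs=1e-12)

    def test_insufficient_dof_gives_p_one(self):
        fit = fit_cell(recs_from([30.0], [0.0], [1.0]), 20.0, 0.0)
        assert fit.p_value == 1.0


class TestGridScan:
    def test_empty_records_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            grid_scan([], GridSpec())

    def test_two_by_two_noise_free_minimum_at_truth(self):
        rng = np.random.default_rng(1)
        theta = rng.uniform(0, 45, 20)
        phi = rng.uniform(0, 3500, 20)
        y = eq1_mean(theta, phi, theta0=20.0, phi0=1500.0, c1=-0.02, c2=2e-4)
        grid = GridSpec(theta_min=10.0, theta_max=20.0, theta_step=10.0,
                        phi_min=1000.0, phi_max=1500.0, phi_step=500.0)
        scan = grid_scan(recs_from(theta, phi, y), grid)
        assert scan.argmin_p() == (20.0, 1500.0)
        i, j = 1, 1
        assert scan.rss_surface[i, j] == pytest.approx(0.0, abs=1e-16)

    def test_all_zero_response_p_surface_is_one(self, pilot_records):
        recs = [DoseResponseRecord(r.subject_id, r.theta, r.phi, 0.0)
                for r in pilot_records]
        scan = grid_scan(recs, GridSpec(theta_step=5.0, phi_step=500.0))
        assert np.all(scan.p_surface == 1.0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=100_000))
    def test_grid_cells_match_fit_cell(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 20)
        theta = rng.uniform(0, 45, n)
        phi = rng.uniform(0, 3500, n)
        y = rng.normal(0, 1, n)
        recs = recs_from(theta, phi, y)
        grid = GridSpec(theta_step=9.0, phi_step=700.0)
        scan = grid_scan(recs, grid)
        for i in rng.choice(scan.theta_grid.size, 3, replace=False):
            for j in rng.choice(scan.phi_grid.size, 3, replace=False):
                fit = fit_cell(recs, float(scan.theta_grid[i]),
                               float(scan.phi_grid[j]))
                assert scan.p_surface[i, j] == pytest.approx(
                    fit.p_value, rel=1e-6, abs=1e-12)
                assert scan.rss_surface[i, j] == pytest.approx(
                    fit.rss, rel=1e-6, abs=1e-10)
                if np.isfinite(scan.c1_surface[i, j]) or np.isfinite(fit.c1):
                    assert scan.c1_surface[i, j] == pytest.approx(
                        fit.c1, rel=1e-6, abs=1e-10)
                if np.isfinite(scan.c2_surface[i, j]) or np.isfinite(fit.c2):
                    assert scan.c2_surface[i, j] == pytest.approx(
                        fit.c2, rel=1e-6, abs=1e-10)

    def test_noise_free_truth_cell_in_min_rss_set(self, pilot_records):
        scan = grid_scan(pilot_records)
        i = int(np.argmin(np.abs(scan.theta_grid - 20.5)))
        j = int(np.argmin(np.abs(scan.phi_grid - 1475.0)))
        assert scan.rss_surface[i, j] == pytest.approx(0.0, abs=1e-12)


def _synthetic_scan(p_surface, theta_grid, phi_grid, n=27):
    p_surface = np.asarray(p_surface, dtype=float)
    return threshold.GridScan(
        theta_grid=np.asarray(theta_grid, float),
        phi_grid=np.asarray(phi_grid, float),
        p_surface=p_surface,
        c1_surface=np.full(p_surface.shape, 1.0),
        c2_surface=np.full(p_surface.shape, np.nan),
        rss_surface=np.ones(p_surface.shape),
        identifiable=np.ones(p_surface.shape, bool),
        n_supra_theta=np.full(len(theta_grid), 5, dtype=int),
        n_supra_phi=np.full(len(phi_grid), 5, dtype=int),
        outcome="amplitude", timepoint="D0", n=n,
        n_cells_tested=p_surface.size)


class TestSelectThresholds:
    def test_p_one_surface_gives_none(self):
        scan = _synthetic_scan(np.ones((3, 3)), [0, 10, 20], [0, 100, 200])
        assert select_thresholds(scan, 0.05) is None

    def test_single_significant_cell(self):
        p = np.ones((3, 3))
        p[1, 2] = 0.001
        scan = _synthetic_scan(p, [0, 10, 20], [0, 100, 200])
        assert select_thresholds(scan, 0.05) == (10.0, 200.0)

    def test_lowest_pair_order(self):
        p = np.ones((2, 2))
        # cells (20.5, 1475) and (25.0, 1800) both significant, equal RSS
        scan = _synthetic_scan(p, [20.5, 25.0], [1475.0, 1800.0])
        scan.p_surface[0, 0] = 0.001
        scan.p_surface[1, 1] = 0.001
        assert select_thresholds(scan, 0.05) == (20.5, 1475.0)

    def test_support_requirement(self):
        p = np.full((2, 2), 0.001)
        scan = _synthetic_scan(p, [0, 10], [0, 100])
        scan.n_supra_theta = np.array([1, 1])
        scan.n_supra_phi = np.array([1, 1])
        assert select_thresholds(scan, 0.05, support_min=3) is None

    def test_profile_region_prefers_best_fit_cells(self, pilot_records):
        scan = grid_scan(pilot_records)
        for alpha in (0.05, 0.01, 0.001):
            sel = select_thresholds(scan, alpha)
            assert sel is not None
            assert sel[0] == pytest.approx(20.5)

    def test_literal_rule_without_profile_region(self, pilot_records):
        scan = grid_scan(pilot_records)
        sel = select_thresholds(scan, 0.05, profile_region=False)
        # with a genuine trend every cell is significant; literal rule
        # returns the grid origin (documented degeneracy)
        assert sel == (0.0, 0.0)

    def test_selection_on_grid(self, pilot_records):
        scan = grid_scan(pilot_records)
        sel = select_thresholds(scan, 0.05)
        assert sel[0] in scan.theta_grid
        assert sel[1] in scan.phi_grid


class TestContourSurface:
    def test_constant_surface_no_contours(self):
        scan = _synthetic_scan(np.ones((4, 4)), [0, 5, 10, 15],
                               [0, 100, 200, 300])
        out = contour_surface(scan, levels=[0.05])
        assert out[0.05] == []

    def test_radial_surface_closed_contours(self):
        tg = np.linspace(0, 45, 40)
        pg = np.linspace(0, 3500, 40)
        tt, pp = np.meshgrid(tg, pg, indexing="ij")
        r2 = ((tt - 22.0) / 20.0) ** 2 + ((pp - 1700.0) / 1500.0) ** 2
        p = np.clip(0.2 * r2, 0, 1)  # analytic bowl, min 0 at centre
        scan = _synthetic_scan(p, tg, pg)
        out = contour_surface(scan, levels=[0.05])
        assert len(out[0.05]) >= 1
        poly = out[0.05][0]
        np.testing.assert_allclose(poly[0], poly[-1], atol=1e-8)
        # contour encloses the minimum
        assert poly[:, 0].min() < 22.0 < poly[:, 0].max()
        assert poly[:, 1].min() < 1700.0 < poly[:, 1].max()

    def test_levels_present_when_crossed(self, pilot_records):
        truth = synth.DoseResponseTruth(
            theta0=20.5, phi0=1475.0, c1=-0.0221, sigma=0.15,
            design=synth.pilot_design(), seed=5)
        scan = grid_scan(synth.generate_dose_response(truth))
        out = contour_surface(scan, levels=[0.05, 0.01, 0.001])
        for level, polys in out.items():
            lo, hi = scan.p_surface.min(), scan.p_surface.max()
            if lo < level < hi:
                assert len(polys) >= 1


class TestVarianceChangeTest:
    def test_identical_samples_not_significant(self):
        x = np.array([0.1, -0.2, 0.5, 0.3, -0.4, 0.2])
        stat, p = variance_change_test(x, x.copy())
        assert stat == pytest.approx(1.0)
        assert p >= 0.5

    def test_scaled_copy_gives_hand_computed_ratio(self):
        rng = np.random.default_rng(3)
        sub = rng.normal(0, 1, 10)
        stat, p = variance_change_test(sub, 10.0 * sub)
        assert stat == pytest.approx(100.0, rel=1e-12)

    def test_null_calibration(self):
        # equal variances: rejection rate at alpha=0.05 within binomial CI
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            sub = rng.normal(0, 1, 15)
            supra = rng.normal(0, 1, 15)
            _, p = variance_change_test(sub, supra)
            rejections += p <= 0.05
        half = 1.96 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rejections / reps - 0.05) <= half

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            variance_change_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            variance_change_test([1.0], [1.0, 2.0])

    def test_brown_forsythe_variant(self):
        rng = np.random.default_rng(7)
        sub = rng.normal(0, 1, 20)
        supra = rng.normal(0, 5, 20)
        _, p = variance_change_test(sub, supra, method="bf")
        assert p < 0.05


class TestInvariantsAndRecovery:
    def test_recovery_improves_as_sigma_shrinks(self):
        design = synth.pilot_design()
        sigma0 = synth.sigma_for_target_p(design, 20.5, -0.0221, 1e-4)
        rates = []
        for mult in (2.0, 1.0, 0.5, 0.25):
            hits = 0
            for seed in range(40):
                truth = synth.DoseResponseTruth(
                    theta0=20.5, phi0=1475.0, c1=-0.0221,
                    sigma=sigma0 * mult, design=design, seed=seed)
                scan = grid_scan(synth.generate_dose_response(truth))
                hits += abs(scan.argmin_p()[0] - 20.5) <= 2.5
            rates.append(hits / 40)
        assert rates == sorted(rates) or \
            all(b >= a - 0.1 for a, b in zip(rates, rates[1:]))
        assert rates[-1] > rates[0]

    def test_recovery_improves_with_larger_n(self):
        base = synth.pilot_design()
        big = base + [(th + 0.51, ph + 12.0) for th, ph in base]
        sigma = synth.sigma_for_target_p(base, 20.5, -0.0221, 1e-4)
        rates = []
        for design in (base, big):
            hits = 0
            for seed in range(40):
                truth = synth.DoseResponseTruth(
                    theta0=20.5, phi0=1475.0, c1=-0.0221, sigma=sigma,
                    design=design, seed=seed)
                scan = grid_scan(synth.generate_dose_response(truth))
                hits += abs(scan.argmin_p()[0] - 20.5) <= 2.5
            rates.append(hits / 40)
        assert rates[1] >= rates[0]
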