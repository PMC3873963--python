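import numpy as np
import pytest

from secrpp import (
    DetectionParams,
    IntensityParams,
    Region,
    TrapCaptures,
    TrapDesign,
    TrapsContext,
    abundance_in_region,
    build_grid,
    density_map,
    density_vs_covariate,
    eb_abundance,
    fit_traps,
    mu_region,
    n0_conditional_mean,
    pi0_traps,
)
from secrpp.fitting import FitResult
from secrpp.simulate import default_trap_grid, sim_centers, sim_habitat, sim_traps


def make_fit(ctx, theta, vcov):
    return FitResult(
        names=ctx.names,
        transforms=ctx.transforms,
        theta=np.asarray(theta, dtype=float),
        loglik=0.0,
        vcov=vcov,
        converged=True,
        context=ctx,
    )


@pytest.fixture(scope="module")
def small_traps_fit():
    """A real MLE on a modest simulated trap-array data set."""
    region = Region(0, 2, 0, 2)
    ss = build_grid(region, 0.2)
    design = TrapDesign(default_trap_grid(6, 0.15), J=4)
    det = DetectionParams(0.3, 0.25)
    ip = IntensityParams([np.log(120.0 / region.area)])
    centers, N = sim_centers(ss, ip, seed=5)
    sim = sim_traps(centers, design, det, seed=6)
    fit = fit_traps(ss, design, sim.captures)
    return fit, N


class TestConditionalMean:
    def test_undetectable_population_gives_mu(self, unit_ss):
        design = TrapDesign(np.array([[0.5, 0.5]]), J=3)
        ip = IntensityParams([np.log(9.0)])
        ctx = TrapsContext(unit_ss, design, TrapCaptures(np.zeros((0, 1), int)))
        theta = np.array([np.log(9.0), -np.inf, np.log(0.3)])  # p0 = 0
        assert n0_conditional_mean(ctx, theta) == pytest.approx(mu_region(unit_ss, ip))

    def test_perfect_detection_gives_zero(self, unit_ss):
        # saturated detection over the whole region: J large, sigma huge
        design = TrapDesign(np.array([[0.5, 0.5]]), J=50)
        ctx = TrapsContext(unit_ss, design, TrapCaptures(np.zeros((0, 1), int)))
        theta = np.array([np.log(9.0), 30.0, np.log(100.0)])  # p0 ~ 1, flat kernel
        assert n0_conditional_mean(ctx, theta) == pytest.approx(0.0, abs=1e-9)

    def test_matches_forward_simulated_undetected_count(self):
        ss = build_grid(Region(0, 1.5, 0, 1.5), 0.05)
        design = TrapDesign(default_trap_grid(4, 0.15, center=(0.75, 0.75)), J=3)
        det = DetectionParams(0.35, 0.12)
        ip = IntensityParams([np.log(60.0 / 2.25)])
        counts = []
        for seed in range(300):
            centers, _ = sim_centers(ss, ip, seed=seed)
            sim = sim_traps(centers, design, det, seed=5000 + seed)
            counts.append((~sim.detected).sum())
        counts = np.asarray(counts, dtype=float)
        expected = mu_region(ss, ip) * pi0_traps(ss, design, det, ip)
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - expected) < 3 * se


class TestEbAbundance:
    def test_known_parameters_leave_poisson_variance_only(self, unit_ss):
        design = TrapDesign(np.array([[0.5, 0.5]]), J=2)
        data = TrapCaptures(np.array([[1], [2]]))
        ctx = TrapsContext(unit_ss, design, data)
        theta = np.array([np.log(10.0), 0.0, np.log(0.3)])
        fit = make_fit(ctx, theta, np.zeros((3, 3)))
        est = eb_abundance(fit)
        n0_mean = n0_conditional_mean(ctx, theta)
        assert est.N_hat == pytest.approx(2 + n0_mean)
        assert est.var_N == pytest.approx(n0_mean)

    def test_interval_is_multiplicatively_symmetric_around_estimate(self, small_traps_fit):
        fit, _ = small_traps_fit
        est = eb_abundance(fit)
        assert est.N_hat >= est.n
        assert est.var_N >= est.n0_mean
        assert est.ci_low <= est.N_hat <= est.ci_high
        C = np.exp(1.959963985 * np.sqrt(np.log1p(est.var_N / est.N_hat**2)))
        assert est.ci_high / est.N_hat == pytest.approx(C, rel=1e-9)
        assert est.N_hat / est.ci_low == pytest.approx(C, rel=1e-9)

    def test_interval_on_undetected_part_is_tighter_below(self, small_traps_fit):
        fit, _ = small_traps_fit
        full = eb_abundance(fit)
        part = eb_abundance(fit, interval_on="n0")
        assert part.ci_low >= full.n  # never below the observed count
        assert part.N_hat == pytest.approx(full.N_hat)

    def test_missing_vcov_warns_and_uses_poisson_floor(self, small_traps_fit):
        fit, _ = small_traps_fit
        crippled = make_fit(fit.context, fit.theta, None)
        with pytest.warns(UserWarning, match="Poisson"):
            est = eb_abundance(crippled)
        assert est.var_N == pytest.approx(est.n0_mean)


class TestSubregionAbundance:
    def test_whole_region_matches_global_estimator(self, small_traps_fit):
        fit, _ = small_traps_fit
        full = eb_abundance(fit)
        sub = abundance_in_region(fit, fit.context.ss.region)
        assert sub.N_hat == pytest.approx(full.N_hat, rel=1e-9)

    def test_empty_mask_gives_zero(self, small_traps_fit):
        fit, _ = small_traps_fit
        est = abundance_in_region(fit, np.zeros(fit.context.ss.G, bool))
        assert est.N_hat == 0.0

    def test_halves_split_symmetrically_without_detections(self, unit_ss):
        design = TrapDesign(np.array([[0.5, 0.5]]), J=2)
        ctx = TrapsContext(unit_ss, design, TrapCaptures(np.zeros((0, 1), int)))
        theta = np.array([np.log(10.0), -np.inf, np.log(0.3)])  # p0=0: nobody seen
        fit = make_fit(ctx, theta, np.zeros((3, 3)))
        left = unit_ss.centers[:, 0] < 0.5
        est_left = abundance_in_region(fit, left)
        est_full = eb_abundance(fit)
        # 3x3 grid: the left mask holds 3 of 9 homogeneous pixels
        assert est_left.N_hat == pytest.approx(est_full.N_hat / 3)

    def test_region_outside_state_space_rejected(self, small_traps_fit):
        fit, _ = small_traps_fit
        with pytest.raises(ValueError, match="outside"):
            abundance_in_region(fit, Region(-1, 1, 0, 1))


class TestDensityMap:
    def test_integrates_to_abundance(self, small_traps_fit):
        fit, _ = small_traps_fit
        m = density_map(fit)
        est = eb_abundance(fit)
        assert m.sum() * fit.context.ss.pixel_area == pytest.approx(est.N_hat, abs=1e-6)

    def test_no_detections_reduces_to_thinned_intensity(self, unit_ss):
        design = TrapDesign(np.array([[0.5, 0.5]]), J=2)
        ctx = TrapsContext(unit_ss, design, TrapCaptures(np.zeros((0, 1), int)))
        theta = np.array([np.log(10.0), -np.inf, np.log(0.3)])
        fit = make_fit(ctx, theta, np.zeros((3, 3)))
        np.testing.assert_allclose(density_map(fit), 10.0)

    def test_tracks_true_intensity_in_habitat_simulation(self):
        from scipy.stats import spearmanr

        region = Region(0, 2, 0, 2)
        raster = sim_habitat(region, 0.08, seed=17)
        ss = build_grid(region, 0.16, raster, degree=2)
        beta = np.array([4.412, 0.557, -1.123])
        ip = IntensityParams(beta)
        design = TrapDesign(default_trap_grid(), J=5)
        det = DetectionParams(0.25, 0.4)
        centers, _ = sim_centers(ss, ip, seed=18)
        sim = sim_traps(centers, design, det, seed=19)
        fit = fit_traps(ss, design, sim.captures)
        rho = spearmanr(density_map(fit), np.exp(ss.X @ beta)).statistic
        assert rho > 0


class TestDensityCurve:
    def test_reference_point_and_band(self):
        region = Region(0, 2, 0, 2)
        ss = build_grid(region, 0.2, sim_habitat(region, 0.1, seed=23), degree=2)
        design = TrapDesign(default_trap_grid(8, 0.12), J=4)
        ctx_beta = np.array([4.412, 0.557, -1.123])
        theta = np.concatenate([ctx_beta, [0.0, np.log(0.3)]])
        data = TrapCaptures(np.array([[1] + [0] * 63]))
        ctx = TrapsContext(ss, design, data)
        fit = make_fit(ctx, theta, 0.01 * np.eye(5))
        curve = density_vs_covariate(fit, values=np.array([ss.cov_mean]))
        assert curve["density"].iloc[0] == pytest.approx(np.exp(4.412))
        full = density_vs_covariate(fit)
        assert np.all(full["lo"] <= full["density"] + 1e-12)
        assert np.all(full["density"] <= full["hi"] + 1e-12)
        # standardized habitat value 1 gives exp(4.412 + 0.557 - 1.123) ~ 46.8
        v1 = density_vs_covariate(fit, values=np.array([ss.cov_mean + ss.cov_sd]))
        assert v1["density"].iloc[0] == pytest.approx(np.exp(3.846), rel=1e-9)
        assert v1["density"].iloc[0] == pytest.approx(46.8, abs=0.1)

    def test_intercept_only_model_rejected(self, small_traps_fit):
        fit, _ = small_traps_fit
        with pytest.raises(ValueError, match="habitat"):
            density_vs_covariate(fit)
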