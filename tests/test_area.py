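import numpy as np
import pytest

from secrpp import (
    AreaCaptures,
    AreaDesign,
    AreaParams,
    IntensityParams,
    Region,
    build_grid,
    cond_area_loglik,
    fit_area,
    intensity,
    loglik_area,
    mu_region,
    pi0_area,
    prob_in_S,
)
from secrpp.simulate import sim_area, sim_centers

from oracles import cond_history_density_area, loglik_area_truncated


class TestProbInS:
    def test_center_of_wide_plot_captures_all_mass(self):
        S = Region(-10, 10, -10, 10)
        assert prob_in_S(np.array([0.0, 0.0]), S, 1.0) == pytest.approx(1.0, abs=1e-10)

    def test_half_mass_on_edge_midpoint(self):
        S = Region(0, 20, -10, 10)
        assert prob_in_S(np.array([0.0, 0.0]), S, 1.0) == pytest.approx(0.5, abs=1e-10)

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(123)
        S = Region(0.0, 1.0, 0.0, 0.6)
        s = np.array([0.35, 0.5])
        sigma = 0.3
        draws = s + sigma * rng.standard_normal((1_000_000, 2))
        inside = S.contains(draws).mean()
        mc_se = np.sqrt(inside * (1 - inside) / 1e6)
        assert abs(prob_in_S(s, S, sigma) - inside) < 3 * mc_se


class TestPi0Area:
    def test_single_survey_expansion(self):
        ss = build_grid(Region(0, 1, 0, 1), 0.25)
        S = Region(0.25, 0.75, 0.25, 0.75)
        design = AreaDesign(S, J=1)
        ap = AreaParams(0.4, 0.15)
        ip = IntensityParams([np.log(7.0)])  # homogeneous: weights cancel
        phibar = prob_in_S(ss.centers, S, ap.sigma).mean()
        assert pi0_area(ss, design, ap, ip) == pytest.approx(1 - 0.4 * phibar, rel=1e-12)

    def test_matches_forward_simulated_nondetection_frequency(self):
        ss = build_grid(Region(0, 1, 0, 1), 0.05)
        S = Region(0.25, 0.75, 0.25, 0.75)
        design = AreaDesign(S, J=3)
        ap = AreaParams(0.5, 0.1)
        ip = IntensityParams([np.log(200.0)])
        undet, total = 0, 0
        for seed in range(40):
            centers, _ = sim_centers(ss, ip, seed=seed)
            sim = sim_area(centers, design, ap, seed=1000 + seed)
            undet += (~sim.detected).sum()
            total += centers.shape[0]
        frac = undet / total
        pi0 = pi0_area(ss, design, ap, ip)
        se = np.sqrt(pi0 * (1 - pi0) / total)
        assert abs(frac - pi0) < 3 * se

    def test_monotone_in_detection_probability_and_occasions(self):
        ss = build_grid(Region(0, 1, 0, 1), 0.1)
        S = Region(0.3, 0.7, 0.3, 0.7)
        ip = IntensityParams([0.0])
        pi0s = [
            pi0_area(ss, AreaDesign(S, J=2), AreaParams(p, 0.1), ip)
            for p in (0.2, 0.4, 0.8)
        ]
        assert pi0s[0] > pi0s[1] > pi0s[2]
        by_J = [
            pi0_area(ss, AreaDesign(S, J=J), AreaParams(0.4, 0.1), ip) for J in (1, 2, 5)
        ]
        assert by_J[0] > by_J[1] > by_J[2]


class TestCondAreaLoglik:
    def test_detection_at_the_center_pixel(self):
        ss = build_grid(Region(0, 1, 0, 1), 0.5)
        S = Region(0.2, 0.8, 0.2, 0.8)
        design = AreaDesign(S, J=1)
        ap = AreaParams(0.7, 0.2)
        g = 0
        u = np.array([[ss.centers[g]]])  # detected exactly at pixel center g
        ll = cond_area_loglik(ss, design, ap, np.array([1]), u[0])
        expected = np.log(0.7) + np.log(1.0 / (2 * np.pi * 0.2**2))
        assert ll[g] == pytest.approx(expected)

    def test_single_nondetection(self):
        ss = build_grid(Region(0, 1, 0, 1), 0.5)
        S = Region(0.2, 0.8, 0.2, 0.8)
        design = AreaDesign(S, J=1)
        ap = AreaParams(0.7, 0.2)
        ll = cond_area_loglik(
            ss, design, ap, np.array([0]), np.full((1, 2), np.nan)
        )
        phi = prob_in_S(ss.centers, S, ap.sigma)
        np.testing.assert_allclose(ll, np.log1p(-0.7 * phi))

    def test_matches_per_survey_recomputation(self, small_area_instance):
        ss, design, ap, ip, data = small_area_instance
        for i in range(data.n):
            ll = cond_area_loglik(ss, design, ap, data.w[i], data.u[i])
            for g in range(0, ss.G, 3):
                expected = cond_history_density_area(
                    ss.centers[g], design.S, design.J, ap.p, ap.sigma, data.w[i], data.u[i]
                )
                assert ll[g] == pytest.approx(np.log(expected))

    def test_location_outside_plot_rejected(self):
        ss = build_grid(Region(0, 1, 0, 1), 0.5)
        design = AreaDesign(Region(0.2, 0.8, 0.2, 0.8), J=1)
        u = np.array([[0.9, 0.9]])
        with pytest.raises(ValueError, match="inside the search plot"):
            cond_area_loglik(ss, design, AreaParams(0.5, 0.2), np.array([1]), u)


class TestLoglikArea:
    def test_empty_data_is_nondetection_mass(self):
        ss = build_grid(Region(0, 1, 0, 1), 0.25)
        design = AreaDesign(Region(0.25, 0.75, 0.25, 0.75), J=2)
        ap = AreaParams(0.5, 0.15)
        ip = IntensityParams([np.log(6.0)])
        data = AreaCaptures(np.zeros((0, 2), int), np.zeros((0, 2, 2)))
        expected = -mu_region(ss, ip) * (1 - pi0_area(ss, design, ap, ip))
        assert loglik_area(ss, design, ap, ip, data) == pytest.approx(expected)

    def test_equals_truncated_marginalization_oracle(self, small_area_instance):
        ss, design, ap, ip, data = small_area_instance
        ll = loglik_area(ss, design, ap, ip, data)
        oracle = loglik_area_truncated(
            ss, design, ap, intensity(ss, ip), data.w, data.u
        )
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_invariant_to_survey_reordering(self, small_area_instance):
        ss, design, ap, ip, data = small_area_instance
        base = loglik_area(ss, design, ap, ip, data)
        flipped = AreaCaptures(data.w[:, ::-1], data.u[:, ::-1])
        assert loglik_area(ss, design, ap, ip, flipped) == pytest.approx(base, rel=1e-12)

    def test_buffer_beyond_five_sigma_changes_nothing(self):
        S = Region(0.0, 1.0, 0.0, 1.0)
        design = AreaDesign(S, J=2)
        ap = AreaParams(0.5, 0.05)
        ip = IntensityParams([np.log(25.0)])
        w = np.array([[1, 1], [0, 1]])
        u = np.full((2, 2, 2), np.nan)
        u[0, 0], u[0, 1], u[1, 1] = (0.4, 0.5), (0.45, 0.55), (0.8, 0.2)
        data = AreaCaptures(w, u)
        lls = []
        for buf in (5 * ap.sigma, 10 * ap.sigma):
            ss = build_grid(S.buffered(buf), 0.025)
            lls.append(loglik_area(ss, design, ap, ip, data))
        assert abs(lls[1] - lls[0]) < 1e-6


class TestFitArea:
    def test_recovers_lizard_scale_parameters(self):
        # homogeneous density ~8 per ha on a 300 m plot, 14 searches
        plot = Region(150, 450, 150, 450)
        ss = build_grid(plot.buffered(150), 12.5)
        design = AreaDesign(plot, J=14)
        ap = AreaParams(0.124, 18.5)
        ip = IntensityParams([np.log(8.06e-4)])
        centers, _ = sim_centers(ss, ip, seed=21)
        sim = sim_area(centers, design, ap, seed=22)
        fit = fit_area(ss, design, sim.captures, buffer_warn=0.0)
        theta_truth = fit.context.pack(ip, ap)
        assert fit.loglik >= fit.context.loglik(theta_truth)
        se = fit.se()
        assert abs(fit.params["sigma"] - 18.5) < 4 * se["sigma"]
        assert abs(fit.params["p"] - 0.124) < 4 * se["p"]
        assert abs(fit.params["beta0"] - np.log(8.06e-4)) < 4 * se["beta0"]

    def test_thin_buffer_triggers_warning(self):
        plot = Region(150, 450, 150, 450)
        ss = build_grid(plot.buffered(20), 12.5)
        design = AreaDesign(plot, J=5)
        centers, _ = sim_centers(ss, IntensityParams([np.log(8e-4)]), seed=31)
        sim = sim_area(centers, design, AreaParams(0.3, 18.5), seed=32)
        with pytest.warns(UserWarning, match="buffer"):
            fit_area(ss, design, sim.captures)
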