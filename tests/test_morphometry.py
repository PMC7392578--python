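"""Foveal metrics: closed forms, brute-force oracles, invariances."""

import numpy as np
import pytest

import foveometrics as fm
from foveometrics.dog import dog_eval
from foveometrics.errors import RimNotFoundError
from foveometrics.morphometry import PRT_DISTANCE_UM
from conftest import random_fits

RIM_CONSTANT = np.sqrt(3.0 + np.sqrt(6.0))  # rim distance / sigma, lone pit


def single_pit_fit(a_pit=100.0, sigma_pit=500.0, baseline=200.0):
    sides = {s: fm.DoGSideParams(a_pit=a_pit, sigma_pit=sigma_pit,
                                 a_para=0.0, sigma_para=5000.0)
             for s in fm.SIDES}
    return fm.DoGFit(baseline=baseline, sides=sides, rss={s: 0.0 for s in fm.SIDES},
                     converged=True, n_points={s: 0 for s in fm.SIDES})


class TestRimEdge:
    def test_single_pit_rim_matches_quartic_root(self):
        # argmax of the pit Gaussian's third derivative solves
        # d^4 - 6 sigma^2 d^2 + 3 sigma^4 = 0 -> d = sigma sqrt(3 + sqrt 6)
        fit = single_pit_fit(sigma_pit=500.0)
        d_star, h_star = fm.locate_rim_edge(fit, "nasal")
        assert d_star == pytest.approx(500.0 * RIM_CONSTANT, abs=1.0)
        assert h_star == pytest.approx(float(dog_eval(fit, "nasal", d_star)))

    def test_single_pit_rim_brute_force_grid(self):
        fit = single_pit_fit(sigma_pit=350.0)
        grid = np.arange(0.01, 3000.0, 0.01)
        brute = grid[np.argmax(dog_eval(fit, "nasal", grid, order=3))]
        d_star, _ = fm.locate_rim_edge(fit, "nasal")
        assert abs(d_star - brute) < 0.02

    def test_random_fits_match_fine_grid_oracle(self):
        for fit in random_fits(8, seed=5):
            for s in fm.SIDES:
                grid = np.arange(0.01, 3000.0, 0.01)
                brute = grid[np.argmax(dog_eval(fit, s, grid, order=3))]
                d_star, _ = fm.locate_rim_edge(fit, s)
                assert abs(d_star - brute) < 1.0

    def test_symmetric_fit_equal_rim_distances(self):
        fit = single_pit_fit()
        dn, _ = fm.locate_rim_edge(fit, "nasal")
        dt, _ = fm.locate_rim_edge(fit, "temporal")
        assert dn == pytest.approx(dt, abs=1e-6)

    def test_no_interior_maximum_raises(self):
        fit = single_pit_fit(sigma_pit=500.0)
        with pytest.raises(RimNotFoundError):
            # search window ends before the rim at ~1167 um
            fm.locate_rim_edge(fit, "nasal", d_max=800.0)


class TestSteepestSlope:
    def test_single_pit_closed_form(self):
        # lone pit Gaussian: |h'| peaks at d = sigma with value A/(sigma sqrt e)
        fit = single_pit_fit(a_pit=100.0, sigma_pit=500.0)
        rim, _ = fm.locate_rim_edge(fit, "nasal")
        slope, angle = fm.steepest_slope(fit, "nasal", rim)
        assert slope == pytest.approx(100.0 / (500.0 * np.sqrt(np.e)), rel=1e-6)
        assert angle == pytest.approx(np.degrees(np.arctan(slope)))

    def test_random_fits_match_grid_oracle(self):
        for fit in random_fits(8, seed=6):
            for s in fm.SIDES:
                rim, _ = fm.locate_rim_edge(fit, s)
                grid = np.arange(0.01, rim, 0.01)
                brute = np.max(np.abs(dog_eval(fit, s, grid, order=1)))
                slope, _ = fm.steepest_slope(fit, s, rim)
                assert slope == pytest.approx(brute, rel=1e-4)


class TestMetrics:
    def test_symmetric_single_pit_width(self):
        fit = single_pit_fit(sigma_pit=500.0)
        m = fm.compute_metrics(fit)
        assert m.width == pytest.approx(2.0 * RIM_CONSTANT * 500.0, abs=2.0)
        assert m.width == m.rim_d_nasal + m.rim_d_temporal

    def test_cft_closed_form(self):
        fit = single_pit_fit(a_pit=100.0, baseline=200.0)
        m = fm.compute_metrics(fit)
        assert m.cft == pytest.approx(100.0)

    def test_area_matches_trapezoid_oracle(self):
        for fit in random_fits(8, seed=7):
            m = fm.compute_metrics(fit)
            xs = np.arange(-m.rim_d_temporal, m.rim_d_nasal, 0.1)
            contour = np.where(xs >= 0,
                               dog_eval(fit, "nasal", np.abs(xs)),
                               dog_eval(fit, "temporal", np.abs(xs)))
            chord = np.interp(xs, [-m.rim_d_temporal, m.rim_d_nasal],
                              [m.rim_h_temporal, m.rim_h_nasal])
            oracle = np.trapezoid(chord - contour, xs)
            assert m.area == pytest.approx(oracle, rel=1e-3)

    def test_prt_missing_when_profile_short(self):
        fit = single_pit_fit()
        x = np.linspace(-800.0, 800.0, 101)
        h = np.asarray(dog_eval(fit, "nasal", np.abs(x)))
        prof = fm.ILMProfile(x=x, h=h)
        m = fm.compute_metrics(fit, prof)
        assert m.prt_nasal is None and m.prt_temporal is None
        assert m.width > 0 and m.cft > 0

    def test_prt_is_fitted_height_at_1000_um(self):
        fit = single_pit_fit()
        m = fm.compute_metrics(fit)
        assert m.prt_nasal == pytest.approx(
            float(dog_eval(fit, "nasal", PRT_DISTANCE_UM)))

    def test_height_scaling_property(self):
        # scaling all amplitudes and baseline by c scales cft, depth, area,
        # slope by c and leaves width and rim distances unchanged
        base = random_fits(1, seed=8)[0]
        c = 1.7
        scaled = fm.DoGFit(
            baseline=base.baseline * c,
            sides={s: fm.DoGSideParams(p.a_pit * c, p.sigma_pit,
                                       p.a_para * c, p.sigma_para)
                   for s, p in base.sides.items()},
            rss={s: 0.0 for s in fm.SIDES}, converged=True,
            n_points={s: 0 for s in fm.SIDES},
        )
        m0, m1 = fm.compute_metrics(base), fm.compute_metrics(scaled)
        assert m1.width == pytest.approx(m0.width, rel=1e-6)
        assert m1.rim_d_nasal == pytest.approx(m0.rim_d_nasal, rel=1e-6)
        assert m1.cft == pytest.approx(c * m0.cft, rel=1e-6)
        assert m1.depth == pytest.approx(c * m0.depth, rel=1e-6)
        assert m1.area == pytest.approx(c * m0.area, rel=1e-6)
        assert m1.slope_nasal == pytest.approx(c * m0.slope_nasal, rel=1e-6)

    def test_mirror_invariance_with_labels_swapped(self, asym_truth, noiseless_fit):
        prof = fm.gen_ilm_profile(asym_truth)
        mirrored = fm.DoGModel(prof.mirrored()).fit()
        m0 = noiseless_fit.metrics()
        m1 = mirrored.metrics()
        assert m1.width == pytest.approx(m0.width, rel=1e-3)
        assert m1.rim_d_nasal == pytest.approx(m0.rim_d_temporal, rel=1e-3)
        assert m1.slope_temporal == pytest.approx(m0.slope_nasal, rel=1e-3)


class TestParafoveaClassification:
    @pytest.mark.parametrize("a_para,expected", [
        (-50.0, "inverted"),
        (50.0, "noninverted"),
        (0.5, "indeterminate"),
    ])
    def test_sign_rule_with_dead_zone(self, a_para, expected):
        sides = {s: fm.DoGSideParams(a_pit=100.0, sigma_pit=400.0,
                                     a_para=a_para, sigma_para=1500.0)
                 for s in fm.SIDES}
        fit = fm.DoGFit(baseline=200.0, sides=sides, rss={}, converged=True,
                        n_points={})
        assert fm.classify_parafovea(fit, "nasal") == expected
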