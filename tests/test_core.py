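"""Analytical model: point source, line source, calibration, scaling."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

import oxykernel as ox
from oxykernel.core import FULL_LENGTH, LineSourceGeometry


def quad_line_pressure(d, r_n, kappa, z_a=None, z_b=None):
    """Independent oracle: adaptive quadrature of the point-source kernel
    along the axis, limits clipped to the contributing length."""
    if d >= r_n:
        return 0.0
    z_m = math.sqrt(r_n**2 - d**2)
    z_a = -z_m if z_a is None else max(z_a, -z_m)
    z_b = z_m if z_b is None else min(z_b, z_m)
    if z_b <= z_a:
        return 0.0
    val, err = quad(
        lambda z: ox.point_source_pressure(math.hypot(d, z), r_n, kappa),
        z_a,
        z_b,
        epsabs=1e-14,
        epsrel=1e-13,
        limit=1000,
        points=[0.0] if z_a < 0.0 < z_b else None,
    )
    return val


class TestPointSource:
    def test_zero_at_diffusion_limit_and_beyond(self):
        assert ox.point_source_pressure(150.0, 150.0, 1.0) == 0.0
        assert ox.point_source_pressure(151.0, 150.0, 1.0) == 0.0

    def test_zero_gradient_at_diffusion_limit(self):
        r_n, eps = 150.0, 1e-6
        g = (
            ox.point_source_pressure(r_n - eps, r_n, 1.0)
            - ox.point_source_pressure(r_n - 2 * eps, r_n, 1.0)
        ) / eps
        assert abs(g) < 1e-4

    def test_half_distance_closed_form(self):
        # r = r_n/2 with unit strength: r_n²/4 + 4·r_n² − 3·r_n² = 1.25·r_n²
        r_n = 80.0
        assert ox.point_source_pressure(r_n / 2, r_n, 1.0) == pytest.approx(
            1.25 * r_n**2, rel=1e-12
        )

    def test_strictly_decreasing_inside(self):
        r = np.linspace(1.0, 149.9, 400)
        p = ox.point_source_pressure(r, 150.0, 1.0)
        assert np.all(np.diff(p) < 0)

    def test_singular_origin_rejected(self):
        with pytest.raises(ValueError):
            ox.point_source_pressure(0.0, 150.0, 1.0)
        with pytest.raises(ValueError):
            ox.point_source_pressure(-1.0, 150.0, 1.0)


class TestLineSource:
    def test_zero_at_and_beyond_diffusion_limit(self):
        assert ox.line_source_pressure(150.0, 150.0, 1.0) == 0.0
        assert ox.line_source_pressure(200.0, 150.0, 1.0) == 0.0

    def test_matches_quadrature_full_length(self, rng):
        for _ in range(25):
            r_n = rng.uniform(40.0, 200.0)
            d = rng.uniform(0.02, 0.98) * r_n
            ours = ox.line_source_pressure(d, r_n, 1.0)
            ref = quad_line_pressure(d, r_n, 1.0)
            assert ours == pytest.approx(ref, rel=1e-8)

    def test_matches_quadrature_partial_limits(self, rng):
        for _ in range(25):
            r_n = rng.uniform(40.0, 200.0)
            d = rng.uniform(0.02, 0.95) * r_n
            z_a = rng.uniform(-1.5, 0.5) * r_n
            z_b = z_a + rng.uniform(0.05, 2.0) * r_n
            ours = ox.line_source_pressure(
                d, r_n, 1.0, LineSourceGeometry(z_a, z_b)
            )
            ref = quad_line_pressure(d, r_n, 1.0, z_a, z_b)
            assert ours == pytest.approx(ref, rel=1e-8, abs=1e-12)

    def test_strictly_decreasing_in_d(self, high):
        d = np.linspace(5.0, 149.9, 300)
        p = ox.line_source_pressure(d, 150.0, high.kappa)
        assert np.all(np.diff(p) < 0)
        assert np.all(p >= 0)

    def test_on_axis_rejected(self):
        with pytest.raises(ValueError):
            ox.line_source_pressure(0.0, 150.0, 1.0)


class TestCalibration:
    @pytest.mark.parametrize("name,p_o,r_n", [("high", 40.0, 150.0), ("low", 20.0, 100.0)])
    def test_round_trip(self, name, p_o, r_n):
        sc = ox.scenario_by_name(name)
        assert sc.p_o == p_o and sc.r_n == r_n
        back = ox.line_source_pressure(sc.r_o, sc.r_n, sc.kappa)
        assert back == pytest.approx(p_o, rel=1e-9)

    def test_kappa_against_quadrature(self):
        # independent: integrate the kernel numerically at the reference
        # geometry and divide into the wall pressure
        ref = quad_line_pressure(5.0, 150.0, 1.0)
        assert ox.high_perfusion().kappa == pytest.approx(40.0 / ref, rel=1e-8)

    def test_wall_inside_diffusion_limit_required(self):
        with pytest.raises(ValueError):
            ox.PerfusionScenario("bad", p_o=40.0, r_n=4.0, r_o=5.0)


class TestScaledDiffusionDistance:
    def test_identity_at_reference_radius(self, high, low):
        assert ox.scaled_diffusion_distance(5.0, high) == pytest.approx(150.0, abs=1e-6)
        assert ox.scaled_diffusion_distance(5.0, low) == pytest.approx(100.0, abs=1e-6)

    def test_strictly_increasing(self, high):
        radii = [1.0, 2.0, 5.0, 8.0, 13.0, 21.0, 34.0, 50.0]
        r_f = [ox.scaled_diffusion_distance(r, high) for r in radii]
        assert all(a < b for a, b in zip(r_f, r_f[1:]))
        assert all(f > r for r, f in zip(radii, r_f))

    @pytest.mark.parametrize(
        "r_v,name,expected",
        [(10.0, "high", 162.97), (20.0, "low", 124.88), (50.0, "high", 219.72)],
    )
    def test_reference_values(self, r_v, name, expected):
        sc = ox.scenario_by_name(name)
        assert ox.scaled_diffusion_distance(r_v, sc) == pytest.approx(expected, abs=0.02)

    def test_table_frame_columns(self):
        tab = ox.diffusion_distance_table([2.0, 5.0])
        assert list(tab.columns) == ["r_v_um", "r_f_high_um", "r_f_low_um"]
        assert tab.shape == (2, 3)


class TestWallPressureShortSegment:
    def test_long_segment_is_reference_pressure_exactly(self, high):
        z_crit = 2 * math.sqrt(150.0**2 - 5.0**2)
        assert ox.wall_pressure_short_segment(z_crit, 5.0, 150.0, high) == 40.0
        assert ox.wall_pressure_short_segment(1000.0, 5.0, 150.0, high) == 40.0

    def test_short_segment_below_reference(self, high):
        p = ox.wall_pressure_short_segment(200.0, 5.0, 150.0, high)
        assert 0.0 < p < 40.0

    def test_vanishes_with_length(self, high):
        assert ox.wall_pressure_short_segment(1e-9, 5.0, 150.0, high) < 1e-6

    def test_monotone_and_continuous_at_crossover(self, high):
        z_crit = 2 * math.sqrt(150.0**2 - 5.0**2)
        lengths = np.linspace(1.0, z_crit * 1.1, 60)
        vals = [ox.wall_pressure_short_segment(L, 5.0, 150.0, high) for L in lengths]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))
        just_below = ox.wall_pressure_short_segment(z_crit - 1e-6, 5.0, 150.0, high)
        assert just_below == pytest.approx(40.0, abs=1e-4)

    def test_matches_quadrature(self, high):
        ref = high.kappa * quad_line_pressure(5.0, 150.0, 1.0, -100.0, 100.0)
        assert ox.wall_pressure_short_segment(200.0, 5.0, 150.0, high) == pytest.approx(
            ref, rel=1e-8
        )


class TestLongitudinalDrop:
    def test_linearity(self):
        assert ox.longitudinal_drop(100.0) == (pytest.approx(7.0), pytest.approx(4.0))
        assert ox.longitudinal_drop(0.0) == (0.0, 0.0)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            ox.longitudinal_drop(-1.0)
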