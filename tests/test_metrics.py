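"""Haemodynamic index computations: closed forms, identities, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spiralgraft.fields import (
    WallShearSeries,
    synth_poiseuille,
    synth_swirl,
    synth_wss_series,
)
from spiralgraft.metrics import (
    MetricSummary,
    osi,
    refold_surface,
    rrt,
    secondary_velocity,
    summarize_plane,
    tawss,
    tawssg,
    unfold_surface,
    wss_spatial_mean,
)


def colinear_sinusoid(amplitude=1.0, n_t=901, period=0.9, n_axial=3, n_theta=4):
    """tau(t) = A sin(2 pi t / T) along the axial direction."""
    s = synth_wss_series(n_axial=n_axial, n_theta=n_theta, n_t=n_t,
                         period=period, base_vector=(1.0, 0.0),
                         pattern="steady")
    phase = np.sin(2 * math.pi * s.times / period)
    tau = amplitude * phase[:, None, None, None] * s.tau / np.linalg.norm(
        s.tau[0, 0, 0]
    )
    return WallShearSeries(s.radius, s.axial, s.theta, s.times, tau, period)


class TestSecondaryVelocity:
    def test_axial_only_field_has_zero_mean(self):
        f = synth_poiseuille(3.0, 0.317)
        assert secondary_velocity(f)[1] == 0.0

    def test_solid_body_mean_closed_form(self):
        f = synth_swirl(3.0, omega=2.5)
        assert secondary_velocity(f)[1] == pytest.approx(2 / 3 * 2.5 * 3.0, rel=1e-3)

    def test_joint_rotation_invariance(self):
        f = synth_swirl(3.0, omega=1.0, n_r=16, n_theta=32)
        _, before = secondary_velocity(f)
        ang = 0.7
        v = math.cos(ang) * f.v - math.sin(ang) * f.w
        w = math.sin(ang) * f.v + math.cos(ang) * f.w
        f.v, f.w = v, w
        assert secondary_velocity(f)[1] == pytest.approx(before, rel=1e-12)


class TestWssSpatialMean:
    def test_constant_field_returns_the_constant(self):
        s = synth_wss_series(n_axial=6, n_theta=8, n_t=5,
                             base_vector=(2.295, 0.0), pattern="steady")
        assert wss_spatial_mean(s) == pytest.approx(2.295, rel=1e-12)

    def test_poiseuille_wall_shear_magnitude(self):
        # tau = 8 mu V / D for fully developed Poiseuille flow
        mu, V, D = 3.5e-3, 0.317, 6e-3
        tau_wall = 8 * mu * V / D
        s = synth_wss_series(n_axial=6, n_theta=8, n_t=5,
                             base_vector=(tau_wall, 0.0), pattern="steady")
        assert wss_spatial_mean(s) == pytest.approx(1.479, abs=1e-3)

    def test_mean_invariant_under_grid_refinement_for_constant(self):
        means = [
            wss_spatial_mean(
                synth_wss_series(n_axial=n, n_theta=2 * n, n_t=4,
                                 base_vector=(1.3, 0.4), pattern="steady")
            )
            for n in (4, 8, 16)
        ]
        assert means[0] == pytest.approx(means[1]) == pytest.approx(means[2])

    def test_masked_region_and_empty_mask(self):
        s = synth_wss_series(n_axial=6, n_theta=8, n_t=5,
                             base_vector=(1.0, 0.0), pattern="steady")
        mask = np.zeros((6, 8), dtype=bool)
        mask[:3] = True
        assert wss_spatial_mean(s, mask=mask) == pytest.approx(1.0)
        with pytest.raises(ValueError, match="no surface nodes"):
            wss_spatial_mean(s, mask=np.zeros((6, 8), dtype=bool))


class TestUnfolding:
    def test_bed_maps_to_vertical_centre(self):
        s = synth_wss_series(n_axial=4, n_theta=36, n_t=4,
                             base_vector=(1.0, 0.0), pattern="steady")
        m = unfold_surface(s, tawss(s))
        j = np.argmin(np.abs(np.degrees(s.theta) - 180.0))
        rel = np.mod(np.degrees(s.theta), 360.0)
        order = np.argsort(rel)
        y_of_bed = m.y[np.where(order == j)[0][0]]
        assert y_of_bed == pytest.approx(math.pi * s.radius, abs=s.radius * 0.2)

    def test_unfolded_extent_is_circumference(self):
        s = synth_wss_series(n_axial=4, n_theta=32, n_t=4, pattern="steady")
        m = unfold_surface(s, tawss(s))
        dy = 2 * math.pi * s.radius / 32
        assert m.y.max() - m.y.min() == pytest.approx(
            2 * math.pi * s.radius - dy, rel=1e-9
        )

    def test_unfold_refold_round_trip(self):
        rng = np.random.default_rng(5)
        s = synth_wss_series(n_axial=5, n_theta=16, n_t=4, pattern="steady")
        values = rng.normal(size=(5, 16))
        m = unfold_surface(s, values, cut_angle=37.0)
        np.testing.assert_array_equal(refold_surface(m, s), values)

    def test_shape_mismatch_rejected(self):
        s = synth_wss_series(n_axial=5, n_theta=16, n_t=4, pattern="steady")
        with pytest.raises(ValueError):
            unfold_surface(s, np.zeros((4, 16)))


class TestTawss:
    def test_steady_series(self):
        s = synth_wss_series(n_axial=4, n_theta=8, n_t=5,
                             base_vector=(1.5, 0.5), pattern="steady")
        assert np.allclose(tawss(s), math.hypot(1.5, 0.5))

    def test_square_wave_magnitude_constant(self):
        s = synth_wss_series(n_axial=4, n_theta=8, n_t=41,
                             pattern="colinear_square_wave",
                             reversed_fraction=0.2, base_vector=(3.0, 0.0))
        assert np.allclose(tawss(s), 3.0)

    def test_rectified_sinusoid_mean(self):
        # time-mean of |A sin| is 2A/pi; trapezoid discretization error only
        A = 2.0
        s = colinear_sinusoid(amplitude=A, n_t=901)
        assert tawss(s)[0, 0] == pytest.approx(2 * A / math.pi, rel=1e-4)


class TestTawssg:
    def make_linear_axial_series(self, g=0.5):
        s = synth_wss_series(n_axial=21, n_theta=8, n_t=4,
                             base_vector=(1.0, 0.0), pattern="steady")
        tau = s.tau.copy()
        tau[..., 0] = 1.0 + g * s.axial[None, :, None]
        return WallShearSeries(s.radius, s.axial, s.theta, s.times, tau, s.period)

    def test_uniform_series_has_zero_gradient(self):
        # a spatially uniform Cartesian WSS vector on the cylinder wall is
        # necessarily axial; all its derivatives vanish
        s = synth_wss_series(n_axial=8, n_theta=8, n_t=4,
                             base_vector=(1.0, 0.0), pattern="steady")
        assert np.allclose(tawssg(s), 0.0, atol=1e-12)

    def test_circumferential_wss_has_analytic_cartesian_gradient(self):
        # constant-magnitude circumferential WSS: the diagonal Cartesian
        # derivative terms combine to sqrt(2)|b sin(t) cos(t)|/R
        b = 0.3
        s = synth_wss_series(n_axial=8, n_theta=256, n_t=4,
                             base_vector=(0.0, b), pattern="steady")
        expected = (6.0 / 0.82) * math.sqrt(2) * np.abs(
            b * np.sin(s.theta) * np.cos(s.theta)
        ) / s.radius
        np.testing.assert_allclose(tawssg(s)[0], expected, atol=2e-4)

    def test_linear_axial_variation_recovered_exactly(self):
        # central differences are exact for linear fields at interior nodes
        g = 0.5  # Pa per mm
        s = self.make_linear_axial_series(g)
        expected = (6.0 / 0.82) * g
        interior = tawssg(s)[1:-1]
        assert np.allclose(interior, expected, rtol=1e-10)

    def test_homogeneity_in_series_scaling(self):
        s = self.make_linear_axial_series(0.5)
        doubled = WallShearSeries(s.radius, s.axial, s.theta, s.times,
                                  2.0 * s.tau, s.period)
        np.testing.assert_allclose(tawssg(doubled), 2.0 * tawssg(s), rtol=1e-12)

    def test_full_tensor_variant_upper_bounds_diagonal_form(self):
        s = self.make_linear_axial_series(0.5)
        assert np.all(
            tawssg(s, full_tensor=True) >= tawssg(s) - 1e-12
        )

    def test_single_node_axis_rejected(self):
        s = synth_wss_series(n_axial=1, n_theta=8, n_t=4, pattern="steady")
        with pytest.raises(ValueError, match="single-node"):
            tawssg(s)


class TestOsiRrt:
    def test_steady_series_has_zero_osi(self):
        s = synth_wss_series(n_axial=4, n_theta=8, n_t=5,
                             base_vector=(2.0, 0.0), pattern="steady")
        assert np.allclose(osi(s), 0.0)
        assert np.allclose(rrt(s), 0.5)

    @pytest.mark.parametrize("p,expected", [(0.25, 0.25), (0.5, 0.5)])
    def test_square_wave_formula(self, p, expected):
        s = synth_wss_series(n_axial=4, n_theta=8, n_t=41,
                             pattern="colinear_square_wave",
                             reversed_fraction=p, base_vector=(1.0, 0.0))
        assert osi(s)[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_square_wave_rrt_value(self):
        # p = 0.25, A = 1: |int tau dt| = (1-2p) A T, so RRT = 2 / Pa
        s = synth_wss_series(n_axial=4, n_theta=8, n_t=41,
                             pattern="colinear_square_wave",
                             reversed_fraction=0.25, base_vector=(1.0, 0.0))
        assert rrt(s)[0, 0] == pytest.approx(2.0, rel=1e-12)

    def test_balanced_square_wave_rrt_divergent(self):
        s = synth_wss_series(n_axial=4, n_theta=8, n_t=41,
                             pattern="colinear_square_wave",
                             reversed_fraction=0.5, base_vector=(1.0, 0.0))
        assert np.all(np.isinf(rrt(s)))

    def test_zero_series_osi_flagged_not_raised(self):
        s = synth_wss_series(n_axial=4, n_theta=8, n_t=5,
                             base_vector=(1.0, 0.0), pattern="steady")
        tau = np.zeros_like(s.tau)
        z = WallShearSeries(s.radius, s.axial, s.theta, s.times, tau, s.period)
        assert np.all(np.isnan(osi(z)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_osi_bounds_and_rrt_identity_for_random_series(self, seed):
        # 0 <= OSI <= 1/2 everywhere; RRT == 1/((1-2 OSI) TAWSS) wherever finite
        rng = np.random.default_rng(seed)
        base = synth_wss_series(n_axial=3, n_theta=6, n_t=7, pattern="steady")
        ax = rng.normal(size=(7, 3, 1))
        circ = rng.normal(size=(7, 3, 1))
        th_hat = np.stack([np.zeros(6), -np.sin(base.theta),
                           np.cos(base.theta)], axis=-1)
        tau = ax[..., None] * np.array([1.0, 0.0, 0.0]) + circ[..., None] * th_hat
        s = WallShearSeries(base.radius, base.axial, base.theta, base.times,
                            tau, base.period)
        o, t_avg, r_res = osi(s), tawss(s), rrt(s)
        assert np.all(o >= 0.0) and np.all(o <= 0.5)
        # triangle inequality: TAWSS >= |mean vector|
        mean_vec = np.trapezoid(s.tau, s.times, axis=0) / s.period
        assert np.all(t_avg >= np.linalg.norm(mean_vec, axis=-1) - 1e-12)
        finite = np.isfinite(r_res)
        ident = 1.0 / ((1.0 - 2.0 * o[finite]) * t_avg[finite])
        np.testing.assert_allclose(r_res[finite], ident, rtol=1e-10)

    def test_rigid_frame_rotation_leaves_indices_unchanged(self):
        # rotate geometry and vectors jointly about the cylinder axis
        s = synth_wss_series(n_axial=4, n_theta=16, n_t=21,
                             pattern="rotating", base_vector=(1.0, 0.0),
                             amplitude=1.4)
        shift = 3  # rotate by 3 grid angles
        rot = 2 * math.pi * shift / 16
        c, sn = math.cos(rot), math.sin(rot)
        Rm = np.array([[1, 0, 0], [0, c, -sn], [0, sn, c]], dtype=float)
        tau_rot = np.einsum("ij,tzqj->tzqi", Rm, s.tau)
        tau_rot = np.roll(tau_rot, shift, axis=2)  # nodes move with the frame
        s_rot = WallShearSeries(s.radius, s.axial, s.theta, s.times,
                                tau_rot, s.period)
        np.testing.assert_allclose(np.roll(osi(s), shift, axis=1), osi(s_rot),
                                   atol=1e-12)
        np.testing.assert_allclose(np.roll(tawss(s), shift, axis=1),
                                   tawss(s_rot), atol=1e-12)


class TestSummaries:
    def test_plane_summary_orders_min_mean_max(self):
        f = synth_swirl(3.0, omega=1.0)
        for s in summarize_plane(f):
            assert s.minimum <= s.mean <= s.maximum

    def test_inconsistent_summary_rejected(self):
        with pytest.raises(ValueError):
            MetricSummary("p", "x", mean=2.0, minimum=0.0, maximum=1.0)
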