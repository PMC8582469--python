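"""Geometry factors, parameter extraction, forward dose, superposition."""

import numpy as np
import pytest

from brachymc import (Pose, Tg43Parameters, extract_parameters, forward_dose,
                      geometry_factor, superpose_plan)
from brachymc.scoring import AnnularMap
from brachymc.tg43 import ExtractionError, ExtrapolationError


class TestGeometryFactor:
    def test_point_source_limit(self):
        """L -> 0: the line factor approaches 1/r^2."""
        g = geometry_factor(2.0, 60.0, 1e-6, "line")
        assert g == pytest.approx(0.25, rel=1e-9)

    def test_quadrature_oracle(self):
        """r = 1 cm, 90 deg, L = 0.3 cm equals numeric integration of
        int ds / s^2 over the line, divided by L."""
        L = 0.3
        s = np.linspace(-L / 2, L / 2, 200_001)
        integrand = 1.0 / (1.0 + s**2)        # distance^2 to (y=1, z=-s)
        oracle = np.trapezoid(integrand, s) / L
        assert geometry_factor(1.0, 90.0, L) == pytest.approx(oracle,
                                                              rel=1e-8)

    def test_mirror_symmetry(self):
        th = np.array([10.0, 35.0, 80.0])
        a = geometry_factor(1.5, th, 0.35)
        b = geometry_factor(1.5, 180.0 - th, 0.35)
        assert np.allclose(a, b, rtol=1e-12)

    def test_on_axis_form(self):
        L = 0.4
        g = geometry_factor(2.0, 0.0, L)
        assert g == pytest.approx(1.0 / (4.0 - L**2 / 4), rel=1e-9)

    def test_on_axis_inside_source_rejected(self):
        with pytest.raises(ValueError):
            geometry_factor(0.1, 0.0, 0.4)


def _synthetic_params():
    r = np.array([0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 5.0, 7.5, 10.0])
    th = np.concatenate([np.arange(2.5, 90, 5), [90.0],
                         np.arange(92.5, 180, 5)])
    g = np.exp(-(r - 1.0) * 0.35)              # smooth, g(1) = 1
    f = 1.0 - 0.4 * np.cos(np.deg2rad(th))**2
    F = np.tile(f / f[th == 90.0], (r.size, 1))
    return Tg43Parameters(
        seed_id="synthetic", dose_rate_constant=0.95,
        active_length_cm=0.3, g_radii_cm=r, g_values=g,
        f_radii_cm=r, f_theta_deg=th, f_values=F)


def _forward_filled_map(params, s_k=1.0):
    """AnnularMap whose cells hold the forward dose of ``params``."""
    amap = AnnularMap.default()
    r = amap.r_centers
    th = amap.theta_centers
    vals = forward_dose(params, s_k, r[:, None] * np.ones_like(th)[None, :],
                        np.ones_like(r)[:, None] * th[None, :])
    amap._sum[:] = (vals * 2).ravel()          # two identical histories
    amap._sumsq[:] = (vals**2 * 2).ravel()
    amap.n_histories = 2
    return amap


class TestRoundTrip:
    def test_forward_then_extract_identity(self):
        """Feeding a map generated from known (Lambda*, g*, F*) through the
        extraction recovers them to 1e-9 relative."""
        p = _synthetic_params()
        amap = _forward_filled_map(p, s_k=1.0)
        out = extract_parameters(amap, 1.0, p.active_length_cm)
        assert out.dose_rate_constant == pytest.approx(
            p.dose_rate_constant, rel=1e-9)
        assert np.allclose(out.g_values, p.g(out.g_radii_cm), rtol=1e-9)
        for i, r in enumerate(out.f_radii_cm):
            assert np.allclose(out.f_values[i],
                               p.F(r, out.f_theta_deg), rtol=1e-9)

    def test_normalization_exact(self):
        out = extract_parameters(_forward_filled_map(_synthetic_params()),
                                 1.0, 0.3)
        ir0 = int(np.argmin(np.abs(out.g_radii_cm - 1.0)))
        it0 = int(np.argmin(np.abs(out.f_theta_deg - 90.0)))
        assert out.g_values[ir0] == 1.0
        assert np.all(out.f_values[:, it0] == 1.0)

    def test_dense_grid_round_trip_1e6(self):
        """forward_dose then re-extraction on a dense grid stays within
        1e-6 relative (interpolation closes on itself)."""
        p = _synthetic_params()
        r = np.linspace(0.3, 4.5, 40)
        th = np.linspace(5.0, 175.0, 35)
        d = forward_dose(p, 2.0, r[:, None] * np.ones_like(th),
                         np.ones_like(r)[:, None] * th[None, :])
        geo = geometry_factor(r[:, None] * np.ones_like(th),
                              np.ones_like(r)[:, None] * th[None, :],
                              p.active_length_cm)
        geo_t = geometry_factor(r, 90.0, p.active_length_cm)
        geo0 = geometry_factor(1.0, 90.0, p.active_length_cm)
        d_t = forward_dose(p, 2.0, r, np.full_like(r, 90.0))
        g_back = d_t / (2.0 * p.dose_rate_constant) * geo0 / geo_t
        assert np.allclose(g_back, p.g(r), rtol=1e-6)
        f_back = d / d_t[:, None] * geo_t[:, None] / geo
        assert np.allclose(f_back, p.F(r[:, None] * np.ones_like(th),
                                       np.ones_like(r)[:, None] * th),
                           rtol=1e-6)

    def test_bin_resolution_insensitivity(self):
        """Doubling the annular resolution changes extracted g by < 1% on
        an exactly-forward-generated map (guards voxel-averaging bias)."""
        p = _synthetic_params()
        out1 = extract_parameters(_forward_filled_map(p), 1.0, 0.3)
        r = AnnularMap.default().r_centers
        fine = AnnularMap(r * 0.9875, r * 1.0125,
                          np.concatenate([np.arange(0, 88, 2.5),
                                          [89.5, 90.5],
                                          np.arange(92.5, 181, 2.5)]))
        rr = fine.r_centers
        tt = fine.theta_centers
        vals = forward_dose(p, 1.0, rr[:, None] * np.ones_like(tt),
                            np.ones_like(rr)[:, None] * tt[None, :])
        fine._sum[:] = (vals * 2).ravel()
        fine._sumsq[:] = (vals**2 * 2).ravel()
        fine.n_histories = 2
        out2 = extract_parameters(fine, 1.0, 0.3)
        assert np.allclose(out1.g_values, out2.g_values, rtol=0.01)


class TestForwardDose:
    def test_reference_point_identity(self):
        p = _synthetic_params()
        assert forward_dose(p, 3.7, 1.0, 90.0) == pytest.approx(
            3.7 * p.dose_rate_constant, rel=1e-12)

    def test_pure_inverse_square(self):
        """g = F = 1 and a point-like line reduce to 1/r^2."""
        r = np.array([0.5, 1.0, 2.0])
        p = Tg43Parameters(
            seed_id="pt", dose_rate_constant=1.0, active_length_cm=1e-6,
            g_radii_cm=r, g_values=np.ones(3),
            f_radii_cm=r, f_theta_deg=np.array([0.0, 90.0, 180.0]),
            f_values=np.ones((3, 3)))
        d1 = forward_dose(p, 1.0, 1.0, 90.0)
        d2 = forward_dose(p, 1.0, 2.0, 90.0)
        assert d1 / d2 == pytest.approx(4.0, rel=1e-6)

    def test_extrapolation_flagged(self):
        p = _synthetic_params()
        with pytest.raises(ExtrapolationError):
            p.g(13.0)      # > 20% beyond the table
        assert p.g(11.5) > 0  # within the policy

    def test_serialization_round_trip(self, tmp_path):
        p = _synthetic_params()
        p.save(tmp_path / "params")
        back = Tg43Parameters.load(tmp_path / "params")
        assert back.dose_rate_constant == pytest.approx(
            p.dose_rate_constant)
        assert np.allclose(back.g_values, p.g_values)
        assert np.allclose(back.f_values, p.f_values, atol=1e-6)


class TestExtractErrors:
    def test_zero_reference_cell_named(self):
        amap = AnnularMap.default()
        amap.n_histories = 2
        with pytest.raises(ExtractionError):
            extract_parameters(amap, 1.0, 0.3)

    def test_nonpositive_sk_rejected(self):
        amap = _forward_filled_map(_synthetic_params())
        with pytest.raises(ExtractionError):
            extract_parameters(amap, 0.0, 0.3)


class TestSuperpose:
    def test_single_seed_identity_pose(self):
        p = _synthetic_params()
        pts = np.array([[10.0, 5.0, 3.0], [0.0, 12.0, -4.0]])
        total = superpose_plan(p, [("s", Pose(), 2.0)], pts)
        r = np.linalg.norm(pts, axis=1) / 10
        th = np.degrees(np.arccos(pts[:, 2] / (r * 10)))
        assert np.allclose(total, forward_dose(p, 2.0, r, th), rtol=1e-9)

    def test_two_colocated_seeds_double(self):
        p = _synthetic_params()
        pts = np.array([[10.0, 0.0, 5.0]])
        one = superpose_plan(p, [("s", Pose(), 1.0)], pts)
        two = superpose_plan(p, [("s", Pose(), 1.0)] * 2, pts)
        assert two[0] == pytest.approx(2 * one[0], rel=1e-12)

    def test_seed_origin_flagged(self):
        p = _synthetic_params()
        out = superpose_plan(p, [("s", Pose(), 1.0)],
                             np.array([[0.0, 0.0, 0.0]]))
        assert np.isnan(out[0])

    def test_67_seed_fixture_matches_bruteforce(self):
        """Vectorized plan superposition equals a naive per-seed loop."""
        from brachymc import forward_dose as fd, make_plan_67
        p = _synthetic_params()
        plan = make_plan_67()
        pts = np.array([[x, y, 0.0] for x in (-30.0, 0.0, 25.0)
                        for y in (-20.0, 10.0)])
        got = superpose_plan(p, [(e.seed_id, e.pose, e.s_k)
                                 for e in plan.entries], pts)
        brute = np.zeros(pts.shape[0])
        for e in plan.entries:
            local = (pts - np.asarray(e.pose.translation)) @ e.pose.rotation
            r = np.linalg.norm(local, axis=1) / 10
            r = np.clip(r, p.g_radii_cm[0] * 0.8, p.g_radii_cm[-1] * 1.2)
            th = np.degrees(np.arccos(np.clip(
                local[:, 2] / np.linalg.norm(local, axis=1), -1, 1)))
            brute += fd(p, e.s_k, r, th)
        assert np.allclose(got, brute, rtol=1e-9)


class TestGeometryFactorProperties:
    """Randomized invariants of the line-source geometry factor."""

    from hypothesis import given, settings, strategies as st

    @given(r=st.floats(0.3, 10.0), th=st.floats(1.0, 179.0),
           L=st.floats(0.05, 0.5))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_positive_symmetric_and_bounded(self, r, th, L):
        g = geometry_factor(r, th, L)
        assert g > 0
        assert g == pytest.approx(geometry_factor(r, 180.0 - th, L),
                                  rel=1e-9)
        # on the transverse plane the line spreads the fluence:
        # G_L(r, 90) = 2 atan(L/2r) / (L r) <= 1/r^2 since atan(x) <= x
        assert geometry_factor(r, 90.0, L) <= 1.0 / r**2 + 1e-15
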