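"""Charge-sheet field model, Langevin bead moment and force maps."""

import numpy as np
import pytest
from scipy import integrate

from mtweezers import (
    BeadModel,
    ChargeSheet,
    MagnetAssembly,
    bead_force,
    bead_moment,
    fit_force_decay,
    force_angle,
    force_map,
    force_vs_height,
    sheet_field,
    total_field,
)
from mtweezers.constants import MU_0
from mtweezers.magnetostatics import SheetEvaluationError, UndefinedAngleError


def quadrature_sheet_field(point, sheet):
    """Brute-force 2D quadrature of the Coulomb kernel — the oracle."""
    out = []
    for comp in range(3):
        def integrand(yp, xp, comp=comp):
            d = np.array([point[0] - xp, point[1] - yp, point[2] - sheet.z0])
            return d[comp] / np.linalg.norm(d) ** 3

        val, _ = integrate.dblquad(
            integrand, sheet.x1, sheet.x2, sheet.y1, sheet.y2,
            epsabs=1e-14, epsrel=1e-10,
        )
        out.append(val)
    return MU_0 * sheet.sigma / (4 * np.pi) * np.array(out)


class TestSheetField:
    sheet = ChargeSheet(-1e-3, 2e-3, -0.5e-3, 1.5e-3, 0.3e-3, 2.0e5)

    def test_matches_quadrature_oracle(self, rng):
        for _ in range(10):
            p = rng.uniform(-3e-3, 3e-3, 3)
            p[2] = rng.uniform(0.5e-3, 4e-3) * rng.choice([-1, 1])
            closed = sheet_field(p, self.sheet)
            oracle = quadrature_sheet_field(p, self.sheet)
            assert np.allclose(closed, oracle, rtol=1e-3, atol=1e-12)

    def test_linear_in_charge_density(self):
        p = np.array([0.5e-3, 0.2e-3, -1e-3])
        zero = ChargeSheet(*vars(self.sheet).values())
        b0 = sheet_field(p, ChargeSheet(-1e-3, 2e-3, -0.5e-3, 1.5e-3, 0.3e-3, 0.0))
        assert np.all(b0 == 0)
        b1 = sheet_field(p, self.sheet)
        b2 = sheet_field(p, ChargeSheet(-1e-3, 2e-3, -0.5e-3, 1.5e-3, 0.3e-3, 4.0e5))
        assert np.allclose(2 * b1, b2, rtol=1e-12)

    def test_far_field_is_point_charge(self):
        # centred square sheet; field at 20x the side along the normal
        side = 1e-3
        sheet = ChargeSheet(-side / 2, side / 2, -side / 2, side / 2, 0.0, 1e5)
        d = 20 * side
        b = sheet_field(np.array([0.0, 0.0, d]), sheet)
        q = sheet.sigma * side**2
        expected = MU_0 * q / (4 * np.pi * d**2)
        assert b[2] == pytest.approx(expected, rel=0.01)
        assert abs(b[0]) < 1e-12 and abs(b[1]) < 1e-12

    def test_mirror_symmetry(self):
        side = 1e-3
        sheet = ChargeSheet(-side / 2, side / 2, -side / 2, side / 2, 0.0, 1e5)
        b_plus = sheet_field(np.array([0.4e-3, 0.1e-3, 1e-3]), sheet)
        b_minus = sheet_field(np.array([-0.4e-3, 0.1e-3, 1e-3]), sheet)
        assert b_plus[2] == pytest.approx(b_minus[2], rel=1e-12)
        assert b_plus[0] == pytest.approx(-b_minus[0], rel=1e-12)

    def test_on_sheet_evaluation_rejected(self):
        with pytest.raises(SheetEvaluationError):
            sheet_field(np.array([0.0, 0.0, 0.3e-3]), self.sheet)


class TestTotalField:
    def test_vertical_component_zero_on_axis(self, assembly):
        b = total_field(np.array([0.0, 0.0, -0.4e-3]), assembly, z_mag=1.0)
        assert abs(b[2]) < 1e-12 * np.linalg.norm(b)

    def test_half_turn_flips_polarity_keeps_magnitude(self, assembly):
        from dataclasses import replace

        p = np.array([50e-6, -30e-6, -0.4e-3])
        b = total_field(p, assembly, z_mag=1.0)
        b_rot = total_field(p, replace(assembly, rotation_angle=np.pi), z_mag=1.0)
        assert np.allclose(b_rot, -b, rtol=1e-9)
        assert np.linalg.norm(b_rot) == pytest.approx(np.linalg.norm(b), rel=1e-12)

    def test_linear_in_remanence(self, assembly):
        from dataclasses import replace

        p = np.array([20e-6, 10e-6, -0.4e-3])
        b1 = total_field(p, assembly, z_mag=2.0)
        b2 = total_field(p, replace(assembly, remanence=2 * assembly.remanence), z_mag=2.0)
        assert np.allclose(b2, 2 * b1, rtol=1e-12)

    def test_divergence_free(self, assembly):
        # central-difference divergence on a 3D stencil in the sample region
        h = 1e-6
        p = np.array([30e-6, -20e-6, -0.4e-3])
        div = 0.0
        for axis in range(3):
            dp = np.zeros(3)
            dp[axis] = h
            div += (
                total_field(p + dp, assembly, 1.0)[axis]
                - total_field(p - dp, assembly, 1.0)[axis]
            ) / (2 * h)
        bmag = np.linalg.norm(total_field(p, assembly, 1.0))
        assert abs(div) < 1e-6 * bmag / h


class TestBeadMoment:
    def test_limits(self, bead):
        assert bead_moment(0.0, bead) == 0.0
        sat = bead.saturation_moment
        assert bead_moment(1e5, bead) == pytest.approx(sat, rel=1e-3)
        # closed-form Langevin value at B = B_0
        assert bead_moment(bead.b_0, bead) == pytest.approx(
            sat * (1 / np.tanh(1) - 1), rel=1e-12
        )

    def test_monotone_increasing(self, bead):
        b = np.linspace(0, 100, 500)
        m = bead_moment(b, bead)
        assert np.all(np.diff(m) > 0)

    def test_small_field_linear_susceptibility(self, bead):
        b = np.linspace(1e-6, 0.1 * bead.b_0, 50)
        m = bead_moment(b, bead)
        linear = bead.saturation_moment * b / (3 * bead.b_0)
        assert np.allclose(m, linear, rtol=0.01)


class TestBeadForce:
    def test_on_axis_force_is_vertical(self, assembly, bead):
        f = bead_force([0.0, 0.0], assembly, bead, z_mag=1.0)
        assert abs(f[0]) < 1e-9 * abs(f[2])
        assert abs(f[1]) < 1e-9 * abs(f[2])
        assert f[2] > 0  # pulls the bead up towards the magnets

    @pytest.mark.parametrize("convention", ["energy", "gradient"])
    def test_gradient_step_converged(self, assembly, bead, convention):
        f1 = bead_force([100.0, 50.0], assembly, bead, 1.0, convention, step_um=1.0)
        f2 = bead_force([100.0, 50.0], assembly, bead, 1.0, convention, step_um=0.5)
        assert np.allclose(f1, f2, rtol=1e-4)

    def test_force_angle_zero_on_axis(self, assembly, bead):
        assert force_angle(0.0, 0.0, 1.0, assembly, bead) == pytest.approx(0.0, abs=1e-6)

    def test_force_angle_grows_off_axis(self, assembly, bead):
        angles = [force_angle(x, 0.0, 1.0, assembly, bead) for x in (0.0, 100.0, 200.0)]
        assert angles == sorted(angles)
        assert angles[-1] > 1.0

    def test_force_angle_undefined_where_fz_vanishes(self, monkeypatch, assembly, bead):
        import mtweezers.magnetostatics as ms

        monkeypatch.setattr(
            ms, "bead_force", lambda *a, **k: np.array([0.5, 0.0, 0.0])
        )
        with pytest.raises(UndefinedAngleError):
            ms.force_angle(200.0, 0.0, 1.0, assembly, bead)


class TestForceMapAndDecay:
    def test_force_map_symmetries(self, assembly, bead):
        fmap = force_map(assembly, bead, 1.0, 400.0, 15, convention="gradient")
        fz = np.abs(fmap.force_pn[..., 2])
        fx = fmap.force_pn[..., 0]
        # reflection through the magnet symmetry plane (x -> -x)
        assert np.allclose(fz, fz[:, ::-1], rtol=1e-7)
        assert np.allclose(fx, -fx[:, ::-1], rtol=1e-6, atol=1e-9)

    def test_variation_decreases_with_height(self, assembly, bead):
        variations = [
            force_map(assembly, bead, z, 400.0, 15).variation_percent
            for z in (0.0, 0.5, 1.0, 2.0)
        ]
        assert variations == sorted(variations, reverse=True)

    def test_variation_vanishes_with_fov(self, assembly, bead):
        small = force_map(assembly, bead, 1.0, 4.0, 11).variation_percent
        large = force_map(assembly, bead, 1.0, 400.0, 11).variation_percent
        assert small < 0.01 * large

    def test_force_map_validates_grid(self, assembly, bead):
        with pytest.raises(ValueError):
            force_map(assembly, bead, 1.0, 400.0, 5)

    def test_force_vs_height_monotone_beyond_gap_edge(self, assembly, bead):
        # the charge-sheet model has a force plateau right at the gap edge;
        # beyond ~0.8 mm the on-axis force decays strictly
        table = force_vs_height(assembly, bead, (0.8, 10.0), 40)
        assert np.all(np.diff(table["f_z_pn"].to_numpy()) < 0)

    def test_force_scales_with_remanence_near_saturation(self, assembly, bead):
        from dataclasses import replace

        f1 = bead_force([0.0, 0.0], assembly, bead, 1.5)[2]
        f2 = bead_force(
            [0.0, 0.0], replace(assembly, remanence=1.2 * assembly.remanence), bead, 1.5
        )[2]
        assert f2 / f1 == pytest.approx(1.2, rel=0.05)

    def test_exponential_fit_self_consistency(self):
        z = np.linspace(1, 8, 40)
        f = 5.0 * np.exp(-(z - 1.0) / 1.7)
        res = fit_force_decay(__import__("pandas").DataFrame({"z_mag_mm": z, "f_z_pn": f}))
        assert res.f0_pn == pytest.approx(5.0, rel=1e-9)
        assert res.l_dec_mm == pytest.approx(1.7, rel=1e-9)
        assert res.max_rel_err_percent < 1e-6

    def test_exponential_fit_requires_points(self):
        import pandas as pd

        table = pd.DataFrame({"z_mag_mm": [1, 2, 3], "f_z_pn": [3, 2, 1]})
        with pytest.raises(ValueError):
            fit_force_decay(table)

    def test_model_decay_length(self, gradient_force_table):
        res = fit_force_decay(gradient_force_table, convention="gradient")
        assert res.l_dec_mm == pytest.approx(1.86, abs=0.15)
        assert res.max_rel_err_percent < 10.0
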