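"""Limaçon rotation patterns, attachment geometry and offset statistics."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest

from mtweezers import (
    BeadModel,
    LimaconParams,
    MagnetAssembly,
    WlcParams,
    attachment_offset_cdf,
    attachment_offset_from_radius,
    attachment_offset_pdf,
    attachment_radius_from_offset,
    fit_limacon,
    has_inner_loop,
    limacon_curve,
    predict_precession_radius,
    sample_attachment_offsets,
)

OMEGA = 2 * np.pi * 0.5  # 0.5 Hz magnet drive


def brute_force_self_intersects(params, n=1500):
    """Segment-intersection scan of one pattern period — the oracle.

    With R_att = 0 the geometric period halves (pure double-frequency
    circle); scanning the full magnet turn would re-trace the same circle
    and spuriously flag overlap as intersection.
    """
    period = 2 * np.pi / params.omega_mag
    if params.r_att_um == 0.0:
        period /= 2.0
    t = np.linspace(0, period, n, endpoint=False)
    c = limacon_curve(params, t)
    p = np.column_stack([c["x"], c["y"]])
    a = p
    b = np.roll(p, -1, axis=0)

    def cross(u, v):
        return u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]

    for i in range(n - 2):
        j = np.arange(i + 2, n - (1 if i == 0 else 0))
        if j.size == 0:
            continue
        p1, p2 = a[i], b[i]
        p3, p4 = a[j], b[j]
        d1 = cross(p4 - p3, p1 - p3)
        d2 = cross(p4 - p3, p2 - p3)
        d3 = cross(p2 - p1, p3 - p1)
        d4 = cross(p2 - p1, p4 - p1)
        if np.any((d1 * d2 < 0) & (d3 * d4 < 0)):
            return True
    return False


class TestLimaconCurve:
    def test_pure_attachment_circle(self):
        params = LimaconParams(0.12, 0.0, omega_mag=OMEGA)
        c = limacon_curve(params, np.linspace(0, 4, 400))
        r = np.hypot(c["x"], c["y"])
        assert np.allclose(r, 0.12, rtol=1e-12)

    def test_pure_precession_circle_at_double_frequency(self):
        params = LimaconParams(0.0, 0.25, omega_mag=OMEGA)
        t = np.linspace(0, 4, 400)
        c = limacon_curve(params, t)
        assert np.allclose(np.hypot(c["x"], c["y"]), 0.25, rtol=1e-12)
        # one magnet turn -> two full revolutions
        phase = np.unwrap(np.arctan2(c["y"], c["x"]))
        assert phase[-1] - phase[0] == pytest.approx(2 * OMEGA * (t[-1] - t[0]), rel=1e-6)

    def test_periodic_with_magnet_turn(self):
        params = LimaconParams(0.12, 0.25, phi_att=0.3, phi_prec=1.1, omega_mag=OMEGA)
        period = 2 * np.pi / OMEGA
        a = limacon_curve(params, np.array([0.1, 0.7]))
        b = limacon_curve(params, np.array([0.1 + period, 0.7 + period]))
        assert np.allclose(a[["x", "y"]], b[["x", "y"]], atol=1e-12)

    def test_requires_increasing_times(self):
        with pytest.raises(ValueError):
            limacon_curve(LimaconParams(0.1, 0.1), np.array([0.0, 0.0, 1.0]))


class TestInnerLoop:
    @pytest.mark.parametrize(
        "r_att, r_prec, expected",
        [
            (0.12, 0.25, True),  # bicircular pattern with inner loop
            (0.12, 0.02, False),  # mono-circular-looking response
            (0.0, 0.3, False),  # pure precession circle
            (0.2, 0.0, False),  # pure attachment circle
            (0.2, 0.11, True),  # just above the 2 R_prec = R_att boundary
            (0.2, 0.09, False),  # just below
        ],
    )
    def test_criterion_matches_brute_force_scan(self, r_att, r_prec, expected):
        params = LimaconParams(r_att, r_prec, omega_mag=OMEGA)
        assert has_inner_loop(params) is expected
        assert brute_force_self_intersects(params) is expected


class TestLimaconFit:
    def test_noise_free_exact_recovery(self):
        truth = LimaconParams(0.12, 0.25, 0.4, 1.9, (3.0, -2.0), OMEGA)
        t = np.arange(0, 8.0, 0.02)
        res = fit_limacon(limacon_curve(truth, t), OMEGA)
        assert res.params.r_att_um == pytest.approx(0.12, abs=1e-12)
        assert res.params.r_prec_um == pytest.approx(0.25, abs=1e-12)
        assert res.params.phi_att == pytest.approx(0.4, abs=1e-10)
        assert res.params.center_um[0] == pytest.approx(3.0, abs=1e-12)
        assert res.residual_rms_um < 1e-12

    def test_unbiased_radii_under_tracking_noise(self, rng):
        truth = LimaconParams(0.12, 0.05, 0.7, 2.4, (0.5, 0.5), OMEGA)
        t = np.arange(0, 8.0, 0.02)  # 4 turns at 50 Hz
        clean = limacon_curve(truth, t)
        est = []
        for _ in range(100):
            noisy = clean.copy()
            noisy["x"] += rng.normal(0, 0.0022, len(t))
            noisy["y"] += rng.normal(0, 0.0022, len(t))
            res = fit_limacon(noisy, OMEGA)
            est.append([res.params.r_att_um, res.params.r_prec_um])
        est = np.array(est)
        assert np.all(np.abs(est.mean(axis=0) - [0.12, 0.05]) < 0.5e-3)  # bias < 0.5 nm
        assert np.all(np.abs(est - [0.12, 0.05]) < 3e-3)  # each within 3 nm

    def test_pure_circle_gives_zero_precession(self):
        truth = LimaconParams(0.15, 0.0, omega_mag=OMEGA)
        res = fit_limacon(limacon_curve(truth, np.arange(0, 8, 0.02)), OMEGA)
        assert res.params.r_att_um == pytest.approx(0.15, abs=1e-12)
        assert res.params.r_prec_um == pytest.approx(0.0, abs=1e-10)

    def test_insufficient_data_rejected(self):
        truth = LimaconParams(0.1, 0.05, omega_mag=OMEGA)
        with pytest.raises(ValueError, match="two full magnet turns"):
            fit_limacon(limacon_curve(truth, np.arange(0, 1.0, 0.02)), OMEGA)

    def test_frequency_doubling_spectrum(self, rng):
        # a misaligned tether with eccentric anchor shows power at the
        # drive frequency and its double only
        truth = LimaconParams(0.12, 0.25, 0.2, 1.0, omega_mag=OMEGA)
        t = np.arange(0, 16.0, 0.02)
        c = limacon_curve(truth, t)
        x = c["x"].to_numpy() + rng.normal(0, 0.0022, len(t))
        spec = np.abs(np.fft.rfft(x - x.mean())) / len(t)
        freqs = np.fft.rfftfreq(len(t), 0.02)
        f_drive = OMEGA / (2 * np.pi)
        peaks = freqs[spec > 10 * np.median(spec[1:])]
        assert np.allclose(sorted(peaks), [f_drive, 2 * f_drive], atol=1e-6)


class TestAttachmentGeometry:
    def test_boundaries(self):
        assert attachment_offset_from_radius(0.0, 0.525) == 0.0
        assert attachment_offset_from_radius(0.525, 0.525) == pytest.approx(0.525)

    def test_worked_example(self):
        # R_att = 0.102 µm on a MyOne bead hides about 10 nm of tether
        assert attachment_offset_from_radius(0.102, 0.525) == pytest.approx(0.010, abs=5e-4)

    def test_round_trip(self):
        for a in (0.0, 0.01, 0.1, 0.5):
            r = attachment_radius_from_offset(a, 0.525)
            assert attachment_offset_from_radius(r, 0.525) == pytest.approx(a, abs=1e-12)

    def test_radius_beyond_bead_rejected(self):
        with pytest.raises(ValueError):
            attachment_offset_from_radius(0.6, 0.525)


class TestOffsetDistribution:
    R = 0.525

    def test_normalized(self):
        total, _ = quad(lambda a: attachment_offset_pdf(a, self.R), 0, self.R)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_vanishes_at_pole_offset(self):
        assert attachment_offset_pdf(self.R, self.R) == 0.0

    def test_cdf_is_antiderivative(self):
        a = np.linspace(0.01, 0.5, 25)
        h = 1e-7
        numeric = (attachment_offset_cdf(a + h, self.R) - attachment_offset_cdf(a - h, self.R)) / (2 * h)
        assert np.allclose(numeric, attachment_offset_pdf(a, self.R), rtol=1e-5)

    def test_matches_sphere_monte_carlo(self, rng):
        # uniform anchors on the sphere, free rotation about the easy axis:
        # A = R(1 - sin(angle to axis)); cos(angle) uniform on [-1, 1]
        u = rng.uniform(-1.0, 1.0, 1_000_000)
        a_mc = self.R * (1.0 - np.sqrt(1.0 - u**2))
        ks = kstest(a_mc, lambda a: attachment_offset_cdf(a, self.R))
        assert ks.statistic < 0.002

    def test_sampler_matches_density(self, rng):
        n = 1_000_000
        samples = sample_attachment_offsets(n, self.R, seed=99)
        assert np.all((samples >= 0) & (samples <= self.R))
        mean_a, _ = quad(lambda a: a * attachment_offset_pdf(a, self.R), 0, self.R)
        se = samples.std() / np.sqrt(n)
        assert abs(samples.mean() - mean_a) < 3 * se
        # analytic mean R(1 - pi/4) as a cross-check of the quadrature
        assert mean_a == pytest.approx(self.R * (1 - np.pi / 4), rel=1e-6)

    def test_sampler_reproducible(self):
        a = sample_attachment_offsets(1000, self.R, seed=5)
        b = sample_attachment_offsets(1000, self.R, seed=5)
        assert np.array_equal(a, b)


class TestPrecessionPrediction:
    wlc = WlcParams(6.8, 50.0)  # 20 kb tether as in the rotation measurements

    def test_zero_on_axis(self, assembly, bead):
        assert predict_precession_radius(0.0, 1.0, assembly, bead, self.wlc) == 0.0

    def test_increases_with_distance_from_axis(self, assembly, bead):
        r = [
            predict_precession_radius(d, 1.0, assembly, bead, self.wlc)
            for d in (0.0, 50.0, 100.0, 200.0)
        ]
        assert r == sorted(r)
        assert r[-1] > 0

    def test_stronger_dependence_at_low_magnet_height(self, assembly, bead):
        low = predict_precession_radius(150.0, 0.2, assembly, bead, self.wlc)
        high = predict_precession_radius(150.0, 1.0, assembly, bead, self.wlc)
        assert low > high
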