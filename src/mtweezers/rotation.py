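"""Limaçon rotation patterns and bead-attachment geometry.

A tether that sits off the magnet rotation axis precesses at twice the
magnet rotation frequency (half a magnet turn restores the same field
intensity pattern with flipped polarity), while an eccentric DNA anchor
on the bead adds a circular component at the drive frequency itself.
The bead's in-plane trajectory is therefore bicircular,

    x(t) = x0 + R_att cos(w t + p_att) + R_prec cos(2 w t + p_prec),
    y(t) = y0 + R_att sin(w t + p_att) + R_prec sin(2 w t + p_prec),

a Limaçon (special epitrochoid) that self-intersects into an inner loop
when 2 R_prec > R_att > 0.  Because the two frequencies are known from
the magnet drive, fitting is a linear projection onto the quadrature
amplitudes — no nonlinear optimization is involved.

The attachment radius converts to the height offset A that the anchor
hides from the length measurement, A = R − sqrt(R² − R_att²), and a
uniform anchor distribution on the sphere (with free rotation about the
horizontal magnetic easy axis) induces the offset probability density

    p(A) = (1 − A/R) / (R sqrt(1 − (1 − A/R)²)),   0 ≤ A ≤ R,

which integrates to one, vanishes at A = R and diverges integrably at
A → 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .magnetostatics import BeadModel, MagnetAssembly, bead_force, force_angle
from .wlc import WlcParams, wlc_extension_at_force

__all__ = [
    "LimaconParams",
    "limacon_curve",
    "has_inner_loop",
    "LimaconModel",
    "LimaconFitResult",
    "fit_limacon",
    "attachment_offset_from_radius",
    "attachment_radius_from_offset",
    "attachment_offset_pdf",
    "attachment_offset_cdf",
    "sample_attachment_offsets",
    "predict_precession_radius",
]


@dataclass(frozen=True)
class LimaconParams:
    """Parameters of the bicircular rotation pattern.

    The attachment component rotates at the magnet drive frequency
    ``omega_mag``; the precession component at exactly twice that —
    a hard constraint of the physics, not a fit parameter.
    """

    r_att_um: float
    r_prec_um: float
    phi_att: float = 0.0
    phi_prec: float = 0.0
    center_um: tuple[float, float] = (0.0, 0.0)
    omega_mag: float = 2.0 * np.pi

    def __post_init__(self) -> None:
        if self.r_att_um < 0 or self.r_prec_um < 0:
            raise ValueError("radii must be non-negative")


def limacon_curve(params: LimaconParams, times) -> pd.DataFrame:
    """Sample the Limaçon pattern at the given times (strictly increasing).

    Returns a DataFrame (t, x, y) in µm; periodic with the magnet turn
    period 2π/omega_mag.  R_prec = 0 degenerates to a circle of radius
    R_att at the drive frequency; R_att = 0 to a circle at twice it.
    """
    t = np.asarray(times, dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    w = params.omega_mag
    x = (
        params.center_um[0]
        + params.r_att_um * np.cos(w * t + params.phi_att)
        + params.r_prec_um * np.cos(2.0 * w * t + params.phi_prec)
    )
    y = (
        params.center_um[1]
        + params.r_att_um * np.sin(w * t + params.phi_att)
        + params.r_prec_um * np.sin(2.0 * w * t + params.phi_prec)
    )
    return pd.DataFrame({"t": t, "x": x, "y": y})


def has_inner_loop(params: LimaconParams) -> bool:
    """Whether the pattern self-intersects into an inner loop.

    True iff 2·R_prec > R_att > 0 (the Limaçon loop condition).
    """
    return bool(2.0 * params.r_prec_um > params.r_att_um > 0.0)


@dataclass
class LimaconFitResult:
    """Fitted Limaçon parameters with residual diagnostics."""

    params: LimaconParams
    residual_rms_um: float
    n_points: int

    def summary(self) -> str:
        p = self.params
        return "\n".join(
            [
                "Limaçon rotation-pattern fit",
                "----------------------------",
                f"R_att  (µm) : {p.r_att_um:8.4f}",
                f"R_prec (µm) : {p.r_prec_um:8.4f}",
                f"phi_att (rad) : {p.phi_att:8.4f}",
                f"phi_prec (rad): {p.phi_prec:8.4f}",
                f"center (µm) : ({p.center_um[0]:.4f}, {p.center_um[1]:.4f})",
                f"residual RMS (µm): {self.residual_rms_um:.5f}",
                f"points: {self.n_points}",
                f"inner loop: {has_inner_loop(p)}",
            ]
        )


class LimaconModel:
    """Linear model of an xy rotation trace at a known drive frequency.

    With the component frequencies fixed at omega and 2·omega, the
    pattern is linear in the quadrature amplitudes (a1, b1, a2, b2) and
    the centre; both coordinates share the amplitudes, so x and y rows
    are stacked into one least-squares system.  Radii come out
    non-negative by construction (phases absorb the sign).
    """

    def __init__(self, times, x_um, y_um, omega_mag: float):
        self.t = np.asarray(times, dtype=float)
        self.x = np.asarray(x_um, dtype=float)
        self.y = np.asarray(y_um, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have matching shapes")
        self.omega_mag = float(omega_mag)
        span = self.t[-1] - self.t[0]
        if span * self.omega_mag < 2.0 * (2.0 * np.pi):
            raise ValueError("need at least two full magnet turns of data")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, omega_mag: float) -> "LimaconModel":
        return cls(frame["t"], frame["x"], frame["y"], omega_mag)

    def fit(self, noise_floor_um: float = 0.0022) -> LimaconFitResult:
        w = self.omega_mag
        c1, s1 = np.cos(w * self.t), np.sin(w * self.t)
        c2, s2 = np.cos(2 * w * self.t), np.sin(2 * w * self.t)
        one = np.ones_like(self.t)
        zero = np.zeros_like(self.t)
        # unknowns: [a1, b1, a2, b2, x0, y0]
        design_x = np.column_stack([c1, -s1, c2, -s2, one, zero])
        design_y = np.column_stack([s1, c1, s2, c2, zero, one])
        design = np.vstack([design_x, design_y])
        target = np.concatenate([self.x, self.y])
        coef, *_ = np.linalg.lstsq(design, target, rcond=None)
        a1, b1, a2, b2, x0, y0 = coef
        r_att = float(np.hypot(a1, b1))
        r_prec = float(np.hypot(a2, b2))
        params = LimaconParams(
            r_att_um=r_att,
            r_prec_um=r_prec,
            phi_att=float(np.arctan2(b1, a1)),
            phi_prec=float(np.arctan2(b2, a2)),
            center_um=(float(x0), float(y0)),
            omega_mag=w,
        )
        resid = target - design @ coef
        rms = float(np.sqrt(np.mean(resid**2)))
        if noise_floor_um and rms > 3.0 * noise_floor_um:
            import warnings

            warnings.warn(
                f"Limaçon fit residual RMS {rms:.4g} µm exceeds 3x the tracking "
                "noise floor; the trace may not be a clean bicircular pattern",
                stacklevel=2,
            )
        return LimaconFitResult(params, rms, self.t.size)


def fit_limacon(trace: pd.DataFrame, omega_mag: float) -> LimaconFitResult:
    """Fit eq.-of-motion radii/phases to an (t, x, y) rotation trace."""
    return LimaconModel.from_frame(trace, omega_mag).fit()


def attachment_offset_from_radius(r_att_um: float, r_bead_um: float) -> float:
    """Height offset A (µm) hidden by an anchor at rotation radius R_att.

    The anchor sits on a horizontal circle of radius R_att about the
    bead's rotation axis: A = R − sqrt(R² − R_att²).
    """
    if not 0.0 <= r_att_um <= r_bead_um:
        raise ValueError("attachment radius must lie in [0, bead radius]")
    return float(r_bead_um - np.sqrt(r_bead_um**2 - r_att_um**2))


def attachment_radius_from_offset(a_um: float, r_bead_um: float) -> float:
    """Inverse of :func:`attachment_offset_from_radius`."""
    if not 0.0 <= a_um <= r_bead_um:
        raise ValueError("offset must lie in [0, bead radius]")
    return float(np.sqrt(r_bead_um**2 - (r_bead_um - a_um) ** 2))


def attachment_offset_pdf(a_um, r_bead_um: float):
    """Probability density (1/µm) of the attachment height offset A.

    Uniform anchor placement on the sphere with free rotation about the
    horizontal easy axis gives A = R(1 − sin α) with polar-angle density
    sin α, hence p(A) = (1 − A/R)/(R·sqrt(1 − (1 − A/R)²)).
    """
    a = np.asarray(a_um, dtype=float)
    if np.any(a < 0) or np.any(a > r_bead_um):
        raise ValueError("offset must lie in [0, bead radius]")
    u = 1.0 - a / r_bead_um
    with np.errstate(divide="ignore"):
        out = u / (r_bead_um * np.sqrt(np.maximum(1.0 - u * u, 0.0)))
    return float(out) if np.isscalar(a_um) else out


def attachment_offset_cdf(a_um, r_bead_um: float):
    """P(A ≤ a) = sqrt(1 − (1 − a/R)²) — the antiderivative of the density."""
    a = np.asarray(a_um, dtype=float)
    if np.any(a < 0) or np.any(a > r_bead_um):
        raise ValueError("offset must lie in [0, bead radius]")
    u = 1.0 - a / r_bead_um
    out = np.sqrt(np.maximum(1.0 - u * u, 0.0))
    return float(out) if np.isscalar(a_um) else out


def sample_attachment_offsets(n: int, r_bead_um: float, seed: int | None = None) -> np.ndarray:
    """Draw n offsets by inverse-CDF sampling of the attachment law.

    A = R(1 − sqrt(1 − q²)) for q uniform on (0, 1); reproducible under
    ``seed``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    q = rng.uniform(0.0, 1.0, n)
    return r_bead_um * (1.0 - np.sqrt(1.0 - q * q))


def predict_precession_radius(
    d_center_um: float,
    z_mag: float,
    assembly: MagnetAssembly,
    bead: BeadModel,
    tether_wlc: WlcParams,
) -> float:
    """Precession radius predicted from the 3D force field (µm).

    Small-angle pendulum geometry: the tether-plus-bead lever of length
    l_ext + R_bead tilts by the local force angle α, so
    R_prec = (l_ext + R_bead)·tan α, with l_ext the equilibrium WLC
    extension at the local vertical force.  Zero on the rotation axis,
    increasing with the distance from it.
    """
    if d_center_um == 0.0:
        return 0.0
    f = bead_force([d_center_um, 0.0], assembly, bead, z_mag)
    alpha = np.radians(force_angle(d_center_um, 0.0, z_mag, assembly, bead))
    l_ext = wlc_extension_at_force(abs(float(f[2])), tether_wlc)
    return float((l_ext + bead.radius_um) * np.tan(alpha))
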