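"""Charge-sheet magnetostatics of a vertically magnetized antiparallel magnet pair.

The permanent-magnet pair that drives a magnetic-tweezers instrument is
modelled, in the magnetostatic analogue of electrostatics, by fictitious
uniformly charged sheets on the top and bottom faces of each magnet
(surface charge density ``sigma = B_r / mu_0`` for remanent field B_r,
with opposite sign patterns on the two magnets because their moments are
antiparallel).  The field of a uniformly charged rectangle has a closed
form in arctan/log terms, which is used throughout; a brute-force
quadrature of the Coulomb kernel serves as an independent oracle in the
test-suite.

The induced moment of a superparamagnetic bead follows a Langevin law
``m(B) = V M_sat (coth(B/B_0) - B_0/B)`` and the force on the bead is
obtained from the field by numerical differentiation, under one of two
conventions (see :func:`bead_force`).

Geometry: z points vertically up towards the magnets, the origin sits on
the rotation axis at the top surface of the flow cell.  ``z_mag`` is the
distance (mm) from the magnet bottom faces to the flow-cell top.  Beads
live ``bead_plane_depth`` (mm) below the flow-cell top — the top
coverslip plus the fluid channel of a standard flow cell.  The gap axis
is x when ``rotation_angle`` is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .constants import (
    FN_PER_N,
    M_PER_MM,
    M_PER_UM,
    MT_PER_T,
    MU_0,
    PN_PER_N,
)

__all__ = [
    "MagnetAssembly",
    "BeadModel",
    "ChargeSheet",
    "ForceMap",
    "sheet_field",
    "total_field",
    "bead_moment",
    "bead_force",
    "force_angle",
    "force_map",
    "force_vs_height",
    "ForceDecayModel",
    "ForceDecayResult",
    "fit_force_decay",
]

ForceConvention = Literal["energy", "gradient"]


class SheetEvaluationError(ValueError):
    """Raised when the field is requested on a charge sheet itself."""


class UndefinedAngleError(ZeroDivisionError):
    """Raised when the force angle is requested where F_z vanishes."""


@dataclass(frozen=True)
class ChargeSheet:
    """A uniformly charged horizontal rectangle (SI units).

    Spans ``[x1, x2] x [y1, y2]`` in the plane ``z = z0`` (metres) and
    carries magnetic surface charge density ``sigma`` (A/m).
    """

    x1: float
    x2: float
    y1: float
    y2: float
    z0: float
    sigma: float


@dataclass(frozen=True)
class BeadModel:
    """Superparamagnetic bead with Langevin magnetization.

    Defaults are the vendor parameters of 1.05 µm MyOne beads.

    Parameters
    ----------
    radius_um : bead radius (µm).
    m_sat : saturation magnetization (kA/m).
    b_0 : characteristic Langevin field (mT).
    """

    radius_um: float = 0.525
    m_sat: float = 43.3
    b_0: float = 12.0

    def __post_init__(self) -> None:
        if self.radius_um <= 0 or self.m_sat <= 0 or self.b_0 <= 0:
            raise ValueError("bead radius, M_sat and B_0 must all be positive")

    @property
    def volume_m3(self) -> float:
        """Bead volume in m³."""
        return 4.0 / 3.0 * np.pi * (self.radius_um * M_PER_UM) ** 3

    @property
    def saturation_moment(self) -> float:
        """Saturation moment V·M_sat in A·m²."""
        return self.volume_m3 * self.m_sat * 1e3


@dataclass(frozen=True)
class MagnetAssembly:
    """Antiparallel pair of vertically magnetized block magnets.

    Lengths in mm; ``remanence`` in tesla.  The two magnets sit on either
    side of a ``gap`` along the x axis (at ``rotation_angle = 0``), with
    opposite vertical magnetization.  ``bead_plane_depth`` is the depth of
    the bead plane below the flow-cell top (coverslip + channel).
    """

    magnet_width: float = 5.0
    magnet_depth: float = 5.0
    magnet_height: float = 5.0
    gap: float = 2.0
    remanence: float = 1.4
    z_mag: float = 1.0
    rotation_angle: float = 0.0
    bead_plane_depth: float = 0.40

    def __post_init__(self) -> None:
        if self.gap <= 0:
            raise ValueError("gap must be positive")
        if self.z_mag < 0:
            raise ValueError("z_mag must be non-negative")

    @property
    def sheet_charge_density(self) -> float:
        """Fictitious sheet charge density rho_M = B_r/mu_0 (A/m)."""
        return self.remanence / MU_0

    def with_height(self, z_mag: float) -> "MagnetAssembly":
        return replace(self, z_mag=z_mag)

    def sheets(self, z_mag: float | None = None) -> list[ChargeSheet]:
        """The four charge sheets (SI) for magnet bottom faces at ``z_mag``."""
        zm = (self.z_mag if z_mag is None else z_mag) * M_PER_MM
        w = self.magnet_width * M_PER_MM
        d = self.magnet_depth * M_PER_MM
        h = self.magnet_height * M_PER_MM
        g = self.gap * M_PER_MM
        rho = self.sheet_charge_density
        out = []
        for side, msign in ((+1, +1), (-1, -1)):  # +x magnet up, -x magnet down
            x_lo = side * g / 2 + (0 if side > 0 else -w)
            x_hi = x_lo + w
            # top face carries +sigma for upward magnetization
            out.append(ChargeSheet(x_lo, x_hi, -d / 2, d / 2, zm + h, msign * rho))
            out.append(ChargeSheet(x_lo, x_hi, -d / 2, d / 2, zm, -msign * rho))
        return out


def sheet_field(point, sheet: ChargeSheet) -> np.ndarray:
    """Magnetic field B (tesla) of one uniformly charged rectangle.

    ``point`` is an (..., 3) array of positions in metres.  Uses the
    closed-form solution of the Coulomb integral over a rectangle; linear
    in the sheet charge density.  Raises on evaluation in the sheet plane
    inside the rectangle, where the field is discontinuous.
    """
    p = np.asarray(point, dtype=float)
    x, y, z = p[..., 0], p[..., 1], p[..., 2]
    w = z - sheet.z0
    on_plane = np.abs(w) < 1e-15
    inside = (
        (x >= sheet.x1) & (x <= sheet.x2) & (y >= sheet.y1) & (y <= sheet.y2)
    )
    if np.any(on_plane & inside):
        raise SheetEvaluationError("field evaluation on a charge sheet is undefined")
    bx = np.zeros_like(x)
    by = np.zeros_like(x)
    bz = np.zeros_like(x)
    for i, u in enumerate((sheet.x1 - x, sheet.x2 - x)):
        for j, v in enumerate((sheet.y1 - y, sheet.y2 - y)):
            s = 1.0 if (i + j) % 2 == 0 else -1.0
            r = np.sqrt(u * u + v * v + w * w)
            bx += s * np.log(v + r)
            by += s * np.log(u + r)
            bz += s * np.arctan2(u * v, w * r)
    pref = MU_0 * sheet.sigma / (4.0 * np.pi)
    return pref * np.stack([bx, by, bz], axis=-1)


def total_field(point, assembly: MagnetAssembly, z_mag: float | None = None) -> np.ndarray:
    """Field B (tesla) of the full magnet pair at ``point`` (m, assembly frame).

    Sums the four sheet contributions; the assembly rotation about the
    vertical axis is applied by counter-rotating the evaluation point.
    """
    p = np.asarray(point, dtype=float)
    theta = assembly.rotation_angle
    if theta != 0.0:
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])
        p = p @ rot.T
    b = np.zeros(np.shape(p), dtype=float)
    for sh in assembly.sheets(z_mag):
        b = b + sheet_field(p, sh)
    if theta != 0.0:
        c, s = np.cos(theta), np.sin(theta)
        rot_back = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        b = b @ rot_back.T
    return b


def bead_moment(b_magnitude, bead: BeadModel) -> np.ndarray | float:
    """Langevin induced moment (A·m²) at field magnitude ``b_magnitude`` (mT).

    m = V·M_sat·[coth(B/B_0) − B_0/B]; a series expansion handles B → 0
    (limit 0, initial slope V·M_sat/(3 B_0)); saturates at V·M_sat.
    """
    b = np.asarray(b_magnitude, dtype=float) / bead.b_0
    if np.any(b < 0):
        raise ValueError("field magnitude must be non-negative")
    small = b < 1e-4
    bs = np.where(small, 1.0, b)  # avoid 0/0 in the masked branch
    langevin = np.where(
        small,
        b / 3.0 - b**3 / 45.0,
        1.0 / np.tanh(bs) - 1.0 / bs,
    )
    out = bead.saturation_moment * langevin
    return float(out) if np.isscalar(b_magnitude) else out


def _bead_points(pos_um, assembly: MagnetAssembly) -> np.ndarray:
    """Positions (..., 2 or 3) in µm → SI points in the assembly frame."""
    p = np.asarray(pos_um, dtype=float)
    if p.shape[-1] == 2:
        p = np.concatenate([p, np.zeros(p.shape[:-1] + (1,))], axis=-1)
    p = p * M_PER_UM
    p = p.copy()
    p[..., 2] -= assembly.bead_plane_depth * M_PER_MM
    return p


def _field_magnitude(points, assembly: MagnetAssembly, z_mag: float | None) -> np.ndarray:
    return np.linalg.norm(total_field(points, assembly, z_mag), axis=-1)


def bead_force(
    pos_um,
    assembly: MagnetAssembly,
    bead: BeadModel,
    z_mag: float | None = None,
    convention: ForceConvention = "energy",
    step_um: float = 1.0,
) -> np.ndarray:
    """Magnetic force (pN, 3-vector) on a bead in the field of view.

    ``pos_um`` is an (..., 2|3) array of (posX, posY[, z]) in µm; the bead
    plane sits ``assembly.bead_plane_depth`` mm below the flow-cell top.

    Two force conventions are supported:

    - ``"energy"`` (default): F = m(|B|) ∇|B|, the thermodynamically
      consistent force for a moment induced along the field with
      Langevin saturation.
    - ``"gradient"``: F = ∇(m(|B|)·|B|) = [m + |B| dm/d|B|] ∇|B|.

    The gradient of |B| is taken by central differences with step
    ``step_um`` (µm), convergence-tested at the default.
    """
    p = _bead_points(pos_um, assembly)
    h = step_um * M_PER_UM
    grad = np.empty(p.shape[:-1] + (3,), dtype=float)
    for axis in range(3):
        dp = np.zeros(3)
        dp[axis] = h
        grad[..., axis] = (
            _field_magnitude(p + dp, assembly, z_mag)
            - _field_magnitude(p - dp, assembly, z_mag)
        ) / (2.0 * h)
    if not np.all(np.isfinite(grad)):
        raise FloatingPointError("non-finite field gradient")
    b_mt = _field_magnitude(p, assembly, z_mag) * MT_PER_T
    m = np.asarray(bead_moment(b_mt, bead))
    if convention == "gradient":
        # d(mB)/dB = m + B dm/dB, with dm/dB from the Langevin law (B in T)
        b_t = b_mt / MT_PER_T
        brel = b_mt / bead.b_0
        small = brel < 1e-4
        bs = np.where(small, 1.0, brel)
        dl_db = np.where(small, 1.0 / 3.0 - brel**2 / 15.0, 1.0 / bs**2 - 1.0 / np.sinh(bs) ** 2)
        dm_db = bead.saturation_moment * dl_db / (bead.b_0 / MT_PER_T)
        m = m + b_t * dm_db
    elif convention != "energy":
        raise ValueError(f"unknown force convention {convention!r}")
    return (m[..., None] * grad) * PN_PER_N


def force_angle(
    pos_x_um: float,
    pos_y_um: float,
    z_mag: float,
    assembly: MagnetAssembly | None = None,
    bead: BeadModel | None = None,
    convention: ForceConvention = "energy",
) -> float:
    """Angle α (degrees) between the force vector and the vertical axis.

    α = arctan(|F_lateral| / |F_z|); zero on the rotation axis by
    symmetry.  Raises :class:`UndefinedAngleError` where F_z = 0.
    """
    assembly = assembly or MagnetAssembly()
    bead = bead or BeadModel()
    f = bead_force([pos_x_um, pos_y_um], assembly, bead, z_mag, convention)
    if f[2] == 0.0:
        raise UndefinedAngleError("force angle undefined where F_z = 0")
    lateral = float(np.hypot(f[0], f[1]))
    return float(np.degrees(np.arctan2(lateral, abs(float(f[2])))))


@dataclass
class ForceMap:
    """Force and field over a rectangular grid in the field of view.

    ``force_pn`` has shape (n, n, 3); ``b_mt`` is the field vector (mT).
    ``variation_percent`` is 100·(max−min)/max of |F| over the grid
    (the |F_z| version is carried alongside); ``max_angle_deg`` the
    largest force angle on the grid.
    """

    pos_x_um: np.ndarray
    pos_y_um: np.ndarray
    z_mag: float
    force_pn: np.ndarray
    b_mt: np.ndarray
    convention: str
    variation_percent: float = field(init=False)
    variation_fz_percent: float = field(init=False)
    max_angle_deg: float = field(init=False)

    def __post_init__(self) -> None:
        fmag = np.linalg.norm(self.force_pn, axis=-1)
        fz = np.abs(self.force_pn[..., 2])
        self.variation_percent = float(100.0 * (fmag.max() - fmag.min()) / fmag.max())
        self.variation_fz_percent = float(100.0 * (fz.max() - fz.min()) / fz.max())
        lateral = np.hypot(self.force_pn[..., 0], self.force_pn[..., 1])
        self.max_angle_deg = float(np.degrees(np.arctan2(lateral, fz)).max())

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (posX_um, posY_um, Fx_pN, Fy_pN, Fz_pN, B_mT)."""
        xx, yy = np.meshgrid(self.pos_x_um, self.pos_y_um)
        return pd.DataFrame(
            {
                "posX_um": xx.ravel(),
                "posY_um": yy.ravel(),
                "Fx_pN": self.force_pn[..., 0].ravel(),
                "Fy_pN": self.force_pn[..., 1].ravel(),
                "Fz_pN": self.force_pn[..., 2].ravel(),
                "B_mT": np.linalg.norm(self.b_mt, axis=-1).ravel(),
            }
        )


def force_map(
    assembly: MagnetAssembly,
    bead: BeadModel,
    z_mag: float,
    fov_extent_um: float = 400.0,
    grid_n: int = 41,
    convention: ForceConvention = "energy",
) -> ForceMap:
    """Map the bead force over a square field of view centred on the axis.

    ``fov_extent_um`` is the full width; the grid spans ±extent/2.
    """
    if grid_n < 11:
        raise ValueError("grid_n must be at least 11")
    if fov_extent_um <= 0:
        raise ValueError("fov_extent_um must be positive")
    half = fov_extent_um / 2.0
    xs = np.linspace(-half, half, grid_n)
    ys = np.linspace(-half, half, grid_n)
    xx, yy = np.meshgrid(xs, ys)
    pos = np.stack([xx, yy], axis=-1)
    f = bead_force(pos, assembly, bead, z_mag, convention)
    b = total_field(_bead_points(pos, assembly), assembly, z_mag) * MT_PER_T
    return ForceMap(xs, ys, z_mag, f, b, convention)


def force_vs_height(
    assembly: MagnetAssembly,
    bead: BeadModel,
    z_range: tuple[float, float] = (0.0, 10.0),
    n_points: int = 60,
    convention: ForceConvention = "energy",
) -> pd.DataFrame:
    """On-axis vertical force versus magnet height.

    Returns a DataFrame with columns ``z_mag_mm`` and ``f_z_pn``.
    """
    lo, hi = z_range
    if lo < 0 or hi > 25:
        raise ValueError("z_range must lie within [0, 25] mm")
    zs = np.linspace(lo, hi, n_points)
    fz = np.array(
        [bead_force([0.0, 0.0], assembly, bead, z, convention)[2] for z in zs]
    )
    return pd.DataFrame({"z_mag_mm": zs, "f_z_pn": fz})


@dataclass
class ForceDecayResult:
    """Single-exponential description of force versus magnet height.

    F(Z) = f0_pn · exp(−(Z − z_ref)/l_dec_mm); error metrics are taken
    over the fitted range against the tabulated model force.
    """

    f0_pn: float
    l_dec_mm: float
    z_ref_mm: float
    max_rel_err_percent: float
    max_abs_err_fn: float
    n_points: int
    residuals_pn: np.ndarray
    convention: str | None = None

    def predict(self, z_mag) -> np.ndarray:
        return self.f0_pn * np.exp(-(np.asarray(z_mag, dtype=float) - self.z_ref_mm) / self.l_dec_mm)

    def summary(self) -> str:
        lines = [
            "Single-exponential force decay fit",
            "----------------------------------",
            f"F_0 (pN, at Z_ref = {self.z_ref_mm:g} mm) : {self.f0_pn:10.4f}",
            f"l_dec (mm)                       : {self.l_dec_mm:10.4f}",
            f"max relative error (%)           : {self.max_rel_err_percent:10.3f}",
            f"max absolute error (fN)          : {self.max_abs_err_fn:10.3f}",
            f"points fitted                    : {self.n_points:10d}",
        ]
        if self.convention:
            lines.append(f"force convention                 : {self.convention:>10s}")
        return "\n".join(lines)


class ForceDecayModel:
    """Least-squares single-exponential model of F(Z_mag).

    Built from a table of on-axis forces (e.g. :func:`force_vs_height`
    output); ``fit`` restricts to ``fit_range`` and anchors the prefactor
    at ``z_ref`` (1 mm by convention).
    """

    def __init__(self, z_mag_mm, f_z_pn, convention: str | None = None):
        self.z_mag_mm = np.asarray(z_mag_mm, dtype=float)
        self.f_z_pn = np.asarray(f_z_pn, dtype=float)
        self.convention = convention

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, convention: str | None = None) -> "ForceDecayModel":
        return cls(frame["z_mag_mm"].to_numpy(), frame["f_z_pn"].to_numpy(), convention)

    def fit(self, fit_range: tuple[float, float] = (1.0, 8.0), z_ref: float = 1.0) -> ForceDecayResult:
        lo, hi = fit_range
        mask = (self.z_mag_mm >= lo) & (self.z_mag_mm <= hi)
        z = self.z_mag_mm[mask]
        f = self.f_z_pn[mask]
        if z.size < 10:
            raise ValueError("need at least 10 points inside the fit range")
        if np.ptp(z) <= 0:
            raise ValueError("degenerate fit range")
        # log-linear start, then nonlinear least squares in force space
        slope, intercept = np.polyfit(z - z_ref, np.log(np.abs(f)), 1)
        p0 = [np.exp(intercept), -1.0 / slope]
        popt, _ = curve_fit(
            lambda zz, f0, ld: f0 * np.exp(-(zz - z_ref) / ld), z, f, p0=p0
        )
        f0, l_dec = float(popt[0]), float(popt[1])
        fit = f0 * np.exp(-(z - z_ref) / l_dec)
        resid = f - fit
        return ForceDecayResult(
            f0_pn=f0,
            l_dec_mm=l_dec,
            z_ref_mm=z_ref,
            max_rel_err_percent=float(100.0 * np.max(np.abs(resid) / np.abs(f))),
            max_abs_err_fn=float(np.max(np.abs(resid)) * FN_PER_N / PN_PER_N),
            n_points=int(z.size),
            residuals_pn=resid,
            convention=self.convention,
        )


def fit_force_decay(
    table: pd.DataFrame,
    fit_range: tuple[float, float] = (1.0, 8.0),
    z_ref: float = 1.0,
    convention: str | None = None,
) -> ForceDecayResult:
    """Functional wrapper around :class:`ForceDecayModel`."""
    return ForceDecayModel.from_frame(table, convention).fit(fit_range, z_ref)
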