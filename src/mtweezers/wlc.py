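"""Worm-like-chain elasticity of double-stranded DNA.

Entropic force–extension law in the seven-coefficient analytical form of
Bouchiat and co-workers, which corrects the Marko–Siggia interpolation
formula with a sixth-order polynomial so that it tracks the exact WLC
solution to ~0.1%:

    F(x) = (k_BT / L_p) [ 1/(4(1-x)^2) - 1/4 + x + sum_{i=2..7} a_i x^i ],

with relative extension x = l/L_c.  The stretching energy has the exact
antiderivative of this expression, used for the energy-versus-extension
analysis.  Units: L_c and extensions in µm, L_p in nm, forces in pN,
energies in k_BT (or J).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .constants import DEFAULT_TEMPERATURE, kbt_joule, kbt_pn_um

__all__ = [
    "WlcParams",
    "BOUCHIAT_COEFFS",
    "wlc_force",
    "wlc_stiffness",
    "wlc_energy",
    "wlc_extension_at_force",
]

#: a_2 .. a_7 of the seven-parameter approximation
BOUCHIAT_COEFFS = np.array(
    [-0.5164228, -2.737418, 16.07497, -38.87607, 39.49944, -14.17718]
)


@dataclass(frozen=True)
class WlcParams:
    """Worm-like chain parameters.

    contour_length_um : contour length L_c (µm)
    persistence_length_nm : persistence length L_p (nm)
    temperature : assay temperature (K), default 22 °C
    """

    contour_length_um: float
    persistence_length_nm: float = 50.0
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.contour_length_um <= 0 or self.persistence_length_nm <= 0:
            raise ValueError("contour and persistence lengths must be positive")

    @property
    def force_scale_pn(self) -> float:
        """k_BT/L_p in pN (≈0.0815 pN for L_p = 50 nm at 22 °C)."""
        return kbt_pn_um(self.temperature) / (self.persistence_length_nm * 1e-3)


def _rel_extension(extension_um, params: WlcParams, allow_one: bool = False) -> np.ndarray:
    x = np.asarray(extension_um, dtype=float) / params.contour_length_um
    if np.any(x < 0) or np.any(x >= 1):
        raise ValueError("extension must satisfy 0 <= extension < contour length")
    return x


def _dimensionless_force(x: np.ndarray, full: bool = True) -> np.ndarray:
    f = 1.0 / (4.0 * (1.0 - x) ** 2) - 0.25 + x
    if full:
        f = f + sum(a * x ** (i + 2) for i, a in enumerate(BOUCHIAT_COEFFS))
    return f


def wlc_force(extension_um, params: WlcParams, full: bool = True):
    """WLC restoring force (pN) at the given end-to-end extension (µm).

    ``full=False`` drops the polynomial correction, leaving the plain
    Marko–Siggia interpolation formula.
    """
    x = _rel_extension(extension_um, params)
    out = params.force_scale_pn * _dimensionless_force(x, full)
    return float(out) if np.isscalar(extension_um) else out


def wlc_stiffness(extension_um, params: WlcParams):
    """dF/dl (pN/µm) of the WLC law at the given extension (µm)."""
    x = _rel_extension(extension_um, params)
    df = 1.0 / (2.0 * (1.0 - x) ** 3) + 1.0
    df = df + sum((i + 2) * a * x ** (i + 1) for i, a in enumerate(BOUCHIAT_COEFFS))
    out = params.force_scale_pn * df / params.contour_length_um
    return float(out) if np.isscalar(extension_um) else out


def wlc_energy(extension_um, params: WlcParams, units: str = "kbt"):
    """Stretching energy E(l) = ∫₀ˡ F dl′ of the WLC law.

    Evaluated with the exact antiderivative of the seven-term force law:

        E(x)/(k_BT L_c/L_p) = 1/(4(1-x)) - 1/4 - x/4 + x²/2
                              + Σ a_i x^(i+1)/(i+1).

    ``units`` is ``"kbt"`` (default), ``"joule"`` or ``"pn_um"``.
    """
    x = _rel_extension(extension_um, params)
    e = 1.0 / (4.0 * (1.0 - x)) - 0.25 - x / 4.0 + x**2 / 2.0
    e = e + sum(a * x ** (i + 3) / (i + 3) for i, a in enumerate(BOUCHIAT_COEFFS))
    e_pn_um = params.force_scale_pn * params.contour_length_um * e
    if units == "pn_um":
        out = e_pn_um
    elif units == "kbt":
        out = e_pn_um / kbt_pn_um(params.temperature)
    elif units == "joule":
        out = e_pn_um / kbt_pn_um(params.temperature) * kbt_joule(params.temperature)
    else:
        raise ValueError(f"unknown energy units {units!r}")
    return float(out) if np.isscalar(extension_um) else out


def wlc_extension_at_force(force_pn, params: WlcParams):
    """Extension (µm) at which the WLC force equals ``force_pn`` (≥ 0 pN).

    Bracketed root-finding on the strictly increasing force law; returns
    0 at zero force.  Round-trips with :func:`wlc_force` to ~1e-12 pN.
    """

    def solve_one(f: float) -> float:
        if f < 0:
            raise ValueError("force must be non-negative")
        if f == 0.0:
            return 0.0
        fs = params.force_scale_pn
        x = brentq(
            lambda xx: _dimensionless_force(np.asarray(xx)) - f / fs,
            0.0,
            1.0 - 1e-12,
            xtol=1e-15,
            rtol=8.9e-16,
        )
        return x * params.contour_length_um

    if np.isscalar(force_pn):
        return solve_one(float(force_pn))
    return np.array([solve_one(float(f)) for f in np.ravel(force_pn)]).reshape(
        np.shape(force_pn)
    )
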