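"""High-throughput tether characterization.

The per-tether protocol converts raw camera traces into worm-like-chain
parameters:

1. surface reference — the lowest bead height recorded at vanishing
   force marks bead-surface contact; all heights are offset-corrected
   against it;
2. attachment correction — the eccentric-anchor offset A (from the
   rotation pattern) is added back to the measured lengths;
3. force calibration — tether tension from the transverse positional
   variance by equipartition, F = k_BT (l_ext + R_bead)/var(x), at
   several magnet heights, reduced to the bead-specific scale F_0 of the
   exponential force law;
4. the dynamic force-extension record is reordered to monotone
   extension and integrated (cumulative trapezoid) into a stretching
   energy curve, which is much smoother than the raw force data;
5. the energy curve is fitted with the WLC stretching energy to extract
   the persistence length L_p and contour length L_c; tethers with
   L_p < 28 nm are classified as multiply tethered.

Ensemble operations summarize many tethers: length-group statistics of
(L_p, L_c), the spread of normalized force scales F_0/<F_0>, and the
attachment-offset histogram against its geometric law.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares
from scipy.stats import kstest

from .constants import DEFAULT_TEMPERATURE, kbt_pn_um
from .rotation import attachment_offset_cdf
from .wlc import WlcParams, wlc_energy

__all__ = [
    "ForceExtensionCurve",
    "EnergyCurve",
    "TetherFitResult",
    "MULTIPLE_TETHER_LP_NM",
    "surface_reference_correct",
    "apply_attachment_correction",
    "calibrate_force_equipartition",
    "fit_force_scale",
    "reorder_monotone",
    "energy_from_force_extension",
    "EnergyWlcModel",
    "fit_energy_wlc",
    "ensemble_analysis",
    "EnsembleReport",
]

#: tethers fitted below this persistence length are multiply tethered
MULTIPLE_TETHER_LP_NM = 28.0


@dataclass
class ForceExtensionCurve:
    """Paired force (pN) and end-to-end extension (µm) arrays.

    ``corrections`` records provenance: the F_0/l_dec used for force
    conversion and the A / surface offsets applied.
    """

    extension_um: np.ndarray
    force_pn: np.ndarray
    corrections: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.extension_um = np.asarray(self.extension_um, dtype=float)
        self.force_pn = np.asarray(self.force_pn, dtype=float)
        if self.extension_um.shape != self.force_pn.shape:
            raise ValueError("extension and force must have matching shapes")
        if not (
            np.all(np.isfinite(self.extension_um)) and np.all(np.isfinite(self.force_pn))
        ):
            raise ValueError("curve contains non-finite values")

    def __len__(self) -> int:
        return self.extension_um.size


@dataclass
class EnergyCurve:
    """Cumulative stretching energy (k_BT) versus extension (µm)."""

    extension_um: np.ndarray
    energy_kbt: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.extension_um = np.asarray(self.extension_um, dtype=float)
        self.energy_kbt = np.asarray(self.energy_kbt, dtype=float)


@dataclass
class TetherFitResult:
    """Worm-like-chain parameters of one tether with diagnostics."""

    persistence_length_nm: float
    contour_length_um: float
    energy_offset_kbt: float
    residual_rms_kbt: float
    classification: str
    corrections: dict = field(default_factory=dict)

    @property
    def is_single(self) -> bool:
        return self.classification == "single"

    def summary(self) -> str:
        return "\n".join(
            [
                "WLC energy-curve fit",
                "--------------------",
                f"L_p (nm)        : {self.persistence_length_nm:8.2f}",
                f"L_c (µm)        : {self.contour_length_um:8.3f}",
                f"E offset (k_BT) : {self.energy_offset_kbt:8.3f}",
                f"residual RMS    : {self.residual_rms_kbt:8.4f} k_BT",
                f"classification  : {self.classification}",
            ]
        )


def surface_reference_correct(
    trace_at_force: pd.DataFrame, trace_no_force: pd.DataFrame
) -> tuple[np.ndarray, float]:
    """Offset-correct measured heights against the zero-force minimum.

    The lowest height recorded with the magnets retracted corresponds to
    the bead resting on the surface; it is subtracted from the heights
    of the force-on trace.  Returns (corrected heights, reference).
    Warns when the zero-force trace never visits the surface (its
    minimum is not clearly separated from its bulk percentiles).
    """
    z_free = trace_no_force["z"].to_numpy()
    reference = float(np.min(z_free))
    spread = float(np.percentile(z_free, 50) - np.percentile(z_free, 1))
    if spread > 0 and (np.percentile(z_free, 1) - reference) > 2.0 * spread:
        warnings.warn(
            "zero-force trace minimum is far below its 1st percentile; the bead "
            "may never have reached the surface",
            stacklevel=2,
        )
    return trace_at_force["z"].to_numpy() - reference, reference


def apply_attachment_correction(lengths_um, a_um: float):
    """Add back the tether length hidden by the eccentric anchor: l + A."""
    if a_um < 0:
        raise ValueError("attachment offset must be non-negative")
    return np.asarray(lengths_um, dtype=float) + a_um


def calibrate_force_equipartition(
    transverse_um,
    l_ext_um: float,
    radius_um: float,
    temperature: float = DEFAULT_TEMPERATURE,
    n_blocks: int = 10,
) -> tuple[float, float]:
    """Tether tension (pN) from transverse fluctuations by equipartition.

    The bead on its tether is an inverted pendulum of lever
    l_ext + R_bead; equipartition of the transverse mode gives
    F = k_BT·(l_ext + R_bead)/var(x).  Returns (force, standard error)
    with the error from block-wise variance estimates.  Warns when the
    two trace halves disagree grossly (non-stationarity).
    """
    x = np.asarray(transverse_um, dtype=float)
    if x.size < 1000:
        raise ValueError("need at least 1000 frames for a variance estimate")
    x = x - x.mean()
    lever = l_ext_um + radius_um
    kbt = kbt_pn_um(temperature)
    var = float(np.var(x))
    force = kbt * lever / var
    half = x.size // 2
    v1, v2 = np.var(x[:half]), np.var(x[half:])
    if max(v1, v2) > 3.0 * min(v1, v2):
        warnings.warn(
            "transverse variance differs by >3x between trace halves; "
            "the segment may not be stationary",
            stacklevel=2,
        )
    blocks = np.array_split(x, n_blocks)
    block_forces = np.array([kbt * lever / np.var(b) for b in blocks])
    se = float(np.std(block_forces, ddof=1) / np.sqrt(n_blocks))
    return force, se


def fit_force_scale(
    z_mag_mm, force_pn, l_dec_mm: float = 1.54, z_ref_mm: float = 1.0
) -> float:
    """Bead-specific force scale F_0 from ≥3 calibration points.

    With the decay length fixed, ln F = ln F_0 − (Z − Z_ref)/l_dec is
    linear with known slope, so the log-space least-squares solution is
    the mean of ln F + (Z − Z_ref)/l_dec.
    """
    z = np.asarray(z_mag_mm, dtype=float)
    f = np.asarray(force_pn, dtype=float)
    if z.size < 3:
        raise ValueError("need force estimates at three or more magnet heights")
    if np.any(f <= 0):
        raise ValueError("force estimates must be positive")
    return float(np.exp(np.mean(np.log(f) + (z - z_ref_mm) / l_dec_mm)))


def reorder_monotone(curve: ForceExtensionCurve) -> ForceExtensionCurve:
    """Stable-sort the curve by ascending extension.

    Thermal scatter makes the raw dynamic record non-monotone; sorting
    before integration removes the resulting scatter from the energy
    curve while preserving the multiset of (extension, force) points.
    """
    order = np.argsort(curve.extension_um, kind="stable")
    return ForceExtensionCurve(
        curve.extension_um[order], curve.force_pn[order], dict(curve.corrections)
    )


def energy_from_force_extension(
    curve: ForceExtensionCurve, temperature: float = DEFAULT_TEMPERATURE
) -> EnergyCurve:
    """Cumulative trapezoidal integral of the force-extension record.

    E(l_k) = Σ ½(F_i + F_{i+1})(l_{i+1} − l_i) from the first point,
    reported in k_BT; non-decreasing whenever F ≥ 0.  The curve should
    be monotone in extension (see :func:`reorder_monotone`).
    """
    if len(curve) == 0:
        raise ValueError("empty curve")
    if len(curve) == 1:
        return EnergyCurve(curve.extension_um, np.zeros(1), temperature)
    e_pn_um = cumulative_trapezoid(curve.force_pn, curve.extension_um, initial=0.0)
    return EnergyCurve(curve.extension_um, e_pn_um / kbt_pn_um(temperature), temperature)


class EnergyWlcModel:
    """Nonlinear least-squares WLC model of a stretching-energy curve.

    E_model(l; L_p, L_c, E0) = E_WLC(l; L_p, L_c) + E0, with the offset
    absorbing the unknown lower integration bound of the measured
    energy.  Bounds: L_p ∈ [5, 150] nm, L_c within [l_max·(1+ε), 1.5·l_max].
    """

    LP_BOUNDS_NM = (5.0, 150.0)

    def __init__(self, energy: EnergyCurve):
        if len(energy.extension_um) < 20:
            raise ValueError("need at least 20 points for an energy-curve fit")
        self.energy = energy

    def fit(
        self,
        lp_init_nm: float = 50.0,
        lc_init_factor: float = 1.05,
        fit_offset: bool = True,
        corrections: dict | None = None,
    ) -> TetherFitResult:
        """Fit (L_p, L_c[, E0]) to the energy curve.

        ``fit_offset=False`` pins the model energy to zero at the first
        measured point — the convention of integrating the measured
        force-extension record from its lowest extension.
        """
        l = self.energy.extension_um
        e = self.energy.energy_kbt
        t = self.energy.temperature
        l_max = float(np.max(l))
        lc_lo = l_max * (1.0 + 1e-4)
        lc_hi = l_max * 1.5
        lc0 = np.clip(lc_init_factor * l_max, lc_lo, lc_hi)

        def model(theta):
            lp, lc = theta[0], theta[1]
            params = WlcParams(lc, lp, t)
            e_model = wlc_energy(l, params, units="kbt")
            if fit_offset:
                return e_model + theta[2]
            return e_model - e_model[0]

        def resid(theta):
            return model(theta) - e

        if fit_offset:
            x0 = [lp_init_nm, lc0, 0.0]
            lo = [self.LP_BOUNDS_NM[0], lc_lo, -np.inf]
            hi = [self.LP_BOUNDS_NM[1], lc_hi, np.inf]
        else:
            x0 = [lp_init_nm, lc0]
            lo = [self.LP_BOUNDS_NM[0], lc_lo]
            hi = [self.LP_BOUNDS_NM[1], lc_hi]
        sol = least_squares(resid, x0=x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
        if not sol.success:
            raise RuntimeError(f"energy-curve fit failed to converge: {sol.message}")
        lp, lc = sol.x[0], sol.x[1]
        e0 = sol.x[2] if fit_offset else 0.0
        rms = float(np.sqrt(np.mean(sol.fun**2)))
        classification = "single" if lp >= MULTIPLE_TETHER_LP_NM else "multiple"
        return TetherFitResult(
            persistence_length_nm=float(lp),
            contour_length_um=float(lc),
            energy_offset_kbt=float(e0),
            residual_rms_kbt=rms,
            classification=classification,
            corrections=corrections or {},
        )


def fit_energy_wlc(energy: EnergyCurve, **kwargs) -> TetherFitResult:
    """Functional wrapper around :class:`EnergyWlcModel`."""
    return EnergyWlcModel(energy).fit(**kwargs)


@dataclass
class EnsembleReport:
    """Summary statistics of a characterized tether ensemble."""

    n_total: int
    n_single: int
    all_filtered: bool
    group_stats: pd.DataFrame
    sigma_f0: float | None
    f0_normalized: np.ndarray
    offsets_um: np.ndarray | None
    offset_ks_pvalue: float | None

    def summary(self) -> str:
        lines = [
            "Ensemble analysis",
            "-----------------",
            f"tethers: {self.n_total} total, {self.n_single} single "
            f"(L_p ≥ {MULTIPLE_TETHER_LP_NM:g} nm)",
        ]
        if self.all_filtered:
            lines.append("all tethers classified as multiply tethered — no statistics")
            return "\n".join(lines)
        if self.sigma_f0 is not None:
            lines.append(f"sigma_F0 (SD of F_0/<F_0>): {self.sigma_f0:.3f}")
        if self.offset_ks_pvalue is not None:
            lines.append(
                f"attachment offsets vs geometric law: KS p = {self.offset_ks_pvalue:.3f}"
            )
        lines.append(self.group_stats.to_string())
        return "\n".join(lines)


def ensemble_analysis(
    results: list[TetherFitResult],
    f0_pn=None,
    offsets_um=None,
    r_bead_um: float = 0.525,
    groups=None,
    group_decimals: int = 1,
) -> EnsembleReport:
    """Ensemble statistics over ≥5 characterized tethers.

    Removes multiply-tethered outliers (L_p < 28 nm), reports mean ± SD
    of L_p and L_c per contour-length group, the SD of the normalized
    force scale F_0/<F_0>, and a KS test of the measured attachment
    offsets against the geometric offset law.  ``groups`` optionally
    labels each tether with its DNA construct (length group); without
    it, groups are formed by rounding the fitted contour length.
    """
    if len(results) < 5:
        raise ValueError("ensemble analysis needs at least 5 tethers")
    if groups is not None and len(groups) != len(results):
        raise ValueError("groups must label every tether")
    keep = [r.is_single for r in results]
    singles = [r for r in results if r.is_single]
    if not singles:
        return EnsembleReport(
            n_total=len(results),
            n_single=0,
            all_filtered=True,
            group_stats=pd.DataFrame(),
            sigma_f0=None,
            f0_normalized=np.array([]),
            offsets_um=None,
            offset_ks_pvalue=None,
        )
    df = pd.DataFrame(
        {
            "lp_nm": [r.persistence_length_nm for r in singles],
            "lc_um": [r.contour_length_um for r in singles],
        }
    )
    if groups is not None:
        df["group_um"] = [g for g, k in zip(groups, keep) if k]
    else:
        df["group_um"] = df["lc_um"].round(group_decimals)
    stats = (
        df.groupby("group_um")
        .agg(
            n=("lp_nm", "size"),
            lp_mean_nm=("lp_nm", "mean"),
            lp_sd_nm=("lp_nm", "std"),
            lc_mean_um=("lc_um", "mean"),
            lc_sd_um=("lc_um", "std"),
        )
        .reset_index()
    )
    sigma_f0 = None
    f0_norm = np.array([])
    if f0_pn is not None:
        f0 = np.asarray(f0_pn, dtype=float)
        f0_norm = f0 / f0.mean()
        sigma_f0 = float(np.std(f0_norm, ddof=1))
    ks_p = None
    offs = None
    if offsets_um is not None:
        offs = np.asarray(offsets_um, dtype=float)
        ks = kstest(offs, lambda a: attachment_offset_cdf(a, r_bead_um))
        ks_p = float(ks.pvalue)
    return EnsembleReport(
        n_total=len(results),
        n_single=len(singles),
        all_filtered=False,
        group_stats=stats,
        sigma_f0=sigma_f0,
        f0_normalized=f0_norm,
        offsets_um=offs,
        offset_ks_pvalue=ks_p,
    )
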