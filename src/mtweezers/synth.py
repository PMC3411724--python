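"""Synthetic multiplexed-experiment generator and protocol orchestrator.

Emulates one multiplexed magnetic-tweezers run: N tethers scattered over
a 300x400 µm field of view with a minimum bead-to-bead separation,
bead-specific force scales drawn log-normally around their mean with
relative spread sigma_F0, attachment offsets drawn from the geometric
sphere law, and — per tether — the four measurement segments of the
characterization protocol:

1. a 25 s hold at maximum force (length measurement),
2. a 130 s zero-force hold (surface reference),
3. a magnet-rotation measurement (Limaçon pattern),
4. a 0.1 mm/s magnet ramp (dynamic force-extension).

``run_full_protocol`` then pushes every tether through the analysis
pipeline and returns per-bead results plus the ensemble report.  All
randomness derives from a single master seed; per-bead sub-seeds are
spawned from (seed, bead id) so ensemble size does not perturb
individual trajectories.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE
from .dynamics import SimProtocol, TetherModel, Trace, simulate_trace
from .magnetostatics import BeadModel, MagnetAssembly
from .pipeline import (
    EnsembleReport,
    ForceExtensionCurve,
    TetherFitResult,
    apply_attachment_correction,
    calibrate_force_equipartition,
    energy_from_force_extension,
    ensemble_analysis,
    fit_energy_wlc,
    fit_force_scale,
    reorder_monotone,
    surface_reference_correct,
)
from .rotation import (
    LimaconParams,
    attachment_offset_from_radius,
    attachment_radius_from_offset,
    fit_limacon,
    limacon_curve,
    predict_precession_radius,
    sample_attachment_offsets,
)
from .wlc import WlcParams

__all__ = [
    "EnsembleConfig",
    "SyntheticTether",
    "generate_positions",
    "generate_ensemble",
    "run_full_protocol",
]

logger = logging.getLogger("mtweezers")

#: dsDNA rise per base pair (µm/bp), for labeling length groups
UM_PER_BP = 0.34e-3


@dataclass(frozen=True)
class EnsembleConfig:
    """Study conditions of a synthetic multiplexed experiment.

    Defaults mirror a standard multiplexed run: a 300x400 µm field of
    view holding up to 60 tethers at ≥15 µm separation, 50 Hz camera
    with 12 nm (z) / 2.2 nm (xy) tracking noise, bead force scales with
    11% relative spread, and the four DNA length groups 2.2/7.3/11.9/
    20.1 kb (contour lengths 0.75/2.48/4.05/6.83 µm at 0.34 nm/bp).
    The force ramp covers Z_mag 1-8 mm — the range over which the
    single-exponential force law used to label the data is valid.
    """

    n_tethers: int = 60
    contour_lengths_um: tuple[float, ...] = (0.75, 2.48, 4.05, 6.83)
    persistence_length_nm: float = 50.0
    f0_mean_pn: float = 6.0
    f0_rel_sd: float = 0.11
    l_dec_mm: float = 1.54
    fov_um: tuple[float, float] = (300.0, 400.0)
    min_separation_um: float = 15.0
    frame_rate_hz: float = 50.0
    sigma_z_um: float = 0.012
    sigma_xy_um: float = 0.0022
    thermal_noise: bool = True
    seed: int = 0
    bead: BeadModel = field(default_factory=BeadModel)
    temperature: float = DEFAULT_TEMPERATURE
    hold_duration_s: float = 25.0
    free_duration_s: float = 130.0
    free_z_mag_mm: float = 20.0
    rotation_turns: float = 4.0
    rotation_hz: float = 0.5
    ramp_z_range_mm: tuple[float, float] = (1.0, 8.0)
    ramp_speed_mm_s: float = 0.1
    calibration_heights_mm: tuple[float, ...] = (1.0, 1.5, 2.0)
    calibration_duration_s: float = 25.0
    max_fit_force_pn: float = 2.0

    def __post_init__(self) -> None:
        if self.n_tethers < 1:
            raise ValueError("need at least one tether")


@dataclass
class SyntheticTether:
    """Ground truth plus the simulated traces of one tether."""

    bead_id: int
    tether: TetherModel
    z_offset_um: float
    traces: dict[str, Trace | pd.DataFrame]
    seed: int


def _bead_seed(master_seed: int, bead_id: int, stream: int = 0) -> int:
    # bead_id -1 is the ensemble-level stream
    ss = np.random.SeedSequence((master_seed, bead_id + 1, stream))
    return int(ss.generate_state(1)[0]) % (2**31 - 1)


def generate_positions(config: EnsembleConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform tether positions respecting the minimum separation.

    Rejection sampling over the field of view (centred coordinates);
    raises after 10^4 consecutive failures (field too crowded).
    """
    w, h = config.fov_um
    placed: list[np.ndarray] = []
    failures = 0
    while len(placed) < config.n_tethers:
        cand = rng.uniform([-w / 2, -h / 2], [w / 2, h / 2])
        if all(np.linalg.norm(cand - p) >= config.min_separation_um for p in placed):
            placed.append(cand)
            failures = 0
        else:
            failures += 1
            if failures > 10_000:
                raise RuntimeError(
                    "could not place tethers at the requested separation; "
                    "field of view too crowded"
                )
    return np.array(placed)


def _measured(trace: Trace, a_um: float, z_offset_um: float) -> pd.DataFrame:
    """Apply the measurement transform: bead-bottom height above surface.

    The anchor sits ``a_um`` above the bead bottom, so the instrument
    records l_ext − A, plus a bead-specific height offset.
    """
    data = trace.data.copy()
    data["z"] = data["z"] - a_um + z_offset_um
    return data


def generate_ensemble(
    config: EnsembleConfig, assembly: MagnetAssembly | None = None
) -> tuple[list[SyntheticTether], pd.DataFrame]:
    """Generate tethers, their ground truth and all protocol traces.

    Returns (tethers, ground-truth table).  Deterministic under the
    config seed; per-bead trajectories are driven by sub-seeds spawned
    from (seed, bead id).
    """
    assembly = assembly or MagnetAssembly()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xC0FFEE)))
    positions = generate_positions(config, rng)
    n = config.n_tethers
    lengths = np.array(
        [config.contour_lengths_um[i % len(config.contour_lengths_um)] for i in range(n)]
    )
    # log-normal force scales with the configured relative spread
    sd_log = np.sqrt(np.log1p(config.f0_rel_sd**2))
    f0 = config.f0_mean_pn * np.exp(
        rng.normal(-0.5 * sd_log**2, sd_log, n)
    )
    offsets = sample_attachment_offsets(
        n, config.bead.radius_um, seed=_bead_seed(config.seed, -1)
    )
    z_offsets = rng.uniform(0.1, 0.6, n)

    tethers: list[SyntheticTether] = []
    rows = []
    ramp_duration = (
        config.ramp_z_range_mm[1] - config.ramp_z_range_mm[0]
    ) / config.ramp_speed_mm_s
    for i in range(n):
        wlc = WlcParams(lengths[i], config.persistence_length_nm, config.temperature)
        tether = TetherModel(
            wlc=wlc,
            bead=config.bead,
            attachment_offset_um=float(offsets[i]),
            f0_pn=float(f0[i]),
            pos_um=(float(positions[i, 0]), float(positions[i, 1])),
        )
        base = dict(
            force_model="exponential",
            l_dec_mm=config.l_dec_mm,
            thermal_noise=config.thermal_noise,
            tracking_noise=config.thermal_noise,
            viscosity_pa_s=0.955e-3,
            temperature=config.temperature,
            frame_rate_hz=config.frame_rate_hz,
            sigma_z_um=config.sigma_z_um,
            sigma_xy_um=config.sigma_xy_um,
            z_wall_um=float(offsets[i]),
        )
        t0 = time.perf_counter()
        hold = simulate_trace(
            tether,
            SimProtocol(
                duration_s=config.hold_duration_s,
                z_start_mm=config.ramp_z_range_mm[0],
                v_mag_mm_s=0.0,
                seed=_bead_seed(config.seed, i, 1),
                **base,
            ),
            bead_id=i,
        )
        free = simulate_trace(
            tether,
            SimProtocol(
                duration_s=config.free_duration_s,
                z_start_mm=config.free_z_mag_mm,
                v_mag_mm_s=0.0,
                seed=_bead_seed(config.seed, i, 2),
                **base,
            ),
            bead_id=i,
        )
        ramp = simulate_trace(
            tether,
            SimProtocol(
                duration_s=ramp_duration,
                z_start_mm=config.ramp_z_range_mm[0],
                v_mag_mm_s=config.ramp_speed_mm_s,
                seed=_bead_seed(config.seed, i, 3),
                **base,
            ),
            bead_id=i,
        )
        calib = {}
        if config.thermal_noise:
            for j, z_cal in enumerate(config.calibration_heights_mm):
                calib[f"calibration_{z_cal:g}mm"] = simulate_trace(
                    tether,
                    SimProtocol(
                        duration_s=config.calibration_duration_s,
                        z_start_mm=z_cal,
                        v_mag_mm_s=0.0,
                        transverse=True,
                        seed=_bead_seed(config.seed, i, 10 + j),
                        **base,
                    ),
                    bead_id=i,
                )
        rotation = _rotation_trace(tether, config, assembly, i)
        traces: dict[str, Trace | pd.DataFrame] = {
            "hold": _measured(hold, offsets[i], z_offsets[i]),
            "free": _measured(free, offsets[i], z_offsets[i]),
            "ramp": _measured(ramp, offsets[i], z_offsets[i]),
            "rotation": rotation,
        }
        for name, tr in calib.items():
            traces[name] = _measured(tr, offsets[i], z_offsets[i])
        tethers.append(
            SyntheticTether(i, tether, float(z_offsets[i]), traces, _bead_seed(config.seed, i))
        )
        rows.append(
            {
                "bead_id": i,
                "contour_length_um": lengths[i],
                "persistence_length_nm": config.persistence_length_nm,
                "f0_pn": f0[i],
                "attachment_offset_um": offsets[i],
                "pos_x_um": positions[i, 0],
                "pos_y_um": positions[i, 1],
                "z_offset_um": z_offsets[i],
            }
        )
        logger.info(
            "generated bead %d (L_c=%.2f µm) in %.2f s", i, lengths[i], time.perf_counter() - t0
        )
    return tethers, pd.DataFrame(rows)


def _rotation_trace(
    tether: TetherModel, config: EnsembleConfig, assembly: MagnetAssembly, bead_id: int
) -> pd.DataFrame:
    """Limaçon rotation measurement at Z_mag = 1 mm with tracking noise."""
    omega = 2.0 * np.pi * config.rotation_hz
    n_frames = int(config.rotation_turns / config.rotation_hz * config.frame_rate_hz)
    t = np.arange(n_frames) / config.frame_rate_hz
    rng = np.random.default_rng(_bead_seed(config.seed, bead_id, 20))
    d_center = float(np.hypot(*tether.pos_um))
    r_prec = predict_precession_radius(d_center, 1.0, assembly, tether.bead, tether.wlc)
    r_att = attachment_radius_from_offset(tether.attachment_offset_um, tether.bead.radius_um)
    params = LimaconParams(
        r_att_um=r_att,
        r_prec_um=r_prec,
        phi_att=rng.uniform(0, 2 * np.pi),
        phi_prec=rng.uniform(0, 2 * np.pi),
        center_um=tether.pos_um,
        omega_mag=omega,
    )
    curve = limacon_curve(params, t)
    if config.thermal_noise:
        curve["x"] += rng.normal(0.0, config.sigma_xy_um, n_frames)
        curve["y"] += rng.normal(0.0, config.sigma_xy_um, n_frames)
    return curve


def characterize_tether(
    synth: SyntheticTether, config: EnsembleConfig
) -> tuple[TetherFitResult, dict]:
    """Run the full analysis pipeline on one synthetic tether.

    Returns the WLC fit plus intermediate quantities (A, F_0, R_att).
    With thermal noise disabled the equipartition calibration is
    undefined (zero variance) and the ground-truth force scale is used.
    """
    omega = 2.0 * np.pi * config.rotation_hz
    rot = fit_limacon(synth.traces["rotation"], omega)
    r_att = min(rot.params.r_att_um, config.bead.radius_um)
    a_um = attachment_offset_from_radius(r_att, config.bead.radius_um)

    ramp = synth.traces["ramp"]
    heights, reference = surface_reference_correct(ramp, synth.traces["free"])
    lengths = apply_attachment_correction(heights, a_um)

    if config.thermal_noise:
        f_est = []
        for z_cal in config.calibration_heights_mm:
            tr = synth.traces[f"calibration_{z_cal:g}mm"]
            l_est = float(np.median(tr["z"])) - reference + a_um
            f, _se = calibrate_force_equipartition(
                tr["x"].to_numpy(), max(l_est, 0.05), config.bead.radius_um, config.temperature
            )
            f_est.append(f)
        f0 = fit_force_scale(
            config.calibration_heights_mm, f_est, l_dec_mm=config.l_dec_mm
        )
    else:
        f0 = synth.tether.f0_pn

    t = ramp["t"].to_numpy()
    z_mag = config.ramp_z_range_mm[0] + config.ramp_speed_mm_s * t
    force = f0 * np.exp(-(z_mag - 1.0) / config.l_dec_mm)
    keep = (force <= config.max_fit_force_pn) & (lengths > 0)
    curve = ForceExtensionCurve(
        lengths[keep],
        force[keep],
        corrections={
            "f0_pn": f0,
            "l_dec_mm": config.l_dec_mm,
            "attachment_offset_um": a_um,
            "surface_reference_um": reference,
        },
    )
    energy = energy_from_force_extension(reorder_monotone(curve), config.temperature)
    fit = fit_energy_wlc(energy, corrections=curve.corrections)
    extras = {
        "f0_pn": f0,
        "attachment_offset_um": a_um,
        "r_att_um": rot.params.r_att_um,
        "r_prec_um": rot.params.r_prec_um,
        "surface_reference_um": reference,
    }
    return fit, extras


def run_full_protocol(
    config: EnsembleConfig, assembly: MagnetAssembly | None = None
) -> tuple[pd.DataFrame, EnsembleReport, pd.DataFrame]:
    """Simulate and characterize a full multiplexed experiment.

    Returns (per-bead results table, ensemble report, ground truth).
    Per-bead failures are isolated: a failing tether is flagged in the
    results table and excluded from the ensemble statistics.
    """
    tethers, truth = generate_ensemble(config, assembly)
    rows = []
    fits: list[TetherFitResult] = []
    groups: list[float] = []
    f0s: list[float] = []
    offsets: list[float] = []
    for synth in tethers:
        t0 = time.perf_counter()
        try:
            fit, extras = characterize_tether(synth, config)
        except Exception as exc:  # noqa: BLE001 - per-bead isolation is the contract
            logger.warning("bead %d failed: %s", synth.bead_id, exc)
            rows.append({"bead_id": synth.bead_id, "ok": False, "error": str(exc)})
            continue
        rows.append(
            {
                "bead_id": synth.bead_id,
                "ok": True,
                "lp_nm": fit.persistence_length_nm,
                "lc_um": fit.contour_length_um,
                "classification": fit.classification,
                **extras,
            }
        )
        fits.append(fit)
        groups.append(float(synth.tether.wlc.contour_length_um))
        f0s.append(extras["f0_pn"])
        offsets.append(extras["attachment_offset_um"])
        logger.info(
            "characterized bead %d in %.2f s", synth.bead_id, time.perf_counter() - t0
        )
    report = ensemble_analysis(
        fits,
        f0_pn=f0s,
        offsets_um=offsets,
        r_bead_um=config.bead.radius_um,
        groups=groups,
    )
    return pd.DataFrame(rows), report, truth
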