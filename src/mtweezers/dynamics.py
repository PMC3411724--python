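"""Overdamped Langevin dynamics of a DNA-bead tether.

The bead's vertical coordinate z (the tether end-to-end extension) obeys
the overdamped equation of motion

    gamma_perp(h) dz/dt = F_mag,z(t) - F_WLC(z) + sqrt(2 k_BT gamma_perp) xi(t),

integrated by the Euler–Maruyama scheme.  The drag coefficient carries
Faxén's wall correction for motion perpendicular to a plane wall at
bead-centre height h = z + R_bead.  The magnetic force follows either a
single-exponential law F_0·exp(-(Z_mag-1 mm)/l_dec) under a magnet ramp
Z_mag(t), or the full charge-sheet field model.  A camera model
(boxcar averaging over the exposure window of each frame plus additive
Gaussian tracking noise) converts the physical trajectory into what the
instrument records; the default is an effectively instantaneous shutter.

Lateral bead motion, when requested, is modelled as an independent
pendulum mode of stiffness F/(l_ext + R_bead) — the geometry that
underlies equipartition force calibration.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, M_PER_UM, kbt_joule, kbt_pn_um
from .magnetostatics import BeadModel, MagnetAssembly, bead_force
from .wlc import WlcParams, wlc_extension_at_force, wlc_force, wlc_stiffness

__all__ = [
    "TetherModel",
    "SimProtocol",
    "Trace",
    "drag_coefficient_perpendicular",
    "drag_coefficient_parallel",
    "stable_timestep",
    "simulate_trace",
    "drag_force_profile",
    "apparent_response_with_offset",
]

#: default water viscosity at 22 °C, Pa·s
DEFAULT_VISCOSITY = 0.955e-3


class SimulationUnstableError(RuntimeError):
    """Raised when an integration step moves the bead by > 5% of L_c."""


def drag_coefficient_perpendicular(
    center_height_um, radius_um: float, viscosity_pa_s: float = DEFAULT_VISCOSITY
):
    """Wall-corrected drag (N·s/m) for motion perpendicular to the wall.

    Faxén's truncated series: gamma = 6 pi eta R / (1 - (9/8)(R/h) +
    (1/2)(R/h)^3), h the bead-centre height.  Reduces to Stokes drag far
    from the wall and exactly doubles it at h = 2R.
    """
    h = np.asarray(center_height_um, dtype=float)
    if np.any(h <= radius_um):
        raise ValueError("bead centre height must exceed the bead radius")
    ratio = radius_um / h
    denom = 1.0 - 9.0 / 8.0 * ratio + 0.5 * ratio**3
    stokes = 6.0 * np.pi * viscosity_pa_s * radius_um * M_PER_UM
    out = stokes / denom
    return float(out) if np.isscalar(center_height_um) else out


def drag_coefficient_parallel(
    center_height_um, radius_um: float, viscosity_pa_s: float = DEFAULT_VISCOSITY
):
    """Wall-corrected drag (N·s/m) for motion parallel to the wall
    (leading-order Faxén term 1/(1 - (9/16)(R/h)))."""
    h = np.asarray(center_height_um, dtype=float)
    if np.any(h <= radius_um):
        raise ValueError("bead centre height must exceed the bead radius")
    stokes = 6.0 * np.pi * viscosity_pa_s * radius_um * M_PER_UM
    out = stokes / (1.0 - 9.0 / 16.0 * (radius_um / h))
    return float(out) if np.isscalar(center_height_um) else out


@dataclass(frozen=True)
class TetherModel:
    """One DNA-bead tether.

    ``attachment_offset_um`` (A) is the height of the DNA anchor above
    the bead's lowest point; ``f0_pn`` the bead-specific force scale at
    Z_mag = 1 mm; ``pos_um`` the tether position in the field of view.
    """

    wlc: WlcParams
    bead: BeadModel = field(default_factory=BeadModel)
    attachment_offset_um: float = 0.0
    f0_pn: float = 6.0
    pos_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.attachment_offset_um <= self.bead.radius_um:
            raise ValueError("attachment offset must lie in [0, bead radius]")
        if self.f0_pn <= 0:
            raise ValueError("force scale F_0 must be positive")


@dataclass(frozen=True)
class SimProtocol:
    """Simulation protocol: magnet trajectory, force model, noise, camera.

    ``v_mag_mm_s = 0`` holds the magnet fixed at ``z_start_mm``;
    otherwise Z_mag(t) = z_start + v_mag·t (default ramp speed
    0.1 mm/s).  ``dt_s = None`` selects a stability-checked time step
    automatically.  ``force_model`` is "exponential" (per-bead F_0 and
    decay length) or "field" (full charge-sheet model, requires
    ``assembly``).  Tracking noise defaults: sigma_z = 12 nm,
    sigma_xy = 2.2 nm at a 50 Hz frame rate.
    """

    duration_s: float = 80.0
    dt_s: float | None = None
    z_start_mm: float = 1.0
    v_mag_mm_s: float = 0.1
    force_model: Literal["exponential", "field"] = "exponential"
    f0_pn: float | None = None
    l_dec_mm: float = 1.55
    assembly: MagnetAssembly | None = None
    thermal_noise: bool = True
    tracking_noise: bool = True
    seed: int = 0
    viscosity_pa_s: float = DEFAULT_VISCOSITY
    temperature: float = DEFAULT_TEMPERATURE
    frame_rate_hz: float = 50.0
    sigma_z_um: float = 0.012
    sigma_xy_um: float = 0.0022
    exposure_s: float | None = None
    z_wall_um: float = 0.0
    transverse: bool = False

    def z_mag_at(self, t_s) -> np.ndarray:
        return self.z_start_mm + self.v_mag_mm_s * np.asarray(t_s, dtype=float)


@dataclass
class Trace:
    """Time series of bead position — the universal exchange object.

    ``data`` columns: t (s), x, y, z (µm), bead_id.  Metadata records the
    frame rate, seed and a hash of the generating protocol.
    """

    data: pd.DataFrame
    frame_rate_hz: float
    seed: int | None = None
    protocol_hash: str | None = None

    def __post_init__(self) -> None:
        t = self.data["t"].to_numpy()
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("trace times must be strictly increasing")
        if not np.all(np.isfinite(self.data[["t", "x", "y", "z"]].to_numpy())):
            raise ValueError("trace contains non-finite values")

    def __len__(self) -> int:
        return len(self.data)


def _protocol_hash(tether: TetherModel, protocol: SimProtocol) -> str:
    payload = repr((tether, protocol)).encode()
    return hashlib.sha1(payload).hexdigest()[:12]


def _sub_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# integration kernels (numba-accelerated when available)
# ---------------------------------------------------------------------------


def _wlc_force_kernel(z, lc, fscale):
    """Seven-term WLC force (pN); z, lc in µm.  numba-compatible scalar."""
    x = z / lc
    if x < 0.0:
        x = 0.0
    f = 0.25 / ((1.0 - x) * (1.0 - x)) - 0.25 + x
    f += (
        -0.5164228 * x**2
        - 2.737418 * x**3
        + 16.07497 * x**4
        - 38.87607 * x**5
        + 39.49944 * x**6
        - 14.17718 * x**7
    )
    return fscale * f


def _euler_z_kernel(
    z0_um,
    n_steps,
    dt,
    f_mag_grid,
    grid_dt,
    lc_um,
    fscale_pn,
    radius_um,
    eta,
    kbt_j,
    z_wall_um,
    noise_on,
    n_per_frame,
    n_exp,
    xi,
):
    """Euler–Maruyama integration of the vertical tether coordinate.

    Positions in µm, forces in pN internally; returns frame-averaged z
    (µm), a status flag (0 ok, 1 instability) and the largest single
    step (µm).  ``xi`` is the pre-drawn standard-normal noise sequence
    (zeros when noise is off).
    """
    n_frames = n_steps // n_per_frame
    z_frames = np.zeros(n_frames)
    z = z0_um
    stokes = 6.0 * np.pi * eta * radius_um * 1e-6
    status = 0
    max_step = 0.0
    acc = 0.0
    count = 0
    frame = 0
    x_cap = 0.9995 * lc_um
    for i in range(n_steps):
        # magnetic force: linear interpolation on the precomputed grid
        tpos = i * dt / grid_dt
        idx = int(tpos)
        if idx >= f_mag_grid.shape[0] - 1:
            idx = f_mag_grid.shape[0] - 2
        w = tpos - idx
        f_mag = f_mag_grid[idx] * (1.0 - w) + f_mag_grid[idx + 1] * w
        h = z + radius_um
        ratio = radius_um / h
        gamma = stokes / (1.0 - 1.125 * ratio + 0.5 * ratio**3)
        f_net_n = (f_mag - _wlc_force_kernel(z, lc_um, fscale_pn)) * 1e-12
        dz = dt * f_net_n / gamma * 1e6  # µm
        # instability = runaway deterministic drift; thermal kicks are physical
        if abs(dz) > 0.05 * lc_um:
            status = 1
            break
        if abs(dz) > max_step:
            max_step = abs(dz)
        if noise_on == 1:
            dz += np.sqrt(2.0 * kbt_j * dt / gamma) * 1e6 * xi[i]
        z = z + dz
        if z < z_wall_um:
            z = 2.0 * z_wall_um - z
        if z > x_cap:
            z = 2.0 * x_cap - z
        if count < n_exp:
            acc += z
        count += 1
        if count == n_per_frame:
            z_frames[frame] = acc / n_exp
            frame += 1
            acc = 0.0
            count = 0
    return z_frames, status, max_step


def _euler_ou_kernel(n_steps, dt, k_grid, gamma_grid, grid_dt, kbt_j, n_per_frame, n_exp, xi):
    """Euler–Maruyama for the transverse pendulum mode (µm output)."""
    n_frames = n_steps // n_per_frame
    out = np.zeros(n_frames)
    x = 0.0
    acc = 0.0
    count = 0
    frame = 0
    for i in range(n_steps):
        tpos = i * dt / grid_dt
        idx = int(tpos)
        if idx >= k_grid.shape[0] - 1:
            idx = k_grid.shape[0] - 2
        w = tpos - idx
        k = k_grid[idx] * (1.0 - w) + k_grid[idx + 1] * w
        gamma = gamma_grid[idx] * (1.0 - w) + gamma_grid[idx + 1] * w
        x += -dt * k / gamma * x + np.sqrt(2.0 * kbt_j * dt / gamma) * 1e6 * xi[i]
        if count < n_exp:
            acc += x
        count += 1
        if count == n_per_frame:
            out[frame] = acc / n_exp
            frame += 1
            acc = 0.0
            count = 0
    return out


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _wlc_force_kernel = njit(cache=True, fastmath=True)(_wlc_force_kernel)
    _euler_z_kernel = njit(cache=True, fastmath=True)(_euler_z_kernel)
    _euler_ou_kernel = njit(cache=True, fastmath=True)(_euler_ou_kernel)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False


# ---------------------------------------------------------------------------
# protocol plumbing
# ---------------------------------------------------------------------------


def _force_grid(tether: TetherModel, protocol: SimProtocol, n_grid: int | None = None):
    """Precompute the applied vertical magnetic force (pN) on a time grid."""
    if n_grid is None:
        # constant magnet height -> constant force; two nodes suffice
        n_grid = 2 if protocol.v_mag_mm_s == 0.0 else 4097
    t = np.linspace(0.0, protocol.duration_s, n_grid)
    z_mag = protocol.z_mag_at(t)
    if protocol.force_model == "exponential":
        f0 = protocol.f0_pn if protocol.f0_pn is not None else tether.f0_pn
        f = f0 * np.exp(-(z_mag - 1.0) / protocol.l_dec_mm)
    elif protocol.force_model == "field":
        if protocol.assembly is None:
            raise ValueError("field force model requires protocol.assembly")
        f = np.array(
            [
                bead_force(list(tether.pos_um), protocol.assembly, tether.bead, zm)[2]
                for zm in z_mag
            ]
        )
    else:
        raise ValueError(f"unknown force model {protocol.force_model!r}")
    return t, f


def stable_timestep(
    tether: TetherModel,
    f_max_pn: float,
    viscosity_pa_s: float = DEFAULT_VISCOSITY,
    temperature: float = DEFAULT_TEMPERATURE,
    safety: float = 0.05,
    barrier_kbt: float = 12.0,
) -> float:
    """Stability-limited Euler time step (s).

    dt = safety · gamma/k_max.  k_max is the WLC stiffness at the
    largest extension the bead plausibly visits: in the tilted potential
    U(l) = E_WLC(l) − F_max·l, the point above the minimum where
    U − U_min = ``barrier_kbt`` k_BT (thermal excursions beyond are
    exponentially rare).  With ``barrier_kbt = 0`` (noise-free runs)
    this is simply the equilibrium extension at the peak force.  Stokes
    drag (a lower bound on the wall-corrected drag) keeps the estimate
    conservative.
    """
    from scipy.optimize import brentq

    from .wlc import wlc_energy

    params = tether.wlc
    lc = params.contour_length_um
    kbt = kbt_pn_um(temperature)
    f_max = max(f_max_pn, 1e-6)
    l_eq = wlc_extension_at_force(f_max, params)

    if barrier_kbt > 0:

        def excess_u(l):  # tilted potential above its minimum, in k_BT
            du = wlc_energy(l, params, units="pn_um") - wlc_energy(l_eq, params, units="pn_um")
            return (du - f_max * (l - l_eq)) / kbt - barrier_kbt

        hi = 0.9995 * lc
        l_stab = hi if excess_u(hi) < 0 else brentq(excess_u, l_eq, hi)
    else:
        l_stab = l_eq
    k_max = wlc_stiffness(min(l_stab, 0.995 * lc), params) * 1e-6  # N/m
    gamma = 6.0 * np.pi * viscosity_pa_s * tether.bead.radius_um * M_PER_UM
    return float(safety * gamma / k_max)


def simulate_trace(tether: TetherModel, protocol: SimProtocol, bead_id: int = 0) -> Trace:
    """Simulate the camera-recorded trajectory of one tether.

    Returns a :class:`Trace` of frame-averaged positions at the protocol
    frame rate; z is the tether extension (µm) in the simulation frame —
    measurement transforms (attachment offset, surface reference) are
    applied downstream.  Identical seeds give identical traces.
    """
    t_grid, f_grid = _force_grid(tether, protocol)
    f_max = float(np.max(np.abs(f_grid)))
    dt_stable = stable_timestep(
        tether,
        f_max,
        protocol.viscosity_pa_s,
        protocol.temperature,
        barrier_kbt=12.0 if protocol.thermal_noise else 0.0,
    )
    dt = protocol.dt_s if protocol.dt_s is not None else dt_stable
    if dt > 2.0 * dt_stable:
        raise ValueError(
            f"dt = {dt:g} s exceeds the stability limit {dt_stable:g} s "
            "(0.05 x drag/stiffness at maximum plausible stiffness)"
        )
    n_per_frame = max(1, int(round(1.0 / (protocol.frame_rate_hz * dt))))
    dt = 1.0 / (protocol.frame_rate_hz * n_per_frame)  # integer steps per frame
    n_steps = int(round(protocol.duration_s * protocol.frame_rate_hz)) * n_per_frame
    if protocol.exposure_s is None:
        n_exp = 1  # effectively instantaneous sampling at the frame instants
    else:
        n_exp = int(np.clip(round(protocol.exposure_s / dt), 1, n_per_frame))
    grid_dt = t_grid[1] - t_grid[0]

    z0 = wlc_extension_at_force(abs(float(f_grid[0])), tether.wlc)
    z0 = max(z0, protocol.z_wall_um)
    kbt_j = kbt_joule(protocol.temperature)
    seeds = _sub_seeds(protocol.seed, 4)

    rng_z = np.random.default_rng(seeds[0])
    xi = (
        rng_z.standard_normal(n_steps)
        if protocol.thermal_noise
        else np.zeros(n_steps)
    )
    z_frames, status, _max_step = _euler_z_kernel(
        z0,
        n_steps,
        dt,
        f_grid,
        grid_dt,
        tether.wlc.contour_length_um,
        tether.wlc.force_scale_pn,
        tether.bead.radius_um,
        protocol.viscosity_pa_s,
        kbt_j,
        protocol.z_wall_um,
        1 if protocol.thermal_noise else 0,
        n_per_frame,
        n_exp,
        xi,
    )
    if status != 0:
        raise SimulationUnstableError(
            "integration step exceeded 5% of the contour length; reduce dt"
        )
    n_frames = z_frames.shape[0]
    # frame timestamps at the centre of the exposure window
    t_frames = (np.arange(n_frames) * n_per_frame + 0.5 * n_exp) * dt

    if protocol.transverse and protocol.thermal_noise:
        # pendulum stiffness F/(l_ext + R) along the ramp; the transverse
        # mode is far softer than z, so it gets its own (larger) time step
        l_eq = np.array([wlc_extension_at_force(max(f, 1e-9), tether.wlc) for f in f_grid])
        lever_um = l_eq + tether.bead.radius_um
        k_grid = np.abs(f_grid) / lever_um * 1e-6  # N/m
        gamma_grid = np.asarray(
            drag_coefficient_parallel(
                lever_um, tether.bead.radius_um, protocol.viscosity_pa_s
            )
        )
        dt_x_stable = 0.05 * float(np.min(gamma_grid) / np.max(k_grid))
        n_per_frame_x = max(1, int(np.ceil(1.0 / (protocol.frame_rate_hz * dt_x_stable))))
        dt_x = 1.0 / (protocol.frame_rate_hz * n_per_frame_x)
        n_steps_x = n_frames * n_per_frame_x
        if protocol.exposure_s is None:
            n_exp_x = 1
        else:
            n_exp_x = int(np.clip(round(protocol.exposure_s / dt_x), 1, n_per_frame_x))
        x_um = _euler_ou_kernel(
            n_steps_x, dt_x, k_grid, gamma_grid, grid_dt, kbt_j,
            n_per_frame_x, n_exp_x,
            np.random.default_rng(seeds[1]).standard_normal(n_steps_x),
        )
        y_um = _euler_ou_kernel(
            n_steps_x, dt_x, k_grid, gamma_grid, grid_dt, kbt_j,
            n_per_frame_x, n_exp_x,
            np.random.default_rng(seeds[2]).standard_normal(n_steps_x),
        )
    else:
        x_um = np.zeros(n_frames)
        y_um = np.zeros(n_frames)

    if protocol.tracking_noise:
        cam = np.random.default_rng(seeds[3])
        z_frames = z_frames + cam.normal(0.0, protocol.sigma_z_um, n_frames)
        x_um = x_um + cam.normal(0.0, protocol.sigma_xy_um, n_frames)
        y_um = y_um + cam.normal(0.0, protocol.sigma_xy_um, n_frames)

    data = pd.DataFrame(
        {"t": t_frames, "x": x_um, "y": y_um, "z": z_frames, "bead_id": bead_id}
    )
    return Trace(
        data,
        frame_rate_hz=protocol.frame_rate_hz,
        seed=protocol.seed,
        protocol_hash=_protocol_hash(tether, protocol),
    )


def drag_force_profile(tether: TetherModel, protocol: SimProtocol) -> pd.DataFrame:
    """Deterministic drag-force budget along a magnet ramp.

    Requires noise disabled.  Returns columns t_s, z_um, f_drag_pn,
    f_mag_z_pn and ratio = F_drag/F_mag,z, with the drag computed as
    gamma_perp(h)·|dz/dt| along the simulated trajectory.
    """
    if protocol.thermal_noise:
        raise ValueError("drag budget requires thermal_noise=False")
    protocol = replace(protocol, tracking_noise=False, transverse=False)
    trace = simulate_trace(tether, protocol)
    t = trace.data["t"].to_numpy()
    z = trace.data["z"].to_numpy()
    dzdt = np.gradient(z, t)
    gamma = drag_coefficient_perpendicular(
        z + tether.bead.radius_um, tether.bead.radius_um, protocol.viscosity_pa_s
    )
    f_drag_pn = gamma * np.abs(dzdt) * M_PER_UM * 1e12
    t_grid, f_grid = _force_grid(tether, protocol)
    f_mag = np.interp(t, t_grid, f_grid)
    return pd.DataFrame(
        {
            "t_s": t,
            "z_um": z,
            "f_drag_pn": f_drag_pn,
            "f_mag_z_pn": f_mag,
            "ratio": f_drag_pn / np.abs(f_mag),
        }
    )


def apparent_response_with_offset(
    tether: TetherModel, protocol: SimProtocol
) -> pd.DataFrame:
    """Force-extension curve in the *measured* convention for A > 0.

    An anchor sitting A above the bead bottom hides length A and biases
    the inferred force: L_meas = L_real − A and
    F_meas = F_real·(L_meas/L_real).  Feeding the result to the fitting
    pipeline quantifies the persistence-length bias of an uncorrected
    eccentric attachment.
    """
    a = tether.attachment_offset_um
    protocol = replace(protocol, tracking_noise=False)
    if protocol.thermal_noise:
        raise ValueError("the offset-bias study is defined on the noise-free response")
    trace = simulate_trace(tether, protocol)
    t = trace.data["t"].to_numpy()
    l_real = trace.data["z"].to_numpy()
    t_grid, f_grid = _force_grid(tether, protocol)
    f_real = np.interp(t, t_grid, f_grid)
    l_meas = l_real - a
    keep = l_meas > 0
    f_meas = f_real[keep] * l_meas[keep] / l_real[keep]
    return pd.DataFrame({"extension_um": l_meas[keep], "force_pn": f_meas})
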