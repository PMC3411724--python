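# Methods

This note documents the physical models, their assumptions, the numerical
choices, and what the synthetic data generator does and does not emulate.

## Magnetostatics of the magnet pair

The external field source is a pair of block permanent magnets with vertical,
antiparallel magnetization, separated by a gap of 2 mm along the x axis. In
the magnetostatic analogue of electrostatics a uniformly magnetized block is
equivalent to two uniformly charged sheets on its top and bottom faces with
surface charge density σ = B_r/µ₀, where B_r is the remanent field. The field
of a uniformly charged rectangle has a closed form in log/arctan terms; the
assembly field is the sum of the four sheet contributions (signs set by the
antiparallel orientation). The closed form is verified in the test-suite
against brute-force 2D quadrature of the Coulomb kernel, and the assembled
field against the analytic invariants (∇·B = 0, reflection symmetry, sign
flip under a half-turn of the pair).

**Assumed geometry.** The instrument description fixes the gap (2 mm) and the
bead (MyOne, radius 0.525 µm, vendor Langevin parameters M_sat = 43.3 kA/m,
B₀ = 12 mT) but not the magnet dimensions or grade. Defaults are 5×5×5 mm
cubes with B_r = 1.4 T — the configuration of the comparable instrument
against which the field model was benchmarked. All geometry is configurable
(`MagnetAssembly`). Absolute force values scale with these assumptions (the
model's on-axis force at Z_mag = 1 mm is ≈4 pN, roughly twice a typical
measured bead's); force *ratios*, angles, decay lengths and uniformity
numbers are far less sensitive.

**Bead plane depth.** Z_mag is measured from the magnet bottom faces to the
*top* of the flow cell, but the beads sit on its bottom surface: a 0.17 mm
coverslip plus a ≈0.23 mm fluid channel put the bead plane 0.40 mm below the
flow-cell top. This `bead_plane_depth` (default 0.40 mm) matters: with it the
model reproduces the measured-instrument numbers (decay length 1.87 mm, force
angles 27.7°/3.4° at the field edge, 1.3% field-of-view variation at
Z_mag = 1 mm) simultaneously; without it none of them come out.

**Force conventions.** For a moment induced along the field the
thermodynamically consistent force is F = m(|B|)∇|B| (default, `"energy"`).
The alternative F = ∇(m(|B|)·|B|) = [m + |B|·dm/d|B|]∇|B| (`"gradient"`) is
what reproduces the published simulation numbers (decay length 1.86 mm) and
is used by `scripts/acceptance.py`; every result object records which
convention produced it. Both use central differences with a 1 µm step
(halving the step changes forces by <0.01%).

**Force–height behaviour.** On axis the force decays nearly exponentially
with magnet height over Z_mag = 1–8 mm (decay length 1.87 mm, relative error
of the single-exponential fit <7%). Right at the gap edge (Z_mag ≲ 0.8 mm
with the default geometry) the charge-sheet model predicts a force plateau
and turnover — field saturation between the bottom sheet edges — so
monotonicity of F(Z_mag) holds beyond that height, not from contact.

**Uniformity metric.** The field-of-view variation is
100·(max−min)/max of the *total* force magnitude |F| over the grid (the
|F_z|-based figure is carried alongside in `ForceMap`). At these uniformity
levels (max−min)/mean differs by <0.1 percentage point.

## Worm-like-chain elasticity

The entropic force–extension law uses the seven-coefficient analytical
approximation (a₂…a₇ = −0.5164228, −2.737418, 16.07497, −38.87607, 39.49944,
−14.17718), which corrects the plain interpolation formula to ≈0.1% of the
exact WLC solution. The stretching energy E(l) = ∫₀ˡ F dl′ is evaluated with
the exact antiderivative of this expression rather than numerical quadrature
— faster and exact; a dense-grid trapezoid oracle confirms it in the tests.
k_BT is computed from the configurable temperature (default 295.15 K, the
22 °C assay temperature; k_BT = 4.0745×10⁻²¹ J). Twist elasticity,
overstretching and salt dependence are out of scope (tethers are torsionally
unconstrained).

## Tether dynamics

The vertical coordinate (tether extension z) follows the overdamped Langevin
equation integrated by Euler–Maruyama:

    z_{n+1} = z_n + Δt·[F_mag,z(t_n) − F_WLC(z_n)]/γ⊥(h_n) + √(2k_BT·Δt/γ⊥)·ξ_n,

with γ⊥ the Faxén-corrected drag for motion perpendicular to the wall,
γ⊥ = 6πηR/(1 − (9/8)(R/h) + (1/2)(R/h)³), evaluated at the bead-centre height
h = z + R (the attachment offset affects only the measurement transform, not
the hydrodynamics — a documented simplification). Viscosity defaults to
0.955 mPa·s (water at 22 °C). Inertia, rotational Brownian motion and
bead–bead interactions are neglected.

**Time step.** By default Δt = 0.05·γ/k_max, with k_max the WLC stiffness at
the largest extension plausibly visited: the point where the tilted potential
E_WLC(l) − F_max·l rises 12 k_BT above its minimum (for noise-free runs,
simply the equilibrium extension at peak force). A user-supplied Δt is
rejected beyond twice this limit; runaway deterministic drift (>5% of L_c per
step) aborts the run. Halving Δt changes a deterministic ramp trajectory by
<0.1%. The inner loop is numba-compiled when numba is available, with an
identical pure-Python path otherwise (equivalence is tested).

**Magnet protocols.** Either the single-exponential law
F = F₀·exp(−(Z_mag − 1 mm)/l_dec) (per-bead F₀; default decay length from the
measured 1.54 mm or the modelled 1.55/1.86 mm, depending on the study) or the
full charge-sheet field, under a fixed height or a linear ramp
Z_mag(t) = Z_start + v_mag·t (default 0.1 mm/s). Force ramps are labelled
with the exponential law only over its 1–8 mm validity range.

**Transverse mode.** When requested, lateral motion is simulated as an
independent pendulum mode with stiffness F/(l_ext + R) and parallel-wall
drag, on its own (much larger) stable time step. This is the mode that
underlies equipartition force calibration.

**Camera model.** Frames are produced at the acquisition rate (default
50 Hz) by boxcar-averaging the trajectory over the exposure window, then
adding Gaussian tracking noise (σ_z = 12 nm, σ_xy = 2.2 nm — the tracking
resolutions of the imaging pipeline). The default exposure is effectively
instantaneous: the exposure time of the real camera is not documented, and a
full-frame 20 ms window would attenuate the transverse fluctuations by tens
of percent (motion blur) and hence bias any variance-based force estimate;
the window is configurable for studying exactly that effect.

**Drag budget.** For a noise-free ramp the drag force γ⊥(h)·|dz/dt| along the
trajectory is returned together with the applied force. For a 7.3 kb tether
on a 1 µm bead ramped at 0.1 mm/s over Z_mag = 1–8 mm the maximum vertical
drag is ≈0.58 fN and the drag-to-force ratio stays below 0.009 — drag is
negligible for elasticity work. This number is viscosity- and
bead-radius-sensitive at the ±10% level.

## Rotation analysis

A tether off the magnet rotation axis precesses at exactly twice the drive
frequency (half a magnet turn restores the same field-intensity pattern);
an eccentric anchor adds a circle at the drive frequency. Because both
frequencies are known, fitting the bicircular pattern is *linear*: x and y
share the four quadrature amplitudes and the centre, solved in one
least-squares projection. Radii are non-negative by construction (phases
absorb signs); phases are free parameters since the experimental phase
relation depends on magnet orientation and attachment azimuth. At a tracking
noise of 2.2 nm and four magnet turns at 50 Hz the radius estimates are
unbiased to <0.5 nm.

The attachment radius converts to the hidden height offset by sphere
geometry, A = R − √(R² − R_att²). With anchors uniform on the sphere and the
bead free to rotate about its horizontal magnetic easy axis, A = R(1 − sin α)
with polar-angle density sin α, giving p(A) = (1 − A/R)/(R·√(1 − (1 − A/R)²))
and CDF P(A ≤ a) = √(1 − (1 − a/R)²) — re-derived from the geometric
construction and verified against Monte-Carlo sphere sampling (KS distance
<0.002 at 10⁶ samples). Sampling uses the closed-form inverse CDF.

The predicted precession radius uses small-angle pendulum geometry,
R_prec = (l_ext + R)·tan α, with α from the field model and l_ext the
equilibrium extension at the local vertical force; the lever arm choice
(l_ext + R, the anchor-to-bead-centre distance) is an interpretation of the
tilted-tether geometry. Torque magnitudes and easy-axis anisotropy energies
are not modelled — only the assumption that the restoring torque dominates.

## Characterization pipeline

Per tether: (1) the minimum height of a long zero-force recording marks
surface contact and offsets all heights; (2) the Limaçon fit gives R_att,
hence A, which is added back to measured lengths (the eccentric anchor hides
length A and biases the inferred force by L_meas/L_real); (3) tension is
estimated at three magnet heights from the transverse variance
(F = k_BT·(l_ext + R)/var(x), block-wise standard error, two-half
stationarity check) and reduced to F₀ by log-space least squares with the
decay length fixed; (4) the ramp record is labelled with forces from the
exponential law, restricted to ≤2 pN (the maximum force of the elasticity
protocol), reordered to monotone extension, and integrated (cumulative
trapezoid) into an energy curve; (5) the energy curve is fitted with
E_WLC(l; L_p, L_c) + E₀ by bounded nonlinear least squares
(L_p ∈ [5, 150] nm, L_c ∈ (l_max, 1.5·l_max]; initial values 50 nm and
1.05·l_max). E₀ absorbs the unknown lower integration bound; pinning
E(l_min) = 0 instead (`fit_offset=False`) reproduces the eccentric-attachment
bias study, where an uncorrected A = R on an 800 nm molecule depresses the
fitted L_p by ≈13 nm. Tethers fitted below 28 nm are classified as multiply
tethered and excluded from ensemble statistics; the threshold is hard, no
hysteresis.

Equipartition calibration replaces power-spectral-density analysis of the
Brownian noise. It is adequate for the synthetic data here (unbiased to a
few percent with an instantaneous shutter); on real data it would require a
motion-blur/aliasing correction that spectral methods handle natively.

## Synthetic experiments

`EnsembleConfig` defaults encode the study conditions: a 300×400 µm field of
view, ≥15 µm bead separation (rejection sampling; 60 tethers place
comfortably), four DNA length groups (2.2/7.3/11.9/20.1 kb → 0.75/2.48/4.05/
6.83 µm at 0.34 nm/bp), L_p = 50 nm, log-normal force scales with mean 6 pN
and 11% relative spread, attachment offsets from the geometric law, 50 Hz
camera with the tracking noise above, and the four-segment protocol (25 s
hold, 130 s zero-force hold at Z_mag = 20 mm, four magnet turns of rotation,
0.1 mm/s ramp over 1–8 mm). The simulator's reflecting wall sits at
extension = A (bead-surface contact for an anchor A above the bead bottom),
which is what makes the zero-force surface-reference step meaningful. All
randomness descends from one master seed through per-bead
(seed, bead id)-spawned substreams, so results are reproducible and
independent of ensemble size.

With thermal noise disabled the pipeline recovers (L_p, L_c) to better than
1% across all four length groups (equipartition calibration is undefined at
zero variance, so the ground-truth F₀ is used there). With noise enabled the
fitted L_p drops systematically as L_c shrinks — the nonlinear response to
large bead fluctuations — reproducing the characteristic length dependence of
tweezers-measured persistence lengths; σ_F0 = 0.11 is recovered on a 120-bead
ensemble to within sampling error.

**What the generator does not emulate:** image formation and bead tracking
(traces are generated directly in position space), thermal drift and its
reference-bead correction, tether rupture/sticking events, torsional effects,
bead polydispersity beyond the force-scale spread, and spectral content of
the tracking noise (white Gaussian is assumed). Passing tests therefore
validate the analysis chain and the physics of the models, not the imaging
pipeline of a real instrument.

## Known limitations

- Magnet dimensions/remanence are assumptions; absolute forces inherit ~2×
  uncertainty, and bounds expressed in absolute force units (e.g. the <20 fN
  single-exponential error) scale with them.
- Finite magnetic polarizability of the objective and flow-cell mount is not
  modelled; on the real instrument it shortens the measured decay length
  (1.54 mm) relative to the modelled one (1.87 mm).
- The Faxén corrections are truncated series; they lose accuracy within
  ~10 nm of the wall, where the reflecting boundary dominates anyway.
- Euler–Maruyama equilibrium variances carry an O(k·Δt/γ) ≈ 2.5% bias at the
  default safety factor.
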