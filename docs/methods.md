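# Methods

`silkflight` implements a quasi-steady blade-element analysis of silk-moth
forward flight: Fourier-series wing/body kinematics, per-strip aerodynamic
forces on rigid flat-plate wings, a bounded multi-start trim-equilibrium
search, and comparisons between body-kinematics configurations that isolate
the aerodynamic role of body pitch and bobbing oscillations.

## Model and assumptions

The combined fore+hindwing of each side is a single rigid flat plate,
discretized into `n_strips` spanwise-uniform chordwise strips (default 200,
midpoint rule).  Per strip of chord `c` and width `dr`, the instantaneous
force is the sum of four quasi-steady components:

- translational lift `|dF_L| = 1/2 ρ C_L v² c dr`, perpendicular to the
  relative airflow in the plane spanned by the airflow and the wing
  normal, signed toward the suction side (the side selected by the sign
  of `n̂·v̂`);
- translational drag `|dF_D| = 1/2 ρ C_D v² c dr`, along the relative
  airflow `v̂`;
- rotational (Kramer) force `dF_rot = ρ C_R v c² α̇_h dr` along the wing
  normal;
- added-mass force
  `dF_adm = −(π/4) ρ [(φ̈ sin α + φ̇ α̇_h cos α) r c² + (1/4) α̈_h c³] dr`
  along the wing normal, the reaction opposing the normal acceleration of
  the entrained air.

`v` is the airspeed of the strip's pitching-axis point in the global frame
(ambient wind defaults to zero); chordwise rotation enters only through the
rotational and added-mass terms, per the quasi-steady decomposition.  The
empirical flat-plate coefficient polynomials are

    C_L(α_v) = k_L (1.552 sin α_v cos α_v + 1.725 sin²α_v cos α_v)
    C_D(α_v) = k_D (0.0596 sin α_v cos α_v + 3.598 sin³α_v)

with the angle of attack `α_v = arccos(−b̂·v̂)` between the chord line
(trailing→leading unit vector `b̂`) and the incident airflow, and
dimensionless scalings `k_L, k_D` that absorb interspecific differences.
The rotational coefficient is the thin-airfoil value `C_R = π(0.75 − ê)`
with the pitching axis at chord fraction `ê` (default quarter-chord,
`ê = 0.25`).

Aerodynamic power is the rate of work done against the airflow by drag,
rotational and added-mass forces, `P = Σ (dF_D + dF_rot + dF_adm)·v`;
lift is perpendicular to `v` and contributes exactly zero (asserted
numerically in the result as `P_lift_residual`).  The wing inertial
reaction on the body is `dF = −(m_w/S) c dr · d(v_g)/dt` per strip — the
printed shorthand `m_w S c dr` is dimensionally a mass-per-unit-area times
strip area, so the implementation uses `(m_w/S) c dr` — summed over strips
and wings; it averages to zero over any exact period.

### Frames and sign conventions

Global frame: x forward (flight direction), z up.  Body frame: pitched
nose-up by χ about y.  Stroke-plane frame: anchored at the hinge, inclined
β to the horizontal about the y-axis and rolled β_r about its own x-axis
(mirrored for the left wing).  Wing frame: sweep φ about the stroke-plane
normal, then deviation θ, then feathering α about the spanwise axis.

The pitch sense of the stroke plane is chosen so that at β = 90° the
plane is vertical with its normal along +x, the dorsal stroke reversal
(the sweep maximum, which also defines wingstroke boundaries; downstroke
= φ decreasing) lies up-backward, and the downstroke sweeps
down-forward.  This is the orientation under which the model reproduces
the observed flight strategy — weight support concentrated in the
downstroke, forward thrust in the upstroke — and under which
wingstroke-mean weight support is attainable inside the measured
parameter bounds; with the opposite sense the mean vertical force is
strongly negative throughout the bounds.  Positive feathering tilts the
leading edge up relative to the stroke plane, and the wing inclination
to the absolute horizontal is `α_h = α − β` exactly (implemented as an
identity, with `α̇_h = α̇ − β̇`).

The left wing is the exact y-mirror of the right.  With symmetric
kinematics and no lateral wind the code exploits this: it evaluates the
right-wing chain and reflects the result, which is bit-identical to
evaluating both chains (verified in tests; the explicit two-chain path
remains available and is used by the symmetry checks).

Angles are degrees in every file and public statistic, radians inside the
trigonometric core.  All rotation-matrix time derivatives (first and
second) are analytic; no finite differencing enters the force model.

## Kinematic waveforms

Every periodic parameter is an order-K Fourier series (K = 3, which
captures moth wingstroke waveforms) at the wingbeat frequency `f`.
Waveform statistics follow the trim-search convention: the mean is the
grid average over one period (equal to the constant coefficient) and the
amplitude is max − min, both evaluated on a fixed 1024-point grid; a
waveform is retargeted to a new mean/amplitude by an affine map on its
coefficients, preserving harmonic ratios and phases.  Phase differences
(e.g. the χ–φ phase) are defined on fundamental harmonics written as
`A cos(2πft + δ)` and reported in [0°, 360°) as how far the first
waveform leads the second; the definition is invariant to amplitude
rescaling.

## Trim search

Steady flight requires the wingstroke means to satisfy `F̄_x = 0`,
`F̄_z = m g`, `M̄_y = 0` (lateral components vanish by symmetry).  The
residual is

    G = (F̄_x/mg)² + (F̄_z/mg − 1)² + (M̄_y/(mg r₂))²

with `r₂` the radius of the second moment of wing area.  Fourteen
parameters are searched inside per-species min/max boxes measured across
recorded wingstrokes: `f`, `β_r`, the mean and amplitude of χ, β, φ, α,
θ, and `k_L`, `k_D`.  Waveform shapes stay fixed; the body-velocity
waveforms keep their means and shapes with the time base rescaled.

Each restart draws a uniform point in the box and proceeds in three
stages: (1) a Nelder–Mead simplex (derivative-free, through the
sinusoidal bound transform `x = lo + (hi−lo)(sin z + 1)/2`) on a reduced
grid (50 strips × 200 steps) localizes a basin; (2) a bounded
finite-difference Gauss–Newton pass (trust-region-reflective least
squares on the 3-component residual vector, unit-box coordinates) drives
the residual toward zero on the reduced grid, then on an intermediate
(100 × 500) and the full grid (200 × 1000).  Because three conditions
constrain fourteen parameters, the zero set of G is generically
eleven-dimensional, so distinct restarts land on distinct solutions; two
solutions are distinct when they differ by more than 2% of the bound
range in at least one parameter.  The default tolerance is G ≤ 1e−6
(achieved G is typically 1e−8–1e−15), the restart budget 60, and bounds
may relax by 2% of each range when validating loaded solutions.  The
reported G is always recomputed at full fidelity, so a stored solution
re-simulated from scratch reproduces it exactly.

## Body-kinematics model variants

With wing angles φ, θ, α fixed: model1 is the (trimmed) time-varying
configuration; model2 freezes χ, β, u, w at their wingstroke means (no
body oscillations); model3 time-shifts them by half a period (harmonic k
phase-shifted by k·180°), putting the body in anti-phase with the wings;
model1a keeps the u, w oscillations but flattens χ (and β, which is
carried by the body — a flag disables the β flattening); model1b keeps χ
(and β) and flattens u, w.  Variants reuse the model1 trim parameters
and are re-simulated, never re-trimmed.  Performance metrics: mean/peak
force magnitude and power, mean fore-aft and vertical force, the
lift-to-drag ratio as the ratio of wingstroke means of the
area-weighted strip C_L and C_D traces, and the χ–φ phase.

## Synthetic-data generator

The generator emulates the structure of the study data so the whole
pipeline runs without downloads:

- the 14 wingstroke parameters are drawn uniformly inside a species'
  bounds (rejection-free by construction; the per-species boxes for
  *Automeris io*, *Actias luna*, *Antheraea polyphemus* and *Hyalophora
  euryalus* are packaged);
- waveform shapes are a dominant fundamental plus 2nd/3rd harmonics of
  relative magnitude `harmonic_decay` (default 0.2) with random phases;
- the body-pitch fundamental is placed so the χ–φ phase difference falls
  in the observed 30°–120° band;
- feathering leads sweep by ~90° (±20° jitter): the wing is flat through
  the downstroke and steep through the upstroke;
- the stroke-plane angle oscillates in anti-phase with χ (±15° jitter):
  the plane steepens as the body pitches nose-down.  The per-species
  amplitude bounds for β and χ are nearly identical, consistent with a
  stroke plane carried by the body;
- the u/w oscillations are not drawn independently: a damped fixed-point
  iteration makes them the dynamic response of the body to the periodic
  aerodynamic-plus-inertial force per unit mass (wing–body coupling),
  keeping the drawn mean flight speed (2–3 m/s) and climb rate.  The
  resulting bobbing amplitudes (~0.5–1.3 m/s) fall in the observed range
  without calibration.  This coupling is what produces the
  power-saving effect of in-band body oscillations; with independently
  drawn u/w phases the effect does not reproduce;
- morphology is a Beta-function planform (`c(r) ∝ (r/R)^(p−1)(1−r/R)^(q−1)`,
  normalized to maximum chord) at silk-moth scale: R 5.5–8 cm, maximum
  chord 0.55–0.75 R, total mass 1.5–3 g, wing mass 5% of total per side,
  hinge offset a fixed fraction of R.  These scales stand in for
  unavailable per-specimen morphometrics and are labelled synthetic.

"Near-trim" mode tunes three quantities the trim search leaves free —
mean flight speed (thrust–drag balance zeroes `F̄_x`), fore-aft hinge
position (zeroes `M̄_y`) and total mass (set to the supported weight) —
by one-dimensional root finding, iterated four times with a final pass at
full fidelity (final G ≲ 1e−12).  This guarantees an in-bounds optimum
for trim-recovery tests.

The landmark forward model places the seven tracked points (head,
thorax–abdomen junction = the COM proxy, abdomen tip, both hinges, right
wingtip, right inner angle) through the same kinematic chain the force
model uses, samples at 1000 frames/s, and adds seeded Gaussian noise
(default sd 0.1 mm) per coordinate.  It does not emulate camera geometry,
occlusion or digitization artefacts.

## Angle extraction

Body pitch is the elevation of the head→abdomen-tip axis.  Wingstrokes
are segmented at maxima of a provisional sweep angle (plane fitted to the
whole wingtip path), with a prominence filter against tracking noise; the
wingbeat frequency from peak spacing is refined by minimizing the
Fourier-fit residual of the sweep series (relative accuracy ~1e−9 on
clean data).  Per wingstroke, the stroke plane is the least-squares (PCA)
plane of the wingtip path about the hinge; β and β_r come from its
normal, sweep/deviation are the azimuth/elevation of the hinge→wingtip
vector in that frame, and feathering comes from the inner-angle marker
after undoing sweep and deviation (convention: the inner-angle point lies
on the trailing side of the pitching axis).  Body velocities are the
analytic derivative of a linear-plus-Fourier fit to the COM-proxy
positions — the linear term carries the mean velocity, avoiding the noise
amplification of raw finite differences.

A per-stroke plane can represent a within-stroke-constant β only.  When
the generating β and θ waveforms are constant the wingtip path is planar
and extraction inverts the forward model to machine precision (all angles
< 1e−6 deg, coefficients re-fit to 1e−10); with oscillating β/θ the
fitted plane is a least-squares compromise that absorbs part of the
deviation, and recovery is accurate to a few percent of the sweep
amplitude.  The exactness tests use planar-path configurations and the
tolerant test documents the in-band behaviour.

## Numerical choices

- Default grids: 200 strips per wing, 1000 time steps per wingstroke;
  wingstroke averages are arithmetic means over the uniform grid.
  Halving either grid changes the mean vertical force and mean power by
  < 0.1% for smooth kinematics (tested).
- Reduced grids used for speed: 50 × 200 inside the trim-search simplex
  (with 100 × 500 and 200 × 1000 refinement passes), 60–100 strips and
  240–500 steps in generator fixed-point iterations and comparison
  tables in tests.  The acceptance script uses the full grid for all
  reported equilibrium quantities and 100 × 500 for the variant tables.
- Degenerate flow: strips with zero airspeed produce zero translational
  force (the flow direction is undefined); a vanishing normal component
  of the airflow makes the lift direction degenerate exactly where the
  lift coefficient vanishes, and is guarded to zero.
- Waveform amplitude is defined on a fixed 1024-point grid, making
  rescaling exactly idempotent; the grid under-resolves the continuous
  extremum by O(10⁻⁶) relative, well inside every tolerance used.
- Seeds: every stochastic step (parameter draws, landmark noise, restart
  draws) flows from an explicit integer seed; identical seeds give
  byte-identical outputs.

## Known limitations

- Rigid flat-plate wings: no bending/torsion, no wake capture or other
  unsteady mechanisms, no Reynolds-number dependence of the coefficient
  polynomials, no body (parasitic) drag.
- Body pitch χ is drawn, not dynamically consistent with the pitching
  moment (that would require the body moment of inertia, which is not
  modelled); only u and w are closed through the force loop.
- The stroke-plane angle is extracted per wingstroke, so a continuous
  β(t) waveform cannot be recovered from landmarks alone — the
  decomposition of a tracked wing orientation into (β, φ, θ, α) per
  frame is underdetermined by one angle.
- Species tables ship only the published parameter bounds and a sample
  trim solution; per-specimen morphometrics and waveform coefficients
  are emulated by the synthetic generator, so quantitative comparisons
  against the study's per-species force/power values require supplying
  the corresponding morphology and kinematics files.
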