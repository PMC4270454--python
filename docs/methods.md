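# Methods

## Scope and model overview

`polywear` predicts sliding wear and creep of a conventional (non-cross-
linked, GUR 1050) UHMWPE acetabular cup articulating against a rigid
cobalt-chrome femoral head over millions of gait cycles, and compares three
simulator motion inputs: a measured-walking-style cycle with all three
rotations on the head, an ISO-style cycle with flexion/extension (FE) and
abduction/adduction (AA) on the cup and internal/external rotation (IER) on
the head, and a two-axis ProSim-style cycle (FE + IER only).  The joint is
a ball-in-socket: a hemispherical cup bearing surface of radius
R = head radius + radial clearance (default 14 mm + 0.04 mm), an 8 mm
polyethylene wall on a rigid backing, the cup inclined 35 degrees under a
vertically applied resultant load (equivalent to a 45-degree anatomical cup
with a 10-degree-medial load vector).

The wear law is the contact-area-dependent form V = C·A·L: wear volume
proportional to nominal contact area and sliding distance, with a wear
coefficient C that is independent of pressure over 1–10 MPa but increases
with the cross-shear ratio (CSR),

    C(CSR) = (8.5e-5 + 9.3·CSR)^0.15 × S,  S = 1e-9 (default).

Dividing by the contact area gives the per-cycle linear wear depth at a
node, δ = Σ_i C(CSR)·L_i, summed over the discrete intervals of the cycle
in which the node carries contact pressure.  Creep deformation follows the
logarithmic law δ_cr = B·p̄·log10(t)·d, with B = 7.97e-4 per MPa per decade
of minutes, p̄ the running time-average nodal contact pressure (unloaded
portions of the cycle included; an average over loaded instants only is a
one-line change in the engine), t the loading time in minutes (clamped at
1 minute, where the law is zero) and d the polyethylene wall thickness.
Creep is irreversible; wear and creep superpose into the total linear
penetration used to update the geometry.

Two printed constants in the source literature are typographically
unusable as printed: the overall scale of C (a garbled exponent) and the
magnitude of B (7.97 per MPa per decade yields strains exceeding the wall
thickness).  The values above are the declared reconstructions: S = 1e-9
reproduces the published coefficient magnitudes at both ends of the CSR
range (2.45e-10 at CSR = 0 against a printed low of 3.2e-10; 1.26e-9 at
CSR = 0.5 inside the printed 1.0–1.6e-9 plateau), and B = 7.97e-4 gives
creep penetrations in the 0.01–0.12 mm range.  Both are config parameters.

## Surface discretisation and geometry updates

Only surface fields are needed (pressures, sliding, CSR, depths), so the
cup is discretised as a Fibonacci lattice on the hemisphere with the equal
area weight 2πR²/n per node, which partitions the hemisphere exactly.  The
default target spacing of 0.5 mm (≈ 4950 nodes on a 28 mm bearing) matches
the contact-converged element length of the finite-element model this
replaces; wear-rate results change by < 0.1% between 1.25 mm and 0.5 mm
spacing, so the resolution is convergence-controlled rather than critical.
Wear and creep accumulate as a scalar radial offset per node: material
removal moves the local cup surface radially outward (local radius
R + penetration), while the head stays a perfect sphere.

The simulation advances in geometry-update intervals.  One representative
cycle is evaluated on the current worn surface, its per-cycle wear is
scaled by the interval length, the creep increment
B·p̄·(log10 t₂ − log10 t₁)·d is added, the penetration field is applied,
and the next interval starts on the corrected geometry.  Because the creep
transient is logarithmic in time, the first 64,000 cycles are split into
10 geometrically spaced intervals; thereafter the update factor is fixed
at 250,000 cycles up to the 5-million-cycle total (30 checkpoints).
Halving the steady update factor changes the 5M-cycle wear volume by
< 0.1%, and the early-phase penetration rate per cycle demonstrably
exceeds the steady-phase rate (the transient the log spacing exists for).

## Kinematics and sliding

Rotations compose in the FE → AA → IER sequence about the global x, y, z
axes (extrinsic fixed-axis composition; an intrinsic variant sits behind a
flag because the source description does not fix the convention).  Each
axis is carried by the component the protocol assigns; the motion that
matters is the head-relative-to-cup rotation R_rel = R_cup^T·R_head, so an
angle on the head and the negated angle on the cup are equivalent — but
the *load direction in the cup frame* is not: with cup-carried motion the
globally vertical load sweeps across the cup surface.  For the two-axis
ProSim case the two published carrier statements contradict each other
(FE-head/IER-cup in the motion table, the reverse in the text); swapping
both carriers inverts R_rel, so the two variants are genuinely different
machines.  The table assignment is the default and `text_carriers=True`
selects the other; neither is declared "correct".

The one-second cycle is discretised at 16 equal time points.  For the
interval between samples j and j+1 the counterface step is
dR = R_rel(j+1)·R_rel(j)^T with rotation vector w, and the slip of the
head across node n is the velocity-form increment R·(w × n): exactly
tangent to the surface, with norm equal to the small-circle path length
swept past the node.  For a constant-axis interval this is exact — purely
reciprocating motion stays exactly unidirectional, and the per-cycle
sliding distance of a single-axis cycle equals (total angular path) ×
(distance to the axis) to machine precision — while mixed-axis intervals
incur an error second-order in the per-interval step (< 0.2 rad here).  A
chord-based increment was rejected: circle chords rotate by half the step
angle, which injects spurious cross-shear into reciprocating motion.
Increments are stored as 2-vectors in a fixed per-node (east, north)
tangent basis of the cup material frame; parallel-transport corrections
over the ≲ 2 mm per-interval steps are neglected, and the CSR result is
insensitive to a rigid rotation of the basis to within the PMO search
tolerance.  Doubling the time sampling (16 → 32) changes the wear rate by
0.1%.

Slide tracks for visualisation follow the cup-node-on-head convention
(the converse is a flag), and the flattened-hemisphere plot is the
azimuthal-equidistant projection about the cup pole, mapping the equator
of a 14.04 mm bearing to a 22.05 mm circle with meridian arc lengths
preserved.

## Waveform reconstruction

The published motion and load profiles exist only as figures, so the
generators use declared analytic shapes: single-harmonic angle waveforms
hitting the tabulated ranges exactly (FE at phase zero; AA and IER lagging
by a configurable phase, default one quarter cycle so FE leads IER), and a
twin-peak stance load — two Gaussian bumps (centres 0.16 and 0.48 of the
cycle, widths 0.08, second peak 0.9 of the first) on a 300 N swing
baseline — amplitude-scaled so the sampled cycle average matches the
printed 1242 / 1293 / 1057 N exactly.  The default phases and peak
parameters are gait-plausible choices fixed once when the generators were
written; the comparison of protocols inherits whatever sensitivity the
true measured waveforms would remove (see Limitations).

## Contact

The polyethylene layer is an elastic foundation (Winkler bed) on the rigid
backing with confined-layer stiffness k = (1−ν)E/[(1+ν)(1−2ν)d]
(= 133.9 MPa/mm at E = 500 MPa, ν = 0.4, d = 8 mm).  Nodal pressure is
k × overclosure against the worn surface, optionally capped at a
perfectly-plastic limit of 3× the 10.8 MPa yield stress (inactive at gait
pressures).  At each time point the rigid head centre translates until the
integrated pressure balances the applied load; the residual is required to
be ≤ 1e-3 of the load.  Equilibrium is the minimum of the convex spring
potential, solved by damped semismooth Newton with the analytic rank-3
Jacobian and an Armijo backtracking line search on the potential; warm
starts across time points and update intervals keep it to a few iterations.
Against the closed-form one-dimensional Winkler ball-in-socket solution the
unworn peak pressure agrees to 0.1%, and the peak changes < 0.5% between
2.0 mm and 0.5 mm meshes.

## Cross-shear ratio and the PMO search

Per node and cycle, the frictional work of interval i is
μ·p_i·a·|L_i| (μ = 1; it cancels in the ratio), resolved into absolute
components along and perpendicular to a candidate direction; the principal
molecular orientation is the direction maximising the parallel sum,
located by an exhaustive 1-degree grid over [0, 180) with ties broken
toward the smaller angle and refined by golden section to 0.01 degree, and
CSR = ΣW_t / (ΣW_t + ΣW_p) at that optimum.  With absolute components the
PMO-optimal CSR is bounded by 0.5 (uniformly swept circular slip reaches
it; reciprocating slip gives 0 to within the angular search tolerance,
≈ 1e-4).  The alternative signed-then-absolute decomposition was examined
and is degenerate: the parallel sum becomes |resultant·d̂|, whose maximiser
aligns with the resultant so the transverse component — and hence CSR — is
identically zero for every node; the absolute decomposition is therefore
the only viable reading, and no option is exposed.  CSR is recomputed once
per geometry-update interval from that interval's pressures, since the
pressure field evolves slowly.  Intervals without contact contribute no
work, which also suppresses spurious cross-shear at nodes loaded only
briefly.

## Reported metrics and problem sizes

Headline metrics per run: the volumetric wear rate as the least-squares
slope of V(cycles) over the final 4 million cycles (the creep transient
excluded; the full-range slope is also reported), maximum linear wear
depth (wear only) and maximum penetration (wear + creep), worn area (area
with wear depth above a 0.01 mm threshold — the threshold is a reporting
knob, not physics, and a sensitivity accessor is provided), maximum CSR,
surface-average per-cycle sliding distance, and the peak pressure at the
cycle's first load peak on the final worn geometry.  Default problem
sizes — 4954 surface nodes (0.5 mm spacing), 16 time points, 30 geometry
updates over 5 million cycles — complete in a few seconds per protocol on
one core; the engine-level tests use 1.25–1.5 mm meshes and shorter
schedules, which the convergence results above show to be metric-
equivalent.

## What the built-in protocols do and do not emulate

The generators reproduce the tabulated rotation ranges, carrier
assignments and printed cycle-average loads of the three study conditions,
with smooth harmonic phase relationships in place of the measured curves.
They do not reproduce measurement noise or the exact phase structure of
gait data, the standard's piecewise waveform shapes, or any load-direction
variation (the resultant stays globally vertical, per the source's stated
loading).  Consequently the absolute wear rates, depths and sliding
averages land within the published bands, while fine protocol contrasts —
the few-percent ISO-vs-walking wear-rate split, the worn-area ordering,
and the surface-maximum CSR (an extreme-value statistic realised at
lightly loaded contact-periphery nodes) — are sensitive to the waveform
details and deviate from the published comparison; the package's own
acceptance tests mark those sub-checks accordingly rather than widening
their bands.

## Known limitations

- The elastic foundation has no lateral coupling or plastic flow: a worn
  pocket of nearly uniform depth re-seats the head without spreading
  pressure, so worn-geometry peak pressures stay near the unworn values
  (8–9 MPa) instead of relaxing toward the published 6–8 MPa; rank and
  rough magnitude are retained.
- PMO has no cross-cycle memory: each interval's CSR comes from that
  interval's representative cycle, which matches the slow evolution of
  the fields but cannot capture orientation history effects.
- The head does not wear, lubrication is not modelled beyond its presence
  in the calibrated coefficient, and strain-softening refinements of the
  cross-shear model are out of scope.
- Sliding is evaluated on the nominal sphere; penetrations < 0.15 mm
  change the radius by ≈ 1%, which is below the other modelling error.
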