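# polywear

Computational wear prediction for ultra-high-molecular-weight polyethylene
(UHMWPE) acetabular cups in total hip replacements, and a comparison of
how hip-simulator motion inputs affect the prediction.

Hip simulators assess implant wear under simplified versions of the
physiological walking cycle, and polyethylene wear is highly sensitive to
*how* the bearing slides, not just how far: multidirectional "cross-shear"
sliding disturbs the strain-hardened molecular orientation of the surface
and accelerates wear.  `polywear` implements a ball-in-socket wear model
that captures this and runs it for millions of gait cycles in seconds:

- **Wear law** — V = C·A·L (wear volume = coefficient × nominal contact
  area × sliding distance), equivalently a per-node linear wear depth
  δ = Σᵢ C(CSR)·Lᵢ over the loaded intervals of a cycle;
- **Cross-shear** — CSR = ΣW_t / (ΣW_t + ΣW_p), the fraction of frictional
  work released perpendicular to the principal molecular orientation
  (PMO), with the PMO found per node by exhaustive direction search;
  C(CSR) = (8.5×10⁻⁵ + 9.3·CSR)^0.15 × 10⁻⁹ for conventional GUR 1050;
- **Contact** — elastic-foundation (Winkler) model of the polyethylene
  layer, k = (1−ν)E/[(1+ν)(1−2ν)d], solved for rigid-head equilibrium at
  16 points of the gait cycle;
- **Creep** — δ_cr = B·p̄·log₁₀(t)·d, superposed with wear into the
  penetration that updates the bearing geometry on a log-then-fixed
  update schedule out to 5 million cycles;
- **Protocols** — built-in measured-walking, ISO-style and two-axis
  ProSim-style motion/load cycles (rotation ranges, moving-component
  assignments and cycle-average loads of 1242/1293/1057 N), or your own
  waveforms from CSV.

## Worked example

Simulate 5 million walking cycles of a 28 mm bearing with 0.04 mm radial
clearance (the defaults), then compare against the two-axis simulator
motion:

```sh
$ polywear run --protocol walking --out runs/walking
walking: wear rate 16.50 mm^3 per 10^6 cycles
  max linear wear depth 0.140 mm
  worn area 923 mm^2 (> 0.01 mm)
  max CSR 0.49
  avg sliding distance 19.5 mm/cycle
  peak pressure at first load peak 8.4 MPa

$ polywear run --protocol prosim --out runs/prosim
prosim: wear rate 14.74 mm^3 per 10^6 cycles
  max linear wear depth 0.125 mm
  worn area 885 mm^2 (> 0.01 mm)
  max CSR 0.50
  avg sliding distance 20.3 mm/cycle
  peak pressure at first load peak 8.3 MPa

$ polywear compare runs/walking runs/prosim
                wear_rate  worn_area  max_linear_wear_depth  max_csr  avg_sliding_distance
vs walking (%)
walking              0.00       0.00                   0.00     0.00                  0.00
prosim             -10.66      -4.12                 -10.91     1.46                  3.82
```

Reading the numbers: the full three-axis walking motion wears the cup at
16.5 mm³ per million cycles; replacing it with the simplified two-axis
simulator motion lowers the predicted volumetric wear by ~11% and spreads
it over a slightly smaller area, while the maximum cross-shear ratio,
average sliding distance and worn-geometry contact pressures stay
essentially unchanged — the simplified motion still generates the
multidirectional sliding that drives polyethylene wear.  Each run
directory contains `summary.json`, the volumetric-wear history
(`v_history.csv`), per-node field maps (`fields.csv` and a ParaView-ready
`fields.vtk` with wear depth, creep, CSR, PMO, sliding distance and
pressure), flattened slide-track polylines (`tracks.csv`) and a log of
per-checkpoint equilibrium residuals.

The same pipeline is available as a library:

```python
import polywear as pw

spec = pw.BearingSpec()                      # 28 mm, 0.04 mm clearance, 35 deg cup
result = pw.run_simulation(spec, pw.make_iso_cycle())
print(result.summary.wear_rate)              # mm^3 per 10^6 cycles
```

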