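# psoct

Simulation and analysis of **polarization-sensitive optical coherence
tomography (PS-OCT)** data for quantifying structural disorder in layered
birefringent samples — multi-layer tape phantoms and skin, where the
collagen-rich dermis dominates birefringence and loses its ordered,
layer-like structure under pathological change (e.g. diabetes).

The package is a library first: import it from Python, or skim the short
narrative scripts in `examples/`.  A thin `psoct` command-line pipeline
(`simulate` / `process` / `analyze` / `orient` / `report`) wraps the same
functions for shell use.

## What it computes

From the two complex detector channels `a0` (co-polarized) and `a1`
(cross-polarized) of a dual-detector PS-OCT system:

* **Stokes field** — I = |a0|² + |a1|², Q = |a1|² − |a0|²,
  U = 2 Re(a0·a1\*), V = 2 Im(a0·a1\*), in the convention where horizontal
  light has Q = −1.
* **Retardation** — arctan(|a1|/|a0|) ∈ [0, π/2], the single-pass phase
  retardation δ(z), linear in depth for a homogeneous slab and folded into
  a triangle wave at the range boundaries.
* **Optic axis** — ½·atan2(·, ·) ∈ [−π/2, π/2]; for circular-input
  dual-detector data the fast axis is encoded in the inter-channel phase and
  is read from the transverse Stokes pair (U, −V).
* **DOPU** — degree of polarization uniformity,
  ‖⟨(Q, U, V)/I⟩‖ ∈ [0, 1] over a box kernel: near 1 in
  polarization-preserving tissue, low in depolarizing tissue.
* **Local birefringence** — Δn = (λ/2π)·dδ_cum/dz, from a fold-unwrapped
  cumulative retardation and a sliding-window least-squares slope.

Depth profiles of these maps are reduced to three disorder metrics inside a
100–500 μm analysis window (where OCT attenuation is nearly flat in skin):
number of prominent peaks, range (max − min), and the average residual from
a fitted cubic.  Groups of samples are compared with one-way ANOVA and
pairwise Welch t-tests against the control group (`ns`/`*`/`**`/`***`).
A structure-tensor orientation histogram (0°–180°) with a circular
dispersion statistic quantifies fiber alignment in texture images.

Because no public PS-OCT dataset accompanies this analysis, the package
ships a first-class Jones-calculus simulator: layered phantoms with
per-layer birefringence, fast axis, reflectivity, depolarizing fraction and
lateral axis disorder; speckle and detector noise; a compressive-deformation
operator; and a severity-staged three-stratum skin phantom.

## Worked example

```sh
python examples/birefringence_recovery.py
```

```
  true dn  noise  recovered  rel err
  5.0e-04   0.00   5.00e-04    0.0%
  5.0e-04   0.05   4.49e-04   10.1%
  1.0e-03   0.00   1.00e-03    0.0%
  1.0e-03   0.05   9.21e-04    7.9%
  2.0e-03   0.00   2.00e-03    0.0%
  2.0e-03   0.05   1.88e-03    6.1%
```

Each row simulates a homogeneous slab of known birefringence at
λ = 1.3 μm, computes the speckle-robust retardation depth profile, unwraps
the [0, π/2] folds and recovers Δn from the slope: exact without noise,
within ~10% under 5% additive detector noise.

```sh
python examples/tape_deformation.py
```

```
 undeformed: 10 layers, total  500.0 um | peaks=2, range=1.563 rad, avg residual=0.250 rad
   deformed: 14 layers, total  574.6 um | peaks=1, range=1.564 rad, avg residual=0.100 rad
```

Compressive deformation (layer-thickness jitter, inter-layer gaps, axis
disorder) dilutes the stack's average birefringence, moving a retardation
fold maximum out of the analysis window — the peak count drops, the in-silico
analogue of detecting lost layer order.  `examples/skin_severity_trend.py`
runs the same chain on severity-staged skin phantoms and prints the group
statistics; `examples/fiber_orientation.py` shows the orientation histogram
tracking fiber disorder.

## Layout

```
src/psoct/
  phantom.py       layered-sample specs, Jones forward model, fiber images
  polarization.py  Stokes, retardation, optic axis, DOPU, unwrap, local Δn
  profiles.py      depth profiles, disorder metrics, group statistics
  orientation.py   structure-tensor orientation histograms
  io.py            YAML specs, TIFF volumes + JSON sidecars, CSV tables
  cli.py           thin click CLI over the above
docs/methods.md    model assumptions, parameter defaults, design choices
examples/          one narrative script per capability
```
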