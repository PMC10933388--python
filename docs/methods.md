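# Methods

## Forward model

The simulator implements the classic single-input PS-OCT scheme: circularly
polarized light illuminates the sample and the backscattered field is
detected in two orthogonal polarization channels.  For a stack of linear
retarders, the detected Jones vector at depth z is modeled as

    a0(z) = g·r(z)·cos δ(z)
    a1(z) = g·r(z)·sin δ(z)·exp(2iθ(z))

with δ(z) = (2π/λ)·∫₀ᶻ Δn dz′ the cumulative **single-pass** phase
retardation through the layer stack, r(z) the layer reflectivity, θ(z) the
local fast-axis orientation and g a per-pixel speckle factor.  The
measured amplitude ratio arctan(|a1|/|a0|) then equals δ(z) independent of
θ, and the fast axis appears as the 2θ phase difference between channels —
the standard axis encoding of circular-input dual-detector instruments.

Assumptions and simplifications:

* single scattering, no dispersion, no confocal point-spread function;
* layer axes enter through the *local* θ(z) only — the non-commuting Jones
  product of layers with different axes is not modeled, so δ(z) is a scalar
  accumulation.  This is exact for co-aligned stacks and a controlled
  approximation for the small axis jitter used in the phantoms;
* the incident polarization state of the emulated commercial instrument is
  not disclosed anywhere we could verify; circular input is assumed because
  it makes the measured retardation axis-independent, matching the defined
  [0, π/2] fold behaviour.

**Speckle** is multiplicative complex circular-Gaussian, *common to both
channels*: it modulates amplitude and phase jointly but preserves the
polarization state, which is why polarization-preserving layers keep DOPU
near 1 under fully developed speckle.  With speckle enabled the pointwise
energy is r²·|g|²; with `speckle=False` it is exactly r², and in both cases
total detected energy is invariant under polarization rotation (verified in
tests by comparing same-seed simulations of different birefringence).

**Depolarization**: each layer's `depol_fraction` f replaces a fraction of
the pixel energy with an independent random polarization state
(energy-matched complex Gaussian channels), giving mean DOPU that decreases
monotonically in f.  **Detector noise** is additive complex Gaussian with
std `noise_sigma × max|a|` per channel.

All randomness flows through one `numpy.random.default_rng(seed)` per
simulation call; simulation and deformation are pure functions of
(arguments, seed).

## Optic-axis reading

The axis formula is the half-angle two-argument arctangent of a pair of
Stokes components.  `compute_optic_axis` offers two pairings:

* `pair="qu"` — ½·atan2(U, Q), the conventional printed form, appropriate
  when the detection basis maps the axis azimuth into the (Q, U) plane;
* `pair="uv"` — ½·atan2(U, −V) read on the transverse pair, used by the
  pipeline default.

The choice is forced by geometry, not taste: with circular illumination and
the channel-derived Stokes convention used here (Q = |a1|² − |a0|²), Q is
pointwise pinned to the retardation (Q = −I·cos 2δ) and carries no axis
information; the axis azimuth lives entirely in the inter-channel phase,
i.e. in (U, V).  Applying the half-angle formula to (U, −V) recovers the
simulator's ground-truth fast axis to within 2° (circular mean, modulo π).

## Retardation, unwrapping and local birefringence

Retardation defaults to the amplitude-ratio reading arctan(|a1|/|a0|),
which is linear in depth for a homogeneous slab and consistent with the
slope definition of Δn; the literal intensity-ratio variant
arctan(I1/I0-style) is available via `mode="intensity"`.  Zero-intensity
pixels receive a configurable fill value and are counted in debug logs.

Confinement to [0, π/2] folds the cumulative retardation into a triangle
wave.  `unwrap_retardation` reconstructs δ_cum globally: fold events are
located as turning points of the lightly smoothed profile with prominence
≥ 25% of π/2 (robust to the noise floor, which rounds real folds well below
π/2), then each fold sample's branch is refined by one-step linear
extrapolation.  On noiseless triangle waves the reconstruction is the exact
straight line; interior folds are always detected because the folded value
traverses the full [0, π/2] between consecutive folds.  A *trailing* partial
fold whose descent has not yet reached the prominence threshold is
inherently ambiguous and may be left unreflected — errors are confined to
the profile tail and bounded by the threshold, and the median-based Δn
summaries exclude profile edges for this reason.

Local birefringence applies Δn = (λ/2π)·dδ_cum/dz with the slope from an
ordinary least-squares line fit in a sliding window (Savitzky–Golay,
polyorder 1, default 15 px ≈ 52 μm; edge windows use the filter's
polynomial interpolation).  Negative slopes are clipped to zero.  For noisy
data, `compute_retardation_profile` first averages detector *intensities*
over the lateral ROI — δ(z) = arctan√(⟨I1⟩/⟨I0⟩) — so dark speckle pixels,
whose individual ratios are noise-dominated, do not bias the profile; slab
recovery is exact noiseless and within ~6–12% at 5% additive noise for
Δn ∈ {5e-4, 1e-3, 2e-3}.

## DOPU

Stokes components are normalized by I pointwise, box-averaged over a
kernel (default 8 × 8 px; zero-intensity pixels excluded from the
neighbourhood mean), and the Euclidean norm of the averaged vector is
clipped into [0, 1].  Neither a kernel size nor the normalization order is
standardized across instruments; normalize-then-average is the common
published definition and is what makes a uniform fully polarized field give
exactly 1.  For kernels of n independent uniformly random unit vectors the
root-mean-square DOPU is exactly 1/√n (3-D random-walk identity); the
*mean* carries the Maxwell-distribution factor ≈ 0.92/√n — tests assert the
RMS form.

## Depth profiles and disorder metrics

Profiles are per-depth mean ± population std over an explicit lateral ROI
(the ROI is a required input; no automatic selection).  Metrics are
computed on the mean curve within an analysis window, default 100–500 μm —
the band where OCT intensity attenuation is nearly flat in skin, so
polarization fluctuations reflect structure rather than signal decay:

* **avg_residual** — mean |data − fit| from a least-squares polynomial,
  default cubic (the functional family is a free choice, configurable;
  RMS available behind a flag);
* **num_peaks** — local maxima of the box-smoothed curve (default 5 px)
  with prominence ≥ 10% of the window's smoothed range; endpoints are never
  peaks, so a fold maximum within a few pixels of the window edge cannot
  establish prominence — a known edge effect;
* **range_value** — max − min over the window.

Group comparison: one-way ANOVA across all groups plus pairwise two-tailed
Welch t-tests against the first (control) group, uncorrected for
multiplicity, coded at 0.05/0.01/0.001.  Zero-variance pairs are flagged
degenerate with a NaN p-value: perfectly separated constant groups (e.g.
peak counts 2 vs 1 in every replicate) have no finite t statistic even
though the separation is maximal — downstream checks then fall back on
strict separation of the group ranges.

## Phantom defaults (documented constants)

| parameter | default | rationale |
|---|---|---|
| axial / lateral pixel | 3.5 / 7 μm | plausible spectral-domain geometry |
| wavelength λ | 1.3 μm | typical 1300 nm swept/SD source |
| tape layer | 50 μm, Δn = 2.2e-3 | ~0.05 mm tape layers; Δn in the range reported for polyethylene tapes, and placing two fold maxima (148, 443 μm) inside the analysis window of a 500 μm stack |
| deformation | jitter ×U(1±0.3), gaps 20 μm w.p. 0.5, axis jitter 0.2 rad | compression: disordered thicknesses, inter-layer gaps |
| epidermis | 60 μm, Δn = 2e-4, depol 0.15 | thin, weakly birefringent |
| dermis | 440 μm, 8 lamellae, Δn_max = 1.5e-3, depol 0.05 | collagen-dominated birefringence; lamellar ±25% modulation |
| hypodermis | Δn = 1e-4, depol 0.6 | strongly depolarizing, lowest DOPU |
| severity s | dermal Δn × (1 − 0.8·s); axis jitter 0.35·s rad | monotone collagen loss / disorganization; only trends, never absolute values, are asserted |

Severity-staged replicates in `dm_trend_report` use 10 replicates per stage
at 256 lateral A-lines by default in the acceptance checks — enough for the
group statistics to stabilize while keeping a full run in seconds.

## What the synthetic data does and does not show

The phantoms reproduce the *mechanisms* the analysis relies on: retardation
slope ↔ birefringence, fold geometry, axis encoding, DOPU degradation with
depolarization, and loss of profile structure with layer disorder.  They do
not reproduce real tissue's multiple scattering, axis heterogeneity with
depth, vascular shadowing, or system birefringence, and layer axes do not
couple through non-commuting Jones products.  Passing tests therefore
validate the processing chain and its closed-form behaviour, not any claim
about in-vivo effect sizes; no animal-derived numeric endpoints are
reproduced, since no such data are deposited.

## Orientation analysis

Local orientation is the minor-eigenvector direction of the
Gaussian-smoothed structure tensor (σ = 2 px), mapped to [0°, 180°) with 0°
horizontal and angles increasing counterclockwise.  The histogram (default
90 bins of 2°) weights pixels by gradient energy — not pixel counts — so
faint background does not dilute the fiber signal; pixels below 5% of the
maximum energy are excluded.  Disorder is summarized as the circular
variance on the doubled-angle circle, 1 − |Σ w·e^{2iθ}|/Σw.  The fiber
image generator applies a 0.8 px Gaussian blur before noise: without it,
rasterization stair-steps bias gradient orientations by a few degrees.
A flat image returns a uniform histogram with dispersion 1 and a warning.

## Known limitations

* The unwrap's trailing-fold ambiguity (above) biases Δn near the deep end
  of a profile; summaries exclude edges.
* Peak counting cannot credit maxima closer to the window edge than the
  smoothing/prominence support.
* The Δn *map* (per-A-line unwrap of per-pixel retardation) is
  speckle-noisy by construction; quantitative Δn should come from the
  ROI-averaged profile.
* Group p-values are uncorrected for multiple comparisons, mirroring common
  practice for this analysis style.
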