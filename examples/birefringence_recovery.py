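"""Local birefringence estimation from the cumulative retardation slope.

Simulates homogeneous slabs of known Δn, computes the speckle-robust
retardation depth profile, unwraps its [0, π/2] folds, and recovers Δn from
the windowed least-squares slope via Δn = (λ/2π)·dδ/dz.
"""

import numpy as np

from psoct import LayerSpec, PhantomSpec, simulate_tomogram
from psoct.polarization import compute_local_birefringence, compute_retardation_profile

print(f"{'true dn':>9} {'noise':>6} {'recovered':>10} {'rel err':>8}")
for dn_true in (5e-4, 1e-3, 2e-3):
    for noise in (0.0, 0.05):
        spec = PhantomSpec(
            layers=(LayerSpec(thickness_um=700.0, birefringence=dn_true),),
            seed=3, noise_sigma=noise,
        )
        tom = simulate_tomogram(spec)
        profile = compute_retardation_profile(tom)
        dn = compute_local_birefringence(
            profile, spec.wavelength_um, spec.axial_px_um, window_px=15
        )
        recovered = float(np.median(dn[15:-15]))
        rel = abs(recovered - dn_true) / dn_true
        print(f"{dn_true:9.1e} {noise:6.2f} {recovered:10.2e} {rel:7.1%}")

print(
    "\nRecovered Δn is the median of the per-depth estimate over the slab\n"
    "interior; noiseless recovery is exact to the axial sampling."
)
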