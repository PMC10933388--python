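"""Layered-tape phantom before and after compressive deformation.

Simulates a 10-layer birefringent tape stack (50 μm layers), deforms it
(thickness jitter, inter-layer gaps, fast-axis disorder), and compares the
retardation depth-profile disorder metrics.  Deformation dilutes the average
birefringence and shifts the retardation fold pattern, so the peak count in
the 100-500 μm analysis window drops.
"""

import numpy as np

from psoct import (
    deform_phantom,
    extract_profile,
    make_tape_phantom,
    profile_metrics,
    simulate_tomogram,
)
from psoct.polarization import compute_retardation

spec = make_tape_phantom(n_layers=10, layer_thickness_um=50.0, seed=0)
deformed = deform_phantom(
    spec, thickness_jitter_frac=0.3, gap_prob=0.5, gap_thickness_um=20.0,
    axis_jitter_rad=0.2, seed=1,
)

for label, s in (("undeformed", spec), ("deformed", deformed)):
    tom = simulate_tomogram(s)
    prof = extract_profile(
        compute_retardation(tom), (0, s.lateral_px), s.axial_px_um,
        parameter_name="retardation",
    )
    m = profile_metrics(prof)
    print(
        f"{label:>11}: {len(s.layers):2d} layers, "
        f"total {s.total_thickness_um:6.1f} um | "
        f"peaks={m.num_peaks}, range={m.range_value:.3f} rad, "
        f"avg residual={m.avg_residual:.3f} rad"
    )

print(
    "\nFewer retardation peaks and a changed fluctuation amplitude after\n"
    "deformation indicate loss of the ordered layer structure."
)
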