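"""Collagen-fiber orientation histograms from texture images.

Generates synthetic fiber textures with increasing angular spread around a
40° mean orientation and summarizes each with the structure-tensor
orientation histogram and its circular dispersion statistic (0 = perfectly
aligned, → 1 = isotropic).
"""

from psoct import make_fiber_image, orientation_histogram

print(f"{'spread (deg)':>12} {'modal (deg)':>12} {'dispersion':>11}")
for spread in (0.0, 15.0, 45.0, 90.0):
    img = make_fiber_image(
        mean_angle_deg=40.0, dispersion_deg=spread, n_fibers=150,
        size_px=256, seed=2,
    )
    hist = orientation_histogram(img, n_bins=90)
    print(f"{spread:12.0f} {hist.modal_angle_deg:12.1f} {hist.dispersion:11.3f}")

print(
    "\nThe dispersion statistic tracks the generator's angular spread:\n"
    "ordered textures keep a sharp modal bin near 40 deg, disordered ones\n"
    "approach a uniform histogram."
)
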