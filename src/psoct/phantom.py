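"""Synthetic dual-detector PS-OCT tomograms of layered birefringent samples.

The forward model is the classic single-input polarization-sensitive OCT
scheme: circularly polarized light illuminates the sample, and the
backscattered field is split onto two orthogonal detectors.  For a stack of
linear retarders the co-polarized channel carries ``r(z)·cos δ(z)`` and the
cross-polarized channel ``r(z)·sin δ(z)``, where ``δ(z) = (2π/λ)·∫ Δn dz`` is
the accumulated single-pass phase retardation and ``r(z)`` the local
reflectivity.  The fast-axis orientation θ of the layer enters as a ``2θ``
phase offset between the channels, which is how a real dual-detector system
encodes the optic axis.

Two phantom families are provided: a multi-layer adhesive-tape stack (a
standard birefringent layer phantom, with a compressive "deformation" that
jitters thicknesses, inserts gaps and disorders fast axes) and a three-stratum
skin phantom (epidermis / dermis / hypodermis) whose dermal collagen order
degrades with a disease-severity parameter.  A separate generator renders
grayscale fiber-texture images for orientation analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from skimage.draw import line_aa

__all__ = [
    "LayerSpec",
    "PhantomSpec",
    "DualChannelTomogram",
    "make_tape_phantom",
    "deform_phantom",
    "make_skin_phantom",
    "simulate_tomogram",
    "make_fiber_image",
]


@dataclass(frozen=True)
class LayerSpec:
    """One homogeneous birefringent layer.

    Parameters
    ----------
    thickness_um : float
        Physical thickness in micrometres; must be > 0.
    birefringence : float
        Index difference Δn between fast and slow axes (dimensionless, ≥ 0).
    fast_axis_rad : float
        Fast-axis orientation in radians, interpreted modulo π.
    scatter_amp : float
        Backscattered amplitude (arbitrary units, ≥ 0).
    depol_fraction : float
        Fraction of per-pixel energy replaced by a random polarization state;
        0 preserves polarization uniformity, 1 fully depolarizes.
    axis_jitter_rad : float
        Standard deviation of lateral fast-axis disorder within the layer.
    """

    thickness_um: float
    birefringence: float = 0.0
    fast_axis_rad: float = 0.0
    scatter_amp: float = 1.0
    depol_fraction: float = 0.0
    axis_jitter_rad: float = 0.0

    def __post_init__(self) -> None:
        if not self.thickness_um > 0:
            raise ValueError(f"layer thickness must be > 0, got {self.thickness_um}")
        if self.birefringence < 0:
            raise ValueError(f"birefringence must be >= 0, got {self.birefringence}")
        if not 0.0 <= self.depol_fraction <= 1.0:
            raise ValueError(
                f"depol_fraction must be in [0, 1], got {self.depol_fraction}"
            )
        if self.scatter_amp < 0:
            raise ValueError(f"scatter_amp must be >= 0, got {self.scatter_amp}")
        if self.axis_jitter_rad < 0:
            raise ValueError(f"axis_jitter_rad must be >= 0, got {self.axis_jitter_rad}")


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of a layered sample plus acquisition geometry.

    The axial extent of the simulated tomogram is derived from the total stack
    thickness (``ceil(total / axial_px_um)`` pixels), so the stack always fits
    the output.  ``noise_sigma`` is the std of additive complex Gaussian
    detector noise relative to the maximum signal amplitude.  ``speckle``
    toggles multiplicative complex circular-Gaussian speckle (common to both
    channels, hence polarization preserving).
    """

    layers: tuple[LayerSpec, ...]
    lateral_px: int = 256
    axial_px_um: float = 3.5
    lateral_px_um: float = 7.0
    wavelength_um: float = 1.3
    noise_sigma: float = 0.0
    seed: int = 0
    speckle: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if len(self.layers) == 0:
            raise ValueError("PhantomSpec requires at least one layer")
        if self.lateral_px < 1:
            raise ValueError("lateral_px must be >= 1")
        if not self.wavelength_um > 0:
            raise ValueError("wavelength_um must be > 0")
        if not self.axial_px_um > 0 or not self.lateral_px_um > 0:
            raise ValueError("pixel spacings must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def total_thickness_um(self) -> float:
        return float(sum(l.thickness_um for l in self.layers))

    @property
    def n_axial(self) -> int:
        return int(math.ceil(self.total_thickness_um / self.axial_px_um))


@dataclass
class DualChannelTomogram:
    """Co-registered complex fields from the two polarization detectors.

    ``a0`` is the co-polarized (detector-0, horizontal) channel and ``a1`` the
    cross-polarized (detector-1, vertical) channel, each of shape
    (depth, lateral).
    """

    a0: np.ndarray
    a1: np.ndarray
    axial_px_um: float
    wavelength_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.a0 = np.asarray(self.a0)
        self.a1 = np.asarray(self.a1)
        if self.a0.shape != self.a1.shape:
            raise ValueError(
                f"channel shapes differ: {self.a0.shape} vs {self.a1.shape}"
            )
        if not self.axial_px_um > 0:
            raise ValueError("axial_px_um must be > 0")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.a0.shape

    def depth_um(self) -> np.ndarray:
        """Depth of each pixel centre below the surface, in μm."""
        return (np.arange(self.a0.shape[0]) + 0.5) * self.axial_px_um


def make_tape_phantom(
    n_layers: int,
    layer_thickness_um: float = 50.0,
    birefringence: float = 2.2e-3,
    seed: int = 0,
    **geometry,
) -> PhantomSpec:
    """Multi-layer adhesive-tape phantom: identical ordered birefringent layers.

    Defaults follow the standard tape phantom: ~0.05 mm per layer, with a
    birefringence in the range reported for polyethylene tapes.  All layers
    share a fixed fast axis and are fully polarization preserving.
    """
    if n_layers < 1:
        raise ValueError(f"n_layers must be >= 1, got {n_layers}")
    if not layer_thickness_um > 0:
        raise ValueError("layer_thickness_um must be > 0")
    layer = LayerSpec(
        thickness_um=float(layer_thickness_um),
        birefringence=float(birefringence),
        fast_axis_rad=0.0,
        scatter_amp=1.0,
        depol_fraction=0.0,
        axis_jitter_rad=0.0,
    )
    return PhantomSpec(layers=(layer,) * int(n_layers), seed=int(seed), **geometry)


def deform_phantom(
    spec: PhantomSpec,
    thickness_jitter_frac: float,
    gap_prob: float,
    gap_thickness_um: float = 20.0,
    axis_jitter_rad: float = 0.0,
    seed: int = 0,
    gap_scatter_amp: float = 0.3,
) -> PhantomSpec:
    """Compression-deformed copy of a layered phantom.

    Layer thicknesses are multiplied by independent uniform draws from
    ``[1 − j, 1 + j]``, a zero-birefringence gap layer of ``gap_thickness_um``
    is inserted after each layer with probability ``gap_prob``, and each fast
    axis is perturbed by centred Gaussian noise of std ``axis_jitter_rad``.
    The input spec is not modified.
    """
    if not 0.0 <= thickness_jitter_frac <= 1.0:
        raise ValueError("thickness_jitter_frac must be in [0, 1]")
    if not 0.0 <= gap_prob <= 1.0:
        raise ValueError(f"gap_prob must be in [0, 1], got {gap_prob}")
    if gap_prob > 0 and not gap_thickness_um > 0:
        raise ValueError("gap_thickness_um must be > 0")

    rng = np.random.default_rng(seed)
    new_layers: list[LayerSpec] = []
    for layer in spec.layers:
        factor = 1.0 + thickness_jitter_frac * rng.uniform(-1.0, 1.0)
        axis = layer.fast_axis_rad + (
            rng.normal(0.0, axis_jitter_rad) if axis_jitter_rad > 0 else 0.0
        )
        new_layers.append(
            replace(layer, thickness_um=layer.thickness_um * factor, fast_axis_rad=axis)
        )
        if rng.uniform() < gap_prob:
            new_layers.append(
                LayerSpec(
                    thickness_um=float(gap_thickness_um),
                    birefringence=0.0,
                    fast_axis_rad=0.0,
                    scatter_amp=gap_scatter_amp,
                    depol_fraction=0.0,
                    axis_jitter_rad=0.0,
                )
            )
    return replace(spec, layers=tuple(new_layers))


# Skin-stratum defaults.  Thicknesses and birefringence magnitudes are
# documented package constants chosen to be plausible for mouse dorsal skin at
# 1300 nm; only monotone trends with severity are ever asserted.
EPIDERMIS_THICKNESS_UM = 60.0
DERMIS_THICKNESS_UM = 440.0
DERMAL_DN_MAX = 1.5e-3
DERMAL_DN_FLOOR_FRAC = 0.2  # dermal Δn at severity 1, as a fraction of max
DERMAL_AXIS_JITTER_MAX = 0.35  # rad, at severity 1
N_DERMAL_LAMELLAE = 8


def make_skin_phantom(
    severity: float,
    seed: int = 0,
    *,
    lateral_px: int = 256,
    noise_sigma: float = 0.02,
) -> PhantomSpec:
    """Three-stratum skin phantom with a diabetes-severity dial in [0, 1].

    Epidermis: thin, weakly birefringent, moderately depolarizing.
    Dermis: thick, strongly birefringent collagen lamellae, weakly
    depolarizing; its birefringence decreases and its fast-axis lateral
    disorder increases monotonically with ``severity`` (collagen loss and
    disorganization).
    Hypodermis: weakly birefringent and strongly depolarizing, so its DOPU is
    lower than that of epidermis and dermis.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError(f"severity must be in [0, 1], got {severity}")

    dermal_dn = DERMAL_DN_MAX * (1.0 - (1.0 - DERMAL_DN_FLOOR_FRAC) * severity)
    dermal_jitter = DERMAL_AXIS_JITTER_MAX * severity

    epidermis = LayerSpec(
        thickness_um=EPIDERMIS_THICKNESS_UM,
        birefringence=2e-4,
        fast_axis_rad=0.0,
        scatter_amp=1.0,
        depol_fraction=0.15,
        axis_jitter_rad=0.05,
    )
    # Dermis as alternating collagen lamellae around the severity-scaled mean.
    lamella_t = DERMIS_THICKNESS_UM / N_DERMAL_LAMELLAE
    dermis = tuple(
        LayerSpec(
            thickness_um=lamella_t,
            birefringence=dermal_dn * (1.25 if k % 2 == 0 else 0.75),
            fast_axis_rad=0.0,
            scatter_amp=1.2,
            depol_fraction=0.05,
            axis_jitter_rad=dermal_jitter,
        )
        for k in range(N_DERMAL_LAMELLAE)
    )
    hypodermis = LayerSpec(
        thickness_um=1292.0,
        birefringence=1e-4,
        fast_axis_rad=0.0,
        scatter_amp=0.5,
        depol_fraction=0.6,
        axis_jitter_rad=0.2,
    )
    return PhantomSpec(
        layers=(epidermis,) + dermis + (hypodermis,),
        lateral_px=lateral_px,
        noise_sigma=noise_sigma,
        seed=int(seed),
    )


def dermal_layers(spec: PhantomSpec) -> tuple[LayerSpec, ...]:
    """The dermal lamellae of a skin phantom (layers 1 .. N_DERMAL_LAMELLAE)."""
    return spec.layers[1 : 1 + N_DERMAL_LAMELLAE]


def _cumulative_retardation(spec: PhantomSpec, z_um: np.ndarray) -> np.ndarray:
    """Single-pass phase retardation δ(z) = (2π/λ)·∫0^z Δn dz' at each depth."""
    tops = np.concatenate(
        [[0.0], np.cumsum([l.thickness_um for l in spec.layers])]
    )
    dn = np.array([l.birefringence for l in spec.layers])
    # optical retardance accumulated at the top of each layer
    cum_at_top = np.concatenate([[0.0], np.cumsum(dn * np.diff(tops))])
    idx = np.clip(np.searchsorted(tops, z_um, side="right") - 1, 0, len(dn) - 1)
    opd = cum_at_top[idx] + dn[idx] * (z_um - tops[idx])
    return (2.0 * np.pi / spec.wavelength_um) * opd


def _layer_index(spec: PhantomSpec, z_um: np.ndarray) -> np.ndarray:
    tops = np.concatenate(
        [[0.0], np.cumsum([l.thickness_um for l in spec.layers])]
    )
    return np.clip(
        np.searchsorted(tops, z_um, side="right") - 1, 0, len(spec.layers) - 1
    )


def simulate_tomogram(spec: PhantomSpec) -> DualChannelTomogram:
    """Render a dual-detector B-scan of a layered phantom.

    Per pixel, the co-channel amplitude is ``g·r·cos δ`` and the cross-channel
    ``g·r·sin δ·exp(2iθ)``, with ``g`` the (optional) common-mode speckle
    field, ``r`` the layer reflectivity, ``δ`` the cumulative single-pass
    retardation and ``θ`` the local fast axis.  A layer's ``depol_fraction``
    blends in an energy-matched random polarization state, and additive complex
    Gaussian detector noise of std ``noise_sigma·max|a|`` is applied last.
    Bit-deterministic given ``spec`` (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    n_z, n_x = spec.n_axial, spec.lateral_px
    z = (np.arange(n_z) + 0.5) * spec.axial_px_um

    delta = _cumulative_retardation(spec, z)
    lidx = _layer_index(spec, z)
    r = np.array([l.scatter_amp for l in spec.layers])[lidx]
    f = np.array([l.depol_fraction for l in spec.layers])[lidx]

    # Lateral fast-axis disorder: one draw per (layer, lateral position).
    axis0 = np.array([l.fast_axis_rad for l in spec.layers])
    jitter_sd = np.array([l.axis_jitter_rad for l in spec.layers])
    layer_axis = axis0[:, None] + jitter_sd[:, None] * rng.standard_normal(
        (len(spec.layers), n_x)
    )
    theta = layer_axis[lidx, :]  # (n_z, n_x)

    if spec.speckle:
        g = (
            rng.standard_normal((n_z, n_x)) + 1j * rng.standard_normal((n_z, n_x))
        ) / np.sqrt(2.0)
    else:
        g = np.ones((n_z, n_x), dtype=complex)

    amp = r[:, None] * g
    a0 = amp * np.cos(delta)[:, None]
    a1 = amp * np.sin(delta)[:, None] * np.exp(2j * theta)

    if np.any(f > 0):
        h0 = (
            rng.standard_normal((n_z, n_x)) + 1j * rng.standard_normal((n_z, n_x))
        ) / 2.0
        h1 = (
            rng.standard_normal((n_z, n_x)) + 1j * rng.standard_normal((n_z, n_x))
        ) / 2.0
        fz = f[:, None]
        a0 = np.sqrt(1.0 - fz) * a0 + np.sqrt(fz) * r[:, None] * h0
        a1 = np.sqrt(1.0 - fz) * a1 + np.sqrt(fz) * r[:, None] * h1

    if spec.noise_sigma > 0:
        amax = max(np.abs(a0).max(), np.abs(a1).max())
        sigma = spec.noise_sigma * amax
        a0 = a0 + sigma * (
            rng.standard_normal((n_z, n_x)) + 1j * rng.standard_normal((n_z, n_x))
        ) / np.sqrt(2.0)
        a1 = a1 + sigma * (
            rng.standard_normal((n_z, n_x)) + 1j * rng.standard_normal((n_z, n_x))
        ) / np.sqrt(2.0)

    meta = {
        "seed": spec.seed,
        "n_layers": len(spec.layers),
        "total_thickness_um": spec.total_thickness_um,
        "noise_sigma": spec.noise_sigma,
        "speckle": spec.speckle,
    }
    return DualChannelTomogram(
        a0=a0,
        a1=a1,
        axial_px_um=spec.axial_px_um,
        wavelength_um=spec.wavelength_um,
        meta=meta,
    )


def fold_maxima_depths_um(
    spec_or_dn, wavelength_um: float | None = None, max_depth_um: float | None = None
) -> np.ndarray:
    """Analytic depths of folded-retardation maxima for a homogeneous slab.

    Maxima of the measured (folded into [0, π/2]) retardation occur where the
    cumulative single-pass retardation δ(z) = (2π/λ)Δn·z crosses odd multiples
    of π/2, i.e. at ``z_k = (2k−1)·λ/(4Δn)``; successive maxima are λ/(2Δn)
    apart and successive extrema λ/(4Δn) apart.
    """
    if isinstance(spec_or_dn, PhantomSpec):
        spec = spec_or_dn
        dns = {l.birefringence for l in spec.layers}
        if len(dns) != 1:
            raise ValueError("closed form requires a homogeneous slab")
        dn = dns.pop()
        wavelength_um = spec.wavelength_um
        max_depth_um = spec.total_thickness_um
    else:
        dn = float(spec_or_dn)
    if dn <= 0:
        return np.array([])
    spacing = wavelength_um / (2.0 * dn)
    first = wavelength_um / (4.0 * dn)
    return np.arange(first, max_depth_um, spacing)


def make_fiber_image(
    mean_angle_deg: float,
    dispersion_deg: float,
    n_fibers: int = 150,
    size_px: int = 256,
    seed: int = 0,
    noise_sigma: float = 0.05,
    blur_sigma: float = 0.8,
) -> np.ndarray:
    """Grayscale texture of anti-aliased fiber segments for orientation tests.

    Fiber orientations are drawn from a normal of std ``dispersion_deg``
    around ``mean_angle_deg`` and interpreted modulo 180°; 0° is the image
    horizontal axis, angles increase counterclockwise (y up).  A slight
    Gaussian blur (``blur_sigma`` px) suppresses rasterization stair-steps
    that would otherwise bias gradient orientations.  Deterministic given
    ``seed``.
    """
    if dispersion_deg < 0:
        raise ValueError("dispersion_deg must be >= 0")
    if size_px < 16:
        raise ValueError("size_px must be >= 16")
    rng = np.random.default_rng(seed)
    img = np.zeros((size_px, size_px), dtype=float)
    for _ in range(int(n_fibers)):
        ang = math.radians(mean_angle_deg + rng.normal(0.0, dispersion_deg))
        # CCW-with-y-up angle -> image (row, col) direction; rows grow downward.
        dc, dr = math.cos(ang), -math.sin(ang)
        r0 = rng.uniform(0, size_px - 1)
        c0 = rng.uniform(0, size_px - 1)
        half = rng.uniform(0.15, 0.35) * size_px
        # Clip the segment to the image parametrically so the drawn direction
        # is exactly the sampled orientation even near the borders.
        t_lo, t_hi = -half, half
        for x0, dx in ((r0, dr), (c0, dc)):
            if abs(dx) < 1e-12:
                continue
            t0 = (0.0 - x0) / dx
            t1 = (size_px - 1.0 - x0) / dx
            t_lo = max(t_lo, min(t0, t1))
            t_hi = min(t_hi, max(t0, t1))
        if t_hi - t_lo < 2.0:
            continue
        rr0 = int(round(r0 + t_lo * dr))
        cc0 = int(round(c0 + t_lo * dc))
        rr1 = int(round(r0 + t_hi * dr))
        cc1 = int(round(c0 + t_hi * dc))
        rr, cc, val = line_aa(rr0, cc0, rr1, cc1)
        img[rr, cc] += val * rng.uniform(0.5, 1.0)
    if blur_sigma > 0:
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(img, blur_sigma)
    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, img.shape)
    return np.clip(img, 0.0, None)
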