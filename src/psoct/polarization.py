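"""Polarization parameters of a dual-detector PS-OCT tomogram.

From the two complex detector channels ``a0`` (co-polarized, horizontal) and
``a1`` (cross-polarized, vertical) this module computes:

* the Stokes field ``(I, Q, U, V)`` in the sign convention where horizontal
  light has Q = −1, vertical Q = +1, 45°-linear U = −1, 135°-linear U = +1 and
  left-circular V = −1;
* retardation ``arctan(|a1|/|a0|) ∈ [0, π/2]`` — the amplitude-ratio reading,
  which equals the single-pass phase retardation of a retarder sample and
  grows linearly with depth in a homogeneous slab (an intensity-ratio variant
  is available behind a switch);
* the optic axis ``½·atan2(·,·) ∈ [−π/2, π/2]``, evaluated either on (U, Q)
  as conventionally printed, or on the transverse pair (U, −V) appropriate for
  circular-input dual-detector data, where the fast axis is encoded in the
  inter-channel phase (see ``compute_optic_axis``);
* DOPU, the norm of the box-averaged intensity-normalized Stokes components,
  in [0, 1];
* local birefringence Δn = (λ/2π)·dδ_cum/dz, from a triangle-wave unwrap of
  the folded retardation followed by a sliding-window least-squares slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.signal import savgol_filter

from .phantom import DualChannelTomogram

__all__ = [
    "StokesField",
    "PolarizationMaps",
    "compute_stokes",
    "compute_retardation",
    "compute_optic_axis",
    "compute_dopu",
    "unwrap_retardation",
    "compute_local_birefringence",
    "compute_polarization_maps",
]

log = logging.getLogger(__name__)

HALF_PI = np.pi / 2.0


@dataclass
class StokesField:
    """Pointwise Stokes parameters I, Q, U, V over (depth, lateral)."""

    i: np.ndarray
    q: np.ndarray
    u: np.ndarray
    v: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {np.shape(c) for c in (self.i, self.q, self.u, self.v)}
        if len(shapes) != 1:
            raise ValueError(f"Stokes components must share one shape, got {shapes}")

    @property
    def shape(self) -> tuple[int, ...]:
        return np.shape(self.i)


@dataclass
class PolarizationMaps:
    """The four derived parameter maps plus acquisition scale factors."""

    retardation: np.ndarray
    optic_axis: np.ndarray
    dopu: np.ndarray
    local_birefringence: np.ndarray
    axial_px_um: float
    wavelength_um: float
    meta: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "retardation": self.retardation,
            "optic_axis": self.optic_axis,
            "dopu": self.dopu,
            "local_birefringence": self.local_birefringence,
        }


def compute_stokes(tom: DualChannelTomogram) -> StokesField:
    """Stokes field of the detected light.

    I = |a0|² + |a1|², Q = |a1|² − |a0|² (detector-0 horizontal, Q = −1),
    U = 2·Re(a0·conj(a1)), V = 2·Im(a0·conj(a1)).  I equals the total detected
    intensity exactly, and Q² + U² + V² = I² pointwise (each pixel is a pure
    polarization state before any spatial averaging).
    """
    a0, a1 = tom.a0, tom.a1
    i0 = np.abs(a0) ** 2
    i1 = np.abs(a1) ** 2
    cross = a0 * np.conj(a1)
    return StokesField(
        i=i0 + i1,
        q=i1 - i0,
        u=2.0 * np.real(cross),
        v=2.0 * np.imag(cross),
        meta={"axial_px_um": tom.axial_px_um, "wavelength_um": tom.wavelength_um},
    )


def compute_retardation(
    tom: DualChannelTomogram, mode: str = "amplitude", fill: float = 0.0
) -> np.ndarray:
    """Folded phase retardation in [0, π/2] from the channel ratio.

    ``mode="amplitude"`` (default) returns arctan(|a1|/|a0|), which equals the
    single-pass retardation δ(z) of a retarder sample; ``mode="intensity"``
    returns the literal intensity-ratio variant arctan(I1/I0).  Pixels where
    both channels vanish get ``fill`` (their count is logged).
    """
    m0 = np.abs(tom.a0)
    m1 = np.abs(tom.a1)
    if mode == "amplitude":
        ret = np.arctan2(m1, m0)
    elif mode == "intensity":
        ret = np.arctan2(m1**2, m0**2)
    else:
        raise ValueError(f"unknown retardation mode {mode!r}")
    dead = (m0 == 0) & (m1 == 0)
    n_dead = int(dead.sum())
    if n_dead:
        log.debug("retardation: %d zero-intensity pixels filled with %g", n_dead, fill)
        ret = np.where(dead, fill, ret)
    return ret


def compute_retardation_profile(
    tom: DualChannelTomogram, roi_lateral: tuple[int, int] | None = None
) -> np.ndarray:
    """Speckle-robust retardation depth profile over a lateral ROI.

    Averages the detector intensities laterally before taking the amplitude
    ratio, δ(z) = arctan√(⟨I1⟩/⟨I0⟩), so dark speckle pixels (whose per-pixel
    ratio is noise dominated) do not bias the profile.  This is the preferred
    input for slope-based birefringence estimation on noisy data.
    """
    lo, hi = (0, tom.shape[1]) if roi_lateral is None else roi_lateral
    i0 = (np.abs(tom.a0[:, lo:hi]) ** 2).mean(axis=1)
    i1 = (np.abs(tom.a1[:, lo:hi]) ** 2).mean(axis=1)
    return np.arctan2(np.sqrt(i1), np.sqrt(i0))


def compute_optic_axis(
    st: StokesField, pair: str = "qu", fill: float = 0.0
) -> np.ndarray:
    """Fast-axis orientation map, ½·atan2(·,·) ∈ [−π/2, π/2].

    ``pair="qu"`` evaluates ½·atan2(U, Q), the conventional printed form,
    appropriate when the detection scheme maps the axis azimuth into the
    (Q, U) plane.  For circular-input dual-detector data Q is pinned to the
    retardation (Q = −I·cos 2δ) and carries no axis information; there the
    axis lives in the inter-channel phase, i.e. in the transverse Stokes pair,
    and ``pair="uv"`` evaluates the same half-angle formula on (U, −V), which
    recovers the sample fast axis.  Degenerate pixels (both arguments zero)
    get ``fill``.
    """
    if pair == "qu":
        y, x = st.u, st.q
    elif pair == "uv":
        y, x = -np.asarray(st.v), st.u
    else:
        raise ValueError(f"unknown optic-axis pair {pair!r}")
    axis = 0.5 * np.arctan2(y, x)
    dead = (np.asarray(y) == 0) & (np.asarray(x) == 0)
    if np.any(dead):
        log.debug("optic axis: %d degenerate pixels filled with %g", dead.sum(), fill)
        axis = np.where(dead, fill, axis)
    return axis


def compute_dopu(st: StokesField, kernel_z: int = 8, kernel_x: int = 8) -> np.ndarray:
    """Degree of polarization uniformity: ‖⟨(Q,U,V)/I⟩‖ over a box kernel.

    Stokes components are normalized by I pointwise before averaging;
    zero-intensity pixels are excluded from the neighbourhood mean.  Output is
    clipped into [0, 1].
    """
    if kernel_z < 1 or kernel_x < 1:
        raise ValueError("kernel dimensions must be >= 1")
    i = np.asarray(st.i, dtype=float)
    if i.ndim != 2:
        raise ValueError("DOPU expects a 2-D (depth, lateral) field")
    if kernel_z > i.shape[0] or kernel_x > i.shape[1]:
        raise ValueError(
            f"kernel {(kernel_z, kernel_x)} larger than field {i.shape}"
        )
    valid = i > 0
    inv = np.where(valid, 1.0 / np.where(valid, i, 1.0), 0.0)
    size = (kernel_z, kernel_x)
    wsum = uniform_filter(valid.astype(float), size=size, mode="nearest")
    acc = 0.0
    for comp in (st.q, st.u, st.v):
        nc = uniform_filter(np.asarray(comp) * inv, size=size, mode="nearest")
        acc = acc + nc**2
    with np.errstate(invalid="ignore", divide="ignore"):
        dopu = np.sqrt(acc) / wsum
    dopu = np.where(wsum > 0, dopu, 0.0)
    return np.clip(dopu, 0.0, 1.0)


def unwrap_retardation(
    ret_profile: np.ndarray,
    prominence_frac: float = 0.25,
    smooth_px: int = 3,
) -> np.ndarray:
    """Cumulative retardation from a folded [0, π/2] profile.

    The folded profile of a sample with nondecreasing cumulative retardation
    is a triangle wave reflected at the 0 and π/2 boundaries.  Fold events are
    located globally as turning points of the (lightly smoothed) profile with
    prominence ≥ ``prominence_frac·π/2`` — robust against the noise-floor
    rounding that keeps real folds below π/2 — then each boundary sample's
    branch is refined by linear extrapolation so a noiseless triangle wave
    reconstructs to the exact straight line.  A profile that never reaches a
    boundary is returned unchanged; the output is nondecreasing for any
    profile generated by a stack of nonnegative-birefringence layers.
    """
    from scipy.signal import find_peaks as _find_peaks

    r = np.asarray(ret_profile, dtype=float)
    if r.ndim != 1:
        raise ValueError("unwrap_retardation expects a 1-D profile")
    tol = 1e-6
    if r.size and (r.min() < -tol or r.max() > HALF_PI + tol):
        raise ValueError("retardation values must lie in [0, pi/2]")
    r = np.clip(r, 0.0, HALF_PI)
    n = r.size
    out = np.empty_like(r)
    if n == 0:
        return out
    if n < 3:
        out[:] = r
        return out

    rs = uniform_filter(r, size=max(int(smooth_px), 1), mode="nearest")
    prom = prominence_frac * HALF_PI
    tops, _ = _find_peaks(rs, prominence=prom)
    bottoms, _ = _find_peaks(-rs, prominence=prom)
    # refine each event to the raw-profile extremum nearby
    events: list[tuple[int, str]] = []
    for t in tops:
        lo, hi = max(t - 2, 0), min(t + 3, n)
        events.append((lo + int(np.argmax(r[lo:hi])), "top"))
    for t in bottoms:
        lo, hi = max(t - 2, 0), min(t + 3, n)
        events.append((lo + int(np.argmin(r[lo:hi])), "bottom"))
    events.sort()
    event_at = dict(events)

    parity = 1 if events and events[0][1] == "bottom" else 0
    base = 0.0
    out[0] = base + r[0] if parity == 0 else base + np.pi - r[0]
    pending: str | None = None  # fold kind to apply starting at the next sample
    for j in range(1, n):
        if pending == "top":
            parity, pending = 1, None
        elif pending == "bottom":
            parity, base, pending = 0, base + np.pi, None
        kind = event_at.get(j)
        expected = "top" if parity == 0 else "bottom"
        if kind == expected:
            if parity == 0:
                cand_same, cand_new = base + r[j], base + np.pi - r[j]
            else:
                cand_same, cand_new = base + np.pi - r[j], base + np.pi + r[j]
            pred = 2.0 * out[j - 1] - out[j - 2] if j >= 2 else out[j - 1]
            if abs(cand_new - pred) < abs(cand_same - pred):
                # the extremum sample already lies past the fold
                if parity == 0:
                    parity = 1
                else:
                    parity, base = 0, base + np.pi
                out[j] = cand_new
            else:
                out[j] = cand_same
                pending = kind
            continue
        out[j] = base + r[j] if parity == 0 else base + np.pi - r[j]
    return out


def compute_local_birefringence(
    ret: np.ndarray,
    wavelength_um: float,
    axial_px_um: float,
    window_px: int = 15,
) -> np.ndarray:
    """Local birefringence Δn = (λ/2π)·dδ_cum/dz per pixel.

    Each A-line of the folded retardation field is unwrapped, the local slope
    is estimated by an ordinary least-squares line fit in a sliding window of
    ``window_px`` samples (edge samples use a polynomial-extrapolated window),
    and the slope is scaled by λ/2π.  Negative slopes are clipped to zero.
    """
    if window_px < 3:
        raise ValueError("window_px must be >= 3")
    r = np.asarray(ret, dtype=float)
    one_d = r.ndim == 1
    if one_d:
        r = r[:, None]
    n_z = r.shape[0]
    if window_px > n_z:
        raise ValueError(f"window_px={window_px} exceeds depth extent {n_z}")
    win = window_px if window_px % 2 == 1 else window_px + 1
    win = min(win, n_z if n_z % 2 == 1 else n_z - 1)
    cum = np.empty_like(r)
    for x in range(r.shape[1]):
        cum[:, x] = unwrap_retardation(r[:, x])
    slope = savgol_filter(
        cum, window_length=win, polyorder=1, deriv=1, delta=axial_px_um,
        axis=0, mode="interp",
    )
    dn = (wavelength_um / (2.0 * np.pi)) * slope
    dn = np.clip(dn, 0.0, None)
    return dn[:, 0] if one_d else dn


def compute_polarization_maps(
    tom: DualChannelTomogram,
    dopu_kernel: tuple[int, int] = (8, 8),
    biref_window_px: int = 15,
    retardation_mode: str = "amplitude",
    axis_pair: str = "uv",
) -> PolarizationMaps:
    """Full tomogram → maps pipeline (retardation, axis, DOPU, Δn).

    The optic axis defaults to the transverse-pair reading (``axis_pair="uv"``)
    because the simulated instrument uses circular illumination, where the
    fast axis is encoded in the phase difference between the two detectors.
    """
    st = compute_stokes(tom)
    ret = compute_retardation(tom, mode=retardation_mode)
    maps = PolarizationMaps(
        retardation=ret,
        optic_axis=compute_optic_axis(st, pair=axis_pair),
        dopu=compute_dopu(st, *dopu_kernel),
        local_birefringence=compute_local_birefringence(
            ret, tom.wavelength_um, tom.axial_px_um, window_px=biref_window_px
        ),
        axial_px_um=tom.axial_px_um,
        wavelength_um=tom.wavelength_um,
        meta={
            "dopu_kernel": list(dopu_kernel),
            "biref_window_px": biref_window_px,
            "retardation_mode": retardation_mode,
            "axis_pair": axis_pair,
        },
    )
    return maps
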