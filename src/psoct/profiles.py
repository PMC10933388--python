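"""Depth profiles of polarization maps and their disorder metrics.

A parameter map (retardation, optic axis, DOPU or local birefringence) is
reduced to a depth profile by averaging laterally over a region of interest.
Three metrics quantify structural (dis)order of the profile within an analysis
window — by default 100–500 μm, the depth band where OCT signal attenuation is
nearly flat in skin so polarization changes are attributable to tissue
structure rather than signal decay:

* ``avg_residual`` — mean absolute distance from the profile to a fitted
  polynomial (default cubic), a fluctuation-amplitude measure;
* ``num_peaks`` — count of prominent local maxima after light smoothing;
* ``range_value`` — max − min of the profile in the window.

Groups of per-sample metric values are compared with one-way ANOVA across all
groups plus pairwise two-tailed Welch t-tests against the first (control)
group, coded ns / * / ** / *** at the 0.05 / 0.01 / 0.001 thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .phantom import make_skin_phantom, simulate_tomogram
from .polarization import compute_polarization_maps

__all__ = [
    "DepthProfile",
    "ProfileMetrics",
    "GroupComparison",
    "extract_profile",
    "fit_profile",
    "count_peaks",
    "profile_range",
    "profile_metrics",
    "compare_groups",
    "dm_trend_report",
    "DEFAULT_WINDOW_UM",
]

DEFAULT_WINDOW_UM = (100.0, 500.0)

PARAMETERS = ("retardation", "optic_axis", "dopu", "local_birefringence")
METRICS = ("num_peaks", "range_value", "avg_residual")


@dataclass
class DepthProfile:
    """Lateral mean ± std of a parameter map along depth."""

    depth_um: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    parameter_name: str = ""
    n_lateral: int = 0

    def __post_init__(self) -> None:
        self.depth_um = np.asarray(self.depth_um, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if not (len(self.depth_um) == len(self.mean) == len(self.std)):
            raise ValueError("depth_um, mean and std must have equal length")
        if np.any(np.diff(self.depth_um) <= 0):
            raise ValueError("depth_um must be strictly increasing")
        if np.any(self.std < 0):
            raise ValueError("std must be nonnegative")

    def window_slice(self, window_um: tuple[float, float]) -> np.ndarray:
        lo, hi = window_um
        sel = (self.depth_um >= lo) & (self.depth_um <= hi)
        if not np.any(sel):
            raise ValueError(f"window {window_um} contains no samples")
        return sel


@dataclass
class ProfileMetrics:
    num_peaks: int
    range_value: float
    avg_residual: float
    window_um: tuple[float, float]

    def __post_init__(self) -> None:
        if self.num_peaks < 0 or self.range_value < 0 or self.avg_residual < 0:
            raise ValueError("metrics must be nonnegative")


@dataclass
class GroupComparison:
    """ANOVA across groups plus pairwise Welch t-tests vs the first group."""

    group_labels: tuple[str, ...]
    metric_name: str
    anova_p: float
    pairwise_p: dict[str, float] = field(default_factory=dict)
    significance: dict[str, str] = field(default_factory=dict)
    degenerate: tuple[str, ...] = ()


def extract_profile(
    field_2d: np.ndarray,
    roi_lateral: tuple[int, int],
    axial_px_um: float,
    parameter_name: str = "",
) -> DepthProfile:
    """Per-depth mean and population std over a lateral ROI [lo, hi)."""
    arr = np.asarray(field_2d, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D (depth, lateral) field")
    lo, hi = int(roi_lateral[0]), int(roi_lateral[1])
    if not (0 <= lo < hi <= arr.shape[1]):
        raise ValueError(
            f"ROI {roi_lateral} invalid for lateral extent {arr.shape[1]}"
        )
    sub = arr[:, lo:hi]
    depth = (np.arange(arr.shape[0]) + 0.5) * axial_px_um
    return DepthProfile(
        depth_um=depth,
        mean=sub.mean(axis=1),
        std=sub.std(axis=1),
        parameter_name=parameter_name,
        n_lateral=hi - lo,
    )


def fit_profile(
    profile: DepthProfile,
    degree: int = 3,
    window_um: tuple[float, float] | None = None,
    residual: str = "abs",
) -> tuple[np.ndarray, float]:
    """Least-squares polynomial fit of the mean curve and its average residual.

    Returns the fitted values on the (windowed) depth grid and the mean
    absolute distance from data to fit (``residual="rms"`` gives the
    root-mean-square distance instead).
    """
    if degree < 0:
        raise ValueError("degree must be >= 0")
    sel = (
        profile.window_slice(window_um)
        if window_um is not None
        else np.ones(len(profile.mean), dtype=bool)
    )
    x = profile.depth_um[sel]
    y = profile.mean[sel]
    if len(x) < degree + 2:
        raise ValueError(
            f"need at least degree+2={degree + 2} samples, got {len(x)}"
        )
    poly = np.polynomial.Polynomial.fit(x, y, deg=degree)
    fitted = poly(x)
    dev = y - fitted
    if residual == "abs":
        avg = float(np.mean(np.abs(dev)))
    elif residual == "rms":
        avg = float(np.sqrt(np.mean(dev**2)))
    else:
        raise ValueError(f"unknown residual kind {residual!r}")
    return fitted, avg


def count_peaks(
    profile: DepthProfile,
    window_um: tuple[float, float] = DEFAULT_WINDOW_UM,
    smooth_px: int = 5,
    prominence_frac: float = 0.1,
) -> int:
    """Count prominent local maxima of the smoothed mean curve in the window.

    The curve is box-smoothed over ``smooth_px`` samples and maxima must have
    prominence ≥ ``prominence_frac`` × (window max − min of the smoothed
    curve).  Window endpoints are never peaks.
    """
    sel = profile.window_slice(window_um)
    y = profile.mean[sel]
    if smooth_px > 1:
        y = uniform_filter1d(y, size=int(smooth_px), mode="nearest")
    span = float(y.max() - y.min())
    if span == 0.0:
        return 0
    peaks, _ = find_peaks(y, prominence=prominence_frac * span)
    return int(len(peaks))


def profile_range(
    profile: DepthProfile, window_um: tuple[float, float] = DEFAULT_WINDOW_UM
) -> float:
    """max − min of the mean curve over the analysis window."""
    sel = profile.window_slice(window_um)
    y = profile.mean[sel]
    return float(y.max() - y.min())


def profile_metrics(
    profile: DepthProfile,
    window_um: tuple[float, float] = DEFAULT_WINDOW_UM,
    degree: int = 3,
    smooth_px: int = 5,
    prominence_frac: float = 0.1,
) -> ProfileMetrics:
    """All three disorder metrics of a profile over one analysis window."""
    _, avg_res = fit_profile(profile, degree=degree, window_um=window_um)
    return ProfileMetrics(
        num_peaks=count_peaks(
            profile, window_um, smooth_px=smooth_px, prominence_frac=prominence_frac
        ),
        range_value=profile_range(profile, window_um),
        avg_residual=avg_res,
        window_um=tuple(window_um),
    )


_SIG_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_code(p: float) -> str:
    if not np.isfinite(p):
        return "na"
    for thr, code in _SIG_LEVELS:
        if p < thr:
            return code
    return "ns"


def compare_groups(
    metric_values: Mapping[str, Sequence[float]], metric_name: str = ""
) -> GroupComparison:
    """One-way ANOVA across all groups + Welch t-tests vs the first group.

    Groups are taken in mapping order; the first is the control.  A pairwise
    test involving a zero-variance group is flagged degenerate and its p-value
    reported as NaN (not computable).
    """
    labels = tuple(metric_values.keys())
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in metric_values.items()}
    for k, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {k!r} needs at least two values")

    if all(a.var() == 0 for a in arrays.values()):
        anova_p = float("nan")
    else:
        with warnings.catch_warnings():
            # (near-)constant groups yield a NaN statistic, reported as such
            warnings.simplefilter("ignore", RuntimeWarning)
            anova_p = float(stats.f_oneway(*arrays.values()).pvalue)

    ref_label = labels[0]
    ref = arrays[ref_label]
    pairwise: dict[str, float] = {}
    codes: dict[str, str] = {}
    degenerate: list[str] = []
    for lab in labels[1:]:
        other = arrays[lab]
        if ref.var() == 0 and other.var() == 0:
            # Both constant: equal means are trivially indistinct, unequal
            # means have no finite t statistic.
            p = 1.0 if ref.mean() == other.mean() else float("nan")
            if not np.isfinite(p):
                degenerate.append(lab)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                p = float(stats.ttest_ind(ref, other, equal_var=False).pvalue)
            if not np.isfinite(p):
                degenerate.append(lab)
        pairwise[lab] = p
        codes[lab] = significance_code(p)
    return GroupComparison(
        group_labels=labels,
        metric_name=metric_name,
        anova_p=anova_p,
        pairwise_p=pairwise,
        significance=codes,
        degenerate=tuple(degenerate),
    )


def dm_trend_report(
    stages: Sequence[float],
    n_replicates: int,
    seed: int = 0,
    window_um: tuple[float, float] = DEFAULT_WINDOW_UM,
    lateral_px: int = 256,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulated severity-trend study over the full analysis chain.

    For each severity stage, ``n_replicates`` skin phantoms are simulated with
    distinct seeds and run through the tomogram → maps → profile → metrics
    chain for all four polarization parameters.  Returns a tidy per-replicate
    metrics table and a comparison table (ANOVA p across stages plus pairwise
    Welch p and codes vs the first stage) for every parameter × metric.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rows = []
    for si, sev in enumerate(stages):
        for k in range(n_replicates):
            rep_seed = (int(seed) + 100_003 * si + k) % (2**31 - 1)
            spec = make_skin_phantom(float(sev), seed=rep_seed, lateral_px=lateral_px)
            maps = compute_polarization_maps(simulate_tomogram(spec))
            for pname, pmap in maps.as_dict().items():
                prof = extract_profile(
                    pmap, (0, spec.lateral_px), spec.axial_px_um, parameter_name=pname
                )
                m = profile_metrics(prof, window_um=window_um)
                rows.append(
                    {
                        "stage": si,
                        "severity": float(sev),
                        "replicate": k,
                        "parameter": pname,
                        "num_peaks": m.num_peaks,
                        "range_value": m.range_value,
                        "avg_residual": m.avg_residual,
                    }
                )
    table = pd.DataFrame(rows)

    comp_rows = []
    stage_labels = [f"stage{si}(sev={sev:g})" for si, sev in enumerate(stages)]
    for pname in PARAMETERS:
        sub = table[table["parameter"] == pname]
        for metric in METRICS:
            groups = {
                stage_labels[si]: sub[sub["stage"] == si][metric].to_numpy()
                for si in range(len(stages))
            }
            cmp_res = compare_groups(groups, metric_name=f"{pname}:{metric}")
            row = {
                "parameter": pname,
                "metric": metric,
                "anova_p": cmp_res.anova_p,
            }
            for lab in stage_labels[1:]:
                row[f"p_vs_{stage_labels[0]}|{lab}"] = cmp_res.pairwise_p[lab]
                row[f"code|{lab}"] = cmp_res.significance[lab]
            comp_rows.append(row)
    comparisons = pd.DataFrame(comp_rows)
    return table, comparisons
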