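"""Polar-angle response curves, equal-area angular estimates, layer indices.

The voxel table is the module's input: one row per voxel with a retinotopic
polar-angle preference (degrees, 0 at the upper vertical meridian, positive
clockwise, in ``[-180, 180)``), a cortical depth fraction in ``[0, 1]``
(0 = pial surface) and one response amplitude per illusion condition
(clockwise / counter-clockwise flash-grab).  GLM fitting, retinotopic
mapping and depth estimation are upstream of this package.

The angular representation of a condition is the polar angle that splits
the area under its (non-negative) response curve into two equal halves
within a hemifield window; the laminar indices contrast normalized curves
between conditions inside fixed polar-angle windows around the stimulated
meridian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .synth import wrap_angle

__all__ = [
    "PolarResponseCurve",
    "AngularEstimate",
    "bin_polar_responses",
    "normalize_curve",
    "normalize_curves_jointly",
    "smooth_circular_hamming",
    "angular_representation",
    "illusion_angle_difference",
    "assign_depth_bin",
    "layer_indices",
    "cousineau_within_ci",
]

N_BINS = 360
BIN_EDGES = np.arange(-180.0, 181.0)  # 1-degree half-open bins [k, k+1)
BIN_CENTERS = BIN_EDGES[:-1] + 0.5

#: polar-angle windows (degrees from the stimulated meridian) for the
#: laminar indices: illusory contrast away from the meridian, input signal
#: centred on it
ILLUSORY_WINDOWS = ((6.0, 14.0), (-14.0, -6.0))
INPUT_WINDOW = (-4.0, 4.0)

LAYERS = ("S", "M", "D")


@dataclass
class PolarResponseCurve:
    """Response amplitude in 360 one-degree polar-angle bins (circular)."""

    bin_centers: np.ndarray
    response: np.ndarray
    condition: str = ""
    layer: str | None = None

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.bin_centers.shape != (N_BINS,) or self.response.shape != (N_BINS,):
            raise ValueError(f"curves must have exactly {N_BINS} bins")


@dataclass(frozen=True)
class AngularEstimate:
    """Equal-area polar-angle estimate within one hemifield."""

    angle: float
    hemifield: str
    condition: str = ""


def bin_polar_responses(
    voxels: pd.DataFrame,
    condition: str,
    *,
    amplitude_col: str | None = None,
    interpolate_empty: bool = True,
) -> PolarResponseCurve:
    """Sort voxels into 360 one-degree polar-angle bins and average.

    Parameters
    ----------
    voxels : DataFrame
        Must carry ``polar_pref`` plus the condition's amplitude column
        (``amp_cw`` / ``amp_ccw``, or ``amplitude_col`` explicitly).
    condition : str
        ``"cw"`` or ``"ccw"`` (used to pick ``amp_<condition>``).
    interpolate_empty : bool
        Fill empty bins by circular linear interpolation between the
        nearest occupied bins (default); otherwise leave them NaN.
    """
    if len(voxels) == 0:
        raise ValueError("voxel table is empty")
    col = amplitude_col or f"amp_{condition}"
    for c in ("polar_pref", col):
        if c not in voxels.columns:
            raise ValueError(f"voxel table lacks column {c!r}")
    pref = wrap_angle(voxels["polar_pref"].to_numpy())
    amp = voxels[col].to_numpy(dtype=float)
    idx = np.floor(pref + 180.0).astype(int)
    idx = np.clip(idx, 0, N_BINS - 1)

    sums = np.bincount(idx, weights=amp, minlength=N_BINS)
    counts = np.bincount(idx, minlength=N_BINS)
    occupied = counts > 0
    if not occupied.any():
        raise ValueError("all polar-angle bins are empty")
    resp = np.full(N_BINS, np.nan)
    resp[occupied] = sums[occupied] / counts[occupied]

    if interpolate_empty and not occupied.all():
        resp = _interp_circular(resp, occupied)
    return PolarResponseCurve(BIN_CENTERS.copy(), resp, condition=condition)


def _interp_circular(values: np.ndarray, occupied: np.ndarray) -> np.ndarray:
    """Linear interpolation of missing bins on the circle."""
    idx = np.arange(N_BINS)
    occ = idx[occupied]
    # periodic extension so interpolation wraps across the -180/180 seam
    xp = np.concatenate([occ - N_BINS, occ, occ + N_BINS]).astype(float)
    fp = np.tile(values[occupied], 3)
    out = values.copy()
    out[~occupied] = np.interp(idx[~occupied].astype(float), xp, fp)
    return out


def normalize_curve(curve: PolarResponseCurve) -> PolarResponseCurve:
    """Min-max normalize a curve to span [0, 1]."""
    return normalize_curves_jointly([curve])[0]


def normalize_curves_jointly(
    curves: Sequence[PolarResponseCurve],
) -> list[PolarResponseCurve]:
    """Min-max normalize curves with one shared min/max across all of them.

    Used when conditions (or layers) must stay comparable after scaling:
    the shared affine map preserves every between-curve ordering.
    """
    if not curves:
        raise ValueError("no curves given")
    stacked = np.concatenate([c.response for c in curves])
    lo, hi = np.nanmin(stacked), np.nanmax(stacked)
    if not np.isfinite(lo) or not np.isfinite(hi) or hi == lo:
        raise ValueError("degenerate normalization: curve set is constant")
    return [replace(c, response=(c.response - lo) / (hi - lo)) for c in curves]


def smooth_circular_hamming(
    curve: PolarResponseCurve, width: float = 60.0
) -> PolarResponseCurve:
    """Circularly smooth with a unit-sum Hamming window (display only).

    The smoothed curve is for plotting; angular estimates and laminar
    indices are always computed from unsmoothed curves.
    """
    if not (1.0 <= width <= 180.0):
        raise ValueError("width must lie in [1, 180] degrees")
    n = int(round(width))
    kernel = np.hamming(n) if n > 1 else np.ones(1)
    kernel = kernel / kernel.sum()
    sm = ndimage.convolve1d(curve.response, kernel, mode="wrap")
    return replace(curve, response=sm)


def _hemifield_bins(hemifield: str) -> np.ndarray:
    """Indices of the 180 bins of a hemifield, ordered along the window.

    Upper hemifield: ``[-90, 90)`` around the upper vertical meridian;
    lower: the complementary half ``[90, 270)`` (wrapped).
    """
    if hemifield == "upper":
        centers_ok = (BIN_CENTERS >= -90.0) & (BIN_CENTERS < 90.0)
        order = np.argsort(BIN_CENTERS[centers_ok])
        return np.where(centers_ok)[0][order]
    if hemifield == "lower":
        unwrapped = np.where(BIN_CENTERS < 0, BIN_CENTERS + 360.0, BIN_CENTERS)
        centers_ok = (unwrapped >= 90.0) & (unwrapped < 270.0)
        order = np.argsort(unwrapped[centers_ok])
        return np.where(centers_ok)[0][order]
    raise ValueError("hemifield must be 'upper' or 'lower'")


def angular_representation(
    curve: PolarResponseCurve, hemifield: str = "upper"
) -> AngularEstimate:
    """Equal-area polar-angle estimate of a response curve.

    Returns the angle at which the cumulative area under the curve (bins
    treated as uniform 1-degree slabs, linear interpolation inside the
    crossing bin) reaches half of the window's total area.  Negative bin
    values are clipped to zero first — the split needs a measure — and the
    number of clipped bins is reported via a warning.
    """
    bins = _hemifield_bins(hemifield)
    vals = curve.response[bins].astype(float)
    if np.isnan(vals).any():
        raise ValueError("curve has NaN bins inside the hemifield window")
    negative = vals < 0
    if negative.any():
        warnings.warn(
            f"clipped {int(negative.sum())} negative bins before area split",
            stacklevel=2,
        )
        vals = np.clip(vals, 0.0, None)
    total = vals.sum()
    if total <= 0:
        raise ValueError("zero total area in hemifield window")
    half = total / 2.0
    cum = np.cumsum(vals)
    i = int(np.searchsorted(cum, half))
    prev = cum[i - 1] if i > 0 else 0.0
    frac = (half - prev) / vals[i]
    start = curve.bin_centers[bins[i]] - 0.5
    angle = float(wrap_angle(start + frac))
    return AngularEstimate(angle=angle, hemifield=hemifield,
                           condition=curve.condition)


def illusion_angle_difference(
    est_cw: AngularEstimate, est_ccw: AngularEstimate
) -> float:
    """Absolute circular difference between two angular estimates (deg).

    This is the summed clockwise + counter-clockwise displacement, i.e.
    twice the per-direction illusory shift.
    """
    if est_cw.hemifield != est_ccw.hemifield:
        raise ValueError(
            f"hemifield mismatch: {est_cw.hemifield!r} vs {est_ccw.hemifield!r}"
        )
    return float(abs(wrap_angle(est_cw.angle - est_ccw.angle)))


def assign_depth_bin(depth_fraction):
    """Map cortical depth fractions to layer bins S/M/D.

    Superficial ``[0, 0.4)``, middle ``[0.4, 0.8)``, deep ``[0.8, 1.0]``
    (right-open except the last bin).
    """
    d = np.asarray(depth_fraction, dtype=float)
    if np.any((d < 0) | (d > 1)):
        raise ValueError("depth fractions must lie in [0, 1]")
    out = np.where(d < 0.4, "S", np.where(d < 0.8, "M", "D"))
    return out if out.ndim else out[()]


def _window_mask(lo: float, hi: float) -> np.ndarray:
    return (BIN_CENTERS >= lo) & (BIN_CENTERS <= hi)


def layer_indices(
    voxels: pd.DataFrame,
    subject: str | None = None,
    *,
    areas: Sequence[str] = ("V1", "V2", "V3"),
) -> pd.DataFrame:
    """Per (area x layer) illusory and input representation indices.

    For each cell the clockwise and counter-clockwise curves are binned and
    jointly min-max normalized (shared scale within the cell).  The
    illusory index averages the condition contrast over the two mirrored
    off-meridian windows, signed so a clockwise displacement of the CW
    curve relative to the CCW curve is positive:

        illusory = ( mean_{[6,14]}(CW - CCW) + mean_{[-14,-6]}(CCW - CW) ) / 2

    The input index is the mean of the condition-averaged normalized curve
    over the on-meridian window ``[-4, 4]``.
    """
    df = voxels
    if subject is not None:
        df = df[df["subject"] == subject]
    if "depth_fraction" not in df.columns:
        raise ValueError("voxel table lacks column 'depth_fraction'")
    df = df.assign(layer=assign_depth_bin(df["depth_fraction"].to_numpy()))

    pos = _window_mask(*ILLUSORY_WINDOWS[0])
    neg = _window_mask(*ILLUSORY_WINDOWS[1])
    mid = _window_mask(*INPUT_WINDOW)

    rows = []
    for area in areas:
        for layer in LAYERS:
            cell = df[(df["area"] == area) & (df["layer"] == layer)]
            if len(cell) == 0:
                warnings.warn(f"empty cell {area}/{layer}", stacklevel=2)
                rows.append(
                    {"area": area, "layer": layer,
                     "illusory_index": np.nan, "input_index": np.nan}
                )
                continue
            cw = bin_polar_responses(cell, "cw")
            ccw = bin_polar_responses(cell, "ccw")
            cw, ccw = normalize_curves_jointly([cw, ccw])
            contrast = cw.response - ccw.response
            illusory = 0.5 * (contrast[pos].mean() - contrast[neg].mean())
            mean_curve = 0.5 * (cw.response + ccw.response)
            rows.append(
                {
                    "area": area,
                    "layer": layer,
                    "illusory_index": float(illusory),
                    "input_index": float(mean_curve[mid].mean()),
                }
            )
    return pd.DataFrame(rows)


def cousineau_within_ci(values, level: float = 0.95) -> pd.DataFrame:
    """Within-subject confidence intervals (Cousineau normalization).

    Each subject's mean across conditions is subtracted from that
    subject's values and the grand mean is added back; per-condition
    t-based CIs of the transformed values then reflect only within-subject
    variability.

    Parameters
    ----------
    values : 2-D array or DataFrame, subjects x conditions
        Complete table (no NaN).
    level : float
        Confidence level, default 0.95.

    Returns
    -------
    DataFrame with columns ``mean``, ``ci_low``, ``ci_high`` per condition.
    """
    if isinstance(values, pd.DataFrame):
        cols = list(values.columns)
        arr = values.to_numpy(dtype=float)
    else:
        arr = np.asarray(values, dtype=float)
        cols = list(range(arr.shape[1])) if arr.ndim == 2 else []
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need a 2-D subjects x conditions table, >= 2 each")
    if np.isnan(arr).any():
        raise ValueError("incomplete table: NaN entries present")
    n = arr.shape[0]
    transformed = arr - arr.mean(axis=1, keepdims=True) + arr.mean()
    mean = transformed.mean(axis=0)
    sem = transformed.std(axis=0, ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=n - 1)
    return pd.DataFrame(
        {"mean": mean, "ci_low": mean - tcrit * sem, "ci_high": mean + tcrit * sem},
        index=cols,
    )
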