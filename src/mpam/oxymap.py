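"""Ratiometric tissue-oxygen mapping from blue/red channel image pairs.

The nanoparticle sensor emits oxygen-independent fluorescence (blue) and
phosphorescence (red) that is quenched by oxygen following single-site
Stern-Volmer kinetics, I0/I = 1 + Ksv*pO2. After background subtraction the
per-pixel blue/red ratio is therefore a monotone function of local oxygen:
rendered as grayscale, low oxygen maps to black and high oxygen to white.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import ChannelPair


@dataclass
class RatioImage:
    """Background-corrected blue/red ratio field with validity mask and gray rendering."""

    ratio: np.ndarray
    valid: np.ndarray
    gray: np.ndarray  # in [0, 1]; monotone non-decreasing in ratio
    bounds: tuple[float, float]


def subtract_background(pair: ChannelPair) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel background subtraction, floored at zero, for both channels."""
    blue = np.asarray(pair.blue, dtype=float)
    red = np.asarray(pair.red, dtype=float)
    if blue.shape != red.shape or blue.shape != np.shape(pair.blue_bg):
        raise ValueError("channel and background images must share one shape")
    blue_corr = np.clip(blue - np.asarray(pair.blue_bg, dtype=float), 0.0, None)
    red_corr = np.clip(red - np.asarray(pair.red_bg, dtype=float), 0.0, None)
    return blue_corr, red_corr


def default_red_floor(pair: ChannelPair, k: float = 3.0) -> float:
    """Validity floor for the red channel: k times the background spread.

    Falls back to a small fraction of the peak corrected red signal when the
    background image is constant (e.g. synthetic backgrounds).
    """
    sd = float(np.std(np.asarray(pair.red_bg, dtype=float)))
    if sd > 0:
        return k * sd
    _, red_corr = subtract_background(pair)
    peak = float(red_corr.max())
    return 1e-6 * peak if peak > 0 else 1e-12


def ratio_map(
    blue_corr: np.ndarray,
    red_corr: np.ndarray,
    red_floor: float,
    gray_bounds: tuple[float, float] | None = None,
) -> RatioImage:
    """Per-pixel blue/red ratio with a red-channel validity floor.

    Pixels with red below ``red_floor`` are invalid (NaN ratio). The gray
    rendering scales the ratio affinely between ``gray_bounds`` (shared,
    study-wide bounds by default ensure cross-day comparability); when bounds
    are omitted the per-image valid min/max are used. Gray is clipped to
    [0, 1] and is monotone non-decreasing in the ratio.
    """
    blue = np.asarray(blue_corr, dtype=float)
    red = np.asarray(red_corr, dtype=float)
    if blue.shape != red.shape:
        raise ValueError("corrected channels must share one shape")
    if red_floor <= 0:
        raise ValueError("red_floor must be positive")
    valid = red >= red_floor
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(valid, blue / np.where(valid, red, 1.0), np.nan)
    if gray_bounds is None:
        if valid.any():
            gray_bounds = (float(np.nanmin(ratio)), float(np.nanmax(ratio)))
        else:
            gray_bounds = (0.0, 1.0)
    lo, hi = gray_bounds
    if not hi > lo:
        gray = np.where(valid, 0.5, np.nan)
    else:
        gray = np.clip((ratio - lo) / (hi - lo), 0.0, 1.0)
        gray = np.where(valid, gray, np.nan)
    return RatioImage(ratio=ratio, valid=valid, gray=gray, bounds=(lo, hi))


def invert_stern_volmer(image: RatioImage, ksv: float, ratio0: float = 1.0) -> np.ndarray:
    """Relative pO2 from the ratio field: pO2 = (R/R0 - 1) / Ksv.

    ``ratio0`` is the zero-oxygen ratio (blue/red with no quenching).
    """
    if ksv <= 0:
        raise ValueError("Ksv must be positive to invert quenching")
    if ratio0 <= 0:
        raise ValueError("zero-oxygen ratio must be positive")
    return (image.ratio / ratio0 - 1.0) / ksv


def mean_gray(image: RatioImage, roi: np.ndarray) -> float:
    """Mean gray value of the rendering over the ROI's valid pixels."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != image.gray.shape:
        raise ValueError("ROI must match the image shape")
    sel = roi & image.valid
    if not sel.any():
        raise ValueError("ROI does not overlap any valid pixel")
    return float(np.mean(image.gray[sel]))


def relative_oxygenation(series, reference: float):
    """Express per-day/group mean-gray values as percent of a reference.

    ``series`` is a DataFrame with columns ``day``, ``group``, ``replicate``
    and ``mean_gray``. Returns per day/group mean +/- SEM of
    100 * mean_gray / reference (SEM NaN for a single replicate).
    """
    import pandas as pd

    if reference <= 0:
        raise ValueError("reference value must be positive")
    df = pd.DataFrame(series).copy()
    df["percent"] = 100.0 * df["mean_gray"] / reference
    out = (
        df.groupby(["day", "group"])["percent"]
        .agg(mean="mean", sem=lambda x: x.sem() if len(x) > 1 else np.nan, n="count")
        .reset_index()
    )
    return out
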