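"""Agarose-gel densitometry: lane profiles to molecular-weight distributions.

A stained HA gel lane is read as a 1-D densitometric profile (intensity vs
migration distance in pixels from the well).  The background is removed with
a rolling-ball (morphological opening) baseline, the ladder bands define a
monotone pixel -> log10(MW) calibration, and each in-range pixel's intensity
becomes the mass weight at its calibrated molecular weight.  Mw, Mn and PDI
then follow from :mod:`hyalkit.mwdist`.

Conventions: distance is 0-based pixels from the configured well row,
increasing toward the gel front; MW decreases strictly with distance.
Pixels migrating outside the ladder's range are excluded (not extrapolated)
and their intensity fraction is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .mwdist import MWDistribution, number_average_mw, polydispersity, weight_average_mw

__all__ = [
    "LaneProfile",
    "GelCalibration",
    "CalibrationError",
    "rolling_ball_background",
    "extract_lane_profile",
    "fit_gel_calibration",
    "lane_to_mwdist",
    "gel_mw_summary",
    "GelSummary",
]


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class LaneProfile:
    """Densitometric intensity vs migration distance for one lane."""

    distance_px: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distance_px, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "distance_px", d)
        object.__setattr__(self, "intensity", i)
        if d.shape != i.shape or d.ndim != 1 or d.size == 0:
            raise ValueError("distance and intensity must be equal-length 1-D vectors")
        if np.any(np.diff(d) <= 0):
            raise ValueError("distances must be strictly ascending")
        if np.any(d < 0):
            raise ValueError("distances must be >= 0")


@dataclass(frozen=True)
class GelCalibration:
    """Ladder-derived monotone map from migration distance to MW.

    Piecewise-linear in (distance_px, log10 MW); exact at every anchor.
    """

    anchors_px: np.ndarray
    anchors_kda: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.anchors_px, dtype=float)
        kda = np.asarray(self.anchors_kda, dtype=float)
        order = np.argsort(px)
        px, kda = px[order], kda[order]
        object.__setattr__(self, "anchors_px", px)
        object.__setattr__(self, "anchors_kda", kda)
        if px.size < 2:
            raise CalibrationError("need at least 2 ladder anchors")
        if np.any(np.diff(px) <= 0):
            raise CalibrationError("duplicate anchor distances")
        diffs = np.diff(kda)
        if np.any(diffs >= 0):
            i = int(np.argmax(diffs >= 0))
            raise CalibrationError(
                "MW must decrease strictly with migration distance; offending "
                f"anchor pair: ({px[i]} px, {kda[i]} kDa) -> ({px[i+1]} px, {kda[i+1]} kDa)"
            )
        if np.any(kda <= 0):
            raise CalibrationError("anchor MWs must be positive")

    @property
    def valid_range(self) -> Tuple[float, float]:
        return float(self.anchors_px[0]), float(self.anchors_px[-1])

    def mw_at(self, distance_px) -> np.ndarray:
        """Interpolated MW (kDa) at the given distances; NaN outside range."""
        d = np.asarray(distance_px, dtype=float)
        logmw = np.interp(d, self.anchors_px, np.log10(self.anchors_kda))
        out = 10.0 ** logmw
        lo, hi = self.valid_range
        return np.where((d < lo) | (d > hi), np.nan, out)

    def px_at(self, mw_kda) -> np.ndarray:
        """Inverse map: migration distance for a given MW (NaN outside range)."""
        mw = np.asarray(mw_kda, dtype=float)
        # anchors are descending in MW; np.interp needs ascending x
        logmw = np.log10(mw)
        xs = np.log10(self.anchors_kda[::-1])
        ys = self.anchors_px[::-1]
        out = np.interp(logmw, xs, ys)
        return np.where((logmw < xs[0]) | (logmw > xs[-1]), np.nan, out)


def rolling_ball_background(profile: LaneProfile, radius: int) -> LaneProfile:
    """Subtract a rolling-ball baseline from a lane profile.

    The baseline is the morphological grey opening of the intensity with a
    flat structuring element of width ``2*radius + 1`` pixels (erosion then
    dilation): the envelope a ball of the given radius traces when rolled
    under the profile.  Output intensities are >= 0 and <= the input, a
    constant offset is removed entirely, and peaks narrower than the ball
    survive.
    """
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    baseline = ndimage.grey_opening(profile.intensity, size=2 * int(radius) + 1, mode="nearest")
    corrected = np.maximum(profile.intensity - baseline, 0.0)
    return LaneProfile(profile.distance_px, corrected)


def extract_lane_profile(
    image: np.ndarray,
    lane_bounds: Tuple[int, int],
    well_row: int = 0,
    aggregate: str = "mean",
) -> LaneProfile:
    """Collapse a lane of a grayscale gel image to a 1-D profile.

    ``lane_bounds`` is the half-open column range ``[lo, hi)`` of the lane;
    rows at or below ``well_row`` become the distance axis (0-based pixels
    from the well).  Dark-background convention: signal = high intensity.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D grayscale array")
    lo, hi = lane_bounds
    if not (0 <= lo < hi <= img.shape[1]):
        raise ValueError(f"lane bounds {lane_bounds} outside image width {img.shape[1]}")
    if not (0 <= well_row < img.shape[0]):
        raise ValueError(f"well_row {well_row} outside image height {img.shape[0]}")
    lane = img[well_row:, lo:hi]
    if aggregate == "mean":
        intensity = lane.mean(axis=1)
    elif aggregate == "sum":
        intensity = lane.sum(axis=1)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return LaneProfile(np.arange(lane.shape[0], dtype=float), intensity)


def fit_gel_calibration(anchors: Sequence[Tuple[float, float]]) -> GelCalibration:
    """Fit the ladder calibration from (migration_px, mw_kda) anchor pairs."""
    arr = np.asarray(list(anchors), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] != 2:
        raise CalibrationError("need >= 2 (px, kDa) anchors")
    return GelCalibration(arr[:, 0], arr[:, 1])


def lane_to_mwdist(
    profile: LaneProfile, calib: GelCalibration, intensity_floor_frac: float = 0.0
) -> Tuple[MWDistribution, float]:
    """Map a background-subtracted lane to a mass-weighted MWDistribution.

    Returns the distribution and the fraction of total intensity carried by
    excluded pixels: those outside the calibration's valid range (excluded,
    not extrapolated) and, when ``intensity_floor_frac`` > 0, those below
    that fraction of the peak intensity.  The floor guards the
    noise-sensitive harmonic mean behind Mn against residual baseline
    noise; it is off by default.
    """
    mw = calib.mw_at(profile.distance_px)
    in_range = ~np.isnan(mw)
    if intensity_floor_frac > 0:
        in_range &= profile.intensity >= intensity_floor_frac * profile.intensity.max()
    total = float(profile.intensity.sum())
    if total <= 0:
        raise ValueError("lane has no intensity")
    in_total = float(profile.intensity[in_range].sum())
    if in_total <= 0:
        raise ValueError("no intensity inside the calibration range")
    excluded_fraction = 1.0 - in_total / total
    masses = mw[in_range]
    weights = profile.intensity[in_range]
    # larger migration = smaller MW: reverse to make masses ascending,
    # merging any pixels that calibrate to the same MW
    order = np.argsort(masses, kind="stable")
    masses, weights = masses[order], weights[order]
    uniq, inv = np.unique(masses, return_inverse=True)
    merged = np.zeros_like(uniq)
    np.add.at(merged, inv, weights)
    keep = merged > 0  # drop pixels carrying no stain
    return MWDistribution(uniq[keep], merged[keep], "mass"), excluded_fraction


class GelSummary(NamedTuple):
    mw_kda: float
    mn_kda: float
    pdi: float
    excluded_fraction: float


def gel_mw_summary(
    profile: LaneProfile, calib: GelCalibration, intensity_floor_frac: float = 0.0
) -> GelSummary:
    """Mw, Mn, PDI and excluded intensity fraction for one lane."""
    dist, excluded = lane_to_mwdist(profile, calib, intensity_floor_frac)
    return GelSummary(
        weight_average_mw(dist), number_average_mw(dist), polydispersity(dist), excluded
    )
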