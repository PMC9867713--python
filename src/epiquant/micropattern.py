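"""Radial quantification of circular micropattern (2D gastruloid) colonies.

Each colony is a confined circular hPSC colony (typically 700 µm across)
that self-organizes concentric germ-layer domains under BMP4. The analysis
locates the colony disk from the nuclei channel, bins pixel intensities into
equal-width annuli from the center, and aggregates colonies per condition as
mean with first/third-quartile band, normalizing every profile by the
maximum of the control condition's mean profile for the same stain.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import ndimage
from shapely import MultiPoint, minimum_bounding_circle

from .thresholds import threshold_otsu_exact
from .types import DataError, ImageStack, ProfileAggregate, RadialProfile

__all__ = ["locate_colony", "radial_profile", "aggregate_and_normalize"]


def locate_colony(
    stack: ImageStack,
    nuclei_channel: str = "DAPI",
    nominal_diameter_um: float = 700.0,
) -> tuple:
    """Colony center (px) and radius (µm) from the nuclei channel.

    The foreground is the largest connected component above the Otsu
    threshold; the center is its centroid and the radius the minimal
    enclosing circle of its pixels. A foreground smaller than 10% of the
    nominal disk area means a failed or partial colony and raises.
    """
    img = stack.channel(nuclei_channel)
    if img.ndim != 2:
        raise DataError("locate_colony expects a 2D field")
    px = stack.pixel_size_um
    img_int = np.round(np.asarray(img, dtype=np.float64)).astype(np.int64)
    if img_int.min() == img_int.max():
        raise DataError("blank field: no colony found")
    fg = ndimage.binary_fill_holes(img_int > threshold_otsu_exact(img_int))
    labels, n = ndimage.label(fg)
    if n == 0:
        raise DataError("no foreground above threshold: no colony found")
    sizes = np.bincount(labels.ravel())[1:]
    comp = labels == (int(np.argmax(sizes)) + 1)
    nominal_area_px = np.pi * (nominal_diameter_um / 2.0 / px) ** 2
    if comp.sum() < 0.1 * nominal_area_px:
        raise DataError(
            f"foreground covers {comp.sum()} px, under 10% of the nominal "
            f"colony disk ({nominal_area_px:.0f} px): failed or partial colony"
        )
    rows, cols = np.nonzero(comp)
    center = (float(rows.mean()), float(cols.mean()))
    circle = minimum_bounding_circle(MultiPoint(np.column_stack([cols, rows])))
    radius_px = np.sqrt(circle.area / np.pi)
    return center, float(radius_px * px)


def radial_profile(
    stack: ImageStack,
    channel: str,
    center: tuple,
    radius_um: float,
    n_bins: int = 50,
    colony_id: str = "",
) -> RadialProfile:
    """Mean intensity per equal-width annulus over [0, radius].

    Pixels beyond the colony radius are excluded (not zero-filled), so edge
    bins are not diluted by background.
    """
    if radius_um <= 0:
        raise DataError("radius must be positive")
    if n_bins < 4:
        raise DataError("need at least 4 radial bins")
    img = stack.channel(channel).astype(np.float64)
    if img.ndim != 2:
        raise DataError("radial_profile expects a 2D field")
    h, w = img.shape
    r0, c0 = center
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise DataError(f"center {center} lies outside the {h}x{w} image")
    px = stack.pixel_size_um
    yy, xx = np.mgrid[0:h, 0:w]
    r_um = np.hypot(yy - r0, xx - c0) * px
    inside = r_um <= radius_um
    bin_idx = np.minimum((r_um[inside] / radius_um * n_bins).astype(int), n_bins - 1)
    n_pixels = np.bincount(bin_idx, minlength=n_bins)
    sums = np.bincount(bin_idx, weights=img[inside], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.divide(sums, n_pixels, out=np.full(n_bins, np.nan), where=n_pixels > 0)
    width = radius_um / n_bins
    centers = (np.arange(n_bins) + 0.5) * width
    return RadialProfile(
        colony_id=colony_id,
        channel=channel,
        r_bin_centers_um=centers,
        mean_intensity=means,
        n_pixels=n_pixels,
        colony_center_px=(r0, c0),
        colony_radius_um=radius_um,
    )


def _check_shared_binning(profiles: Sequence[RadialProfile]) -> np.ndarray:
    ref = profiles[0].r_bin_centers_um
    for p in profiles[1:]:
        if len(p.r_bin_centers_um) != len(ref) or not np.allclose(
            p.r_bin_centers_um, ref
        ):
            raise DataError("all profiles must share one radial binning")
        if p.channel != profiles[0].channel:
            raise DataError("all profiles in one aggregate must share one channel")
    return ref


def aggregate_and_normalize(
    profiles: Sequence[RadialProfile],
    control_profiles: Sequence[RadialProfile],
    condition: str = "test",
) -> ProfileAggregate:
    """Across-colony aggregate normalized to the control maximum.

    Mean, Q1 and Q3 per radial bin across colonies, every profile divided by
    the maximum of the control condition's mean profile for the same stain —
    so the control's own normalized mean profile peaks at exactly 1.0.
    """
    if not control_profiles:
        raise DataError("control profile set must be nonempty")
    if not profiles:
        raise DataError("profile set must be nonempty")
    ref = _check_shared_binning(list(profiles) + list(control_profiles))
    control_stack = np.vstack([p.mean_intensity for p in control_profiles])
    control_mean = np.nanmean(control_stack, axis=0)
    norm = float(np.nanmax(control_mean))
    if not np.isfinite(norm) or norm <= 0:
        raise DataError("control mean profile has no positive maximum; normalization undefined")
    data = np.vstack([p.mean_intensity for p in profiles]) / norm
    return ProfileAggregate(
        channel=profiles[0].channel,
        condition=condition,
        r_bin_centers_um=ref,
        mean=np.nanmean(data, axis=0),
        q1=np.nanpercentile(data, 25, axis=0),
        q3=np.nanpercentile(data, 75, axis=0),
        n_colonies=len(profiles),
        normalization_factor=norm,
    )
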