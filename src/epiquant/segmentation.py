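"""ImageJ-style mask construction for monolayer fields.

Nuclei are segmented from the DAPI channel by median filtering, automatic
Huang thresholding and a distance-transform watershed split of touching
nuclei; nuclear-marker positivity is called after rolling-ball background
subtraction, white top-hat filtering and automatic Otsu thresholding; the
disrupted-epithelium mask is derived from the junction (ZO1) channel with a
sliding-window junction-continuity score (or supplied manually); per-cell
apical surfaces are the areas delimited by the junction network.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import median as median_filter
from skimage.measure import regionprops
from skimage.morphology import (
    disk,
    remove_small_holes,
    remove_small_objects,
    skeletonize,
    white_tophat,
)
from skimage.restoration import rolling_ball
from skimage.segmentation import watershed

from .thresholds import threshold_huang, threshold_otsu_exact
from .types import DataError, ImageStack, MarkerCallTable, NucleusTable, RegionMask

__all__ = [
    "SegmentationParams",
    "segment_nuclei",
    "call_nuclear_marker",
    "detect_disrupted_regions",
    "load_manual_mask",
    "measure_apical_surfaces",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the mask-construction stage.

    The thresholding methods themselves are parameter-free (automatic
    Huang/Otsu); these knobs cover the filter radii and size gates that an
    ImageJ user would set interactively.
    """

    median_radius_px: int = 2
    expected_nucleus_diameter_um: float = 10.0
    nucleus_area_bounds_um2: tuple = (25.0, 400.0)
    rolling_ball_radius_px: int = 20
    tophat_radius_px: int = 10
    positive_pixel_fraction: float = 0.5
    continuity_window_um: float = 30.0
    continuity_rel_cutoff: float = 0.5
    min_disrupted_area_um2: float = 500.0


def segment_nuclei(
    stack: ImageStack,
    nuclei_channel: str = "DAPI",
    params: SegmentationParams = SegmentationParams(),
    intensity_channels: tuple = (),
) -> NucleusTable:
    """Label nuclei in a 2D field.

    Median filter -> Huang threshold -> fill holes -> watershed split of
    touching nuclei seeded at distance-transform maxima -> area gate.
    ``intensity_channels`` adds a ``mean_<name>`` column per listed channel.
    """
    img = stack.channel(nuclei_channel)
    if img.ndim != 2:
        raise DataError("segment_nuclei expects a 2D field")
    px = stack.pixel_size_um

    smoothed = median_filter(img, footprint=disk(params.median_radius_px))
    if smoothed.min() == smoothed.max():  # blank field
        return _empty_nucleus_table(img.shape, intensity_channels)
    thr = threshold_huang(smoothed)
    fg = ndimage.binary_fill_holes(smoothed > thr)
    lo_px = int(np.ceil(params.nucleus_area_bounds_um2[0] / px**2))
    fg = remove_small_objects(fg, max_size=max(lo_px // 2, 4) - 1)
    if not fg.any():
        return _empty_nucleus_table(img.shape, intensity_channels)

    dist = ndimage.distance_transform_edt(fg)
    min_sep = max(2, int(round(0.5 * params.expected_nucleus_diameter_um / px)))
    peaks = peak_local_max(dist, min_distance=min_sep, labels=fg, exclude_border=False)
    markers = np.zeros_like(dist, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers, mask=fg)

    lo, hi = params.nucleus_area_bounds_um2
    rows = []
    keep_map = np.zeros_like(labels)
    next_label = 0
    intensity_imgs = {c: stack.channel(c) for c in intensity_channels}
    for prop in regionprops(labels):
        area_um2 = prop.area * px**2
        if not lo <= area_um2 <= hi:
            continue
        next_label += 1
        keep_map[labels == prop.label] = next_label
        row = {
            "centroid_row": prop.centroid[0],
            "centroid_col": prop.centroid[1],
            "area_um2": area_um2,
        }
        for name, chan in intensity_imgs.items():
            row[f"mean_{name}"] = float(chan[labels == prop.label].mean())
        rows.append(row)
    records = pd.DataFrame(rows, index=pd.RangeIndex(1, next_label + 1, name="label"))
    if not rows:
        return _empty_nucleus_table(img.shape, intensity_channels)
    return NucleusTable(label_map=keep_map, records=records)


def _empty_nucleus_table(shape: tuple, intensity_channels: tuple) -> NucleusTable:
    cols = ["centroid_row", "centroid_col", "area_um2"] + [
        f"mean_{c}" for c in intensity_channels
    ]
    return NucleusTable(
        label_map=np.zeros(shape, dtype=np.int32),
        records=pd.DataFrame(columns=cols, index=pd.Index([], name="label")),
    )


def call_nuclear_marker(
    stack: ImageStack,
    nuclei: NucleusTable,
    marker_channel: str,
    params: SegmentationParams = SegmentationParams(),
) -> MarkerCallTable:
    """Call each nucleus positive or negative for a nuclear marker.

    Rolling-ball background subtraction, then white top-hat, then automatic
    Otsu thresholding of the filtered marker image; a nucleus is positive
    iff at least ``positive_pixel_fraction`` of its pixels exceed the
    threshold. An empty nucleus table yields an empty call table.
    """
    img = stack.channel(marker_channel).astype(np.float64)
    if nuclei.n_nuclei == 0:
        return MarkerCallTable(
            marker_name=marker_channel,
            calls=pd.Series(dtype=bool),
            threshold_used=float("nan"),
        )
    if params.rolling_ball_radius_px > 0:
        img = img - rolling_ball(img, radius=params.rolling_ball_radius_px)
    filtered = white_tophat(img, footprint=disk(params.tophat_radius_px))
    filtered_int = np.clip(np.round(filtered), 0, 65535).astype(np.uint16)
    if filtered_int.min() == filtered_int.max():  # featureless marker channel
        thr = float(filtered_int.max())
    else:
        thr = float(threshold_otsu_exact(filtered_int))
    above = filtered_int > thr

    labels = nuclei.label_map
    n = nuclei.n_nuclei
    n_above = ndimage.sum_labels(above, labels, index=np.arange(1, n + 1))
    n_pix = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    frac = np.divide(n_above, n_pix, out=np.zeros(n), where=n_pix > 0)
    calls = pd.Series(frac >= params.positive_pixel_fraction, index=nuclei.records.index)
    return MarkerCallTable(
        marker_name=marker_channel,
        calls=calls,
        threshold_used=thr,
        positive_fraction_rule=params.positive_pixel_fraction,
    )


def detect_disrupted_regions(
    stack: ImageStack,
    junction_channel: str = "ZO1",
    params: SegmentationParams = SegmentationParams(),
    mean_cell_diameter_um: float = 15.0,
) -> RegionMask:
    """Detect regions where the junction network is fragmented or absent.

    The thresholded, skeletonized junction network of an intact epithelium
    has a characteristic line density of about ``2/d`` (d = mean cell
    diameter in px, the Voronoi edge-length-per-area of confluent packing).
    A sliding window (default 30 µm) measures local skeleton coverage;
    pixels whose coverage falls below ``continuity_rel_cutoff`` times the
    intact-epithelium density, grouped into components larger than
    ``min_disrupted_area_um2``, form the disrupted mask.
    """
    img = stack.channel(junction_channel).astype(np.float64)
    if img.ndim != 2:
        raise DataError("detect_disrupted_regions expects a 2D field")
    px = stack.pixel_size_um
    img = ndimage.gaussian_filter(img, sigma=1.0)
    img_int = np.round(img).astype(np.int64)
    if img_int.min() == img_int.max():
        # no junction signal anywhere: the whole field is disrupted
        return RegionMask(mask=np.ones(img.shape, dtype=bool), provenance="auto")
    network = img_int > threshold_otsu_exact(img_int)
    if not network.any():
        return RegionMask(mask=np.ones(img.shape, dtype=bool), provenance="auto")
    skel = skeletonize(network)

    win = max(3, int(round(params.continuity_window_um / px)))
    coverage = ndimage.uniform_filter(skel.astype(np.float64), size=win)
    d_px = mean_cell_diameter_um / px
    cutoff = params.continuity_rel_cutoff * (2.0 / d_px)
    disrupted = coverage < cutoff

    min_px = int(round(params.min_disrupted_area_um2 / px**2))
    disrupted = remove_small_objects(disrupted, max_size=min_px - 1)
    disrupted = remove_small_holes(disrupted, max_size=min_px - 1)
    return RegionMask(mask=disrupted, provenance="auto")


def load_manual_mask(path, stack: ImageStack) -> RegionMask:
    """Load a manually drawn disrupted-area mask (PNG/TIFF, nonzero = true)."""
    from . import io as eio

    mask = eio.read_mask(Path(path))
    expected = stack.shape[-2:]
    if mask.shape != tuple(expected):
        raise DataError(
            f"manual mask shape {mask.shape} does not match image shape {tuple(expected)}"
        )
    return RegionMask(mask=mask, provenance="manual")


def measure_apical_surfaces(
    stack: ImageStack,
    junction_channel: str = "ZO1",
    params: SegmentationParams = SegmentationParams(),
    exclude: Optional[RegionMask] = None,
    max_cell_area_um2: float = 2500.0,
) -> pd.DataFrame:
    """Per-cell apical surface areas delimited by the junction network.

    Cells are the connected components (4-connectivity) of the complement
    of the thresholded, skeletonized junction network; the 1-px skeleton
    itself belongs to no cell, so areas are the pixels strictly enclosed by
    the junction line. Cells touching the image border, overlapping an
    excluded (disrupted) region, or larger than ``max_cell_area_um2``
    (unclosed network) are dropped. Returns a DataFrame (cell_id,
    centroid_row, centroid_col, area_um2) suitable for violin-plot
    summaries.
    """
    img = stack.channel(junction_channel).astype(np.float64)
    if img.ndim != 2:
        raise DataError("measure_apical_surfaces expects a 2D field")
    px = stack.pixel_size_um
    img_int = np.round(ndimage.gaussian_filter(img, sigma=1.0)).astype(np.int64)
    if img_int.min() == img_int.max():
        raise DataError("junction channel is featureless; no cells delimitable")
    network = img_int > threshold_otsu_exact(img_int)
    if not network.any():
        raise DataError("no junction network above threshold; no cells delimitable")
    skel = skeletonize(network)
    labels, _ = ndimage.label(~skel, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))

    border = np.zeros(labels.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    drop = set(np.unique(labels[border])) - {0}
    if exclude is not None:
        drop |= set(np.unique(labels[exclude.mask])) - {0}

    rows = []
    for prop in regionprops(labels):
        if prop.label in drop:
            continue
        area = prop.area * px**2
        if area > max_cell_area_um2:
            continue
        rows.append(
            {
                "cell_id": prop.label,
                "centroid_row": prop.centroid[0],
                "centroid_col": prop.centroid[1],
                "area_um2": area,
            }
        )
    return pd.DataFrame(rows, columns=["cell_id", "centroid_row", "centroid_col", "area_um2"])
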