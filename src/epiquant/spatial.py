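"""Concentric distance-ring statistics around disrupted epithelial areas.

The core spatial statistic: every pixel is assigned to a distance band away
from the disrupted-region mask (exact Euclidean distance transform; default
bands 0-30, 30-60, 60-90, >90 µm, plus the inside-disrupted "0 µm" class),
cells are binned by nucleus centroid, the positive-cell percentage is
computed per band, and an ordinary-least-squares slope is fitted to the
percentage-vs-distance profile. Also covers organized-area time courses and
axial (z) peak-to-peak distances between two stains.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .types import (
    DEFAULT_RING_EDGES_UM,
    RING_LABELS,
    DataError,
    DistanceProfile,
    ImageStack,
    MarkerCallTable,
    NucleusTable,
    RegionMask,
    RingBinning,
    SlopeResult,
    ZProfilePair,
)

__all__ = [
    "make_ring_masks",
    "bin_positive_fractions",
    "fit_distance_slope",
    "area_fraction_timecourse",
    "zprofile_peak_distance",
    "ring_bin_centers_um",
]


def make_ring_masks(
    region: RegionMask,
    pixel_size_um: float,
    edges_um: Sequence = DEFAULT_RING_EDGES_UM,
) -> RingBinning:
    """Concentric distance-band masks around the disrupted mask.

    Distances are exact Euclidean (distance transform of the non-disrupted
    pixels, in µm); bands are half-open ``[a, b)`` with an unbounded last
    band, and the disrupted pixels themselves form the first ("0 µm") class.
    The resulting masks are pairwise disjoint and tile the image. An empty
    disrupted mask has no reference structure and raises; a mask covering
    the whole image is valid but flagged ``degenerate`` (all outer bands
    empty).
    """
    if pixel_size_um <= 0:
        raise DataError("pixel_size_um must be positive")
    edges = tuple(float(e) for e in edges_um)
    if list(edges) != sorted(edges) or edges[0] != 0.0:
        raise DataError("edges_um must be increasing and start at 0")
    mask = region.mask
    if not mask.any():
        raise DataError("empty disrupted mask: no reference structure for distances")
    if mask.all():
        rings = [mask.copy()] + [np.zeros_like(mask) for _ in edges]
        return RingBinning(
            edges_um=edges, ring_masks=rings, pixel_size_um=pixel_size_um, degenerate=True
        )
    dist_um = ndimage.distance_transform_edt(~mask) * pixel_size_um
    # band i (i>=1) holds non-disrupted pixels with lo <= d < hi
    rings = [mask.copy()]
    for lo, hi in zip(edges, list(edges[1:]) + [np.inf]):
        rings.append(~mask & (dist_um >= lo) & (dist_um < hi))
    return RingBinning(edges_um=edges, ring_masks=rings, pixel_size_um=pixel_size_um)


def ring_bin_centers_um(edges_um: Sequence = DEFAULT_RING_EDGES_UM) -> np.ndarray:
    """Representative distances per bin for the per-µm x convention.

    The inside-disrupted bin sits at 0; each band at its midpoint; the
    unbounded last band at its lower edge plus half the preceding width.
    """
    e = [float(x) for x in edges_um]
    centers = [0.0]
    for lo, hi in zip(e[:-1], e[1:]):
        centers.append(0.5 * (lo + hi))
    centers.append(e[-1] + 0.5 * (e[-1] - e[-2]))
    return np.asarray(centers)


def bin_positive_fractions(
    nuclei: NucleusTable,
    calls: MarkerCallTable,
    rings: RingBinning,
) -> DistanceProfile:
    """Per-ring positive-cell counts and percentages.

    Each nucleus is assigned to the ring containing its centroid (rounded to
    the nearest pixel). Empty bins report NaN, not 0: a band with no cells
    carries no information.
    """
    if not nuclei.records.index.equals(calls.calls.index):
        raise DataError("nucleus labels and marker calls do not match")
    n_bins = len(rings.ring_masks)
    idx_map = rings.ring_index_map
    n_cells = np.zeros(n_bins, dtype=int)
    n_pos = np.zeros(n_bins, dtype=int)
    if nuclei.n_nuclei:
        r = np.clip(
            np.round(nuclei.records["centroid_row"]).astype(int), 0, idx_map.shape[0] - 1
        )
        c = np.clip(
            np.round(nuclei.records["centroid_col"]).astype(int), 0, idx_map.shape[1] - 1
        )
        bins = idx_map[r, c]
        pos = calls.calls.to_numpy()
        for b in range(n_bins):
            sel = bins == b
            n_cells[b] = int(sel.sum())
            n_pos[b] = int(pos[sel].sum())
    return DistanceProfile(
        bin_labels=RING_LABELS if n_bins == len(RING_LABELS) else tuple(map(str, range(n_bins))),
        n_cells=n_cells,
        n_positive=n_pos,
        marker_name=calls.marker_name,
    )


def fit_distance_slope(
    profile: DistanceProfile,
    x_convention: str = "bin_index",
    edges_um: Sequence = DEFAULT_RING_EDGES_UM,
) -> SlopeResult:
    """Ordinary least squares of positive percentage against ring position.

    ``x`` is the ring index 0..4 by default, or representative distances in
    µm (``x_convention="bin_center_um"``). NaN (empty) bins are excluded;
    fewer than two usable bins is an error.
    """
    y = profile.fraction_percent
    if x_convention == "bin_index":
        x = np.arange(len(y), dtype=float)
    elif x_convention == "bin_center_um":
        x = ring_bin_centers_um(edges_um)[: len(y)]
    else:
        raise DataError(f"unknown x_convention {x_convention!r}")
    ok = np.isfinite(y)
    if ok.sum() < 2:
        raise DataError("need at least two non-empty bins to fit a slope")
    res = stats.linregress(x[ok], y[ok])
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    return SlopeResult(
        m=float(res.slope),
        intercept=float(res.intercept),
        x_convention=x_convention,
        r_squared=r2,
        stderr=float(res.stderr),
        n_used=int(ok.sum()),
    )


def area_fraction_timecourse(
    masks: Sequence, organized: bool = True
) -> pd.DataFrame:
    """Tidy table of disrupted/organized area percentage over time.

    ``masks`` is a sequence of ``(time, RegionMask)``; organized percent is
    the complement of the disrupted percent at every time point.
    """
    times = [t for t, _ in masks]
    if len(set(times)) != len(times):
        raise DataError("duplicate time points in time course")
    rows = []
    for t, rm in sorted(masks, key=lambda p: p[0]):
        disrupted = rm.area_fraction_percent
        rows.append(
            {
                "time": t,
                "disrupted_percent": disrupted,
                "organized_percent": 100.0 - disrupted,
            }
        )
    df = pd.DataFrame(rows)
    df["percent"] = df["organized_percent"] if organized else df["disrupted_percent"]
    return df


def _refine_peak(y: np.ndarray) -> tuple:
    """Sub-step peak position by 3-point parabolic interpolation."""
    k = int(np.argmax(y))
    if k == 0 or k == len(y) - 1:
        return float(k), True
    denom = y[k - 1] - 2.0 * y[k] + y[k + 1]
    delta = 0.0 if denom == 0 else 0.5 * (y[k - 1] - y[k + 1]) / denom
    return float(k) + float(np.clip(delta, -0.5, 0.5)), False


def zprofile_peak_distance(
    stack: ImageStack,
    channel_a: str,
    channel_b: str,
    roi: Optional[Union[tuple, np.ndarray]] = None,
) -> ZProfilePair:
    """Axial distance (nm) between the intensity peaks of two stains.

    Both channels are averaged per z-slice within the ROI (a ``(slice,
    slice)`` pair or a 2D boolean mask; whole frame when omitted), peak
    positions are refined to sub-step precision by parabolic interpolation,
    and their separation is reported in nm. ``edge_peak_flag`` marks a peak
    on the first or last slice, where the separation is unreliable.
    """
    if not stack.is_3d or stack.z_step_um is None:
        raise DataError("z-profile analysis needs a 3D stack with z_step_um set")
    a = stack.channel(channel_a).astype(np.float64)
    b = stack.channel(channel_b).astype(np.float64)
    if roi is None:
        sel_a = a.reshape(a.shape[0], -1)
        sel_b = b.reshape(b.shape[0], -1)
    elif isinstance(roi, np.ndarray):
        if roi.dtype != bool or roi.shape != a.shape[1:]:
            raise DataError("ROI mask must be boolean with the frame shape")
        sel_a, sel_b = a[:, roi], b[:, roi]
    else:
        ys, xs = roi
        sel_a = a[:, ys, xs].reshape(a.shape[0], -1)
        sel_b = b[:, ys, xs].reshape(b.shape[0], -1)
    prof_a = sel_a.mean(axis=1)
    prof_b = sel_b.mean(axis=1)
    pa, edge_a = _refine_peak(prof_a)
    pb, edge_b = _refine_peak(prof_b)
    dist_nm = abs(pa - pb) * stack.z_step_um * 1000.0
    z_um = np.arange(a.shape[0]) * stack.z_step_um
    return ZProfilePair(
        z_um=z_um,
        intensity_a=prof_a,
        intensity_b=prof_b,
        peak_distance_nm=float(dist_nm),
        edge_peak_flag=bool(edge_a or edge_b),
        channel_a=channel_a,
        channel_b=channel_b,
    )
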