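"""Core data containers shared by every pipeline stage.

Conventions: pixel coordinates are 0-based ``(row, col)`` with the origin at
the top-left pixel center; all physical quantities are in µm (areas in µm²)
via ``pixel_size_um``. Images are stored channel-by-name so that stages can
ask for stains ("DAPI", "ZO1", "BRACH", ...) rather than channel indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd


class EpiquantError(Exception):
    """Base class for errors raised by this package."""


class DataError(EpiquantError):
    """Input data violate a documented precondition."""


class ConfigError(EpiquantError):
    """A run configuration is invalid."""


@dataclass
class ImageStack:
    """Named-channel image with physical pixel size.

    Parameters
    ----------
    channels
        Mapping stain name -> 2D ``(y, x)`` or 3D ``(z, y, x)`` array of
        non-negative intensities. All channels must share one shape.
    pixel_size_um
        Lateral pixel size in µm/px (isotropic in x/y).
    z_step_um
        Axial step in µm between z-slices, required for z-profile analysis.
    """

    channels: dict
    pixel_size_um: float
    z_step_um: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise DataError("ImageStack needs at least one channel")
        if self.pixel_size_um <= 0:
            raise DataError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise DataError(f"channels must share one shape, got {sorted(shapes)}")
        self.channels = {k: np.asarray(v) for k, v in self.channels.items()}
        if self.z_step_um is not None and self.z_step_um <= 0:
            raise DataError("z_step_um must be positive when given")

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape

    @property
    def is_3d(self) -> bool:
        return len(self.shape) == 3

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise DataError(
                f"channel {name!r} not in stack (have: {sorted(self.channels)})"
            ) from None


@dataclass
class NucleusTable:
    """Labeled nuclei with per-nucleus measurements.

    ``label_map`` is an integer image (0 = background, labels 1..n
    consecutive). ``records`` is a DataFrame indexed by label with columns
    ``centroid_row``, ``centroid_col`` (px), ``area_um2`` and one
    ``mean_<channel>`` column per requested intensity channel.
    """

    label_map: np.ndarray
    records: pd.DataFrame

    def __post_init__(self) -> None:
        labels = np.asarray(self.records.index)
        if len(labels) and not np.array_equal(np.sort(labels), np.arange(1, len(labels) + 1)):
            raise DataError("nucleus labels must be consecutive 1..n")
        if len(labels) and (self.records["area_um2"] <= 0).any():
            raise DataError("every nucleus must have positive area")

    @property
    def n_nuclei(self) -> int:
        return len(self.records)


@dataclass
class MarkerCallTable:
    """Per-nucleus positivity calls for one nuclear marker."""

    marker_name: str
    calls: pd.Series  # bool, indexed by nucleus label
    threshold_used: float
    positive_fraction_rule: float = 0.5

    def __post_init__(self) -> None:
        self.calls = self.calls.astype(bool)

    @property
    def n_total(self) -> int:
        return len(self.calls)

    @property
    def n_positive(self) -> int:
        return int(self.calls.sum())


@dataclass
class RegionMask:
    """Binary disrupted-epithelium mask with its exact area fraction."""

    mask: np.ndarray
    provenance: str = "auto"  # "auto" | "manual" | "truth"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise DataError("RegionMask must be 2D")
        if self.provenance not in ("auto", "manual", "truth"):
            raise DataError(f"unknown provenance {self.provenance!r}")

    @property
    def area_fraction_percent(self) -> float:
        """Exactly 100 × true pixels / total pixels."""
        return 100.0 * float(self.mask.sum()) / self.mask.size


#: Default concentric distance-band edges (µm) away from disrupted areas.
DEFAULT_RING_EDGES_UM = (0.0, 30.0, 60.0, 90.0)

#: Bin labels: inside the disrupted zone, then half-open distance bands.
RING_LABELS = ("0", "+30", "+60", "+90", ">+90")


@dataclass
class RingBinning:
    """Concentric distance-ring masks around a disrupted-region mask.

    Five pairwise-disjoint masks tiling the image: inside-disrupted, then
    [0,30), [30,60), [60,90), [90,inf) µm away (half-open intervals).
    """

    edges_um: tuple
    ring_masks: list
    pixel_size_um: float
    degenerate: bool = False  # disrupted mask covered the whole image

    def __post_init__(self) -> None:
        if len(self.ring_masks) != len(self.edges_um) + 1:
            raise DataError("need one ring mask per band plus the inside-disrupted mask")

    @property
    def ring_index_map(self) -> np.ndarray:
        """Integer image: 0 = inside disrupted, 1..4 = distance bands."""
        out = np.zeros(self.ring_masks[0].shape, dtype=np.int8)
        for i, m in enumerate(self.ring_masks):
            out[m] = i
        return out


@dataclass
class DistanceProfile:
    """Positive-cell fraction per distance ring (percent; NaN = empty bin)."""

    bin_labels: tuple
    n_cells: np.ndarray
    n_positive: np.ndarray
    marker_name: str = ""

    def __post_init__(self) -> None:
        self.n_cells = np.asarray(self.n_cells, dtype=int)
        self.n_positive = np.asarray(self.n_positive, dtype=int)
        if (self.n_positive > self.n_cells).any():
            raise DataError("n_positive cannot exceed n_cells in any bin")

    @property
    def fraction_percent(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.n_cells > 0, 100.0 * self.n_positive / self.n_cells, np.nan
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": list(self.bin_labels),
                "n_cells": self.n_cells,
                "n_positive": self.n_positive,
                "fraction_percent": self.fraction_percent,
            }
        )


@dataclass
class SlopeResult:
    """Least-squares slope of positive fraction against ring position."""

    m: float
    intercept: float
    x_convention: str  # "bin_index" | "bin_center_um"
    r_squared: float
    stderr: float = float("nan")
    n_used: int = 0  # number of non-empty bins in the fit

    def __post_init__(self) -> None:
        if self.x_convention not in ("bin_index", "bin_center_um"):
            raise DataError(f"unknown x_convention {self.x_convention!r}")
        if np.isfinite(self.r_squared) and not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise DataError("r_squared must be in [0, 1]")

    @property
    def ci95(self) -> tuple:
        """95% CI for the slope (Student's t with n_used - 2 dof)."""
        from scipy import stats as _stats

        crit = _stats.t.ppf(0.975, self.n_used - 2) if self.n_used > 2 else 1.96
        half = crit * self.stderr
        return (self.m - half, self.m + half)


@dataclass
class ZProfilePair:
    """Mean z-intensity profiles of two channels and their peak separation."""

    z_um: np.ndarray
    intensity_a: np.ndarray
    intensity_b: np.ndarray
    peak_distance_nm: float
    edge_peak_flag: bool
    channel_a: str = ""
    channel_b: str = ""


@dataclass
class RadialProfile:
    """Mean intensity of one channel in equal-width annuli of one colony."""

    colony_id: str
    channel: str
    r_bin_centers_um: np.ndarray
    mean_intensity: np.ndarray
    n_pixels: np.ndarray
    colony_center_px: tuple
    colony_radius_um: float

    def __post_init__(self) -> None:
        r = np.asarray(self.r_bin_centers_um, dtype=float)
        if np.any(np.diff(r) <= 0):
            raise DataError("r_bin_centers_um must be strictly increasing")
        if r[-1] > self.colony_radius_um:
            raise DataError("last bin center exceeds colony radius")


@dataclass
class ProfileAggregate:
    """Across-colony mean and quartile band of normalized radial profiles."""

    channel: str
    condition: str
    r_bin_centers_um: np.ndarray
    mean: np.ndarray
    q1: np.ndarray
    q3: np.ndarray
    n_colonies: int
    normalization_factor: float

    def __post_init__(self) -> None:
        if self.n_colonies < 1:
            raise DataError("aggregate needs at least one colony")
        if self.normalization_factor <= 0:
            raise DataError("normalization factor must be positive")
        if np.any(self.q1 > self.q3 + 1e-12):
            raise DataError("per-bin Q1 must not exceed Q3")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_um": self.r_bin_centers_um,
                "mean": self.mean,
                "q1": self.q1,
                "q3": self.q3,
            }
        ).assign(channel=self.channel, condition=self.condition)
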