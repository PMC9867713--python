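"""Synthetic fluorescence-microscopy fields with known ground truth.

Two kinds of field are emulated, matching the biology the pipeline
quantifies:

* **Confluent epithelial monolayers** — a jittered-grid / Voronoi cell
  tessellation whose junction channel (ZO1-like) is the polygonal edge
  network, with irregular patches where the network is fragmented into foci
  or erased ("disrupted areas"), nuclei (DAPI-like) at cell centers, and a
  nuclear marker whose per-cell positivity probability depends on the cell's
  true distance band from the disrupted patches.
* **Circular micropattern colonies** (2D gastruloids, default 700 µm
  diameter) whose channels carry concentric fate domains — annular intensity
  bands — plus read noise.

Every generated field comes with the exact ground truth (masks, label maps,
per-cell ring indices and positivity, noise-free radial profiles), so each
analysis stage can be validated by parameter recovery. Images are rendered
as 16-bit unsigned with additive Gaussian read noise, the common microscope
output format.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.segmentation import find_boundaries

from .types import DataError, ImageStack, MarkerCallTable, NucleusTable

__all__ = [
    "MonolayerSpec",
    "MonolayerTruth",
    "ColonySpec",
    "ColonyTruth",
    "generate_monolayer",
    "generate_colony_set",
    "generate_timecourse",
    "truth_to_tables",
]


@dataclass(frozen=True)
class MonolayerSpec:
    """Parameters of a synthetic epithelial-monolayer field.

    ``marker_prob_by_ring`` gives the positivity probability of the nuclear
    marker for cells in the four distance bands 0–30, 30–60, 60–90 and
    >90 µm from the disrupted areas (cells inside a disrupted patch have
    distance 0 and belong to the first band).
    """

    field_size_px: tuple = (512, 512)
    pixel_size_um: float = 1.0
    mean_cell_diameter_um: float = 15.0
    disrupted_fraction_target: float = 0.4
    n_patches: int = 4
    marker_prob_by_ring: tuple = (0.9, 0.7, 0.5, 0.3)
    junction_disruption_style: str = "foci"  # "foci" | "erased"
    marker_channel: str = "BRACH"
    noise_sd: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.marker_prob_by_ring) != 4:
            raise DataError("marker_prob_by_ring needs exactly 4 entries")
        if not all(0.0 <= p <= 1.0 for p in self.marker_prob_by_ring):
            raise DataError("marker probabilities must lie in [0, 1]")
        if not 0.0 <= self.disrupted_fraction_target <= 1.0:
            raise DataError("disrupted_fraction_target must lie in [0, 1]")
        if self.junction_disruption_style not in ("foci", "erased"):
            raise DataError(
                f"unknown junction_disruption_style {self.junction_disruption_style!r}"
            )
        if self.pixel_size_um <= 0 or self.mean_cell_diameter_um <= 0:
            raise DataError("physical sizes must be positive")
        if self.n_patches < 1:
            raise DataError("n_patches must be a positive integer")
        if self.noise_sd < 0:
            raise DataError("noise_sd must be non-negative")


@dataclass
class MonolayerTruth:
    """Exact ground truth accompanying a generated monolayer field."""

    disrupted_mask: np.ndarray  # bool (y, x)
    cell_label_map: np.ndarray  # int (y, x), labels 1..n
    cell_centers_px: np.ndarray  # (n, 2) float, (row, col) per label 1..n
    positive_cell_ids: frozenset
    per_cell_ring_index: dict  # label -> 0..3
    per_cell_area_um2: dict  # label -> area

    def __post_init__(self) -> None:
        labels = set(np.unique(self.cell_label_map)) - {0}
        if not self.positive_cell_ids <= labels:
            raise DataError("positive_cell_ids must be labels of cell_label_map")
        if set(self.per_cell_ring_index) != labels:
            raise DataError("every cell needs exactly one ring index")

    @property
    def disrupted_fraction(self) -> float:
        return float(self.disrupted_mask.mean())

    def to_frame(self, pixel_size_um: float) -> pd.DataFrame:
        labels = sorted(self.per_cell_ring_index)
        return pd.DataFrame(
            {
                "cell_id": labels,
                "centroid_row_px": self.cell_centers_px[np.array(labels) - 1, 0],
                "centroid_col_px": self.cell_centers_px[np.array(labels) - 1, 1],
                "ring_index": [self.per_cell_ring_index[c] for c in labels],
                "positive": [c in self.positive_cell_ids for c in labels],
                "area_um2": [self.per_cell_area_um2[c] for c in labels],
            }
        )


def _cell_centers(spec: MonolayerSpec, rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid cell centers reproducing confluent epithelial packing."""
    h, w = spec.field_size_px
    d_px = spec.mean_cell_diameter_um / spec.pixel_size_um
    if d_px < 3.0:
        raise DataError(
            f"cell diameter {spec.mean_cell_diameter_um} µm is below resolution "
            f"at {spec.pixel_size_um} µm/px"
        )
    if d_px > min(h, w) / 2:
        raise DataError(
            f"cell diameter {spec.mean_cell_diameter_um} µm cannot pack into a "
            f"{h}x{w} px field at {spec.pixel_size_um} µm/px"
        )
    rows = np.arange(d_px / 2, h, d_px)
    cols = np.arange(d_px / 2, w, d_px)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    centers = np.column_stack([rr.ravel(), cc.ravel()])
    centers += rng.uniform(-0.35 * d_px, 0.35 * d_px, size=centers.shape)
    centers[:, 0] = np.clip(centers[:, 0], 0, h - 1)
    centers[:, 1] = np.clip(centers[:, 1], 0, w - 1)
    return centers


def _disrupted_mask(spec: MonolayerSpec, rng: np.random.Generator) -> np.ndarray:
    """Irregular patches hitting the target area fraction near-exactly.

    Gaussian bumps at ``n_patches`` random sites, roughened by smoothed
    noise, thresholded at the quantile that yields the requested fraction —
    so the truth fraction equals the target to within quantile ties.
    """
    h, w = spec.field_size_px
    f = spec.disrupted_fraction_target
    if f <= 0.0:
        return np.zeros((h, w), dtype=bool)
    if f >= 1.0:
        return np.ones((h, w), dtype=bool)
    sigma = np.sqrt(f * h * w / spec.n_patches / np.pi)
    margin = min(sigma, min(h, w) / 4)
    sites = np.column_stack(
        [
            rng.uniform(margin, h - margin, spec.n_patches),
            rng.uniform(margin, w - margin, spec.n_patches),
        ]
    )
    yy, xx = np.mgrid[0:h, 0:w]
    bumps = np.zeros((h, w))
    for r0, c0 in sites:
        bumps += np.exp(-((yy - r0) ** 2 + (xx - c0) ** 2) / (2 * sigma**2))
    d_px = spec.mean_cell_diameter_um / spec.pixel_size_um
    rough = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=d_px)
    rough /= max(rough.std(), 1e-12)
    fld = ndimage.gaussian_filter(bumps + 0.08 * rough, sigma=d_px / 2)
    return fld > np.quantile(fld, 1.0 - f)


def _soft_disk(dist: np.ndarray, radius: float, softness: float = 0.8) -> np.ndarray:
    """Smooth-edged disk profile in [0, 1] from a distance field."""
    return 1.0 / (1.0 + np.exp((dist - radius) / softness))


def _finish_channel(
    img: np.ndarray, rng: np.random.Generator, noise_sd: float, baseline: float = 100.0
) -> np.ndarray:
    out = img + baseline
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.round(out), 0, 65535).astype(np.uint16)


def generate_monolayer(spec: MonolayerSpec) -> tuple:
    """Render a monolayer field and its ground truth.

    Returns ``(ImageStack, MonolayerTruth)``. Channels: ``DAPI`` (nuclei),
    ``ZO1`` (junction network, fragmented or erased inside disrupted
    patches) and one nuclear marker channel named ``spec.marker_channel``.
    Identical spec + seed gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_size_px
    px = spec.pixel_size_um
    d_px = spec.mean_cell_diameter_um / px

    centers = _cell_centers(spec, rng)
    tree = cKDTree(centers)
    yy, xx = np.mgrid[0:h, 0:w]
    dist_to_center, idx = tree.query(np.column_stack([yy.ravel(), xx.ravel()]))
    label_map = (idx + 1).reshape(h, w).astype(np.int32)
    dist_to_center = dist_to_center.reshape(h, w)

    disrupted = _disrupted_mask(spec, rng)

    # ring index per cell from the exact Euclidean distance of its center;
    # with no disrupted patches every cell is beyond the last edge
    if disrupted.any():
        edt_um = ndimage.distance_transform_edt(~disrupted) * px
        center_px = np.clip(np.round(centers).astype(int), 0, [h - 1, w - 1])
        center_dist = edt_um[center_px[:, 0], center_px[:, 1]]
        ring_index = np.digitize(center_dist, [30.0, 60.0, 90.0])  # 0..3
    else:
        ring_index = np.full(len(centers), 3)

    probs = np.asarray(spec.marker_prob_by_ring)[ring_index]
    positive = rng.random(len(centers)) < probs
    positive_ids = frozenset(np.flatnonzero(positive) + 1)

    # --- DAPI: soft nuclear disks at cell centers -------------------------
    nuc_r = 0.32 * d_px
    nuc_profile = _soft_disk(dist_to_center, nuc_r)
    dapi = 3000.0 * nuc_profile

    # --- ZO1: Voronoi edge network, broken inside disrupted patches -------
    network = find_boundaries(label_map, mode="thick")
    zo1 = np.where(network, 2500.0, 0.0)
    zo1[disrupted] = 0.0
    if spec.junction_disruption_style == "foci" and disrupted.any():
        in_rows, in_cols = np.nonzero(disrupted)
        n_foci = max(1, int(disrupted.sum() / (d_px**2)))
        pick = rng.choice(len(in_rows), size=min(n_foci, len(in_rows)), replace=False)
        foci = np.zeros((h, w))
        foci[in_rows[pick], in_cols[pick]] = 1.0
        foci = ndimage.grey_dilation(foci, size=(3, 3))
        zo1 += 2500.0 * foci * disrupted
    zo1 = ndimage.gaussian_filter(zo1, sigma=0.6)

    # --- marker: nuclear signal in positive cells -------------------------
    pos_lookup = np.zeros(len(centers) + 1, dtype=bool)
    pos_lookup[list(positive_ids)] = True
    marker = 2500.0 * nuc_profile * pos_lookup[label_map]

    stack = ImageStack(
        channels={
            "DAPI": _finish_channel(dapi, rng, spec.noise_sd),
            "ZO1": _finish_channel(zo1, rng, spec.noise_sd),
            spec.marker_channel: _finish_channel(marker, rng, spec.noise_sd),
        },
        pixel_size_um=px,
    )
    areas_px = np.bincount(label_map.ravel(), minlength=len(centers) + 1)
    truth = MonolayerTruth(
        disrupted_mask=disrupted,
        cell_label_map=label_map,
        cell_centers_px=centers,
        positive_cell_ids=positive_ids,
        per_cell_ring_index={i + 1: int(ring_index[i]) for i in range(len(centers))},
        per_cell_area_um2={
            i + 1: float(areas_px[i + 1]) * px**2 for i in range(len(centers))
        },
    )
    return stack, truth


def truth_to_tables(
    truth: MonolayerTruth, spec: MonolayerSpec
) -> tuple[NucleusTable, MarkerCallTable]:
    """Ground-truth cell table re-expressed as segmentation-stage outputs.

    Lets the distance-ring statistics be validated on exact per-cell truth,
    independently of segmentation quality.
    """
    n = len(truth.cell_centers_px)
    records = pd.DataFrame(
        {
            "centroid_row": truth.cell_centers_px[:, 0],
            "centroid_col": truth.cell_centers_px[:, 1],
            "area_um2": [truth.per_cell_area_um2[i + 1] for i in range(n)],
        },
        index=pd.RangeIndex(1, n + 1, name="label"),
    )
    nuclei = NucleusTable(label_map=truth.cell_label_map, records=records)
    calls = MarkerCallTable(
        marker_name=spec.marker_channel,
        calls=pd.Series(
            [i + 1 in truth.positive_cell_ids for i in range(n)],
            index=records.index,
        ),
        threshold_used=float("nan"),
    )
    return nuclei, calls


# --------------------------------------------------------------------------
# Micropattern colonies
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ColonySpec:
    """Circular micropattern colony set with concentric fate domains.

    ``fate_domains`` entries are ``(channel, inner_frac, outer_frac,
    intensity)``: the channel carries ``intensity`` for radii with
    r/R in [inner_frac, outer_frac). Domains on one channel must not
    overlap. A DAPI channel (uniform nuclear signal over the disk) is always
    rendered.
    """

    diameter_um: float = 700.0
    pixel_size_um: float = 2.0
    fate_domains: tuple = (
        ("SOX2", 0.0, 0.5, 2000.0),
        ("BRACH", 0.7, 1.0, 2000.0),
    )
    colony_noise_sd: float = 50.0
    n_colonies: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diameter_um <= 0 or self.pixel_size_um <= 0:
            raise DataError("colony geometry must be positive")
        if self.n_colonies < 1:
            raise DataError("n_colonies must be positive")
        by_channel: dict = {}
        for chan, fin, fout, inten in self.fate_domains:
            if not (0.0 <= fin < fout <= 1.0):
                raise DataError(
                    f"domain on {chan!r}: need 0 <= inner < outer <= 1, "
                    f"got ({fin}, {fout})"
                )
            for a, b in by_channel.get(chan, []):
                if fin < b and a < fout:
                    raise DataError(f"overlapping fate domains on channel {chan!r}")
            by_channel.setdefault(chan, []).append((fin, fout))


@dataclass
class ColonyTruth:
    """Noise-free radial intensity profiles shared by all colonies of a set."""

    r_frac_centers: np.ndarray  # bin centers as r/R
    profiles: dict  # channel -> intensity per bin
    radius_um: float

    def profile_um(self, channel: str) -> tuple:
        return self.r_frac_centers * self.radius_um, self.profiles[channel]


def _domain_value(domains: Sequence, channel: str, r_frac: np.ndarray) -> np.ndarray:
    out = np.zeros_like(r_frac, dtype=float)
    for chan, fin, fout, inten in domains:
        if chan != channel:
            continue
        inside = (r_frac >= fin) & ((r_frac < fout) | ((fout >= 1.0) & (r_frac <= 1.0)))
        out[inside] += inten
    return out


def generate_colony_set(spec: ColonySpec, n_truth_bins: int = 50) -> tuple:
    """Render ``n_colonies`` micropattern images plus the shared truth.

    Returns ``(stacks, truth)``; each stack is a disk of the requested
    diameter with its fate-domain intensities plus independent read noise,
    the truth the noise-free radial function on ``n_truth_bins`` annuli.
    """
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size_um
    radius_um = spec.diameter_um / 2.0
    r_px = radius_um / px
    margin = 10
    size = int(np.ceil(2 * r_px)) + 2 * margin
    c0 = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    r_um = np.hypot(yy - c0, xx - c0) * px
    disk = r_um <= radius_um
    r_frac = np.where(disk, r_um / radius_um, np.inf)

    channel_names = sorted({d[0] for d in spec.fate_domains} | {"DAPI"})
    base: dict = {}
    for name in channel_names:
        if name == "DAPI":
            img = np.where(disk, 2000.0, 0.0)
            img += _domain_value(spec.fate_domains, "DAPI", r_frac) * disk
        else:
            img = _domain_value(spec.fate_domains, name, r_frac) * disk
        base[name] = img

    stacks = []
    for _ in range(spec.n_colonies):
        stacks.append(
            ImageStack(
                channels={
                    name: _finish_channel(img, rng, spec.colony_noise_sd)
                    for name, img in base.items()
                },
                pixel_size_um=px,
            )
        )

    edges = np.linspace(0.0, 1.0, n_truth_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    profiles = {
        name: (
            np.full(n_truth_bins, 2000.0)
            + _domain_value(spec.fate_domains, "DAPI", centers)
            if name == "DAPI"
            else _domain_value(spec.fate_domains, name, centers)
        )
        for name in channel_names
    }
    truth = ColonyTruth(r_frac_centers=centers, profiles=profiles, radius_um=radius_um)
    return stacks, truth


def generate_timecourse(base: MonolayerSpec, organized_fraction_curve: dict) -> list:
    """Monolayer fields along a junction-reassembly time course.

    ``organized_fraction_curve`` maps time (h) to the organized-area
    fraction; each field is generated with disrupted fraction
    ``1 - organized`` and a time-point-specific seed derived from the base
    seed. Returns ``[(time, ImageStack, MonolayerTruth), ...]`` in time
    order.
    """
    for t, v in organized_fraction_curve.items():
        if not 0.0 <= v <= 1.0:
            raise DataError(f"organized fraction at t={t} must lie in [0,1], got {v}")
    out = []
    for i, t in enumerate(sorted(organized_fraction_curve)):
        spec_t = replace(
            base,
            disrupted_fraction_target=1.0 - organized_fraction_curve[t],
            seed=(base.seed * 1000 + i) % (2**31 - 1),
        )
        stack, truth = generate_monolayer(spec_t)
        out.append((t, stack, truth))
    return out
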