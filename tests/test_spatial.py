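"""Distance-ring statistics: oracles, invariants and parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from conftest import brute_force_nearest_distance
from epiquant.spatial import (
    area_fraction_timecourse,
    bin_positive_fractions,
    fit_distance_slope,
    make_ring_masks,
    ring_bin_centers_um,
    zprofile_peak_distance,
)
from epiquant.synthetic import MonolayerSpec, generate_monolayer, truth_to_tables
from epiquant.types import (
    DataError,
    DistanceProfile,
    ImageStack,
    RegionMask,
    RING_LABELS,
)


def random_blob_mask(seed, shape=(64, 64), frac=0.2):
    rng = np.random.default_rng(seed)
    fld = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=6)
    return fld > np.quantile(fld, 1 - frac)


@pytest.mark.parametrize("seed", range(8))
def test_ring_masks_partition_the_image(seed):
    mask = random_blob_mask(seed)
    rings = make_ring_masks(RegionMask(mask=mask), pixel_size_um=2.0)
    stackd = np.stack([m.astype(int) for m in rings.ring_masks])
    assert (stackd.sum(axis=0) == 1).all()  # disjoint and tiling


@pytest.mark.parametrize("seed", range(4))
def test_ring_assignment_equals_brute_force_distance(seed):
    """Every pixel's band matches the O(N*M) nearest-disrupted-pixel oracle."""
    mask = random_blob_mask(100 + seed, shape=(48, 48), frac=0.15)
    px = 2.5
    rings = make_ring_masks(RegionMask(mask=mask), pixel_size_um=px)
    d_um = brute_force_nearest_distance(mask) * px
    expected = np.zeros(mask.shape, dtype=int)
    edges = [0.0, 30.0, 60.0, 90.0, np.inf]
    off = ~mask
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        expected[off & (d_um >= lo) & (d_um < hi)] = i + 1
    assert np.array_equal(rings.ring_index_map, expected)


def test_first_ring_matches_analytic_annulus_area():
    """0-30 µm band around a 50 px disk == pi*(80^2-50^2) within 2%."""
    size = 256
    yy, xx = np.mgrid[0:size, 0:size]
    disk = np.hypot(yy - 128, xx - 128) <= 50
    rings = make_ring_masks(RegionMask(mask=disk), pixel_size_um=1.0)
    analytic = np.pi * (80.0**2 - 50.0**2)
    assert rings.ring_masks[1].sum() == pytest.approx(analytic, rel=0.02)


def test_degenerate_and_empty_masks():
    full = RegionMask(mask=np.ones((32, 32), dtype=bool))
    rings = make_ring_masks(full, pixel_size_um=1.0)
    assert rings.degenerate
    assert all(not m.any() for m in rings.ring_masks[1:])
    with pytest.raises(DataError, match="empty"):
        make_ring_masks(RegionMask(mask=np.zeros((32, 32), dtype=bool)), 1.0)


def test_all_positive_cells_give_100_percent_everywhere(monolayer40):
    spec, _, truth = monolayer40
    nuclei, calls = truth_to_tables(truth, spec)
    calls.calls[:] = True
    rings = make_ring_masks(
        RegionMask(mask=truth.disrupted_mask, provenance="truth"), spec.pixel_size_um
    )
    profile = bin_positive_fractions(nuclei, calls, rings)
    frac = profile.fraction_percent
    assert np.all(frac[profile.n_cells > 0] == 100.0)


def test_empty_ring_reports_nan_not_zero():
    profile = DistanceProfile(
        bin_labels=RING_LABELS,
        n_cells=np.array([10, 0, 5, 0, 2]),
        n_positive=np.array([5, 0, 1, 0, 0]),
    )
    frac = profile.fraction_percent
    assert np.isnan(frac[1]) and np.isnan(frac[3])
    assert frac[4] == 0.0  # a sampled-but-negative ring is 0, not NaN


def test_planted_ring_probabilities_recovered(large_monolayer):
    """Per-ring positive fractions sit inside binomial 95% CIs of the truth."""
    spec, _, truth = large_monolayer
    nuclei, calls = truth_to_tables(truth, spec)
    rings = make_ring_masks(
        RegionMask(mask=truth.disrupted_mask, provenance="truth"), spec.pixel_size_um
    )
    profile = bin_positive_fractions(nuclei, calls, rings)
    # bins "0" and "+30" both carry the first planted probability
    planted = np.array([spec.marker_prob_by_ring[0]] + list(spec.marker_prob_by_ring))
    assert (profile.n_cells >= 200).all()
    # Bonferroni-adjusted per-bin intervals: family confidence 95%
    # across the five simultaneous bins (per-bin z for alpha = 0.05/5)
    z = 2.576
    for k in range(5):
        n, p = profile.n_cells[k], planted[k]
        half = z * np.sqrt(p * (1 - p) / n)
        assert abs(profile.fraction_percent[k] / 100 - p) <= half + 1e-12


def test_centroid_binning_matches_truth_ring_indices(large_monolayer):
    spec, _, truth = large_monolayer
    nuclei, calls = truth_to_tables(truth, spec)
    rings = make_ring_masks(
        RegionMask(mask=truth.disrupted_mask, provenance="truth"), spec.pixel_size_um
    )
    idx_map = rings.ring_index_map
    centers = np.round(truth.cell_centers_px).astype(int)
    measured_band = idx_map[centers[:, 0], centers[:, 1]]
    # collapse the inside-disrupted band onto the first distance band, which
    # is how the generator assigns its 4 ring indices
    collapsed = np.maximum(measured_band - 1, 0)
    planted = np.array([truth.per_cell_ring_index[i + 1] for i in range(len(centers))])
    assert (collapsed == planted).mean() > 0.999


def test_slope_closed_form_exact():
    profile = DistanceProfile(
        bin_labels=RING_LABELS,
        n_cells=np.full(5, 100),
        n_positive=np.array([100, 88, 76, 64, 52]),
    )
    res = fit_distance_slope(profile)
    assert res.m == pytest.approx(-12.0)
    assert res.r_squared == pytest.approx(1.0)
    assert res.x_convention == "bin_index"


def test_constant_profile_has_zero_slope():
    profile = DistanceProfile(
        bin_labels=RING_LABELS, n_cells=np.full(5, 50), n_positive=np.full(5, 20)
    )
    assert fit_distance_slope(profile).m == pytest.approx(0.0)


def test_slope_per_um_convention_rescales():
    profile = DistanceProfile(
        bin_labels=RING_LABELS,
        n_cells=np.full(5, 100),
        n_positive=np.array([100, 88, 76, 64, 52]),
    )
    res = fit_distance_slope(profile, x_convention="bin_center_um")
    assert res.x_convention == "bin_center_um"
    assert res.m < 0
    centers = ring_bin_centers_um()
    assert centers == pytest.approx([0.0, 15.0, 45.0, 75.0, 105.0])


def test_slope_needs_two_usable_bins():
    profile = DistanceProfile(
        bin_labels=RING_LABELS,
        n_cells=np.array([50, 0, 0, 0, 0]),
        n_positive=np.array([10, 0, 0, 0, 0]),
    )
    with pytest.raises(DataError, match="two"):
        fit_distance_slope(profile)


def test_slope_recovery_coverage_and_null_centering():
    """Planted linear ring gradients: the OLS 95% CI covers the planted
    slope in >=90% of replicates; uniform positivity centers on 0."""
    rng = np.random.default_rng(1234)
    n_per_ring, beta, p0 = 400, -0.12, 0.9
    planted_m = 100 * beta
    covered = 0
    null_ms = []
    for _ in range(100):
        probs = p0 + beta * np.arange(5)
        n_pos = rng.binomial(n_per_ring, probs)
        prof = DistanceProfile(
            bin_labels=RING_LABELS,
            n_cells=np.full(5, n_per_ring),
            n_positive=n_pos,
        )
        res = fit_distance_slope(prof)
        lo, hi = res.ci95
        covered += lo <= planted_m <= hi
        n_pos_null = rng.binomial(n_per_ring, np.full(5, 0.4))
        null = DistanceProfile(
            bin_labels=RING_LABELS,
            n_cells=np.full(5, n_per_ring),
            n_positive=n_pos_null,
        )
        null_ms.append(fit_distance_slope(null).m)
    assert covered >= 90
    null_ms = np.asarray(null_ms)
    se = null_ms.std(ddof=1) / np.sqrt(len(null_ms))
    assert abs(null_ms.mean()) < 2 * se + 0.05


def test_timecourse_table_and_complement_identity():
    masks = []
    for i, t in enumerate((0, 9, 18)):
        m = np.zeros((50, 50), dtype=bool)
        m.ravel()[: (i + 1) * 500] = True
        masks.append((t, RegionMask(mask=m)))
    df = area_fraction_timecourse(masks)
    assert list(df["time"]) == [0, 9, 18]
    assert np.allclose(df["organized_percent"] + df["disrupted_percent"], 100.0)
    single = area_fraction_timecourse(masks[:1])
    assert len(single) == 1
    with pytest.raises(DataError, match="duplicate"):
        area_fraction_timecourse([masks[0], (0, masks[1][1])])


def make_zstack(mu_a, mu_b, z_step=0.3, n=20, sigma=0.5):
    z = np.arange(n) * z_step
    a = np.exp(-((z - mu_a) ** 2) / (2 * sigma**2))
    b = np.exp(-((z - mu_b) ** 2) / (2 * sigma**2))
    shape = (n, 6, 6)
    return ImageStack(
        channels={
            "ZO1": np.round(4000 * a)[:, None, None] * np.ones(shape, dtype=int),
            "BMPR1A": np.round(4000 * b)[:, None, None] * np.ones(shape, dtype=int),
        },
        pixel_size_um=0.1,
        z_step_um=z_step,
    )


def test_zprofile_identical_channels_zero_distance():
    stack = make_zstack(2.0, 2.0)
    zp = zprofile_peak_distance(stack, "ZO1", "ZO1")
    assert zp.peak_distance_nm == 0.0


def test_zprofile_recovers_planted_separation():
    stack = make_zstack(2.0, 3.2)  # 1.2 µm apart on a 0.3 µm grid
    zp = zprofile_peak_distance(stack, "ZO1", "BMPR1A")
    assert zp.peak_distance_nm == pytest.approx(1200.0, abs=150.0)
    assert not zp.edge_peak_flag


def test_zprofile_monotone_profile_flags_edge_peak():
    n = 15
    ramp = np.arange(1, n + 1)[:, None, None] * np.ones((n, 4, 4), dtype=int)
    stack = ImageStack(
        channels={"A": ramp, "B": ramp[::-1].copy()}, pixel_size_um=0.1, z_step_um=0.25
    )
    assert zprofile_peak_distance(stack, "A", "B").edge_peak_flag


def test_zprofile_requires_3d_stack():
    stack = ImageStack(
        channels={"A": np.ones((8, 8), dtype=int), "B": np.ones((8, 8), dtype=int)},
        pixel_size_um=0.1,
    )
    with pytest.raises(DataError, match="3D"):
        zprofile_peak_distance(stack, "A", "B")
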