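"""Isoscape grid I/O, interval assignment and summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orcascape import (
    IsoscapeGrid,
    MarineEstimate,
    assign_interval,
    assign_specimens,
    mask_summary,
    read_isoscape,
    write_isoscape,
)
from orcascape.isoscape import EmptyGridError, FormatError, IntervalError


def small_grid():
    return IsoscapeGrid(
        lat=np.array([10.0, 20.0, 30.0]),
        lon=np.array([-40.0, -30.0, -20.0]),
        values=np.arange(1.0, 10.0).reshape(3, 3),
        missing=np.zeros((3, 3), bool),
    )


def test_netcdf_roundtrip(tmp_path):
    grid = small_grid()
    path = tmp_path / "iso.nc"
    write_isoscape(grid, path)
    back = read_isoscape(path)
    assert np.array_equal(back.lat, grid.lat)
    assert np.array_equal(back.lon, grid.lon)
    assert np.array_equal(back.values, grid.values)
    assert np.array_equal(back.missing, grid.missing)


def test_csv_dialect_matches_netcdf(tmp_path):
    grid = small_grid()
    write_isoscape(grid, tmp_path / "iso.nc")
    write_isoscape(grid, tmp_path / "iso.csv")
    a = read_isoscape(tmp_path / "iso.nc")
    b = read_isoscape(tmp_path / "iso.csv")
    assert np.array_equal(a.values, b.values)
    assert np.array_equal(a.lat, b.lat) and np.array_equal(a.lon, b.lon)


def test_descending_latitudes_are_normalised(tmp_path):
    grid = small_grid()
    flipped = IsoscapeGrid(
        lat=grid.lat[::-1].copy(),
        lon=grid.lon,
        values=grid.values[::-1].copy(),
        missing=grid.missing[::-1].copy(),
    )
    assert np.array_equal(flipped.lat, grid.lat)
    assert np.array_equal(flipped.values, grid.values)
    write_isoscape(flipped, tmp_path / "flip.nc")
    assert np.array_equal(read_isoscape(tmp_path / "flip.nc").values, grid.values)


def test_missing_variable_is_format_error(tmp_path):
    import xarray as xr

    xr.Dataset({"foo": (("lat", "lon"), np.ones((2, 2)))}, coords={"lat": [0, 1], "lon": [0, 1]}).to_netcdf(
        tmp_path / "bad.nc"
    )
    with pytest.raises(FormatError, match="d18o"):
        read_isoscape(tmp_path / "bad.nc")


def test_all_missing_grid_rejected():
    with pytest.raises(EmptyGridError):
        IsoscapeGrid(
            lat=np.array([0.0]),
            lon=np.array([0.0]),
            values=np.array([[np.nan]]),
            missing=np.array([[True]]),
        )


def test_assign_interval_enumeration():
    mask = assign_interval(small_grid(), (2.0, 4.0))
    assert mask.n_cells == 3 and not mask.empty
    assert mask.mask.sum() == 3


def test_assign_interval_above_grid_maximum_is_empty():
    mask = assign_interval(small_grid(), (9.5, 12.0))
    assert mask.empty and mask.n_cells == 0


def test_assign_interval_unbounded_selects_all_valid():
    grid = small_grid()
    mask = assign_interval(grid, (-math.inf, math.inf))
    assert mask.n_cells == grid.n_valid == 9


def test_assign_interval_excludes_missing_cells():
    grid = small_grid()
    missing = grid.missing.copy()
    missing[0, 0] = True
    grid2 = IsoscapeGrid(grid.lat, grid.lon, grid.values, missing)
    mask = assign_interval(grid2, (-math.inf, math.inf))
    assert mask.n_cells == 8


def test_inverted_interval_rejected():
    with pytest.raises(IntervalError):
        assign_interval(small_grid(), (4.0, 2.0))


@settings(derandomize=True, max_examples=40)
@given(
    lo1=st.floats(-3, 3),
    w1=st.floats(0, 2),
    extra=st.floats(0, 2),
    seed=st.integers(0, 1000),
)
def test_mask_monotone_under_interval_widening(lo1, w1, extra, seed):
    rng = np.random.default_rng(seed)
    vals = rng.normal(0, 2, (5, 6))
    vals[rng.random((5, 6)) < 0.2] = np.nan
    if not np.isfinite(vals).any():
        vals[0, 0] = 0.0
    grid = IsoscapeGrid(np.arange(5.0), np.arange(6.0), vals, ~np.isfinite(vals))
    inner = assign_interval(grid, (lo1, lo1 + w1))
    outer = assign_interval(grid, (lo1 - extra, lo1 + w1 + extra))
    assert np.all(outer.mask[inner.mask])  # inner ⊆ outer


@settings(derandomize=True, max_examples=40)
@given(seed=st.integers(0, 1000), lo=st.floats(-2, 2), w=st.floats(0, 3))
def test_assignment_equals_brute_force_scan(seed, lo, w):
    rng = np.random.default_rng(seed)
    vals = rng.normal(0, 1.5, (4, 5))
    vals[rng.random((4, 5)) < 0.25] = np.nan
    if not np.isfinite(vals).any():
        vals[0, 0] = 0.0
    grid = IsoscapeGrid(np.arange(4.0), np.arange(5.0), vals, ~np.isfinite(vals))
    mask = assign_interval(grid, (lo, lo + w))
    for i in range(4):
        for j in range(5):
            expect = bool(np.isfinite(vals[i, j]) and lo <= vals[i, j] <= lo + w)
            assert bool(mask.mask[i, j]) is expect


def test_masks_insensitive_to_longitude_rotation():
    grid = small_grid()
    rot = IsoscapeGrid(grid.lat, np.roll(grid.lon, 1), np.roll(grid.values, 1, axis=1), np.roll(grid.missing, 1, axis=1))
    a = assign_interval(grid, (2.0, 6.0))
    b = assign_interval(rot, (2.0, 6.0))
    assert a.n_cells == b.n_cells
    assert np.array_equal(np.sort(grid.values[a.mask]), np.sort(rot.values[b.mask]))


def test_mask_summary_cases():
    grid = small_grid()
    empty = mask_summary(assign_interval(grid, (100.0, 101.0)), grid)
    assert empty.fraction == 0.0 and empty.lat_min is None
    full = mask_summary(assign_interval(grid, (-math.inf, math.inf)), grid)
    assert full.fraction == 1.0
    partial = mask_summary(assign_interval(grid, (2.0, 4.0)), grid)
    assert partial.fraction == pytest.approx(1 / 3)
    assert partial.lat_min == 10.0 and partial.lat_max == 20.0


def test_assign_specimens_order_and_empty_flag():
    grid = small_grid()
    ests = [
        MarineEstimate("low", 2.0, 1.0, 0.95, 1.0, 3.0),
        MarineEstimate("too-high", 20.0, 1.0, 0.95, 18.0, 22.0),
    ]
    masks = assign_specimens(ests, grid)
    assert [m.specimen_id for m in masks] == ["low", "too-high"]
    assert not masks[0].empty and masks[1].empty
    assert assign_specimens([], grid) == []


def test_front_grid_confines_low_estimates_to_high_latitudes():
    """With a sharp poleward depletion step, a whale with low inferred source
    δ¹⁸O can only be assigned north of the front."""
    lat = np.linspace(0, 80, 17)
    lon = np.linspace(-60, 0, 13)
    vals = 1.0 - 0.02 * lat[:, None] + (-3.0) * (lat[:, None] >= 40.0) + np.zeros((1, 13))
    grid = IsoscapeGrid(lat, lon, vals, np.zeros(vals.shape, bool))
    low = assign_interval(grid, (-3.5, -2.0))
    s = mask_summary(low, grid)
    assert s.n_cells > 0 and s.lat_min >= 40.0
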