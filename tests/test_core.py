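"""Core data model: I/O round-trips, geometry, whole-tractogram resampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bundleseg.core import (
    ReferenceGrid,
    Tractogram,
    TractogramFormatError,
    read_tractogram,
    resample_streamline_points,
    resample_tractogram_count,
    streamline_arclength,
    supersample_polyline,
    write_tractogram,
)


def _toy_tractogram():
    grid = ReferenceGrid((20, 20, 20), np.eye(4))
    streamlines = [
        np.array([[1.0, 1.0, 1.0], [5.0, 2.0, 3.0], [9.5, 4.0, 3.0]]),
        np.array([[2.0, 2.0, 2.0], [2.0, 2.0, 12.0]]),
        np.array([[0.5, 10.0, 3.0], [4.0, 11.0, 5.0], [8.0, 12.0, 7.0], [12.0, 13.0, 9.0]]),
    ]
    return Tractogram(streamlines, grid)


@pytest.mark.parametrize("fmt", ["trk", "tck"])
def test_write_read_roundtrip(tmp_path, fmt):
    t = _toy_tractogram()
    path = tmp_path / f"toy.{fmt}"
    write_tractogram(t, path)
    back = read_tractogram(path, grid=t.grid if fmt == "tck" else None)
    assert len(back) == len(t)
    for a, b in zip(t.streamlines, back.streamlines):
        assert a.shape == b.shape
        np.testing.assert_allclose(a, b, atol=1e-4)


def test_trk_grid_recovered_from_header(tmp_path):
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = [-10.0, 5.0, 0.0]
    grid = ReferenceGrid((30, 30, 30), affine)
    t = Tractogram([np.array([[0.0, 0.0, 0.0], [10.0, 4.0, 6.0]])], grid)
    path = tmp_path / "g.trk"
    write_tractogram(t, path)
    back = read_tractogram(path)
    assert back.grid.dims == grid.dims
    np.testing.assert_allclose(back.grid.affine, affine, atol=1e-5)


def test_trk_nonidentity_affine_returns_world_mm(tmp_path):
    """Points stored in voxel space must come back through the header affine.

    Oracle: hand application of the 4x4 matrix to the stored voxel points.
    """
    from nibabel import streamlines as nibs

    A = np.array(
        [[2.0, 0, 0, 10.0], [0, 2.0, 0, -5.0], [0, 0, 2.0, 3.0], [0, 0, 0, 1.0]]
    )
    vox_pts = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
    world_expected = vox_pts @ A[:3, :3].T + A[:3, 3]
    tg = nibs.Tractogram([vox_pts.astype(np.float32)], affine_to_rasmm=A)
    header = {
        "voxel_to_rasmm": A.astype(np.float32),
        "dimensions": np.array([20, 20, 20], np.int16),
        "voxel_sizes": np.array([2, 2, 2], np.float32),
        "voxel_order": "RAS",
    }
    path = tmp_path / "affine.trk"
    nibs.save(tg, str(path), header=header)
    back = read_tractogram(path)
    np.testing.assert_allclose(back.streamlines[0], world_expected, atol=1e-3)


def test_malformed_file_raises_format_error(tmp_path):
    bad = tmp_path / "bad.trk"
    bad.write_bytes(b"this is not a trackvis header")
    with pytest.raises(TractogramFormatError, match="malformed"):
        read_tractogram(bad)


def test_single_point_streamline_rejected(tmp_path):
    from nibabel import streamlines as nibs

    tg = nibs.Tractogram(
        [np.array([[1.0, 1.0, 1.0]], dtype=np.float32)], affine_to_rasmm=np.eye(4)
    )
    path = tmp_path / "short.tck"
    nibs.save(tg, str(path))
    with pytest.raises(TractogramFormatError):
        read_tractogram(path, grid=ReferenceGrid((10, 10, 10), np.eye(4)))


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def test_arclength_straight_segment():
    assert streamline_arclength(np.array([[0, 0, 0], [0, 0, 10.0]])) == pytest.approx(10.0)


def test_arclength_square_perimeter():
    square = np.array(
        [[0, 0, 0], [5, 0, 0], [5, 5, 0], [0, 5, 0], [0, 0, 0]], dtype=float
    )
    assert streamline_arclength(square) == pytest.approx(20.0)


@settings(deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_arclength_matches_bruteforce_sum(seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(0, 10, (50, 3))
    brute = sum(
        float(np.sqrt(((pts[i + 1] - pts[i]) ** 2).sum())) for i in range(len(pts) - 1)
    )
    assert streamline_arclength(pts) == pytest.approx(brute, rel=1e-12)


def test_resample_points_straight_midpoint():
    s = np.array([[0, 0, 0], [0, 0, 10.0]])
    out = resample_streamline_points(s, 3)
    np.testing.assert_allclose(out[1], [0, 0, 5.0])
    np.testing.assert_allclose(out[[0, -1]], s)


def test_resample_points_idempotent_on_equidistant():
    s = np.array([[0, 0, 0], [0, 0, 2.5], [0, 0, 5.0], [0, 0, 7.5], [0, 0, 10.0]])
    out = resample_streamline_points(s, 5)
    np.testing.assert_allclose(out, s, atol=1e-6)


def test_resample_points_right_angle_dense_walk_oracle():
    """Arc-length positions on a 10+10 mm right angle vs a 0.001 mm walk."""
    s = np.array([[0, 0, 0], [10.0, 0, 0], [10.0, 10.0, 0]])
    out = resample_streamline_points(s, 5)
    walk = supersample_polyline(s, 0.001)
    cum = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(walk, axis=0), axis=1))]
    )
    for target, pt in zip([0.0, 5.0, 10.0, 15.0, 20.0], out):
        idx = int(np.argmin(np.abs(cum - target)))
        np.testing.assert_allclose(pt, walk[idx], atol=5e-3)


def test_resample_points_k_below_two_rejected():
    with pytest.raises(ValueError):
        resample_streamline_points(np.array([[0, 0, 0], [1, 1, 1.0]]), 1)


# ---------------------------------------------------------------------------
# Whole-tractogram resampling
# ---------------------------------------------------------------------------

def test_resample_count_identity():
    t = _toy_tractogram()
    out = resample_tractogram_count(t, len(t), seed=1)
    assert len(out) == len(t)
    for a, b in zip(t.streamlines, out.streamlines):
        np.testing.assert_array_equal(a, b)


def test_resample_count_deterministic_and_distinct(rng):
    grid = ReferenceGrid((10, 10, 10), np.eye(4))
    sl = [np.array([[i * 0.05, 0, 0], [i * 0.05, 0, 1.0]]) for i in range(100)]
    t = Tractogram(sl, grid)
    a = resample_tractogram_count(t, 10, seed=7)
    b = resample_tractogram_count(t, 10, seed=7)
    firsts_a = {float(s[0, 0]) for s in a.streamlines}
    firsts_b = {float(s[0, 0]) for s in b.streamlines}
    assert firsts_a == firsts_b
    assert len(a) == 10 and len(firsts_a) == 10
    originals = {float(s[0, 0]) for s in t.streamlines}
    assert firsts_a <= originals


def test_resample_count_upsampling_needs_flag():
    t = _toy_tractogram()
    with pytest.raises(ValueError, match="allow_duplicates"):
        resample_tractogram_count(t, 5, seed=0)
    up = resample_tractogram_count(t, 5, seed=0, allow_duplicates=True)
    assert len(up) == 5


def test_resample_count_uniform_inclusion_frequency():
    """10-from-100 subsampling is measure-preserving in expectation.

    Over 1000 seeded draws every id should be included with frequency ~0.1;
    a chi-square goodness-of-fit test against the uniform inclusion law
    checks all 100 frequencies jointly (a per-id z-bound would be a test on
    the maximum of 100 near-Gaussians and reject a correct sampler too often).
    """
    from scipy import stats as sps

    grid = ReferenceGrid((10, 10, 10), np.eye(4))
    sl = [np.array([[i * 0.05, 0, 0], [i * 0.05, 0, 1.0]]) for i in range(100)]
    t = Tractogram(sl, grid)
    counts = np.zeros(100)
    n_draws = 1000
    for s in range(n_draws):
        out = resample_tractogram_count(t, 10, seed=s)
        for pts in out.streamlines:
            counts[int(round(pts[0, 0] / 0.05))] += 1
    assert counts.sum() == n_draws * 10
    chi2 = ((counts - 100.0) ** 2 / 100.0).sum()
    p = sps.chi2.sf(chi2, df=99)
    assert p > 1e-3


def test_voxel_world_bijection_on_small_grid():
    affine = np.diag([1.5, 2.0, 1.0, 1.0])
    affine[:3, 3] = [-7.0, 3.0, 0.5]
    grid = ReferenceGrid((10, 10, 10), affine)
    idx = np.stack(np.meshgrid(*[np.arange(10)] * 3, indexing="ij"), axis=-1).reshape(-1, 3)
    world = grid.voxel_to_world(idx)
    np.testing.assert_array_equal(grid.voxel_of(world), idx)


def test_labels_must_reference_existing_ids():
    grid = ReferenceGrid((10, 10, 10), np.eye(4))
    with pytest.raises(ValueError, match="unknown streamline ids"):
        Tractogram([np.array([[0, 0, 0], [1, 1, 1.0]])], grid, labels={5: "AF"})
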