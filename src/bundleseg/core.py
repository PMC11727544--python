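"""Streamline/tractogram data model, TRK/TCK and NIfTI I/O, geometric primitives.

All in-memory geometry lives in world millimetres (RAS). The TRK dialect's
voxel-space storage quirk is normalised at read/write time by nibabel, so the
rest of the package never sees anything but world coordinates.

Voxel convention: the grid is voxel-centred, i.e. voxel ``i`` covers the
half-open world region that maps back into ``[i - 0.5, i + 0.5)`` along each
axis under the inverse affine.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel import streamlines as nib_streamlines


class TractogramFormatError(ValueError):
    """A tractogram file is malformed or violates the streamline invariants."""


# ---------------------------------------------------------------------------
# Reference grid and binary masks
# ---------------------------------------------------------------------------

@dataclass
class ReferenceGrid:
    """Anatomical voxel grid: dimensions plus a voxel-index -> world-mm affine."""

    dims: tuple[int, int, int]
    affine: np.ndarray  # 4x4

    def __post_init__(self) -> None:
        self.dims = tuple(int(d) for d in self.dims)
        if len(self.dims) != 3 or any(d <= 0 for d in self.dims):
            raise ValueError(f"dims must be 3 positive integers, got {self.dims}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        self._inv = np.linalg.inv(self.affine)

    # -- coordinate mapping --------------------------------------------------

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (continuous) voxel indices, shape (..., 3), to world mm."""
        idx = np.asarray(indices, dtype=np.float64)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points to continuous voxel coordinates."""
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self._inv[:3, :3].T + self._inv[:3, 3]

    def voxel_of(self, points: np.ndarray) -> np.ndarray:
        """Integer voxel index containing each world point (half-open cells)."""
        return np.floor(self.world_to_voxel(points) + 0.5).astype(np.int64)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """True where a world point falls inside the gridded volume."""
        v = self.world_to_voxel(points)
        lo = v >= -0.5
        hi = v < np.asarray(self.dims, dtype=np.float64) - 0.5
        return (lo & hi).all(axis=-1)

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_as(self, other: "ReferenceGrid", atol: float = 1e-6) -> bool:
        return self.dims == other.dims and np.allclose(self.affine, other.affine, atol=atol)


@dataclass
class BinaryMask:
    """Boolean voxel occupancy on a :class:`ReferenceGrid`."""

    grid: ReferenceGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != self.grid.dims:
            raise ValueError(
                f"mask shape {self.data.shape} does not match grid dims {self.grid.dims}"
            )

    @classmethod
    def from_voxels(cls, grid: ReferenceGrid, voxels: np.ndarray) -> "BinaryMask":
        vox = np.atleast_2d(np.asarray(voxels, dtype=np.int64))
        data = np.zeros(grid.dims, dtype=bool)
        if vox.size:
            if (vox < 0).any() or (vox >= np.asarray(grid.dims)).any():
                raise ValueError("flagged voxel index outside grid dims")
            data[vox[:, 0], vox[:, 1], vox[:, 2]] = True
        return cls(grid, data)

    def count(self) -> int:
        return int(self.data.sum())


def read_mask(path: str | Path, grid: ReferenceGrid | None = None) -> BinaryMask:
    img = nib.load(str(path))
    g = ReferenceGrid(tuple(img.shape[:3]), np.asarray(img.affine))
    if grid is not None and not grid.same_as(g):
        raise ValueError(f"mask grid in {path} does not match the expected grid")
    return BinaryMask(g, np.asarray(img.dataobj) > 0)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Streamlines and tractograms
# ---------------------------------------------------------------------------

def validate_streamline(points: np.ndarray) -> np.ndarray:
    """Check the streamline invariants and return the points as float64.

    A streamline needs >= 2 points, all finite, with consecutive points
    distinct (hence strictly positive arc length).
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise TractogramFormatError(
            f"streamline must be an (n>=2, 3) array, got shape {pts.shape}"
        )
    if not np.isfinite(pts).all():
        raise TractogramFormatError("streamline contains non-finite coordinates")
    if (np.linalg.norm(np.diff(pts, axis=0), axis=1) == 0).any():
        raise TractogramFormatError("streamline has coincident consecutive points")
    return pts


@dataclass
class Tractogram:
    """A set of streamlines with a reference grid and optional id -> label map.

    Streamline ids are the list positions ``0 .. n-1``.
    """

    streamlines: list[np.ndarray]
    grid: ReferenceGrid
    labels: dict[int, str] | None = None
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        if self.validate:
            self.streamlines = [validate_streamline(s) for s in self.streamlines]
        if self.labels is not None:
            bad = [i for i in self.labels if not (0 <= i < len(self.streamlines))]
            if bad:
                raise ValueError(f"labels reference unknown streamline ids: {bad[:5]}")

    def __len__(self) -> int:
        return len(self.streamlines)

    def ids(self) -> range:
        return range(len(self.streamlines))

    def subset(self, ids) -> "Tractogram":
        ids = sorted(int(i) for i in ids)
        labels = None
        if self.labels is not None:
            labels = {new: self.labels[old] for new, old in enumerate(ids) if old in self.labels}
        return Tractogram(
            [self.streamlines[i] for i in ids], self.grid, labels, validate=False
        )


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def streamline_arclength(points: np.ndarray) -> float:
    """Polyline arc length (mm): sum of Euclidean segment lengths."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("arc length needs at least 2 points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _cumulative_arclength(pts: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_streamline_points(points: np.ndarray, k: int) -> np.ndarray:
    """Resample a polyline to ``k`` points equidistant in arc length.

    The first and last points are preserved exactly.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    pts = np.asarray(points, dtype=np.float64)
    cum = _cumulative_arclength(pts)
    target = np.linspace(0.0, cum[-1], k)
    out = np.empty((k, 3))
    for ax in range(3):
        out[:, ax] = np.interp(target, cum, pts[:, ax])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def supersample_polyline(points: np.ndarray, max_spacing: float = 0.5) -> np.ndarray:
    """Original vertices plus extra points so no gap exceeds ``max_spacing`` mm."""
    pts = np.asarray(points, dtype=np.float64)
    seg = np.diff(pts, axis=0)
    lengths = np.linalg.norm(seg, axis=1)
    pieces = [pts[:1]]
    for i, (length, d) in enumerate(zip(lengths, seg)):
        n = max(1, int(np.ceil(length / max_spacing)))
        t = np.arange(1, n + 1, dtype=np.float64)[:, None] / n
        pieces.append(pts[i] + t * d)
    return np.concatenate(pieces, axis=0)


# ---------------------------------------------------------------------------
# Whole-tractogram resampling
# ---------------------------------------------------------------------------

def resample_tractogram_count(
    t: Tractogram, n: int, seed: int, allow_duplicates: bool = False
) -> Tractogram:
    """Draw a tractogram with exactly ``n`` streamlines.

    Downsampling takes a uniform random subset without replacement.
    Upsampling (duplication with replacement) must be requested explicitly via
    ``allow_duplicates`` because duplicated streamlines bias density-based
    measures. Deterministic given ``seed``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    total = len(t)
    if n == total:
        return Tractogram(list(t.streamlines), t.grid, dict(t.labels) if t.labels else None,
                          validate=False)
    if n < total:
        keep = np.sort(rng.choice(total, size=n, replace=False))
    elif allow_duplicates:
        extra = rng.choice(total, size=n - total, replace=True)
        keep = np.concatenate([np.arange(total), np.sort(extra)])
    else:
        raise ValueError(
            f"requested {n} streamlines from {total}; pass allow_duplicates=True to upsample"
        )
    labels = None
    if t.labels is not None:
        labels = {new: t.labels[int(old)] for new, old in enumerate(keep) if int(old) in t.labels}
    return Tractogram([t.streamlines[int(i)] for i in keep], t.grid, labels, validate=False)


# ---------------------------------------------------------------------------
# Tractogram I/O (TRK / TCK via nibabel, labels as CSV sidecar)
# ---------------------------------------------------------------------------

_FORMATS = {"trk", "tck"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported tractogram format {fmt!r}; expected trk or tck")
    return fmt


def read_tractogram(
    path: str | Path,
    format: str | None = None,
    grid: ReferenceGrid | None = None,
) -> Tractogram:
    """Read a TRK or TCK file; coordinates are returned in world mm.

    TRK headers carry the anatomical grid; for TCK (which stores world
    coordinates but no grid) a ``grid`` must be supplied.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        f = nib_streamlines.load(str(path))
    except Exception as exc:  # malformed header or truncated body
        size = path.stat().st_size
        raise TractogramFormatError(
            f"malformed {fmt} file {path} ({size} bytes): {exc}"
        ) from exc
    if fmt == "trk":
        hdr = f.header
        file_grid = ReferenceGrid(
            tuple(int(d) for d in hdr["dimensions"]),
            np.asarray(hdr["voxel_to_rasmm"], dtype=np.float64),
        )
        grid = grid or file_grid
    elif grid is None:
        raise ValueError("reading a TCK file requires an explicit reference grid")
    streamlines = []
    for i, s in enumerate(f.tractogram.streamlines):
        try:
            streamlines.append(validate_streamline(np.asarray(s, dtype=np.float64)))
        except TractogramFormatError as exc:
            raise TractogramFormatError(f"streamline {i} in {path}: {exc}") from exc
    return Tractogram(streamlines, grid, validate=False)


def write_tractogram(t: Tractogram, path: str | Path, format: str | None = None) -> None:
    """Write a tractogram as TRK (with grid header) or TCK (world mm)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    nib_t = nib_streamlines.Tractogram(
        [s.astype(np.float32) for s in t.streamlines], affine_to_rasmm=np.eye(4)
    )
    if fmt == "trk":
        header = {
            "voxel_to_rasmm": t.grid.affine.astype(np.float32),
            "dimensions": np.asarray(t.grid.dims, dtype=np.int16),
            "voxel_sizes": t.grid.voxel_sizes.astype(np.float32),
            "voxel_order": "RAS",
        }
        nib_streamlines.save(nib_t, str(path), header=header)
    else:
        nib_streamlines.save(nib_t, str(path))


def write_labels(labels: dict[int, str], path: str | Path) -> None:
    """Two-column (id, label) CSV sidecar."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "label"])
        for i in sorted(labels):
            w.writerow([i, labels[i]])


def read_labels(path: str | Path) -> dict[int, str]:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or rows[0][:2] != ["id", "label"]:
        raise ValueError(f"{path} is not an (id, label) CSV sidecar")
    return {int(r[0]): r[1] for r in rows[1:]}


def write_ids(ids, path: str | Path) -> None:
    """One-column streamline-id CSV (a segmentation result)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id"])
        for i in sorted(int(x) for x in ids):
            w.writerow([i])


def read_ids(path: str | Path) -> set[int]:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or rows[0][:1] != ["id"]:
        raise ValueError(f"{path} is not an id CSV")
    return {int(r[0]) for r in rows[1:]}
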