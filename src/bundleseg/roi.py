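"""ROI-based bundle extraction.

A bundle recipe is an ordered conjunction of terms, mirroring how filters are
chained in interactive dissection software:

* an :class:`ROI` — a binary voxel mask or a parametric axis-aligned box in
  world mm — with 'Any Part' (waypoint) or 'No Part' (veto) logic;
* a :class:`SliceFilter` — a plane whose crossers are discarded (used at the
  midline to exclude commissural streamlines).

Membership tests sample the streamline vertices plus supersampled segment
points at <= 0.5 mm spacing, so a segment piercing a thin ROI strictly
between its vertices is still caught. Slice crossing uses strict
inequalities: a point exactly on the plane belongs to neither side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BinaryMask, ReferenceGrid, Tractogram, supersample_polyline

SUPERSAMPLE_SPACING = 0.5  # mm, half the phantom voxel size

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class Box:
    """Axis-aligned box in world mm; membership is inclusive of the faces."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        self.lo = np.asarray(self.lo, dtype=float)
        self.hi = np.asarray(self.hi, dtype=float)
        if self.lo.shape != (3,) or self.hi.shape != (3,):
            raise ValueError("box lo/hi must be 3-vectors")
        if not (self.hi > self.lo).all():
            raise ValueError("box must have positive extents")

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return ((pts >= self.lo) & (pts <= self.hi)).all(axis=-1)


@dataclass
class ROI:
    shape: Box | BinaryMask
    logic: str = "any_part"

    def __post_init__(self) -> None:
        if self.logic not in ("any_part", "no_part"):
            raise ValueError(f"logic must be any_part or no_part, got {self.logic!r}")
        if self.logic == "any_part" and isinstance(self.shape, BinaryMask):
            if self.shape.count() == 0:
                raise ValueError("inclusion ROI mask is empty")


@dataclass
class SliceFilter:
    """Discard streamlines with points strictly on both sides of a plane."""

    axis: str
    coordinate: float
    mode: str = "exclude_crossing"

    def __post_init__(self) -> None:
        if self.axis not in _AXES:
            raise ValueError(f"axis must be one of {sorted(_AXES)}")
        if self.mode != "exclude_crossing":
            raise ValueError("only exclude_crossing slice filters are supported")


@dataclass
class BundleRecipe:
    name: str
    terms: list

    def __post_init__(self) -> None:
        if not any(isinstance(t, ROI) and t.logic == "any_part" for t in self.terms):
            raise ValueError(f"recipe {self.name!r} has no inclusion (any_part) term")


# ---------------------------------------------------------------------------
# Per-streamline predicates
# ---------------------------------------------------------------------------

def _touches(samples: np.ndarray, shape: Box | BinaryMask, grid: ReferenceGrid) -> bool:
    if isinstance(shape, Box):
        return bool(shape.contains(samples).any())
    if not shape.grid.same_as(grid):
        raise ValueError("ROI mask grid does not match the tractogram grid")
    vox = grid.voxel_of(samples)
    dims = np.asarray(grid.dims)
    inside = ((vox >= 0) & (vox < dims)).all(axis=1)
    if not inside.any():
        return False
    vox = vox[inside]
    return bool(shape.data[vox[:, 0], vox[:, 1], vox[:, 2]].any())


def streamline_in_roi(points: np.ndarray, roi: ROI, grid: ReferenceGrid) -> bool:
    """Evaluate one ROI term: any_part -> touched, no_part -> not touched."""
    samples = supersample_polyline(points, SUPERSAMPLE_SPACING)
    touched = _touches(samples, roi.shape, grid)
    return touched if roi.logic == "any_part" else not touched


def streamline_crosses_slice(points: np.ndarray, f: SliceFilter) -> bool:
    """True iff the streamline has points strictly on both sides of the plane."""
    coords = np.asarray(points, dtype=float)[:, _AXES[f.axis]]
    return bool((coords > f.coordinate).any() and (coords < f.coordinate).any())


# ---------------------------------------------------------------------------
# Recipe application
# ---------------------------------------------------------------------------

def apply_recipe(t: Tractogram, recipe: BundleRecipe) -> set[int]:
    """Ids satisfying every term of the recipe (conjunction); deterministic.

    Slice filters are interpreted as exclusion of crossers.
    """
    result: set[int] = set()
    for i, pts in enumerate(t.streamlines):
        samples = None
        ok = True
        for term in recipe.terms:
            if isinstance(term, SliceFilter):
                if streamline_crosses_slice(pts, term):
                    ok = False
                    break
            elif isinstance(term, ROI):
                if samples is None:
                    samples = supersample_polyline(pts, SUPERSAMPLE_SPACING)
                touched = _touches(samples, term.shape, t.grid)
                if (term.logic == "any_part") != touched:
                    ok = False
                    break
            else:
                raise TypeError(f"unknown recipe term {term!r}")
        if ok:
            result.add(i)
    return result


# ---------------------------------------------------------------------------
# Default recipes for the deformation-free phantom geometry
# ---------------------------------------------------------------------------
#
# The real-data analog of these boxes is drawn by an operator on each
# patient's colour-FA map; in phantom space they are fixed parametric boxes.
# Coordinates are free parameters of the study design, chosen against the
# deformation-free bundle centerlines and wide enough to keep admitting each
# bundle under the cohort's per-subject deformations.

def _box(lo, hi, logic) -> ROI:
    return ROI(Box(np.asarray(lo, float), np.asarray(hi, float)), logic)


def default_recipes(
    grid: ReferenceGrid | None = None,
    refined: bool = True,
    x_mid: float = 90.0,
) -> dict[str, BundleRecipe]:
    """The four bundle recipes.

    ``refined=False`` drops the later-added refinements (the insula exclusion
    for the AF and the axial extensions of the IFOF exclusions), exposing the
    base waypoint heuristics only.
    """
    midline = SliceFilter("x", x_mid)

    cor_af = _box([30, 98, 90], [60, 104, 135], "any_part")      # coronal deep-WM waypoint
    ax_temp = _box([34, 58, 58], [62, 104, 64], "any_part")      # axial temporal waypoint
    insula = _box([35, 95, 68], [55, 120, 82], "no_part")        # insula-level exclusion
    temporal_plane = _box([0, 0, 58], [x_mid, 216, 64], "no_part")   # temporal/parietal segregation
    frontal_plane = _box([0, 98, 0], [x_mid, 104, 180], "no_part")   # frontal segregation

    stem = _box([34, 106, 52], [50, 112, 80], "any_part")        # external-capsule stem
    dorsal_cor = _box([30, 106, 82], [60, 112, 135], "no_part")  # above the stem
    ventral_cor = _box([30, 106, 24], [60, 112, 48], "no_part")  # below the stem
    dorsal_ax = _box([34, 90, 95], [54, 104, 102], "no_part")    # axial extension, dorsal
    ventral_ax = _box([34, 52, 34], [60, 82, 44], "no_part")     # axial extension, ventral

    af_terms = [cor_af, ax_temp] + ([insula] if refined else []) + [midline]
    ifof_terms = [stem, dorsal_cor, ventral_cor]
    if refined:
        ifof_terms += [dorsal_ax, ventral_ax]
    ifof_terms.append(midline)

    return {
        "AF": BundleRecipe("AF", af_terms),
        "AF_ant": BundleRecipe("AF_ant", [cor_af, temporal_plane, midline]),
        "AF_post": BundleRecipe("AF_post", [ax_temp, frontal_plane, midline]),
        "IFOF": BundleRecipe("IFOF", ifof_terms),
    }
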