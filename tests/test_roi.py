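"""ROI filtering: membership predicates, recipe semantics, oracle equivalence."""

import numpy as np
import pytest

from bundleseg import phantom as ph
from bundleseg.core import BinaryMask, ReferenceGrid, supersample_polyline
from bundleseg.roi import (
    ROI,
    Box,
    BundleRecipe,
    SliceFilter,
    apply_recipe,
    default_recipes,
    streamline_crosses_slice,
    streamline_in_roi,
)

from conftest import random_tractogram

GRID = ReferenceGrid((20, 20, 20), np.eye(4))


def test_full_volume_mask_any_and_no_part():
    full = BinaryMask(GRID, np.ones(GRID.dims, bool))
    s = np.array([[2.0, 2, 2], [5.0, 5, 5]])
    assert streamline_in_roi(s, ROI(full, "any_part"), GRID)
    assert not streamline_in_roi(s, ROI(full, "no_part"), GRID)


def test_empty_mask_vacuous():
    empty = BinaryMask(GRID, np.zeros(GRID.dims, bool))
    s = np.array([[2.0, 2, 2], [5.0, 5, 5]])
    assert streamline_in_roi(s, ROI(empty, "no_part"), GRID)
    # an empty mask is useless as an inclusion waypoint and is rejected
    with pytest.raises(ValueError, match="empty"):
        ROI(empty, "any_part")


def test_segment_piercing_thin_voxel_between_vertices():
    """A 2-point streamline whose segment pierces one flagged voxel strictly
    between its vertices must be caught; oracle: 0.01 mm dense sampling."""
    mask = BinaryMask.from_voxels(GRID, np.array([[10, 10, 10]]))
    s = np.array([[5.0, 10.0, 10.0], [15.0, 10.0, 10.0]])  # passes through (10,10,10)
    roi = ROI(mask, "any_part")
    assert streamline_in_roi(s, roi, GRID)
    dense = supersample_polyline(s, 0.01)
    vox = GRID.voxel_of(dense)
    oracle = bool((vox == [10, 10, 10]).all(axis=1).any())
    assert streamline_in_roi(s, roi, GRID) == oracle


def test_slice_crossing_semantics():
    f = SliceFilter("x", 10.0)
    left = np.array([[2.0, 0, 0], [9.0, 0, 0]])
    straddle = np.array([[9.0, 0, 0], [11.0, 0, 0]])
    touching = np.array([[9.0, 0, 0], [10.0, 0, 0]])  # ends ON the plane
    assert not streamline_crosses_slice(left, f)
    assert streamline_crosses_slice(straddle, f)
    assert not streamline_crosses_slice(touching, f)


# ---------------------------------------------------------------------------
# apply_recipe
# ---------------------------------------------------------------------------

def _brute_force_apply(t, recipe):
    """Independent per-streamline, per-term evaluation with dense sampling."""
    out = set()
    for i, pts in enumerate(t.streamlines):
        keep = True
        for term in recipe.terms:
            if isinstance(term, SliceFilter):
                c = pts[:, {"x": 0, "y": 1, "z": 2}[term.axis]]
                if (c > term.coordinate).any() and (c < term.coordinate).any():
                    keep = False
            else:
                dense = supersample_polyline(pts, 0.05)
                if isinstance(term.shape, Box):
                    touched = bool(
                        ((dense >= term.shape.lo) & (dense <= term.shape.hi))
                        .all(axis=1).any()
                    )
                else:
                    vox = t.grid.voxel_of(dense)
                    inside = ((vox >= 0) & (vox < np.asarray(t.grid.dims))).all(axis=1)
                    vox = vox[inside]
                    touched = bool(
                        term.shape.data[vox[:, 0], vox[:, 1], vox[:, 2]].any()
                    ) if len(vox) else False
                if (term.logic == "any_part") != touched:
                    keep = False
            if not keep:
                break
        if keep:
            out.add(i)
    return out


def test_apply_recipe_toy_three_streamlines():
    """One true AF-like id, one missing the axial waypoint, one commissural."""
    grid = ph.default_grid()
    recipes = default_recipes()
    af = recipes["AF"]
    cor, ax = af.terms[0].shape, af.terms[1].shape
    both = np.array([[45.0, 101.0, 110.0], [45.0, 80.0, 61.0]])  # hits cor then ax
    cor_only = np.array([[45.0, 101.0, 110.0], [45.0, 80.0, 110.0]])
    commissural = np.array([[45.0, 101.0, 110.0], [45.0, 80.0, 61.0], [140.0, 80.0, 61.0]])
    t = ph.Tractogram([both, cor_only, commissural], grid)
    assert cor.contains(both).any() and ax.contains(supersample_polyline(both, 0.5)).any()
    result = apply_recipe(t, af)
    assert result == {0}
    assert result == _brute_force_apply(t, af)


def test_total_inclusion_and_total_exclusion(rng):
    t = random_tractogram(rng, n=30)
    whole = ROI(Box([0.0, 0, 0], [63.0, 63, 63]), "any_part")
    mid = SliceFilter("x", 32.0)
    r = BundleRecipe("all", [whole, mid])
    got = apply_recipe(t, r)
    non_crossers = {
        i for i, s in enumerate(t.streamlines) if not streamline_crosses_slice(s, mid)
    }
    assert got == non_crossers
    r2 = BundleRecipe("none", [whole, ROI(Box([0.0, 0, 0], [63.0, 63, 63]), "no_part")])
    assert apply_recipe(t, r2) == set()


def test_recipe_without_inclusion_term_rejected():
    with pytest.raises(ValueError, match="inclusion"):
        BundleRecipe("bad", [ROI(Box([0, 0, 0], [1, 1, 1]), "no_part")])


def test_exclusions_are_anti_monotone(rng):
    """Adding any exclusion term never enlarges the result (random recipes)."""
    for trial in range(10):
        t = random_tractogram(rng, n=40)
        lo = rng.uniform(0, 40, 3)
        base = BundleRecipe("b", [ROI(Box([0.0, 0, 0], [63.0, 63, 63]), "any_part")])
        extra = ROI(Box(lo, lo + rng.uniform(2, 20, 3)), "no_part")
        bigger = BundleRecipe("b+", base.terms + [extra])
        assert apply_recipe(t, bigger) <= apply_recipe(t, base)


def test_apply_recipe_matches_brute_force_on_random_tractograms(rng):
    """Exact oracle equivalence on random tractograms and random terms."""
    for trial in range(15):
        t = random_tractogram(rng, n=25)
        lo1 = rng.uniform(0, 45, 3)
        lo2 = rng.uniform(0, 45, 3)
        vox = rng.integers(0, 64, (rng.integers(1, 200), 3))
        recipe = BundleRecipe(
            "r",
            [
                ROI(Box(lo1, lo1 + rng.uniform(5, 18, 3)), "any_part"),
                ROI(BinaryMask.from_voxels(t.grid, vox), "no_part"),
                ROI(Box(lo2, lo2 + rng.uniform(5, 18, 3)),
                    "any_part" if rng.random() < 0.5 else "no_part"),
                SliceFilter("xyz"[rng.integers(3)], float(rng.uniform(10, 50))),
            ],
        )
        assert apply_recipe(t, recipe) == _brute_force_apply(t, recipe)


# ---------------------------------------------------------------------------
# Default recipes on phantoms
# ---------------------------------------------------------------------------

def test_af_recipe_exact_on_artefact_free_subject(clean_subject):
    """With no artefacts and no deformation, each recipe returns exactly its
    ground-truth label set."""
    t = clean_subject.tractogram
    recipes = default_recipes()
    for bundle in ph.BUNDLE_NAMES:
        truth = {i for i, l in t.labels.items() if l == bundle}
        assert apply_recipe(t, recipes[bundle]) == truth, bundle


def test_af_post_returns_only_posterior_streamlines(flat_subject):
    """The frontal-segregation plane leaves no streamline with points at or
    anterior to it."""
    t = flat_subject.tractogram
    recipes = default_recipes()
    plane = recipes["AF_post"].terms[1]
    assert plane.logic == "no_part"
    y_lo = plane.shape.lo[1]
    for i in apply_recipe(t, recipes["AF_post"]):
        assert (t.streamlines[i][:, 1] < y_lo).all()


def test_ifof_extended_exclusions_give_strict_subset():
    """Extending the IFOF exclusion ROIs to the axial plane removes part of
    the dorsal-loop population: strict monotone shrinkage."""
    cfg = ph.PhantomConfig(n_per_bundle=40, n_per_artefact=0, n_background=0)
    subj = ph.generate_subject(
        cfg.bundle_specs(),
        [ph.ArtefactSpec("dorsal_loop", 60)],
        ph.SubjectSpec(0, seed=55),
    )
    t = subj.tractogram
    base = apply_recipe(t, default_recipes(refined=False)["IFOF"])
    extended = apply_recipe(t, default_recipes(refined=True)["IFOF"])
    assert extended < base  # strict subset
    removed = {t.labels[i] for i in base - extended}
    assert removed == {"dorsal_loop"}
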