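"""Shared fixtures: small phantom subjects and reusable geometry."""

import numpy as np
import pytest

from bundleseg import phantom as ph
from bundleseg.core import ReferenceGrid, Tractogram


@pytest.fixture(scope="session")
def small_config():
    """Reduced-count study conditions for fast per-module tests."""
    return ph.PhantomConfig(n_per_bundle=60, n_per_artefact=20, n_background=100)


@pytest.fixture(scope="session")
def flat_subject(small_config):
    """One deformation-free labeled subject with all artefact populations."""
    spec = ph.SubjectSpec(0, seed=123)
    return ph.generate_subject(
        small_config.bundle_specs(), small_config.artefact_specs(), spec
    )


@pytest.fixture(scope="session")
def clean_subject(small_config):
    """A deformation-free, artefact-free subject (bundles only)."""
    spec = ph.SubjectSpec(1, seed=321)
    return ph.generate_subject(small_config.bundle_specs(), [], spec)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_tractogram(rng, n=20, points=8, scale=50.0, grid=None):
    """Random smooth-ish polylines for oracle-equivalence tests."""
    grid = grid or ReferenceGrid((64, 64, 64), np.eye(4))
    streamlines = []
    for _ in range(n):
        p0 = rng.uniform(5, 58, 3)
        steps = rng.normal(0, scale / points, (points - 1, 3))
        pts = np.vstack([p0, p0 + np.cumsum(steps, axis=0)])
        pts = np.clip(pts, 1.0, 62.0)
        # enforce distinct consecutive points after clipping
        keep = np.concatenate(
            [[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9]
        )
        pts = pts[keep]
        if len(pts) < 2:
            continue
        streamlines.append(pts)
    return Tractogram(streamlines, grid)
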