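"""Synthetic labeled tractogram phantoms.

Emulates the study conditions this package is built to analyse: four left
association bundles with characteristic trajectories — the arcuate fasciculus
(AF) arching around the Sylvian fissure from frontal to temporal cortex, its
indirect anterior (fronto-parietal) and posterior (temporo-parietal) segments,
and the long inferior fronto-occipital fasciculus (IFOF) funnelled through a
narrow stem at the external/extreme capsule — plus the recurrent artefact
streamline populations that contaminate ROI-based dissections of real
tractograms:

* ``parietal_ending``: AF-lookalikes that dip through the temporal waypoint
  territory but bend back up and terminate in the parietal lobe;
* ``u_fiber``: short (< 40 mm) arcs connecting adjacent gyri next to a
  waypoint ROI;
* ``dorsal_loop``: streamlines that pass the IFOF stem and then curve back
  dorsally towards the frontal region;
* ``projection_vertical``: vertical projection-like streamlines crossing the
  AF waypoint territory;
* ``commissural``: streamlines crossing the midline plane;
* ``background``: unstructured smooth clutter elsewhere in the volume.

The phantom lives on a 180 x 216 x 180 grid at 1 mm isotropic resolution with
an identity affine (MNI-like extents, so recipe coordinates read
anatomically); bundles occupy the left half, with the midline at x = 90 mm.
Streamlines are tubes around a smooth spline centerline: a per-streamline
constant transverse offset with Rayleigh-distributed magnitude plus
low-frequency sinusoidal jitter, with small random end trimming.
Per-subject variability is a small rigid rotation plus anisotropic scaling of
all control points about the hemisphere centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .core import ReferenceGrid, Tractogram, streamline_arclength

# ---------------------------------------------------------------------------
# Phantom space
# ---------------------------------------------------------------------------

DEFAULT_DIMS = (180, 216, 180)
X_MID = 90.0
HEMI_CENTER = np.array([45.0, 105.0, 90.0])

BUNDLE_NAMES = ("AF", "AF_ant", "AF_post", "IFOF")
ARTEFACT_PATTERNS = (
    "parietal_ending",
    "u_fiber",
    "dorsal_loop",
    "projection_vertical",
    "commissural",
    "background",
)


def default_grid() -> ReferenceGrid:
    return ReferenceGrid(DEFAULT_DIMS, np.eye(4))


# Control points (world mm) of the deformation-free bundle centerlines.
BUNDLE_CENTERLINES: dict[str, np.ndarray] = {
    # frontal -> longitudinal arc -> dorso-ventral descent into the temporal lobe
    "AF": np.array(
        [
            [45, 150, 100],
            [44, 125, 111],
            [43, 102, 116],
            [42, 85, 112],
            [43, 75, 95],
            [45, 73, 75],
            [47, 80, 58],
            [48, 88, 50],
        ],
        dtype=float,
    ),
    # fronto-parietal, stays dorsal (never descends to the temporal plane)
    "AF_ant": np.array(
        [
            [47, 148, 92],
            [46, 124, 104],
            [46, 104, 110],
            [46, 88, 112],
            [46, 72, 114],
        ],
        dtype=float,
    ),
    # temporo-parietal, entirely posterior to the frontal-segregation plane
    "AF_post": np.array(
        [
            [48, 84, 50],
            [47, 78, 64],
            [46, 72, 86],
            [46, 68, 102],
            [45, 64, 114],
        ],
        dtype=float,
    ),
    # long antero-posterior course through the narrow external-capsule stem
    "IFOF": np.array(
        [
            [48, 150, 75],
            [44, 128, 71],
            [42, 109, 65],
            [43, 88, 61],
            [44, 68, 62],
            [45, 50, 66],
            [46, 35, 71],
        ],
        dtype=float,
    ),
}


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class BundleSpec:
    name: str
    centerline: np.ndarray  # (m >= 3, 3) control points, world mm
    radius: float = 2.2     # Rayleigh scale of the transverse dispersion (mm)
    n_streamlines: int = 500
    step: float = 2.0       # point spacing along generated streamlines (mm)
    jitter: float = 0.8     # amplitude scale of the sinusoidal jitter (mm)
    trim: float = 4.0       # max random end trimming per end (mm)

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.shape[0] < 3:
            raise ValueError("centerline needs >= 3 control points")
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.n_streamlines < 0:
            raise ValueError("n_streamlines must be >= 0")


@dataclass
class ArtefactSpec:
    pattern: str
    n_streamlines: int = 100
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pattern not in ARTEFACT_PATTERNS:
            raise ValueError(
                f"unknown artefact pattern {self.pattern!r}; "
                f"expected one of {ARTEFACT_PATTERNS}"
            )
        if self.n_streamlines < 0:
            raise ValueError("n_streamlines must be >= 0")


@dataclass
class SubjectSpec:
    subject_id: int
    seed: int
    rotation_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: np.ndarray = field(default_factory=lambda: np.ones(3))

    MAX_ROTATION = 10.0  # deg, per axis
    MAX_SCALE_DEV = 0.10

    def __post_init__(self) -> None:
        self.rotation_deg = np.asarray(self.rotation_deg, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if (np.abs(self.rotation_deg) > self.MAX_ROTATION).any():
            raise ValueError(f"rotation exceeds +/-{self.MAX_ROTATION} deg")
        if (np.abs(self.scale - 1.0) > self.MAX_SCALE_DEV).any():
            raise ValueError(f"scale factors exceed +/-{self.MAX_SCALE_DEV:.0%}")


def deformation_matrix(subj: SubjectSpec, center: np.ndarray = HEMI_CENTER) -> np.ndarray:
    """4x4 affine: anisotropic scale then rotation, both about ``center``."""
    ax, ay, az = np.deg2rad(subj.rotation_deg)
    Rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]])
    Ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]])
    Rz = np.array([[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]])
    M = Rx @ Ry @ Rz @ np.diag(subj.scale)
    out = np.eye(4)
    out[:3, :3] = M
    out[:3, 3] = center - M @ center
    return out


def apply_deformation(points: np.ndarray, deformation: np.ndarray | None) -> np.ndarray:
    if deformation is None:
        return np.asarray(points, dtype=float)
    pts = np.asarray(points, dtype=float)
    return pts @ deformation[:3, :3].T + deformation[:3, 3]


# ---------------------------------------------------------------------------
# Tube machinery
# ---------------------------------------------------------------------------

def smooth_centerline(control_points: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Dense polyline through the control points (natural cubic spline,
    chord-length parameterisation), sampled at ~``spacing`` mm."""
    ctrl = np.asarray(control_points, dtype=float)
    chord = np.linalg.norm(np.diff(ctrl, axis=0), axis=1)
    keep = np.concatenate([[True], chord > 1e-9])  # spline needs strict knots
    ctrl = ctrl[keep]
    if ctrl.shape[0] < 2:
        raise ValueError("centerline has fewer than 2 distinct control points")
    chord = np.linalg.norm(np.diff(ctrl, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(chord)])
    spline = CubicSpline(u, ctrl, axis=0, bc_type="natural")
    dense_u = np.linspace(0.0, u[-1], max(8, int(np.ceil(u[-1] / (spacing * 0.25)))))
    dense = spline(dense_u)
    total = streamline_arclength(dense)
    n = max(2, int(np.round(total / spacing)) + 1)
    cum = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))])
    target = np.linspace(0.0, cum[-1], n)
    out = np.empty((n, 3))
    for axn in range(3):
        out[:, axn] = np.interp(target, cum, dense[:, axn])
    return out


def _normal_frames(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit fields spanning the plane normal to the local tangent."""
    tan = np.gradient(pts, axis=0)
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    mean_t = tan.mean(axis=0)
    ref = np.eye(3)[np.argmin(np.abs(mean_t))]  # least-aligned axis, no flips
    n1 = np.cross(tan, ref)
    norms = np.linalg.norm(n1, axis=1, keepdims=True)
    bad = norms[:, 0] < 1e-8  # tangent momentarily parallel to ref
    if bad.any():
        alt = np.cross(tan[bad], np.roll(ref, 1))
        n1[bad] = alt
        norms = np.linalg.norm(n1, axis=1, keepdims=True)
    n1 /= norms
    n2 = np.cross(tan, n1)
    n2 /= np.linalg.norm(n2, axis=1, keepdims=True)
    return n1, n2


def _tube_streamline(
    centerline: np.ndarray,
    radius: float,
    jitter: float,
    step: float,
    trim: float,
    rng: np.random.Generator,
) -> np.ndarray:
    cum = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(centerline, axis=0), axis=1))]
    )
    total = cum[-1]
    u0 = rng.uniform(0.0, trim) if trim > 0 else 0.0
    u1 = rng.uniform(0.0, trim) if trim > 0 else 0.0
    length = max(total - u0 - u1, 4 * step)
    u0 = min(u0, total - length)
    n = max(3, int(np.round(length / step)) + 1)
    svals = np.linspace(u0, u0 + length, n)
    base = np.empty((n, 3))
    for axn in range(3):
        base[:, axn] = np.interp(svals, cum, centerline[:, axn])
    n1, n2 = _normal_frames(base)
    r = rng.rayleigh(radius) if radius > 0 else 0.0
    theta = rng.uniform(0.0, 2 * np.pi)
    a, b = r * np.cos(theta), r * np.sin(theta)
    off1 = np.full(n, a)
    off2 = np.full(n, b)
    if jitter > 0:
        phase = svals / total  # in [0, 1]
        for off in (off1, off2):
            amp = jitter * rng.uniform(0.5, 1.5)
            freq = rng.integers(1, 3)  # 1 or 2 cycles along the bundle
            phi = rng.uniform(0.0, 2 * np.pi)
            off += amp * np.sin(2 * np.pi * freq * phase + phi)
    return base + off1[:, None] * n1 + off2[:, None] * n2


# ---------------------------------------------------------------------------
# Bundle generation
# ---------------------------------------------------------------------------

def generate_bundle(
    spec: BundleSpec,
    deformation: np.ndarray | None = None,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Generate ``spec.n_streamlines`` labeled tube streamlines.

    Each streamline is a smooth perturbation of the (deformed) spline
    centerline; deterministic given the seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    ctrl = apply_deformation(spec.centerline, deformation)
    dense = smooth_centerline(ctrl, spacing=1.0)
    return [
        _tube_streamline(dense, spec.radius, spec.jitter, spec.step, spec.trim, rng)
        for _ in range(spec.n_streamlines)
    ]


def deformed_centerline(spec: BundleSpec, deformation: np.ndarray | None) -> np.ndarray:
    """The subject's smooth centerline polyline (the clustering template)."""
    return smooth_centerline(apply_deformation(spec.centerline, deformation), spacing=2.0)


# ---------------------------------------------------------------------------
# Artefact generation
# ---------------------------------------------------------------------------

def _artefact_controls(pattern: str, rng: np.random.Generator, params: dict) -> np.ndarray:
    """Per-streamline control points for one artefact streamline."""
    j = params.get("control_jitter", 1.5)

    if pattern == "parietal_ending":
        # follows the AF longitudinal course, dips through the temporal
        # waypoint territory, then bends back up to a parietal terminus
        base = np.array(
            [
                [45, 150, 98],
                [44, 118, 112],
                [43, 98, 114],
                [43, 84, 96],
                [44, 79, 56],
                [45, 70, 84],
                [45, 62, 112],
            ],
            dtype=float,
        )
    elif pattern == "u_fiber":
        if rng.random() < 0.5:  # dorsal site, next to the AF coronal waypoint
            base = np.array([[44, 92, 112], [45, 101, 120], [46, 110, 112]], dtype=float)
        else:  # temporal site, next to the axial temporal waypoint
            base = np.array([[48, 72, 52], [47, 79, 66], [46, 86, 52]], dtype=float)
        j = min(j, 1.0)  # keep arcs comfortably below the 40 mm bound
    elif pattern == "dorsal_loop":
        # passes the IFOF stem, then turns dorsally; the turn position varies
        # so only part of the population meets the extended exclusion ROI
        ty = rng.uniform(72.0, 98.0)
        base = np.array(
            [
                [48, 146, 70],
                [43, 109, 64],
                [44, ty + 2, 58],
                [45, ty - 6, 86],
                [46, ty - 2, 104],
                [47, ty + 6, 114],
            ],
            dtype=float,
        )
    elif pattern == "projection_vertical":
        x0 = rng.uniform(40.0, 50.0)
        y0 = rng.uniform(99.0, 101.0)
        base = np.array(
            [[x0, y0, 134], [x0, y0, 102], [x0, y0, 68], [x0, y0, 40]], dtype=float
        )
        return base + rng.normal(0.0, 0.8, size=base.shape)
    elif pattern == "commissural":
        x0 = rng.uniform(46.0, 55.0)
        z0 = rng.uniform(105.0, 118.0)
        base = np.array(
            [[x0, 101, z0], [90, 103, z0 + 10], [180 - x0, 101, z0]], dtype=float
        )
    elif pattern == "background":
        lo = np.array([10.0, 18.0, 12.0])
        hi = np.array([86.0, 198.0, 168.0])
        p0 = rng.uniform(lo, hi)
        pts = [p0]
        for _ in range(4):
            step = rng.normal(0.0, 22.0, size=3)
            pts.append(np.clip(pts[-1] + step, lo, hi))
        return np.asarray(pts)
    else:  # pragma: no cover - guarded by ArtefactSpec
        raise ValueError(f"unknown artefact pattern {pattern!r}")
    return base + rng.normal(0.0, j, size=base.shape)


_ARTEFACT_TUBE = dict(radius=1.6, jitter=0.5, trim=2.0, step=2.0)

_BG_LO = np.array([10.0, 14.0, 10.0])
_BG_HI = np.array([86.0, 202.0, 170.0])


def _fit_into_box(pts: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Uniformly scale/shift a polyline so it lies inside [lo, hi].

    Used for background clutter, whose spline can overshoot its control
    points; scaling about the centroid keeps the curve smooth.
    """
    pmin, pmax = pts.min(axis=0), pts.max(axis=0)
    extent = pmax - pmin
    box = hi - lo
    with np.errstate(divide="ignore"):
        scale = min(1.0, np.min(np.where(extent > 0, box / np.maximum(extent, 1e-9), 1.0)))
    center = (pmin + pmax) / 2
    out = (pts - center) * scale + center
    pmin, pmax = out.min(axis=0), out.max(axis=0)
    shift = np.maximum(lo - pmin, 0.0) - np.maximum(pmax - hi, 0.0)
    return out + shift


def generate_artefacts(
    specs: list[ArtefactSpec],
    deformation: np.ndarray | None = None,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> list[tuple[np.ndarray, str]]:
    """Generate labeled artefact streamlines for every spec, in order."""
    if rng is None:
        rng = np.random.default_rng(seed)
    out: list[tuple[np.ndarray, str]] = []
    for spec in specs:
        tube = dict(_ARTEFACT_TUBE)
        tube.update({k: v for k, v in spec.params.items() if k in tube})
        if spec.pattern == "background":
            tube.update(radius=0.0, jitter=0.0, trim=0.0)
        for _ in range(spec.n_streamlines):
            ctrl = _artefact_controls(spec.pattern, rng, spec.params)
            if spec.pattern != "background":
                ctrl = apply_deformation(ctrl, deformation)
            dense = smooth_centerline(ctrl, spacing=1.0)
            pts = _tube_streamline(dense, tube["radius"], tube["jitter"],
                                   tube["step"], tube["trim"], rng)
            if spec.pattern == "background":
                pts = _fit_into_box(pts, _BG_LO, _BG_HI)
            out.append((pts, spec.pattern))
    return out


# ---------------------------------------------------------------------------
# Subjects and cohorts
# ---------------------------------------------------------------------------

def default_bundle_specs(n_per_bundle: int = 500, **tube_kwargs) -> list[BundleSpec]:
    return [
        BundleSpec(name, BUNDLE_CENTERLINES[name], n_streamlines=n_per_bundle, **tube_kwargs)
        for name in BUNDLE_NAMES
    ]


def default_artefact_specs(
    n_per_pattern: int = 100, n_background: int = 1000
) -> list[ArtefactSpec]:
    specs = [
        ArtefactSpec(p, n_per_pattern)
        for p in ARTEFACT_PATTERNS
        if p != "background"
    ]
    specs.append(ArtefactSpec("background", n_background))
    return specs


@dataclass
class PhantomSubject:
    tractogram: Tractogram
    spec: SubjectSpec
    templates: dict[str, np.ndarray]  # bundle -> deformed centerline polyline


@dataclass
class PhantomCohort:
    subjects: list[PhantomSubject]

    def __len__(self) -> int:
        return len(self.subjects)


def generate_subject(
    bundles: list[BundleSpec],
    artefacts: list[ArtefactSpec],
    subj: SubjectSpec,
    grid: ReferenceGrid | None = None,
) -> PhantomSubject:
    """One labeled tractogram: bundles + artefacts, complete label map.

    Raises if any generated point falls outside the grid (grid too small).
    """
    grid = grid or default_grid()
    deformation = deformation_matrix(subj)
    rng = np.random.default_rng(subj.seed)
    streamlines: list[np.ndarray] = []
    labels: dict[int, str] = {}
    for bspec in bundles:
        for pts in generate_bundle(bspec, deformation, rng=rng):
            labels[len(streamlines)] = bspec.name
            streamlines.append(pts)
    for pts, pattern in generate_artefacts(artefacts, deformation, rng=rng):
        labels[len(streamlines)] = pattern
        streamlines.append(pts)
    if streamlines:
        allpts = np.concatenate(streamlines, axis=0)
        if not grid.contains(allpts).all():
            raise ValueError(
                f"subject {subj.subject_id}: generated points fall outside the "
                f"{grid.dims} grid; enlarge the grid"
            )
    templates = {b.name: deformed_centerline(b, deformation) for b in bundles}
    tractogram = Tractogram(streamlines, grid, labels, validate=False)
    return PhantomSubject(tractogram, subj, templates)


@dataclass
class PhantomConfig:
    """The study conditions of a synthetic cohort."""

    n_per_bundle: int = 500
    n_per_artefact: int = 100
    n_background: int = 1000
    radius: float = 2.2
    jitter: float = 0.8
    trim: float = 4.0
    step: float = 2.0
    max_rotation_deg: float = 5.0
    max_scale_dev: float = 0.05

    def bundle_specs(self) -> list[BundleSpec]:
        return default_bundle_specs(
            self.n_per_bundle, radius=self.radius, jitter=self.jitter,
            trim=self.trim, step=self.step,
        )

    def artefact_specs(self) -> list[ArtefactSpec]:
        return default_artefact_specs(self.n_per_artefact, self.n_background)


def generate_cohort(
    config: PhantomConfig | None,
    n_subjects: int = 25,
    master_seed: int = 42,
    grid: ReferenceGrid | None = None,
) -> PhantomCohort:
    """``n_subjects`` labeled tractograms with distinct seeds and deformations.

    The master seed fans out to per-subject seeds by fixed arithmetic
    (``master_seed + subject_index``); fully deterministic.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2 (paired statistics undefined)")
    config = config or PhantomConfig()
    grid = grid or default_grid()
    bundles = config.bundle_specs()
    artefacts = config.artefact_specs()
    subjects = []
    for i in range(n_subjects):
        seed = int(master_seed) + i
        drng = np.random.default_rng(seed + 900_000)  # deformation draw stream
        spec = SubjectSpec(
            subject_id=i,
            seed=seed,
            rotation_deg=drng.uniform(-config.max_rotation_deg, config.max_rotation_deg, 3),
            scale=drng.uniform(1 - config.max_scale_dev, 1 + config.max_scale_dev, 3),
        )
        subjects.append(generate_subject(bundles, artefacts, spec, grid))
    return PhantomCohort(subjects)
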