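"""Streamline-based segmentation.

The metric is the minimum average direct-flip (MDF) distance: both
streamlines are resampled to a fixed number of points and the mean pointwise
Euclidean distance is taken in direct and in reversed point order, keeping
the minimum — so the metric is invariant to the arbitrary orientation of a
tracked streamline.

Clustering follows a dissimilarity-representation design: each streamline is
embedded by its MDF distances to a small set of reference streamlines chosen
by farthest-first traversal, k-means partitions the embedding, and a
k-medoids-style refinement in the original MDF space extracts one medoid
prototype per cluster and reassigns members to their nearest prototype until
the partition is stable. Prototypes are the abstraction an operator works
with: the selection operations (pick / invert / remove-unselected /
select-all / expand) manipulate clusters through them.

``auto_segment_by_template`` is a scripted surrogate for interactive visual
selection: iteratively cluster, keep clusters whose prototype lies within
``tau_select`` of a template streamline, drop the rest, refine with more
clusters, and finally keep the individual streamlines within ``tau_final`` of
the template.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .core import Tractogram, resample_streamline_points


@dataclass
class DistanceConfig:
    n_points: int = 20

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")


# ---------------------------------------------------------------------------
# MDF distance
# ---------------------------------------------------------------------------

def resample_many(streamlines, n_points: int) -> np.ndarray:
    """Stack streamlines resampled to ``n_points`` into an (n, k, 3) array.

    Stored as float32: distances are in mm on a decimetre-scale volume, so
    single precision is far below any meaningful tolerance and halves the
    memory traffic of the pairwise-distance kernels.
    """
    return np.stack(
        [resample_streamline_points(s, n_points) for s in streamlines]
    ).astype(np.float32)


def _mean_pointwise(a: np.ndarray, B: np.ndarray) -> np.ndarray:
    d = a - B
    return np.sqrt(np.einsum("...k,...k->...", d, d)).mean(axis=-1)


def mdf_cross(A: np.ndarray, B: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Pairwise MDF between two stacks of resampled streamlines.

    A: (n, k, 3), B: (m, k, 3) -> (n, m). Chunked over rows to bound memory.
    """
    A = np.asarray(A, dtype=np.float32)
    B = np.asarray(B, dtype=np.float32)
    n = A.shape[0]
    Bf = np.ascontiguousarray(B[:, ::-1, :])
    out = np.empty((n, B.shape[0]), dtype=np.float64)
    for i in range(0, n, chunk):
        a = A[i:i + chunk, None, :, :]
        direct = _mean_pointwise(a, B[None])
        flipped = _mean_pointwise(a, Bf[None])
        out[i:i + chunk] = np.minimum(direct, flipped)
    return out


def mdf_distance(a: np.ndarray, b: np.ndarray, cfg: DistanceConfig | None = None) -> float:
    """MDF distance between two streamlines (mm); symmetric, flip-invariant."""
    cfg = cfg or DistanceConfig()
    ra = resample_streamline_points(a, cfg.n_points)
    rb = resample_streamline_points(b, cfg.n_points)
    direct = float(np.linalg.norm(ra - rb, axis=1).mean())
    flipped = float(np.linalg.norm(ra - rb[::-1], axis=1).mean())
    return min(direct, flipped)


# ---------------------------------------------------------------------------
# Clustering with medoid prototypes
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    k: int
    assignment: dict[int, int]   # streamline id -> cluster index
    prototypes: dict[int, int]   # cluster index -> medoid streamline id

    def members(self, cluster: int) -> set[int]:
        return {i for i, c in self.assignment.items() if c == cluster}


def _farthest_first(R: np.ndarray, p: int, start: int) -> np.ndarray:
    """Indices of ``p`` reference streamlines by farthest-first traversal."""
    chosen = [start]
    dmin = mdf_cross(R, R[[start]])[:, 0]
    while len(chosen) < p:
        nxt = int(np.argmax(dmin))  # ties -> lowest index
        chosen.append(nxt)
        dmin = np.minimum(dmin, mdf_cross(R, R[[nxt]])[:, 0])
    return np.asarray(chosen)


_MEDOID_EXACT_LIMIT = 300


def _medoid_rows(R: np.ndarray, rows: np.ndarray) -> int:
    """Row index (into ``rows``) of the medoid under MDF.

    Exact (all pairwise distances) up to ``_MEDOID_EXACT_LIMIT`` members;
    beyond that the summed distance is scored against a deterministic
    evenly-spaced subsample of co-members, which keeps medoid extraction
    near-linear on large clusters.
    """
    m = len(rows)
    if m <= 2:
        return 0  # any member minimizes the sum; ties -> lowest index
    sub = R[rows]
    if m <= _MEDOID_EXACT_LIMIT:
        total = mdf_cross(sub, sub).sum(axis=1)
    else:
        ref = sub[np.linspace(0, m - 1, _MEDOID_EXACT_LIMIT // 2).astype(int)]
        total = mdf_cross(sub, ref).sum(axis=1)
    return int(np.argmin(total))


def cluster_streamlines(
    t: Tractogram,
    ids=None,
    k: int = 50,
    cfg: DistanceConfig | None = None,
    seed: int = 0,
    max_iter: int = 6,
    resampled: np.ndarray | None = None,
) -> ClusterModel:
    """Partition streamlines into <= k non-empty clusters with medoid prototypes.

    At convergence every member is assigned to its nearest prototype (ties
    resolved toward the lowest cluster index), so the partition agrees with a
    brute-force nearest-prototype assignment.
    """
    cfg = cfg or DistanceConfig()
    ids = sorted(t.ids()) if ids is None else sorted(int(i) for i in ids)
    n = len(ids)
    if n == 0:
        raise ValueError("cannot cluster an empty id set")
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")

    if resampled is not None:
        R = resampled[ids]  # full-tractogram stack shared across calls
    else:
        R = resample_many([t.streamlines[i] for i in ids], cfg.n_points)
    if k == n:
        return ClusterModel(k, {i: c for c, i in enumerate(ids)},
                            {c: i for c, i in enumerate(ids)})

    rng = np.random.default_rng(seed)
    p = min(40, n)
    refs = _farthest_first(R, p, start=int(rng.integers(n)))
    E = mdf_cross(R, R[refs])
    km = KMeans(n_clusters=k, n_init=2, random_state=int(seed) % (2**31))
    assign = km.fit_predict(E)

    # k-medoids-style alternation in MDF space: medoid extraction, then
    # nearest-prototype reassignment (ties -> lowest cluster index), until
    # the partition is stable. Empty clusters are dropped by the relabeling.
    for _ in range(max_iter):
        labels = np.unique(assign)
        rowsets = [np.flatnonzero(assign == c) for c in labels]
        medoid_rows = np.array([rows[_medoid_rows(R, rows)] for rows in rowsets])
        old = np.searchsorted(labels, assign)  # compact relabeling
        new = np.argmin(mdf_cross(R, R[medoid_rows]), axis=1)
        if np.array_equal(new, old):
            assign = old
            break
        assign = new
    else:
        # schedule exhausted without a fixed point: keep the last assignment
        # and recompute medoids so prototypes match their clusters
        labels = np.unique(assign)
        rowsets = [np.flatnonzero(assign == c) for c in labels]
        medoid_rows = np.array([rows[_medoid_rows(R, rows)] for rows in rowsets])
        assign = np.searchsorted(labels, assign)

    assignment = {ids[row]: int(c) for row, c in enumerate(assign)}
    prototypes = {int(c): ids[int(medoid_rows[int(c)])] for c in np.unique(assign)}
    return ClusterModel(len(prototypes), assignment, prototypes)


# ---------------------------------------------------------------------------
# Selection operations
# ---------------------------------------------------------------------------

@dataclass
class SelectionState:
    active_ids: set[int]
    selected: set[int] = field(default_factory=set)
    history: list[str] = field(default_factory=list)


def apply_selection_op(
    state: SelectionState,
    model: ClusterModel,
    op: str,
    cluster: int | None = None,
    radius: float | None = None,
    t: Tractogram | None = None,
    cfg: DistanceConfig | None = None,
) -> SelectionState:
    """One interactive-style operation on the current clustering.

    pick: add a cluster to the selection; invert: complement the selection
    within the current clusters; remove_unselected: shrink the active ids to
    members of selected clusters; select_all: select every cluster; expand:
    also select clusters whose prototype is within ``radius`` mm (MDF) of a
    selected prototype.
    """
    all_clusters = set(model.prototypes)
    selected = set(state.selected)
    active = set(state.active_ids)
    if op == "pick":
        if cluster not in all_clusters:
            raise KeyError(f"cluster {cluster} does not exist")
        selected.add(cluster)
    elif op == "invert":
        selected = all_clusters - selected
    elif op == "select_all":
        selected = set(all_clusters)
    elif op == "remove_unselected":
        keep = set()
        for c in selected:
            keep |= model.members(c)
        active &= keep
        selected = set(selected)
    elif op == "expand":
        if radius is None or t is None:
            raise ValueError("expand needs a radius and the tractogram")
        cfg = cfg or DistanceConfig()
        proto_ids = sorted(all_clusters)
        P = resample_many(
            [t.streamlines[model.prototypes[c]] for c in proto_ids], cfg.n_points
        )
        sel_rows = [j for j, c in enumerate(proto_ids) if c in selected]
        if sel_rows:
            D = mdf_cross(P, P[sel_rows])
            near = D.min(axis=1) <= radius
            selected |= {proto_ids[j] for j in np.flatnonzero(near)}
    else:
        raise ValueError(f"unknown selection op {op!r}")
    return SelectionState(active, selected, state.history + [op])


# ---------------------------------------------------------------------------
# Template-guided scripted segmentation
# ---------------------------------------------------------------------------

@dataclass
class TemplatePolicy:
    tau_select: float = 15.0            # mm, prototype-to-template gate
    tau_final: float = 8.0              # mm, per-streamline final gate
    k_schedule: tuple = (50, 100, 200, 400)


def auto_segment_by_template(
    t: Tractogram,
    template,
    policy: TemplatePolicy | None = None,
    cfg: DistanceConfig | None = None,
    seed: int = 0,
    ids=None,
    resampled: np.ndarray | None = None,
) -> set[int]:
    """Scripted template-guided selection: the reproducible surrogate for
    interactive prototype picking.

    Iterates: cluster the active set with increasing k, keep clusters whose
    medoid prototype has MDF < tau_select to the nearest template streamline,
    drop the rest; stop when the schedule is exhausted or k reaches the
    active-set size; finally keep individual streamlines with MDF < tau_final
    to the nearest template. The active set never grows.
    """
    policy = policy or TemplatePolicy()
    cfg = cfg or DistanceConfig()
    if len(t) == 0:
        return set()
    template = list(template)
    if not template:
        raise ValueError("template must contain at least one streamline")
    T = resample_many(template, cfg.n_points)
    active = sorted(t.ids()) if ids is None else sorted(int(i) for i in ids)
    if resampled is None:
        resampled = resample_many(t.streamlines, cfg.n_points)

    for round_i, k in enumerate(policy.k_schedule):
        if k >= len(active) or not active:
            break
        model = cluster_streamlines(t, active, k, cfg, seed=seed + round_i,
                                    resampled=resampled)
        proto_ids = sorted(model.prototypes)
        P = resampled[[model.prototypes[c] for c in proto_ids]]
        d = mdf_cross(P, T).min(axis=1)
        state = SelectionState(set(active))
        for c, dc in zip(proto_ids, d):
            if dc < policy.tau_select:
                state = apply_selection_op(state, model, "pick", cluster=c)
        state = apply_selection_op(state, model, "remove_unselected")
        active = sorted(state.active_ids)
        if not active:
            return set()

    if not active:
        return set()
    d = mdf_cross(resampled[active], T).min(axis=1)
    return {i for i, di in zip(active, d) if di < policy.tau_final}
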