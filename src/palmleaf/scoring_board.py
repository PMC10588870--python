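"""Scoring-board clustering and the cluster-based total-LA estimator.

Field protocol: every leaf of a plant is laid on a board of nested squares
(3.5×3.5 up to 15.5×15.5 inches in 1-inch steps) and binned by the smallest
square that contains its length × width footprint.  A couple of leaves per
cluster are sampled as representatives and measured (or their area is
predicted allometrically); the plant total is then

    total LA = Σ_i (LA_rep · LN)_i      over the plant's N clusters,

where LA_rep is the representative leaf area of cluster i and LN its leaf
count.  With every leaf its own representative the sum reduces exactly to
the sum of individual leaf areas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .allometry import AllometricModel
from .io import LeafRecord

__all__ = [
    "CM_PER_INCH",
    "OVERFLOW",
    "BoardSpec",
    "ClusterAssignment",
    "PlantSummary",
    "assign_cluster",
    "group_leaves",
    "select_representatives",
    "total_leaf_area",
    "estimate_plant_total",
]

CM_PER_INCH = 2.54

#: Cell label for leaves larger than the board's outermost square.
OVERFLOW = math.inf

# tolerance for "exactly on a grid line" comparisons, in inches; absorbs the
# cm→inch floating-point round trip
_GRID_EPS = 1e-9


@dataclass(frozen=True)
class BoardSpec:
    """Geometry of the scoring board (inches).

    Grid lines sit at ``min_cell, min_cell + step, …, max_cell``.  A value
    exactly on a line belongs to that line's cell (closed upper bound);
    values beyond ``max_cell`` fall in an explicit overflow cell.
    """

    min_cell: float = 3.5
    max_cell: float = 15.5
    step: float = 1.0
    cm_per_inch: float = CM_PER_INCH

    def __post_init__(self) -> None:
        if not (self.min_cell < self.max_cell):
            raise ValueError("min_cell must be < max_cell")
        if not self.step > 0:
            raise ValueError("step must be > 0")

    @property
    def grid_lines(self) -> np.ndarray:
        n = int(round((self.max_cell - self.min_cell) / self.step)) + 1
        return self.min_cell + self.step * np.arange(n)

    def cell_of(self, value_cm: float) -> float:
        """Smallest grid line (inches) ≥ the value; OVERFLOW past the board."""
        if not value_cm > 0:
            raise ValueError(f"dimension must be > 0, got {value_cm}")
        inches = value_cm / self.cm_per_inch
        if inches <= self.min_cell + _GRID_EPS:
            return float(self.min_cell)
        if inches > self.max_cell + _GRID_EPS:
            return OVERFLOW
        k = math.ceil((inches - self.min_cell) / self.step - _GRID_EPS)
        return float(self.min_cell + k * self.step)


@dataclass
class ClusterAssignment:
    """One occupied scoring-board cell of a plant.

    ``key`` is the (L_cell, W_cell) pair in inches (``inf`` marks
    overflow).  ``LA_rep`` is the representative leaf area in cm², set by
    :func:`select_representatives` or by an allometric prediction.
    """

    key: tuple[float, float]
    members: list[LeafRecord]
    representative_ids: list[str] = field(default_factory=list)
    LA_rep: float | None = None

    @property
    def LN(self) -> int:
        return len(self.members)

    @property
    def member_leaf_ids(self) -> list[str]:
        return [m.leaf_id for m in self.members]


@dataclass(frozen=True)
class PlantSummary:
    """Per-plant aggregate of the cluster-based estimator."""

    plant_id: str
    n_clusters: int
    total_LA: float  # cm²

    @property
    def total_LA_m2(self) -> float:
        return self.total_LA / 10_000.0


def assign_cluster(L_cm: float, W_cm: float, board: BoardSpec | None = None) -> tuple[float, float]:
    """Scoring-board cell for a leaf of length L and width W (cm)."""
    board = board or BoardSpec()
    return (board.cell_of(L_cm), board.cell_of(W_cm))


def group_leaves(leaves: list[LeafRecord], board: BoardSpec | None = None) -> list[ClusterAssignment]:
    """Partition one plant's leaves into scoring-board clusters.

    Every leaf lands in exactly one cluster, so cluster sizes sum to the
    number of leaves.  Clusters are returned sorted by key (overflow last).
    """
    if not leaves:
        raise ValueError("no leaves to group")
    plant_ids = {leaf.plant_id for leaf in leaves}
    if len(plant_ids) > 1:
        raise ValueError(f"leaves span multiple plants: {sorted(plant_ids)}")
    board = board or BoardSpec()
    by_key: dict[tuple[float, float], list[LeafRecord]] = {}
    for leaf in leaves:
        key = assign_cluster(leaf.L, leaf.W, board)
        by_key.setdefault(key, []).append(replace(leaf, cluster_key=key))
    return [ClusterAssignment(key=k, members=v) for k, v in sorted(by_key.items())]


def select_representatives(
    cluster: ClusterAssignment,
    k: int = 2,
    seed: int | np.random.Generator = 0,
) -> ClusterAssignment:
    """Sample min(k, LN) representatives uniformly without replacement.

    ``LA_rep`` becomes the arithmetic mean of the representatives' measured
    areas (left unset if any representative lacks a measurement — the
    hybrid path fills it by prediction instead).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_pick = min(k, cluster.LN)
    idx = sorted(rng.choice(cluster.LN, size=n_pick, replace=False).tolist())
    reps = [cluster.members[i] for i in idx]
    la_rep = None
    if all(m.LA is not None for m in reps):
        la_rep = float(np.mean([m.LA for m in reps]))
    rep_ids = {m.leaf_id for m in reps}
    members = [
        replace(m, is_representative=m.leaf_id in rep_ids) for m in cluster.members
    ]
    return ClusterAssignment(
        key=cluster.key,
        members=members,
        representative_ids=[m.leaf_id for m in reps],
        LA_rep=la_rep,
    )


def total_leaf_area(clusters: list[ClusterAssignment], plant_id: str | None = None) -> PlantSummary:
    """Plant total: Σ (LA_rep · LN) over clusters, in cm²."""
    if not clusters:
        raise ValueError("no clusters")
    for c in clusters:
        if c.LA_rep is None:
            raise ValueError(f"cluster {c.key} has no representative leaf area")
        if not c.LA_rep > 0:
            raise ValueError(f"cluster {c.key}: LA_rep must be > 0")
    if plant_id is None:
        plant_id = clusters[0].members[0].plant_id if clusters[0].members else "?"
    total = float(sum(c.LA_rep * c.LN for c in clusters))
    return PlantSummary(plant_id=plant_id, n_clusters=len(clusters), total_LA=total)


def estimate_plant_total(
    leaves: list[LeafRecord],
    board: BoardSpec | None = None,
    mode: str = "photo",
    model: AllometricModel | None = None,
    k: int = 2,
    seed: int = 0,
) -> tuple[PlantSummary, list[ClusterAssignment]]:
    """Cluster one plant's leaves and estimate its total leaf area.

    ``mode="photo"`` uses the representatives' measured LA (the
    cluster-based photography method); ``mode="hybrid"`` predicts each
    representative's LA from its L and W with the given allometric model,
    so no per-leaf area measurement is needed.
    """
    board = board or BoardSpec()
    rng = np.random.default_rng(seed)
    clusters = [select_representatives(c, k=k, seed=rng) for c in group_leaves(leaves, board)]
    if mode == "photo":
        missing = [c.key for c in clusters if c.LA_rep is None]
        if missing:
            raise ValueError(
                f"photo mode needs measured LA for representatives; missing in {missing}"
            )
    elif mode == "hybrid":
        if model is None:
            raise ValueError("hybrid mode needs an allometric model")
        clusters = [
            replace(
                c,
                LA_rep=float(
                    np.mean(
                        [model.predict(m.L, m.W) for m in c.members if m.is_representative]
                    )
                ),
            )
            for c in clusters
        ]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return total_leaf_area(clusters), clusters
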