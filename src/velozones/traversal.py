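"""Velocity binning, traversal (bin-transition) counts and graph affinity.

A *traversal* is the change in velocity between two adjacent samples,
recorded as a transition between 0.1 m/s velocity bins on [0, 10] m/s.
Pooled traversal counts form the weighted graph that spectral clustering
partitions; a small beta term on the bin chain keeps unvisited bins
connected so clusters stay contiguous in velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trace import TIME_TOL, VelocityTrace

__all__ = [
    "BinGrid",
    "TraversalMatrix",
    "AffinityMatrix",
    "bin_index",
    "traversal_matrix",
    "pool_traversals",
    "affinity_from_traversals",
]

DEFAULT_BETA = 0.1


class BinningError(ValueError):
    """Velocity outside the grid, or a degenerate trace."""


@dataclass(frozen=True)
class BinGrid:
    """Uniform velocity grid: half-open bins, the top bin closed at v_max."""

    v_min: float = 0.0
    v_max: float = 10.0
    width: float = 0.1

    def __post_init__(self) -> None:
        n = (self.v_max - self.v_min) / self.width
        if self.width <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError("grid width must evenly divide the velocity range")

    @property
    def n_bins(self) -> int:
        return int(round((self.v_max - self.v_min) / self.width))

    @property
    def centers(self) -> np.ndarray:
        """Bin-centre velocities, used as the 1-D coordinates for WCSS."""
        return self.v_min + (np.arange(self.n_bins) + 0.5) * self.width

    @property
    def lower_edges(self) -> np.ndarray:
        return self.v_min + np.arange(self.n_bins) * self.width

    def index(self, v: np.ndarray | float) -> np.ndarray | int:
        """Bin index of velocity v; v == v_max maps into the top (closed) bin."""
        v = np.asarray(v, dtype=float)
        if np.any(v < self.v_min) or np.any(v > self.v_max):
            raise BinningError(
                f"velocity outside [{self.v_min}, {self.v_max}]; run cleaning first"
            )
        idx = np.floor((v - self.v_min) / self.width).astype(np.intp)
        idx = np.minimum(idx, self.n_bins - 1)  # closes the top bin
        return idx if idx.ndim else int(idx)


def bin_index(v: float, grid: BinGrid | None = None) -> int:
    """Index of the bin containing velocity ``v`` (scalar convenience)."""
    grid = grid or BinGrid()
    return int(grid.index(v))


@dataclass(frozen=True)
class TraversalMatrix:
    """Counts of bin-to-bin transitions between adjacent retained samples."""

    counts: np.ndarray
    grid: BinGrid = field(default_factory=BinGrid)
    source: str = "unknown"

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        n = self.grid.n_bins
        if c.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def occupancy(self) -> np.ndarray:
        """Per-bin occupancy weights: diagonal-inclusive row sums of counts."""
        return self.counts.sum(axis=1).astype(float)


def traversal_matrix(trace: VelocityTrace, grid: BinGrid | None = None) -> TraversalMatrix:
    """Count traversals of one cleaned trace.

    Only pairs of consecutive samples exactly 1/sample_hz apart are
    counted; pairs spanning a cleaning gap contribute nothing.
    """
    grid = grid or BinGrid()
    if len(trace) < 2:
        raise BinningError("need at least 2 samples to count traversals")
    idx = grid.index(trace.velocities)
    dt = np.diff(trace.times)
    contiguous = np.abs(dt - 1.0 / trace.sample_hz) <= TIME_TOL
    counts = np.zeros((grid.n_bins, grid.n_bins), dtype=np.int64)
    np.add.at(counts, (idx[:-1][contiguous], idx[1:][contiguous]), 1)
    return TraversalMatrix(counts, grid, source=f"{trace.player_id}/{trace.match_id}")


def pool_traversals(matrices: list[TraversalMatrix]) -> TraversalMatrix:
    """Element-wise sum over matrices sharing a grid."""
    if not matrices:
        raise ValueError("cannot pool an empty list of traversal matrices")
    grid = matrices[0].grid
    if any(m.grid != grid for m in matrices):
        raise ValueError("all traversal matrices must share one grid")
    total = np.zeros_like(matrices[0].counts)
    for m in matrices:
        total = total + m.counts
    return TraversalMatrix(total, grid, source="pooled")


@dataclass(frozen=True)
class AffinityMatrix:
    """Symmetric graph affinity over velocity bins.

    weights = S + beta * C, where S is the symmetrised traversal matrix
    scaled so its largest entry is 1 (a zero matrix stays zero) and C is
    the bin-chain adjacency (ones on the +/-1 off-diagonals).  The chain
    term guarantees connectivity, so empty bins still join their
    velocity-adjacent neighbours rather than arbitrary clusters.
    """

    weights: np.ndarray
    beta: float
    grid: BinGrid = field(default_factory=BinGrid)
    occupancy: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape[0] != w.shape[1]:
            raise ValueError("affinity must be square")
        if not np.allclose(w, w.T):
            raise ValueError("affinity must be symmetric")
        if np.any(w < 0):
            raise ValueError("affinity must be non-negative")
        object.__setattr__(self, "weights", w)

    @property
    def degrees(self) -> np.ndarray:
        return self.weights.sum(axis=1)


def affinity_from_traversals(
    T: TraversalMatrix, beta: float = DEFAULT_BETA
) -> AffinityMatrix:
    """Build the beta-smoothed affinity matrix from traversal counts."""
    if beta <= 0:
        raise ValueError("beta must be positive (it provides chain connectivity)")
    S = (T.counts + T.counts.T) / 2.0
    peak = S.max()
    if peak > 0:
        S = S / peak
    n = T.grid.n_bins
    C = np.zeros((n, n))
    off = np.arange(n - 1)
    C[off, off + 1] = 1.0
    C[off + 1, off] = 1.0
    return AffinityMatrix(S + beta * C, beta=beta, grid=T.grid, occupancy=T.occupancy)
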