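"""Spectral clustering of velocity bins and the two-stage threshold procedure.

Stage 1 pools all retained match files of a cohort into one traversal
graph, clusters it at every candidate k and picks the elbow of the
within-cluster-sum-of-squares (WCSS) curve.  Stage 2 re-clusters each match
file independently at that fixed k, reads off the boundary velocity between
each pair of adjacent clusters, and averages boundaries by rank across the
cohort's matches to give the reported thresholds.

Clustering is normalised spectral clustering on the bin-chain affinity:
symmetric normalised Laplacian, embedding by the k bottom eigenvectors,
row normalisation, then seeded k-means.  Because the affinity carries a
beta chain term, clusters come out contiguous in velocity on all but
pathological inputs; a deterministic local repair handles the rest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .trace import VelocityTrace
from .traversal import (
    AffinityMatrix,
    BinGrid,
    TraversalMatrix,
    affinity_from_traversals,
    pool_traversals,
    traversal_matrix,
)

__all__ = [
    "ClusterSolution",
    "ElbowCurve",
    "ZoneThresholds",
    "ClusteringError",
    "spectral_cluster",
    "elbow_point",
    "elbow_select",
    "extract_boundaries",
    "derive_cohort_thresholds",
]

logger = logging.getLogger(__name__)

DEFAULT_KMEANS_SEED = 20230021  # arbitrary documented constant
DEFAULT_K_RANGE = (2, 10)


class ClusteringError(ValueError):
    """Clustering preconditions violated or an unrepairable solution."""


@dataclass(frozen=True)
class ClusterSolution:
    """Bin-to-category labelling at one value of k.

    Labels are 0..k-1 ordered by ascending cluster mean velocity; ``wcss``
    is the occupancy-weighted within-cluster sum of squares of bin-centre
    velocities (units m^2/s^2); ``contiguous`` records whether every
    cluster is a single run of adjacent bins.
    """

    k: int
    labels: np.ndarray
    wcss: float
    contiguous: bool


@dataclass(frozen=True)
class ElbowCurve:
    """WCSS as a function of k, with the selected inflection point."""

    k_values: np.ndarray
    wcss_values: np.ndarray
    k_star: int


@dataclass(frozen=True)
class ZoneThresholds:
    """Cohort movement-category thresholds with per-match provenance.

    ``boundaries`` are the k-1 strictly increasing velocities separating k
    categories; zone z spans [boundaries[z-1], boundaries[z]) with zone 0
    starting at 0.  ``per_match_boundaries`` is the table the mean was
    taken over (one row per retained match, unrounded).
    """

    cohort: str
    k: int
    boundaries: np.ndarray
    per_match_boundaries: np.ndarray = field(repr=False)
    match_ids: list[str] = field(default_factory=list, repr=False)
    elbow: ElbowCurve | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if len(b) != self.k - 1:
            raise ClusteringError("expected k-1 boundaries")
        if len(b) and (np.any(np.diff(b) <= 0) or b[0] <= 0):
            raise ClusteringError("boundaries must be strictly increasing and positive")
        object.__setattr__(self, "boundaries", b)

    @property
    def boundaries_rounded(self) -> np.ndarray:
        """Boundaries to 0.01 m/s, the reporting precision."""
        return np.round(self.boundaries, 2)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "cohort": self.cohort,
            "k": self.k,
            "boundaries": [round(float(b), 2) for b in self.boundaries],
            "boundaries_unrounded": [float(b) for b in self.boundaries],
            "per_match_boundaries": {
                mid: [float(x) for x in row]
                for mid, row in zip(self.match_ids, self.per_match_boundaries)
            },
            "elbow": None
            if self.elbow is None
            else {
                "k_values": [int(k) for k in self.elbow.k_values],
                "wcss": [float(w) for w in self.elbow.wcss_values],
                "k_star": int(self.elbow.k_star),
            },
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# core clustering
# ---------------------------------------------------------------------------

def _spectral_embedding(A: AffinityMatrix, k: int) -> np.ndarray:
    W = A.weights
    d = W.sum(axis=1)
    if np.any(d <= 0):
        raise ClusteringError("affinity has a zero-degree node; beta smoothing missing?")
    d_inv_sqrt = 1.0 / np.sqrt(d)
    L = np.eye(len(W)) - d_inv_sqrt[:, None] * W * d_inv_sqrt[None, :]
    L = (L + L.T) / 2.0  # enforce exact symmetry for eigh
    _, vecs = eigh(L, subset_by_index=(0, k - 1))
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    nz = norms[:, 0] > 0
    vecs[nz] = vecs[nz] / norms[nz]
    return vecs


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs as (label, start, stop) with stop exclusive."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((int(labels[start]), start, i))
            start = i
    return out


def _repair_contiguity(labels: np.ndarray, W: np.ndarray, occ: np.ndarray) -> np.ndarray:
    """Deterministic local repair of non-contiguous labellings.

    One occupancy-weighted mode filter (window of 3 bins), then any
    remaining fragment (a run differing from both neighbours) is absorbed
    into the neighbouring run with the larger summed affinity across the
    fragment's boundary.
    """
    n = len(labels)
    w = occ + 1e-12  # keep empty bins votable, break ties by current label below
    new = labels.copy()
    for i in range(n):
        lo, hi = max(0, i - 1), min(n, i + 2)
        votes: dict[int, float] = {}
        for j in range(lo, hi):
            votes[labels[j]] = votes.get(labels[j], 0.0) + w[j]
        best = max(votes.items(), key=lambda kv: (kv[1], kv[0] == labels[i]))
        new[i] = best[0]
    labels = new

    guard = 0
    while guard < n:
        guard += 1
        runs = _runs(labels)
        by_label: dict[int, list[int]] = {}
        for ridx, (lab, _, _) in enumerate(runs):
            by_label.setdefault(lab, []).append(ridx)
        fragmented = {lab: idxs for lab, idxs in by_label.items() if len(idxs) > 1}
        if not fragmented:
            break
        # the fragment is the detached run with the least occupancy mass among
        # runs of split labels (its label's heaviest run is the cluster's home);
        # ties break toward the leftmost run for determinism
        candidates = []
        for lab, idxs in fragmented.items():
            masses = [(w[runs[r][1]:runs[r][2]].sum(), r) for r in idxs]
            masses.sort()
            candidates.extend(masses[:-1])  # all but the heaviest run
        mass, ridx = min(candidates, key=lambda mr: (mr[0], runs[mr[1]][1]))
        lab, a, b = runs[ridx]
        left = runs[ridx - 1][0] if ridx > 0 else None
        right = runs[ridx + 1][0] if ridx + 1 < len(runs) else None
        aff_left = float(W[a - 1, a]) if left is not None else -np.inf
        aff_right = float(W[b, b - 1]) if (right is not None and b < n) else -np.inf
        labels[a:b] = left if aff_left >= aff_right else right
    return labels


def _weighted_wcss(labels: np.ndarray, centers: np.ndarray, weights: np.ndarray) -> float:
    wcss = 0.0
    for lab in np.unique(labels):
        m = labels == lab
        wsum = weights[m].sum()
        if wsum <= 0:
            continue
        mu = float(np.average(centers[m], weights=weights[m]))
        wcss += float(np.sum(weights[m] * (centers[m] - mu) ** 2))
    return wcss


def spectral_cluster(
    A: AffinityMatrix,
    k: int,
    seed: int = DEFAULT_KMEANS_SEED,
    occupancy: np.ndarray | None = None,
) -> ClusterSolution:
    """Normalised spectral clustering of the bin graph into k categories.

    Embedding rows are clustered with seeded k-means (10 restarts); raw
    clusters are re-ordered by ascending occupancy-weighted mean bin
    velocity and repaired to contiguity when needed.  WCSS is computed on
    bin-centre velocities with per-bin occupancy weights, so the elbow
    curve reflects the physical velocity structure the thresholds live in.
    """
    n = A.weights.shape[0]
    if not (2 <= k <= 20):
        raise ClusteringError("k must be between 2 and 20")
    if k > n:
        raise ClusteringError("k exceeds the number of bins")
    occ = occupancy if occupancy is not None else A.occupancy
    if occ is None:
        occ = np.ones(n)
    occ = np.asarray(occ, dtype=float)

    emb = _spectral_embedding(A, k)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed % (2**32))
    # degree weights make the k-means step consistent with the normalised-cut
    # objective (weighted-kernel-k-means equivalence); without them, chains of
    # never-visited bins held together only by the beta term can capture a
    # centroid at the expense of genuinely occupied velocity regions.
    raw = km.fit_predict(emb, sample_weight=A.weights.sum(axis=1))

    centers = A.grid.centers if A.grid.n_bins == n else np.arange(n) + 0.5

    # order clusters by ascending (occupancy-weighted) mean velocity
    order_keys = []
    for lab in range(k):
        m = raw == lab
        wsum = occ[m].sum()
        mu = np.average(centers[m], weights=occ[m]) if wsum > 0 else centers[m].mean()
        order_keys.append(mu)
    remap = {old: new for new, old in enumerate(np.argsort(order_keys))}
    labels = np.array([remap[l] for l in raw], dtype=np.intp)

    contiguous = bool(np.all(np.diff(labels) >= 0))
    if not contiguous:
        labels = _repair_contiguity(labels, A.weights, occ)
        runs = _runs(labels)
        if len(runs) == len(set(labels)):
            # relabel runs in bin order; along a chain this is ascending velocity
            labels = np.repeat(np.arange(len(runs), dtype=np.intp),
                               [b - a for _, a, b in runs])
            contiguous = True
    if len(np.unique(labels)) != k:
        raise ClusteringError(
            f"contiguity repair collapsed the solution below k={k} clusters"
        )
    wcss = _weighted_wcss(labels, centers, occ)
    return ClusterSolution(k=k, labels=labels, wcss=wcss, contiguous=bool(contiguous))


# ---------------------------------------------------------------------------
# elbow selection
# ---------------------------------------------------------------------------

def elbow_point(k_values: np.ndarray, wcss_values: np.ndarray) -> int:
    """Inflection k: interior argmax of the second difference of log WCSS.

    The discrete curvature log W(k-1) - 2 log W(k) + log W(k+1) measures
    the *relative* flattening of the curve, so the rule is invariant to the
    overall WCSS scale; on raw WCSS the largest absolute curvature of a
    steeply decaying curve almost always sits at the smallest k regardless
    of the data's cluster structure.  Ties break toward the smaller k, and
    the endpoints of the tested range are never selected.
    """
    k_values = np.asarray(k_values)
    w = np.asarray(wcss_values, dtype=float)
    if len(k_values) < 3:
        raise ClusteringError("need at least three k values to locate an elbow")
    logw = np.log(np.maximum(w, max(w.max(), 1e-300) * 1e-15))
    d2 = logw[:-2] - 2 * logw[1:-1] + logw[2:]
    return int(k_values[1:-1][int(np.argmax(d2))])


def elbow_select(
    A: AffinityMatrix,
    k_min: int = DEFAULT_K_RANGE[0],
    k_max: int = DEFAULT_K_RANGE[1],
    seed: int = DEFAULT_KMEANS_SEED,
    occupancy: np.ndarray | None = None,
) -> ElbowCurve:
    """Run spectral clustering over k in [k_min, k_max] and pick the elbow."""
    if k_min < 2 or k_max < k_min + 2:
        raise ClusteringError("need k_min >= 2 and k_max >= k_min + 2")
    ks = np.arange(k_min, k_max + 1)
    wcss = np.array([spectral_cluster(A, int(k), seed, occupancy).wcss for k in ks])
    rises = np.diff(wcss) > 1e-6 * max(wcss[0], 1e-300)
    if rises.any():
        logger.warning(
            "WCSS not monotone at k=%s (k-means local optima)", ks[1:][rises].tolist()
        )
    return ElbowCurve(k_values=ks, wcss_values=wcss, k_star=elbow_point(ks, wcss))


# ---------------------------------------------------------------------------
# boundaries and the two-stage cohort procedure
# ---------------------------------------------------------------------------

def extract_boundaries(sol: ClusterSolution, grid: BinGrid | None = None) -> np.ndarray:
    """Boundary velocities between adjacent clusters of a contiguous solution.

    Each boundary is the lower edge of the first bin of the upper cluster.
    """
    grid = grid or BinGrid()
    if not sol.contiguous:
        raise ClusteringError("solution is not contiguous; repair must run first")
    change = np.flatnonzero(np.diff(sol.labels) != 0) + 1
    return grid.lower_edges[change]


def derive_cohort_thresholds(
    traces: list[VelocityTrace],
    k: int | str = "auto",
    grid: BinGrid | None = None,
    beta: float = 0.1,
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
    seed: int = DEFAULT_KMEANS_SEED,
    cohort: str | None = None,
) -> ZoneThresholds:
    """The full two-stage procedure for one cohort of cleaned traces.

    Stage 1 (only when ``k='auto'``): pool every trace's traversals and run
    elbow selection over ``k_range``.  Stage 2: cluster each match file
    independently at the fixed k, extract its boundaries, and average
    boundaries by rank across matches.  Matches whose per-file clustering
    fails are excluded from the mean and logged.
    """
    if not traces:
        raise ClusteringError("need at least one retained trace")
    grid = grid or BinGrid()
    cohort = cohort or traces[0].sex

    per_trace = [traversal_matrix(t, grid) for t in traces]

    elbow = None
    if k == "auto":
        pooled = pool_traversals(per_trace)
        A = affinity_from_traversals(pooled, beta)
        elbow = elbow_select(A, k_range[0], k_range[1], seed)
        k_fixed = elbow.k_star
    else:
        k_fixed = int(k)

    rows, match_ids = [], []
    for trace, T in zip(traces, per_trace):
        try:
            A_i = affinity_from_traversals(T, beta)
            sol = spectral_cluster(A_i, k_fixed, seed)
            b = extract_boundaries(sol, grid)
            if len(b) != k_fixed - 1:
                raise ClusteringError("wrong boundary count")
        except ClusteringError as exc:
            logger.warning("excluding match %s from the mean: %s", T.source, exc)
            continue
        rows.append(b)
        match_ids.append(trace.match_id)
    if not rows:
        raise ClusteringError("every match failed per-file clustering")
    table = np.vstack(rows)
    return ZoneThresholds(
        cohort=cohort,
        k=k_fixed,
        boundaries=table.mean(axis=0),
        per_match_boundaries=table,
        match_ids=match_ids,
        elbow=elbow,
    )
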