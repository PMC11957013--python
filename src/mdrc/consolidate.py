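"""Consolidation of bootstrap ensembles and 2D distribution projections.

A bootstrap ensemble holds many alternative component sets for the same
voxel.  To form one representative distribution, components are pooled
across bootstrap solutions and grouped by k-means clustering with the L1
distance (centroids are coordinate-wise medians, i.e. k-medians) over
normalized features — Diso(ω) and DΔ²(ω) at the two probe frequencies,
principal-axis direction, R1 and R2.  Each cluster is then collapsed to a
single component by taking the per-parameter median and the median weight.

Consolidated distributions are visualized as 64x64 weight meshes on the
Diso-DΔ², Diso-R1 and Diso-R2 planes; ROI-level distributions are the
across-scan mean of per-scan normalized ROI sums.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .forward import VoxelDistribution
from .inversion import VoxelEnsemble

__all__ = [
    "KMediansL1",
    "ensemble_features",
    "cluster_components",
    "consolidate_voxel",
    "consolidate_ensemble",
    "MeshConfig",
    "Projection2D",
    "project_2d",
    "roi_average_projection",
]

logger = logging.getLogger(__name__)

PLANES = ("diso_ddelta2", "diso_r1", "diso_r2")


class KMediansL1(BaseEstimator, ClusterMixin):
    """k-means clustering with the L1 (cityblock) metric.

    Under L1, the within-cluster cost is minimized by the coordinate-wise
    median, so centroid updates are medians (k-medians).  Initialization is
    a k-means++-style greedy seeding using L1 distances.

    Parameters
    ----------
    n_clusters : int
    max_iter : int
    n_init : int
        Independent restarts; the labeling with the lowest total L1 cost wins.
    random_state : int or Generator, optional

    Attributes
    ----------
    cluster_centers_ : ndarray (n_clusters, n_features)
    labels_ : ndarray (n_samples,)
    inertia_ : float
        Total L1 distance of samples to their centroids.
    """

    def __init__(self, n_clusters: int = 2, max_iter: int = 100, n_init: int = 4,
                 random_state=None):
        self.n_clusters = n_clusters
        self.max_iter = max_iter
        self.n_init = n_init
        self.random_state = random_state

    @staticmethod
    def _l1(X, C):
        return np.abs(X[:, None, :] - C[None]).sum(axis=2)

    def _init_centers(self, X, k, rng):
        n = len(X)
        centers = [X[rng.integers(n)]]
        for _ in range(1, k):
            d = self._l1(X, np.asarray(centers)).min(axis=1)
            if d.sum() <= 0:
                centers.append(X[rng.integers(n)])
            else:
                centers.append(X[rng.choice(n, p=d / d.sum())])
        return np.asarray(centers)

    def _run_once(self, X, k, rng):
        C = self._init_centers(X, k, rng)
        labels = np.zeros(len(X), dtype=int)
        for _ in range(self.max_iter):
            d = self._l1(X, C)
            new_labels = d.argmin(axis=1)
            for j in range(k):
                members = X[new_labels == j]
                if len(members):
                    C[j] = np.median(members, axis=0)
                else:  # re-seed empty cluster at the worst-fit point
                    C[j] = X[d.min(axis=1).argmax()]
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
        inertia = self._l1(X, C)[np.arange(len(X)), labels].sum()
        return C, labels, float(inertia)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(X) == 0:
            raise ValueError("X must be a nonempty 2D array")
        k = min(self.n_clusters, len(X))
        rng = (self.random_state if isinstance(self.random_state, np.random.Generator)
               else np.random.default_rng(self.random_state))
        best = None
        for _ in range(self.n_init):
            result = self._run_once(X, k, rng)
            if best is None or result[2] < best[2]:
                best = result
        self.cluster_centers_, self.labels_, self.inertia_ = best
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        return self._l1(np.asarray(X, float), self.cluster_centers_).argmin(axis=1)


def _pool_ensemble(ensemble: VoxelEnsemble) -> tuple[VoxelDistribution, np.ndarray]:
    """Concatenate all components across bootstrap solutions.

    Returns the pooled distribution and the solution index of each component.
    """
    sols = [s for s in ensemble.solutions if len(s) > 0]
    if not sols:
        raise ValueError("ensemble has no components")
    names = ("d0", "d_par", "d_perp", "gamma_par", "gamma_perp",
             "theta", "phi", "r1", "r2", "w")
    pooled = VoxelDistribution(**{
        n: np.concatenate([getattr(s, n) for s in sols]) for n in names
    })
    src = np.concatenate([np.full(len(s), i) for i, s in enumerate(sols)])
    return pooled, src


def ensemble_features(
    pooled: VoxelDistribution, omega_eval: tuple[float, float]
) -> np.ndarray:
    """Normalized clustering features for pooled ensemble components.

    Columns: Diso(ω₁), Diso(ω₂), DΔ²(ω₁), DΔ²(ω₂), the principal-axis
    direction encoded as (sinθcosφ, sinθsinφ, |cosθ|) to avoid angular
    wrap-around, R1 and R2 — each divided by its maximal absolute value.
    """
    cols = []
    for om in omega_eval:
        d_iso, d_delta = pooled.iso_anisotropy(float(om))
        cols += [d_iso, d_delta**2]
    axes = pooled.principal_axes()
    cols += [axes[:, 0], axes[:, 1], np.abs(axes[:, 2]), pooled.r1, pooled.r2]
    X = np.column_stack(cols)
    scale = np.abs(X).max(axis=0)
    scale[scale == 0] = 1.0
    return X / scale


def _default_k(ensemble: VoxelEnsemble) -> int:
    counts = ensemble.component_counts()
    counts = counts[counts > 0]
    return max(int(round(float(np.median(counts)))), 1)


def cluster_components(
    ensemble: VoxelEnsemble,
    omega_eval: tuple[float, float],
    k: int | None = None,
    rng=None,
) -> np.ndarray:
    """Cluster pooled ensemble components with L1 k-medians.

    ``k`` defaults to the median number of nonzero-weight components across
    bootstrap solutions (the ensemble's own complexity estimate).
    Returns one label per pooled component (pooling order: solutions in
    ensemble order, components within each solution in order).
    """
    pooled, _ = _pool_ensemble(ensemble)
    if k is None:
        k = _default_k(ensemble)
    if k < 1:
        raise ValueError("k must be >= 1")
    X = ensemble_features(pooled, omega_eval)
    est = KMediansL1(n_clusters=k, random_state=rng)
    return est.fit(X).labels_


def consolidate_voxel(
    ensemble: VoxelEnsemble, labels: np.ndarray
) -> VoxelDistribution:
    """Collapse each cluster into a single component by per-parameter medians.

    The weight of each consolidated component is the median of the member
    weights (not renormalized; normalization happens at projection time).
    """
    pooled, _ = _pool_ensemble(ensemble)
    labels = np.asarray(labels)
    if len(labels) != len(pooled):
        raise ValueError("labels must cover all pooled components")
    names = ("d0", "d_par", "d_perp", "gamma_par", "gamma_perp",
             "theta", "phi", "r1", "r2", "w")
    out = {n: [] for n in names}
    for lab in np.unique(labels):
        members = pooled.select(labels == lab)
        for n in names:
            out[n].append(float(np.median(getattr(members, n))))
    cons = {n: np.asarray(v) for n, v in out.items()}
    # medians of different columns can mildly violate d_par/d_perp <= d0
    cons["d_par"] = np.minimum(cons["d_par"], cons["d0"])
    cons["d_perp"] = np.minimum(cons["d_perp"], cons["d0"])
    return VoxelDistribution(**cons)


def consolidate_ensemble(
    ensemble: VoxelEnsemble,
    omega_eval: tuple[float, float],
    k: int | None = None,
    rng=None,
) -> VoxelDistribution:
    """Cluster + consolidate in one call."""
    labels = cluster_components(ensemble, omega_eval, k=k, rng=rng)
    return consolidate_voxel(ensemble, labels)


@dataclass(frozen=True)
class MeshConfig:
    """Axis ranges/scales of the 64x64 projection meshes.

    Diso is log-scaled over the inversion limits; DΔ² is linear on [0, 1];
    R1 and R2 are linear over their limits.
    """

    n_bins: int = 64
    diso_range: tuple[float, float] = (5e-12, 5e-9)
    ddelta2_range: tuple[float, float] = (0.0, 1.0)
    r1_range: tuple[float, float] = (0.1, 4.0)
    r2_range: tuple[float, float] = (4.0, 100.0)

    def axes(self, plane: str) -> tuple[np.ndarray, str, np.ndarray, str]:
        """(x_edges, x_scale, y_edges, y_scale) for a plane id."""
        x_edges = np.geomspace(*self.diso_range, self.n_bins + 1)
        if plane == "diso_ddelta2":
            y_edges = np.linspace(*self.ddelta2_range, self.n_bins + 1)
        elif plane == "diso_r1":
            y_edges = np.linspace(*self.r1_range, self.n_bins + 1)
        elif plane == "diso_r2":
            y_edges = np.linspace(*self.r2_range, self.n_bins + 1)
        else:
            raise ValueError(f"unknown plane {plane!r}; expected one of {PLANES}")
        return x_edges, "log", y_edges, "linear"


@dataclass
class Projection2D:
    """2D weight mesh of a distribution on one parameter plane."""

    plane: str
    weights: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    x_scale: str = "log"
    y_scale: str = "linear"

    def normalized(self) -> "Projection2D":
        total = self.weights.sum()
        w = self.weights / total if total > 0 else self.weights
        return Projection2D(self.plane, w, self.x_edges, self.y_edges,
                            self.x_scale, self.y_scale)

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


def _bin_index(values: np.ndarray, edges: np.ndarray) -> tuple[np.ndarray, int]:
    idx = np.searchsorted(edges, values, side="right") - 1
    n_out = int(np.sum((idx < 0) | (idx > len(edges) - 2)))
    return np.clip(idx, 0, len(edges) - 2), n_out


def project_2d(
    distribution: VoxelDistribution,
    plane: str,
    omega: float,
    mesh: MeshConfig | None = None,
) -> Projection2D:
    """Deposit component weights on a 64x64 mesh in the requested plane.

    Components outside the axis ranges are clipped to the edge cells (and
    counted in a log message).  Total deposited weight equals the total
    component weight; call :meth:`Projection2D.normalized` to normalize.
    """
    if len(distribution) == 0:
        raise ValueError("cannot project an empty distribution")
    mesh = mesh or MeshConfig()
    x_edges, x_scale, y_edges, y_scale = mesh.axes(plane)
    d_iso, d_delta = distribution.iso_anisotropy(float(omega))
    x = d_iso
    if plane == "diso_ddelta2":
        y = d_delta**2
    elif plane == "diso_r1":
        y = distribution.r1
    else:
        y = distribution.r2
    ix, n_out_x = _bin_index(x, x_edges)
    iy, n_out_y = _bin_index(y, y_edges)
    if n_out_x or n_out_y:
        logger.info(
            "project_2d(%s): %d component coordinate(s) clipped to edge cells",
            plane, n_out_x + n_out_y,
        )
    weights = np.zeros((mesh.n_bins, mesh.n_bins))
    np.add.at(weights, (ix, iy), distribution.w)
    return Projection2D(plane, weights, x_edges, y_edges, x_scale, y_scale)


def roi_average_projection(
    projections_by_scan: Sequence[Sequence[Projection2D]],
) -> Projection2D:
    """ROI-averaged projection: per-scan ROI sum -> normalize -> scan mean.

    Parameters
    ----------
    projections_by_scan : sequence of sequences
        Outer index: scan; inner: the per-voxel projections of the ROI in
        that scan.  All projections must share plane and mesh.
    """
    scans = [list(vs) for vs in projections_by_scan]
    if not scans or any(len(vs) == 0 for vs in scans):
        raise ValueError("every scan must contribute at least one voxel projection")
    ref = scans[0][0]
    per_scan = []
    for voxels in scans:
        total = np.zeros_like(ref.weights)
        for p in voxels:
            if p.plane != ref.plane or p.weights.shape != ref.weights.shape:
                raise ValueError("all projections must share plane and mesh")
            total += p.weights
        s = total.sum()
        per_scan.append(total / s if s > 0 else total)
    mean = np.mean(per_scan, axis=0)
    out = Projection2D(ref.plane, mean, ref.x_edges, ref.y_edges,
                       ref.x_scale, ref.y_scale)
    return out.normalized()
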