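"""Activity-pattern clustering on ILR-transformed daily budgets.

Cross-sectional k-means (Lloyd's algorithm, best of ``n_init`` random
initialisations) groups sows on the single farrowing day; the longitudinal
variant clusters whole per-period trajectories by flattening the
``days x coordinates`` matrix of each sow and applying the same algorithm --
the joint Euclidean distance over all days, as used by multivariate
longitudinal k-means implementations.  The number of clusters is chosen by
the elbow rule on the within-cluster inertia profile.

Cluster labels (``A``, ``B``, ...) are assigned by descending cluster size,
with ties broken by the lexicographic order of the cluster centres, so that
labels are stable across runs with the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import InputDataError

__all__ = [
    "ClusterResults",
    "cluster_cross_sectional",
    "cluster_longitudinal",
    "kmeans_sweep",
    "elbow_select_k",
    "TrajectoryKMeans",
    "most_discriminating_trait",
]


@dataclass
class ClusterResults:
    """A fitted k-means partition of sows (or sow trajectories)."""

    k: int
    centers: np.ndarray  # (k, p) in (flattened) coordinate space
    assignments: np.ndarray  # 0-based cluster index per sample
    inertia: float
    n_init: int
    seed: int
    trajectory_shape: tuple[int, int] | None = None  # (days, coords) if longitudinal
    sweep_inertias: dict[int, float] | None = None

    @property
    def labels(self) -> np.ndarray:
        """Letter label per sample: 'A' = largest cluster."""
        order = self.cluster_order()
        letter = {c: chr(ord("A") + rank) for rank, c in enumerate(order)}
        return np.array([letter[c] for c in self.assignments])

    def cluster_order(self) -> list[int]:
        """Clusters sorted by descending size, ties by lexicographic centre."""
        sizes = np.bincount(self.assignments, minlength=self.k)
        return sorted(range(self.k), key=lambda c: (-sizes[c], tuple(self.centers[c])))

    def sizes(self) -> pd.Series:
        lab = self.labels
        return pd.Series(lab).value_counts().sort_index()

    def summary(self) -> str:
        lines = [f"k-means partition: k={self.k}, inertia={self.inertia:.4g}"]
        order = self.cluster_order()
        sizes = np.bincount(self.assignments, minlength=self.k)
        for rank, c in enumerate(order):
            lines.append(
                f"  cluster {chr(ord('A') + rank)}: n={sizes[c]}, "
                f"center={np.array2string(self.centers[c], precision=3)}"
            )
        return "\n".join(lines)


def cluster_cross_sectional(
    X: np.ndarray, k: int, n_init: int = 50, seed: int = 0
) -> ClusterResults:
    """Lloyd k-means on coordinate vectors, best of ``n_init`` random starts."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InputDataError("X must be a 2-D array of coordinate vectors")
    n = X.shape[0]
    if k < 1 or k > n:
        raise InputDataError(f"k must lie in [1, n={n}]")
    km = KMeans(
        n_clusters=k, init="random", n_init=n_init, random_state=seed, algorithm="lloyd"
    ).fit(X)
    return ClusterResults(
        k=k,
        centers=km.cluster_centers_,
        assignments=km.labels_.astype(int),
        inertia=float(km.inertia_),
        n_init=n_init,
        seed=seed,
    )


def _stack_trajectories(trajs: "Sequence[np.ndarray] | np.ndarray") -> np.ndarray:
    arrs = [np.asarray(t, dtype=float) for t in trajs]
    if not arrs:
        raise InputDataError("no trajectories supplied")
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs) or len(shape) != 2:
        raise InputDataError("trajectories must all be (days x coords) with equal shape")
    if any(np.isnan(a).any() for a in arrs):
        raise InputDataError("trajectories must be complete (no missing day)")
    return np.stack(arrs)


def cluster_longitudinal(
    trajs: "Sequence[np.ndarray] | np.ndarray",
    k: int,
    n_init: int = 50,
    seed: int = 0,
) -> ClusterResults:
    """k-means on whole trajectories via the flattened joint distance.

    By construction this is identical to :func:`cluster_cross_sectional`
    applied to the row-flattened ``n x (T * (D-1))`` matrix with the same
    seed protocol.
    """
    arr = _stack_trajectories(trajs)
    n, t, p = arr.shape
    res = cluster_cross_sectional(arr.reshape(n, t * p), k, n_init=n_init, seed=seed)
    res.trajectory_shape = (t, p)
    return res


def kmeans_sweep(
    X: np.ndarray,
    k_values: Sequence[int],
    n_init: int = 50,
    seed: int = 0,
) -> dict[int, ClusterResults]:
    """Fit a range of k with a nested-initialisation safeguard.

    After the standard best-of-``n_init`` fit for each k, if the inertia
    exceeds the previous k's, one extra Lloyd run is started from the
    previous centres plus the point farthest from its centre; Lloyd descent
    from that start is guaranteed not to exceed the previous inertia, so the
    sweep's inertia profile is non-increasing in k.
    """
    X = np.asarray(X, dtype=float)
    out: dict[int, ClusterResults] = {}
    prev: ClusterResults | None = None
    for k in sorted(k_values):
        res = cluster_cross_sectional(X, k, n_init=n_init, seed=seed)
        if prev is not None and res.inertia > prev.inertia:
            d = np.linalg.norm(X - prev.centers[prev.assignments], axis=1)
            init = np.vstack([prev.centers, X[np.argmax(d)]])[:k]
            km = KMeans(n_clusters=k, init=init, n_init=1, algorithm="lloyd").fit(X)
            if km.inertia_ < res.inertia:
                res = ClusterResults(
                    k=k,
                    centers=km.cluster_centers_,
                    assignments=km.labels_.astype(int),
                    inertia=float(km.inertia_),
                    n_init=n_init,
                    seed=seed,
                )
        out[k] = res
        prev = res
    return out


def elbow_select_k(inertias: Mapping[int, float]) -> int:
    """Elbow rule: interior k with the largest second difference of inertia.

    Requires inertias for at least three consecutive values of k.  Ties are
    broken toward the smaller k (so a linear decay yields the smallest
    interior k).
    """
    ks = sorted(inertias)
    if len(ks) < 3:
        raise InputDataError("elbow selection needs inertias for at least 3 values of k")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise InputDataError("elbow selection needs consecutive values of k")
    best_k, best_d2 = None, -np.inf
    for k in ks[1:-1]:
        d2 = (inertias[k - 1] - inertias[k]) - (inertias[k] - inertias[k + 1])
        if d2 > best_d2:  # strict: ties keep the smaller k
            best_k, best_d2 = k, d2
    return int(best_k)


class TrajectoryKMeans:
    """Model-style front end: fit a k sweep and pick k by the elbow rule.

    Parameters
    ----------
    data:
        Either a 2-D ``n x p`` coordinate matrix (cross-sectional) or a 3-D
        ``n x T x p`` trajectory array / list of equal-shape matrices.
    k_range:
        Inclusive (min, max) range of cluster counts for the sweep.
    """

    def __init__(
        self,
        data: "np.ndarray | Sequence[np.ndarray]",
        k_range: tuple[int, int] = (1, 6),
        n_init: int = 50,
        seed: int = 0,
    ) -> None:
        arr = np.asarray(data, dtype=float) if not isinstance(data, np.ndarray) else data
        if arr.ndim == 3:
            self._traj_shape = arr.shape[1:]
            self._X = arr.reshape(arr.shape[0], -1)
        elif arr.ndim == 2:
            self._traj_shape = None
            self._X = arr
        else:
            raise InputDataError("data must be 2-D coordinates or 3-D trajectories")
        self.k_range = k_range
        self.n_init = n_init
        self.seed = seed

    def fit(self, k: int | None = None) -> ClusterResults:
        """Fit with a fixed ``k``, or sweep ``k_range`` and use the elbow rule."""
        if k is not None:
            res = cluster_cross_sectional(self._X, k, self.n_init, self.seed)
        else:
            lo, hi = self.k_range
            hi = min(hi, self._X.shape[0])
            sweep = kmeans_sweep(self._X, range(lo, hi + 1), self.n_init, self.seed)
            inertias = {kk: r.inertia for kk, r in sweep.items()}
            if len(inertias) >= 3:
                k_star = elbow_select_k(inertias)
            else:
                k_star = min(inertias)  # degenerate sweep: smallest k
            res = sweep[k_star]
            res.sweep_inertias = inertias
        if self._traj_shape is not None:
            res.trajectory_shape = tuple(self._traj_shape)
        return res


def most_discriminating_trait(
    traits: pd.DataFrame, labels: np.ndarray, candidates: Sequence[str]
) -> str:
    """Raw trait with the largest standardised mean difference between the
    two largest clusters.

    Used to decide which raw behavioural trait "mainly explains" a cluster
    contrast when substituting a cluster factor by a continuous trait.
    """
    lab = pd.Series(np.asarray(labels), index=traits.index)
    top = lab.value_counts().index[:2]
    if len(top) < 2:
        raise InputDataError("need at least two clusters to contrast")
    a, b = (traits.loc[lab == g, list(candidates)] for g in top)
    pooled = np.sqrt((a.var(ddof=1).fillna(0.0) + b.var(ddof=1).fillna(0.0)) / 2.0)
    smd = (a.mean() - b.mean()).abs() / pooled.replace(0.0, np.nan)
    if smd.isna().all():
        raise InputDataError("no candidate trait varies between the clusters")
    return str(smd.idxmax())
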