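"""From-scratch k-means on pooled one-dimensional modulus data.

The movement-intensity moduli of all recording instances are pooled into a
single 1-D dataset (each value keeping its instance of origin) and
partitioned with Lloyd's algorithm. On scalars the Euclidean metric reduces
to the absolute difference; assignments therefore minimise squared
difference to the nearest centroid, which matches the within-cluster
sum-of-squares (SSE) objective exactly.

Implementation notes
--------------------
* Initialisation: k-means++ (D^2 sampling) by default, or uniform sampling
  of distinct values; multiple restarts, best result by lowest SSE.
* Nearest-centroid ties break to the lowest cluster index.
* An empty cluster during Lloyd iteration is re-seeded with the pooled
  point farthest from its currently assigned centroid, keeping k fixed.
* Cluster labels in a result are sorted by ascending centroid, so label 0
  is always the lowest-intensity cluster. Relabelling does not change the
  partition or its SSE.
* ``optimal_1d_kmeans_dp`` computes the globally SSE-optimal clustering by
  dynamic programming over breakpoints in sorted order (optimal 1-D
  clusters are contiguous once the data are sorted). It is the exact
  oracle used to test the iterative solver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import RecordingInstance

_SSE_SLACK = 1e-9  # relative slack for floating-point SSE comparisons


@dataclass(frozen=True)
class PooledModuli:
    """All instances' moduli concatenated, with per-sample provenance."""

    values: np.ndarray
    instance_ids: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        ids = np.asarray(self.instance_ids, dtype=object)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "instance_ids", ids)
        if values.ndim != 1 or values.size != ids.size:
            raise ValueError("values and instance_ids must be 1-D and aligned")

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    def indices_for(self, instance_id: str) -> np.ndarray:
        return np.flatnonzero(self.instance_ids == instance_id)

    def split(self) -> dict[str, np.ndarray]:
        """Recover the per-instance series (inverse of pooling)."""
        out: dict[str, np.ndarray] = {}
        for iid in dict.fromkeys(self.instance_ids):  # preserves order
            out[iid] = self.values[self.indices_for(iid)]
        return out


def pool_instances(instances: Sequence[RecordingInstance]) -> PooledModuli:
    """Concatenate all instances' moduli into one dataset with provenance."""
    if len(instances) == 0:
        raise ValueError("need at least one recording instance to pool")
    values = np.concatenate([inst.moduli for inst in instances])
    ids = np.concatenate(
        [np.full(inst.n_samples, inst.instance_id, dtype=object) for inst in instances]
    )
    return PooledModuli(values=values, instance_ids=ids)


@dataclass(frozen=True)
class ClusteringResult:
    """A k-way partition of pooled 1-D data.

    ``centroids`` are sorted ascending; ``assignments[i]`` is the cluster
    index of ``values[i]`` in the dataset the fit was run on.
    """

    k: int
    centroids: np.ndarray
    assignments: np.ndarray = field(repr=False)
    sse: float
    n_iter: int
    converged: bool
    instance_ids: np.ndarray | None = field(default=None, repr=False)

    def validate(self, values: np.ndarray) -> None:
        """Check internal consistency against the data that produced it."""
        values = np.asarray(values, dtype=float)
        if self.assignments.shape != values.shape:
            raise AssertionError("assignments not aligned with values")
        if self.assignments.min() < 0 or self.assignments.max() >= self.k:
            raise AssertionError("cluster index out of range")
        sse = 0.0
        for u in range(self.k):
            members = values[self.assignments == u]
            if members.size:
                if abs(members.mean() - self.centroids[u]) > 1e-9 * (1 + abs(self.centroids[u])):
                    raise AssertionError(f"centroid {u} is not the mean of its members")
                sse += float(((members - self.centroids[u]) ** 2).sum())
        if abs(sse - self.sse) > _SSE_SLACK * (1 + sse):
            raise AssertionError("stored SSE does not match recomputation")


def _check_inputs(values: np.ndarray, k: int) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot cluster an empty dataset")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    if k < 1:
        raise ValueError("k must be >= 1")
    if np.unique(x).size < k:
        raise ValueError(f"k={k} exceeds the number of distinct values")
    return x


def _sse_of(x: np.ndarray, centroids: np.ndarray, assign: np.ndarray) -> float:
    return float(((x - centroids[assign]) ** 2).sum())


def _kpp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    # greedy k-means++: sample a few D^2-weighted candidates per step and
    # keep the one that most reduces the potential
    n_trials = 2 + int(np.log(k)) if k > 1 else 1
    centroids = [float(x[rng.integers(x.size)])]
    d2 = (x - centroids[0]) ** 2
    for _ in range(1, k):
        total = d2.sum()
        if total <= 0:
            # all remaining mass sits on existing centroids; pick a new value
            fresh = np.setdiff1d(np.unique(x), np.asarray(centroids))
            chosen = float(fresh[rng.integers(fresh.size)])
            centroids.append(chosen)
            d2 = np.minimum(d2, (x - chosen) ** 2)
            continue
        candidates = rng.choice(x, size=n_trials, p=d2 / total)
        pots = [np.minimum(d2, (x - c) ** 2).sum() for c in candidates]
        chosen = float(candidates[int(np.argmin(pots))])
        centroids.append(chosen)
        d2 = np.minimum(d2, (x - chosen) ** 2)
    return np.asarray(centroids, dtype=float)


def _random_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    distinct = np.unique(x)
    return np.sort(rng.choice(distinct, size=k, replace=False)).astype(float)


def _lloyd(
    x: np.ndarray, centroids: np.ndarray, k: int, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    assign_prev: np.ndarray | None = None
    sse_prev = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # assignment step; argmin breaks ties to the lowest cluster index
        assign = np.abs(x[:, None] - centroids[None, :]).argmin(axis=1)
        sse = _sse_of(x, centroids, assign)
        if sse > sse_prev * (1 + _SSE_SLACK) + _SSE_SLACK:
            raise RuntimeError("Lloyd SSE increased between iterations")
        sse_prev = sse

        counts = np.bincount(assign, minlength=k)
        if (counts == 0).any():
            # re-seed each empty cluster with the point farthest from its
            # current centroid, then re-assign
            dist = np.abs(x - centroids[assign])
            for u in np.flatnonzero(counts == 0):
                far = int(dist.argmax())
                centroids = centroids.copy()
                centroids[u] = x[far]
                dist[far] = -np.inf
            assign_prev = None
            continue

        if assign_prev is not None and np.array_equal(assign, assign_prev):
            converged = True
            break
        new_centroids = np.array([x[assign == u].mean() for u in range(k)])
        shift = float(np.abs(new_centroids - centroids).max())
        centroids = new_centroids
        assign_prev = assign
        if shift < tol:
            converged = True
            # final assignment pass, then make centroids exact member means
            assign = np.abs(x[:, None] - centroids[None, :]).argmin(axis=1)
            centroids = np.array(
                [x[assign == u].mean() if (assign == u).any() else centroids[u] for u in range(k)]
            )
            break

    sse = _sse_of(x, centroids, assign)
    return centroids, assign, sse, n_iter, converged


def _sorted_labels(
    centroids: np.ndarray, assign: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Relabel clusters so centroid order is ascending."""
    order = np.argsort(centroids, kind="stable")
    relabel = np.empty_like(order)
    relabel[order] = np.arange(order.size)
    return centroids[order], relabel[assign]


def kmeans_fit(
    values: np.ndarray | Sequence[float],
    k: int,
    *,
    init: str = "kpp",
    n_restarts: int = 10,
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 300,
    instance_ids: np.ndarray | None = None,
) -> ClusteringResult:
    """Lloyd's k-means on 1-D data, best of ``n_restarts`` by SSE.

    Parameters
    ----------
    values : array-like of float
        The pooled moduli.
    k : int
        Number of clusters; must not exceed the number of distinct values.
    init : {"kpp", "random"}
        Centroid initialisation: k-means++ D^2 sampling or uniform sampling
        of distinct values.
    n_restarts : int
        Independent initialisations; the run with the lowest SSE wins
        (earlier restart wins exact ties, so results are seed-deterministic).
    seed : int, optional
        Seeds every restart via ``numpy.random.SeedSequence`` spawning.
    tol : float
        Convergence threshold on the maximum centroid shift.
    max_iter : int
        Iteration cap per restart; non-convergence yields ``converged=False``
        and a warning.
    """
    x = _check_inputs(values, k)
    if init not in ("kpp", "random"):
        raise ValueError(f"unknown init {init!r}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    init_fn = _kpp_init if init == "kpp" else _random_init
    children = np.random.SeedSequence(seed).spawn(n_restarts)
    best: tuple[float, int] | None = None
    best_run: tuple[np.ndarray, np.ndarray, float, int, bool] | None = None
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        centroids0 = init_fn(x, k, rng)
        run = _lloyd(x, centroids0, k, tol, max_iter)
        if best is None or run[2] < best[0]:
            best = (run[2], r)
            best_run = run
    assert best_run is not None
    centroids, assign, sse, n_iter, converged = best_run
    if not converged:
        warnings.warn(
            f"k-means did not converge within {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    centroids, assign = _sorted_labels(centroids, assign)
    result = ClusteringResult(
        k=k,
        centroids=centroids,
        assignments=assign,
        sse=float(sse),
        n_iter=n_iter,
        converged=converged,
        instance_ids=None if instance_ids is None else np.asarray(instance_ids, dtype=object),
    )
    result.validate(x)
    return result


def assign_to_centroids(values: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Nearest-centroid assignment (ties to the lowest index)."""
    x = np.asarray(values, dtype=float).ravel()
    return np.abs(x[:, None] - np.asarray(centroids, dtype=float)[None, :]).argmin(axis=1)


def optimal_1d_kmeans_dp(
    values: np.ndarray | Sequence[float],
    k: int,
    *,
    instance_ids: np.ndarray | None = None,
) -> ClusteringResult:
    """Globally SSE-optimal 1-D k-means by dynamic programming.

    Optimal 1-D clusters are contiguous in sorted order, so the optimum is
    found by DP over segment breakpoints with prefix-sum segment costs in
    O(k n^2). Serves as the exact oracle for :func:`kmeans_fit`.
    """
    x = _check_inputs(values, k)
    n = x.size
    order = np.argsort(x, kind="stable")
    xs = x[order]
    s1 = np.concatenate([[0.0], np.cumsum(xs)])
    s2 = np.concatenate([[0.0], np.cumsum(xs**2)])

    def seg_cost(i: np.ndarray, j: int) -> np.ndarray:
        # SSE of sorted segment xs[i:j] for a vector of start indices i
        cnt = j - i
        total = s1[j] - s1[i]
        return (s2[j] - s2[i]) - total**2 / cnt

    dp = np.full((k + 1, n + 1), np.inf)
    dp[0, 0] = 0.0
    split = np.zeros((k + 1, n + 1), dtype=int)
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            i = np.arange(m - 1, j)
            cand = dp[m - 1, i] + seg_cost(i, j)
            best = int(cand.argmin())
            dp[m, j] = cand[best]
            split[m, j] = m - 1 + best

    # recover breakpoints and label sorted values by segment
    labels_sorted = np.empty(n, dtype=int)
    j = n
    for m in range(k, 0, -1):
        i = split[m, j]
        labels_sorted[i:j] = m - 1
        j = i
    assign = np.empty(n, dtype=int)
    assign[order] = labels_sorted
    centroids = np.array([x[assign == u].mean() for u in range(k)])
    result = ClusteringResult(
        k=k,
        centroids=centroids,
        assignments=assign,
        sse=float(dp[k, n]),
        n_iter=0,
        converged=True,
        instance_ids=None if instance_ids is None else np.asarray(instance_ids, dtype=object),
    )
    result.validate(x)
    return result
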