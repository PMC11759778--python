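"""Percentile-peak reduction, dominant-cluster assignment and label mapping.

Tremor episodes are not evenly distributed in time, so each recording
instance is summarised by its intensity peaks: the samples whose modulus
exceeds the instance's own 95th percentile (``top_fraction`` p = 0.95,
computed per instance on its modulus distribution). The instance-level
prediction is the *dominant cluster* — the modal k-means label among those
top samples.

Because k-means labels are arbitrary, dominant clusters are aligned with
clinical scores by exhaustive permutation mapping: every one-to-one
assignment of cluster labels to score values is scored and the
accuracy-maximising bijection is kept. For the cluster counts used here
(k <= 4) the k! search is exact and instant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np


@dataclass(frozen=True)
class DominantClusterAssignment:
    """Instance-level prediction derived from the top-percentile samples."""

    instance_id: str
    dominant_cluster: int
    n_top: int
    top_fraction: float

    def __post_init__(self) -> None:
        if self.n_top < 1:
            raise ValueError("n_top must be >= 1")


@dataclass(frozen=True)
class LabelMapping:
    """An accuracy-maximising bijection from cluster labels to scores."""

    mapping: Mapping[int, int]
    accuracy: float

    def apply(self, clusters: Sequence[int] | np.ndarray) -> np.ndarray:
        """Map an array of cluster labels to scores."""
        return np.asarray([self.mapping[int(c)] for c in np.asarray(clusters).ravel()])


def top_percentile_indices(moduli: np.ndarray | Sequence[float], p: float = 0.95) -> np.ndarray:
    """Indices of samples strictly above the instance's p-quantile.

    The quantile uses linear interpolation between order statistics and
    selection is strict (``modulus > quantile``), matching the "top 5%"
    reading of the cut. A constant series has nothing strictly above its
    quantile; the fallback then returns the maximal values so the set is
    never empty.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must lie in (0, 1), got {p}")
    m = np.asarray(moduli, dtype=float).ravel()
    if m.size == 0:
        raise ValueError("moduli must be non-empty")
    cut = np.quantile(m, p, method="linear")
    idx = np.flatnonzero(m > cut)
    if idx.size == 0:
        idx = np.flatnonzero(m == m.max())
    return idx


def dominant_cluster(
    assignments: np.ndarray | Sequence[int],
    top_indices: np.ndarray | Sequence[int],
    *,
    instance_id: str = "",
    top_fraction: float = 0.95,
) -> DominantClusterAssignment:
    """Modal cluster label among the top-percentile samples.

    Ties break to the lowest cluster index (deterministic).
    """
    assignments = np.asarray(assignments, dtype=int).ravel()
    top_indices = np.asarray(top_indices, dtype=int).ravel()
    if top_indices.size == 0:
        raise ValueError("top_indices must be non-empty")
    if top_indices.min() < 0 or top_indices.max() >= assignments.size:
        raise ValueError("top_indices out of range")
    labels, counts = np.unique(assignments[top_indices], return_counts=True)
    modal = int(labels[counts == counts.max()].min())
    return DominantClusterAssignment(
        instance_id=instance_id,
        dominant_cluster=modal,
        n_top=int(top_indices.size),
        top_fraction=top_fraction,
    )


def map_labels_by_permutation(
    predicted: Sequence[int] | np.ndarray,
    truth: Sequence[int] | np.ndarray,
    score_labels: Sequence[int] | None = None,
) -> LabelMapping:
    """Exhaustive accuracy-maximising mapping of cluster labels to scores.

    Every injective assignment of the distinct cluster labels onto the
    score label set is evaluated; the one with the highest accuracy wins,
    ties breaking to the lexicographically smallest assignment (ordered by
    ascending cluster label). The number of distinct clusters must not
    exceed the number of score labels.
    """
    predicted = np.asarray(predicted, dtype=int).ravel()
    truth = np.asarray(truth, dtype=int).ravel()
    if predicted.size != truth.size:
        raise ValueError(
            f"predicted ({predicted.size}) and truth ({truth.size}) differ in length"
        )
    if predicted.size == 0:
        raise ValueError("cannot map empty label sequences")
    clusters = sorted(set(int(c) for c in predicted))
    scores = sorted(set(int(t) for t in truth)) if score_labels is None else sorted(
        set(int(s) for s in score_labels)
    )
    if len(clusters) > len(scores):
        raise ValueError(
            f"{len(clusters)} distinct clusters cannot map injectively onto "
            f"{len(scores)} score labels"
        )
    n = truth.size
    best_key: tuple[float, tuple[int, ...]] | None = None
    best_perm: tuple[int, ...] | None = None
    for perm in itertools.permutations(scores, len(clusters)):
        lut = dict(zip(clusters, perm))
        acc = float(np.mean([lut[int(c)] == int(t) for c, t in zip(predicted, truth)]))
        key = (-acc, perm)
        if best_key is None or key < best_key:
            best_key = key
            best_perm = perm
    assert best_perm is not None and best_key is not None
    return LabelMapping(mapping=dict(zip(clusters, best_perm)), accuracy=-best_key[0])
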