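"""Model/Results interface orchestrating the three classification tasks.

``TremorSeverityModel`` is built from a list of recording instances (or a
cohort directory, or a synthetic configuration) and a task specification;
``fit()`` runs pooling -> k-means -> per-instance dominant-cluster
assignment -> permutation label mapping -> evaluation and returns a
``TremorSeverityResults`` object carrying every intermediate artifact, the
metrics and a ``summary()`` table.

Tasks
-----
1. Tremor vs non-tremor: PD and HC instances pooled, k = 2, truth
   binarised to tremor (score >= 1) vs non-tremor (score 0).
2. Multiclass severity among PD patients: k = number of distinct observed
   scores, truth used as-is.
3. Binarised severity among PD patients: an independent k = 2 clustering
   with scores 1-2 collapsed to "milder" (1) and score 3 kept as
   "moderate" (2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import (
    ClusteringResult,
    PooledModuli,
    assign_to_centroids,
    kmeans_fit,
    pool_instances,
)
from .evaluation import (
    BinaryMetrics,
    EvaluationReport,
    binary_metrics,
    confusion_matrix,
    multiclass_metrics,
)
from .exceptions import ConfigurationError, EmptyInstanceError
from .io import (
    RecordingInstance,
    read_annotations,
    read_ground_truth,
    read_recording,
)
from .preprocessing import make_instance
from .severity import (
    DominantClusterAssignment,
    LabelMapping,
    dominant_cluster,
    map_labels_by_permutation,
    top_percentile_indices,
)
from .synthetic import REST_LABEL, SimulationConfig, simulate_cohort

TRANSFORMS = ("tremor_binary", "identity", "severity_binary")


@dataclass(frozen=True)
class TaskSpec:
    """Which instances a task uses, its k, and its label transform."""

    task: int
    groups: tuple[str, ...]
    k: int | None
    label_transform: str
    positive: int | None

    def __post_init__(self) -> None:
        if self.label_transform not in TRANSFORMS:
            raise ConfigurationError(f"unknown label transform {self.label_transform!r}")


_TASK_SPECS = {
    1: TaskSpec(task=1, groups=("PD", "HC"), k=2, label_transform="tremor_binary", positive=1),
    2: TaskSpec(task=2, groups=("PD",), k=None, label_transform="identity", positive=None),
    3: TaskSpec(task=3, groups=("PD",), k=2, label_transform="severity_binary", positive=2),
}


def task_spec(task: int) -> TaskSpec:
    """Canonical specification for tasks 1, 2 and 3."""
    try:
        return _TASK_SPECS[task]
    except KeyError:
        raise ConfigurationError(f"task must be 1, 2 or 3, got {task}") from None


def transform_score(score: int, how: str) -> int:
    """Apply a task's label transform to a clinical score."""
    if how == "identity":
        return int(score)
    if how == "tremor_binary":
        return int(int(score) >= 1)
    if how == "severity_binary":
        if int(score) < 1:
            raise ConfigurationError(
                "severity binarisation is defined for PD scores 1-3 only"
            )
        return 2 if int(score) >= 3 else 1
    raise ConfigurationError(f"unknown label transform {how!r}")


def instances_from_config(
    config: SimulationConfig, rest_labels: Sequence[str] = (REST_LABEL,)
) -> list[RecordingInstance]:
    """Simulate a cohort and preprocess it into recording instances."""
    recordings, truths = simulate_cohort(config)
    return [
        make_instance(rec, ann, rest_labels, truth.group, truth.true_score)
        for (rec, ann), truth in zip(recordings, truths)
    ]


def instances_from_cohort_dir(
    path: Path | str, rest_labels: Sequence[str] = (REST_LABEL,)
) -> list[RecordingInstance]:
    """Load ``{id}_acc.csv`` / ``{id}_annotations.csv`` per ground-truth row.

    Instances without any usable rest annotation are excluded (a warning
    would hide a data problem, so the exclusion is strict and explicit in
    the returned set).
    """
    path = Path(path)
    truth = read_ground_truth(path / "ground_truth.csv")
    instances = []
    for row in truth.itertuples(index=False):
        recording = read_recording(
            path / f"{row.instance_id}_acc.csv", instance_id=str(row.instance_id)
        )
        annotations = read_annotations(path / f"{row.instance_id}_annotations.csv")
        try:
            instances.append(
                make_instance(
                    recording, annotations, rest_labels, row.group, int(row.updrs_3_17)
                )
            )
        except EmptyInstanceError:
            continue
    return instances


class TremorSeverityModel:
    """Unsupervised tremor-severity model over a cohort of instances.

    Parameters
    ----------
    instances : sequence of RecordingInstance
        The preprocessed cohort; instances outside the task's groups are
        ignored by ``fit``.
    task : int or TaskSpec
        One of the three classification tasks (see module docstring).
    top_fraction : float
        Percentile cut p for the dominant-cluster reduction (default 0.95).
    exclude_hc_from_fit : bool
        If True (task 1 only), centroids are fitted on PD moduli alone and
        HC samples are assigned to the nearest fitted centroid afterwards.
        The default pools every instance into one clustering run.
    """

    def __init__(
        self,
        instances: Sequence[RecordingInstance],
        task: int | TaskSpec = 1,
        *,
        top_fraction: float = 0.95,
        exclude_hc_from_fit: bool = False,
    ) -> None:
        self.spec = task if isinstance(task, TaskSpec) else task_spec(task)
        self.instances = [i for i in instances if i.group in self.spec.groups]
        if not self.instances:
            raise ConfigurationError(
                f"no instances in groups {self.spec.groups} for task {self.spec.task}"
            )
        self.top_fraction = float(top_fraction)
        self.exclude_hc_from_fit = bool(exclude_hc_from_fit)
        self.truth = np.array(
            [transform_score(i.true_score, self.spec.label_transform) for i in self.instances]
        )

    @classmethod
    def from_cohort_dir(
        cls,
        path: Path | str,
        task: int | TaskSpec = 1,
        rest_labels: Sequence[str] = (REST_LABEL,),
        **kwargs,
    ) -> "TremorSeverityModel":
        return cls(instances_from_cohort_dir(path, rest_labels), task, **kwargs)

    @classmethod
    def from_synthetic(
        cls, config: SimulationConfig, task: int | TaskSpec = 1, **kwargs
    ) -> "TremorSeverityModel":
        return cls(instances_from_config(config), task, **kwargs)

    def resolve_k(self, k: int | None = None) -> int:
        """Task k: explicit > task default > number of distinct scores."""
        resolved = k or self.spec.k or int(np.unique(self.truth).size)
        if resolved > len(self.instances):
            raise ConfigurationError(
                f"k={resolved} exceeds the {len(self.instances)} available instances"
            )
        return resolved

    def fit(
        self,
        *,
        k: int | None = None,
        seed: int | None = 0,
        n_restarts: int = 10,
        init: str = "kpp",
        tol: float = 1e-8,
        max_iter: int = 300,
    ) -> "TremorSeverityResults":
        """Run the full pipeline and return a results object."""
        k = self.resolve_k(k)
        pooled = pool_instances(self.instances)

        if self.exclude_hc_from_fit and "HC" in self.spec.groups:
            fit_values = np.concatenate(
                [i.moduli for i in self.instances if i.group == "PD"]
            )
        else:
            fit_values = pooled.values
        clustering = kmeans_fit(
            fit_values,
            k,
            init=init,
            n_restarts=n_restarts,
            seed=seed,
            tol=tol,
            max_iter=max_iter,
        )
        # assignment of every pooled sample (identical to the fit assignment
        # when the fit used the full pool)
        assignments = assign_to_centroids(pooled.values, clustering.centroids)

        dominants: list[DominantClusterAssignment] = []
        for inst in self.instances:
            idx = pooled.indices_for(inst.instance_id)
            top = top_percentile_indices(inst.moduli, self.top_fraction)
            dominants.append(
                dominant_cluster(
                    assignments[idx],
                    top,
                    instance_id=inst.instance_id,
                    top_fraction=self.top_fraction,
                )
            )
        predicted_clusters = np.array([d.dominant_cluster for d in dominants])
        classes = sorted(int(c) for c in np.unique(self.truth))
        mapping = map_labels_by_permutation(predicted_clusters, self.truth, classes)
        predicted = mapping.apply(predicted_clusters)
        cm = confusion_matrix(self.truth, predicted, classes)
        report = multiclass_metrics(cm, classes, task=self.spec.task)
        binary = (
            binary_metrics(cm, classes, self.spec.positive)
            if self.spec.positive is not None and len(classes) == 2
            else None
        )
        return TremorSeverityResults(
            model=self,
            k=k,
            seed=seed,
            pooled=pooled,
            assignments=assignments,
            clustering=clustering,
            dominants=dominants,
            mapping=mapping,
            predicted=predicted,
            report=report,
            binary=binary,
        )


@dataclass(frozen=True)
class TremorSeverityResults:
    """Everything a fitted task produced."""

    model: TremorSeverityModel
    k: int
    seed: int | None
    pooled: PooledModuli = field(repr=False)
    assignments: np.ndarray = field(repr=False)
    clustering: ClusteringResult
    dominants: list[DominantClusterAssignment] = field(repr=False)
    mapping: LabelMapping
    predicted: np.ndarray = field(repr=False)
    report: EvaluationReport
    binary: BinaryMetrics | None

    @property
    def accuracy(self) -> float:
        return self.report.accuracy

    def per_instance_frame(self) -> pd.DataFrame:
        """Instance-level table: truth, dominant cluster, mapped score."""
        return pd.DataFrame(
            {
                "instance_id": [i.instance_id for i in self.model.instances],
                "group": [i.group for i in self.model.instances],
                "true_score": [i.true_score for i in self.model.instances],
                "task_label": self.model.truth,
                "dominant_cluster": [d.dominant_cluster for d in self.dominants],
                "mapped_score": self.predicted,
                "n_top": [d.n_top for d in self.dominants],
            }
        )

    def clusters_frame(self) -> pd.DataFrame:
        """Long-format per-sample table (instance_id, j, modulus_g, cluster)."""
        ids = self.pooled.instance_ids
        j = np.concatenate(
            [np.arange(n) for n in pd.Series(ids).groupby(ids, sort=False).size()]
        )
        return pd.DataFrame(
            {
                "instance_id": ids,
                "j": j,
                "modulus_g": self.pooled.values,
                "cluster": self.assignments,
            }
        )

    def to_dict(self) -> dict:
        out = {
            "task": self.model.spec.task,
            "k": self.k,
            "seed": self.seed,
            "n_instances": len(self.model.instances),
            "sse": self.clustering.sse,
            "n_iter": self.clustering.n_iter,
            "converged": self.clustering.converged,
            "centroids": self.clustering.centroids.tolist(),
            "mapping": {str(c): int(s) for c, s in self.mapping.mapping.items()},
            "report": self.report.to_dict(),
        }
        if self.binary is not None:
            out["binary"] = {
                "positive": self.model.spec.positive,
                "accuracy": self.binary.accuracy,
                "precision": self.binary.precision,
                "recall": self.binary.recall,
                "f1": self.binary.f1,
                "tp": self.binary.tp,
                "fp": self.binary.fp,
                "tn": self.binary.tn,
                "fn": self.binary.fn,
            }
        return out

    def summary(self) -> str:
        lines = [
            f"Task {self.model.spec.task}: k={self.k}, "
            f"{len(self.model.instances)} instances, "
            f"{self.pooled.n_samples} pooled samples",
            f"centroids (g): {np.array2string(self.clustering.centroids, precision=4)}",
            f"SSE: {self.clustering.sse:.6g}  "
            f"(iterations: {self.clustering.n_iter}, converged: {self.clustering.converged})",
            f"cluster -> score mapping: {dict(self.mapping.mapping)}",
            self.report.summary(),
        ]
        if self.binary is not None:
            lines.append(
                f"binary (positive={self.model.spec.positive}): "
                f"accuracy {self.binary.accuracy:.2f}, precision {self.binary.precision:.2f}, "
                f"recall {self.binary.recall:.2f}, F1 {self.binary.f1:.2f}"
            )
        return "\n".join(lines)

    def save(self, out_dir: Path | str) -> None:
        """Write clusters, per-instance assignments and the report JSON."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.clusters_frame().to_csv(out_dir / "clusters.csv", index=False)
        self.per_instance_frame().to_csv(out_dir / "dominant.csv", index=False)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_task(
    instances: Sequence[RecordingInstance],
    task: int,
    *,
    seed: int | None = 0,
    k: int | None = None,
    top_fraction: float = 0.95,
    exclude_hc_from_fit: bool = False,
    **fit_kwargs,
) -> TremorSeverityResults:
    """Convenience wrapper: build the model for ``task`` and fit it."""
    model = TremorSeverityModel(
        instances,
        task,
        top_fraction=top_fraction,
        exclude_hc_from_fit=exclude_hc_from_fit,
    )
    return model.fit(k=k, seed=seed, **fit_kwargs)
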