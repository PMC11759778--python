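"""Rest-segment extraction, mean-centering and modulus reduction.

The three steps turn a raw triaxial recording plus its clinic-task
annotations into a recording instance, the unit of downstream analysis:

1. ``extract_rest_segments`` keeps the samples whose timestamps fall in an
   annotated rest interval and concatenates them in temporal order.
2. ``mean_center`` subtracts the per-axis arithmetic mean of the instance,
   removing the constant gravity/orientation offset and any constant
   individual bias. Centering is computed once over the concatenated rest
   samples of the instance, not per segment.
3. ``modulus`` reduces each centered sample to its Euclidean norm
   sqrt(x*^2 + y*^2 + z*^2), an orientation-invariant scalar measure of
   movement intensity.

Individual samples — not time windows — are the unit throughout; the
clustering stage operates on the pooled scalar moduli directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import EmptyInstanceError
from .io import AnnotationInterval, RecordingInstance, TriaxialRecording, validate_annotations


@dataclass(frozen=True)
class CenteredSegment:
    """Mean-centered triaxial samples of one recording instance.

    Each axis of ``data`` has zero arithmetic mean (to numerical precision).
    """

    instance_id: str | None
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2 or data.shape[1] != 3 or data.shape[0] < 1:
            raise ValueError("centered data must be a non-empty (n, 3) array")

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[0])


def extract_rest_segments(
    recording: TriaxialRecording,
    annotations: Sequence[AnnotationInterval],
    rest_labels: Sequence[str] | set[str],
) -> np.ndarray:
    """Concatenate the samples falling inside annotated rest intervals.

    Interval membership is half-open, ``start <= t < end``; annotations are
    required to be non-overlapping, so no sample is selected twice.

    Returns
    -------
    ndarray, shape (m, 3)
        Rest-period acceleration samples in temporal order.

    Raises
    ------
    EmptyInstanceError
        If no rest annotation overlaps the recording. Such instances carry
        no usable resting-state signal and must be excluded, mirroring the
        exclusion of subjects whose annotation files lack rest timestamps.
    """
    validate_annotations(annotations)
    rest_labels = set(rest_labels)
    mask = np.zeros(recording.n_samples, dtype=bool)
    for interval in annotations:
        if interval.label in rest_labels:
            mask |= interval.contains(recording.t)
    if not mask.any():
        raise EmptyInstanceError(
            f"{recording.instance_id}: no samples fall inside a rest interval "
            f"(rest labels: {sorted(rest_labels)})"
        )
    return recording.acc[mask]


def mean_center(
    samples: np.ndarray, instance_id: str | None = None
) -> CenteredSegment:
    """Subtract the per-axis mean of a recording instance's samples.

    Geometrically this moves the origin to the average point, cancelling the
    constant gravity component and sensor-orientation bias while leaving
    dynamic movement untouched.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 1:
        raise ValueError("samples must be a non-empty (n, 3) array")
    return CenteredSegment(instance_id=instance_id, data=arr - arr.mean(axis=0))


def modulus(segment: CenteredSegment | np.ndarray) -> np.ndarray:
    """Euclidean norm of each centered triaxial sample.

    The result is non-negative, has the same length as the input and is
    invariant to any rotation of the sensor frame, so the downstream
    clustering sees movement intensity regardless of direction.
    """
    data = segment.data if isinstance(segment, CenteredSegment) else np.asarray(segment, dtype=float)
    return np.linalg.norm(data, axis=1)


def make_instance(
    recording: TriaxialRecording,
    annotations: Sequence[AnnotationInterval],
    rest_labels: Sequence[str] | set[str],
    group: str,
    true_score: int,
) -> RecordingInstance:
    """Run extract -> center -> modulus and wrap the result."""
    rest = extract_rest_segments(recording, annotations, rest_labels)
    centered = mean_center(rest, instance_id=recording.instance_id)
    return RecordingInstance(
        instance_id=recording.instance_id,
        group=group,
        true_score=int(true_score),
        moduli=modulus(centered),
    )
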