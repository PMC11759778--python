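"""Data model and CSV readers/writers.

Containers
----------
``TriaxialRecording``
    One sensor recording: a strictly increasing time base (seconds from
    recording start) and an ``(n, 3)`` array of x/y/z acceleration in g.
``AnnotationInterval``
    A labelled clinic-task interval ``[start, end)`` in seconds. Interval
    membership is half-open so adjacent intervals never double-count a
    sample.
``RecordingInstance``
    One subject-limb's concatenated rest-period movement-intensity moduli
    together with its group (PD / HC) and clinician-assigned rest-tremor
    score (MDS-UPDRS item 3.17, 0-4).

File formats (comma-separated, dot decimal, mandatory header):

* accelerometer CSV: ``t_s, ax_g, ay_g, az_g``
* annotation CSV: ``label, start_s, end_s``
* ground-truth CSV: ``instance_id, group, updrs_3_17``

The per-instance clustering tables of the original study ship as package
fixtures ``table2`` (binary tremor vs non-tremor, 25 instances), ``table3``
(multiclass severity, 14 PD instances) and ``table4`` (binarised severity,
14 PD instances); :func:`load_fixture` returns them as DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParseError

RECORDING_COLUMNS = ("t_s", "ax_g", "ay_g", "az_g")
ANNOTATION_COLUMNS = ("label", "start_s", "end_s")
GROUND_TRUTH_COLUMNS = ("instance_id", "group", "updrs_3_17")

#: expected row counts of the packaged per-instance result tables
FIXTURE_ROWS = {"table2": 25, "table3": 14, "table4": 14}

#: maximum relative deviation of inter-sample spacing from the nominal period
SPACING_RTOL = 0.01


@dataclass(frozen=True)
class TriaxialRecording:
    """A timestamped triaxial accelerometer stream.

    Parameters
    ----------
    instance_id : str
        Identifier of the subject-limb recording.
    sampling_rate : float
        Nominal sampling frequency in Hz (31.25 Hz for the emulated sensor).
    t : ndarray, shape (n,)
        Sample times in seconds, strictly increasing, uniformly spaced
        within ``SPACING_RTOL`` of ``1 / sampling_rate``.
    acc : ndarray, shape (n, 3)
        Acceleration in g, columns x/y/z, finite values only.
    """

    instance_id: str
    sampling_rate: float
    t: np.ndarray
    acc: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        acc = np.asarray(self.acc, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "acc", acc)
        if t.ndim != 1 or acc.shape != (t.size, 3):
            raise ParseError(
                f"{self.instance_id}: expected t (n,) and acc (n, 3), "
                f"got {t.shape} and {acc.shape}"
            )
        if t.size == 0:
            raise ParseError(f"{self.instance_id}: empty recording")
        if not (np.isfinite(t).all() and np.isfinite(acc).all()):
            raise ParseError(f"{self.instance_id}: non-finite values")
        if self.sampling_rate <= 0:
            raise ParseError(f"{self.instance_id}: sampling_rate must be > 0")
        if t.size > 1:
            dt = np.diff(t)
            if not (dt > 0).all():
                row = int(np.flatnonzero(dt <= 0)[0]) + 1
                raise ParseError(
                    f"{self.instance_id}: timestamps not strictly increasing "
                    f"at row {row}"
                )
            period = 1.0 / self.sampling_rate
            if np.abs(dt / period - 1.0).max() > SPACING_RTOL:
                raise ParseError(
                    f"{self.instance_id}: inter-sample spacing deviates more "
                    f"than {SPACING_RTOL:.0%} from 1/sampling_rate"
                )

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class AnnotationInterval:
    """A labelled task interval ``[start, end)`` in seconds."""

    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ParseError(
                f"annotation {self.label!r}: start {self.start} must be "
                f"< end {self.end}"
            )

    def contains(self, t: np.ndarray) -> np.ndarray:
        """Half-open membership mask for sample times ``t``."""
        t = np.asarray(t, dtype=float)
        return (t >= self.start) & (t < self.end)


def validate_annotations(annotations: Sequence[AnnotationInterval]) -> None:
    """Raise :class:`ParseError` if intervals of one recording overlap."""
    ordered = sorted(annotations, key=lambda a: a.start)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start < prev.end:
            raise ParseError(
                f"annotations {prev.label!r} and {cur.label!r} overlap"
            )


@dataclass(frozen=True)
class RecordingInstance:
    """One subject-limb's rest-period movement-intensity series.

    ``moduli`` holds the Euclidean norms of the mean-centered triaxial
    samples of all rest segments, concatenated in temporal order.
    """

    instance_id: str
    group: str
    true_score: int
    moduli: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        moduli = np.asarray(self.moduli, dtype=float)
        object.__setattr__(self, "moduli", moduli)
        if self.group not in ("PD", "HC"):
            raise ParseError(f"{self.instance_id}: group must be PD or HC")
        if not 0 <= int(self.true_score) <= 4:
            raise ParseError(f"{self.instance_id}: score must be in 0..4")
        if self.group == "HC" and self.true_score != 0:
            raise ParseError(
                f"{self.instance_id}: healthy controls are scored 0 at rest"
            )
        if moduli.ndim != 1 or moduli.size < 1:
            raise ParseError(f"{self.instance_id}: moduli must be non-empty 1-D")
        if not np.isfinite(moduli).all() or (moduli < 0).any():
            raise ParseError(f"{self.instance_id}: moduli must be finite, >= 0")

    @property
    def n_samples(self) -> int:
        return int(self.moduli.size)


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def _read_csv(path: Path | str, columns: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV, missing file ...
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def _numeric(df: pd.DataFrame, col: str, path: Path | str) -> np.ndarray:
    coerced = pd.to_numeric(df[col], errors="coerce")
    bad = coerced.isna() & df[col].notna()
    if bad.any() or coerced.isna().any():
        row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
        raise ParseError(f"{path}: non-numeric value in column {col!r}, row {row}")
    return coerced.to_numpy(dtype=float)


def read_recording(path: Path | str, instance_id: str | None = None) -> TriaxialRecording:
    """Read an accelerometer CSV and infer the sampling rate.

    The sampling rate is the reciprocal of the median inter-sample spacing;
    the constructor then enforces monotone, uniform timestamps.
    """
    path = Path(path)
    df = _read_csv(path, RECORDING_COLUMNS)
    if len(df) < 2:
        raise ParseError(f"{path}: need at least 2 samples to infer sampling rate")
    t = _numeric(df, "t_s", path)
    dt = np.diff(t)
    if not (dt > 0).all():
        row = int(np.flatnonzero(dt <= 0)[0]) + 1
        raise ParseError(f"{path}: timestamps not strictly increasing at row {row}")
    acc = np.column_stack([_numeric(df, c, path) for c in RECORDING_COLUMNS[1:]])
    fs = 1.0 / float(np.median(dt))
    return TriaxialRecording(
        instance_id=instance_id or path.stem,
        sampling_rate=fs,
        t=t,
        acc=acc,
    )


def write_recording(recording: TriaxialRecording, path: Path | str) -> None:
    df = pd.DataFrame(
        {
            "t_s": recording.t,
            "ax_g": recording.acc[:, 0],
            "ay_g": recording.acc[:, 1],
            "az_g": recording.acc[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.9f")


def read_annotations(path: Path | str) -> list[AnnotationInterval]:
    path = Path(path)
    df = _read_csv(path, ANNOTATION_COLUMNS)
    start = _numeric(df, "start_s", path)
    end = _numeric(df, "end_s", path)
    annotations = [
        AnnotationInterval(label=str(lbl), start=float(s), end=float(e))
        for lbl, s, e in zip(df["label"], start, end)
    ]
    validate_annotations(annotations)
    return annotations


def write_annotations(annotations: Sequence[AnnotationInterval], path: Path | str) -> None:
    df = pd.DataFrame(
        {
            "label": [a.label for a in annotations],
            "start_s": [a.start for a in annotations],
            "end_s": [a.end for a in annotations],
        }
    )
    df.to_csv(path, index=False, float_format="%.9f")


def read_ground_truth(path: Path | str) -> pd.DataFrame:
    df = _read_csv(path, GROUND_TRUTH_COLUMNS)
    df["updrs_3_17"] = df["updrs_3_17"].astype(int)
    return df


def write_ground_truth(df: pd.DataFrame, path: Path | str) -> None:
    df.to_csv(path, index=False)


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the packaged per-instance result tables.

    Parameters
    ----------
    name : {"table2", "table3", "table4"}
        ``table2``: 25 instances, binary tremor vs non-tremor (score 1 =
        tremor, 0 = non-tremor). ``table3``: 14 PD instances, severity
        scores 1-3 with the published predominant-cluster and mapped-score
        columns. ``table4``: 14 PD instances, binarised severity (1 =
        slight/mild, 2 = moderate).
    """
    if name not in FIXTURE_ROWS:
        raise ValueError(f"unknown fixture {name!r}; expected one of {sorted(FIXTURE_ROWS)}")
    ref = resources.files("tremorclust").joinpath(f"fixtures/{name}.csv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    if len(df) != FIXTURE_ROWS[name]:
        raise ParseError(
            f"fixture {name}: expected {FIXTURE_ROWS[name]} rows, got {len(df)}"
        )
    return df
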