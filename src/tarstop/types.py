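"""Core domain types for prioritized-screening simulation.

A screening *dataset* is an ordered corpus of records with binary
include/exclude labels. A *screening trace* is one simulated pass over a
dataset: the order in which records were screened, the labels in that
order, and periodic snapshots of the ranking model's scores over the
still-unseen records. A *trace prefix* is the information a reviewer
(or a stopping criterion) would have after screening the first ``t``
records of a trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Record",
    "Dataset",
    "ScoreSnapshot",
    "ScreeningTrace",
    "TracePrefix",
    "trace_prefix",
    "inclusion_curve",
]


class ValidationError(ValueError):
    """Raised when input data violates a domain invariant."""


@dataclass(frozen=True)
class Record:
    """One bibliographic record with its screening decision.

    ``label`` is 1 for an included (relevant) record and 0 for an
    excluded one.
    """

    id: str
    title: str
    abstract: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValidationError(
                f"record {self.id!r}: label must be 0 or 1, got {self.label!r}"
            )


@dataclass
class Dataset:
    """Ordered collection of labeled records (the ground-truth corpus)."""

    records: list[Record]
    name: str = "dataset"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.records) < 1:
            raise ValidationError("dataset must contain at least one record")
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValidationError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Record]:
        return iter(self.records)

    @property
    def n_records(self) -> int:
        """Dataset size N."""
        return len(self.records)

    @property
    def n_relevant(self) -> int:
        """Number of relevant records R = sum of labels."""
        return sum(r.label for r in self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=np.int64)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]


@dataclass
class ScoreSnapshot:
    """Ranking-model scores over unseen records at one retraining point.

    ``taken_after`` is the number of records screened when the snapshot
    was produced; ``scores`` maps each then-unseen record id to a score
    in [0, 1].
    """

    iteration: int
    taken_after: int
    scores: dict[str, float]

    def __post_init__(self) -> None:
        if self.iteration < 1:
            raise ValidationError("snapshot iteration must be >= 1")
        for rid, s in self.scores.items():
            if not (0.0 <= s <= 1.0):
                raise ValidationError(
                    f"snapshot score for {rid!r} outside [0, 1]: {s}"
                )


@dataclass
class ScreeningTrace:
    """One simulated screening run over a dataset.

    The first ``init_size`` positions of ``order`` are the initial
    random sample; the remainder is the prioritized phase.
    ``iteration_boundaries`` lists the screened-counts at which the
    ranking model was retrained.
    """

    dataset_name: str
    order: list[str]
    labels_in_order: np.ndarray
    init_size: int
    snapshots: list[ScoreSnapshot] = field(default_factory=list)
    seed: int = 0
    iteration_boundaries: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels_in_order = np.asarray(self.labels_in_order, dtype=np.int64)
        if len(self.order) != len(self.labels_in_order):
            raise ValidationError("order and labels_in_order length mismatch")
        if self.init_size > len(self.order):
            raise ValidationError("init_size exceeds trace length")
        if not np.isin(self.labels_in_order, (0, 1)).all():
            raise ValidationError("labels_in_order must be binary")
        self.snapshots = sorted(self.snapshots, key=lambda s: s.taken_after)
        if self.snapshots and self.snapshots[0].taken_after < self.init_size:
            raise ValidationError(
                "first snapshot precedes the end of the initial sample"
            )

    @property
    def n_records(self) -> int:
        return len(self.order)

    @property
    def n_relevant(self) -> int:
        return int(self.labels_in_order.sum())

    @cached_property
    def cumulative_includes(self) -> np.ndarray:
        """rho_t for t = 0..N (length N+1, rho_0 = 0)."""
        out = np.zeros(self.n_records + 1, dtype=np.int64)
        np.cumsum(self.labels_in_order, out=out[1:])
        return out

    def prefix(self, t: int) -> "TracePrefix":
        return trace_prefix(self, t)


class TracePrefix:
    """Read-only view of a trace truncated at checkpoint ``t``.

    This is exactly the information available to a stopping criterion
    mid-screening: the labels of the first ``t`` records in screening
    order, the initial-sample size, and the most recent score snapshot
    (with records screened since the snapshot removed).
    """

    def __init__(self, trace: ScreeningTrace, t: int):
        if not (0 <= t <= trace.n_records):
            raise IndexError(
                f"prefix length {t} outside [0, {trace.n_records}]"
            )
        self._trace = trace
        self.t = t
        self.N = trace.n_records
        self.init_size = trace.init_size

    @property
    def labels(self) -> np.ndarray:
        """Labels of the first t screened records (screening order)."""
        return self._trace.labels_in_order[: self.t]

    @property
    def n_includes(self) -> int:
        """rho_t: cumulative includes after t records."""
        return int(self._trace.cumulative_includes[self.t])

    @cached_property
    def seen_ids(self) -> frozenset[str]:
        return frozenset(self._trace.order[: self.t])

    @property
    def snapshot_history(self) -> list[ScoreSnapshot]:
        """All snapshots taken at or before t."""
        return [s for s in self._trace.snapshots if s.taken_after <= self.t]

    @cached_property
    def latest_scores(self) -> dict[str, float] | None:
        """Scores of the most recent snapshot at or before t, restricted
        to records not yet screened at t; None when no snapshot
        qualifies."""
        history = self.snapshot_history
        if not history:
            return None
        snap = history[-1]
        screened_since = set(self._trace.order[snap.taken_after : self.t])
        if not screened_since:
            return dict(snap.scores)
        return {
            rid: s for rid, s in snap.scores.items() if rid not in screened_since
        }


def trace_prefix(trace: ScreeningTrace, t: int) -> TracePrefix:
    """View of ``trace`` truncated after the t-th screened record.

    Raises IndexError if ``t`` is outside [0, N].
    """
    return TracePrefix(trace, t)


def inclusion_curve(trace: ScreeningTrace) -> np.ndarray:
    """Cumulative inclusion (gain) curve of a trace.

    Returns an array of shape (N, 2) with rows (t, rho_t) for
    t = 1..N; rho_t is nondecreasing with rho_N = R.
    """
    rho = trace.cumulative_includes[1:]
    t = np.arange(1, trace.n_records + 1)
    return np.column_stack([t, rho])
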