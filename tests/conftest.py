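import numpy as np
import pytest
from hypothesis import settings

from tarstop.types import ScoreSnapshot, ScreeningTrace

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


def trace_from_labels(labels, init_size=0, snapshots=(), name="toy", seed=0):
    """Build a minimal trace from a label sequence (ids x0, x1, ...)."""
    labels = np.asarray(labels, dtype=np.int64)
    ids = [f"x{i}" for i in range(len(labels))]
    return ScreeningTrace(
        dataset_name=name,
        order=ids,
        labels_in_order=labels,
        init_size=init_size,
        snapshots=list(snapshots),
        seed=seed,
    )


def prefix_with_scores(seen_labels, unseen_scores, N=None, init_size=0):
    """Prefix at t = len(seen_labels) whose latest snapshot scores the
    unseen records with the given values."""
    t = len(seen_labels)
    n_unseen = len(unseen_scores)
    N = N if N is not None else t + n_unseen
    labels = np.zeros(N, dtype=np.int64)
    labels[:t] = seen_labels
    snap = ScoreSnapshot(
        iteration=1,
        taken_after=t,
        scores={f"x{t + i}": float(s) for i, s in enumerate(unseen_scores)},
    )
    trace = trace_from_labels(labels, init_size=init_size, snapshots=[snap])
    return trace.prefix(t)


@pytest.fixture
def toy_trace():
    """Hand-built 10-record trace: labels 1,1,0,1,0,0,1,0,0,0 (R = 4)."""
    return trace_from_labels([1, 1, 0, 1, 0, 0, 1, 0, 0, 0])
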