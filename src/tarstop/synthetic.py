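"""Synthetic corpora and screening traces.

Real fully-annotated screening datasets are rarely shareable, so this
module generates stand-ins with the statistical shape such datasets
exhibit: a few thousand records, a low inclusion rate, and — for
traces — a gain curve with a random-sampling diagonal over the initial
sample, a steep prioritized segment that converges exponentially, and
optional zero-inclusion plateaus (the "steps" produced when a ranker
exhausts one cluster of relevant records before finding the next).

Two generator levels are provided. :func:`generate_corpus` builds a
token-level labeled corpus for end-to-end simulator tests;
:func:`generate_trace` builds a screening trace directly from a small
parametric model of the gain curve, so stopping criteria can be tested
without running any machine learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .types import Dataset, Record, ScoreSnapshot, ScreeningTrace

__all__ = [
    "CorpusParams",
    "TraceParams",
    "ConfigurationError",
    "generate_corpus",
    "generate_trace",
    "batch_generate",
]


class ConfigurationError(ValueError):
    """Raised for generator parameter combinations that cannot be honored."""


@dataclass(frozen=True)
class CorpusParams:
    """Parameters of the token-level corpus generator.

    Defaults reproduce the average shape of real screening datasets:
    N = 3600 records at a 5% inclusion rate, relevant records drawn
    from a small number of topical clusters.
    """

    N: int = 3600
    inclusion_rate: float = 0.05
    n_clusters: int = 3
    vocab_size: int = 5000
    doc_length_mean: float = 150.0
    topic_mix: float = 0.35
    seed: int = 0
    name: str | None = None

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ConfigurationError("N must be >= 1")
        if not (0.0 < self.inclusion_rate < 1.0):
            raise ConfigurationError("inclusion_rate must be in (0, 1)")
        if round(self.N * self.inclusion_rate) < 1:
            raise ConfigurationError("N * inclusion_rate rounds to zero relevant records")
        if self.n_clusters < 1:
            raise ConfigurationError("n_clusters must be >= 1")
        if not (0.0 < self.topic_mix < 1.0):
            raise ConfigurationError("topic_mix must be in (0, 1)")


@dataclass(frozen=True)
class TraceParams:
    """Parameters of the parametric trace generator.

    ``curve_rate`` is the steepness beta of the prioritized gain curve
    g(u) = (1 - exp(-beta*u)) / (1 - exp(-beta)) over the normalized
    prioritized region u in (0, 1]; beta -> 0 degenerates to random
    ordering, large beta to a near-ideal ranking. ``plateaus`` are
    (start_fraction, width_fraction) pairs, fractions of the
    prioritized region, inserted as zero-inclusion gaps. Score
    snapshots draw Beta-distributed scores by true label; includes
    score higher on average than excludes.
    """

    N: int = 3600
    R: int = 180
    init_size: int = 500
    curve_rate: float = 12.0
    plateaus: tuple[tuple[float, float], ...] = ()
    snapshot_interval: int | None = 25
    score_beta_include: tuple[float, float] = (4.0, 2.0)
    score_beta_exclude: tuple[float, float] = (1.0, 6.0)
    seed: int = 0
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.R < self.N):
            raise ConfigurationError("need 0 < R < N")
        if not (0 < self.init_size < self.N):
            raise ConfigurationError("need 0 < init_size < N")
        if self.curve_rate < 0:
            raise ConfigurationError("curve_rate must be >= 0")
        a1, b1 = self.score_beta_include
        a0, b0 = self.score_beta_exclude
        if min(a1, b1, a0, b0) <= 0:
            raise ConfigurationError("Beta shape parameters must be positive")
        if a1 / (a1 + b1) <= a0 / (a0 + b0):
            raise ConfigurationError(
                "include scores must exceed exclude scores on average"
            )
        for s, w in self.plateaus:
            if not (0.0 < s < 1.0) or not (0.0 < w < 1.0):
                raise ConfigurationError("plateau fractions must be in (0, 1)")


# ---------------------------------------------------------------------------
# corpus generation


def _zipf_weights(k: int, exponent: float = 1.1) -> np.ndarray:
    w = 1.0 / np.arange(1, k + 1) ** exponent
    return w / w.sum()


def generate_corpus(params: CorpusParams) -> Dataset:
    """Generate a labeled corpus of synthetic abstracts.

    Exactly ``round(N * inclusion_rate)`` records are relevant.
    Relevant records draw a fraction ``topic_mix`` of their tokens from
    their cluster's topic vocabulary; all remaining tokens (and all
    tokens of irrelevant records) come from a shared Zipf-like
    background distribution. Deterministic given ``seed``.
    """
    if params.vocab_size < params.n_clusters * 10:
        raise ConfigurationError(
            "vocab_size must be at least 10 words per cluster "
            f"({params.n_clusters * 10}), got {params.vocab_size}"
        )
    rng = np.random.default_rng(params.seed)
    N = params.N
    R = int(round(N * params.inclusion_rate))
    vocab = np.array([f"w{i:05d}" for i in range(params.vocab_size)])

    background = _zipf_weights(params.vocab_size)
    # each cluster's topic lives on its own block of vocabulary, disjoint
    # from the other clusters (tail of the vocab, where background mass is low)
    block = max(10, params.vocab_size // (10 * params.n_clusters))
    topic_supports = []
    hi = params.vocab_size
    for c in range(params.n_clusters):
        lo = hi - block
        topic_supports.append(np.arange(lo, hi))
        hi = lo
    topic_dists = [_zipf_weights(len(s), 0.8) for s in topic_supports]

    labels = np.zeros(N, dtype=np.int64)
    labels[rng.choice(N, size=R, replace=False)] = 1
    clusters = rng.integers(0, params.n_clusters, size=N)

    records: list[Record] = []
    for i in range(N):
        n_tokens = max(5, rng.poisson(params.doc_length_mean))
        if labels[i] == 1:
            c = clusters[i]
            from_topic = rng.random(n_tokens) < params.topic_mix
            tokens = np.empty(n_tokens, dtype=vocab.dtype)
            k_top = int(from_topic.sum())
            tokens[from_topic] = vocab[
                rng.choice(topic_supports[c], size=k_top, p=topic_dists[c])
            ]
            tokens[~from_topic] = vocab[
                rng.choice(params.vocab_size, size=n_tokens - k_top, p=background)
            ]
        else:
            tokens = vocab[rng.choice(params.vocab_size, size=n_tokens, p=background)]
        title = " ".join(tokens[: min(8, n_tokens)])
        abstract = " ".join(tokens[min(8, n_tokens):])
        records.append(
            Record(id=f"d{i:05d}", title=title, abstract=abstract, label=int(labels[i]))
        )
    name = params.name or f"synthetic-corpus-N{N}-seed{params.seed}"
    return Dataset(records=records, name=name, metadata={"seed": params.seed, "R": R})


# ---------------------------------------------------------------------------
# trace generation


def _inverse_gain(v: np.ndarray, beta: float) -> np.ndarray:
    """Inverse of g(u) = (1 - exp(-beta u)) / (1 - exp(-beta))."""
    if beta < 1e-9:
        return v
    return -np.log1p(-v * (1.0 - np.exp(-beta))) / beta


def _plateau_layout(M: int, plateaus: Sequence[tuple[float, float]]) -> list[tuple[int, int]]:
    """Translate plateau fractions into disjoint (start, length) record
    intervals within a prioritized region of M records."""
    intervals = []
    for s, w in sorted(plateaus):
        start = int(round(s * M))
        length = int(round(w * M))
        intervals.append((start, length))
    prev_end = -1
    for start, length in intervals:
        if start <= prev_end:
            raise ConfigurationError("plateau intervals overlap")
        if start + length > M:
            raise ConfigurationError("plateau extends past the prioritized region")
        prev_end = start + length
    return intervals


def generate_trace(params: TraceParams) -> ScreeningTrace:
    """Generate a parametric screening trace.

    The first ``init_size`` labels are a uniform draw without
    replacement from the full label multiset (the random-sampling
    phase). The remaining relevant records are placed in the
    prioritized region so the cumulative gain curve follows
    g(u) = (1 - e^(-beta u))/(1 - e^(-beta)), with zero-inclusion gaps
    spliced in at each plateau. Score snapshots every
    ``snapshot_interval`` records draw unseen-record scores from
    Beta(a1, b1) for includes and Beta(a0, b0) for excludes.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(params.seed)
    N, R, n0 = params.N, params.R, params.init_size
    M = N - n0

    all_labels = np.zeros(N, dtype=np.int64)
    all_labels[:R] = 1
    all_labels = rng.permutation(all_labels)
    init_labels = all_labels[:n0]
    R_prio = int(R - init_labels.sum())

    gaps = _plateau_layout(M, params.plateaus)
    M_eff = M - sum(length for _, length in gaps)
    if M_eff <= 0:
        raise ConfigurationError("plateaus cover the entire prioritized region")
    if M_eff < R_prio:
        raise ConfigurationError(
            "plateaus leave too little room for the remaining relevant records"
        )

    # place includes at g-distributed continuous times, excludes evenly
    u_inc = np.sort(_inverse_gain(rng.random(R_prio), params.curve_rate))
    n_exc = M_eff - R_prio
    u_exc = (np.arange(n_exc) + 0.5) / max(n_exc, 1)
    times = np.concatenate([u_inc, u_exc])
    seq_labels = np.concatenate(
        [np.ones(R_prio, dtype=np.int64), np.zeros(n_exc, dtype=np.int64)]
    )
    effective = seq_labels[np.argsort(times, kind="stable")]

    prio = np.zeros(M, dtype=np.int64)
    is_gap = np.zeros(M, dtype=bool)
    for start, length in gaps:
        is_gap[start : start + length] = True
    prio[~is_gap] = effective

    labels_in_order = np.concatenate([init_labels, prio])
    assert int(labels_in_order.sum()) == R

    ids = [f"r{i:05d}" for i in range(N)]  # order == identity by construction

    snapshots: list[ScoreSnapshot] = []
    boundaries: list[int] = []
    if params.snapshot_interval:
        a1, b1 = params.score_beta_include
        a0, b0 = params.score_beta_exclude
        iteration = 0
        for taken_after in range(n0, N, params.snapshot_interval):
            iteration += 1
            unseen_labels = labels_in_order[taken_after:]
            scores = np.where(
                unseen_labels == 1,
                rng.beta(a1, b1, size=N - taken_after),
                rng.beta(a0, b0, size=N - taken_after),
            )
            snapshots.append(
                ScoreSnapshot(
                    iteration=iteration,
                    taken_after=taken_after,
                    scores={
                        ids[i]: float(scores[i - taken_after])
                        for i in range(taken_after, N)
                    },
                )
            )
            boundaries.append(taken_after)

    name = params.name or f"synthetic-trace-N{N}-R{R}-seed{params.seed}"
    return ScreeningTrace(
        dataset_name=name,
        order=ids,
        labels_in_order=labels_in_order,
        init_size=n0,
        snapshots=snapshots,
        seed=params.seed,
        iteration_boundaries=boundaries,
    )


def batch_generate(
    specs: Sequence[CorpusParams | TraceParams], seeds: Sequence[int]
) -> dict[str, Dataset | ScreeningTrace]:
    """Generate one artifact per (spec, seed) pair.

    Artifact names embed the seed; duplicate (name, seed) combinations
    raise a collision error. Mirrors the practice of running several
    seeded screening simulations per dataset.
    """
    if not specs or not seeds:
        raise ConfigurationError("specs and seeds must be nonempty")
    out: dict[str, Dataset | ScreeningTrace] = {}
    for spec in specs:
        base = spec.name or type(spec).__name__
        for seed in seeds:
            key = f"{base}-seed{seed}"
            if key in out:
                raise ConfigurationError(f"duplicate artifact name {key!r}")
            stamped = replace(spec, seed=seed, name=key)
            if isinstance(stamped, CorpusParams):
                out[key] = generate_corpus(stamped)
            else:
                out[key] = generate_trace(stamped)
    return out
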