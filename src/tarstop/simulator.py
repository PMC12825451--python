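"""Priority-screening simulator.

Simulates a reviewer screening a fully labeled corpus with
model-assisted prioritization: an initial uniformly random sample,
then adaptive retraining batches in which a pool of classifier
families (TF-IDF features, seeded random hyperparameter search,
cross-validated recall selection) ranks the unseen records so the most
likely includes are screened next. The output is a complete
:class:`~tarstop.types.ScreeningTrace` — every record is screened, no
stopping — with a score snapshot at every retraining, so stopping
criteria can be replayed over the trace afterwards.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.calibration import CalibratedClassifierCV
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.metrics import recall_score
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import LinearSVC

from .types import Dataset, ScoreSnapshot, ScreeningTrace

__all__ = [
    "SimulatorConfig",
    "ModelChoice",
    "vectorize",
    "batch_target_size",
    "select_best_model",
    "simulate_screening",
]

logger = logging.getLogger(__name__)

KNOWN_FAMILIES = ("logistic_regression", "svm", "sgd", "gbm")


@dataclass(frozen=True)
class SimulatorConfig:
    """Knobs of the screening simulation.

    Defaults: an initial random sample of 500 records, retraining
    batches bounded by [25, 200] with a nominal size growing 10% per
    iteration, batches closing once at least two new includes are
    found, and the model family + hyperparameters re-selected every
    four iterations.
    """

    init_size: int = 500
    batch_lower: int = 25
    batch_upper: int = 200
    growth_rate: float = 0.10
    min_new_includes_per_batch: int = 2
    model_reuse_iterations: int = 4
    model_families: tuple[str, ...] = KNOWN_FAMILIES
    tuning_budget: int = 20
    cv_folds: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_lower > self.batch_upper:
            raise ValueError("batch_lower must be <= batch_upper")
        if self.growth_rate < 0:
            raise ValueError("growth_rate must be >= 0")
        unknown = set(self.model_families) - set(KNOWN_FAMILIES)
        if unknown:
            raise ValueError(f"unknown model families: {sorted(unknown)}")
        if not self.model_families:
            raise ValueError("need at least one model family")


@dataclass
class ModelChoice:
    """Winner of one model-selection round."""

    family: str
    hyperparameters: dict
    selection_score: float  # cross-validated recall on the seen set


def vectorize(dataset: Dataset):
    """Sparse TF-IDF features from concatenated title + abstract.

    Standard smoothed-idf, l2-normalized weighting:
    tf * (ln((1 + n)/(1 + df)) + 1), rows normalized to unit length.
    A record with no text yields an all-zero row. Row order follows the
    dataset order; the result is deterministic.
    """
    texts = [f"{r.title} {r.abstract}".strip() for r in dataset.records]
    vec = TfidfVectorizer()
    try:
        return vec.fit_transform(texts)
    except ValueError:
        # corpus with an empty vocabulary (all-empty texts)
        return sp.csr_matrix((len(texts), 0))


def batch_target_size(iteration: int, config: SimulatorConfig) -> int:
    """Nominal batch size: min(upper, round(lower * (1 + growth)^j))."""
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    target = round(config.batch_lower * (1.0 + config.growth_rate) ** iteration)
    return int(min(config.batch_upper, target))


# ---------------------------------------------------------------------------
# model pool

def _sample_hyperparameters(family: str, rng: np.random.Generator) -> dict:
    cw = [None, "balanced"][int(rng.integers(2))]
    if family == "logistic_regression":
        return {"C": float(10 ** rng.uniform(-2, 2)), "class_weight": cw}
    if family == "svm":
        return {"C": float(10 ** rng.uniform(-2, 2)), "class_weight": cw}
    if family == "sgd":
        return {"alpha": float(10 ** rng.uniform(-6, -2)), "class_weight": cw}
    if family == "gbm":
        return {
            "n_estimators": int(rng.integers(50, 151)),
            "num_leaves": int(rng.integers(15, 64)),
            "learning_rate": float(10 ** rng.uniform(-1.5, -0.5)),
            "min_child_samples": int(rng.integers(5, 31)),
        }
    raise ValueError(f"unknown model family {family!r}")


def _build_estimator(family: str, hyperparameters: dict, seed: int):
    """Estimator with probability outputs in [0, 1].

    Linear SVMs have no native probabilities; their decision values are
    mapped through a sigmoid fitted on cross-validated decision values
    (Platt scaling).
    """
    if family == "logistic_regression":
        return LogisticRegression(max_iter=2000, **hyperparameters)
    if family == "svm":
        base = LinearSVC(**hyperparameters)
        return CalibratedClassifierCV(base, method="sigmoid", cv=3)
    if family == "sgd":
        return SGDClassifier(loss="log_loss", max_iter=2000, tol=1e-4,
                             random_state=seed, **hyperparameters)
    if family == "gbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            random_state=seed, deterministic=True, n_jobs=1, verbose=-1,
            **hyperparameters,
        )
    raise ValueError(f"unknown model family {family!r}")


def select_best_model(
    features, labels: np.ndarray, config: SimulatorConfig, seed: int
) -> ModelChoice:
    """Random hyperparameter search across the model pool.

    Each family gets ``tuning_budget`` trials scored by stratified
    cross-validated recall of the 0.5-thresholded classifier on the
    seen records; the globally best (family, hyperparameters) wins.
    Ties are broken by family order in the config, then trial index
    (first strictly better wins).
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("model selection needs both an include and an exclude")
    rng = np.random.default_rng(seed)
    n_min = int(min((labels == c).sum() for c in classes))
    folds = min(config.cv_folds, n_min)

    best: ModelChoice | None = None
    for family in config.model_families:
        for trial in range(config.tuning_budget):
            hp = _sample_hyperparameters(family, rng)
            est = _build_estimator(family, hp, seed=int(rng.integers(2**31)))
            try:
                if folds >= 2:
                    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
                    score = float(
                        cross_val_score(est, features, labels, cv=cv, scoring="recall").mean()
                    )
                else:
                    # too few includes to cross-validate: in-sample recall
                    est.fit(features, labels)
                    score = float(recall_score(labels, est.predict(features)))
            except Exception as exc:  # a misbehaving trial must not kill the run
                logger.debug("trial failed (%s, %s): %s", family, hp, exc)
                continue
            if best is None or score > best.selection_score:
                best = ModelChoice(family=family, hyperparameters=hp, selection_score=score)
    if best is None:
        raise RuntimeError("every model-selection trial failed")
    return best


# ---------------------------------------------------------------------------
# screening loop

def simulate_screening(
    dataset: Dataset, config: SimulatorConfig | None = None, seed: int | None = None
) -> ScreeningTrace:
    """Simulate one full prioritized screening pass over a dataset.

    Phase 1 screens ``init_size`` uniformly random records (extended
    randomly until both classes are seen, if necessary). Phase 2
    repeats: select (or reuse, for ``model_reuse_iterations``
    iterations) the best model, refit on all seen records, snapshot its
    scores over the unseen records, then screen in descending score
    order until the batch closes — at the first of: at least
    ``min_new_includes_per_batch`` new includes found and the batch at
    least ``batch_lower`` long; the batch reaching ``batch_upper``; or
    no unseen records remaining. Terminates with all N records
    screened.
    """
    config = config or SimulatorConfig()
    seed = config.seed if seed is None else seed
    n = dataset.n_records
    if config.init_size >= n:
        raise ValueError(f"init_size {config.init_size} must be below N={n}")
    if dataset.n_relevant < 1:
        raise ValueError("dataset has no relevant records to find")

    rng = np.random.default_rng(seed)
    features = vectorize(dataset)
    labels_all = dataset.labels
    ids = dataset.ids

    unseen = list(rng.permutation(n))
    order: list[int] = []

    def screen(idx: int) -> None:
        order.append(idx)

    for _ in range(config.init_size):
        screen(unseen.pop())
    # single-class fallback: keep screening at random until both classes seen
    while unseen and len(np.unique(labels_all[order])) < 2:
        screen(unseen.pop())

    snapshots: list[ScoreSnapshot] = []
    boundaries: list[int] = []
    choice: ModelChoice | None = None
    estimator = None
    iteration = 0
    while unseen:
        seen_y = labels_all[order]
        if choice is None or iteration % config.model_reuse_iterations == 0:
            choice = select_best_model(
                features[order], seen_y, config, seed=int(rng.integers(2**31))
            )
            logger.info(
                "iteration %d: selected %s (cv recall %.3f)",
                iteration, choice.family, choice.selection_score,
            )
        estimator = _build_estimator(
            choice.family, choice.hyperparameters, seed=int(rng.integers(2**31))
        )
        estimator.fit(features[order], seen_y)
        probs = estimator.predict_proba(features[unseen])[:, 1]
        probs = np.clip(probs, 0.0, 1.0)

        taken_after = len(order)
        boundaries.append(taken_after)
        snapshots.append(
            ScoreSnapshot(
                iteration=iteration + 1,
                taken_after=taken_after,
                scores={ids[u]: float(p) for u, p in zip(unseen, probs)},
            )
        )

        ranked = [unseen[i] for i in np.argsort(-probs, kind="stable")]
        batch_len = 0
        new_includes = 0
        for idx in ranked:
            screen(idx)
            batch_len += 1
            new_includes += int(labels_all[idx])
            if (
                new_includes >= config.min_new_includes_per_batch
                and batch_len >= config.batch_lower
            ) or batch_len >= config.batch_upper:
                break
        unseen = ranked[batch_len:]
        iteration += 1

    trace = ScreeningTrace(
        dataset_name=dataset.name,
        order=[ids[i] for i in order],
        labels_in_order=labels_all[np.array(order)],
        init_size=config.init_size,
        snapshots=snapshots,
        seed=seed,
        iteration_boundaries=boundaries,
    )
    assert trace.n_records == n and trace.n_relevant == dataset.n_relevant
    return trace
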