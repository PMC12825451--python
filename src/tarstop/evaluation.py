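"""Evaluation harness: checkpoint sweeps, stopping metrics, summaries.

Stopping criteria are applied at a fixed checkpoint schedule (every
``interval`` records from the end of the initial sample, with the full
trace length always included as final checkpoint). The reported
stopping point is the first checkpoint at which the criterion fired;
metrics compare it against the theoretically optimal stopping point for
a recall target on the same trace.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stopping import (
    REGISTRY,
    TARGET_AWARE,
    CriterionState,
    StoppingConfig,
    evaluate_method,
    qbcb_sample_size,
)
from .types import ScreeningTrace, TracePrefix, trace_prefix

__all__ = [
    "NEVER",
    "StopDecision",
    "EvaluationRow",
    "checkpoint_schedule",
    "apply_schedule",
    "optimal_stop_index",
    "evaluate_stop",
    "evaluate_decision",
    "aggregate",
    "composite_curves",
    "sample_target_set",
    "config_digest",
]

logger = logging.getLogger(__name__)

#: sentinel stop index for a criterion that never fired
NEVER = None


@dataclass
class StopDecision:
    """Where one criterion (with one hyperparameter setting) stopped."""

    method: str
    config: StoppingConfig
    trace_id: str
    stop_index: int | None  # NEVER when the criterion never fired
    checkpoint_values: list[tuple[int, float | None, bool]] = field(default_factory=list)

    @property
    def stopped(self) -> bool:
        return self.stop_index is not None


@dataclass
class EvaluationRow:
    """Metrics of one stop decision against one recall target."""

    trace_id: str
    method: str
    config_digest: str
    recall_target: float
    stop_index: int  # NEVER mapped to N
    stopped: bool
    optimal_stop: int
    achieved_recall: float
    target_missed: bool
    missed_proportion: float
    additional_work: float
    work_saved_fraction: float


def config_digest(config: StoppingConfig) -> str:
    payload = repr(sorted(asdict(config).items())).encode()
    return hashlib.sha1(payload).hexdigest()[:10]


def checkpoint_schedule(trace: ScreeningTrace, interval: int = 15) -> list[int]:
    """Checkpoints n0, n0+interval, ... with N always included last."""
    if interval < 1:
        raise ValueError("interval must be >= 1")
    n0, n = trace.init_size, trace.n_records
    points = list(range(max(n0, 1), n, interval))
    points.append(n)
    return points


def sample_target_set(
    trace: ScreeningTrace, n_targets: int, seed: int
) -> frozenset[str]:
    """Uniform sample (without replacement) of relevant record ids,
    capped at the number of relevant records in the trace."""
    rng = np.random.default_rng(seed)
    relevant = [
        rid for rid, lab in zip(trace.order, trace.labels_in_order) if lab == 1
    ]
    n = min(n_targets, len(relevant))
    if n == 0:
        return frozenset()
    return frozenset(rng.choice(np.array(relevant), size=n, replace=False).tolist())


def apply_schedule(
    trace: ScreeningTrace,
    method: str,
    config: StoppingConfig,
    interval: int = 15,
    seed: int = 0,
    full_series: bool = False,
) -> StopDecision:
    """Apply one criterion over the checkpoint schedule of a trace.

    The stopping point is the first checkpoint at which the criterion's
    effective trigger holds ("end of the first batch"). APRIORI's
    sustained-window rule — the point condition must hold at ``window``
    consecutive checkpoints — is applied here, since a single prefix
    cannot see earlier checkpoints. TM_QBCB's hidden target set is
    drawn here (seeded) so the criterion itself stays pure.

    By default the value series is retained up to and including the
    firing checkpoint; ``full_series=True`` evaluates every checkpoint.
    """
    if method not in REGISTRY:
        raise KeyError(f"unknown stopping method {method!r}")
    target_set: frozenset[str] | None = None
    if method == "TM_QBCB":
        n_targets = config.n_targets
        if n_targets is None:
            n_targets = qbcb_sample_size(
                config.require("recall_target"), config.require("confidence")
            )
        target_set = sample_target_set(trace, n_targets, seed)

    window = config.window if method == "APRIORI" else 1
    if not window or window < 1:
        window = 1

    series: list[tuple[int, float | None, bool]] = []
    stop_index: int | None = NEVER
    consecutive = 0
    for t in checkpoint_schedule(trace, interval):
        prefix = trace_prefix(trace, t)
        state = evaluate_method(method, prefix, config, seed=seed, target_set=target_set)
        series.append((t, state.value, state.triggered))
        consecutive = consecutive + 1 if state.triggered else 0
        if stop_index is NEVER and consecutive >= window:
            stop_index = t
            if not full_series:
                break
    return StopDecision(
        method=method,
        config=config,
        trace_id=trace.dataset_name,
        stop_index=stop_index,
        checkpoint_values=series,
    )


def optimal_stop_index(trace: ScreeningTrace, recall_target: float) -> int:
    """Smallest t at which rho_t >= ceil(tau * R)."""
    r = trace.n_relevant
    if r < 1:
        raise ValueError("trace has no relevant records")
    needed = max(1, math.ceil(recall_target * r))
    cum = trace.cumulative_includes
    # cum is nondecreasing; first index with cum[t] >= needed
    return int(np.searchsorted(cum, needed, side="left"))


def evaluate_stop(
    trace: ScreeningTrace,
    stop_index: int | None,
    recall_target: float,
    method: str = "",
    config: StoppingConfig | None = None,
) -> EvaluationRow:
    """Score one stopping point against one recall target.

    A criterion that never fired is treated as stopping at N, with
    additional work 100% by convention. Additional work is the signed
    fraction of the post-optimal remainder screened; negative values
    mean the criterion fired before the optimal point.
    """
    n = trace.n_records
    r = trace.n_relevant
    stopped = stop_index is not NEVER
    t_stop = n if stop_index is NEVER else int(stop_index)
    rho = int(trace.cumulative_includes[t_stop])
    needed = max(1, math.ceil(recall_target * r))
    t_opt = optimal_stop_index(trace, recall_target)
    if not stopped:
        additional_work = 1.0
    elif t_opt >= n:
        additional_work = 0.0
    else:
        additional_work = (t_stop - t_opt) / (n - t_opt)
    return EvaluationRow(
        trace_id=trace.dataset_name,
        method=method,
        config_digest=config_digest(config) if config is not None else "",
        recall_target=recall_target,
        stop_index=t_stop,
        stopped=stopped,
        optimal_stop=t_opt,
        achieved_recall=rho / r,
        target_missed=rho < needed,
        missed_proportion=max(0, needed - rho) / needed,
        additional_work=additional_work,
        work_saved_fraction=1.0 - t_stop / n,
    )


def evaluate_decision(
    trace: ScreeningTrace,
    decision: StopDecision,
    recall_targets: Sequence[float],
) -> list[EvaluationRow]:
    """Evaluation rows for one decision.

    Target-aware methods are scored against their own configured
    target; target-agnostic ones are replicated across the reference
    targets.
    """
    if decision.method in TARGET_AWARE and decision.config.recall_target is not None:
        targets = [decision.config.recall_target]
    else:
        targets = list(recall_targets)
    return [
        evaluate_stop(trace, decision.stop_index, tau, decision.method, decision.config)
        for tau in targets
    ]


_PCTL_INTERP = "linear"  # quantile interpolation rule, fixed and documented


def aggregate(rows: Iterable[EvaluationRow] | pd.DataFrame) -> pd.DataFrame:
    """Summarize evaluation rows per (method, recall target).

    Columns: percent of runs that missed the target, mean achieved
    recall (x100) with the 10th-90th percentile range, and mean
    additional work (x100, may be negative for early stops).
    Percentiles use linear interpolation between order statistics.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame([asdict(r) for r in rows])
    if df.empty:
        logger.warning("aggregate: no evaluation rows")
        return pd.DataFrame(
            columns=[
                "method", "recall_target", "n", "pct_target_missed",
                "recall_mean", "recall_q10", "recall_q90", "additional_work_mean",
            ]
        )
    out = []
    for (method, tau), g in df.groupby(["method", "recall_target"], sort=True):
        if g.empty:  # pragma: no cover - groupby never yields empty groups
            logger.warning("aggregate: empty group (%s, %s) omitted", method, tau)
            continue
        rec = g["achieved_recall"].to_numpy()
        out.append(
            {
                "method": method,
                "recall_target": tau,
                "n": len(g),
                "pct_target_missed": 100.0 * g["target_missed"].mean(),
                "recall_mean": 100.0 * rec.mean(),
                "recall_q10": 100.0 * np.percentile(rec, 10, method=_PCTL_INTERP),
                "recall_q90": 100.0 * np.percentile(rec, 90, method=_PCTL_INTERP),
                "additional_work_mean": 100.0 * g["additional_work"].mean(),
            }
        )
    return pd.DataFrame(out)


def composite_curves(
    traces: Sequence[ScreeningTrace],
    grid_size: int = 1001,
    percentiles: Sequence[float] = (5, 25, 75, 95),
    histogram_target: float = 0.99,
) -> dict:
    """Composite of normalized gain curves across traces.

    Each curve is normalized to (fraction screened, fraction of
    includes found) and resampled by linear interpolation on a fixed
    grid; the bundle contains the mean and percentile envelopes plus
    the distribution of normalized optimal stopping points for the
    histogram recall target.
    """
    if not traces:
        raise ValueError("need at least one trace")
    grid = np.linspace(0.0, 1.0, grid_size)
    curves = np.empty((len(traces), grid_size))
    opt_positions = []
    for i, tr in enumerate(traces):
        n, r = tr.n_records, tr.n_relevant
        x = np.arange(n + 1) / n
        y = tr.cumulative_includes / r
        curves[i] = np.interp(grid, x, y)
        opt_positions.append(optimal_stop_index(tr, histogram_target) / n)
    return {
        "grid": grid,
        "mean": curves.mean(axis=0),
        "percentiles": {
            p: np.percentile(curves, p, axis=0, method=_PCTL_INTERP)
            for p in percentiles
        },
        "optimal_stop_positions": np.array(opt_positions),
        "histogram_target": histogram_target,
    }
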