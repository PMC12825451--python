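"""Stopping criteria for prioritized screening.

Each criterion is a pure function of a :class:`~tarstop.types.TracePrefix`
(the information available to a reviewer mid-screening) and a
:class:`StoppingConfig`, returning a :class:`CriterionState` with the
criterion's primary statistic and whether it fired at this checkpoint.
Criteria never raise during a sweep: when a required input is absent
(e.g. no score snapshot yet) they return ``triggered=False`` with an
absent value.

The fifteen methods fall into three broad families:

* **label-sequence heuristics** — consecutive-exclude rules
  (HEURISTIC_FIX/FRAC), window precision (BATCHPRECISION), screened-count
  rules (METHOD2399), gain-curve shape detection (KNEE, CURVE_FITTING,
  IPP);
* **score-based recall estimators** — HEURISTIC_SCORES (a.k.a. Quant),
  QUANT_CI, APRIORI, SAL_TAU, S-CAL, HEURISTIC_RANDOM;
* **statistical certification** — CMH's hypergeometric hypothesis test
  and the TM_QBCB target method with its binomial sample-size bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
from scipy import optimize, stats

from .types import TracePrefix

__all__ = [
    "StoppingConfig",
    "CriterionState",
    "ConfigurationError",
    "REGISTRY",
    "METHOD_NAMES",
    "TARGET_AWARE",
    "evaluate_method",
    "hypergeom_cdf",
    "qbcb_sample_size",
]


class ConfigurationError(ValueError):
    """Raised for missing or out-of-domain stopping hyperparameters."""


@dataclass(frozen=True)
class StoppingConfig:
    """Hyperparameters of a stopping criterion.

    Only the fields relevant to ``method`` are read; a field that a
    method requires but that is set to ``None`` raises a
    :class:`ConfigurationError`.

    recall_target
        Target recall tau in (0, 1].
    confidence
        Confidence level c in (0, 1); alpha = 1 - c.
    window
        Window size W (checkpoints for APRIORI, records for
        BATCHPRECISION).
    scaling_factor
        Multiplicative adjustment kappa (METHOD2399, S-CAL, SAL_TAU).
    """

    method: str = ""
    recall_target: float | None = 0.95
    confidence: float | None = 0.95
    window: int | None = 3
    precision_threshold: float | None = 0.05
    consecutive_n: int | None = 100
    consecutive_fraction: float | None = 0.05
    slope_ratio_threshold: float | None = 6.0
    curve_threshold: float | None = 0.02
    poly_degree: int | None = 5
    num_windows: int | None = 10
    scaling_factor: float | None = 1.0
    sample_size: int | None = 50
    n_targets: int | None = None
    normalization: str = "none"

    def __post_init__(self) -> None:
        if self.recall_target is not None and not (0.0 < self.recall_target <= 1.0):
            raise ConfigurationError("recall_target must be in (0, 1]")
        if self.confidence is not None and not (0.0 < self.confidence < 1.0):
            raise ConfigurationError("confidence must be in (0, 1)")
        for name in ("precision_threshold", "consecutive_fraction"):
            v = getattr(self, name)
            if v is not None and not (0.0 < v <= 1.0):
                raise ConfigurationError(f"{name} must be in (0, 1]")
        if self.normalization not in ("none", "minmax", "softmax"):
            raise ConfigurationError(
                f"unknown normalization {self.normalization!r}"
            )

    def require(self, *names: str):
        vals = []
        for name in names:
            v = getattr(self, name)
            if v is None:
                raise ConfigurationError(
                    f"method {self.method or '?'} requires hyperparameter {name!r}"
                )
            vals.append(v)
        return vals[0] if len(vals) == 1 else vals


@dataclass
class CriterionState:
    """Outcome of one criterion evaluation at one checkpoint."""

    triggered: bool
    value: float | None = None
    diagnostics: dict = field(default_factory=dict)


def _not_applicable(**diag) -> CriterionState:
    return CriterionState(triggered=False, value=None, diagnostics=diag)


# ---------------------------------------------------------------------------
# shared numeric kernels


def hypergeom_cdf(k: int, N: int, K: int, n: int) -> float:
    """P(X <= k) for X ~ Hypergeometric(N, K, n).

    N is the population size, K the number of successes in the
    population, n the number of draws.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"hypergeometric parameters out of range: N={N}, K={K}, n={n}")
    return float(stats.hypergeom.cdf(k, N, K, n))


def qbcb_sample_size(recall_target: float, confidence: float) -> int:
    """Smallest target-set size n certifying recall >= tau at confidence c.

    If n relevant records are drawn uniformly from all relevant records
    and screening has found all n of them, then under the hypothesis
    recall < tau the probability of that event is below tau^n; the
    bound requires tau^n <= 1 - c.
    """
    tau, c = recall_target, confidence
    if not (0.0 < tau < 1.0):
        raise ConfigurationError("recall_target must be in (0, 1) for the binomial bound")
    if not (0.0 < c < 1.0):
        raise ConfigurationError("confidence must be in (0, 1)")
    alpha = 1.0 - c
    n = 1
    while tau**n > alpha:
        n += 1
    return n


def _trailing_excludes(labels: np.ndarray) -> int:
    ones = np.flatnonzero(labels == 1)
    if len(ones) == 0:
        return len(labels)
    return len(labels) - int(ones[-1]) - 1


# ---------------------------------------------------------------------------
# statistical certification


def cmh(prefix: TracePrefix, config: StoppingConfig, seed=None) -> CriterionState:
    """Hypergeometric test that the recall target is already met.

    Null hypothesis: at least ``X_min = floor(rho_t (1-tau)/tau) + 1``
    relevant records remain unseen (i.e. the recall target is missed).
    For every candidate start ``s`` the includes observed in positions
    s+1..t are compared against drawing without replacement from the
    remaining population; the reported p-value is the minimum over
    starts, and the criterion fires when it drops below alpha = 1 - c.
    """
    tau, c = config.require("recall_target", "confidence")
    t, N = prefix.t, prefix.N
    labels = np.asarray(prefix.labels)
    rho = int(labels.sum())
    if rho == 0:
        return CriterionState(False, 1.0, {"reason": "no includes yet"})
    x_min = math.floor(rho * (1.0 - tau) / tau) + 1
    if x_min > N - t:
        # fewer unseen records than the smallest violating count: the
        # null is impossible at every start
        return CriterionState(True, 0.0, {"x_min": x_min})
    cum = np.concatenate([[0], np.cumsum(labels)])
    s = np.arange(t)
    n_s = t - s
    k_s = rho - cum[s]
    N_s = N - s
    K_s = x_min + k_s
    p = stats.hypergeom.cdf(k_s, N_s, K_s, n_s)
    value = float(np.min(p))
    return CriterionState(value < 1.0 - c, value, {"x_min": x_min, "argmin_start": int(np.argmin(p))})


def tm_qbcb(
    prefix: TracePrefix,
    config: StoppingConfig,
    seed=None,
    target_set: frozenset[str] | None = None,
) -> CriterionState:
    """Target method: stop once every hidden known-relevant record is seen.

    ``target_set`` is a uniform sample of relevant record ids drawn
    ahead of time (by the evaluation harness); finding all of them
    certifies the recall target at the configured confidence via the
    binomial bound of :func:`qbcb_sample_size`.
    """
    if not target_set:
        return _not_applicable(reason="no target set")
    found = len(target_set & prefix.seen_ids)
    value = found / len(target_set)
    return CriterionState(found == len(target_set), value, {"targets": len(target_set)})


# ---------------------------------------------------------------------------
# score-based recall estimators


def quant(prefix: TracePrefix, config: StoppingConfig, seed=None) -> CriterionState:
    """Score-sum recall estimate (HEURISTIC_SCORES / Quant).

    The expected number of unseen relevant records is the sum of the
    (probability-calibrated) model scores over unseen records; stop
    when rho / (rho + E) reaches the recall target.
    """
    tau = config.require("recall_target")
    scores = prefix.latest_scores
    if scores is None:
        return _not_applicable(reason="no score snapshot")
    rho = prefix.n_includes
    e_hat = float(sum(scores.values()))
    denom = rho + e_hat
    value = rho / denom if denom > 0 else 1.0
    return CriterionState(value >= tau, value, {"expected_unseen": e_hat})


def quant_ci(prefix: TracePrefix, config: StoppingConfig, seed=None) -> CriterionState:
    """Quant with a one-sided upper confidence bound on unseen relevants.

    Treating each unseen score as an independent Bernoulli probability,
    the variance of the unseen-relevant count is sum s(1-s); the
    estimate is inflated by z_c standard deviations before computing
    the recall, making the rule conservative.
    """
    tau, c = config.require("recall_target", "confidence")
    scores = prefix.latest_scores
    if scores is None:
        return _not_applicable(reason="no score snapshot")
    rho = prefix.n_includes
    vals = np.fromiter(scores.values(), dtype=float, count=len(scores))
    e_hat = float(vals.sum())
    var = float((vals * (1.0 - vals)).sum())
    e_up = e_hat + stats.norm.ppf(c) * math.sqrt(var)
    denom = rho + e_up
    value = rho / denom if denom > 0 else 1.0
    return CriterionState(value >= tau, value, {"expected_upper": e_up})


def apriori(prefix: TracePrefix, config: StoppingConfig, seed=None) -> CriterionState:
    """Classifier-predicted-remaining recall.

    The number of unseen records the ranker classifies as includes
    (score >= 0.5) stands in for the remaining relevant records; the
    point condition is rho / (rho + B) >= threshold. The harness
    additionally requires the condition to hold over ``window``
    consecutive checkpoints before stopping.
    """
    tau = config.require("recall_target")
    scores = prefix.latest_scores
    if scores is None:
        return _not_applicable(reason="no score snapshot")
    rho = prefix.n_includes
    b = sum(1 for s in scores.values() if s >= 0.5)
    denom = rho + b
    value = rho / denom if denom > 0 else 0.0
    return CriterionState(value >= tau, value, {"predicted_remaining": b})


def heuristic_random(prefix: TracePrefix, config: StoppingConfig, seed=None) -> CriterionState:
    """Extrapolate total relevants from the initial random sample.

    R_hat = max(rho_t, p_hat * N) with p_hat the inclusion rate in the
    initial sample; never fires when the sample contained no includes.
    """
    tau = config.require("recall_target")
    n0 = prefix.init_size
    if prefix.t < n0:
        return _not_applicable(reason="still inside the initial sample")
    sample_inc = int(np.asarray(prefix.labels[:n0]).sum())
    if sample_inc == 0:
        return _not_applicable(reason="no includes in initial sample")
    rho = prefix.n_includes
    r_hat = max(float(rho), sample_inc / n0 * prefix.N)
    value = rho / r_hat if r_hat > 0 else 0.0
    return CriterionState(value >= tau, value, {"r_hat": r_hat})


def s_cal(prefix: TracePrefix, config: StoppingConfig, seed=None) -> CriterionState:
    """Segment-sampled recall estimate (S-CAL style).

    The prioritized region is partitioned at the retraining boundaries;
    from each segment a capped uniform sub-sample of labels is drawn
    and scaled up to estimate the relevant records seen, summed with
    the exact count from the initial sample and inflated by
    ``scaling_factor``.
    """
    tau, sample_size, kappa = config.require(
        "recall_target", "sample_size", "scaling_factor"
    )
    history = prefix.snapshot_history
    if not history:
        return _not_applicable(reason="no retraining boundaries yet")
    rng = np.random.default_rng(seed)
    labels = np.asarray(prefix.labels)
    n0 = prefix.init_size
    points = sorted({n0, prefix.t} | {s.taken_after for s in history if n0 <= s.taken_after <= prefix.t})
    est = float(labels[:n0].sum())
    for a, b in zip(points[:-1], points[1:]):
        size = b - a
        m = min(sample_size, size)
        if m <= 0:
            continue
        idx = rng.choice(size, size=m, replace=False)
        inc = int(labels[a:b][idx].sum())
        est += inc * size / m
    r_hat = kappa * est
    rho = prefix.n_includes
    if r_hat <= 0:
        return _not_applicable(reason="estimated zero relevant records")
    value = rho / r_hat
    return CriterionState(value >= tau, value, {"r_hat": r_hat})


def _normalize_scores(vals: np.ndarray, how: str) -> np.ndarray:
    if how == "none":
        return vals
    if how == "minmax":
        lo, hi = vals.min(), vals.max()
        if hi <= lo:
            return np.zeros_like(vals)
        return (vals - lo) / (hi - lo)
    if how == "softmax":
        z = np.exp(vals - vals.max())
        return z / z.sum()
    raise ConfigurationError(f"unknown normalization {how!r}")


def sal_tau(prefix: TracePrefix, config: StoppingConfig, seed=None) -> CriterionState:
    """Score-mass recall estimate gated by its rate of change (SAL-tau).

    The (normalized) score mass over unseen records at the two most
    recent snapshots gives both a recall estimate
    rho / (rho + kappa * M_j) and a relative rate of change; the rule
    fires when the estimate reaches the target while the score mass has
    stabilized (relative change below alpha = 1 - c).
    """
    tau, c, kappa = config.require("recall_target", "confidence", "scaling_factor")
    history = prefix.snapshot_history
    if len(history) < 2:
        return _not_applicable(reason="fewer than two snapshots")
    prev, cur = history[-2], history[-1]

    def mass(snapshot) -> float:
        if not snapshot.scores:
            return 0.0
        vals = np.fromiter(snapshot.scores.values(), dtype=float, count=len(snapshot.scores))
        return float(_normalize_scores(vals, config.normalization).sum())

    m_prev, m_cur = mass(prev), mass(cur)
    delta = (m_prev - m_cur) / max(m_prev, 1e-9)
    rho = prefix.n_includes
    denom = rho + kappa * m_cur
    value = rho / denom if denom > 0 else 0.0
    return CriterionState(
        value >= tau and delta < 1.0 - c, value, {"score_mass": m_cur, "delta": delta}
    )


# ---------------------------------------------------------------------------
# label-sequence heuristics and curve-shape rules


def heuristic_fix(prefix: TracePrefix, config: StoppingConfig, seed=None) -> CriterionState:
    """Fixed number of consecutive excludes."""
    n = config.require("consecutive_n")
    run = _trailing_excludes(np.asarray(prefix.labels))
    return CriterionState(run >= n, float(run), {"threshold": n})


def heuristic_frac(prefix: TracePrefix, config: StoppingConfig, seed=None) -> CriterionState:
    """Consecutive excludes as a fraction of the dataset size."""
    frac = config.require("consecutive_fraction")
    n = math.ceil(frac * prefix.N)
    run = _trailing_excludes(np.asarray(prefix.labels))
    return CriterionState(run >= n, float(run), {"threshold": n})


def batch_precision(prefix: TracePrefix, config: StoppingConfig, seed=None) -> CriterionState:
    """Stop when the inclusion rate of the last W screened records
    falls below the precision threshold (marginal precision)."""
    thresh, w = config.require("precision_threshold", "window")
    if prefix.t < prefix.init_size + w:
        return _not_applicable(reason="window not yet past the initial sample")
    recent = np.asarray(prefix.labels[-w:])
    value = float(recent.sum()) / w
    return CriterionState(value < thresh, value, {"window": w})


def method2399(prefix: TracePrefix, config: StoppingConfig, seed=None) -> CriterionState:
    """Fire once t - kappa * rho_t reaches 2399 screened records."""
    kappa = config.require("scaling_factor")
    value = prefix.t - kappa * prefix.n_includes
    return CriterionState(value >= 2399, float(value), {})


def knee(prefix: TracePrefix, config: StoppingConfig, seed=None) -> CriterionState:
    """Kneedle-style elbow detection on the gain curve.

    The curve is normalized to the unit square and smoothed with a
    polynomial fit; the knee is the point of maximum distance above the
    diagonal. A minimum distance guards against degenerate (diagonal)
    curves; the rule fires when the slope before the knee exceeds the
    slope after it by the configured ratio.
    """
    ratio_thresh, curve_thresh, degree = config.require(
        "slope_ratio_threshold", "curve_threshold", "poly_degree"
    )
    t = prefix.t
    labels = np.asarray(prefix.labels)
    rho = int(labels.sum())
    if rho == 0 or t < max(degree + 2, 4):
        return _not_applicable(reason="curve too short or empty")
    x = np.arange(1, t + 1) / t
    cum = np.cumsum(labels)
    y = cum / rho
    with np.errstate(all="ignore"):
        coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
        y_hat = np.polynomial.polynomial.polyval(x, coeffs)
    dist = y_hat - x
    k = int(np.argmax(dist))
    max_dist = float(dist[k])
    if max_dist < curve_thresh:
        return _not_applicable(max_distance=max_dist)
    x_k = k + 1  # knee position in record units
    if x_k >= t:
        return _not_applicable(reason="knee at the end of the curve")
    rho_k = int(cum[k])
    slope_pre = rho_k / x_k
    slope_post = (rho - rho_k + 1) / (t - x_k)
    value = slope_pre / slope_post
    return CriterionState(
        value >= ratio_thresh, value, {"knee": x_k, "max_distance": max_dist}
    )


def curve_fitting(prefix: TracePrefix, config: StoppingConfig, seed=None) -> CriterionState:
    """Negative-exponential fit of the gain curve.

    The cumulative curve is averaged within ``num_windows`` equal
    windows and y = a (1 - e^(-b x)) is fitted by nonlinear least
    squares; a one-sided lower recall bound rho / (a + z_c SE(a)) must
    reach the target, with a convergent fit, b > 0 and a <= N.
    """
    tau, c, n_win = config.require("recall_target", "confidence", "num_windows")
    t = prefix.t
    labels = np.asarray(prefix.labels)
    rho = int(labels.sum())
    if rho == 0 or t < 2 * n_win:
        return _not_applicable(reason="curve too short or empty")
    cum = np.cumsum(labels).astype(float)
    pos = np.arange(1, t + 1, dtype=float)
    edges = np.linspace(0, t, n_win + 1).astype(int)
    x = np.array([pos[a:b].mean() for a, b in zip(edges[:-1], edges[1:]) if b > a])
    y = np.array([cum[a:b].mean() for a, b in zip(edges[:-1], edges[1:]) if b > a])

    a0 = max(rho / tau, 1.0)
    frac = min(max(1.0 - y[-1] / a0, 1e-6), 1.0 - 1e-9)
    b0 = max(-math.log(frac) / x[-1], 1e-6)
    model = lambda xx, a, b: a * (1.0 - np.exp(-b * xx))
    try:
        with np.errstate(all="ignore"):
            popt, pcov = optimize.curve_fit(
                model, x, y, p0=(a0, b0), maxfev=5000,
                bounds=((1e-9, 1e-12), (np.inf, np.inf)),
            )
    except (RuntimeError, ValueError):
        return _not_applicable(reason="fit did not converge")
    a_hat, b_hat = float(popt[0]), float(popt[1])
    se_a = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else math.inf
    if not math.isfinite(se_a):
        return _not_applicable(a_hat=a_hat, reason="unstable fit covariance")
    bound = rho / (a_hat + stats.norm.ppf(c) * se_a) if a_hat + stats.norm.ppf(c) * se_a > 0 else 0.0
    triggered = bound >= tau and b_hat > 1e-8 and a_hat <= prefix.N
    return CriterionState(triggered, bound, {"a_hat": a_hat, "b_hat": b_hat, "se_a": se_a})


def ipp(prefix: TracePrefix, config: StoppingConfig, seed=None) -> CriterionState:
    """Inhomogeneous Poisson-process estimate of remaining relevants.

    Include occurrences in the prioritized region are binned into
    ``num_windows`` windows; an exponentially decaying per-record rate
    lambda(x) = a e^(-b x) is fitted to the window rates, the expected
    remaining count mu is its integral from t to N, and the rule fires
    when P(X <= allowed_missed | mu) reaches the confidence level.
    """
    tau, c, n_win = config.require("recall_target", "confidence", "num_windows")
    t, n0 = prefix.t, prefix.init_size
    if t <= n0 + n_win:
        return _not_applicable(reason="prioritized region too short")
    labels = np.asarray(prefix.labels)
    rho = int(labels.sum())
    if rho == 0:
        return _not_applicable(reason="no includes yet")
    positions = np.flatnonzero(labels[n0:]) + n0 + 1  # 1-based include positions
    edges = np.linspace(n0, t, n_win + 1)
    counts, _ = np.histogram(positions, bins=edges)
    widths = np.diff(edges)
    rates = counts / widths
    x = 0.5 * (edges[:-1] + edges[1:])
    if counts.sum() == 0:
        return _not_applicable(reason="no includes in the prioritized region")
    model = lambda xx, a, b: a * np.exp(-b * xx)
    r0 = max(rates[0], 1e-6)
    try:
        with np.errstate(all="ignore"):
            popt, _ = optimize.curve_fit(
                model, x, rates, p0=(r0, 1e-3), maxfev=5000,
                bounds=((1e-12, 1e-12), (np.inf, np.inf)),
            )
    except (RuntimeError, ValueError):
        return _not_applicable(reason="rate fit did not converge")
    a_hat, b_hat = float(popt[0]), float(popt[1])
    if b_hat <= 1e-8:
        return _not_applicable(reason="flat rate (no decay)")
    mu = (a_hat / b_hat) * (math.exp(-b_hat * t) - math.exp(-b_hat * prefix.N))
    allowed = math.floor(rho * (1.0 - tau) / tau)
    value = float(stats.poisson.cdf(allowed, mu))
    return CriterionState(
        value >= c, value,
        {"mu": mu, "allowed_missed": allowed, "a_hat": a_hat, "b_hat": b_hat},
    )


# ---------------------------------------------------------------------------
# registry

REGISTRY: dict[str, Callable[..., CriterionState]] = {
    "APRIORI": apriori,
    "BATCHPRECISION": batch_precision,
    "CMH": cmh,
    "CURVE_FITTING": curve_fitting,
    "HEURISTIC_FIX": heuristic_fix,
    "HEURISTIC_FRAC": heuristic_frac,
    "HEURISTIC_RANDOM": heuristic_random,
    "HEURISTIC_SCORES": quant,
    "IPP": ipp,
    "KNEE": knee,
    "METHOD2399": method2399,
    "QUANT_CI": quant_ci,
    "S-CAL": s_cal,
    "SAL_TAU": sal_tau,
    "TM_QBCB": tm_qbcb,
}

METHOD_NAMES = tuple(sorted(REGISTRY))

#: methods whose stopping rule is parameterized by a recall target /
#: threshold of their own (evaluated against that target); the rest are
#: target-agnostic and are evaluated against a grid of reference targets
TARGET_AWARE = frozenset(
    {
        "APRIORI",
        "CMH",
        "CURVE_FITTING",
        "HEURISTIC_RANDOM",
        "HEURISTIC_SCORES",
        "IPP",
        "QUANT_CI",
        "S-CAL",
        "SAL_TAU",
        "TM_QBCB",
    }
)


def evaluate_method(
    name: str,
    prefix: TracePrefix,
    config: StoppingConfig,
    seed=None,
    target_set: frozenset[str] | None = None,
) -> CriterionState:
    """Evaluate one registered criterion at one checkpoint."""
    try:
        fn = REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown stopping method {name!r}; known: {', '.join(METHOD_NAMES)}"
        ) from None
    if name == "TM_QBCB":
        return fn(prefix, config, seed=seed, target_set=target_set)
    return fn(prefix, config, seed=seed)
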