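"""Stopping criteria: examples, oracles and invariants."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from tarstop.evaluation import apply_schedule
from tarstop.stopping import (
    ConfigurationError,
    REGISTRY,
    StoppingConfig,
    apriori,
    batch_precision,
    cmh,
    curve_fitting,
    evaluate_method,
    heuristic_fix,
    heuristic_frac,
    heuristic_random,
    hypergeom_cdf,
    ipp,
    knee,
    method2399,
    qbcb_sample_size,
    quant,
    quant_ci,
    s_cal,
    sal_tau,
    tm_qbcb,
)
from tarstop.synthetic import TraceParams, generate_trace
from tarstop.types import ScoreSnapshot

from conftest import prefix_with_scores, trace_from_labels


def cfg(**kw):
    return StoppingConfig(**kw)


def exact_hypergeom_cdf(k, N, K, n):
    """Exact rational enumeration oracle."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for j in range(max(0, n + K - N), min(k, n, K) + 1):
        total += Fraction(math.comb(K, j) * math.comb(N - K, n - j), denom)
    return total


class TestHypergeomCdf:
    def test_hand_enumeration(self):
        # [C(4,0)C(6,3) + C(4,1)C(6,2)] / C(10,3) = 80/120
        assert hypergeom_cdf(1, 10, 4, 3) == pytest.approx(2 / 3, abs=1e-12)

    def test_cmh_component_example(self):
        # P(X <= 0) with N=20, K=3, n=10 = C(17,10)/C(20,10)
        assert hypergeom_cdf(0, 20, 3, 10) == pytest.approx(19448 / 184756, abs=1e-12)

    def test_full_support(self):
        assert hypergeom_cdf(4, 10, 4, 7) == 1.0
        assert hypergeom_cdf(12, 10, 4, 7) == 1.0

    def test_empty_support(self):
        assert hypergeom_cdf(0, 10, 8, 7) == 0.0  # k < n + K - N = 5
        assert hypergeom_cdf(-1, 10, 2, 3) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_cdf(1, 10, 11, 3)

    @pytest.mark.parametrize("N,K,n", [(7, 3, 4), (15, 6, 9), (25, 10, 13), (30, 29, 2)])
    def test_matches_rational_oracle(self, N, K, n):
        for k in range(-1, n + 2):
            assert hypergeom_cdf(k, N, K, n) == pytest.approx(
                float(exact_hypergeom_cdf(k, N, K, n)), abs=1e-12
            )


class TestCMH:
    def test_no_includes_yet(self):
        state = cmh(trace_from_labels([0] * 30).prefix(20),
                    cfg(method="CMH", recall_target=0.8, confidence=0.95))
        assert state.value == 1.0 and not state.triggered

    def test_all_sampled_relevant_gives_p_one(self):
        # k_s = n_s at every start: CDF at maximum support
        tr = trace_from_labels([1] * 5 + [0] * 15)
        state = cmh(tr.prefix(5), cfg(method="CMH", recall_target=0.8, confidence=0.95))
        assert state.value == pytest.approx(1.0)

    def test_component_p_value_against_oracle(self):
        # trace engineered so one start reproduces a hand-enumerable CDF:
        # t=10 all excludes after 0 includes won't work (rho=0 guard), so
        # use rho=3 at the front, pure-exclude tail; verify min_s p_s
        # against direct enumeration over all starts
        labels = [1, 1, 1] + [0] * 12
        tr = trace_from_labels(labels)
        tau, t, N = 0.8, 15, 15
        state = cmh(tr.prefix(t), cfg(method="CMH", recall_target=tau, confidence=0.95))
        rho = 3
        x_min = math.floor(rho * (1 - tau) / tau) + 1
        cum = np.concatenate([[0], np.cumsum(labels)])
        expected = min(
            float(exact_hypergeom_cdf(
                int(rho - cum[s]), N - s, x_min + int(rho - cum[s]), t - s))
            for s in range(t)
        )
        assert state.value == pytest.approx(expected, abs=1e-12)

    def test_impossible_null_triggers_with_p_zero(self):
        # fewer unseen records than the smallest violating count
        labels = [1] * 10 + [0] * 2
        tr = trace_from_labels(labels + [0])
        state = cmh(tr.prefix(12), cfg(method="CMH", recall_target=0.8, confidence=0.95))
        # x_min = floor(10*0.25)+1 = 3 > N - t = 1
        assert state.triggered and state.value == 0.0

    def test_p_value_monotone_under_trailing_excludes(self):
        rng = np.random.default_rng(4)
        config = cfg(method="CMH", recall_target=0.9, confidence=0.95)
        for _ in range(25):
            n = int(rng.integers(6, 15))
            labels = rng.integers(0, 2, size=n).tolist() + [0]
            if sum(labels) == 0:
                labels[0] = 1
            tr = trace_from_labels(labels)
            p_before = cmh(tr.prefix(n), config).value
            p_after = cmh(tr.prefix(n + 1), config).value
            assert p_after <= p_before + 1e-12


class TestQuantFamily:
    def test_quant_direct_sum(self):
        p = prefix_with_scores([1] * 8, [0.5, 0.5, 1.0])
        state = quant(p, cfg(method="HEURISTIC_SCORES", recall_target=0.9))
        assert state.value == pytest.approx(0.8)

    def test_quant_no_unseen_records(self):
        p = prefix_with_scores([1, 0, 1], [])
        state = quant(p, cfg(method="HEURISTIC_SCORES", recall_target=0.9))
        assert state.value == 1.0 and state.triggered

    def test_quant_all_zero_scores(self):
        p = prefix_with_scores([1, 1], [0.0, 0.0, 0.0])
        assert quant(p, cfg(recall_target=0.9)).value == 1.0

    def test_quant_not_applicable_without_scores(self):
        p = trace_from_labels([1, 0, 1, 0]).prefix(3)
        state = quant(p, cfg(recall_target=0.9))
        assert not state.triggered and state.value is None

    def test_quant_ci_closed_form(self):
        # E=2, V=1, E_up = 2 + 1.6449, value = 8 / 11.6449
        p = prefix_with_scores([1] * 8, [0.5] * 4)
        state = quant_ci(p, cfg(recall_target=0.9, confidence=0.95))
        z = stats.norm.ppf(0.95)
        assert state.value == pytest.approx(8 / (8 + 2 + z), abs=1e-9)
        assert state.value == pytest.approx(0.687, abs=5e-4)

    def test_quant_ci_equals_quant_for_degenerate_scores(self):
        p = prefix_with_scores([1] * 5, [0.0, 1.0, 1.0, 0.0])
        a = quant(p, cfg(recall_target=0.9)).value
        b = quant_ci(p, cfg(recall_target=0.9, confidence=0.95)).value
        assert a == pytest.approx(b)

    def test_quant_ci_never_exceeds_quant(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            seen = rng.integers(0, 2, size=int(rng.integers(2, 20)))
            scores = rng.random(int(rng.integers(1, 30)))
            p = prefix_with_scores(seen, scores)
            q = quant(p, cfg(recall_target=0.9)).value
            qc = quant_ci(p, cfg(recall_target=0.9, confidence=0.95)).value
            assert qc <= q + 1e-12


class TestCurveFitting:
    def _exponential_labels(self, a, b, t):
        x = np.arange(t + 1)
        return np.diff(np.round(a * (1 - np.exp(-b * x)))).astype(int)

    def test_noiseless_recovery_within_one_percent(self):
        labels = self._exponential_labels(100, 0.01, 1500)
        tr = trace_from_labels(labels)
        state = curve_fitting(
            tr.prefix(1500), cfg(recall_target=0.95, confidence=0.95, num_windows=10))
        a_hat = state.diagnostics["a_hat"]
        assert abs(a_hat - 100) / 100 < 0.01
        rho = int(labels.sum())
        # recall estimate is rho_t / a_hat
        assert rho / a_hat == pytest.approx(1.0, abs=0.01)

    def test_linear_curve_never_triggers(self):
        labels = np.zeros(1000, dtype=int)
        labels[::10] = 1
        state = curve_fitting(
            trace_from_labels(labels).prefix(1000),
            cfg(recall_target=0.95, confidence=0.95, num_windows=10))
        assert not state.triggered

    def test_noisy_recovery_within_ten_percent(self):
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed + 3)
            labels = (rng.random(1500) < np.exp(-0.01 * np.arange(1, 1501))).astype(int)
            state = curve_fitting(
                trace_from_labels(labels).prefix(1500),
                cfg(recall_target=0.95, confidence=0.95, num_windows=20))
            a_hat = state.diagnostics.get("a_hat")
            errs.append(abs(a_hat - 100) / 100 if a_hat else 1.0)
        assert np.mean(errs) < 0.10


class TestConsecutiveExcludes:
    def test_run_resets_on_include(self):
        p = trace_from_labels([0, 0, 0, 1]).prefix(4)
        assert heuristic_fix(p, cfg(consecutive_n=2)).value == 0.0

    def test_long_run_triggers(self):
        p = trace_from_labels([1] + [0] * 200).prefix(201)
        state = heuristic_fix(p, cfg(consecutive_n=100))
        assert state.triggered and state.value == 200

    def test_frac_threshold_arithmetic(self):
        p = trace_from_labels([1] + [0] * 1999).prefix(500)
        state = heuristic_frac(p, cfg(consecutive_fraction=0.05))
        assert state.diagnostics["threshold"] == 100  # ceil(0.05 * 2000)

    def test_frac_one_requires_all_excludes(self):
        tr = trace_from_labels([1] + [0] * 49)
        state = heuristic_frac(tr.prefix(50), cfg(consecutive_fraction=1.0))
        assert not state.triggered

    def test_frac_equals_fix_at_ceiling(self):
        # paired sweeps on 10 synthetic traces
        for seed in range(10):
            tr = generate_trace(TraceParams(N=600, R=30, init_size=100,
                                            seed=seed, snapshot_interval=None))
            n = math.ceil(0.05 * tr.n_records)
            d_frac = apply_schedule(tr, "HEURISTIC_FRAC",
                                    cfg(method="HEURISTIC_FRAC", consecutive_fraction=0.05))
            d_fix = apply_schedule(tr, "HEURISTIC_FIX",
                                   cfg(method="HEURISTIC_FIX", consecutive_n=n))
            assert d_frac.stop_index == d_fix.stop_index


class TestHeuristicRandom:
    def test_extrapolation_arithmetic(self):
        # 50 includes in a 500-record sample of 1000 -> R_hat = 100
        labels = np.zeros(1000, dtype=int)
        labels[:50] = 1  # the 50 includes all inside the initial sample
        labels[500:540] = 1
        tr = trace_from_labels(labels, init_size=500)
        state = heuristic_random(tr.prefix(900), cfg(recall_target=0.9))
        assert state.diagnostics["r_hat"] == pytest.approx(100.0)
        assert state.triggered  # rho = 90 >= 0.9 * 100

    def test_zero_includes_in_sample_never_triggers(self):
        labels = np.zeros(200, dtype=int)
        labels[100:110] = 1
        tr = trace_from_labels(labels, init_size=100)
        state = heuristic_random(tr.prefix(150), cfg(recall_target=0.5))
        assert not state.triggered and state.value is None

    def test_value_clamped_when_rho_exceeds_extrapolation(self):
        labels = np.zeros(400, dtype=int)
        labels[0] = 1  # p_hat = 1/100 -> p_hat * N = 4
        labels[100:110] = 1  # rho grows past 4
        tr = trace_from_labels(labels, init_size=100)
        state = heuristic_random(tr.prefix(110), cfg(recall_target=0.99))
        assert state.value == pytest.approx(1.0)


class TestBatchPrecision:
    def test_low_window_precision_triggers(self):
        labels = [1] * 20 + [0] * 98 + [1, 0]
        tr = trace_from_labels(labels, init_size=10)
        state = batch_precision(tr.prefix(120),
                                cfg(precision_threshold=0.05, window=100))
        assert state.value == pytest.approx(0.01)
        assert state.triggered

    def test_warm_up_guard(self):
        tr = trace_from_labels([0] * 120, init_size=50)
        state = batch_precision(tr.prefix(60), cfg(precision_threshold=0.05, window=100))
        assert not state.triggered and state.value is None

    def test_window_values_match_rolling_oracle(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(0, 2, size=300)
        tr = trace_from_labels(labels, init_size=20)
        w = 50
        kernel = np.ones(w) / w
        rolling = np.convolve(labels, kernel, mode="valid")  # rolling-mean oracle
        for t in range(100, 301, 37):
            state = batch_precision(tr.prefix(t), cfg(precision_threshold=0.5, window=w))
            assert state.value == pytest.approx(rolling[t - w])


class TestApriori:
    def test_all_unseen_predicted_irrelevant(self):
        p = prefix_with_scores([1, 0, 1], [0.1, 0.4, 0.2])
        state = apriori(p, cfg(recall_target=0.9))
        assert state.value == 1.0

    def test_predicted_remaining_equals_found(self):
        p = prefix_with_scores([1] * 3, [0.9, 0.8, 0.6])
        state = apriori(p, cfg(recall_target=0.9))
        assert state.value == pytest.approx(0.5)

    def test_sustained_window_rule(self):
        # value crosses the threshold at exactly two checkpoints, then
        # dips: with window 3 the criterion must not fire; with a third
        # consecutive crossing it fires at that checkpoint
        def build(n_high):
            n, interval = 100, 10
            labels = np.zeros(n, dtype=int)
            labels[:5] = 1
            snaps = []
            high_at = {20 + 10 * i for i in range(n_high)}
            for it, ta in enumerate(range(10, n, interval), 1):
                score = 0.9 if ta not in high_at else 0.1  # 0.1 -> B=0 -> value 1
                snaps.append(ScoreSnapshot(
                    iteration=it, taken_after=ta,
                    scores={f"x{j}": score for j in range(ta, n)}))
            return trace_from_labels(labels, init_size=10, snapshots=snaps)

        config = cfg(method="APRIORI", recall_target=0.9, window=3)
        two = apply_schedule(build(2), "APRIORI", config, interval=10)
        assert two.stop_index is None
        three = apply_schedule(build(3), "APRIORI", config, interval=10)
        assert three.stop_index == 40


class TestKnee:
    def test_perfect_elbow_triggers_and_matches_closed_form(self):
        r = 60
        labels = np.array([1] * r + [0] * 540)
        tr = trace_from_labels(labels)
        state = knee(tr.prefix(600),
                     cfg(slope_ratio_threshold=6.0, curve_threshold=0.02, poly_degree=5))
        assert state.triggered
        x_k = state.diagnostics["knee"]
        cum = np.cumsum(labels)
        rho_k, rho_t, t = cum[x_k - 1], cum[-1], 600
        expected = (rho_k / x_k) * (t - x_k) / (rho_t - rho_k + 1)
        assert state.value == pytest.approx(expected)

    def test_diagonal_curve_never_triggers(self):
        labels = np.zeros(400, dtype=int)
        labels[::4] = 1  # exact constant slope
        state = knee(trace_from_labels(labels).prefix(400),
                     cfg(slope_ratio_threshold=2.0, curve_threshold=0.02, poly_degree=3))
        assert not state.triggered

    def test_argmax_matches_grid_oracle(self):
        rng = np.random.default_rng(12)
        labels = (rng.random(500) < np.linspace(0.5, 0.01, 500)).astype(int)
        tr = trace_from_labels(labels)
        t, degree = 500, 5
        state = knee(tr.prefix(t),
                     cfg(slope_ratio_threshold=1e9, curve_threshold=0.0, poly_degree=degree))
        # brute-force grid oracle over all checkpoints
        x = np.arange(1, t + 1) / t
        y = np.cumsum(labels) / labels.sum()
        coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
        dist = np.polynomial.polynomial.polyval(x, coeffs) - x
        assert state.diagnostics["knee"] == int(np.argmax(dist)) + 1


class TestMethod2399:
    def test_small_dataset_never_triggers(self):
        tr = trace_from_labels([1] * 10 + [0] * 990, init_size=100)
        d = apply_schedule(tr, "METHOD2399", cfg(method="METHOD2399", scaling_factor=1.0))
        assert d.stop_index is None

    def test_threshold_arithmetic(self):
        labels = np.zeros(3000, dtype=int)
        labels[:100] = 1
        tr = trace_from_labels(labels)
        assert not method2399(tr.prefix(2498), cfg(scaling_factor=1.0)).triggered
        assert method2399(tr.prefix(2499), cfg(scaling_factor=1.0)).triggered

    def test_zero_factor_ignores_includes(self):
        labels = np.ones(2500, dtype=int)
        tr = trace_from_labels(labels[:2400].tolist() + [0] * 100)
        assert method2399(tr.prefix(2399), cfg(scaling_factor=0.0)).triggered


class TestSCal:
    def _trace(self, seed=0):
        return generate_trace(TraceParams(N=900, R=60, init_size=150,
                                          snapshot_interval=100, seed=seed))

    def test_exhaustive_sampling_recovers_exact_count(self):
        tr = self._trace()
        state = s_cal(tr.prefix(600),
                      cfg(recall_target=0.9, sample_size=10_000, scaling_factor=1.0),
                      seed=1)
        assert state.value == pytest.approx(1.0)

    def test_scaling_factor_deflates_recall(self):
        tr = self._trace()
        state = s_cal(tr.prefix(600),
                      cfg(recall_target=0.9, sample_size=10_000, scaling_factor=1.05),
                      seed=1)
        assert state.value == pytest.approx(1 / 1.05, abs=1e-9)

    def test_estimator_unbiased_over_seeded_draws(self):
        tr = self._trace(seed=5)
        t = 650
        true_seen = int(tr.cumulative_includes[t])
        estimates = []
        for s in range(500):
            state = s_cal(tr.prefix(t),
                          cfg(recall_target=0.9, sample_size=20, scaling_factor=1.0),
                          seed=s)
            estimates.append(state.diagnostics["r_hat"])
        assert np.mean(estimates) == pytest.approx(true_seen, rel=0.02)

    def test_purity_same_seed_same_state(self):
        tr = self._trace()
        config = cfg(recall_target=0.9, sample_size=5, scaling_factor=1.0)
        a = s_cal(tr.prefix(600), config, seed=42)
        b = s_cal(tr.prefix(600), config, seed=42)
        assert a.value == b.value and a.triggered == b.triggered


class TestSalTau:
    def _prefix(self, scores_a, scores_b, seen=(1, 1, 0)):
        n = len(seen) + len(scores_b)
        labels = np.zeros(n, dtype=int)
        labels[: len(seen)] = seen
        snaps = [
            ScoreSnapshot(iteration=1, taken_after=len(seen),
                          scores={f"x{len(seen)+i}": s for i, s in enumerate(scores_a)}),
            ScoreSnapshot(iteration=2, taken_after=len(seen),
                          scores={f"x{len(seen)+i}": s for i, s in enumerate(scores_b)}),
        ]
        tr = trace_from_labels(labels, snapshots=snaps)
        return tr.prefix(len(seen))

    def test_identical_snapshots_zero_delta(self):
        p = self._prefix([0.5, 0.5], [0.5, 0.5])
        state = sal_tau(p, cfg(recall_target=0.99, confidence=0.95, scaling_factor=1.0))
        assert state.diagnostics["delta"] == 0.0

    def test_zero_mass_gives_full_recall(self):
        p = self._prefix([0.5, 0.5], [0.0, 0.0])
        state = sal_tau(p, cfg(recall_target=0.99, confidence=0.95, scaling_factor=1.0))
        assert state.value == 1.0

    def test_minmax_of_constant_scores_is_zero_mass(self):
        p = self._prefix([0.7, 0.7], [0.7, 0.7])
        state = sal_tau(p, cfg(recall_target=0.99, confidence=0.95,
                               scaling_factor=1.0, normalization="minmax"))
        assert state.diagnostics["score_mass"] == 0.0

    def test_single_snapshot_not_applicable(self):
        snap = ScoreSnapshot(iteration=1, taken_after=2, scores={"x2": 0.5})
        tr = trace_from_labels([1, 0, 0], snapshots=[snap])
        state = sal_tau(tr.prefix(2), cfg(recall_target=0.9, confidence=0.95,
                                          scaling_factor=1.0))
        assert not state.triggered and state.value is None


class TestIPP:
    def _decaying_trace(self, a=0.2, b=0.002, n=2000):
        x = np.arange(1, n + 1)
        cum_rate = np.cumsum(a * np.exp(-b * x))
        labels = np.diff(np.floor(np.concatenate([[0], cum_rate]))).astype(int)
        return trace_from_labels(labels, init_size=1)

    def test_recovers_decaying_rate(self):
        tr = self._decaying_trace()
        state = ipp(tr.prefix(2000), cfg(recall_target=0.95, confidence=0.95,
                                         num_windows=20))
        assert state.diagnostics["a_hat"] == pytest.approx(0.2, rel=0.02)
        assert state.diagnostics["b_hat"] == pytest.approx(0.002, rel=0.02)

    def test_exhausted_rate_triggers(self):
        # evaluating at the end: expected remaining mu ~ 0, Poisson CDF = 1
        tr = self._decaying_trace()
        state = ipp(tr.prefix(2000), cfg(recall_target=0.95, confidence=0.99,
                                         num_windows=20))
        assert state.value == pytest.approx(1.0) and state.triggered

    def test_flat_rate_not_applicable(self):
        labels = np.zeros(1000, dtype=int)
        labels[::20] = 1
        tr = trace_from_labels(labels, init_size=1)
        state = ipp(tr.prefix(1000), cfg(recall_target=0.95, confidence=0.95,
                                         num_windows=10))
        assert not state.triggered and state.value is None


class TestQbcbSampleSize:
    def test_standard_bound_values(self):
        assert qbcb_sample_size(0.95, 0.95) == 59
        assert qbcb_sample_size(0.8, 0.95) == 14

    def test_tiny_confidence_needs_one_record(self):
        assert qbcb_sample_size(0.5, 1e-9) == 1

    @pytest.mark.parametrize("tau,c", [(0.7, 0.9), (0.9, 0.99), (0.99, 0.5)])
    def test_minimality(self, tau, c):
        n = qbcb_sample_size(tau, c)
        assert tau**n <= 1 - c < tau ** (n - 1) if n > 1 else tau**n <= 1 - c


class TestTmQbcb:
    def test_fires_when_last_target_screened(self):
        labels = np.zeros(60, dtype=int)
        labels[[3, 10, 41]] = 1
        tr = trace_from_labels(labels, init_size=5)
        targets = frozenset({"x3", "x10", "x41"})
        config = cfg(recall_target=0.8, confidence=0.95)
        assert not tm_qbcb(tr.prefix(41), config, target_set=targets).triggered
        state = tm_qbcb(tr.prefix(42), config, target_set=targets)
        assert state.triggered and state.value == 1.0

    def test_single_target(self):
        labels = np.zeros(20, dtype=int)
        labels[7] = 1
        tr = trace_from_labels(labels)
        assert tm_qbcb(tr.prefix(8), cfg(), target_set=frozenset({"x7"})).triggered

    def test_coverage_of_binomial_bound(self):
        # over 200 seeded synthetic traces at tau=0.8, c=0.95, the rule
        # stops below the target recall in at most 5% of runs
        misses = 0
        n_runs = 200
        for seed in range(n_runs):
            tr = generate_trace(TraceParams(N=600, R=60, init_size=100,
                                            seed=seed, snapshot_interval=None))
            config = cfg(method="TM_QBCB", recall_target=0.8, confidence=0.95)
            d = apply_schedule(tr, "TM_QBCB", config, interval=15, seed=seed)
            t_stop = d.stop_index if d.stop_index is not None else tr.n_records
            recall = tr.cumulative_includes[t_stop] / tr.n_relevant
            misses += recall < 0.8
        assert misses / n_runs <= 0.05


class TestSweepRobustness:
    def test_missing_required_hyperparameter_raises(self):
        p = trace_from_labels([1, 0, 1]).prefix(3)
        with pytest.raises(ConfigurationError, match="recall_target"):
            cmh(p, cfg(method="CMH", recall_target=None, confidence=0.95))

    def test_invalid_domain_rejected(self):
        with pytest.raises(ConfigurationError):
            cfg(recall_target=1.5)
        with pytest.raises(ConfigurationError):
            cfg(normalization="zscore")

    @pytest.mark.parametrize("with_scores", [True, False])
    def test_every_method_handles_sparse_inputs(self, with_scores):
        # no method may raise during a sweep, even with no includes,
        # no snapshots, or a bare two-record prefix
        if with_scores:
            prefixes = [prefix_with_scores([0, 0], [0.2, 0.8]),
                        prefix_with_scores([1], [0.5])]
        else:
            prefixes = [trace_from_labels([0, 0, 0]).prefix(2),
                        trace_from_labels([1, 0]).prefix(1)]
        for name in REGISTRY:
            for p in prefixes:
                state = evaluate_method(name, p, cfg(method=name), seed=0,
                                        target_set=frozenset({"x0"}))
                assert state.triggered in (True, False)
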