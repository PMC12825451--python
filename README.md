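# tarstop

Simulation and evaluation of **stopping criteria for prioritized
screening** in systematic reviews and maps.

## The problem

In technology-assisted review (TAR), a ranking model trained on prior
include/exclude decisions continuously reorders the unscreened records
so that relevant ones are seen first. The work savings this promises
only materialize with a reliable rule for *when it is safe to stop
screening* — i.e. a stopping criterion that certifies, from the
screening history and (optionally) the model's scores, that a recall
target τ has been reached. Choosing such a rule badly either misses
relevant records or forfeits the savings.

`tarstop` is an evaluation framework for such rules. It decouples the
two mechanisms of TAR:

1. a **priority-ranking simulator** that replays a fully labeled
   corpus through an initial random sample and adaptive retraining
   batches (TF-IDF features; logistic-regression, linear-SVM, SGD and
   gradient-boosting families; seeded hyperparameter search with
   cross-validated recall selection), producing a complete *screening
   trace* with score snapshots at every retraining — no stopping;
2. a library of **fifteen stopping criteria** — consecutive-exclude
   heuristics, window precision, gain-curve knee detection,
   negative-exponential curve fitting, Poisson-process rate modelling,
   score-sum recall estimators with and without confidence intervals,
   segment-sampled estimation, a hypergeometric hypothesis test (CMH)
   and a hidden-target certification method (TM_QBCB) — replayed over
   traces at fixed checkpoints (every 15 records by default).

Each stop decision is scored against the theoretically optimal
stopping point t\*(τ) = min{t : ρ_t ≥ ⌈τR⌉}, where ρ_t is the number
of includes after screening t of N records and R the total relevant
count: achieved recall ρ_T/R, the proportion of the target missed, and
the signed *additional work* (T − t\*)/(N − t\*), with 100% meaning
the criterion never fired.

Because fully annotated review datasets are rarely shareable, the
package ships a **synthetic generator** that emulates their
statistical shape at two levels: token-level labeled corpora (for
end-to-end simulator runs) and parametric traces whose gain curve
follows a random-sampling diagonal, then a convergent exponential
g(u) = (1 − e^(−βu))/(1 − e^(−β)), optionally interrupted by
zero-inclusion plateaus — the "steps" that fool many stopping rules.

## Worked example

```python
from tarstop import (TraceParams, generate_trace, StoppingConfig,
                     apply_schedule, evaluate_stop)

trace = generate_trace(TraceParams(N=3000, R=150,
                                   plateaus=((0.4, 0.05),), seed=1))
config = StoppingConfig(method="CMH", recall_target=0.8, confidence=0.95)
decision = apply_schedule(trace, "CMH", config, interval=15)
row = evaluate_stop(trace, decision.stop_index, 0.8)
print(decision.stop_index, round(row.achieved_recall, 4),
      round(row.additional_work, 3), row.target_missed)
```

prints

```
1565 0.9933 0.329 False
```

The hypergeometric rule fired at checkpoint 1565 of 3000 with 149 of
150 relevant records already found (recall 99.3% against the 80%
target — characteristically conservative), having screened 32.9% of
the records remaining past the optimal stopping point; the target was
not missed.

The same sweep is available from the shell:

```bash
tarstop generate-trace --n 3000 --r 150 --plateau 0.4:0.05 --seed 1 --out trace.json
tarstop apply --trace trace.json --method CMH \
    --param recall_target=0.8 --param confidence=0.95 --out stops.csv
tarstop evaluate --trace trace.json --stops stops.csv --out eval.csv
tarstop report --eval eval.csv --out summary.csv
```

and `tarstop run --config run.yaml` executes the full pipeline
(generate/simulate → apply grid → evaluate → summarize) with a
reproducibility manifest.

## Layout

| module | contents |
| --- | --- |
| `tarstop.types` / `tarstop.io` | domain types (Dataset, ScreeningTrace, TracePrefix), JSONL/CSV/JSON readers and writers |
| `tarstop.synthetic` | corpus and trace generators |
| `tarstop.simulator` | prioritized-screening simulation |
| `tarstop.stopping` | the fifteen stopping criteria + registry |
| `tarstop.evaluation` | checkpoint harness, metrics, summaries, composite curves |
| `tarstop.pipeline` / `tarstop.cli` | run configuration, orchestration, command line |

See `docs/methods.md` for the models, estimators, defaults and known
limitations.
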