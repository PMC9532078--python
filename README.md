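# sparrowforge

Chaos-enhanced sparrow search optimization, a 14-function benchmark harness,
and a swarm-trained feedforward classifier for binary clinical-outcome
prediction on a synthetic tabular cohort.

## What's inside

| Module | Purpose |
| --- | --- |
| `sparrowforge.benchmarks` | Fourteen box-constrained test objectives (F1–F14: Sphere … Three-hump), all with known optimum 0 |
| `sparrowforge.chaos` | Nine chaotic maps (tent, chebyshev, circle, iterative, sine, singer, sinusoidal, logistic, cubic), sequence generation, domain mapping, midpoint perturbation |
| `sparrowforge.optimizer` | Baseline sparrow search (discoverers / followers / scouts) and the improved loop: chaotic initialization + greedy Gaussian mutation + chaotic perturbation |
| `sparrowforge.harness` | Repeated-run experiments (variants × functions × seeds) with tidy CSV summaries and convergence traces |
| `sparrowforge.network` | Dense sigmoid feedforward net with a flat weight-vector encoding and MSE loss |
| `sparrowforge.trainer` | Swarm weight search minimizing training MSE, optional full-batch Adam refinement with analytic gradients |
| `sparrowforge.cohort` | Synthetic 398-record cohort generator (26 features: 17 blood indicators, 7 tumor metrics, age, gender) with exact category counts and a configurable feature→outcome signal |
| `sparrowforge.evaluation` | Confusion-matrix rates, hand-rolled ROC/AUC (= Mann–Whitney concordance), stratified k-fold cross-validation |
| `sparrowforge.cli` | `sparrowforge benchmark | simulate | train | evaluate` |

## CLI examples

```bash
# registry of the 14 benchmark functions
sparrowforge benchmark --list

# repeated-run comparison: 2 functions x 2 variants x 20 seeded repeats
sparrowforge benchmark --functions F1,F10 --variants ssa,iterative \
    --repeats 20 --seed 1 --out results.csv --traces traces/

# synthetic cohort with exact reference category counts
sparrowforge simulate --n 398 --seed 1 --exact-counts --out cohort.csv

# swarm-search network weights, then score with ROC export
sparrowforge train --data cohort.csv --arch 26-4-1 --pop 30 --iters 150 \
    --refine-epochs 800 --seed 7 --out model.json
sparrowforge evaluate --data cohort.csv --model model.json \
    --out metrics.json --roc-out roc.csv
```

Every artifact-writing command drops a `*.config.yaml` next to its output
recording the resolved parameters, and all commands are deterministic given
`--seed`.

## Notes

- Minimization convention throughout; positions are hard-clamped to the
  search box.
- The quartic objective (F6) includes a uniform[0,1) noise term and takes
  an RNG; pass `noise=False` for deterministic evaluation.
- In classification, the positive class is the death outcome (the majority
  class, 75%); features are standardized with training-fold statistics only.
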