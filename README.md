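# shakebox

Signal-detection analysis of children's exploratory play: do children shake
a box for longer when the two hypotheses about its contents are harder to
tell apart?

`shakebox` is an analysis pipeline for experiments in which a child hears a
box that hides one of two marble numerosities and either chooses which of
two boxes to open (forced choice) or shakes the box freely while their
exploration time is measured.  The package provides the discriminability
model, a synthetic-cohort generator with the same statistical structure as
the experimental designs, the full regression battery, forced-choice
statistics, model comparison, and a reproducible command-line pipeline.

## The model

The internal representation of an auditorily perceived numerosity *n* is
modeled as a Gaussian on a log scale with mean log *n* and common standard
deviation σ (the approximate-number-system convention).  The
discriminability of a contrast between *l* and *m* marbles is therefore the
standard signal-detection index

    d' = |log l − log m| / σ

which depends only on the ratio of the counts (Weber's law).  The central
behavioral prediction is that a child's *normalized playtime* — the trial's
share of the child's total playtime across their four trials, times four,
so each child's mean is exactly 1 — increases linearly in −d′.  Ideal 2AFC
accuracy is Φ(d′/√2).  Two heuristic difficulty models are included for
comparison: the absolute difference |l − m| and the negative ratio
−min/max.

## Worked example

```bash
python analysis/01_simulate.py      # 96 synthetic children, 384 trials
python analysis/02_fit_exploration.py
```

prints (seed 1, generator defaults):

```
fitted coefficients (95% CI):
                    neg_dprime: beta=+0.2576 [+0.2314, +0.2838]  (ols-cluster)
                  hidden_count: beta=-0.0005 [-0.0080, +0.0070]  (ols-cluster)
                   trial_order: beta=-0.0454 [-0.0689, -0.0219]  (ols-cluster)
                        dprime: beta=+1.0904 [+0.6617, +1.5191]  (logit-cluster)
    neg_dprime_condition_means: beta=+0.9878 [+0.9644, +0.9959]  (pearson)
positive individual slopes:
  all: 91/96 (95%; CI [0.90, 0.99])
```

Reading the numbers: the cohort was generated with a true playtime slope of
0.24 on −d′, no effect of the hidden count, a −0.051 decline per trial, and
an accuracy slope of 1.12 log-odds per unit d′.  The battery recovers each:
normalized playtime rises 0.26 per unit −d′ (children spend a larger share
of their play on harder discriminations), the hidden-count effect is null,
exploration declines slightly over trials, accuracy rises with d′, the
per-contrast mean playtimes correlate at r = 0.99 with the model, and 95%
of individual children have a positive playtime-on-difficulty slope.
`analysis/03_forced_choice.py` and `analysis/04_compare_models.py` add the
box-choice proportions (with normal-approximation and exact Clopper-Pearson
CIs) and the heuristic-model comparison; `analysis/05_report.py` collects
everything into `results/analysis/report.md`.

The same pipeline is available as a CLI:

```bash
shakebox all --seed 1 --out-dir run1           # simulate -> analyze -> compare -> report
shakebox analyze run1/trials.csv --choices-csv run1/choices.csv \
    --out-dir run1 --ci-method exact --estimator mixed
```

Real data can be analyzed by supplying a CSV with columns
`child_id, experiment, trial_order, n_a, n_b, hidden, playtime_s,
response_count, correct` (plus optional `age_years`).

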