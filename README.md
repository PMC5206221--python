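# sludgeqspr

QSPR models for the sorption of pharmaceuticals to sewage sludge.

During waste-water treatment, an active pharmaceutical ingredient (API)
partitions between sludge and the aqueous phase according to the
partition coefficient K_d = [API]_sludge / [API]_aqueous (L kg⁻¹).
Predicting log K_d from molecular descriptors supports environmental
fate assessment without slow sorption experiments, but is hard: APIs are
mostly ionisable, so hydrophobicity (log K_ow) alone is a weak
predictor, and literature K_d values for the same compound scatter by
about an order of magnitude across sludges and studies.

This package implements, as a tested reusable library, the modelling
pipeline used in that setting:

* **Descriptor reduction** — coefficient-of-variation filter, then
  unsupervised forward selection (UFS), which grows a descriptor subset
  of minimal multiple correlation.
* **Linear models** — per-charge-class univariate
  `log K_d = a + b·log K_ow` lines with leverage-based outlier
  screening; forward-backward stepwise regression; NIPALS partial least
  squares with the component count chosen by leave-one-out
  cross-validated R², and loading-based descriptor rankings.  Fit
  statistics: R², R²_adj, predicted R² (PRESS), R²_cv, MUE.
* **Bayesian neural networks** — single-hidden-layer tanh perceptrons
  trained under MacKay's evidence framework with automatic relevance
  determination (one weight-decay precision α per input); committees of
  the best-evidence networks; ARD descriptor relevance rankings.
* **Experiment protocols** — five independent random 237/60
  train/test divisions of 297 pooled measurements, leakage-safe
  per-split preprocessing, and production models refit on the full
  dataset.
* **Synthetic data** — a generator reproducing the statistical
  structure of the curated literature dataset (charge-class counts,
  replicate spread, class-dependent log K_ow slopes, collinear
  descriptor blocks, optional smooth nonlinearity) with saved ground
  truth, so every stage has a parameter-recovery test surface.

The original study's descriptor tables come from commercial software
and are not redistributable; the synthetic generator is how this
package validates the protocols end to end.

## Worked example

```python
import sludgeqspr as sq

table, truth = sq.generate_dataset(sq.GeneratorConfig(seed=0))
results = sq.run_univariate_experiment(table)
for name in ("uncharged", "positive", "combined"):
    m = results[name]["model"]
    print(f"{name:>10}: slope {m.slope:+.2f}  R2 {m.r2:.2f}  (n={m.n})")
```

prints

```
 uncharged: slope +0.42  R2 0.46  (n=92)
  positive: slope +0.44  R2 0.65  (n=105)
  combined: slope +0.29  R2 0.32  (n=297)
```

The uncharged and positively charged classes recover their generating
slopes (0.42, 0.45) and show usable correlations, while the pooled model
is much weaker — mixing charge classes with different baselines destroys
the log K_ow correlation, which is the central argument for charge-aware
and multivariate models.  The scripts in `examples/` walk through each
capability (generation, reduction, the five-split PLS protocol, ANN
committees and ARD ranking) and print the numbers they compute.

A thin CLI mirrors the library for batch use:

```bash
sludgeqspr generate --out table.csv --seed 0
sludgeqspr evaluate table.csv --out-dir runs/demo --seed 0
sludgeqspr rank runs/demo/production_committee.json
```

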