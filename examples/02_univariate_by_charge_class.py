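"""Classic single-descriptor models: log K_d = a + b log K_ow per charge class.

Hydrophobicity alone predicts sorption moderately well for uncharged and
positively charged compounds and poorly for the pooled dataset — the
motivation for charge-aware multivariate models.
"""

import sludgeqspr as sq

table, truth = sq.generate_dataset(sq.GeneratorConfig(seed=0))
results = sq.run_univariate_experiment(table)

for name, res in results.items():
    m = res["model"]
    lev = res["leverage"]
    flagged = len(lev.flagged) if lev is not None else 0
    print(f"{name:>10}: log K_d = {m.slope:+.2f} log K_ow {m.intercept:+.2f}   "
          f"R2 = {m.r2:.2f}  (n = {m.n}, high-leverage points: {flagged})")

print()
print("The pooled ('combined') R2 is well below the best class R2: mixing")
print("charge classes with different intercepts destroys the correlation.")
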