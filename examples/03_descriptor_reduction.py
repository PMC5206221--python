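"""Descriptor reduction: CV filter + unsupervised forward selection (UFS).

UFS keeps a subset of descriptors with minimal multiple correlation.  The
synthetic table contains deliberately redundant columns (linear
combinations of others); UFS should reject exactly those.
"""

import sludgeqspr as sq

table, truth = sq.generate_dataset(sq.GeneratorConfig(seed=0))
reduced, report = sq.reduce_descriptors(table, cv_threshold=0.05, ufs_r2_max=0.99)

print(f"started with {len(table.descriptor_names)} descriptors")
print(f"removed by CV filter: {report.removed_by_cv or 'none'}")
print(f"selected by UFS ({len(report.ufs_order)}): {', '.join(report.ufs_order)}")
print(f"stop reason: {report.stop_reason.value}")

rejected = set(table.descriptor_names) - set(report.ufs_order) - set(report.removed_by_cv)
print(f"rejected as multiply-correlated: {sorted(rejected)}")
print(f"known redundant columns in the truth: {sorted(truth.redundant_columns)}")
print("  -> every constructed redundant column should appear in the rejected set.")
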