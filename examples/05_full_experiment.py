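"""A full experiment grid: reductions x classifiers x CV designs.

Runs a small lam grid of stability-selected pLDA plus the t-test baseline
with both classifiers under both CV designs on one synthetic cohort, prints
the summary table (percent metrics to one decimal), and compares two runs
with McNemar's paired test.
"""

import logging

import pldacv as p

logging.disable(logging.WARNING)

geom = p.bias_demo_geometry(p=500)
spec = p.SyntheticSpec(
    geometry=geom, n_per_class=(10, 10), seed=5,
    clusters=(p.Cluster(center=(2, 5, 5), radius=1.5, delta=0.25),))

config = p.ExperimentConfig(
    reductions=p.plda_grid((1.0, 3.0), K=25) +
    (p.ReducerSpec("ttest", p_threshold=0.01),),
    classifiers=(p.ClassifierSpec("lda"), p.ClassifierSpec("linsvm")),
    designs=("c", "rc"),
    synthetic=spec,
    seed=17)
report = p.run_experiment(config)

cols = ["reduction", "lam", "classifier", "design", "n_features_mean",
        "accuracy", "sensitivity", "specificity"]
print(p.format_summary(report.summary)[cols].to_string(index=False))

# paired comparison: LDA vs linear SVM, nested design, lam = 3.0
runs = {(c.classifier, c.design, c.lam): c.run for c in report.cells
        if c.reduction == "plda"}
res = p.mcnemar_compare(runs[("lda", "rc", 3.0)], runs[("linsvm", "rc", 3.0)])
print(f"\nMcNemar LDA vs linSVM (rc, lam=3.0): discordant "
      f"{res.only_a_correct}+{res.only_b_correct}, p = {res.pvalue:.3f} "
      f"({res.method})")
print("-> with a weak planted effect the nested-design accuracies are "
      "modest and the two classifiers are statistically indistinguishable.")
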