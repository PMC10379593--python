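"""One-seed senior / junior / fused study with DeLong comparisons.

Balances the cohort 1:1, cross-validates at case level, trains one
knowledge tensor per arm per fold, pools test scores into one ROC per
arm and compares the arms pairwise. The fused arm trains on the union
of senior and junior training knowledge but is tested on junior
annotations — what a junior reader plus the senior correction achieves.
"""

from birads_tensor import GeneratorConfig, PipelineConfig, TrainConfig, run_experiment, simulate_cohort

cases = simulate_cohort(GeneratorConfig(n_cases=500, senior_noise=0.05, junior_noise=0.25, seed=1))
config = PipelineConfig(train=TrainConfig(n_epochs=200), n_folds=2, seed=1)
results = run_experiment(cases, config)

print(f"balanced to {results['n_images']} images from {results['n_cases']} cases")
for arm in ("senior", "fused", "junior"):
    r = results["arms"][arm]
    lo, hi = r["auc_ci"]
    print(
        f"{arm:>6}: AUC={r['auc']:.3f} (95% CI {lo:.3f}-{hi:.3f}) "
        f"acc={r['accuracy']:.3f} sens={r['sensitivity']:.3f} spec={r['specificity']:.3f} f1={r['f1']:.3f}"
    )
for pair, d in results["delong"].items():
    print(f"DeLong {pair}: z={d['z']:+.2f} p={d['p_value']:.4f}")
# expect senior > fused > junior: fusing the cleaner senior training
# knowledge partially corrects the junior model's noisy associations
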