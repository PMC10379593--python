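"""Knowledge tensor vs KNN and SVM on the senior annotation channel.

The classical baselines see the same one-hot encoded characteristics;
the comparison asks whether the tensor model extracts more from the
ten categorical features than distance- or margin-based classifiers.
"""

from birads_tensor import GeneratorConfig, PipelineConfig, TrainConfig, run_experiment, simulate_cohort

cases = simulate_cohort(GeneratorConfig(n_cases=300, seed=2))
config = PipelineConfig(
    train=TrainConfig(n_epochs=200),
    n_folds=2,
    arms=("senior",),
    include_baselines=True,
    seed=2,
)
results = run_experiment(cases, config)

r = results["arms"]["senior"]
print(f"knowledge tensor (senior): AUC={r['auc']:.3f} f1={r['f1']:.3f}")
for name, rep in results["baselines"].items():
    print(f"{name:>24}: AUC={rep['auc']:.3f} f1={rep['f1']:.3f}")
for pair, d in results["delong"].items():
    print(f"DeLong {pair}: p={d['p_value']:.4f}")
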