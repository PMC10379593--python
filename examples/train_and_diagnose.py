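"""Train a knowledge tensor and diagnose held-out patients.

Pathology edges of the last 10 cases are masked out; the model sees
their characteristic edges only and must complete the missing
(patient, pathology, ?) link.
"""

from birads_tensor import (
    GeneratorConfig,
    TrainConfig,
    annotation_to_triples,
    build_graph,
    cohort_records,
    mask_test_pathology,
    predict_label,
    predict_malignancy,
    simulate_cohort,
    train,
)

cases = simulate_cohort(GeneratorConfig(n_cases=80, seed=5))
records = cohort_records(cases, "senior")
graph = build_graph([t for r in records for t in annotation_to_triples(r)])

test_cases = [c.case_id for c in cases[-10:]]
train_triples, queries = mask_test_pathology(graph, test_cases)
result = train(train_triples, graph, TrainConfig(seed=5))
print(f"trained: final loss {result.loss_trace[-1]:.4f} after {len(result.loss_trace)} epochs")

correct = 0
for q in queries:
    p = predict_malignancy(result.model, q.head)
    label = predict_label(result.model, q.head)
    correct += label == q.true_tail
    print(f"  {q.head}: P(malignant)={p:.3f} -> {label} (truth: {q.true_tail})")
print(f"{correct}/{len(queries)} held-out diagnoses correct")
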