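"""Turn annotations into knowledge triples and inspect the graph.

Every image contributes eleven triples: ten (image, characteristic,
value) statements plus one (image, pathology, benign|malignant) edge.
"""

from birads_tensor import (
    GeneratorConfig,
    annotation_to_triples,
    build_graph,
    cohort_records,
    simulate_cohort,
)

cases = simulate_cohort(GeneratorConfig(n_cases=50, seed=3))
records = cohort_records(cases, "senior")
triples = [t for rec in records for t in annotation_to_triples(rec)]
graph = build_graph(triples)

print(f"{len(records)} images -> n={graph.n} unique triples")
print(f"|E|={len(graph.entities)} entities: p={graph.p} image heads, q={graph.q} value/pathology tails")
print(f"m={graph.m} relations: {graph.relations}")
print("example triples:")
for t in graph.triples[:3]:
    print("  ", t)
# the tails are namespaced relation=value, so 'present' under two
# characteristics never collapses into one entity
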