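"""Simulate a dual-annotator BUS cohort and write both annotation tables.

The generator draws a benign/malignant label per case (78% malignant by
default), class-conditional BI-RADS characteristics per image, and two
readings of the same truth: a senior channel with a 5% flip rate and a
junior channel with a 25% flip rate.
"""

from birads_tensor import GeneratorConfig, simulate_cohort, write_annotation_table

config = GeneratorConfig(n_cases=100, seed=7)
cases = simulate_cohort(config)

n_mal = sum(c.pathology == "malignant" for c in cases)
print(f"{len(cases)} cases: {n_mal} malignant, {len(cases) - n_mal} benign")

disagree = total = 0
for case in cases:
    for img in case.image_ids:
        for name, value in case.senior_annotations[img].items():
            total += 1
            disagree += value != case.junior_annotations[img][name]
print(f"senior/junior disagreement: {disagree / total:.3f} of {total} readings")
print("(two independent flips at 0.05 and 0.25 disagree ~28% of the time)")

write_annotation_table(cases, "senior", "senior.csv")
write_annotation_table(cases, "junior", "junior.csv")
print("wrote senior.csv and junior.csv")
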