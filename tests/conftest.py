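import numpy as np
import pytest

from birads_tensor import (
    GeneratorConfig,
    Triple,
    build_graph,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """60 cases, default study conditions, fixed seed."""
    return simulate_cohort(GeneratorConfig(n_cases=60, seed=11))


@pytest.fixture(scope="session")
def tiny_separable_graph():
    """Four patients, two characteristics, perfectly separable pathology.

    Malignant patients read suspicious on both characteristics, benign
    patients on neither — the smallest graph where the pathology edge is
    recoverable from the features alone.
    """
    triples = []
    for pid, label in (("a::0", "malignant"), ("b::0", "malignant"),
                       ("c::0", "benign"), ("d::0", "benign")):
        v = "present" if label == "malignant" else "absent"
        triples.append(Triple(pid, "shape", f"shape={v}"))
        triples.append(Triple(pid, "margin", f"margin={v}"))
        triples.append(Triple(pid, "pathology", label))
    return build_graph(triples)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
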