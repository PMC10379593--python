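"""Class balancing for knowledge-tensor training.

Tensor-decomposition link predictors are sensitive to the benign/malignant
mix, so cohorts are balanced before training: random undersampling of the
majority class (the default, matching a 1:1 target), or oversampling of
the minority class by *fictitious heads* — because head entities are
real-named (one per image), plain row duplication adds no new entities and
does nothing to the tensor-space optimization, so each duplicate instead
receives a freshly minted head entity carrying a copy of the source
image's characteristic and pathology triples.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .graph import Triple

__all__ = ["undersample", "oversample_fictitious", "FICTITIOUS_PREFIX"]

#: Fictitious head ids are tagged so they can be excluded from test queries.
FICTITIOUS_PREFIX = "synthetic::"


def undersample(
    images_by_class: Mapping[str, Sequence[str]],
    ratio: float = 1.0,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Randomly undersample the majority class.

    ``ratio`` is the target minority:majority proportion (1.0 means equal
    counts). The minority class is untouched; the majority class is
    subsampled uniformly without replacement. Deterministic under seed.
    """
    if len(images_by_class) != 2:
        raise ValueError("expected exactly two classes")
    if any(len(v) == 0 for v in images_by_class.values()):
        raise ValueError("both classes must be non-empty")
    if not 0.0 < ratio <= 1.0:
        raise ValueError("ratio (minority:majority) must be in (0, 1]")
    (a, imgs_a), (b, imgs_b) = images_by_class.items()
    if len(imgs_a) <= len(imgs_b):
        minority, majority = (a, imgs_a), (b, imgs_b)
    else:
        minority, majority = (b, imgs_b), (a, imgs_a)
    target_majority = int(round(len(minority[1]) / ratio))
    if target_majority > len(majority[1]):
        raise ValueError(
            f"ratio {ratio} unattainable: needs {target_majority} majority "
            f"samples, only {len(majority[1])} available"
        )
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(majority[1]), size=target_majority, replace=False)
    selected = [majority[1][i] for i in sorted(keep)]
    out = {minority[0]: list(minority[1]), majority[0]: selected}
    return {label: out[label] for label in images_by_class}


def oversample_fictitious(
    minority_images: Sequence[str],
    triples_by_head: Mapping[str, Iterable[Triple]],
    target_count: int,
    seed: int = 0,
) -> tuple[list[str], list[Triple]]:
    """Oversample a class to ``target_count`` images with fictitious heads.

    Samples source images with replacement; each copy gets a fresh
    ``synthetic::``-prefixed head id that inherits every triple of its
    source. Returns (new head ids, their triples); originals are untouched.
    """
    current = len(minority_images)
    if target_count < current:
        raise ValueError(f"target_count {target_count} below current count {current}")
    rng = np.random.default_rng(seed)
    new_heads: list[str] = []
    new_triples: list[Triple] = []
    for i in range(target_count - current):
        source = minority_images[int(rng.integers(current))]
        fresh = f"{FICTITIOUS_PREFIX}{source}::{i}"
        new_heads.append(fresh)
        for t in triples_by_head[source]:
            new_triples.append(Triple(fresh, t.relation, t.tail))
    return new_heads, new_triples


def is_fictitious(head_id: str) -> bool:
    return head_id.startswith(FICTITIOUS_PREFIX)
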