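"""Senior-knowledge correction of the junior model.

A senior reader's BI-RADS annotations are treated as the gold standard
used to correct the model trained on a junior reader's noisier
annotations. Two fusion strategies are provided:

``data_union``
    Pool the senior and junior training triples and train one model on
    the union; the cleaner senior statements act as a correction bias on
    the shared value-entity and core parameters, while evaluation still
    uses junior-annotated test queries.

``core_blend``
    Train the junior model warm-started from the senior model's
    parameters (so the two cores live in comparable spaces), then blend
    the core tensors: W_fused = alpha * W_senior + (1 - alpha) * W_junior,
    keeping the junior entity/relation embeddings. By linearity of the
    trilinear score, every fused score is the same convex combination of
    the senior-core and junior-core scores.

The warm-start alignment required by ``core_blend`` is this package's own
construction — without a shared parameter space, blending two
independently trained cores would be meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .graph import Triple
from .tucker import TuckerModel

__all__ = ["FusionConfig", "fuse_data_level", "fuse_core_tensors"]


@dataclass
class FusionConfig:
    strategy: str = "data_union"
    alpha: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("data_union", "core_blend"):
            raise ValueError(f"unknown fusion strategy {self.strategy!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")


def fuse_data_level(
    senior_train_triples: Iterable[Triple],
    junior_train_triples: Iterable[Triple],
) -> list[Triple]:
    """Union of the two training triple sets (deduplicated, senior first).

    Both sets must reference a shared vocabulary: the same patient heads
    and the same relation alphabet. Disjoint claims about one patient are
    both retained — that is the point of the union.
    """
    senior = list(dict.fromkeys(Triple(*t) for t in senior_train_triples))
    junior = list(dict.fromkeys(Triple(*t) for t in junior_train_triples))
    s_heads = {t.head for t in senior}
    j_heads = {t.head for t in junior}
    if s_heads != j_heads:
        raise ValueError(
            "vocabulary mismatch: senior and junior triples cover different patients "
            f"({len(s_heads ^ j_heads)} heads differ)"
        )
    s_rels = {t.relation for t in senior}
    j_rels = {t.relation for t in junior}
    if s_rels != j_rels:
        raise ValueError(
            f"vocabulary mismatch: relation sets differ ({sorted(s_rels ^ j_rels)})"
        )
    fused = dict.fromkeys(senior)
    fused.update(dict.fromkeys(junior))
    return list(fused)


def fuse_core_tensors(
    senior_model: TuckerModel,
    junior_model: TuckerModel,
    config: FusionConfig | None = None,
) -> TuckerModel:
    """Blend the senior core into the junior model's core tensor.

    Requires dimension-matched models over identical vocabularies (the
    junior model should have been trained warm-started from the senior
    one). Returns a model with junior embeddings and the blended core.
    """
    config = config or FusionConfig(strategy="core_blend")
    if senior_model.core.shape != junior_model.core.shape:
        raise ValueError(
            f"core shape mismatch: {senior_model.core.shape} vs {junior_model.core.shape}"
        )
    if senior_model.entities != junior_model.entities:
        raise ValueError("entity spaces are not aligned")
    if senior_model.relations != junior_model.relations:
        raise ValueError("relation spaces are not aligned")
    alpha = config.alpha
    fused_core = alpha * senior_model.core + (1.0 - alpha) * junior_model.core
    return TuckerModel(
        entity_embeddings=junior_model.entity_embeddings.copy(),
        relation_embeddings=junior_model.relation_embeddings.copy(),
        core=fused_core,
        entities=list(junior_model.entities),
        relations=list(junior_model.relations),
    )
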