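"""Core record types shared across the package.

An :class:`AnnotationRecord` is one radiologist's reading of one breast
ultrasound (BUS) image: the ten BI-RADS morphological characteristics plus
the pathology ground truth (benign/malignant) established by biopsy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The ten BI-RADS characteristics used throughout: each is a per-image
#: morphological descriptor a radiologist marks as present or absent.
CHARACTERISTICS: tuple[str, ...] = (
    "angular",
    "calcification",
    "distortion",
    "indistinct",
    "margin",
    "micro_lobulation",
    "orientation",
    "posterior",
    "shape",
    "speculation",
)

PATHOLOGY_RELATION = "pathology"
BENIGN = "benign"
MALIGNANT = "malignant"
PATHOLOGY_VALUES = (BENIGN, MALIGNANT)

#: Default binary alphabet for a characteristic: the first value is the
#: "suspicious" one (the reading that raises concern for malignancy).
SUSPICIOUS = "present"
NOT_SUSPICIOUS = "absent"


class SchemaError(ValueError):
    """An annotation record or table violates the documented schema."""


@dataclass
class AnnotationRecord:
    """One image's annotation by one reader.

    Parameters
    ----------
    case_id, image_id:
        Opaque identifiers; together they name the image.
    annotator:
        ``"senior"`` or ``"junior"`` (free-form strings are accepted for
        real data with named readers).
    pathology:
        ``"benign"`` or ``"malignant"`` — the biopsy result, identical
        across readers of the same image.
    characteristics:
        Mapping characteristic name -> categorical value.
    """

    case_id: str
    image_id: str
    annotator: str
    pathology: str
    characteristics: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pathology not in PATHOLOGY_VALUES:
            raise SchemaError(
                f"pathology must be one of {PATHOLOGY_VALUES}, got {self.pathology!r}"
            )
        for name in self.characteristics:
            if name not in CHARACTERISTICS:
                raise SchemaError(f"unknown characteristic {name!r}")

    @property
    def head_id(self) -> str:
        """Knowledge-graph head entity id for this image (``case::image``)."""
        return f"{self.case_id}::{self.image_id}"


def head_to_case(head_id: str) -> str:
    """Recover the case id from a ``case::image`` head entity id."""
    return head_id.split("::", 1)[0]
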