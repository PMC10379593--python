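"""Synthetic dual-annotator BUS-report cohorts.

The generator emulates the statistical structure a knowledge-tensor
diagnosis pipeline assumes: a latent benign/malignant label per case,
class-conditional categorical BI-RADS characteristics per image, and two
annotation channels — a low-noise "senior" reading and a higher-noise
"junior" reading of the same underlying truth. Pathology is ground truth
(biopsy), so it is never corrupted; only characteristic readings are.

Noise is an independent symmetric flip per image and characteristic:
with probability epsilon the recorded value is replaced by a uniformly
chosen *different* value from that characteristic's alphabet.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .records import (
    BENIGN,
    CHARACTERISTICS,
    MALIGNANT,
    NOT_SUSPICIOUS,
    SUSPICIOUS,
    AnnotationRecord,
)

__all__ = [
    "GeneratorConfig",
    "AnnotatedCase",
    "ConfigurationError",
    "DEFAULT_CHAR_PROBS",
    "simulate_cohort",
    "cohort_records",
    "cases_from_records",
    "write_annotation_table",
]


class ConfigurationError(ValueError):
    """A generator configuration violates its invariants."""


# Class-conditional probability of the suspicious reading,
# (P[suspicious | malignant], P[suspicious | benign]) per characteristic.
# BI-RADS descriptors differ widely in discriminative power in practice
# (shape/margin/speculation are strong malignancy markers; posterior
# features and micro-lobulation are weak), so the defaults span
# strong-to-weak discriminators rather than ten exchangeable features.
DEFAULT_CHAR_PROBS: dict[str, tuple[float, float]] = {
    "angular": (0.80, 0.10),
    "calcification": (0.65, 0.25),
    "distortion": (0.70, 0.15),
    "indistinct": (0.60, 0.30),
    "margin": (0.85, 0.20),
    "micro_lobulation": (0.55, 0.30),
    "orientation": (0.75, 0.15),
    "posterior": (0.50, 0.35),
    "shape": (0.85, 0.10),
    "speculation": (0.75, 0.10),
}


@dataclass
class GeneratorConfig:
    """Study conditions for one simulated cohort.

    ``malignancy_prevalence`` defaults to the image-level class mix of the
    motivating dataset (≈78% malignant). ``senior_noise``/``junior_noise``
    are per-characteristic flip probabilities with junior ≥ senior.
    ``images_per_case`` may be an int or an inclusive ``(lo, hi)`` range.
    """

    n_cases: int = 500
    images_per_case: int | tuple[int, int] = 1
    malignancy_prevalence: float = 0.78
    char_probs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CHAR_PROBS)
    )
    senior_noise: float = 0.05
    junior_noise: float = 0.25
    alphabets: dict[str, tuple[str, ...]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ConfigurationError("n_cases must be positive")
        lo, hi = self.images_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("images_per_case must be a positive int or range")
        if not 0.0 <= self.malignancy_prevalence <= 1.0:
            raise ConfigurationError("malignancy_prevalence must be in [0, 1]")
        for eps, name in ((self.senior_noise, "senior_noise"), (self.junior_noise, "junior_noise")):
            if not 0.0 <= eps < 0.5:
                raise ConfigurationError(f"{name} must be in [0, 0.5)")
        if self.junior_noise < self.senior_noise:
            raise ConfigurationError("junior_noise must be >= senior_noise")
        if set(self.char_probs) != set(CHARACTERISTICS):
            raise ConfigurationError(
                "char_probs must configure exactly the ten BI-RADS characteristics"
            )
        for name, (p_mal, p_ben) in self.char_probs.items():
            if not (0.0 <= p_mal <= 1.0 and 0.0 <= p_ben <= 1.0):
                raise ConfigurationError(f"char_probs[{name!r}] out of [0, 1]")
        for name, values in self.alphabets.items():
            if name not in CHARACTERISTICS:
                raise ConfigurationError(f"alphabet for unknown characteristic {name!r}")
            if len(values) < 2 or len(set(values)) != len(values):
                raise ConfigurationError(f"alphabet for {name!r} needs >=2 distinct values")

    @property
    def images_range(self) -> tuple[int, int]:
        if isinstance(self.images_per_case, int):
            return self.images_per_case, self.images_per_case
        lo, hi = self.images_per_case
        return int(lo), int(hi)

    def alphabet(self, name: str) -> tuple[str, ...]:
        """Value set for a characteristic; index 0 is the suspicious value."""
        return self.alphabets.get(name, (SUSPICIOUS, NOT_SUSPICIOUS))


@dataclass
class AnnotatedCase:
    """One case: ground-truth pathology plus both readers' annotations."""

    case_id: str
    image_ids: list[str]
    pathology: str
    senior_annotations: dict[str, dict[str, str]]
    junior_annotations: dict[str, dict[str, str]]


def _draw_value(rng: np.random.Generator, alphabet: tuple[str, ...], p_susp: float) -> str:
    """Class-conditional draw: suspicious value w.p. p_susp, rest uniform."""
    if rng.random() < p_susp:
        return alphabet[0]
    others = alphabet[1:]
    return others[rng.integers(len(others))]


def _corrupt(rng: np.random.Generator, value: str, alphabet: tuple[str, ...], eps: float) -> str:
    if eps > 0.0 and rng.random() < eps:
        others = [v for v in alphabet if v != value]
        return others[rng.integers(len(others))]
    return value


def simulate_cohort(config: GeneratorConfig) -> list[AnnotatedCase]:
    """Simulate a cohort of annotated cases.

    Pathology labels are Bernoulli(``malignancy_prevalence``); true
    characteristics are class-conditional draws; each channel is the truth
    flipped independently at its channel's noise rate. The same config and
    seed always yield the same cohort.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.images_range
    cases: list[AnnotatedCase] = []
    for i in range(config.n_cases):
        case_id = f"case{i:05d}"
        pathology = MALIGNANT if rng.random() < config.malignancy_prevalence else BENIGN
        n_images = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        image_ids = [f"img{j}" for j in range(n_images)]
        senior: dict[str, dict[str, str]] = {}
        junior: dict[str, dict[str, str]] = {}
        for image_id in image_ids:
            s_ann: dict[str, str] = {}
            j_ann: dict[str, str] = {}
            for name in CHARACTERISTICS:
                alphabet = config.alphabet(name)
                p_mal, p_ben = config.char_probs[name]
                truth = _draw_value(
                    rng, alphabet, p_mal if pathology == MALIGNANT else p_ben
                )
                s_ann[name] = _corrupt(rng, truth, alphabet, config.senior_noise)
                j_ann[name] = _corrupt(rng, truth, alphabet, config.junior_noise)
            senior[image_id] = s_ann
            junior[image_id] = j_ann
        cases.append(AnnotatedCase(case_id, image_ids, pathology, senior, junior))
    return cases


def cohort_records(cases: list[AnnotatedCase], channel: str) -> list[AnnotationRecord]:
    """Flatten one annotation channel into per-image records."""
    if channel not in ("senior", "junior"):
        raise ValueError(f"channel must be 'senior' or 'junior', got {channel!r}")
    records = []
    for case in cases:
        annotations = case.senior_annotations if channel == "senior" else case.junior_annotations
        for image_id in case.image_ids:
            records.append(
                AnnotationRecord(
                    case_id=case.case_id,
                    image_id=image_id,
                    annotator=channel,
                    pathology=case.pathology,
                    characteristics=dict(annotations[image_id]),
                )
            )
    return records


def cases_from_records(
    senior_records: list[AnnotationRecord], junior_records: list[AnnotationRecord]
) -> list[AnnotatedCase]:
    """Pair two per-image record lists (one per channel) back into cases.

    Both channels must cover the same images and agree on pathology
    (it is ground truth, not an annotation).
    """
    s_by_img = {(r.case_id, r.image_id): r for r in senior_records}
    j_by_img = {(r.case_id, r.image_id): r for r in junior_records}
    if set(s_by_img) != set(j_by_img):
        raise ValueError("senior and junior channels cover different images")
    cases: dict[str, AnnotatedCase] = {}
    for key in s_by_img:
        s, j = s_by_img[key], j_by_img[key]
        if s.pathology != j.pathology:
            raise ValueError(f"pathology disagrees between channels for image {key}")
        case = cases.get(s.case_id)
        if case is None:
            case = AnnotatedCase(s.case_id, [], s.pathology, {}, {})
            cases[s.case_id] = case
        case.image_ids.append(s.image_id)
        case.senior_annotations[s.image_id] = dict(s.characteristics)
        case.junior_annotations[j.image_id] = dict(j.characteristics)
    return list(cases.values())


def write_annotation_table(cases: list[AnnotatedCase], channel: str, path: str | Path) -> None:
    """Write one channel of a cohort as the documented annotation CSV.

    Columns: ``case_id,image_id,annotator,pathology`` followed by the ten
    characteristics in canonical order; one row per image; UTF-8.
    """
    records = cohort_records(cases, channel)
    header = ["case_id", "image_id", "annotator", "pathology", *CHARACTERISTICS]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec in records:
            writer.writerow(
                [rec.case_id, rec.image_id, rec.annotator, rec.pathology]
                + [rec.characteristics[c] for c in CHARACTERISTICS]
            )
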