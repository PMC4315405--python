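"""Functional/structural site annotations and noisy-OR probability combination.

Variants falling at annotated functional or structural sites (binding
sites, metal-binding residues, active sites, intra-membrane regions,
catalytic/regulatory sites, ...) show strong class bias. Annotation types
whose training variants are dominated by one class (majority proportion
above a threshold, default 0.85) are retained; the pathogenic proportion
Pa of a retained type acts as a prior which is merged with the forest
probability Prf by the noisy-OR rule

    Pc = Pa + Prf - Pa * Prf.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .io import Dataset, VariantRecord


@dataclass(frozen=True)
class SiteAnnotation:
    """One annotated interval on a protein (one-based, inclusive bounds)."""

    protein_id: str
    start: int
    end: int
    type: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError("site bounds must be >= 1")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    def contains(self, protein_id: str, position: int) -> bool:
        return protein_id == self.protein_id and self.start <= position <= self.end


def read_sites(path) -> list[SiteAnnotation]:
    """Read a site annotation TSV (protein_id, start, end, type)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "type": str})
    return [
        SiteAnnotation(r.protein_id, int(r.start), int(r.end), r.type)
        for r in df.itertuples(index=False)
    ]


def write_sites(sites: list[SiteAnnotation], path) -> None:
    pd.DataFrame(
        [(s.protein_id, s.start, s.end, s.type) for s in sites],
        columns=["protein_id", "start", "end", "type"],
    ).to_csv(path, sep="\t", index=False)


@dataclass
class AnnotationModel:
    """Selected annotation types with their pathogenic-class priors.

    ``pa_by_type[t]`` is the proportion of pathogenic variants among
    training variants overlapping sites of type ``t``; only types whose
    majority-class proportion exceeds ``threshold`` are retained. Pa is
    estimated from training data only.
    """

    selected_types: set[str] = field(default_factory=set)
    pa_by_type: dict[str, float] = field(default_factory=dict)
    threshold: float = 0.85
    tie_rule: str = "most_informative"  # or "first_match"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "selected_types": sorted(self.selected_types),
                    "pa_by_type": self.pa_by_type,
                    "threshold": self.threshold,
                    "tie_rule": self.tie_rule,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "AnnotationModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            selected_types=set(d["selected_types"]),
            pa_by_type=d["pa_by_type"],
            threshold=d["threshold"],
            tie_rule=d.get("tie_rule", "most_informative"),
        )


def _sites_by_protein(sites: list[SiteAnnotation]) -> dict[str, list[SiteAnnotation]]:
    by_protein: dict[str, list[SiteAnnotation]] = defaultdict(list)
    for s in sites:
        by_protein[s.protein_id].append(s)
    return by_protein


def select_annotation_types(
    training: Dataset,
    sites: list[SiteAnnotation],
    threshold: float = 0.85,
    tie_rule: str = "most_informative",
) -> AnnotationModel:
    """Retain annotation types with strong single-class bias.

    For each type, the pathogenic proportion Pa among labelled training
    variants falling inside any of its sites is computed; the type is
    retained when max(Pa, 1-Pa) > threshold. Types overlapped by no
    training variant are excluded with a warning.
    """
    by_protein = _sites_by_protein(sites)
    counts: dict[str, list[int]] = defaultdict(lambda: [0, 0])  # [pathogenic, neutral]
    for rec in training:
        if rec.label is None:
            continue
        hit_types = {
            s.type
            for s in by_protein.get(rec.protein_id, ())
            if s.start <= rec.position <= s.end
        }
        for t in hit_types:
            counts[t][0 if rec.label == "pathogenic" else 1] += 1

    model = AnnotationModel(threshold=threshold, tie_rule=tie_rule)
    all_types = {s.type for s in sites}
    for t in sorted(all_types):
        n_path, n_neut = counts.get(t, [0, 0])
        total = n_path + n_neut
        if total == 0:
            import warnings

            warnings.warn(f"annotation type {t!r} has no overlapping training variants")
            continue
        pa = n_path / total
        if max(pa, 1 - pa) > threshold:
            model.selected_types.add(t)
            model.pa_by_type[t] = pa
    return model


def combine_probability(pa: float, prf: float, mode: str = "noisy_or") -> float:
    """Merge the annotation prior Pa with the forest probability Prf.

    Default is the noisy-OR rule Pc = Pa + Prf - Pa*Prf, bounded below by
    max(Pa, Prf) and above by 1; Pa = 0 is the identity and Pa = 1 is
    absorbing. Noisy-OR can only raise the pathogenicity probability, so
    ``mode="symmetric"`` instead mirrors the rule for neutral-biased
    priors (Pa < 0.5): the neutral probabilities 1-Pa and 1-Prf are
    noisy-OR'd, giving Pc = Pa*Prf, which pushes the combined probability
    toward neutral.
    """
    if not (0.0 <= pa <= 1.0) or not (0.0 <= prf <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    if mode not in ("noisy_or", "symmetric"):
        raise ValueError("mode must be 'noisy_or' or 'symmetric'")
    if mode == "symmetric" and pa < 0.5:
        return pa * prf
    return pa + prf - pa * prf


def annotate_variant(
    variant: VariantRecord,
    sites: list[SiteAnnotation],
    model: AnnotationModel,
) -> float | None:
    """Pa of the selected annotation type covering the variant, if any.

    When several selected types overlap the position, the default rule
    takes the type whose Pa is farthest from 0.5 (most informative);
    ``tie_rule="first_match"`` takes the first overlapping site in input
    order instead.
    """
    hits = [
        s.type
        for s in sites
        if s.type in model.selected_types and s.contains(variant.protein_id, variant.position)
    ]
    if not hits:
        return None
    if model.tie_rule == "first_match":
        return model.pa_by_type[hits[0]]
    best = max(
        dict.fromkeys(hits),  # preserve order for deterministic ties
        key=lambda t: (abs(model.pa_by_type[t] - 0.5), t),
    )
    return model.pa_by_type[best]


def annotation_priors(
    dataset: Dataset, sites: list[SiteAnnotation], model: AnnotationModel
) -> pd.Series:
    """Per-variant Pa (NaN where no selected site overlaps)."""
    vals = [annotate_variant(rec, sites, model) for rec in dataset]
    return pd.Series(
        [float("nan") if v is None else v for v in vals],
        index=dataset.variant_ids,
        name="pa",
    )
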