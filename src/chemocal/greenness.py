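"""Analytical-greenness scoring: eco-scale, AGREE, GAPI.

Three complementary ways of grading how environmentally friendly an
analytical procedure is:

* Eco-scale — itemized penalty points (reagents, instrument energy,
  occupational hazard, waste) subtracted from a base of 100.
* AGREE — twelve principle scores in [0, 1], combined as a weighted
  arithmetic mean into a single decimal.
* GAPI — fifteen categorical fields colored green/yellow/red; methods are
  compared by red counts.

Penalty points and segment/field values are user inputs (ledgers/config);
this module computes the scores, ratings and comparisons.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import yaml

__all__ = [
    "PenaltyItem",
    "EcoScaleResult",
    "eco_scale",
    "AgreeAssessment",
    "agree_score",
    "GapiProfile",
    "gapi_compare",
    "load_greenness_config",
]

PENALTY_CATEGORIES = ("reagent", "instrument_energy", "occupational_hazard", "waste")


@dataclasses.dataclass(frozen=True)
class PenaltyItem:
    label: str
    category: str
    penalty_points: int

    def __post_init__(self) -> None:
        if self.category not in PENALTY_CATEGORIES:
            raise ValueError(
                f"category must be one of {PENALTY_CATEGORIES}, got {self.category!r}"
            )
        if self.penalty_points < 0:
            raise ValueError("penalty points must be >= 0")


@dataclasses.dataclass(frozen=True)
class EcoScaleResult:
    total_pp: int
    score: int
    rating: str


def eco_scale(items: Sequence[PenaltyItem]) -> EcoScaleResult:
    """Score = 100 - total penalty points, with the standard rating bands.

    100 -> ideal; > 75 -> excellent; 50-75 -> acceptable; < 50 -> inadequate.
    """
    total = sum(i.penalty_points for i in items)
    if total > 100:
        raise ValueError(f"total penalty points {total} exceed the base of 100")
    score = 100 - total
    if score == 100:
        rating = "ideal"
    elif score > 75:
        rating = "excellent"
    elif score >= 50:
        rating = "acceptable"
    else:
        rating = "inadequate"
    return EcoScaleResult(total_pp=total, score=score, rating=rating)


@dataclasses.dataclass(frozen=True)
class AgreeAssessment:
    """Twelve principle scores in [0, 1] with positive importance weights."""

    segment_scores: tuple[float, ...]
    weights: tuple[float, ...] = tuple([1.0] * 12)

    def __post_init__(self) -> None:
        if len(self.segment_scores) != 12 or len(self.weights) != 12:
            raise ValueError("AGREE needs exactly 12 segment scores and weights")
        if any(not (0.0 <= s <= 1.0) for s in self.segment_scores):
            raise ValueError("segment scores must lie in [0, 1]")
        if any(w <= 0 for w in self.weights):
            raise ValueError("weights must be positive")


#: Default color bands for an AGREE value (score threshold, class), highest first.
AGREE_COLOR_BANDS = ((0.85, "dark green"), (0.7, "green"), (0.55, "yellow"),
                     (0.4, "orange"), (0.0, "red"))


def agree_score(
    assessment: AgreeAssessment,
    color_bands=AGREE_COLOR_BANDS,
) -> tuple[float, str]:
    """Weighted arithmetic mean of the twelve segment scores + color class.

    Invariant to uniform rescaling of the weights; bounded by the smallest
    and largest segment score.
    """
    wsum = sum(assessment.weights)
    overall = sum(
        w * s for w, s in zip(assessment.weights, assessment.segment_scores)
    ) / wsum
    for threshold, name in color_bands:
        if overall >= threshold:
            return overall, name
    return overall, color_bands[-1][1]


GAPI_COLORS = ("green", "yellow", "red")


@dataclasses.dataclass(frozen=True)
class GapiProfile:
    """Fifteen categorical assessment fields, each green/yellow/red."""

    fields: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.fields) != 15:
            raise ValueError(f"GAPI profile needs exactly 15 fields, got {len(self.fields)}")
        bad = [f for f in self.fields if f not in GAPI_COLORS]
        if bad:
            raise ValueError(f"invalid GAPI colors: {bad}")

    def counts(self) -> dict[str, int]:
        return {c: sum(f == c for f in self.fields) for c in GAPI_COLORS}


def gapi_compare(a: GapiProfile, b: GapiProfile) -> dict:
    """Per-color counts and the fewer-reds verdict (ties reported as tie)."""
    ca, cb = a.counts(), b.counts()
    if ca["red"] < cb["red"]:
        verdict = "a"
    elif cb["red"] < ca["red"]:
        verdict = "b"
    else:
        verdict = "tie"
    return {
        "a_counts": ca,
        "b_counts": cb,
        "red_difference": ca["red"] - cb["red"],
        "greener": verdict,
    }


def load_greenness_config(path) -> dict:
    """Parse a YAML greenness config into typed scoring inputs.

    Recognized keys: ``ecoscale: items: [{label, category, pp}, ...]``,
    ``agree: {scores: [12 floats], weights: [12 floats]?}``,
    ``gapi: {a: [15 colors], b: [15 colors]?}``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out: dict = {}
    if "ecoscale" in raw:
        out["ecoscale"] = [
            PenaltyItem(
                label=item["label"],
                category=item["category"],
                penalty_points=int(item["pp"]),
            )
            for item in raw["ecoscale"]["items"]
        ]
    if "agree" in raw:
        kwargs = {"segment_scores": tuple(float(s) for s in raw["agree"]["scores"])}
        if "weights" in raw["agree"]:
            kwargs["weights"] = tuple(float(w) for w in raw["agree"]["weights"])
        out["agree"] = AgreeAssessment(**kwargs)
    if "gapi" in raw:
        out["gapi"] = {
            key: GapiProfile(fields=tuple(raw["gapi"][key]))
            for key in raw["gapi"]
        }
    return out
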