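"""Frequency-weighted ACR TI-RADS feature scoring of sub-nodular regions.

Per-category occurrence probabilities (echogenicity, composition, echogenic
foci) are multiplied by the ACR TI-RADS risk points and summed into a single
weighted score per region class. Shape and margin attributes are excluded:
they are defined for whole nodules only. Relative localization (on/off the
nodule margin) is tabulated but carries no risk points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "RISK_POINTS",
    "FeatureFrequencyTable",
    "weighted_scores",
    "tabulate_from_ratings",
    "report_frame",
]

logger = logging.getLogger(__name__)

ECHOGENICITY_CATEGORIES = ("very hypoechoic", "hypoechoic", "isoechoic")
COMPOSITION_CATEGORIES = ("solid",)
FOCI_CATEGORIES = ("macro-calcification", "punctate calcification", "none")
LOCALIZATION_CATEGORIES = ("on margin", "not on margin")

# ACR TI-RADS risk points per scoreable category. Localization carries none.
RISK_POINTS: dict[str, int] = {
    "very hypoechoic": 3,
    "hypoechoic": 2,
    "isoechoic": 1,
    "solid": 2,
    "punctate calcification": 3,
    "macro-calcification": 1,
    "none": 0,
    # untested in practice (never observed in an all-solid cohort) but
    # defined per ACR TI-RADS composition points
    "cystic": 0,
    "spongiform": 0,
    "mixed cystic and solid": 1,
}

_EXCLUDED_ATTRIBUTES = ("shape", "margin")


class RatingValidationError(ValueError):
    pass


@dataclass
class FeatureFrequencyTable:
    """Counts and probabilities of scoreable features in one region class."""

    region_class: str  # "hot" | "inactivated"
    n_nodules: int
    echogenicity: dict[str, int]
    composition: dict[str, int]
    foci: dict[str, int]
    localization: dict[str, int] = field(default_factory=dict)

    def probabilities(self, attribute: str) -> dict[str, float]:
        counts: Mapping[str, int] = getattr(self, attribute)
        return {cat: c / self.n_nodules for cat, c in counts.items()}

    @classmethod
    def from_probabilities(
        cls,
        region_class: str,
        n_nodules: int,
        echogenicity: Mapping[str, float],
        composition: Mapping[str, float],
        foci: Mapping[str, float],
        localization: Mapping[str, float] | None = None,
    ) -> "FeatureFrequencyTable":
        to_counts = lambda probs: {
            k: int(round(p * n_nodules)) for k, p in probs.items()
        }
        return cls(
            region_class=region_class,
            n_nodules=n_nodules,
            echogenicity=to_counts(echogenicity),
            composition=to_counts(composition),
            foci=to_counts(foci),
            localization=to_counts(localization or {}),
        )


def weighted_scores(
    table: FeatureFrequencyTable,
    points: Mapping[str, int] = RISK_POINTS,
) -> dict:
    """Probability-weighted risk points per category plus the summed score.

    The sum runs over echogenicity + composition + echogenic foci only;
    localization is descriptive.
    """
    per_category: dict[str, float] = {}
    total = 0.0
    for attribute in ("echogenicity", "composition", "foci"):
        for category, prob in table.probabilities(attribute).items():
            if category not in points:
                raise KeyError(f"no risk points defined for category {category!r}")
            score = prob * points[category]
            per_category[category] = score
            total += score
    return {"per_category": per_category, "sum": total}


def tabulate_from_ratings(
    per_nodule_ratings: Iterable[Mapping[str, str]],
    region_class: str = "hot",
) -> FeatureFrequencyTable:
    """Aggregate per-nodule feature records into a frequency table.

    Each record needs ``echogenicity``, ``composition`` and ``foci``;
    ``localization`` is optional. Whole-nodule-only attributes (shape,
    margin) are ignored with a logged notice.
    """
    ratings = list(per_nodule_ratings)
    echogenicity: dict[str, int] = {}
    composition: dict[str, int] = {}
    foci: dict[str, int] = {}
    localization: dict[str, int] = {}
    noticed_excluded = set()
    for idx, record in enumerate(ratings):
        for attr in _EXCLUDED_ATTRIBUTES:
            if attr in record and attr not in noticed_excluded:
                logger.info(
                    "ignoring whole-nodule attribute %r in ratings", attr
                )
                noticed_excluded.add(attr)
        for attr, bucket in (
            ("echogenicity", echogenicity),
            ("composition", composition),
            ("foci", foci),
        ):
            value = record.get(attr)
            if value is None or value == "":
                raise RatingValidationError(
                    f"record {idx} missing required attribute {attr!r}"
                )
            bucket[value] = bucket.get(value, 0) + 1
        loc = record.get("localization")
        if loc:
            localization[loc] = localization.get(loc, 0) + 1
    return FeatureFrequencyTable(
        region_class=region_class,
        n_nodules=len(ratings),
        echogenicity=echogenicity,
        composition=composition,
        foci=foci,
        localization=localization,
    )


def report_frame(
    tables: Iterable[FeatureFrequencyTable],
    points: Mapping[str, int] = RISK_POINTS,
) -> pd.DataFrame:
    """Long-format report: one row per (region class, attribute, category)."""
    rows = []
    for table in tables:
        scores = weighted_scores(table, points)
        for attribute in ("localization", "echogenicity", "composition", "foci"):
            counts: Mapping[str, int] = getattr(table, attribute)
            for category, count in counts.items():
                rows.append(
                    {
                        "region_class": table.region_class,
                        "attribute": attribute,
                        "category": category,
                        "frequency": count,
                        "probability": count / table.n_nodules,
                        "weighted_score": (
                            scores["per_category"].get(category)
                            if attribute != "localization"
                            else None
                        ),
                    }
                )
        rows.append(
            {
                "region_class": table.region_class,
                "attribute": "sum",
                "category": "sum",
                "frequency": table.n_nodules,
                "probability": 1.0,
                "weighted_score": scores["sum"],
            }
        )
    return pd.DataFrame(rows)
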