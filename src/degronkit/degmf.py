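"""Quantitative mutation-impact scoring for degrons (DegMF-style).

Each annotated mutation receives a score in [0, 1] combining (i) a weight
for its functional category — how directly the change attacks the
degradation signal — and (ii) the magnitude of the biochemical change of the
substitution, measured on three standard scales (Kyte–Doolittle hydropathy,
formal side-chain charge at pH 7, side-chain volume), each normalised by its
full range:

    score = w_category + w_biochem * mean(|Δhydropathy|/9.0,
                                          |Δcharge|/2.0,
                                          |Δvolume|/range)

clamped to [0, 1]. Normalisation is by construction (the weight scheme is
validated so the maximum attainable raw score is 1), never by per-batch
min–max, so a score does not depend on what else is in the batch. A mutation
is called *actionable* when its score strictly exceeds 0.5.

The default weights are reimplementation defaults chosen to respect the
qualitative ordering of the categories (direct motif/PTM disruption >
flanking-lysine loss > network rewiring); the whole scheme is config-driven
and validated, so calibrated weights can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .alphabet import (
    CHARGE_PH7,
    CHARGE_RANGE,
    HYDROPATHY_RANGE,
    KYTE_DOOLITTLE,
    SIDE_CHAIN_VOLUME,
    VOLUME_RANGE,
)
from .annotate import CATEGORIES, MutationAnnotation

ACTIONABLE_THRESHOLD = 0.5

DEFAULT_CATEGORY_WEIGHTS = {
    "altering_motif": 0.6,
    "blocking_phospho": 0.6,
    "blocking_ubiq": 0.6,
    "substituting_flanking_lysine": 0.4,
    "rewiring_network": 0.2,
}
DEFAULT_BIOCHEM_WEIGHT = 0.4


class ConfigError(ValueError):
    """Invalid impact-score configuration."""


@dataclass(frozen=True)
class DegMFConfig:
    category_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS)
    )
    biochem_weight: float = DEFAULT_BIOCHEM_WEIGHT
    hydropathy_range: float = HYDROPATHY_RANGE
    charge_range: float = CHARGE_RANGE
    volume_range: float = VOLUME_RANGE

    def __post_init__(self) -> None:
        missing = set(CATEGORIES) - set(self.category_weights)
        if missing:
            raise ConfigError(f"category weights missing {sorted(missing)}")
        for cat, w in self.category_weights.items():
            if not 0.0 <= w <= 1.0:
                raise ConfigError(f"weight for {cat} out of [0,1]: {w}")
        if not 0.0 <= self.biochem_weight <= 1.0:
            raise ConfigError(f"biochem_weight out of [0,1]: {self.biochem_weight}")
        peak = max(self.category_weights.values()) + self.biochem_weight
        if abs(peak - 1.0) > 1e-6:
            raise ConfigError(
                "max(category weight) + biochem_weight must equal 1 so the "
                f"maximum attainable raw score is 1; got {peak}"
            )
        for name in ("hydropathy_range", "charge_range", "volume_range"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "DegMFConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            category_weights=dict(
                raw.get("category_weights", DEFAULT_CATEGORY_WEIGHTS)
            ),
            biochem_weight=float(raw.get("biochem_weight", DEFAULT_BIOCHEM_WEIGHT)),
        )


@dataclass(frozen=True)
class DegMFScore:
    annotation_ref: tuple  # (protein_id, position, ref, alt, degron start/end, motif)
    category: str
    components: dict[str, float]
    score: float
    actionable: bool


def _biochem_terms(ref: str, alt: str, config: DegMFConfig) -> dict[str, float]:
    return {
        "hydropathy_term": min(
            1.0, abs(KYTE_DOOLITTLE[ref] - KYTE_DOOLITTLE[alt]) / config.hydropathy_range
        ),
        "charge_term": min(
            1.0, abs(CHARGE_PH7[ref] - CHARGE_PH7[alt]) / config.charge_range
        ),
        "volume_term": min(
            1.0,
            abs(SIDE_CHAIN_VOLUME[ref] - SIDE_CHAIN_VOLUME[alt]) / config.volume_range,
        ),
    }


def score_substitution(
    ref_aa: str, alt_aa: str, category: str, config: DegMFConfig | None = None
) -> tuple[float, dict[str, float]]:
    """Score one substitution given its functional category.

    Returns (score, components); the score is the category weight plus the
    biochemistry weight times the mean of the three normalised property
    deltas, clamped to [0, 1].
    """
    config = config or DegMFConfig()
    if ref_aa == alt_aa:
        raise ValueError(
            f"synonymous substitution {ref_aa}->{alt_aa}: upstream filter failure"
        )
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    terms = _biochem_terms(ref_aa, alt_aa, config)
    category_term = config.category_weights[category]
    raw = category_term + config.biochem_weight * (
        sum(terms.values()) / len(terms)
    )
    score = min(1.0, max(0.0, raw))
    components = {"category_term": category_term, **terms}
    return score, components


def score_mutation(
    annotation: MutationAnnotation, config: DegMFConfig | None = None
) -> DegMFScore:
    """Impact score for one annotated mutation; actionable iff score > 0.5."""
    m = annotation.mutation
    score, components = score_substitution(
        m.ref_aa, m.alt_aa, annotation.category, config
    )
    return DegMFScore(
        annotation_ref=(
            m.protein_id,
            m.position,
            m.ref_aa,
            m.alt_aa,
            annotation.degron_ref[1],
            annotation.degron_ref[2],
            annotation.degron_ref[3],
        ),
        category=annotation.category,
        components=components,
        score=score,
        actionable=score > ACTIONABLE_THRESHOLD,
    )


def score_batch(
    annotations: Iterable[MutationAnnotation], config: DegMFConfig | None = None
) -> tuple[pd.DataFrame, int]:
    """Score a batch; returns (table, actionable count).

    The table carries one row per annotation with the component columns, and
    supports the per-category score-distribution summary.
    """
    config = config or DegMFConfig()
    rows = []
    for ann in annotations:
        s = score_mutation(ann, config)
        row = {
            "protein_id": s.annotation_ref[0],
            "position": s.annotation_ref[1],
            "ref_aa": s.annotation_ref[2],
            "alt_aa": s.annotation_ref[3],
            "degron_start": s.annotation_ref[4],
            "degron_end": s.annotation_ref[5],
            "motif_name": s.annotation_ref[6],
            "category": s.category,
        }
        row.update(s.components)
        row["score"] = s.score
        row["actionable"] = s.actionable
        rows.append(row)
    table = pd.DataFrame(rows)
    n_actionable = int(table["actionable"].sum()) if len(table) else 0
    return table, n_actionable


def category_score_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Score distribution per category (n, mean, median, quartiles)."""
    if table.empty:
        return pd.DataFrame(
            columns=["category", "n", "mean", "median", "q25", "q75"]
        )
    g = table.groupby("category")["score"]
    return (
        pd.DataFrame(
            {
                "n": g.size(),
                "mean": g.mean(),
                "median": g.median(),
                "q25": g.quantile(0.25),
                "q75": g.quantile(0.75),
            }
        )
        .reset_index()
    )
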