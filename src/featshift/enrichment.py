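"""Feature-level enrichment testing and Bayesian ACMG/AMP reclassification.

Enrichment: for each protein feature, variants are cross-tabulated as
pathogenic/benign × inside/outside the feature and tested with a two-sided
Fisher's exact test; the odds ratio is OR = a·d / (b·c) with a = pathogenic
inside, b = benign inside, c = pathogenic outside, d = benign outside.

Reclassification: ACMG/AMP evidence is combined under the Bayesian point
framework.  Each criterion contributes points by strength tier (supporting 1,
moderate 2, strong 4, very strong 8; benign evidence counts negative), the
combined odds are ``O = O_vs ** (points / 8)`` with ``O_vs = 350`` for a full
very-strong criterion, and the probability of pathogenicity is

    PoP = O·prior / ((O − 1)·prior + 1)

with prior 0.1.  Variants with 0.1 < PoP < 0.9 are of uncertain significance
(VUS); PoP ≥ 0.9 is pathogenic and PoP ≤ 0.1 benign.  A VUS sitting inside a
feature flagged pathogenic-enriched gains the moderate criterion PM1, and is
*reclassified* when the added evidence moves it out of the VUS band.  All
framework constants are configurable.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import VariantRecord, format_protein_variant

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "Evidence",
    "EvidenceSet",
    "PoPResult",
    "FrameworkParams",
    "TIER_POINTS",
    "build_contingency",
    "fisher_enrichment",
    "enrich_features",
    "compute_pop",
    "classify_pop",
    "reclassify_vus",
]

TIER_POINTS = {"supporting": 1, "moderate": 2, "strong": 4, "very strong": 8}


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    """Pathogenic/benign × in-feature/out-of-feature counts."""

    a: int  # pathogenic inside
    b: int  # benign inside
    c: int  # pathogenic outside
    d: int  # benign outside

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("contingency table is empty")


@dataclasses.dataclass(frozen=True)
class EnrichmentResult:
    feature: str
    table: ContingencyTable
    odds_ratio: float          # inf when b·c == 0 and a·d > 0
    or_infinite: bool
    p_value: float
    direction: str             # "pathogenic-enriched" | "benign-enriched" | "neither"


@dataclasses.dataclass(frozen=True)
class Evidence:
    """One ACMG/AMP criterion: name, strength tier and sign."""

    criterion: str
    tier: str                  # supporting | moderate | strong | very strong
    sign: str = "pathogenic"   # or "benign"

    def __post_init__(self) -> None:
        if self.tier not in TIER_POINTS:
            raise ValueError(f"unknown evidence tier {self.tier!r}")
        if self.sign not in {"pathogenic", "benign"}:
            raise ValueError(f"unknown evidence sign {self.sign!r}")

    @property
    def points(self) -> int:
        p = TIER_POINTS[self.tier]
        return p if self.sign == "pathogenic" else -p


PM1 = Evidence("PM1", "moderate", "pathogenic")


@dataclasses.dataclass(frozen=True)
class EvidenceSet:
    items: tuple[Evidence, ...] = ()

    @property
    def points(self) -> int:
        return sum(e.points for e in self.items)

    def with_pm1(self) -> "EvidenceSet":
        if any(e.criterion == "PM1" for e in self.items):
            return self
        return EvidenceSet(self.items + (PM1,))


@dataclasses.dataclass(frozen=True)
class FrameworkParams:
    """Constants of the Bayesian point combiner, all overridable."""

    prior: float = 0.1
    odds_very_strong: float = 350.0

    def __post_init__(self) -> None:
        if not (0 < self.prior < 1):
            raise ValueError("prior must lie in (0, 1)")
        if self.odds_very_strong <= 1:
            raise ValueError("odds_very_strong must exceed 1")


@dataclasses.dataclass(frozen=True)
class PoPResult:
    variant: VariantRecord
    pop: float
    classification: str        # pathogenic | VUS | benign

    @staticmethod
    def from_pop(variant: VariantRecord, pop: float) -> "PoPResult":
        return PoPResult(variant, pop, classify_pop(pop))


def classify_pop(pop: float) -> str:
    """Class boundaries: pathogenic ≥ 0.9, benign ≤ 0.1, VUS in between."""
    if pop >= 0.9:
        return "pathogenic"
    if pop <= 0.1:
        return "benign"
    return "VUS"


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def build_contingency(variants: Sequence[VariantRecord],
                      feature_membership: Sequence[bool]
                      ) -> tuple[ContingencyTable, int]:
    """Cross-tabulate labeled variants by feature membership.

    ``feature_membership[i]`` says whether variant i lies inside the feature
    (from annotated or predicted label tracks).  VUS/unlabeled variants are
    excluded; their count is returned alongside the table.
    """
    if len(variants) != len(feature_membership):
        raise ValueError("variants and membership flags differ in length")
    if not variants:
        raise ValueError("empty variant set")
    a = b = c = d = 0
    excluded = 0
    for variant, inside in zip(variants, feature_membership):
        if variant.label == "pathogenic":
            if inside:
                a += 1
            else:
                c += 1
        elif variant.label == "benign":
            if inside:
                b += 1
            else:
                d += 1
        else:
            excluded += 1
    return ContingencyTable(a, b, c, d), excluded


def fisher_enrichment(table: ContingencyTable, feature: str = "",
                      alpha: float = 0.05,
                      haldane_correction: bool = False) -> EnrichmentResult:
    """Two-sided Fisher's exact test and odds ratio for one 2×2 table.

    OR = a·d / (b·c).  With a zero in b·c the OR is reported as infinity and
    flagged (or, with ``haldane_correction``, computed after adding 0.5 to
    every cell); the exact p-value is computed either way.  Direction is
    pathogenic-enriched when OR > 1 and p ≤ alpha, benign-enriched when
    OR < 1 and p ≤ alpha, otherwise neither.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    or_infinite = False
    if haldane_correction:
        odds_ratio = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    elif b * c == 0:
        if a * d == 0:
            odds_ratio = float("nan")
        else:
            odds_ratio = float("inf")
            or_infinite = True
    else:
        odds_ratio = (a * d) / (b * c)
    if p <= alpha and odds_ratio > 1:
        direction = "pathogenic-enriched"
    elif p <= alpha and odds_ratio < 1:
        direction = "benign-enriched"
    else:
        direction = "neither"
    return EnrichmentResult(feature=feature, table=table,
                            odds_ratio=float(odds_ratio),
                            or_infinite=or_infinite, p_value=float(p),
                            direction=direction)


def enrich_features(tables: Mapping[str, ContingencyTable],
                    alpha: float = 0.05,
                    multiple_testing: str = "bh") -> pd.DataFrame:
    """Test every feature's table, with multiplicity control across features.

    With ``multiple_testing="bh"`` (default) the per-feature p-values are
    Benjamini–Hochberg adjusted and direction calls use the adjusted values
    at FDR ``alpha``; ``"none"`` uses raw p-values.
    """
    if multiple_testing not in {"bh", "none"}:
        raise ValueError("multiple_testing must be 'bh' or 'none'")
    features = sorted(tables)
    raw = [fisher_enrichment(tables[f], feature=f, alpha=alpha)
           for f in features]
    pvals = np.array([r.p_value for r in raw])
    if multiple_testing == "bh" and len(pvals):
        adjusted = stats.false_discovery_control(pvals, method="bh")
    else:
        adjusted = pvals
    rows = []
    for r, p_adj in zip(raw, adjusted):
        if p_adj <= alpha and r.odds_ratio > 1:
            direction = "pathogenic-enriched"
        elif p_adj <= alpha and r.odds_ratio < 1:
            direction = "benign-enriched"
        else:
            direction = "neither"
        rows.append({
            "feature": r.feature, "a": r.table.a, "b": r.table.b,
            "c": r.table.c, "d": r.table.d, "odds_ratio": r.odds_ratio,
            "p_value": r.p_value, "p_adjusted": float(p_adj),
            "direction": direction,
        })
    return pd.DataFrame(rows, columns=["feature", "a", "b", "c", "d",
                                       "odds_ratio", "p_value", "p_adjusted",
                                       "direction"])


# ---------------------------------------------------------------------------
# Probability of pathogenicity
# ---------------------------------------------------------------------------

def compute_pop(evidence: EvidenceSet,
                params: FrameworkParams = FrameworkParams()) -> float:
    """Bayesian point-framework probability of pathogenicity.

    ``O = O_vs ** (points/8)``; ``PoP = O·prior / ((O−1)·prior + 1)``.
    With no evidence O = 1 and PoP equals the prior exactly.
    """
    points = evidence.points
    odds = params.odds_very_strong ** (points / 8.0)
    return (odds * params.prior) / ((odds - 1.0) * params.prior + 1.0)


def reclassify_vus(variants_with_evidence: Sequence[tuple[VariantRecord, EvidenceSet]],
                   enriched_membership: Sequence[bool],
                   params: FrameworkParams = FrameworkParams()) -> pd.DataFrame:
    """PM1-driven reclassification of baseline-VUS variants.

    For each variant, the baseline PoP is computed without PM1.  Variants
    whose baseline class is VUS *and* which lie inside at least one
    pathogenic-enriched feature (``enriched_membership``) are re-scored with
    PM1 added.  Returns a per-variant report; the attached ``reclassified_
    fraction`` attribute is (class changes) / (baseline VUS count).
    """
    if len(variants_with_evidence) != len(enriched_membership):
        raise ValueError("membership flags must match the variant list")
    rows = []
    n_vus = n_reclassified = 0
    for (variant, evidence), in_enriched in zip(variants_with_evidence,
                                                enriched_membership):
        pop_before = compute_pop(evidence, params)
        class_before = classify_pop(pop_before)
        pop_after, class_after = pop_before, class_before
        pm1_applied = False
        if class_before == "VUS" and in_enriched:
            pm1_applied = True
            pop_after = compute_pop(evidence.with_pm1(), params)
            class_after = classify_pop(pop_after)
        if class_before == "VUS":
            n_vus += 1
            if class_after != class_before:
                n_reclassified += 1
        rows.append({
            "variant": format_protein_variant(variant),
            "pop_before": pop_before, "pop_after": pop_after,
            "class_before": class_before, "class_after": class_after,
            "pm1_applied": pm1_applied,
            "reclassified": class_after != class_before,
        })
    report = pd.DataFrame(rows, columns=["variant", "pop_before", "pop_after",
                                         "class_before", "class_after",
                                         "pm1_applied", "reclassified"])
    report.attrs["n_vus"] = n_vus
    report.attrs["n_reclassified"] = n_reclassified
    report.attrs["reclassified_fraction"] = (
        n_reclassified / n_vus if n_vus else math.nan
    )
    return report
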