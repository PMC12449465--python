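"""Ethnicity-specific population cancer incidence construction.

National age-specific incidences are adapted to broad ethnic groups by
multiplying by incidence rate ratios (IRRs).  Published IRRs are usually
expressed relative to the White group; re-standardising them against the
whole population (using the ethnic composition p_e) makes the national
incidence the reference:

    R_e = r_e / sum_e' p_e' r_e'          so that   sum_e p_e R_e = 1.

This keeps the model internally consistent — the composition-weighted mean
of the ethnic incidence curves reproduces the national curve at every age —
and backward compatible: an Unknown ethnicity gets ratio 1 and hence the
unmodified national incidence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "CANCERS",
    "ETHNICITIES",
    "IncidenceTable",
    "IrrSet",
    "EthnicComposition",
    "restandardise_irr",
    "apply_irr",
    "male_bc_rates",
    "asian_grouping",
    "load_uk_irr",
]

CANCERS: tuple[str, ...] = (
    "breast_female",
    "ovarian",
    "prostate",
    "pancreatic_female",
    "pancreatic_male",
    "breast_male",
)

# Broad self-reported ethnicity vocabulary; "Asian" is the pooled group used
# for incidence lookups, "National" labels an un-adapted table.
ETHNICITIES: tuple[str, ...] = (
    "White",
    "Black",
    "Asian",
    "EastAsian",
    "SouthAsian",
    "Mixed",
    "Unknown",
)


@dataclass(frozen=True)
class IncidenceTable:
    """Age-specific cause-specific incidence for one cancer, birth cohort and
    ethnicity.  Rates are hazards in events per person-year on a contiguous
    one-year age grid (half-open intervals [a, a+1))."""

    cancer: str
    cohort: str
    ethnicity: str
    ages: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "rates", rates)
        if self.cancer not in CANCERS:
            raise ValueError(f"unknown cancer {self.cancer!r}")
        if ages.shape != rates.shape or ages.ndim != 1 or ages.size == 0:
            raise ValueError("ages and rates must be equal-length 1-D arrays")
        if not np.all(np.diff(ages) == 1):
            raise ValueError("age grid must be contiguous one-year steps")
        if ages[0] < 0 or ages[-1] > 100:
            raise ValueError("ages must lie within [0, 100]")
        if np.any(rates < 0) or not np.all(np.isfinite(rates)):
            raise ValueError("rates must be finite and non-negative")

    def rate_at(self, age: int) -> float:
        if not self.ages[0] <= age <= self.ages[-1]:
            raise KeyError(f"age {age} outside table range")
        return float(self.rates[age - self.ages[0]])

    def scaled(self, factor: float, ethnicity: str | None = None) -> "IncidenceTable":
        return replace(
            self,
            rates=self.rates * factor,
            ethnicity=self.ethnicity if ethnicity is None else ethnicity,
        )


@dataclass(frozen=True)
class IrrSet:
    """Incidence rate ratios per ethnicity, relative either to the White
    group (``vs_White``) or to the whole population (``vs_Population``)."""

    reference: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if self.reference not in ("vs_White", "vs_Population"):
            raise ValueError(f"unknown reference {self.reference!r}")
        for eth, r in self.values.items():
            if r <= 0:
                raise ValueError(f"non-positive rate ratio for {eth}")
        if self.reference == "vs_White" and self.values.get("White") != 1:
            raise ValueError("a vs_White ratio set must have White = 1")


@dataclass(frozen=True)
class EthnicComposition:
    """Proportion of each broad ethnic group in the reference population."""

    proportions: dict[str, float]

    def __post_init__(self) -> None:
        for eth, p in self.proportions.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"proportion for {eth} outside [0, 1]")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition sums to {total}, expected 1")


def restandardise_irr(irr_vs_white: IrrSet, composition: EthnicComposition) -> IrrSet:
    """Rescale rate ratios so the whole population is the reference.

    R_e = r_e / sum_e' p_e' r_e'.  The output satisfies the conservation
    identity sum_e p_e R_e = 1 and preserves all pairwise ratios; the
    operation is scale-invariant in r and idempotent on an already
    population-referenced set (with the same composition).
    """
    if set(irr_vs_white.values) != set(composition.proportions):
        raise ValueError(
            "ethnicity keys differ between ratios "
            f"({sorted(irr_vs_white.values)}) and composition "
            f"({sorted(composition.proportions)})"
        )
    mean_ratio = sum(
        composition.proportions[e] * r for e, r in irr_vs_white.values.items()
    )
    return IrrSet(
        reference="vs_Population",
        values={e: r / mean_ratio for e, r in irr_vs_white.values.items()},
    )


def asian_grouping(ethnicity: str) -> str:
    """Map East and South Asian to the pooled Asian group used for incidence
    rate ratios (small registration counts force pooling); all other labels
    map to themselves."""
    return "Asian" if ethnicity in ("EastAsian", "SouthAsian") else ethnicity


def apply_irr(national: IncidenceTable, irr: IrrSet, ethnicity: str) -> IncidenceTable:
    """Scale a national incidence table by the population-referenced rate
    ratio of ``ethnicity``.  Unknown ethnicity keeps the national rates
    unchanged (ratio 1), preserving backward compatibility."""
    if irr.reference != "vs_Population":
        raise ValueError("ratios must be re-standardised to vs_Population first")
    if ethnicity == "Unknown":
        factor = 1.0
    else:
        key = asian_grouping(ethnicity)
        if key not in irr.values:
            raise KeyError(f"no incidence rate ratio for ethnicity {ethnicity!r}")
        factor = irr.values[key]
    return national.scaled(factor, ethnicity=ethnicity)


def male_bc_rates(national: IncidenceTable, ethnicity: str = "Unknown") -> IncidenceTable:
    """Male breast cancer incidence, assumed independent of ethnicity (no
    registration data support ethnic ratios): the national table is returned
    for every ethnicity, relabelled only."""
    return national.scaled(1.0, ethnicity=ethnicity)


def load_uk_irr(cancer: str) -> IrrSet:
    """Published UK population-referenced rate ratios for ``cancer`` (2016
    composition; Asian = pooled South + East Asian)."""
    text = resources.files("ethnirisk.data").joinpath("uk_irr_2016.yaml").read_text()
    data = yaml.safe_load(text)
    if cancer not in data["values"]:
        raise KeyError(f"no published rate ratios for cancer {cancer!r}")
    return IrrSet(reference=data["reference"], values=dict(data["values"][cancer]))
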