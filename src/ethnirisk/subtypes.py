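"""Breast tumour subtype distributions for pathogenic-variant carriers.

Tumours are classified into three subtypes: ER-positive, triple negative
(TN: ER, PR and HER2 negative), and ER-negative-but-not-TN.  Population
subtype proportions vary by age band and ethnicity; carriers of PVs in
susceptibility genes have systematically different subtype odds (e.g. BRCA1
tumours are predominantly TN), with the odds ratios themselves varying with
age at diagnosis.

Carrier proportions are derived by an odds update of the population
distribution:

    p_carrier(s) propto p_pop(s) * exp( log_OR(s) + slope(s) * (age - ref) )

renormalised over the three subtypes (the reference subtype has log-OR 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SUBTYPES", "SubtypeDistribution", "SubtypeEffect", "carrier_subtype_distribution"]

SUBTYPES: tuple[str, ...] = ("ER_positive", "TN", "ER_negative_not_TN")


@dataclass(frozen=True)
class AgeBand:
    low: int
    high: int  # inclusive

    def __contains__(self, age) -> bool:
        return self.low <= age <= self.high


@dataclass
class SubtypeDistribution:
    """Population subtype probabilities keyed by (age band, ethnicity).

    ``by_age_ethnicity`` maps ((low, high), ethnicity) -> probability dict
    over SUBTYPES; queries snap to the containing band.
    """

    by_age_ethnicity: dict[tuple[tuple[int, int], str], dict[str, float]]

    def __post_init__(self) -> None:
        for key, probs in self.by_age_ethnicity.items():
            if set(probs) != set(SUBTYPES):
                raise ValueError(f"{key}: probabilities must cover {SUBTYPES}")
            vec = np.array([probs[s] for s in SUBTYPES])
            if np.any(vec < 0) or abs(vec.sum() - 1.0) > 1e-9:
                raise ValueError(f"{key}: probabilities must be a simplex point")

    def lookup(self, age: int, ethnicity: str) -> dict[str, float]:
        for (band, eth), probs in self.by_age_ethnicity.items():
            if eth == ethnicity and band[0] <= age <= band[1]:
                return probs
        raise KeyError(f"no subtype distribution for age {age}, ethnicity {ethnicity!r}")


@dataclass
class SubtypeEffect:
    """Per-gene subtype odds ratios with per-year age interactions on the
    log scale, centred at ``reference_age``.  The reference subtype's
    log-OR is fixed at 0."""

    gene: str
    log_or_by_subtype: dict[str, float]
    age_interaction_by_subtype: dict[str, float] = field(default_factory=dict)
    reference_age: int = 50

    def __post_init__(self) -> None:
        if not any(abs(v) < 1e-12 for v in self.log_or_by_subtype.values()):
            raise ValueError(f"{self.gene}: one subtype must be the log-OR reference (0)")

    def log_or(self, subtype: str, age: int) -> float:
        base = self.log_or_by_subtype.get(subtype, 0.0)
        slope = self.age_interaction_by_subtype.get(subtype, 0.0)
        return base + slope * (age - self.reference_age)


def carrier_subtype_distribution(
    pop: SubtypeDistribution, effect: SubtypeEffect, age: int, ethnicity: str
) -> dict[str, float]:
    """Age-, ethnicity- and gene-specific subtype probabilities for a PV
    carrier, by odds-updating the population distribution."""
    base = pop.lookup(age, ethnicity)
    unnorm = {s: base[s] * float(np.exp(effect.log_or(s, age))) for s in SUBTYPES}
    total = sum(unnorm.values())
    return {s: v / total for s, v in unnorm.items()}
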