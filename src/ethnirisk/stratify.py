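"""Population risk distributions and guideline risk-category proportions.

Absolute lifetime risks (age 20-80) are computed for every combination of
the requested predictors (PGS on a standard-normal quadrature grid, QRF
categories, MD/BIRADS categories), weighted by the frequency of each
combination in the ethnic reference population (factors independent within
ethnicity).  The weighted risk distribution is then binned against national
guideline thresholds: NICE breast cancer categories are population (<17%
lifetime risk), moderate (17-30%) and high (>=30%); the ovarian scheme uses
3.5% and 5% (the surgery-discussion threshold).  Thresholds belong to the
upper category.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .pgs import AncestryParams
from .risk import ETHNICITY_TO_ANCESTRY, ModelConfig, RiskCalculator, gauss_hermite_grid

__all__ = [
    "RiskDistribution",
    "CategoryScheme",
    "NICE_BC",
    "NICE_EOC",
    "enumerate_distribution",
    "categorise",
    "population_mixture",
]


@dataclass
class RiskDistribution:
    """Weighted set of (absolute risk, probability mass) points."""

    risks: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        self.risks = np.asarray(self.risks, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.risks.shape != self.masses.shape or self.risks.ndim != 1:
            raise ValueError("risks and masses must be equal-length 1-D arrays")
        if np.any(self.masses < 0) or abs(self.masses.sum() - 1.0) > 1e-9:
            raise ValueError("masses must be non-negative and sum to 1")
        if np.any((self.risks < 0) | (self.risks > 1)):
            raise ValueError("risks must lie in [0, 1]")

    def mean(self) -> float:
        return float(self.masses @ self.risks)

    def variance(self) -> float:
        m = self.mean()
        return float(self.masses @ (self.risks - m) ** 2)

    def quantile(self, q: float) -> float:
        order = np.argsort(self.risks)
        cum = np.cumsum(self.masses[order])
        idx = int(np.searchsorted(cum, q))
        return float(self.risks[order][min(idx, self.risks.size - 1)])


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered lifetime-risk cut points; categories are half-open with the
    threshold belonging to the upper category."""

    name: str
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        if not all(0.0 < t < 1.0 for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1)")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")


NICE_BC = CategoryScheme("nice_bc", (0.17, 0.30))
NICE_EOC = CategoryScheme("nice_eoc", (0.035, 0.05))


def enumerate_distribution(
    ethnicity: str,
    predictors: set[str] | frozenset[str],
    config: ModelConfig,
    from_age: int = 20,
    to_age: int = 80,
    calculator: RiskCalculator | None = None,
) -> RiskDistribution:
    """Weighted lifetime-risk distribution over all combinations of the
    requested predictors (subset of {"PGS", "QRF", "MD"}) for one ethnicity.

    PGS is discretised on the polygene quadrature grid of standard-normal Z
    values; factor combinations are weighted by the product of their
    per-ethnicity category frequencies (independence across factors).
    Requesting PGS for Mixed ethnicity without ancestry information is an
    error (no single-ancestry standardisation parameters exist).
    """
    predictors = set(predictors)
    unknown = predictors - {"PGS", "QRF", "MD"}
    if unknown:
        raise ValueError(f"unknown predictors: {sorted(unknown)}")
    calc = calculator or RiskCalculator(config, ethnicity)
    n_ages = calc.ages.size
    sd = config.polygene.sd_row(n_ages)

    rows: list[np.ndarray] = [np.zeros(n_ages)]
    weights: list[float] = [1.0]

    def cross(level_rows: list[np.ndarray], level_weights: list[float]) -> None:
        nonlocal rows, weights
        rows = [r + lr for r, lr in itertools.product(rows, level_rows)]
        weights = [w * lw for w, lw in itertools.product(weights, level_weights)]

    systems = []
    if "QRF" in predictors:
        systems.extend(config.qrf_factors)
    if "MD" in predictors:
        if config.birads is None:
            raise ValueError("MD requested but no BIRADS system configured")
        systems.append(config.birads)
    for system in systems:
        prev = system.prevalences(ethnicity)
        level_rows = [
            np.broadcast_to(np.asarray(system.log_rr[lv], dtype=float), (n_ages,)).copy()
            if np.ndim(system.log_rr[lv]) else np.full(n_ages, float(system.log_rr[lv]))
            for lv in system.levels
        ]
        cross(level_rows, [prev[lv] for lv in system.levels])

    residual_alpha = None
    if "PGS" in predictors:
        ancestry = ETHNICITY_TO_ANCESTRY.get(ethnicity)
        if ancestry is None:
            raise ValueError(
                f"PGS requested for {ethnicity!r} ethnicity: no single-ancestry "
                "standardisation parameters; supply an ancestry profile instead"
            )
        if ancestry not in config.pgs_params:
            raise KeyError(f"no PGS parameters configured for ancestry {ancestry}")
        par: AncestryParams = config.pgs_params[ancestry]
        residual_alpha = par.alpha
        nodes, node_w = gauss_hermite_grid(config.polygene.n_nodes)
        # measured polygene contribution alpha * Z on the hazard scale
        cross([sd * (par.alpha * z) for z in nodes], list(node_w))

    obs = np.stack(rows)
    risks = calc.risks_for_multipliers(
        obs, from_age=from_age, to_age=to_age, residual_alpha=residual_alpha
    )
    return RiskDistribution(risks=risks, masses=np.array(weights))


def categorise(dist: RiskDistribution, scheme: CategoryScheme) -> np.ndarray:
    """Probability mass per risk category: bins [0, t1), [t1, t2), ...,
    [t_last, 1]."""
    idx = np.digitize(dist.risks, scheme.thresholds)
    out = np.zeros(len(scheme.thresholds) + 1)
    np.add.at(out, idx, dist.masses)
    return out


def population_mixture(per_ethnicity: dict[str, RiskDistribution], composition) -> RiskDistribution:
    """Composition-weighted union of per-ethnicity risk distributions (the
    all-ethnicity population distribution)."""
    props = composition.proportions if hasattr(composition, "proportions") else dict(composition)
    if abs(sum(props.values()) - 1.0) > 1e-9:
        raise ValueError("composition proportions must sum to 1")
    missing = set(props) - set(per_ethnicity)
    if missing:
        raise KeyError(f"no risk distribution for: {sorted(missing)}")
    risks = np.concatenate([per_ethnicity[e].risks for e in props])
    masses = np.concatenate([per_ethnicity[e].masses * p for e, p in props.items()])
    return RiskDistribution(risks=risks, masses=masses)
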