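"""Incidence-constrained multiplicative hazard model and absolute risks.

The cancer hazard for a woman with genotype/risk-factor stratum g is

    lambda_g(t) = lambda_0(t) * RR_g(t),

where the stratum relative risk multiplies contributions from questionnaire
risk factors (QRFs), mammographic density (MD), pathogenic variants (PVs) in
major susceptibility genes, and a standard-normal polygene x_P (entering as
exp(sd_P(t) * x_P)).  The baseline lambda_0(t) is not free: it is solved so
that the survivor-weighted cohort-average incidence reproduces the
population incidence mu(t) at every age,

    lambda_0(t) = mu(t) * sum_g pi_g S_g(t) / sum_g pi_g S_g(t) RR_g(t),

sequentially in age with S_g the stratum survivor function.  Risks for a
partially observed profile are survivor-weighted mixtures over the
unobserved components (residual polygene on a Gauss-Hermite grid, untested
genes over their carrier prevalence), so a fully unobserved profile
reproduces the population incidence exactly.

Absolute risk between ages a and b is the cause-specific cumulative risk
1 - exp(-sum_t lambda(t)) over integer ages in [a, b); competing mortality
is deliberately not modelled here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite_e import hermegauss

from .incidence import IncidenceTable, IrrSet, apply_irr
from .pgs import (
    ANCESTRIES,
    EUROPEAN,
    AncestryParams,
    AncestryProfile,
    NormalisedPgs,
)

__all__ = [
    "RiskStratum",
    "PolygeneSpec",
    "MajorGene",
    "FactorSystem",
    "RiskProfile",
    "ModelConfig",
    "RiskCalculator",
    "constrain_baseline",
    "cohort_average_incidence",
    "absolute_risk",
    "carrier_lifetime_risk",
    "gauss_hermite_grid",
    "ETHNICITY_TO_ANCESTRY",
]

# Self-reported ethnicity proxies genetic ancestry when no ancestry profile
# is available (used for PV frequencies and PGS parameters).  Mixed has no
# single proxy: PGS-bearing calculations require an ancestry profile.
ETHNICITY_TO_ANCESTRY: dict[str, str | None] = {
    "White": "European",
    "Black": "African",
    "EastAsian": "EastAsian",
    "SouthAsian": "SouthAsian",
    "Asian": "EastAsian",
    "Mixed": None,
    "Unknown": "European",
}


def gauss_hermite_grid(n: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Probabilists' Gauss-Hermite nodes/weights for integrating against a
    standard normal; weights normalised to sum to 1."""
    nodes, weights = hermegauss(n)
    return nodes, weights / weights.sum()


def _as_age_row(value, n_ages: int) -> np.ndarray:
    row = np.asarray(value, dtype=float)
    if row.ndim == 0:
        return np.full(n_ages, float(row))
    if row.shape != (n_ages,):
        raise ValueError(f"expected scalar or length-{n_ages} age profile")
    return row


@dataclass(frozen=True)
class RiskStratum:
    """One fully crossed stratum: prevalence at birth and a log relative
    risk per age."""

    label: str
    prevalence: float
    log_rr_by_age: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")


@dataclass
class PolygeneSpec:
    """Residual-familial polygene: standard-normal x_P entering the hazard
    as exp(sd_by_age(t) * x_P), discretised on a Gauss-Hermite grid.

    ``sd_by_age`` is the model polygenic SD on the log-hazard scale (a
    configurable stand-in; scalar = age-constant).
    """

    sd_by_age: float | np.ndarray = 1.2
    n_nodes: int = 64

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 quadrature nodes")
        if np.any(np.asarray(self.sd_by_age, dtype=float) <= 0):
            raise ValueError("polygenic sd must be positive")

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        nodes, weights = gauss_hermite_grid(self.n_nodes)
        if abs(weights.sum() - 1.0) > 1e-9:
            raise AssertionError("quadrature weights must sum to 1")
        return nodes, weights

    def sd_row(self, n_ages: int) -> np.ndarray:
        return _as_age_row(self.sd_by_age, n_ages)


@dataclass
class MajorGene:
    """A susceptibility gene carrying rare pathogenic variants, modelled as
    dominant: carrier prevalence 2q(1-q) + q^2 from allele frequency q
    (ancestry-specific; CHEK2 is the notable case, with c.1100del largely
    confined to Europeans)."""

    gene: str
    pv_frequency_by_ancestry: dict[str, float]
    rr_by_age: float | np.ndarray

    def __post_init__(self) -> None:
        for anc, q in self.pv_frequency_by_ancestry.items():
            if not 0.0 <= q < 0.05:
                raise ValueError(f"{self.gene}: allele frequency {q} for {anc} not in [0, 0.05)")
        if np.any(~np.isfinite(np.asarray(self.rr_by_age, dtype=float))):
            raise ValueError(f"{self.gene}: non-finite relative risk")

    def allele_frequency(self, ancestry: str | AncestryProfile | None) -> float:
        if isinstance(ancestry, AncestryProfile):
            return sum(
                p * self.allele_frequency(anc)
                for anc, p in ancestry.proportions.items()
            )
        if ancestry is None:
            ancestry = EUROPEAN
        return self.pv_frequency_by_ancestry.get(
            ancestry, self.pv_frequency_by_ancestry[EUROPEAN]
        )

    def carrier_prevalence(self, ancestry: str | AncestryProfile | None) -> float:
        q = self.allele_frequency(ancestry)
        return 2.0 * q * (1.0 - q) + q * q


@dataclass
class FactorSystem:
    """A categorical multiplicative risk factor (a QRF, or MD on the BIRADS
    scale): per-level log relative risks and per-ethnicity level
    prevalences (key ``default`` is the fallback)."""

    name: str
    levels: tuple[str, ...]
    log_rr: dict[str, float | np.ndarray]
    prevalence_by_ethnicity: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for eth, dist in self.prevalence_by_ethnicity.items():
            if set(dist) != set(self.levels):
                raise ValueError(f"{self.name}/{eth}: levels do not match prevalence keys")
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{self.name}/{eth}: prevalences sum to {total}")
        if set(self.log_rr) != set(self.levels):
            raise ValueError(f"{self.name}: levels do not match log_rr keys")

    def prevalences(self, ethnicity: str) -> dict[str, float]:
        if ethnicity in self.prevalence_by_ethnicity:
            return self.prevalence_by_ethnicity[ethnicity]
        if "default" in self.prevalence_by_ethnicity:
            return self.prevalence_by_ethnicity["default"]
        raise KeyError(f"{self.name}: no prevalence distribution for {ethnicity!r}")


@dataclass
class RiskProfile:
    """What is known about one woman.  Unset components are integrated over
    their population distribution."""

    ethnicity: str = "Unknown"
    ancestry_profile: AncestryProfile | None = None
    pgs: NormalisedPgs | None = None
    qrf_categories: dict[str, str] = field(default_factory=dict)
    birads: str | None = None
    carrier_status: dict[str, str] = field(default_factory=dict)


@dataclass
class ModelConfig:
    """Full model configuration for one cancer: national incidence, ethnic
    rate ratios, major genes, polygene scale, factor systems and PGS
    standardisation parameters."""

    cancer: str
    national: IncidenceTable
    irr: IrrSet | None = None
    genes: list[MajorGene] = field(default_factory=list)
    polygene: PolygeneSpec = field(default_factory=PolygeneSpec)
    qrf_factors: list[FactorSystem] = field(default_factory=list)
    birads: FactorSystem | None = None
    pgs_params: dict[str, AncestryParams] = field(default_factory=dict)

    def incidence_for(self, ethnicity: str) -> IncidenceTable:
        if self.irr is None or ethnicity == "Unknown":
            return self.national.scaled(1.0, ethnicity=ethnicity)
        return apply_irr(self.national, self.irr, ethnicity)

    def factor(self, name: str) -> FactorSystem:
        for f in self.qrf_factors:
            if f.name == name:
                return f
        if self.birads is not None and self.birads.name == name:
            return self.birads
        raise KeyError(f"factor {name!r} is not part of the solved stratification")


# ---------------------------------------------------------------------------
# Core solver


@dataclass(frozen=True)
class _Axis:
    """One independent component of the stratification grid."""

    name: str
    masses: np.ndarray  # (L,), sums to 1
    log_rr: np.ndarray  # (L, A)


def _expand(axes: list[_Axis], n_ages: int) -> tuple[np.ndarray, np.ndarray]:
    """Cartesian product of axes -> (masses (G,), log_rr (G, A))."""
    masses = np.ones(1)
    log_rr = np.zeros((1, n_ages))
    for ax in axes:
        masses = np.multiply.outer(masses, ax.masses).ravel()
        log_rr = (log_rr[:, None, :] + ax.log_rr[None, :, :]).reshape(-1, n_ages)
    return masses, log_rr


def _solve_baseline(mu: np.ndarray, masses: np.ndarray, rr: np.ndarray) -> np.ndarray:
    """Sequential age-by-age baseline solve (rr is (G, A))."""
    if np.any(mu > 1.0):
        raise ValueError("population incidence exceeds one event per person-year; "
                         "the yearly hazard grid is too coarse")
    n_ages = mu.size
    survivors = np.ones_like(masses)
    lam0 = np.empty(n_ages)
    for t in range(n_ages):
        at_risk = masses * survivors
        lam0[t] = mu[t] * at_risk.sum() / (at_risk @ rr[:, t])
        survivors = survivors * np.exp(-lam0[t] * rr[:, t])
    return lam0


def constrain_baseline(population: IncidenceTable, strata: list[RiskStratum]) -> np.ndarray:
    """Solve the baseline hazard over the population table's age grid so the
    survivor-weighted average incidence of ``strata`` reproduces the
    population incidence at every age."""
    masses = np.array([s.prevalence for s in strata])
    if abs(masses.sum() - 1.0) > 1e-9:
        raise ValueError(f"stratum prevalences sum to {masses.sum()}, expected 1")
    n_ages = population.ages.size
    rr = np.exp(np.stack([_as_age_row(s.log_rr_by_age, n_ages) for s in strata]))
    return _solve_baseline(population.rates, masses, rr)


def cohort_average_incidence(
    lam0: np.ndarray, masses: np.ndarray, rr: np.ndarray
) -> np.ndarray:
    """Survivor-weighted cohort-average incidence implied by a baseline and
    stratification; equals the constraining population incidence when lam0
    came from the solver."""
    n_ages = lam0.size
    survivors = np.ones_like(masses)
    out = np.empty(n_ages)
    for t in range(n_ages):
        at_risk = masses * survivors
        out[t] = (at_risk @ rr[:, t]) * lam0[t] / at_risk.sum()
        survivors = survivors * np.exp(-lam0[t] * rr[:, t])
    return out


def absolute_risk(hazard, from_age: int, to_age: int, ages: np.ndarray | None = None) -> float:
    """Cause-specific cumulative risk 1 - exp(-sum hazard) over integer ages
    in [from_age, to_age).  ``hazard`` is a mapping age -> rate, or an array
    aligned with ``ages``."""
    if from_age >= to_age:
        raise ValueError("from_age must be below to_age")
    span = range(from_age, to_age)
    if isinstance(hazard, dict):
        missing = [a for a in span if a not in hazard]
        if missing:
            raise KeyError(f"hazard undefined at ages {missing[:3]}...")
        total = sum(hazard[a] for a in span)
    else:
        hazard = np.asarray(hazard, dtype=float)
        if ages is None:
            raise ValueError("ages required with an array hazard")
        idx = np.searchsorted(ages, [from_age, to_age])
        if ages[0] > from_age or ages[-1] < to_age - 1:
            raise KeyError("hazard does not cover the requested age span")
        total = float(hazard[idx[0]: idx[1]].sum())
    return 1.0 - float(np.exp(-total))


# ---------------------------------------------------------------------------
# Profile-level calculator


class RiskCalculator:
    """Solves the constrained baseline for one ethnicity and evaluates
    hazards/absolute risks for arbitrary partially observed profiles.

    The reference stratification crosses every configured component (genes x
    QRFs x MD x polygene grid) at its population prevalence for the
    ethnicity; profile hazards condition on the observed components and
    survivor-weight over the rest.
    """

    def __init__(self, config: ModelConfig, ethnicity: str = "Unknown",
                 ancestry: str | AncestryProfile | None = None):
        self.config = config
        self.ethnicity = ethnicity
        if ancestry is None:
            ancestry = ETHNICITY_TO_ANCESTRY.get(ethnicity, EUROPEAN)
        self.ancestry = ancestry
        self.population = config.incidence_for(ethnicity)
        self.ages = self.population.ages
        self._n_ages = self.ages.size
        axes = self._reference_axes()
        masses, log_rr = _expand(axes, self._n_ages)
        self._ref_rr = np.exp(log_rr)
        self._ref_masses = masses
        self.baseline = _solve_baseline(self.population.rates, masses, self._ref_rr)

    # -- stratification assembly

    def _factor_axis(self, system: FactorSystem, observed: str | None) -> _Axis:
        n = self._n_ages
        if observed is not None:
            if observed not in system.levels:
                raise KeyError(f"{system.name}: unknown level {observed!r}")
            return _Axis(system.name, np.ones(1),
                         _as_age_row(system.log_rr[observed], n)[None, :])
        prev = system.prevalences(self.ethnicity)
        masses = np.array([prev[lv] for lv in system.levels])
        rows = np.stack([_as_age_row(system.log_rr[lv], n) for lv in system.levels])
        return _Axis(system.name, masses, rows)

    def _gene_axis(self, gene: MajorGene, status: str) -> _Axis:
        n = self._n_ages
        log_rr = np.log(_as_age_row(gene.rr_by_age, n))
        if status == "carrier":
            return _Axis(gene.gene, np.ones(1), log_rr[None, :])
        if status == "non-carrier":
            return _Axis(gene.gene, np.ones(1), np.zeros((1, n)))
        if status == "untested":
            f = gene.carrier_prevalence(self.ancestry)
            return _Axis(gene.gene, np.array([1.0 - f, f]),
                         np.stack([np.zeros(n), log_rr]))
        raise ValueError(f"unknown carrier status {status!r} for {gene.gene}")

    def _polygene_axis(self, pgs: NormalisedPgs | None) -> list[_Axis]:
        n = self._n_ages
        sd = self.config.polygene.sd_row(n)
        nodes, weights = self.config.polygene.grid()
        if pgs is None:
            # fully latent polygene: x_P on the standard-normal grid
            return [_Axis("polygene", weights, np.outer(nodes, sd))]
        # measured part alpha*Z plus residual of variance 1 - alpha^2
        z_scaled = pgs.alpha * pgs.z
        resid_sd = float(np.sqrt(1.0 - pgs.alpha**2))
        measured = _Axis("pgs", np.ones(1), (sd * z_scaled)[None, :])
        residual = _Axis("polygene_residual", weights,
                         np.outer(nodes * resid_sd, sd))
        return [measured, residual]

    def _reference_axes(self) -> list[_Axis]:
        axes = [self._gene_axis(g, "untested") for g in self.config.genes]
        for system in self.config.qrf_factors:
            axes.append(self._factor_axis(system, None))
        if self.config.birads is not None:
            axes.append(self._factor_axis(self.config.birads, None))
        axes.extend(self._polygene_axis(None))
        return axes

    def _profile_axes(self, profile: RiskProfile) -> list[_Axis]:
        known = dict(profile.qrf_categories)
        names = {f.name for f in self.config.qrf_factors}
        if self.config.birads is not None:
            names.add(self.config.birads.name)
        unknown_factors = set(known) - names
        if unknown_factors:
            raise KeyError(
                f"profile references factors absent from the stratification: "
                f"{sorted(unknown_factors)}"
            )
        configured = {g.gene for g in self.config.genes}
        unknown_genes = set(profile.carrier_status) - configured
        if unknown_genes:
            raise KeyError(f"unknown gene(s) in profile: {sorted(unknown_genes)}")
        axes = [
            self._gene_axis(g, profile.carrier_status.get(g.gene, "untested"))
            for g in self.config.genes
        ]
        for system in self.config.qrf_factors:
            axes.append(self._factor_axis(system, known.get(system.name)))
        if self.config.birads is not None:
            axes.append(self._factor_axis(self.config.birads, profile.birads))
        axes.extend(self._polygene_axis(profile.pgs))
        return axes

    # -- evaluation

    def hazard_for_profile(self, profile: RiskProfile | None = None) -> np.ndarray:
        """Survivor-weighted mixture hazard over the components not observed
        in ``profile`` (empty profile -> population incidence)."""
        profile = profile or RiskProfile(ethnicity=self.ethnicity)
        masses, log_rr = _expand(self._profile_axes(profile), self._n_ages)
        rr = np.exp(log_rr)
        survivors = np.ones_like(masses)
        out = np.empty(self._n_ages)
        for t in range(self._n_ages):
            at_risk = masses * survivors
            out[t] = self.baseline[t] * (at_risk @ rr[:, t]) / at_risk.sum()
            survivors = survivors * np.exp(-self.baseline[t] * rr[:, t])
        return out

    def absolute_risk(self, profile: RiskProfile | None = None,
                      from_age: int = 20, to_age: int = 80) -> float:
        hazard = self.hazard_for_profile(profile)
        return absolute_risk(hazard, from_age, to_age, ages=self.ages)

    def risks_for_multipliers(self, obs_log_rr: np.ndarray,
                              from_age: int = 20, to_age: int = 80,
                              residual_alpha: float | None = None,
                              chunk: int = 128) -> np.ndarray:
        """Vectorised absolute risks for many observed log-RR age rows.

        ``obs_log_rr`` is (C, A): each row the summed log relative risk of
        the observed components of one predictor combination (including any
        measured PGS contribution).  The latent part (untested genes, and
        the polygene residual when ``residual_alpha`` is the measured-score
        alpha, or the full polygene when None) is survivor-weighted out.
        """
        n = self._n_ages
        obs_log_rr = np.atleast_2d(np.asarray(obs_log_rr, dtype=float))
        if obs_log_rr.shape[1] != n:
            raise ValueError("observed log-RR rows must span the age grid")
        latent = [self._gene_axis(g, "untested") for g in self.config.genes]
        sd = self.config.polygene.sd_row(n)
        nodes, weights = self.config.polygene.grid()
        scale = 1.0 if residual_alpha is None else float(np.sqrt(1.0 - residual_alpha**2))
        latent.append(_Axis("polygene", weights, np.outer(nodes * scale, sd)))
        u_mass, u_log = _expand(latent, n)
        u_rr = np.exp(u_log)  # (U, A)
        lo, hi = np.searchsorted(self.ages, [from_age, to_age])
        risks = np.empty(obs_log_rr.shape[0])
        for start in range(0, obs_log_rr.shape[0], chunk):
            block = np.exp(obs_log_rr[start:start + chunk])  # (c, A)
            rr = block[:, None, :] * u_rr[None, :, :]  # (c, U, A)
            haz = self.baseline[None, None, :] * rr
            # survivor function entering each age (exclusive cumulative)
            cum = np.cumsum(haz, axis=2)
            surv = np.exp(-(cum - haz))
            at_risk = u_mass[None, :, None] * surv
            mix_haz = (at_risk * haz).sum(axis=1) / at_risk.sum(axis=1)
            risks[start:start + chunk] = 1.0 - np.exp(-mix_haz[:, lo:hi].sum(axis=1))
        return risks


def carrier_lifetime_risk(gene: str, ethnicity: str, config: ModelConfig,
                          from_age: int = 20, to_age: int = 80) -> float:
    """Absolute risk between ``from_age`` and ``to_age`` for a PV carrier in
    ``gene``, polygene and other components integrated out, using the
    ethnicity-specific incidence."""
    if gene not in {g.gene for g in config.genes}:
        raise KeyError(f"gene {gene!r} is not configured")
    calc = RiskCalculator(config, ethnicity)
    profile = RiskProfile(ethnicity=ethnicity, carrier_status={gene: "carrier"})
    return calc.absolute_risk(profile, from_age, to_age)
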