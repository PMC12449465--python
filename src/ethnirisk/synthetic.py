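"""Synthetic fixtures: toy PGS panels, admixed genotypes, incidence curves
and risk-factor configurations.

Everything needed to exercise the full pipeline is generated in memory from
a seed, with no external downloads.  The admixture simulator draws, per
individual and per SNP independently, an ancestry label from the profile
proportions and then a diploid genotype at that ancestry's frequency under
HWE — the locus-independent admixture model that underlies the
mixed-ancestry PGS variance formula, whose cross-ancestry term
4 sum_k w_k^2 Var_i(q_ik) is exactly the haplotype covariance induced by
the two homologous copies sharing local ancestry (no linkage or ancestry
tracts; see the methods note).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .incidence import IncidenceTable, load_uk_irr
from .pgs import (
    ANCESTRIES,
    DEFAULT_PGS_PARAMS,
    AncestryParams,
    AncestryProfile,
    PgsModel,
    SnpEntry,
)
from .risk import FactorSystem, MajorGene, ModelConfig, PolygeneSpec

__all__ = [
    "make_toy_pgs_model",
    "simulate_admixed_genotypes",
    "make_toy_incidence",
    "make_toy_factor_system",
    "make_toy_config",
    "make_uk_like_config",
]


def make_toy_pgs_model(
    n_snps: int = 10,
    seed: int = 0,
    name: str = "TOY",
    alphas: dict[str, float] | None = None,
) -> PgsModel:
    """Random PGS panel with analytically consistent per-ancestry moments.

    Weights ~ Normal(0, 0.1^2); effect-allele frequencies ~ Uniform(0.05,
    0.95) independently per ancestry.  Under HWE the per-ancestry mean and
    SD of the raw score are exact: mu_i = 2 sum_k q_ik w_k and
    sigma_i^2 = 2 sum_k q_ik (1 - q_ik) w_k^2.  Alphas default to the
    breast 309-SNP published values.
    """
    rng = np.random.default_rng(seed)
    weights = rng.normal(0.0, 0.1, n_snps)
    freqs = rng.uniform(0.05, 0.95, (len(ANCESTRIES), n_snps))
    if alphas is None:
        alphas = {a: DEFAULT_PGS_PARAMS["BC-309"][a][2] for a in ANCESTRIES}
    snps = [
        SnpEntry(
            snp_id=f"{(k % 22) + 1}_{10_000 + 137 * k}_A_G",
            effect_allele="G",
            weight=float(weights[k]),
            freq_by_ancestry={a: float(freqs[i, k]) for i, a in enumerate(ANCESTRIES)},
        )
        for k in range(n_snps)
    ]
    params = {}
    for i, anc in enumerate(ANCESTRIES):
        q = freqs[i]
        mu = float(2.0 * np.sum(q * weights))
        sd = float(math.sqrt(2.0 * np.sum(q * (1.0 - q) * weights**2)))
        params[anc] = AncestryParams(mu=mu, sd=sd, alpha=alphas[anc])
    return PgsModel(name=name, snps=snps, params_by_ancestry=params)


def simulate_admixed_genotypes(
    model: PgsModel, profile: AncestryProfile, n: int, seed: int = 0
) -> np.ndarray:
    """(n, K) dosage matrix under per-SNP independent admixture: each
    individual at each locus draws one ancestry from the profile, then a
    diploid genotype ~ Binomial(2, q) at that ancestry's frequency (both
    homologous copies share local ancestry, matching the cross-ancestry
    covariance term of the mixed-ancestry variance formula)."""
    rng = np.random.default_rng(seed)
    p = profile.as_vector()
    q = model.freq_matrix()  # (M, K)
    cum = np.cumsum(p)
    k = model.n_snps
    anc = np.searchsorted(cum, rng.random((n, k)), side="right")
    anc = np.minimum(anc, len(ANCESTRIES) - 1)
    q_sel = q[anc, np.arange(k)[None, :]]
    return rng.binomial(2, q_sel).astype(np.int8)


def make_toy_incidence(
    shape: float = 6.0,
    scale: float = 1.0,
    peak_age: float = 60.0,
    seed: int | None = None,
    *,
    cancer: str = "breast_female",
    cohort: str = "toy",
    ethnicity: str = "Unknown",
    max_age: int = 89,
    lifetime_risk: float | None = None,
) -> IncidenceTable:
    """Smooth unimodal incidence curve over ages 0..max_age (gamma-shaped,
    mode at ``peak_age``).  ``scale`` multiplies the curve directly; if
    ``lifetime_risk`` is given, the curve is instead calibrated exactly so
    that 1 - exp(-sum rates) equals it.  Deterministic; ``seed`` accepted
    for generator-API symmetry."""
    del seed
    ages = np.arange(0, max_age + 1)
    base = stats.gamma.pdf(ages + 0.5, a=shape, scale=peak_age / (shape - 1.0))
    if lifetime_risk is not None:
        if not 0.0 < lifetime_risk < 1.0:
            raise ValueError("lifetime_risk must lie in (0, 1)")
        factor = -math.log1p(-lifetime_risk) / base.sum()
    else:
        factor = scale
    return IncidenceTable(
        cancer=cancer, cohort=cohort, ethnicity=ethnicity, ages=ages, rates=base * factor
    )


def make_toy_factor_system(
    name: str = "factor",
    n_levels: int = 3,
    seed: int = 0,
    ethnicities: tuple[str, ...] = ("default",),
    rr_scale: float = 0.25,
) -> FactorSystem:
    """Random categorical risk factor: level log-RRs ~ Normal(0, rr_scale^2)
    with the first level as reference, Dirichlet(2) prevalences per
    ethnicity."""
    rng = np.random.default_rng(seed)
    levels = tuple(f"L{i}" for i in range(n_levels))
    log_rr = {lv: (0.0 if i == 0 else float(rng.normal(0.0, rr_scale)))
              for i, lv in enumerate(levels)}
    prevalence = {
        eth: dict(zip(levels, rng.dirichlet(np.full(n_levels, 2.0))))
        for eth in ethnicities
    }
    return FactorSystem(name=name, levels=levels, log_rr=log_rr,
                        prevalence_by_ethnicity=prevalence)


def make_toy_config(seed: int = 0, lifetime_risk: float = 0.04,
                    n_nodes: int = 64) -> ModelConfig:
    """Small but complete model configuration for tests: one major gene, two
    QRFs, a 3-level density factor, a modest polygene, and toy incidence."""
    eths = ("White", "Black", "EastAsian", "SouthAsian", "Mixed", "default")
    return ModelConfig(
        cancer="breast_female",
        national=make_toy_incidence(lifetime_risk=lifetime_risk, ethnicity="National"),
        irr=None,
        genes=[
            MajorGene(
                gene="GENE1",
                pv_frequency_by_ancestry={a: 0.001 for a in ANCESTRIES},
                rr_by_age=5.0,
            )
        ],
        polygene=PolygeneSpec(sd_by_age=0.8, n_nodes=n_nodes),
        qrf_factors=[
            make_toy_factor_system("qrf_a", 3, seed=seed + 1, ethnicities=eths),
            make_toy_factor_system("qrf_b", 2, seed=seed + 2, ethnicities=eths),
        ],
        birads=make_toy_factor_system("birads", 3, seed=seed + 3, ethnicities=eths),
        pgs_params={a: AncestryParams(*DEFAULT_PGS_PARAMS["BC-309"][a]) for a in ANCESTRIES},
    )


# ---------------------------------------------------------------------------
# Realistic UK-like configurations
#
# Parameter values below are illustrative defaults assembled from the
# epidemiological literature (PV frequencies and relative risks of the
# BOADICEA gene set, BCSC-like density odds ratios, typical QRF effects and
# published ethnicity-specific rate ratios); they are synthetic stand-ins
# for the full proprietary model tables and are chosen once to be realistic,
# not fitted to any output.


def _step_rr(ages: np.ndarray, steps: list[tuple[int, float]]) -> np.ndarray:
    """Piecewise-constant RR curve: steps = [(age_from, rr), ...]."""
    out = np.empty(ages.size)
    for age_from, rr in steps:
        out[ages >= age_from] = rr
    out[ages < steps[0][0]] = steps[0][1]
    return out


_BIRADS_PREV = {
    # density distributions: Asian women shifted dense, Black women fattier
    "White": {"a": 0.10, "b": 0.41, "c": 0.39, "d": 0.10},
    "Black": {"a": 0.13, "b": 0.45, "c": 0.35, "d": 0.07},
    "EastAsian": {"a": 0.06, "b": 0.34, "c": 0.43, "d": 0.17},
    "SouthAsian": {"a": 0.06, "b": 0.35, "c": 0.42, "d": 0.17},
    "Asian": {"a": 0.06, "b": 0.34, "c": 0.43, "d": 0.17},
    "Mixed": {"a": 0.09, "b": 0.40, "c": 0.40, "d": 0.11},
    "default": {"a": 0.10, "b": 0.41, "c": 0.39, "d": 0.10},
}


def make_uk_like_config(cancer: str = "BC") -> ModelConfig:
    """UK-like breast ("BC") or ovarian ("EOC") model configuration with
    published ethnic rate ratios, the BRCA1/BRCA2/CHEK2 gene set and
    plausible factor systems.  See the methods note for provenance and the
    stand-in status of each block."""
    ages = np.arange(0, 90)
    eur = 0.0026  # CHEK2 PV allele frequency, European (c.1100del dominated)
    non_eur = 0.00109  # pooled non-European CHEK2 PV frequency
    if cancer == "BC":
        national = make_toy_incidence(
            shape=5.0, peak_age=64.0, lifetime_risk=0.12,
            cancer="breast_female", cohort="1980-1989", ethnicity="National",
        )
        genes = [
            MajorGene("BRCA1", {a: 0.00064 for a in ANCESTRIES},
                      _step_rr(ages, [(0, 18.0), (40, 12.0), (50, 7.0), (60, 4.0)])),
            MajorGene("BRCA2", {a: 0.00102 for a in ANCESTRIES},
                      _step_rr(ages, [(0, 16.0), (40, 11.0), (50, 8.0), (60, 5.5)])),
            MajorGene("CHEK2",
                      {"European": eur, "African": non_eur,
                       "EastAsian": non_eur, "SouthAsian": non_eur},
                      2.5),
        ]
        qrf = [
            FactorSystem(
                "parity", ("nulliparous", "1-2", "3+"),
                {"nulliparous": 0.0, "1-2": math.log(0.92), "3+": math.log(0.85)},
                {
                    "White": {"nulliparous": 0.20, "1-2": 0.60, "3+": 0.20},
                    "Black": {"nulliparous": 0.18, "1-2": 0.52, "3+": 0.30},
                    "EastAsian": {"nulliparous": 0.26, "1-2": 0.60, "3+": 0.14},
                    "SouthAsian": {"nulliparous": 0.14, "1-2": 0.54, "3+": 0.32},
                    "Mixed": {"nulliparous": 0.22, "1-2": 0.58, "3+": 0.20},
                    "default": {"nulliparous": 0.20, "1-2": 0.60, "3+": 0.20},
                },
            ),
            FactorSystem(
                "alcohol", ("none", "moderate", "high"),
                {"none": 0.0, "moderate": math.log(1.06), "high": math.log(1.18)},
                {
                    "White": {"none": 0.30, "moderate": 0.55, "high": 0.15},
                    "Black": {"none": 0.55, "moderate": 0.38, "high": 0.07},
                    "EastAsian": {"none": 0.70, "moderate": 0.27, "high": 0.03},
                    "SouthAsian": {"none": 0.80, "moderate": 0.18, "high": 0.02},
                    "Mixed": {"none": 0.40, "moderate": 0.48, "high": 0.12},
                    "default": {"none": 0.30, "moderate": 0.55, "high": 0.15},
                },
            ),
            FactorSystem(
                "mht", ("never", "past", "current"),
                {"never": 0.0, "past": math.log(1.03), "current": math.log(1.30)},
                {
                    "White": {"never": 0.62, "past": 0.23, "current": 0.15},
                    "Black": {"never": 0.75, "past": 0.15, "current": 0.10},
                    "EastAsian": {"never": 0.80, "past": 0.12, "current": 0.08},
                    "SouthAsian": {"never": 0.82, "past": 0.11, "current": 0.07},
                    "Mixed": {"never": 0.68, "past": 0.20, "current": 0.12},
                    "default": {"never": 0.62, "past": 0.23, "current": 0.15},
                },
            ),
        ]
        birads = FactorSystem(
            "birads", ("a", "b", "c", "d"),
            {"a": math.log(0.55), "b": 0.0, "c": math.log(1.40), "d": math.log(2.00)},
            _BIRADS_PREV,
        )
        return ModelConfig(
            cancer="breast_female", national=national,
            irr=load_uk_irr("breast_female"), genes=genes,
            polygene=PolygeneSpec(sd_by_age=1.2, n_nodes=64),
            qrf_factors=qrf, birads=birads,
            pgs_params={a: AncestryParams(*DEFAULT_PGS_PARAMS["BC-309"][a])
                        for a in ANCESTRIES},
        )
    if cancer == "EOC":
        national = make_toy_incidence(
            shape=6.0, peak_age=68.0, lifetime_risk=0.018,
            cancer="ovarian", cohort="1980-1989", ethnicity="National",
        )
        genes = [
            MajorGene("BRCA1", {a: 0.00064 for a in ANCESTRIES},
                      _step_rr(ages, [(0, 30.0), (50, 18.0), (60, 10.0)])),
            MajorGene("BRCA2", {a: 0.00102 for a in ANCESTRIES},
                      _step_rr(ages, [(0, 4.0), (50, 9.0), (60, 7.0)])),
        ]
        qrf = [
            FactorSystem(
                "parity", ("nulliparous", "1-2", "3+"),
                {"nulliparous": 0.0, "1-2": math.log(0.80), "3+": math.log(0.68)},
                {
                    "White": {"nulliparous": 0.20, "1-2": 0.60, "3+": 0.20},
                    "Black": {"nulliparous": 0.18, "1-2": 0.52, "3+": 0.30},
                    "EastAsian": {"nulliparous": 0.26, "1-2": 0.60, "3+": 0.14},
                    "SouthAsian": {"nulliparous": 0.14, "1-2": 0.54, "3+": 0.32},
                    "Mixed": {"nulliparous": 0.22, "1-2": 0.58, "3+": 0.20},
                    "default": {"nulliparous": 0.20, "1-2": 0.60, "3+": 0.20},
                },
            ),
            FactorSystem(
                "oc_use", ("never", "lt5y", "ge5y"),
                {"never": 0.0, "lt5y": math.log(0.78), "ge5y": math.log(0.57)},
                {
                    "White": {"never": 0.30, "lt5y": 0.35, "ge5y": 0.35},
                    "Black": {"never": 0.45, "lt5y": 0.32, "ge5y": 0.23},
                    "EastAsian": {"never": 0.60, "lt5y": 0.25, "ge5y": 0.15},
                    "SouthAsian": {"never": 0.65, "lt5y": 0.22, "ge5y": 0.13},
                    "Mixed": {"never": 0.38, "lt5y": 0.33, "ge5y": 0.29},
                    "default": {"never": 0.30, "lt5y": 0.35, "ge5y": 0.35},
                },
            ),
        ]
        return ModelConfig(
            cancer="ovarian", national=national,
            irr=load_uk_irr("ovarian"), genes=genes,
            polygene=PolygeneSpec(sd_by_age=1.0, n_nodes=64),
            qrf_factors=qrf, birads=None,
            pgs_params={a: AncestryParams(*DEFAULT_PGS_PARAMS["EOC-36"][a])
                        for a in ANCESTRIES},
        )
    raise ValueError(f"unknown cancer short-code {cancer!r} (use 'BC' or 'EOC')")
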