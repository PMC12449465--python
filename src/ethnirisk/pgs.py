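"""Polygenic score (PGS) models with ancestry-aware standardisation.

A PGS model is a SNP panel with per-effect-allele weights, per-ancestry
allele frequencies and per-ancestry standardisation parameters
(mean mu_i, SD sigma_i, and alpha_i, the square root of the proportion of
the model polygenic variance explained by the score in ancestry i).

The raw score R = sum_k w_k x_k is ancestry-independent; standardisation is
not.  For single-ancestry genomes Z_i = (R - mu_i) / sigma_i.  For mixed
genetic ancestry (no single ancestry proportion above its threshold) the
score variance depends both on the admixture proportions P_i and on the
between-ancestry variance of allele frequencies:

    sigma^2 = sum_i P_i sigma_i^2
              + 4 sum_k w_k^2 ( sum_i P_i q_ik^2 - (sum_i P_i q_ik)^2 )

and the corrected normalised score and overall alpha are

    Z = sum_i P_i alpha_i Z_i / ( sigma * sum_i P_i alpha_i / sigma_i )
    alpha = sum_i P_i alpha_i sigma_i / sigma .

Because sigma exceeds the weighted average of the sigma_i, both Z and alpha
are attenuated relative to naive weighted averages of the single-ancestry
values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EUROPEAN",
    "AFRICAN",
    "EAST_ASIAN",
    "SOUTH_ASIAN",
    "ANCESTRIES",
    "SINGLE_ANCESTRY_THRESHOLDS",
    "DEFAULT_PGS_PARAMS",
    "CHEK2_PROXY_SNPS",
    "SnpEntry",
    "AncestryParams",
    "PgsModel",
    "AncestryProfile",
    "NormalisedPgs",
    "PolygenePartition",
    "compute_raw_pgs",
    "normalise_single",
    "classify_profile",
    "mixed_sigma",
    "mixed_z_alpha",
    "partition_polygene",
    "alpha_from_variance",
    "alpha_by_proportionality",
    "select_model_variant",
]

# Genetic ancestry vocabulary (fixed order used for deterministic tie-breaks).
EUROPEAN = "European"
AFRICAN = "African"
EAST_ASIAN = "EastAsian"
SOUTH_ASIAN = "SouthAsian"
ANCESTRIES: tuple[str, ...] = (EUROPEAN, AFRICAN, EAST_ASIAN, SOUTH_ASIAN)

# A genome is "single ancestry" when its main ancestry proportion reaches the
# threshold; South Asian uses a lower cut-off.
SINGLE_ANCESTRY_THRESHOLDS: dict[str, float] = {
    EUROPEAN: 0.8,
    AFRICAN: 0.8,
    EAST_ASIAN: 0.8,
    SOUTH_ASIAN: 0.7,
}

# Published ancestry-specific standardisation parameters (mu, sigma, alpha)
# for the CanRisk/BOADICEA breast (309- and 307-SNP) and ovarian (36-SNP)
# PGS models.  Unknown/other ancestries fall back to the European row.
DEFAULT_PGS_PARAMS: dict[str, dict[str, tuple[float, float, float]]] = {
    "BC-309": {
        EUROPEAN: (-0.335, 0.615, 0.499),
        AFRICAN: (0.292, 0.547, 0.196),
        EAST_ASIAN: (0.268, 0.555, 0.326),
        SOUTH_ASIAN: (-0.160, 0.602, 0.331),
    },
    "BC-307": {
        EUROPEAN: (-0.005, 0.613, 0.497),
        AFRICAN: (0.634, 0.547, 0.196),
        EAST_ASIAN: (0.611, 0.555, 0.326),
        SOUTH_ASIAN: (0.179, 0.601, 0.329),
    },
    "EOC-36": {
        EUROPEAN: (0.007, 0.322, 0.223),
        AFRICAN: (-0.152, 0.254, 0.178),
        EAST_ASIAN: (-0.161, 0.235, 0.171),
        SOUTH_ASIAN: (-0.180, 0.278, 0.194),
    },
}

# SNPs correlated with the CHEK2 c.1100del pathogenic variant; the 307-SNP
# breast PGS excludes them so CHEK2 sequencing results are not double-counted.
CHEK2_PROXY_SNPS: tuple[str, str] = ("22_29203724_C_T", "22_29551872_A_G")


@dataclass(frozen=True)
class SnpEntry:
    """One SNP of a PGS panel: weight on the effect allele and per-ancestry
    effect-allele frequencies (``chr_pos_ref_alt`` id convention)."""

    snp_id: str
    effect_allele: str
    weight: float
    freq_by_ancestry: dict[str, float]

    def __post_init__(self) -> None:
        if not math.isfinite(self.weight):
            raise ValueError(f"{self.snp_id}: non-finite weight")
        for anc, q in self.freq_by_ancestry.items():
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"{self.snp_id}: frequency {q} for {anc} outside [0, 1]")


@dataclass(frozen=True)
class AncestryParams:
    """Standardisation parameters (mu, sigma, alpha) for one ancestry."""

    mu: float
    sd: float
    alpha: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"sd must be positive, got {self.sd}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass
class PgsModel:
    """A PGS panel plus per-ancestry standardisation parameters.

    ``chek2_safe`` marks the variant with CHEK2-correlated SNPs removed,
    usable alongside CHEK2 sequencing results.
    """

    name: str
    snps: list[SnpEntry]
    params_by_ancestry: dict[str, AncestryParams]
    chek2_safe: bool = False

    def __post_init__(self) -> None:
        if len(self.snps) < 1:
            raise ValueError("a PGS model needs at least one SNP")
        unknown = set(self.params_by_ancestry) - set(ANCESTRIES)
        if unknown:
            raise ValueError(f"unknown ancestry keys: {sorted(unknown)}")
        coerced = {
            a: p if isinstance(p, AncestryParams) else AncestryParams(*p)
            for a, p in self.params_by_ancestry.items()
        }
        self.params_by_ancestry = coerced

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def params(self, ancestry: str) -> AncestryParams:
        """Parameters for ``ancestry``, falling back to European for
        unknown/other ancestries (published convention)."""
        if ancestry in self.params_by_ancestry:
            return self.params_by_ancestry[ancestry]
        if EUROPEAN in self.params_by_ancestry:
            return self.params_by_ancestry[EUROPEAN]
        raise KeyError(f"no parameters for {ancestry} and no European fallback")

    def weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.snps])

    def freq_matrix(self, ancestries: tuple[str, ...] = ANCESTRIES) -> np.ndarray:
        """(len(ancestries), K) matrix of effect-allele frequencies.

        Raises KeyError naming the SNP and ancestry on a missing entry.
        """
        out = np.empty((len(ancestries), self.n_snps))
        for i, anc in enumerate(ancestries):
            for k, snp in enumerate(self.snps):
                try:
                    out[i, k] = snp.freq_by_ancestry[anc]
                except KeyError:
                    raise KeyError(
                        f"SNP {snp.snp_id} has no allele frequency for ancestry {anc}"
                    ) from None
        return out


@dataclass(frozen=True)
class AncestryProfile:
    """Proportions of the genome attributable to each ancestry (sum to 1)."""

    proportions: dict[str, float]

    def __post_init__(self) -> None:
        for anc, p in self.proportions.items():
            if anc not in ANCESTRIES:
                raise ValueError(f"unknown ancestry {anc!r}")
            if p < 0:
                raise ValueError(f"negative proportion for {anc}")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"ancestry proportions sum to {total}, expected 1")

    def proportion(self, ancestry: str) -> float:
        return self.proportions.get(ancestry, 0.0)

    def as_vector(self, ancestries: tuple[str, ...] = ANCESTRIES) -> np.ndarray:
        return np.array([self.proportion(a) for a in ancestries])

    @classmethod
    def single(cls, ancestry: str) -> "AncestryProfile":
        return cls({ancestry: 1.0})


@dataclass(frozen=True)
class NormalisedPgs:
    """Standardised PGS: Z score, alpha, the sigma used, and how the
    ancestry was handled (``single:<ancestry>`` or ``mixed``)."""

    z: float
    alpha: float
    sigma_used: float
    ancestry_mode: str

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.sigma_used <= 0:
            raise ValueError("sigma_used must be positive")


@dataclass(frozen=True)
class PolygenePartition:
    """Split of the standardised polygene x_P = alpha * Z + x_R with
    residual x_R ~ N(0, 1 - alpha^2)."""

    z_scaled: float
    residual_variance: float

    def __post_init__(self) -> None:
        if not 0.0 < self.residual_variance < 1.0:
            raise ValueError("residual variance must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Raw scoring


def compute_raw_pgs(
    dosages: dict[str, float],
    model: PgsModel,
    profile: AncestryProfile | None = None,
) -> float:
    """Raw PGS: sum over panel SNPs of weight x effect-allele dosage.

    The raw score does not depend on ancestry.  Panel SNPs absent from
    ``dosages`` are imputed at their profile-weighted expected dosage
    2 * sum_i P_i q_ik (European frequencies when no profile is supplied);
    dosage keys not in the panel are ignored with a warning.
    """
    if not dosages:
        raise ValueError("no dosages supplied")
    panel_ids = {s.snp_id for s in model.snps}
    if not panel_ids & set(dosages):
        raise ValueError("no supplied dosage matches any SNP in the model panel")
    unknown = len(set(dosages) - panel_ids)
    if unknown:
        warnings.warn(f"{unknown} dosage id(s) not in model panel ignored", stacklevel=2)
    if profile is None:
        profile = AncestryProfile.single(EUROPEAN)
    total = 0.0
    for snp in model.snps:
        x = dosages.get(snp.snp_id)
        if x is None:
            x = 2.0 * sum(
                p * snp.freq_by_ancestry.get(anc, snp.freq_by_ancestry.get(EUROPEAN, 0.0))
                for anc, p in profile.proportions.items()
            )
        total += snp.weight * x
    return total


# ---------------------------------------------------------------------------
# Single-ancestry standardisation


def normalise_single(raw: float, ancestry: str, model: PgsModel) -> NormalisedPgs:
    """Standardise a raw score with single-ancestry parameters:
    Z_i = (R - mu_i) / sigma_i.  Unknown ancestries use the European row."""
    par = model.params(ancestry)
    mode = ancestry if ancestry in model.params_by_ancestry else EUROPEAN
    return NormalisedPgs(
        z=(raw - par.mu) / par.sd,
        alpha=par.alpha,
        sigma_used=par.sd,
        ancestry_mode=f"single:{mode}",
    )


def classify_profile(profile: AncestryProfile) -> str | None:
    """Return the main ancestry if the profile is single-ancestry
    (proportion >= 0.8, or >= 0.7 for South Asian), else None (mixed).

    Ancestries are scanned by descending proportion with the fixed
    European < African < East Asian < South Asian order breaking exact ties,
    so classification is deterministic.
    """
    order = sorted(
        ANCESTRIES,
        key=lambda a: (-profile.proportion(a), ANCESTRIES.index(a)),
    )
    for anc in order:
        if profile.proportion(anc) >= SINGLE_ANCESTRY_THRESHOLDS[anc]:
            return anc
    return None


# ---------------------------------------------------------------------------
# Mixed-ancestry correction


def mixed_sigma(profile: AncestryProfile, model: PgsModel) -> float:
    """SD of the raw PGS for an admixed genome.

    sigma^2 = sum_i P_i sigma_i^2
              + 4 sum_k w_k^2 ( sum_i P_i q_ik^2 - (sum_i P_i q_ik)^2 )

    The second term is the between-ancestry variance of the expected allele
    dosage and is always >= 0, so the mixed sigma is at least the
    P-weighted root-mean-square of the single-ancestry sigmas.
    """
    active = tuple(a for a in ANCESTRIES if profile.proportion(a) > 0)
    p = profile.as_vector(active)
    sig = np.array([model.params(a).sd for a in active])
    w = model.weights()
    q = model.freq_matrix(active)  # (M, K)
    between = p @ (q**2) - (p @ q) ** 2  # per-SNP frequency variance, >= 0
    var = float(p @ sig**2 + 4.0 * np.sum(w**2 * between))
    return math.sqrt(var)


def mixed_z_alpha(raw: float, profile: AncestryProfile, model: PgsModel) -> NormalisedPgs:
    """Corrected normalised score and overall alpha for mixed ancestry.

    Z = sum_i P_i alpha_i Z_i / ( sigma * sum_i P_i alpha_i / sigma_i ),
    alpha = sum_i P_i alpha_i sigma_i / sigma, with sigma from
    :func:`mixed_sigma`.  At P_i = 1 both collapse to the single-ancestry
    values exactly.
    """
    sigma = mixed_sigma(profile, model)
    num_z = num_a = den_z = 0.0
    for anc in ANCESTRIES:
        p = profile.proportion(anc)
        if p == 0:
            continue
        par = model.params(anc)
        z_i = (raw - par.mu) / par.sd
        num_z += p * par.alpha * z_i
        den_z += p * par.alpha / par.sd
        num_a += p * par.alpha * par.sd
    return NormalisedPgs(
        z=num_z / (sigma * den_z),
        alpha=num_a / sigma,
        sigma_used=sigma,
        ancestry_mode="mixed",
    )


def normalise(raw: float, profile: AncestryProfile, model: PgsModel) -> NormalisedPgs:
    """Standardise ``raw`` using the single-ancestry route when one ancestry
    dominates the profile, otherwise the mixed-ancestry correction."""
    main = classify_profile(profile)
    if main is not None:
        return normalise_single(raw, main, model)
    return mixed_z_alpha(raw, profile, model)


def partition_polygene(npgs: NormalisedPgs) -> PolygenePartition:
    """Partition the standardised polygene: measured part alpha*Z, residual
    variance 1 - alpha^2 (so the total polygene keeps unit variance)."""
    return PolygenePartition(
        z_scaled=npgs.alpha * npgs.z,
        residual_variance=1.0 - npgs.alpha**2,
    )


# ---------------------------------------------------------------------------
# Alpha derivation routes


def alpha_from_variance(model: PgsModel, ancestry: str, polygenic_sd: float) -> float:
    """Alpha from the variance explained by the score under HWE and linkage
    equilibrium: v = sum_k 2 q_ik (1 - q_ik) w_k^2, alpha = sqrt(v) / sd.

    Used where direct case-control alpha estimates are unavailable (the
    ovarian-score route).  Raises if the implied alpha reaches 1, which
    signals an inconsistent ``polygenic_sd``.
    """
    if polygenic_sd <= 0:
        raise ValueError("polygenic_sd must be positive")
    w = model.weights()
    q = model.freq_matrix((ancestry,))[0]
    v = float(np.sum(2.0 * q * (1.0 - q) * w**2))
    alpha = math.sqrt(v) / polygenic_sd
    if alpha >= 1.0:
        raise ValueError(
            f"variance explained ({v:.4g}) implies alpha >= 1; polygenic_sd "
            f"{polygenic_sd} is inconsistent with the score"
        )
    return alpha


def alpha_by_proportionality(alpha_ref: float, or_ref: float, or_target: float) -> float:
    """Transfer alpha between ancestries assuming alpha is proportional to
    the log odds-ratio per SD (the route used for African-ancestry breast
    scores, referenced to East Asian effect sizes)."""
    if or_ref <= 1.0 or or_target <= 1.0:
        raise ValueError("odds ratios must exceed 1")
    return alpha_ref * math.log(or_target) / math.log(or_ref)


def select_model_variant(models, chek2_sequenced: bool) -> PgsModel:
    """Pick the CHEK2-safe (307-SNP) panel when CHEK2 sequencing data are
    available — preventing double-counting of c.1100del — else the full
    309-SNP panel."""
    for m in models:
        if m.chek2_safe == chek2_sequenced:
            return m
    kind = "CHEK2-safe" if chek2_sequenced else "full"
    raise LookupError(f"no {kind} PGS model variant registered")
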