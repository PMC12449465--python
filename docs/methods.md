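# Methods

## Model overview

`ethnirisk` implements the parameter-adaptation layer of a BOADICEA-style
multifactorial cancer risk model: it does not fit anything to individual
data. All inputs are population-level parameters — SNP weights and
per-ancestry allele frequencies, per-ancestry score moments (μᵢ, σᵢ) and
variance fractions (αᵢ), ethnic incidence rate ratios, per-ethnicity risk
factor distributions, and pathogenic-variant (PV) frequencies and relative
risks. Outputs are genotype/risk-factor-specific hazards, absolute risks,
and population risk distributions by ethnicity.

Two distinct groupings are used deliberately: *self-reported ethnicity*
selects incidences, questionnaire-risk-factor (QRF) and density
distributions; *genetic ancestry* selects PGS and PV-frequency parameters.
Where an ancestry profile is unavailable, ethnicity proxies ancestry
(White → European, Black → African, East/South Asian → the corresponding
ancestry, Unknown → European). Mixed ethnicity has no single-ancestry
proxy: PGS-bearing calculations for Mixed require an explicit ancestry
profile, and stratification requests for Mixed + PGS are rejected.

## Polygenic score standardisation

The raw score R = Σₖ wₖxₖ uses effect-allele dosages; missing panel SNPs
are imputed at the profile-weighted expected dosage 2 Σᵢ Pᵢqᵢₖ, which is
unbiased under the same admixture model that underlies the mixed-variance
formula. Single-ancestry genomes (main proportion ≥ 0.8; ≥ 0.7 for South
Asian) use Zᵢ = (R − μᵢ)/σᵢ with that ancestry's α. Unknown or unlisted
ancestries use the European parameter row (the shipped published
convention).

For mixed genomes the score variance is

σ² = Σᵢ Pᵢσᵢ² + 4 Σₖ wₖ²( Σᵢ Pᵢqᵢₖ² − (Σᵢ Pᵢqᵢₖ)² ),

i.e. the P-mixture of within-ancestry variances plus a cross-ancestry term
proportional to the between-ancestry variance of allele frequency. The
factor 4 encodes the assumption that the two homologous copies at a locus
share local ancestry (the haplotype covariance equals the between-ancestry
frequency variance); the fixture simulator therefore draws one ancestry
per individual per locus and a Binomial(2, q) genotype, and matches the
formula within Monte-Carlo error, whereas independent per-haplotype draws
would not. The corrected score and alpha,

Z = Σ PᵢαᵢZᵢ / (σ Σ Pᵢαᵢ/σᵢ),  α = Σ Pᵢαᵢσᵢ / σ,

collapse exactly to the single-ancestry values at Pᵢ = 1.

A note on the attenuation property: σ ≥ √(Σ Pᵢσᵢ²) ≥ Σ Pᵢσᵢ always, so α
never exceeds the *σ-weighted* average of the αᵢ. The stronger statement
α ≤ Σ Pᵢαᵢ (plain weighted average) additionally needs the cross-ancestry
variance term to be non-negligible relative to the spread of the σᵢ; it
holds on moment-coherent panels (σᵢ derived from the same frequencies and
weights as the cross term), which is how the property is tested, but it is
not an algebraic identity for arbitrary parameter combinations.

Two α-derivation routes are provided for panels lacking direct estimates:
from variance explained, α = √(Σₖ 2qᵢₖ(1 − qᵢₖ)wₖ²)/σ_polygenic, assuming
HWE and linkage equilibrium (no LD correction is attempted — none is
defined for these panels); and by proportionality to the log odds-ratio
per SD, α_target = α_ref · ln(OR_target)/ln(OR_ref), used only where a
reference ancestry with a known α and OR exists. The
retrospective-likelihood estimator used to obtain the shipped α values is
out of scope; the values themselves are configuration.

The 307-SNP breast panel (CHEK2 c.1100del-correlated SNPs
22_29203724_C_T and 22_29551872_A_G removed) is selected whenever CHEK2
sequencing results are available, so the variant's effect is not counted
both as a PV and through its PGS proxies. Its mean differs markedly from
the 309-SNP panel (European μ −0.005 vs −0.335), so the panels are never
interchangeable.

## Ethnicity-specific incidences

Incidence rate ratios (IRRs) relative to the White group are
re-standardised against the whole population with composition p_e:
R_e = r_e / Σ p_e r_e. This guarantees Σ p_e R_e = 1 (so the
composition-weighted ethnic curves reproduce the national curve at every
age), preserves pairwise ratios, is scale-invariant in r, and is
idempotent on already population-referenced sets. IRRs are assumed
independent of age and birth cohort — a stated modelling assumption, kept
as a limitation hook for future age-varying ratios. East and South Asian
share a pooled "Asian" ratio (registration counts are too small to
separate them); male breast cancer keeps the national incidence for every
ethnicity; Unknown ethnicity maps to ratio 1 exactly, which is what makes
the adapted model backward compatible. The published UK ratio table (2016
composition) is shipped as packaged data; the composition itself is an
explicit input, not a constant, because it depends on the census year.

Rates are stored as events per person-year on a one-year age grid
(half-open [a, a+1) intervals, piecewise-constant hazards); files carry
rates per 100,000 person-years for readability.

## Constrained hazard model

The stratification crosses major genes (dominant model; carrier prevalence
2q(1 − q) + q² from allele frequency q), categorical QRFs, BIRADS density,
and a standard-normal polygene entering as exp(s(t)·x_P), discretised on a
64-node probabilists' Gauss–Hermite grid (normalised weights; ~1e-6
accuracy for lognormal mixing, and the constrained solve reproduces the
input incidence to < 1e-10 in the tests). Factors are independent within
ethnicity — the multiplicative construction this model family uses. The
baseline solves sequentially in age:

λ₀(t) = μ(t) · Σ_g π_g S_g(t) / Σ_g π_g S_g(t) RR_g(t),

with survivor functions updated before each age. Per-stratum yearly
hazards above 1 are tolerated (they are rates, not probabilities; the
extreme quadrature nodes produce them at negligible weight); the solver
rejects only μ(t) > 1 per person-year or non-finite solves.

Profile hazards condition on observed components and survivor-weight over
unobserved ones (untested genes over carrier prevalence, the polygene
residual over quadrature after fixing the measured part αZ). A fully
unobserved profile therefore reproduces the population incidence exactly,
and averaging profile risks over Z ~ N(0,1) recovers the PGS-unknown risk
to better than 1e-3.

Absolute risk over [a, b) is the cause-specific cumulative risk
1 − exp(−Σ hazard); competing mortality is deliberately not modelled (a
hook exists in the interface), keeping lifetime-risk semantics simple and
reproducible. Lifetime risk means ages 20–80 throughout.

The polygenic SD on the log-hazard scale defaults to an age-constant 1.2
(breast) / 1.0 (ovarian). These are configurable stand-ins: the model
family uses age-dependent polygenic SDs whose exact curves are internal to
the upstream implementation, so the defaults are labelled as such and
every entry point accepts an age-profile array.

## Tumour subtypes

Carrier subtype distributions follow an odds update:
p_carrier(s) ∝ p_pop(s) · exp(log OR(s) + slope(s)·(age − 50)),
renormalised over {ER-positive, TN, ER-negative-not-TN}. The reference
subtype's log-OR is pinned to 0. The 50-year centring of the age
interaction is a package choice (midpoint of typical reporting bands) and
configurable; queries snap to the containing age band of the input
distribution. The odds-update form was chosen over a full multinomial
refit because only ORs and interactions are available as inputs.

## Stratification

Risk distributions enumerate the Cartesian product of the requested
predictors — QRF categories × BIRADS categories × PGS on the 64-node
standard-normal grid — with masses from per-ethnicity category frequencies
and quadrature weights. Categories are half-open with thresholds belonging
to the upper category (17% is moderate, 30% is high), matching guideline
phrasing; the top bin is closed at 1. Mixtures across ethnicities weight
whole distributions by the ethnic composition. The distribution mean
reproduces the predictor-free population risk to ~1e-3 (the residual is a
Jensen gap between averaging cumulative risks and cumulating the average
hazard, which grows with risk level and predictor variance).

## Synthetic data: what it does and does not emulate

The generators produce: random PGS panels with moment-coherent per-ancestry
parameters (μᵢ = 2Σqᵢₖwₖ, σᵢ² = 2Σqᵢₖ(1 − qᵢₖ)wₖ², published αᵢ attached);
admixed genotypes under per-locus independent admixture (no LD, no
ancestry tracts — sufficient because every formula implemented here is
locus-independent); gamma-shaped incidence curves with exactly calibrated
lifetime risk; and random or realistic factor systems. The UK-like
configurations pair the shipped published rate ratios and PGS parameters
with plausible literature-informed stand-ins for the gene set
(BRCA1/BRCA2/CHEK2 frequencies and age-banded relative risks, including
the lower pooled non-European CHEK2 PV frequency of 0.00109), QRF and
BIRADS effects and per-ethnicity distributions. Passing tests on these
fixtures demonstrate the correctness of the machinery and the qualitative
ethnic patterns (lower and narrower non-White risk distributions, ordered
carrier risks); they do not certify the numerical accuracy of any
particular published risk table, which would require the proprietary
upstream parameter sets (full QRF/MD tables, incidence curves and
age-dependent polygenic variances).

## Problem sizes and numerical choices

Defaults used by the test suite and the acceptance script: 10-SNP toy
panels; 1e5 simulated genomes for the mixed-σ Monte-Carlo comparison
(3 MC SE tolerance); 1000 random profiles/ratio sets for the attenuation
and conservation properties; 64-node quadrature everywhere the polygene is
integrated; a 1e6-individual forward microsimulation for the two-stratum
constraint check; vectorised risk enumeration chunked at 128 predictor
combinations to bound memory. Ties in ancestry classification are broken
by largest proportion, then the fixed order European < African <
East Asian < South Asian, for determinism. Strand-ambiguous (A/T, C/G)
sites in VCF input are accepted as-is with a warning; dosages are flipped
(2 − x) when the effect allele is the record's REF.

## Known limitations

- No pedigree/family-history engine, no segregation likelihood, no
  mutation-probability computation; carrier status is an input.
- No competing mortality; lifetime risks are pure cause-specific
  cumulative risks.
- IRRs constant in age and cohort; QRF and density distributions constant
  in age within the two broad bands the inputs provide.
- HWE and linkage equilibrium assumed wherever variances are derived from
  allele frequencies.
- Ancestry proportions are inputs; no inference from genotypes.
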