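# ethnirisk

Ethnicity-adapted absolute risk prediction for female breast cancer (BC) and
epithelial ovarian cancer (EOC), in the BOADICEA/CanRisk model family.

Most multifactorial cancer risk models were developed in White/European
populations. Applying them unchanged to other ethnic groups mis-calibrates
both the *level* of risk (population incidences differ by ethnicity) and the
*spread* of risk (European-trained polygenic scores discriminate less well in
other ancestries, and are mis-standardised for admixed genomes). `ethnirisk`
implements the machinery needed to adapt a BOADICEA-style model to an
ethnically diverse population:

* **Multi-ancestry PGS standardisation.** A polygenic score
  R = Σₖ wₖ xₖ is ancestry-independent, but its standardisation is not:
  Zᵢ = (R − μᵢ)/σᵢ with per-ancestry mean/SD, and the score enters the
  polygene as x_P = αZ + x_R with x_R ~ N(0, 1 − α²), where α² is the
  proportion of the model polygenic variance the score explains in that
  ancestry. For mixed genetic ancestry (no ancestry proportion ≥ 0.8, or
  ≥ 0.7 for South Asian) the corrected parameters are

  σ² = Σᵢ Pᵢσᵢ² + 4 Σₖ wₖ² ( Σᵢ Pᵢ qᵢₖ² − (Σᵢ Pᵢ qᵢₖ)² ),
  Z = Σᵢ PᵢαᵢZᵢ / ( σ Σᵢ Pᵢαᵢ/σᵢ ),  α = Σᵢ Pᵢαᵢσᵢ / σ,

  which attenuate the score's effect relative to naive weighted averages.
  Published (μ, σ, α) for the 309-SNP/307-SNP BC and 36-SNP EOC panels are
  shipped; the 307-SNP variant (CHEK2 c.1100del-correlated SNPs removed) is
  selected automatically when CHEK2 sequencing results are supplied.
* **Ethnicity-specific incidences.** Published incidence rate ratios vs the
  White group are re-standardised against the whole population,
  R_e = r_e / Σ p_e r_e, so that composition-weighted ethnic incidence
  curves reproduce the national curve exactly and missing ethnicity falls
  back to the national model unchanged.
* **Incidence-constrained hazards.** Per-stratum hazards
  λ_g(t) = λ₀(t)·RR_g(t) over genes × questionnaire risk factors (QRFs) ×
  mammographic density (BIRADS) × a standard-normal polygene, with λ₀
  solved age-by-age so the survivor-weighted cohort average reproduces the
  population incidence. Absolute risk over [a, b) is 1 − exp(−Σ λ(t)).
* **Carrier tumour-subtype distributions** (ER-positive / triple-negative /
  ER-negative-not-TN) by odds-updating population proportions with
  gene-specific, age-interacting odds ratios.
* **Risk stratification** against NICE thresholds (BC: 17%/30% lifetime
  risk; EOC: 3.5%/5%), enumerating all predictor combinations weighted by
  their per-ethnicity frequencies.

## Worked example

Score an admixed genome (50% European / 50% African) on a toy 10-SNP panel
and standardise it with the mixed-ancestry correction:

```python
from ethnirisk import AncestryProfile, compute_raw_pgs, normalise, partition_polygene
from ethnirisk.synthetic import make_toy_pgs_model, simulate_admixed_genotypes

model = make_toy_pgs_model(n_snps=10, seed=1)
profile = AncestryProfile({"European": 0.5, "African": 0.5})
dosages = dict(zip((s.snp_id for s in model.snps),
                   map(float, simulate_admixed_genotypes(model, profile, 1, seed=4)[0])))
raw = compute_raw_pgs(dosages, model, profile)
npgs = normalise(raw, profile, model)   # classifies the profile, then standardises
part = partition_polygene(npgs)
```

This prints (via the obvious `print` calls):

```
raw PGS          : 0.2475
mode             : mixed
sigma (mixed)    : 0.1400
Z (corrected)    : 0.7805
alpha (corrected): 0.3166
polygene part    : alpha*Z = 0.2471, residual var = 0.8998
```

The corrected σ (0.1400) exceeds the weighted average of the two ancestry
SDs because allele frequencies differ between ancestries; consequently the
corrected α (0.317) sits *below* the naive average of the European (0.499)
and African (0.196) values — the score is deliberately down-weighted for
admixed genomes. `partition_polygene` then splits the unit-variance
polygene into the measured part αZ and a residual of variance 1 − α².

The same machinery drives ethnicity-level results: with the UK-like breast
configuration (`ethnirisk.synthetic.make_uk_like_config("BC")`, which uses
the shipped published rate ratios), `carrier_lifetime_risk("BRCA2", eth,
config)` orders carrier risks White > Black > East Asian > Mixed, and
`enumerate_distribution` + `categorise` show far fewer Black than White
women above the NICE moderate/high thresholds — the central consequence of
adapting the model.

A CLI mirrors the library (`ethnirisk pgs score|normalise|mix`,
`ethnirisk incidence restandardise|apply`, `ethnirisk risk absolute|carrier`,
`ethnirisk stratify`, `ethnirisk subtypes`, `ethnirisk simulate`); run
`ethnirisk --help`.

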