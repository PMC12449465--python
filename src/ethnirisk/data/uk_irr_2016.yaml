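# Incidence rate ratios by broad ethnic group, relative to the whole UK
# population (2016 census ethnic composition; derived from Public Health
# England registrations 2013-2017).  South and East Asian groups are pooled
# as "Asian".  Ratios are assumed independent of age and birth cohort.
reference: vs_Population
values:
  breast_female:
    White: 1.037
    Black: 0.84
    Asian: 0.747
    Mixed: 0.653
  ovarian:
    White: 1.045
    Black: 0.69
    Asian: 0.752
    Mixed: 0.533
  prostate:
    White: 1.002
    Black: 2.094
    Asian: 0.541
    Mixed: 0.782
  pancreatic_female:
    White: 1.028
    Black: 1.234
    Asian: 0.638
    Mixed: 0.781
  pancreatic_male:
    White: 1.029
    Black: 1.111
    Asian: 0.689
    Mixed: 0.782
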