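# Default sensitivity grid: study-selection criteria x analysis types.
# Each scenario is analysed with a conventional random-effects model and
# with Bayesian models under a vague (RR 0.25-4) and an informative
# (RR 1-2) prior on the pooled effect; the tau prior is Jeffreys throughout.
scenarios:
  - name: All studies
    filter: {}
    analyses: &default_analyses
      - model: random_dl
        label: conventional
      - model: bayes
        prior: [0.25, 4]
        label: bayesian, vague
      - model: bayes
        prior: [1, 2]
        label: bayesian, informative
  - name: Caucasian/*4
    filter: {population: caucasian, required_allele: "*4"}
    analyses: *default_analyses
  - name: Asian/*10
    filter: {population: asian, required_allele: "*10"}
    analyses: *default_analyses
  - name: RR<=2
    filter: {rr_max: 2}
    analyses: *default_analyses
  - name: Tumour DNA
    filter: {dna_source: tumour}
    analyses: *default_analyses
  - name: Non-neoplastic DNA
    filter: {dna_source: non_neoplastic}
    analyses: *default_analyses
  # manual fine-tuning of the selection, as a stakeholder might do:
  - name: Asian/*10, RR<=2
    filter: {population: asian, required_allele: "*10", rr_max: 2}
    analyses: *default_analyses
  - name: RR<=2, genotyping *4
    filter: {rr_max: 2, required_allele: "*4"}
    analyses: *default_analyses
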