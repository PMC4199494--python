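# African / European two-deme history (Gravel et al. 2011 low-coverage
# parameter set, collapsed to the two demes used here).
# Times in generations before present (25-yr generations); sizes diploid.
# European growth starts at the EU-AS split (N0 = 1032, 0.38%/generation).
name: afr_eur
pop_names: [AFR, EUR]
generation_time: 25.0
mutation_rate: 2.36e-8
T_split: 2040
deme0:
  - {start: 0, end: 2040, N_end: 14474, growth: 0.0}
deme1:
  - {start: 0, end: 920, N_end: 1032, growth: 0.0038}
  - {start: 920, end: 2040, N_end: 1861, growth: 0.0}
anc_epochs:
  - [2040, 14474]
  - [5920, 7310]
migration:
  - [0, 920, 2.5e-5]
  - [920, 2040, 15.0e-5]
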