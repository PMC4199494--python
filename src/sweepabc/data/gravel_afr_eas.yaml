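# African / East Asian two-deme history (Gravel et al. 2011 low-coverage
# parameter set, collapsed to the two demes used here).
# Times in generations before present (25-yr generations); sizes diploid.
# Out-of-Africa split 51 kya = 2040 generations; EU-AS split 23 kya = 920
# generations marks the end of the non-African bottleneck (N_B = 1861) and
# the start of East Asian exponential growth (N0 = 554, 0.48%/generation).
name: afr_eas
pop_names: [AFR, EAS]
generation_time: 25.0
mutation_rate: 2.36e-8
T_split: 2040
deme0:
  - {start: 0, end: 2040, N_end: 14474, growth: 0.0}
deme1:
  - {start: 0, end: 920, N_end: 554, growth: 0.0048}
  - {start: 920, end: 2040, N_end: 1861, growth: 0.0}
anc_epochs:
  - [2040, 14474]   # African size back to the 148 kya expansion
  - [5920, 7310]    # ancestral size beyond 148 kya
migration:
  - [0, 920, 0.78e-5]     # AFR <-> EAS after the EU-AS split
  - [920, 2040, 15.0e-5]  # AFR <-> OOA bottleneck population
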