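# Methods

## The inference problem

A derived allele at a known focal site segregates in two diverged
populations — an African population where it is at intermediate frequency
and a non-African population where it is at high frequency or near
fixation. Three competing histories could have produced this pattern:

* **NTR** — the allele is neutral everywhere; its frequency differences are
  drift.
* **SDN** (hard sweep) — the allele was beneficial from the moment it arose,
  with selection coefficient `s_A` in the African/ancestral population and a
  possibly different coefficient `s_NA` in the non-African population after
  the split.
* **SSV** (soft sweep) — the allele segregated neutrally until time `t_mut`,
  when it became beneficial (coefficient `s_NA`) in the non-African
  population only, starting from standing frequency `f0`.

The package decides between these models, and estimates their parameters,
with rejection ABC: large numbers of simulations under each model are
summarised by the same statistics as the observed data, and the simulations
closest to the observation carry the posterior.

## Demographic model

Both populations descend from one ancestral population that splits at the
out-of-Africa event, 51 kya (2,040 generations at 25 yr/generation). The
shipped parameterisations transcribe the Gravel et al. (2011) low-coverage
fit, collapsed to two demes:

| quantity | value |
| --- | --- |
| ancestral size (beyond 148 kya) | 7,310 diploids |
| African size (from 148 kya) | 14,474 |
| out-of-Africa bottleneck (51–23 kya) | 1,861 |
| East Asian growth (23 kya →) | N0 = 554, 0.48%/gen |
| European growth (23 kya →) | N0 = 1,032, 0.38%/gen |
| migration AFR ↔ bottleneck | 15 × 10⁻⁵ per gen |
| migration AFR ↔ EAS / AFR ↔ EUR | 0.78 × 10⁻⁵ / 2.5 × 10⁻⁵ |
| mutation rate | 2.36 × 10⁻⁸ /bp/gen |

The African deme carries the ancestral line backward in time, so a
"two-deme" model is really a piecewise single/two-deme history. Any other
two-deme history can be supplied as YAML; single-deme reductions of the
same histories back the demographic-null neutrality tests.

## Simulator

### Focal-allele trajectories

The focal variant's frequency path is simulated forward in time with a
per-generation Wright–Fisher update: deterministic selection with genotype
fitnesses 1 : 1+hs : 1+s (dominance h, default 0.5), symmetric migration at
the epoch's rate, then binomial drift at the epoch's size. For SDN/NTR the
path starts from one copy at `t_mut` — in the ancestral population when the
allele predates the split, otherwise in the African deme (the non-African
deme is then seeded by migration). For SSV the standing frequency `f0` is
imposed in both demes at `t_mut` (a shared standing variant); the pre-onset
history is generated by running the neutral binomial process backward from
`f0` until loss, which is the time-reversal of a neutral path conditioned on
reaching `f0`. A pre-onset path that fixes backward would mean the allele is
ancestral, so the draw is rejected.

All simulations are **conditioned on the variant segregating in both demes
at present**, by rejection, with the parameters redrawn from the prior on
every rejection. The accepted draws therefore realise the non-uniform
*effective* prior; acceptance rates are first-class outputs (reported per
batch) because they define that prior. Priors are uniform within the bounds:
SDN `s_A ~ U(0, 1.5%)`, `s_NA ~ U(0.5%, 5%)`, `t_mut ~ U(40, 70) kya`; SSV
`s_NA ~ U(0, 5%)`, `f0 ~ U(0, 20%)`, `t_mut ~ U(21, 51) kya`; NTR
appearance time `~ U(40, 70) kya`.

Trajectories run at full, unrescaled resolution. The phases that decide a
draw's fate — establishment of a single copy, colonisation of the second
deme by migrants, the approach to fixation, the reverse pre-onset walk —
are all boundary phenomena with O(1) copy numbers, exactly where
population-size rescaling is least faithful; since rejected attempts die
young, the unrescaled loop is affordable.

### Linked variation

Haplotypes over the surveyed region (default 12 kb, focal site at 8 kb so
that the 6 kb-upstream + 2 kb-downstream window fits) are generated by a
structured coalescent conditioned on the trajectory, the same construction
used by trajectory-conditioned sweep simulators: sampled lineages are
labelled by deme and focal-site allelic class; within a class, lineages
coalesce at the rate set by that class's frequency path; recombination
moves flanking material between backgrounds (a breakpoint between a
lineage's material and the focal site re-draws its class from the current
frequency); at the allele's origin the derived class collapses into a
single lineage. Mutation is infinite-sites at the demography's rate,
recombination uniform at 1.76 cM/Mb.

This backward pass runs on a rescaled clock (λ = 10 by default: sizes N/λ,
rates ×λ, generations /λ, the standard speed/fidelity trade): generations
are stepped one by one while the variant exists or sizes change each
generation, and the deep neutral phase uses exponential-jump sampling over
the piecewise-constant ancestral epochs. The region is discretised into 48
recombination loci (breakpoints between loci, mutation positions
continuous within them); per-lineage ancestral material is a locus bitmask
plus per-locus descendant bitsets, so segregating mutations are emitted on
the fly without storing the full ancestral recombination graph, and loci
that reach their MRCA are pruned.

Sample sizes default to 100 haplotypes per deme (50 diploids). The sampled
focal column is a binomial draw around the trajectory's final frequencies,
redrawn until the pooled sample is polymorphic. Calibration: under
constant-N neutrality the engine reproduces Watterson's E[S] = 4NμL·a_n,
mean Tajima's D ≈ 0 and mean Fay & Wu's H ≈ 0, and its site-count
distribution is indistinguishable from an independent coalescent simulator
(two-sample KS; see the test suite).

## Summary statistics

The default registry has 22 entries: {π, Watterson's θ, Tajima's D, Fay &
Wu's H} × {4 kb symmetric, 8 kb asymmetric window} × both populations,
Reynolds F_ST at the focal site, Weir–Cockerham F_ST (ratio of sums of the
1984 variance components, with observed heterozygosity from
consecutive-haplotype genotype pairing) over the 4 kb window and the whole
region, raw XP-EHH at the focal site, and the derived-allele frequency in
each population. The source analysis counts "16" statistics while listing
the same families; no decomposition we could construct yields exactly 16,
so the registry computes the full both-population set and is configurable
for alternative readings.

Notable conventions, each configurable:

* **Fay & Wu's H** is the unnormalised 2000 form θ_π − θ_H.
* **EHH/iHH**: EHH between core and target includes both end columns; iHH
  integrates EHH against genetic distance by trapezoid, each direction
  truncated at the first site where EHH < 0.05 (that closing trapezoid
  included); when EHH never falls below the threshold the integral extends
  to the region edge with the last value and the result is flagged
  edge-truncated. Edge-truncated values are used as-is: simulated and
  observed regions share one length, so the truncation cancels in the ABC.
* **XP-EHH** in the registry uses the site-wise pooled core — EHH over all
  haplotypes of each population from the focal site, whose value at
  distance zero is the core-site homozygosity — which is the statistic's
  original cross-population form and is defined for every polymorphic
  focal site. The allele-specific variant (core = derived carriers) is
  available but is undefined whenever a deme's sample carries fewer than
  two derived copies, which under conditioned neutral simulations happens
  often enough to discard most rows. Raw (unstandardised) XP-EHH enters
  the registry because the ABC z-scores every statistic across the
  simulation set; genome-wide standardisation has no analogue for
  simulated regions.
* **iHS** (genome-scan use, not in the ABC registry) is
  ln(iHH_ancestral/iHH_derived) with a 5% minor-allele-frequency filter,
  standardised within 1% derived-frequency bins; bins with fewer than two
  scores merge into the nearest populated bin.
* **Empirical p-values** count ties as exceedances; zero exceedances
  report the floor bound 1/N, flagged, never p = 0.
* Undefined statistics (D with S = 0, F_ST at a doubly monomorphic site,
  zero iHH) raise, and become flagged NaN sentinels in summary vectors.

## ABC

Statistics are z-scored across the simulation table (constant columns
dropped), reduced to 7 partial-least-squares components — discriminant PLS
on dummy-coded model labels for model choice, ordinary PLS on the
parameters for estimation — and the 1% of simulations nearest the observed
vector in component space (Euclidean, ties kept) are retained. Model
posteriors are retained-count shares weighted inversely by each model's
training count, under equal model priors; Bayes factors are posterior
ratios, with zero counts reported as 1/n_retained floor bounds. Pure
rejection (uniform weights among retained) is the default, with
Epanechnikov distance-kernel weighting of the retained set available as
an option; the
post-rejection regression machinery of ABC toolboxes is deliberately not
emulated beyond an optional local-linear adjustment, because its defaults
are undocumented and pure rejection is reproducible and assumption-light.
Parameter posteriors come from the retained draws: mode by Gaussian KDE
(Silverman bandwidth) on a 512-point grid, 95% credible interval from the
2.5/97.5% quantiles, values clamped to the prior support after adjustment;
fewer than 50 retained rows flags the interval unstable.

Simulations with sentinel entries are dropped (and counted) before any
fit; a sentinel in the observed vector removes that statistic from the
run's registry with a warning. Model-choice training sets are balanced by
downsampling to the smallest model's count so unequal budgets cannot
masquerade as evidence.

**Cross-validated power.** `cross_validate_power` holds out pseudo-observed
simulations per model, fits the reduction once on the remaining (balanced)
training set, and assigns each held-out vector to the argmax-posterior
model; per-model correct-assignment rates come with binomial standard
errors. The shipped evaluation uses 20,000 training simulations and 200
held-out datasets per model — two orders of magnitude below the original
analysis's 8 × 10⁵ reference tables, a deliberate desk-scale choice.

**Dominance comparison.** `dominance_model_choice` pools reference tables
for {SDN, SSV} × h ∈ {0, 0.38, 0.5} plus NTR into one rejection run; the
dominance marginal sums SDN and SSV within each h, and SDN/SSV are also
renormalised within each dominance model.

## Numerical and design choices

* Coordinates are 0-based half-open internally; VCF input is the single
  1-based surface. Haplotypes are polarised at read time (0 ancestral,
  1 derived) using upper-case (high-confidence) ancestral-allele
  annotations only, by default; sites without a usable ancestral call,
  indels and multiallelic records are dropped and counted. Missing or
  unphased genotypes are hard errors, never imputed.
* The compound di-nucleotide focal variant is modelled as one biallelic
  locus; when reading 1000 Genomes-style data the overlapping indel record
  stands in for it.
* One top-level seed; stage seeds derive via `SeedSequence([seed, stage])`,
  per-simulation seeds via `SeedSequence([seed, row])`, so batches are
  deterministic, order-independent and resumable from checkpoints. Prior
  draws happen in vectorised blocks with the rejection loop compiled;
  the generator is seeded once per block.
* The trajectory grid stores one frequency per λ generations; the
  coalescent reads frequencies off that grid.
* `retain_fraction`, `n_components`, window extents, the EHH truncation
  threshold, λ, and the statistic registry are all configurable run
  parameters; defaults are stated above.

## What the generator does and does not emulate

The synthetic data reproduce: two-population out-of-Africa structure with
migration, conditioned selected/neutral focal trajectories with dominance,
linked neutral variation shaped by those trajectories, uniform
recombination, and complete, phased, polarised haplotypes. They do not
emulate: variable recombination (hotspots), sequencing or phasing error,
ancestral-allele misidentification, background selection, recurrent
mutation at the focal site, or more than two demes. Passing tests
therefore validate the inference machinery under the stated model, not
robustness to those real-data complications.

## Known limitations

* Conditioning on *segregation only* leaves the present-day focal
  frequencies highly model-informative: conditioned NTR draws sit at low
  frequency in both demes, SSV draws at low African / near-fixed
  non-African frequency, SDN draws at high African frequency (selection
  acts there from the allele's origin). The three models therefore occupy
  largely disjoint corners of frequency space, which makes cross-validated
  model choice on this generator's own draws easier — especially for SSV —
  than it would be under the stricter alternative of conditioning each
  trajectory on matching an *observed* pair of present-day frequencies
  (the convention of trajectory-bridge simulators, under which frequencies
  carry no between-model information and discrimination rests on haplotype
  structure alone). That stricter conditioning requires backward bridge
  simulation (forward rejection is hopeless for, say, neutral near-fixation)
  and is not implemented; the rejection scheme here is the package's
  defined behaviour.
* Pure rejection is used for model choice; no post-rejection regression
  (GLM-style) reweighting of retained simulations is applied by default.
* Reference-table sizes of 2 × 10⁴ per model (the shipped evaluation
  scale) leave visible Monte-Carlo noise in posterior proportions at 1%
  retention; production analyses should scale the tables up.
* SSV imposes the same standing frequency in both demes at onset; letting
  the demes drift apart before onset would require conditioning the
  two-deme pre-onset history on both surviving, which rejection makes
  expensive for small `f0`.
* The λ-rescaled coalescent slightly coarsens very recent haplotype
  structure (events within λ generations of the present).
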