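# Methods

## The statistic

`hapscan` detects recent or ongoing selective sweeps that happened in one
population but not in a closely related one. A sweep drags a long, nearly
homozygous haplotype to high frequency faster than recombination and
mutation can break it up, so in the swept population pairs of chromosomes
stay identical-by-state (IBS) over unusually long stretches around the
selected site.

For haplotypes *i*, *j* and a test site *k*, let `L_ij(k)` be the number of
consecutive segregating sites in the maximal IBS run containing *k*
(counted including *k*; 0 if the pair differs at *k*; truncated at the ends
of the data). With `SL(k)` the mean of `L_ij(k)` over all unordered pairs
in a haplotype set,

* **nSL(k)** `= ln( SL_A(k) / SL_D(k) )` compares ancestral- vs
  derived-allele carriers within one population;
* **XP-nSL(k)** `= ln( SL_P1(k) / SL_P2(k) )` compares two populations on a
  shared site list. Positive values point to a sweep in population 1.

Distance is measured in numbers of segregating sites, so no recombination
map is required. The natural log is used; any other base would rescale
scores and be absorbed by normalization.

### Truncation options

The untruncated definition above is the package default and is what the
brute-force oracle tests pin down exactly. Production genome scans in this
statistic family additionally truncate the tract extension, and the
published calibration numbers reflect those truncations, so the simulation
-study profile (`ScoreOpts`) enables them:

* `ehh_cutoff = 0.05` — extension from the core stops once the pooled
  haplotype homozygosity (fraction of pairs IBS throughout the extended
  interval) decays below 5%;
* `max_extend = 100` — extension is capped at 100 sites either side of the
  core;
* `min_maf_core = 0.05` — scores are left undefined at cores whose minor
  allele frequency is below 5% in both populations (all sites still count
  toward tract lengths).

Both kernels (a per-pair run-splitting kernel for the exact definition and
a partition-refinement homozygosity kernel for the truncated form) are
numba-compiled and agree exactly when truncation is disabled — this
equivalence is tested. In neutral pilot runs the truncation choice moves
the central-window max-score median from ~1.1 (untruncated) to ~2.0
(truncated), bracketing the published 2.093; the cutoff does almost all of
the work, the cap and MAF filter are nearly inert under neutrality.

## Normalization

Raw log-ratio scores have demography-dependent location and scale, so they
are standardized: `norm = (raw - mean) / sd`, with mean and sd (population
formula, n denominator) taken from a baseline — either the genome-wide
empirical distribution or neutral simulations of a matched demography,
pooled across chromosomes/replicates. XP-nSL uses a single genome-wide
bin; nSL is binned by derived-allele frequency (10 equal-width bins by
default) because its raw distribution shifts with frequency. Sites with
`norm > 2` (roughly the top 2% of neutral scores) are flagged "extreme".

## Window scan

Linked sites produce clusters of extreme scores, so detection is
window-based: non-overlapping 100-kb windows tiled from coordinate 1
(trailing partial windows kept), summarized by the number of defined
scores, the fraction of extreme scores, and the maximum score. Windows
with more than `min_snps = 10` sites are ranked by site count into
`qbins = 10` near-equal-occupancy bins (ties broken by genomic order);
within each bin, windows strictly above the 99th percentile of the
extreme-score fraction are flagged — so at most ~1% of the genome can be
flagged even under complete neutrality. Strictly-above (rather than
at-or-above) is used; with continuous fractions the distinction is a
measure-zero tie-break. Adjacent flagged windows merge into candidate
regions; each gene overlapping a window with a defined max score inherits
the best such max score; a permutation test (uniform placement of
non-overlapping same-sized regions, chromosomes weighted by length) asks
whether the number of distinct genes hit is unusually small or large.

## The simulation study

The synthetic-data generator reproduces the two-population divergence
model used to calibrate the scan for the rhesus-macaque high-altitude
analysis (diploid sizes, generations before present):

| parameter | value | role |
|---|---|---|
| N1 | 16,188 | population 1 (selected), present back to split |
| N2 / N3 / N4 | 3,730 / 4,506 / 20,768 | population 2 at present / after T1 / after T2 |
| N5 | 66,210 | ancestral population |
| T1 / T2 / T3 | 4,660 / 5,605 / 9,468 | size-change and split times |

with mu = 2.5e-8 and r = 5.126e-9 per bp per generation, 500-kb segments,
and 46 + 44 sampled haplotypes. `scale_parameters` reproduces the
coalescent-scaled encoding of this model (theta = 809.425, scaled split
time 0.146214905642895, alpha = 2·N_ref·s); the published command implies
N_ref = 16,188.5 while the rounded table value is 16,188 — a ~0.003%
discrepancy that is immaterial but documented. The published scaled
recombination parameter (165.967) is itself rounded inconsistently with
the stated per-bp rate (which gives 165.9645).

Sweeps use additive per-copy selection (fitnesses 1 : 1+s : 1+2s) at the
segment midpoint of population 1, hidden from the sampled data (the
conservative choice — the adaptive site itself is assumed unsampled).
Hard sweeps arise de novo (e = 0); soft sweeps arise neutral and turn
beneficial at establishment frequency e. Conditioning is either on the
allele frequency f at sampling or on fixation g generations before
sampling.

### Engine

Each sweep replicate is built in three steps.

1. A per-generation allele-frequency trajectory for population 1 is drawn
   by a forward Wright-Fisher sampler: the standing-variation phase (for
   e > 0) as a reversed loss-conditioned neutral walk from e down to a
   single copy, then the selected phase by rejection sampling, stopping at
   the first crossing of f or appending g post-fixation generations. The
   sampler is cross-checked against an independent plain Wright-Fisher
   oracle for conditional fixation times.
2. The sample's genealogy is run backward through that trajectory by a
   structured Wright-Fisher coalescent with recombination
   (`hapscan._sweepengine`): lineages carry their ancestral material and
   an allelic class; each backward generation every lineage picks a parent
   chromosome uniformly within its class (multiple mergers arise naturally
   when the favoured class is small), and recombination splits a lineage
   at a uniform breakpoint, the piece on the far side of the sweep site
   re-drawing its class with probability equal to the current allele
   frequency. In the trajectory's first generation the favoured class is
   a single copy, so all remaining carriers coalesce onto the mutation's
   origin haplotype. Crucially this includes the standing phase, during
   which carriers keep coalescing at the (frequency-scaled) neutral rate —
   the main source of the soft-sweep haplotype signal. (msprime's built-in
   sweep model omits the standing phase entirely, which pilot runs showed
   erases nearly all soft-sweep signal.)
3. Because the divergence model has no post-split migration, the two
   daughter populations are independent back to the split: population 1's
   remaining lineages finish neutral coalescence to T3 in msprime
   (`initial_state` continuation), population 2 is simulated separately to
   T3, the partial tree sequences are disjointly unioned, and coalescence
   finishes in the ancestral population.

Neutral replicates use a single msprime call with the full demography;
under neutrality the staged and direct constructions are the same process.
Mutations are laid down under an infinite-sites binary model and snapped
to integer bp (collisions shifted by +1; sites pushed past the segment
end dropped).

If a trajectory is longer than the time back to the split (possible for
e = 0.2 soft sweeps, whose standing phase is long), the structured phase
is truncated at the split and remaining carriers are released unmerged —
a documented approximation outside the calibration grid used here.

### Calibration quantities

Normalizing neutral replicates against their own pooled scores, the max
normalized score in the central 100 kb of each replicate gives the null
max-score distribution; its 99th percentile ("neutral99") is the
max-score detection threshold. Window-method thresholds come from the
same neutral central windows via the binned top-1% construction, which
pins the neutral false-positive rate near 1% by construction. Power is
the fraction of sweep replicates whose central window (or central-window
max) exceeds the neutral threshold. Mismatched-history experiments
("Rand"/"Under"/"Over": parameters redrawn within their 95% CIs, or the
present-day sizes pushed to the CI endpoints that under-/over-state the
size contrast) re-normalize the matched neutral replicates with a wrong
baseline; the "Over" history shifts scores strongly positive (population
2 simulated far too small makes its tracts far too long, so the baseline
mean is far too negative) and floods the scan with false positives,
while "Rand"/"Under" shift scores negative and silence it.

### Problem sizes

The package's test and acceptance profiles run the study at reduced scale:
500 neutral replicates (vs 5,349 published), 150-300 replicates per
mismatched history for baselines, and a pooled subset of the sweep grid
(s in {0.02, 0.05}, e up to 0.05, f in {0.9, 1.0} and g = 50, ~6-9
replicates per cell, >= 100 pooled per claim). At these sizes the
sampling error of the reported quantiles is ~0.05-0.15 score units and of
the rates ~1%, which the asserted tolerances accommodate. What the
passing tests show is that the pipeline reproduces the published
calibration and power behaviour of the statistic under the stated model —
not that the macaque analysis itself is reproduced, which would require
the real genotype data and annotation.

## Numerical choices

* Standard deviations use the n denominator; fixed for bit
  reproducibility, immaterial at genome scale.
* Quantiles use numpy's default linear interpolation.
* Site-count bin assignment for out-of-sample windows clamps to the
  fitted range (a sweep window with more sites than any neutral window
  falls in the top bin).
* All randomness flows from a single integer seed per operation;
  replicate i of a batch uses seed + i, and sub-seeds are drawn from
  `numpy.random.default_rng` kept below 2^31 for the C-level engines.
* Undefined scores (NaN) propagate through normalization and are excluded
  from window site counts; `sl = 0` (possible only for two-haplotype
  populations) also yields an undefined score.

## Limitations

* Sweep simulation assumes the sweep completes (backward in time) within
  population 1's constant-size epoch; very weak selection (s << 0.01)
  could leak past the split, where the engine would silently treat
  remaining favoured lineages as neutral.
* Missing or unphased genotypes are rejected, not imputed.
* The permutation test places regions uniformly; it does not condition on
  site density or recombination landscape.
* No migration after the split is modelled, matching the calibration
  demography; applying simulated-baseline normalization to populations
  with gene flow would need a different generator.
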