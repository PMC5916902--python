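# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical conventions. Nothing here states a result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Interactome harmonization

Three assay families arrive on incompatible scales. CRAC counts are
modelled as depth × abundance × affinity; the pipeline removes depth and
abundance in turn:

1. **Hits per million** — counts scaled so each library sums to 10⁶
   (relative tolerance 10⁻⁹ enforced). An all-zero library is an error
   ("empty library").
2. **Per-transcript unit norm** — for each transcript, the vector of hpm
   values across *all supplied CRAC experiments jointly* (all RBPs and
   replicates) is divided by its Euclidean norm, so ∑ᵢ xᵢ² = 1. The span
   matters: abundance is common to every library, so the joint span cancels
   it; normalizing only within one RBP's replicates would cancel the
   affinity signal itself (with near-identical replicates every value would
   collapse toward 1/√r). A `unit_norm_scope="per_rbp"` switch exists for
   comparison. Transcripts with an all-zero vector are left at zero,
   flagged, and always categorized very-low/none.
3. **Min–max rescale to [0, 1]** — per experiment by default (columns of a
   binding heat map are compared within, not across, experiments); a global
   variant sits behind `rescale_scope="global"`. A constant experiment
   rescales to all zeros with a recorded warning rather than an error.
4. **Quartile categories** — transcripts ranked by descending score and cut
   into four contiguous groups whose sizes differ by at most one; when
   N mod 4 ≠ 0 the extra members go to the strongest categories first. Ties
   break by a stable sort with transcript id as the final key; an all-tied
   experiment warns.

RIP scores are quartiled per experiment as published; CLIP calls map
directly to bound/unbound and carry no 0–1 score.

## Running-sum enrichment

Unweighted (Kolmogorov–Smirnov) form by default, because the weighting used
in any particular published ranking is rarely recoverable; a
`weighting_exponent` ≥ 0 reweights member increments by |score|^p. The null
is gene-label permutation — random same-size sets — the only null available
for a single ranked profile. For the unweighted statistic the walk's
extrema occur immediately before/after member positions, so the ES of a
permuted set is computed in O(s) from its member ranks; permutation nulls
are fully vectorized.

The default alternative is **"greater"** (enrichment): p is the add-one
tail probability that a random set scores at least the observed ES. This
one-sided test is calibrated — P(p ≤ α) = α under the null, verified at
α = 0.05 over 1000 simulated null rankings (universe 500, set size 7,
199 permutations each). A sign-adaptive rule that mirrors the comparison to
whichever side the observed ES happens to fall on is a two-sided test with
α on each side and doubles the type-I rate; it is therefore not the
default. "less" and "two-sided" (|ES| comparison) are selectable.

## RIP-qPCR quantification

Relative quantity q = dilution × E^(−Ct) with efficiency E ∈ (1, 2],
default 2.0 (perfect doubling; no efficiencies are usually reported with
IP experiments, and per-primer values can be supplied in the well table).
Technical replicates are averaged on the Ct scale; a spread above 0.5
cycles warns. Percent of IP scales the measured input aliquot up by the
share of material it represents. Fold over control normalizes by bait
recovery first and the no-tag value second; the two orders differ by a
constant per target, so folds are unaffected — the bait-first order is
kept for readability. A zero no-tag denominator is an error unless a
pseudocount is explicitly configured (then a warning).

## Polysome distributions

Fourteen 0.9-ml fractions by default, classes light = 1–6 (free mRNPs),
monosome = 7–8, polysome = 9–13, fraction 14 unassigned; all configurable.
Monosome fractions span the 80S peak and belong to neither the repressed
nor the actively translated numerator. Spike correction divides by the
*relative* (mean-centred) spike recovery so it is unit-free and an
equal-recovery gradient is untouched. The heavy-polysome subrange
(≥ 4 ribosomes/mRNA) defaults to fractions 11–13 but is gradient-specific
and therefore a parameter, not a constant.

## Turnover

Dilution calibration is least squares through the origin (zero protein,
zero signal); the uncentred r² equals 1 on noiseless proportional data. A
free-intercept variant is not fitted by default — films with a background
offset should background-subtract upstream. Decay is single-exponential,
fit by OLS on log₂(amount) versus time with a free intercept so t = 0
measurement noise does not anchor the curve; k = −slope·ln 2 is clipped at
0 with a warning when a series apparently grows, and t½ = ln 2/k (∞ at
k = 0). The exponential model is this package's formalization of
"relative amount versus time" plots; fits are labelled as model-based
estimates in the output tables.

## Transcriptome replicates

Dye-swapped replicates are sign-flipped before averaging (an involution:
flipping twice restores the input). Between-replicate SD uses the n−1
denominator, so two replicates give |difference|/√2. The consistency
filter removes genes with SD strictly greater than 0.5 (a gene at exactly
0.5 is retained); genes with a single replicate have no SD and are removed
with a "single replicate" flag. Category-versus-baseline comparisons use
the two-sided Mann–Whitney–Wilcoxon test by default, with Welch's t-test
as the alternative; no multiple-testing correction is applied across the
three category tests by default (single-test reporting is the convention
being reproduced), and a Benjamini–Hochberg switch is easy to add at the
call site since raw p-values are returned.

## Motif scanning

Consensus scanning only (no PWM/EM discovery): fixed IUPAC strings and
triplet repeats expanded to their full consensus. U ≡ T on both sides; N is
a wildcard on both sides. Only the mRNA sense strand is scanned.
Coordinates are 1-based inclusive to match probe-naming conventions such
as "21–80"; the I/O layer writes BED (0-based half-open) alongside.
Correctness is established by exact agreement with an independent
position-by-position matcher over 1000 seeded random 500-nt sequences.

## Synthetic-data generator

The generator supplies the statistical structure each stage assumes, not a
mechanistic simulation:

* **Binding counts** are gamma-Poisson: rate Γ(1/d, d·μ) with
  μ = depth · affinity · expression (normalized), dispersion d = 0.2 by
  default; d = 0 degenerates to deterministic half-up rounding of μ so the
  zero-noise limit is exact. Expression is lognormal with sdlog 1.5 — a
  deliberately strong confound. The default panel is one *specific* binder
  (affinity sdlog 1.5) plus two *generic* mRNA-binding factors (sdlog 0.3),
  two replicates each at depth 2 × 10⁶. The heterogeneous panel mirrors a
  real RBP survey (a sequence-specific hnRNP among general export/packaging
  factors) and is also what makes the per-transcript unit norm informative:
  with several equally wide independent affinity priors the shared norm
  denominator mixes the affinities and caps the achievable score–affinity
  correlation near 0.7 regardless of spread. RIP-type experiments emit rank
  percentiles of noised log-affinity; CLIP-type experiments threshold
  affinity at the 75th percentile.
* **Polysome profiles** are two discretized Gaussian bumps over fraction
  indices (light peak at 3, polysomal peak at 11), mixed (1−θ)/θ,
  renormalized over fractions 1..F, then multiplied by per-fraction spike
  recovery factors (uniform in 1 ± 0.3) and lognormal mean-1 noise
  (CV 0.1); the spike is emitted with the same recovery factors and its own
  noise. The default peak width is 1.2 fractions: with the 9–13 polysome
  window a pure polysomal peak then keeps ≈ 97% of its mass in-window, so
  planted θ is recoverable within ±0.05 across θ ∈ {0.2, 0.5, 0.8}; a
  substantially wider bump (e.g. σ = 1.5) leaks > 8% of the polysomal
  component past the window boundaries and biases recovery at high θ
  beyond that tolerance by construction.
* **Chase series** are 2^(−t/t½) with lognormal mean-1 noise (CV 0.05);
  t = 0 is defined as 1 before noise, and t½ = ∞ yields a constant series.
* **qPCR tables** are built backwards from planted folds so the noiseless
  roundtrip through the quantification module is exact to float precision:
  Ct = offset − log_E(q) + N(0, sd), three technical replicates, input
  aliquot 10%, distinct bait recoveries for the tagged (0.8) and no-tag
  (0.25) samples so the bait normalization is actually exercised.
* **Dye-swap ratios** store the negated orientation for swapped replicates;
  a planted per-gene inconsistency s offsets the two oriented replicates by
  ∓ s/√2 around the fold, so the measured n−1 SD equals s when measurement
  noise (default sd 0.15) is off — making the SD > 0.5 filter's recovery
  set exactly predictable.
* **Sequences** are uniform random ACGT with the consensus site written in
  at recorded 1-based positions in half of the sequences.

One global seed expands into per-stage child streams via
`SeedSequence(seed, spawn_key=(stage_index,))` with fixed stage indices
(binding 0, polysome 1, chase 2, qpcr 3, microarray 4, sequences 5), so
stages are individually reproducible and byte-identical under a repeated
(config, seed).

What the generator does **not** emulate: read- or fragment-level data (no
FASTQ, no crosslink-site geometry), GC or length biases, correlated
affinities between RBPs, partial ribosome loading between the two polysome
populations, two-phase protein decay, dye-specific intensity bias, or
probe-level microarray noise. Passing recovery tests therefore shows the
estimators are correct under their assumed error models, not that those
models capture every failure mode of real data.

## Simulation sizes and seeds

The validation battery uses: 2000 transcripts for the confound-removal
study; 1000 null rankings and 200 planted-shift rankings (universe 500,
set size 7, 199 permutations) for permutation-test calibration and power;
8 targets per planted θ for polysome recovery; 100 chase series (true
t½ = 30 min, 5% noise) for half-life recovery; 200 runs of 200 genes for
the category-downshift power check; 1000 random 500-nt sequences for
scanner/oracle agreement; and a 200-transcript end-to-end pipeline run
executed twice for checksum determinism. These sizes give stable estimates
(Monte-Carlo SE well inside each tolerance) while keeping the whole battery
in the tens of seconds. All studies derive their randomness from a single
seed argument.

## Known limitations

* The enrichment module reports no leading-edge subsets and no multi-set
  FDR; both are additive extensions.
* PWM scanning with log-odds thresholds is not implemented; consensus
  strings only.
* The polysome module consumes fraction quantifications; it does not
  process A254 traces or call peak boundaries.
* Absolute copy-number qPCR and standard-curve efficiency estimation are
  out of scope; efficiencies are inputs.
* The quartile category map and the ∑ᵢ xᵢ² = 1 span are conventions chosen
  here (documented above); published heat maps built with different spans
  will differ in detail even on identical inputs.
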