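# Methods notes

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical choices a maintainer would want to know. It states no empirical
result that the test suite does not itself compute.

## Coordinates and containers

All coordinates are 0-based half-open (BED convention) throughout, including
internally; "book-ended" intervals (end of one equals start of the next) do
not overlap and are not merged at the default `max_gap=0`. `IntervalSet`
keeps its members sorted by (chrom, start, end) and silently drops exact
(chrom, start, end, name) duplicates. Strand defaults to unstranded and
only matters for footprinting and gene association.

## Synthetic data: the stated world

The generator emulates a nine-condition differentiation time course
(D0; D3A, D3NMP; D4A/H/SC; D5A/H/SC) with ten region classes whose
open-condition sets encode the qualitative dynamics of the system: `neural`
open in all D4/D5 conditions, `anterior`/`hindbrain`/`spinal_cord` open only
in their own D4/D5 conditions, `NMP` open only at D3NMP, `NMP_SC` at D3NMP
plus D4/D5SC, `A_H` and `H_SC` in the respective shared conditions,
`epiblast` only at D0, and `background` never. Defaults:

| parameter | default | rationale |
|---|---|---|
| accessibility multiplier (open / closed) | 6 / 1 | the source dynamics are qualitative (z-profiles); 6× gives log2FC ≈ 2.6, comfortably past the |log2FC| > 1 gate without being trivial |
| baseline fragments per region per library | 100 | desk-scale depth; ~100–300 k fragments per library at defaults |
| NB dispersion (1/size) | 0.05 | typical biological replicate CV (~25%) for ATAC counts |
| replicates per condition | 3 | minimum for a stable dispersion estimate; invariant requires ≥ 2 |
| fragment length mixture | 0.55·N(60, 15²) + 0.45·N(200, 40²), truncated to [10, 2000] | bimodal sub-nucleosomal / mono-nucleosomal profile of ATAC libraries; truncation mirrors the usual 2 kb mapping cap |
| per-region strength | lognormal, sd 0.5 on the log scale, drawn once per region and shared by all samples | real peak strengths span orders of magnitude and are a property of the region; without this heterogeneity replicate peak scores carry no rank correlation and no IDR procedure can operate |
| background scatter | 10% of fragments, uniform genome-wide | keeps the toy peak caller honest |
| motif fraction / protection | 25% of regions; p_prot = 0.2 | a planted caudal-homeodomain (TTTATGAT-core) motif; protection thins Tn5 cuts in bound cores to 20% |

Fragment generation: per-region counts are NB draws (Poisson below
dispersion 1e-10); midpoints uniform in the region; footprint protection is
applied at the fragment level — each fragment is kept with probability
`p_prot` per insertion endpoint falling inside a bound motif core (the
endpoints are +4/−5-shifted cut positions). Because fragments are atomic,
thinning an endpoint necessarily removes its mate as well; at default motif
and region sizes this changes bound-region counts by ~3% and is ignored
downstream.

Determinism: one root seed; every stage and sample draws from
`numpy.random.default_rng([seed, stage_tag, sample_index])`, so subsets can
be regenerated independently and bit-identically. The pipeline derives
stage seeds as `blake2b(f"{seed}:{stage}")` folded to 31 bits.

Not emulated: read-level artefacts (sequencing errors, mapping ambiguity,
duplicates), GC and Tn5 sequence bias, copy-number variation, chromatin
domains and correlated background. A green test therefore establishes that
the statistics recover a planted signal under NB noise with realistic peak
geometry — not that they are robust to alignment artefacts.

## Peak calling and consensus

The candidate caller slides a 300 bp window (step 100) and tests the number
of overlapping fragments against Poisson(λ) with
λ = n_fragments × (window + mean fragment length) / genome size — the
expected overlap count under uniform placement. Windows with upper-tail
p < 0.01 are merged; each peak's score is −log10 of its best window p and
its summit the maximum-coverage base. This is a deliberate stand-in for a
model-based caller: only the significance level is carried over.

IDR: matched replicate peak pairs (reciprocal best overlap, ties to the
smaller start) are rank-transformed (ECDF, ranks/(n+1)), mapped to pseudo
scores by numerically inverting the mixture marginal on a 4096-point grid,
and fitted by EM (init μ=1, σ²=1, ρ=0.5, π₁=0.5; tolerance 1e-6 on the
log-likelihood; 500 iterations max). Identifiability constraints: μ ≥ 0 and
ρ ∈ [0.1, 0.999]. Without the ρ floor the two components coincide on null
data (independent replicates) and the fit labels everything reproducible;
with it, the noise component absorbs null data and the mean global IDR on
independent scores is correctly high. The local idr is the posterior noise
probability; the global IDR is the running mean of sorted local values, and
the 0.1 gate applies to the global value by default (a flag selects local).

On a matched list containing only genuine peaks the mixture still carves
out its weakest tail (there is nothing else to anchor the noise component);
this is inherent to the model and the reason relaxed candidate lists are
the recommended input in practice.

Counting: a fragment increments every consensus region it overlaps by
≥ 1 bp, so a spanning fragment counts in both neighbours. Consensus regions
must be non-overlapping (guaranteed by merging).

## Differential accessibility

Median-of-ratios size factors; per-region NB Wald test of condition A vs
reference B: log2FC = log2((mean_A + 0.5)/(mean_B + 0.5)) on normalised
counts, variance from the NB relation Var = μ + φμ² via the delta method,
two-sided normal p. The dispersion φ is the per-region method-of-moments
estimate pooled over the two conditions, **floored by the across-region mean
estimate**: with 2–3 replicates the raw per-region estimate makes the Wald
statistic behave like a 4-df t treated as normal (≈12% null rejections at
α = 0.05); borrowing strength across regions restores calibration (the
suite verifies the null p < 0.05 fraction lands in [0.02, 0.09]) while
letting genuinely noisier regions keep a larger SE. Regions with fewer than
10 fragments across the contrast get p = 1 and a `low_count` flag.
Positive log2FC means more accessible in the non-reference condition.

## SOM classification

Input rows are per-condition replicate means of normalised counts,
z-scored per region with the sample sd (n−1); constant rows are zeroed,
flagged, and excluded from training. The 5×5 map uses an offset hexagonal
layout (odd rows shifted half a cell, rows √3/2 apart), batch training for
100 epochs: weights initialised from a seeded sample of input rows, BMU by
Euclidean distance (ties to the lowest unit index), units reset to the
Gaussian-neighbourhood-weighted data mean with σ decaying linearly from 2.5
to 0.5 grid units. Batch mode (rather than online) makes training
deterministic given the seed; quantization error is recorded per epoch and
must not increase overall.

Unit labelling automates the by-eye merging of map cells into named groups:
each unit's member-mean z profile is compared by cosine similarity to
centred condition-indicator patterns (one per class, including the shared
A/H, H/SC and NMP/SC combinations; the all-zero background indicator
carries no signal and is skipped); below similarity 0.5, or for empty
units, the unit stays unclassified. Ties break by pattern order.

## Footprinting

Insertion events: plus-strand cut at fragment start + 4; minus-strand cut
at the last covered base (end − 1) shifted −5, i.e. stored position
end − 6. The sub-nucleosomal filter (< 100 bp) applies to footprinting
only, not to counting. PWM scanning discretises log2-odds scores at 1/1000
bit and computes the exact score distribution under the background by
dynamic programming; the threshold for a scan p-value is the smallest
*achievable* score whose exceedance probability is ≤ p, which makes the DP
agree exactly with brute-force word enumeration. Overlapping same-strand
hits resolve to the best scorer. Insertion matrices span motif ± 150 bp,
are column-reversed for minus-strand hits, and pool both insertion strands
(a two-channel variant was considered and rejected as unneeded for the
posterior).

The footprint model is a two-component mixture: bound sites draw their
window counts X|N ~ Multinomial(N, λ) with λ free (it learns the core
depletion) and N ~ NB(μ_b, φ); unbound sites use the flat profile and
NB(μ_u, φ); the mixing prior is logistic in the PWM score. EM details: λ is
MAP-estimated with a Dirichlet(1) smoothing pseudocount (one per window
position); μ updates are exact weighted-mean MLEs; φ is updated by bounded
1-D maximisation on log10 φ ∈ [−4, 1] and only accepted when it improves
the objective; the logistic coefficients are fitted by IRLS with step
halving. Every M-substep is therefore an ascent step and the traced
objective — observed-data log-likelihood plus the Dirichlet smoothing term
— is non-decreasing at every iteration. Components are identified by
μ_b ≥ μ_u (responsibilities are flipped if violated, which at the
median-count initialisation never triggers in practice). Bound calls use
posterior ≥ 0.99 for genome-wide scans and ≥ 0.9 for peak-summit scans.

TSS enrichment aggregates strand-oriented insertions over TSS ± 2 kb,
smooths with a 50 bp running mean (nearest-edge handling, so the window
boundary does not fabricate a minimum), and reports max/min of the smoothed
profile; a zero minimum is reported as infinite with a flag.

## Enrichment and gene association

Fisher mode treats the *region* as the unit: a 2×2 table over the universe
(query × target-overlap), one-sided (enrichment) exact p, BH across
targets, enriched at adjusted p < 0.01. Binomial mode works on base-pair
fractions: p = upper tail of Binomial(|query|, merged annotation bases /
genome size). Genomic context is assigned by the feature containing the
region midpoint with priority promoter (TSS ± 3 kb, the common annotation
default) > exonic > intronic > distal intergenic.

Gene association follows the basal-plus-extension recipe: basal domain 5 kb
upstream / 1 kb downstream of the TSS (strand-oriented, irrespective of
other genes); each side then extends to the nearest other gene's
basal-domain edge, capped at 1 Mb beyond the basal edge and at chromosome
bounds. Extensions of neighbouring genes may overlap in the gap between
them (a region there maps to both genes); because extension stops exactly
at the neighbouring basal edge, abutting basal domains leave no gap and no
tie-break is needed. A region associates with every gene whose extended
domain it overlaps by ≥ 1 bp.

Rank-sum comparisons use midranks; the p-value is exact (enumeration of
group assignments) when min(n, m) ≤ 8 and n + m ≤ 20, otherwise a normal
approximation with tie correction and continuity correction. Accessibility
correlations are Pearson r on log2(normalised mean + 1).

## Pipeline

Stages run in a fixed dependency order (simulate → peaks → idr → consensus
→ counts → diff → som → footprint → enrich); each reads its inputs from the
run directory, so stages re-run individually, and a JSON manifest records
parameters, per-stage seeds, wall times and output SHA-256 checksums —
re-running with the same config and seed reproduces identical checksums.
Config files are YAML; validation reports all problems at once (unknown
keys with a closest-match suggestion, type errors, out-of-range values).
The footprint stage analyses the D3 FGF/WNT condition (where the planted
motif is bound) and skips gracefully with a warning when fewer than 100
motif hits survive matching.

## Known limitations

- The Poisson caller has no local background model; strong closed-region
  accessibility (multiplier 1 is open chromatin too, just less so) means
  essentially every planted region is called in every condition, and
  condition specificity is established downstream by the differential test.
- The IDR fit degrades on matched lists without any irreproducible
  contingent (see above); π₁ recovery is validated on the model's own world.
- The footprint model omits covariates beyond the PWM score (conservation,
  TSS distance) and any Tn5 sequence-bias correction.
- The Wald test's across-region dispersion floor assumes regions share a
  broadly similar mean-variance relation; strongly heteroskedastic real
  data would warrant a trended estimate instead.
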