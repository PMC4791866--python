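# Methods

## The measurement model

Array CGH reports, per genomic probe, the log2 ratio of tumor to
reference DNA abundance.  We model a sample's profile as a
piecewise-constant copy-number signal plus i.i.d. Gaussian probe noise:

    v_i = μ(i) + ε_i,   ε_i ~ N(0, σ²),

where μ is zero on copy-neutral probes and takes a constant value on
each aberrant interval.  Real aCGH noise is heavier-tailed and spatially
correlated ("waves"); the generator can add a sinusoidal wave artifact
(`wave_amplitude`, off by default), but correlated noise is otherwise
out of model — see Limitations.

## Noise and centering

σ is estimated per sample as `median(|v_{i+1} − v_i|) / (0.6745·√2)`
over consecutive non-missing pairs within a chromosome.  First
differences cancel the piecewise-constant signal except at breakpoints,
so the estimate is insensitive to aberrations while breakpoints occupy
fewer than half the positions; the constant makes it consistent for
Gaussian noise.  This is the same idea as the derivative log-ratio
spread commonly used for aCGH QC.

Centering assumes copy-neutral probes form the majority population: the
shift is the argmax of a Gaussian-kernel density estimate of the profile
values (Silverman bandwidth, grid search polished by bounded scalar
minimization, so re-centering an already centered profile moves it by
< 1e-6).  `iterative_recenter` then alternates calling with re-centering
on the median of probes outside called segments, which protects the
baseline when the aberrant fraction is large; it is translation
invariant, and falls back to mode centering with a warning if every
probe is called.  Missing values are skipped, never imputed.

## Segment calling

The caller scores an interval I by S(I) = Σ_{k∈I} v_k / (σ√|I|) and
extracts, per chromosome, the interval maximizing |S|; if
|S| ≥ `score_threshold` it is emitted and the flanks are searched
recursively, so segments of one sample never overlap.  Afterwards
segments with |mean log2| < `min_abs_log2` are discarded and the call
(loss/gain) is the sign of the mean.  Defaults 4.0 and 0.2 are the
standard operating point for 44K tumor arrays.  Missing probes
contribute nothing to the sum and are excluded from |I|.

Numerical choices: the maximal-interval search is exact (prefix-sum
scan; dense O(n²) score matrix up to 2048-probe gaps, a chunked scan
beyond); ties on |S| break toward the longer interval, then the smaller
start index, making output deterministic.  The mean filter is applied to
the segment mean, not per probe.  An exhaustive greedy enumeration of
all O(n²) intervals (`brute_force_caller`) implements the same contract
independently and is compared against the production caller in tests;
agreement is exact on random planted profiles.

Under the model, S is approximately standard normal, so noise-free
planted blocks with |amplitude| ≥ min_abs_log2 and
n ≥ (threshold·σ/amplitude)² probes are recovered exactly; with σ = 0.1
noise the probe-level F1 measured over 20 simulation seeds is ≈ 0.98,
the residual errors being single-probe boundary wobble.

## Ternary matrix and recurrent regions

Calls are projected onto the probe grid as {−1, 0, +1}.  Recurrent
regions for a sample group and direction are maximal runs of consecutive
probes (never crossing a chromosome boundary) whose carrier percentage
strictly exceeds `min_percent`; a region's carriers are the samples
altered at *every* probe of the run, a deliberate choice — the
alternative ("any part of the run") inflates carrier counts under noisy
breakpoints.  Group-private alterations require ≥ `min_carriers_a`
carriers in one group and zero alteration of either direction in the
background group at every probe.  Coordinates are 0-based half-open
throughout, so printed region sizes equal stop − start exactly;
percentages are rounded half-up to one decimal in tables (integer
display is half-up to zero decimals).

## Clustering

Pairwise distances are Hamming counts over probes altered in
≥ `min_altered` samples (default 3), which strips noise-only probes;
loss vs gain disagrees exactly as loss vs neutral does.  Agglomeration
is complete linkage, written in-package so the tie rule is explicit:
among minimal-distance pairs, merge the pair whose lexicographically
smallest member id is smallest (then the smaller partner).  This makes
the dendrogram invariant to sample order; on tie-free inputs the merge
heights equal scipy's.  The tree is cut into k groups (default 4,
exposed, with cluster sizes reported rather than an automatic-k
statistic).  Outliers are detected by iteratively cutting at k, dropping
clusters of size ≤ `max_outlier_cluster_size` (default 1), and
re-clustering the remainder — a rule of this package's own design, since
"too far from everything" has no canonical definition in hierarchical
clustering.

## Cohort statistics

Genomic instability is the per-sample count of called loss and gain
segments.  Cluster pairs are compared with a two-sided Student t-test,
pooled variance by default (Welch via flag); the pairwise p-values are
reported uncorrected with a Benjamini–Hochberg column alongside for
transparency.

Overall survival uses the Kaplan–Meier product-limit estimator and the
log-rank (Mantel–Cox) test, both delegated to lifelines; follow-up is
administratively right-censored at `horizon_years` (default 10) before
testing, the standard reading of a fixed-horizon overall-survival
analysis.  Both the (k−1)-df omnibus test and per-cluster one-vs-rest
tests are reported, because "one cluster has poor survival" is naturally
a one-vs-rest contrast while the omnibus test guards the family.

Known property: at cohort scale (≈ 12 subjects per group, 4 groups) the
chi-square approximation of the omnibus log-rank is anticonservative —
our null simulations measure a type-I error of ≈ 0.07 at α = 0.05
(1000+ replicates, exponential survival, 10-year horizon), and R's
`survival::survdiff` reproduces the same p-values and rejection rate on
identical data.  The inflation grows with the number of small risk sets
(≈ 0.085 uncensored) and vanishes by n ≈ 470.  Two-group comparisons at
the same n are calibrated (≈ 0.05).  Interpret small omnibus p-values
near 0.05 at this cohort size with care.

## Enrichment

Region-derived gene lists are unranked, so over-representation uses the
hypergeometric upper tail P(X ≥ k) with BH-adjusted q-values.  The
default universe is the genes overlapping any probe — the
array-constrained background, which is the defensible null for lists
that can only ever contain array-covered genes; a whole-collection
universe can be supplied instead.  Ranked-list statistics (mHG) and
EASE-style modified Fisher tests are intentionally not implemented.

## Synthetic cohorts

`simulate_cohort` emulates the target study design: 40 + 3 + 4 samples
on a 6-chromosome × 150-probe grid at 43 kb spacing (a desk-scale
stand-in for a 4x44K array), four cluster templates — two loss-heavy
with disjoint region sets, one quiet, one gain-heavy — assigned
round-robin so groups come out of similar size, carrier-private deletion
regions planted only in BRCA1/BRCA2 samples, and a designated BRCA1
locus deleted in a configurable fraction (default 0.29) of
BRCA1-IHC-negative samples.  Planted amplitudes are ±0.45–0.58 log2 —
single-copy changes attenuated by normal-cell admixture as seen in FFPE
material — on σ = 0.1 probe noise.  Overlapping planted regions add, so
the generative model stays linear and the truth set unambiguous.
Survival is exponential per cluster (default hazards 0.06/0.25/0.04/0.08
per year), censored at 10 years; the exponential was chosen for its
closed-form median, which makes recovery tests sharp.  All randomness
flows from one integer seed through `numpy.random.SeedSequence` spawns
(one stream per sample, one for metadata, one for survival), so equal
configs give byte-identical cohorts.

What passing on synthetic data does *not* show: robustness to wave
artifacts and spatially correlated noise, intensity-dependent dye bias,
probe-specific response, CNV polymorphisms in the reference, or
violations of proportional hazards — none of which the generator
produces by default.

## Problem sizes used in the shipped checks

Replicated experiments run at desk scale: 200 profiles for
caller-vs-oracle agreement, 20 seeds × 10 profiles × 600 probes for
probe-level F1, 20 cohort seeds for cluster recovery, 1000 null
replicates for log-rank calibration and 20 seeds for power.  These sizes
give Monte-Carlo standard errors comfortably below the decision margins
of each check while keeping the full suite to a few minutes.

## Known limitations

* ADM-style callers in vendor software differ in unpublished details;
  this caller is the open interval-score formulation, not a clone.
* Per-probe vs per-segment application of the mean-ratio filter is a
  genuine ambiguity in the field; the per-segment-mean reading is
  implemented.
* No multi-sample joint segmentation, CBS/HMM alternatives, Cox
  modelling, or competing risks.
* Cytoband names and real genome-build gene annotations are accepted as
  input but never derived internally.
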