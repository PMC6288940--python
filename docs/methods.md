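# Methods

This note documents the models, rules and numerical choices behind
`cnvpop`, and what the synthetic cohort does and does not establish about
behaviour on real data.

## Coordinates

All intervals are half-open `[start, end)`, so `length = end − start`.
Published coordinate tables in this problem domain print positions whose
accompanying lengths satisfy exactly this identity, so printed
`(start, end)` pairs can be used directly. BED input/output is native
(0-based half-open); GFF3 is 1-based closed and converted on read.
Windows are anchored at position 0 per chromosome; the final partial
window keeps its true base span when averaging depth. Sex chromosomes are
excluded from genome-fraction statistics by default (the analysis is
autosomal); this is configurable.

## Caller filters and consensus

The two ingested caller dialects carry exactly the statistics their
filters use. Caller A (coarse-window, one call per event): losses with
median expected log fold change strictly below −1 and gains strictly
above 0.6 are kept. Caller B (100 bp windows, fragmented): calls of
length ≥ 1 kb (inclusive) with `q0 < 0.5` and `p < 0.001` (both strict)
are kept. These inequalities are deliberate: a het-deletion call sitting
exactly at −1 is rejected.

A caller-A call becomes a consensus CNV when same-sample caller-B calls
cover ≥ `min_overlap_fraction` (default 0.8) of its span. Two choices are
load-bearing:

* **Denominator = the caller-A call.** The 80 % rule does not name its
  denominator; we use the fraction of the A call covered, because caller B
  fragments events ~10:1 (a reciprocal rule would fail every fragment) and
  because consensus yield is naturally accounted as a share of A calls.
* **Union-based support.** Coverage is the union of all overlapping
  same-sample B calls, making consensus exactly invariant to how B
  fragments an event. A best-single-fragment rule would not be.

If any overlapping B call disagrees with A on loss/gain, the whole
consensus call is routed to depth arbitration with its state unset.

Sample outliers are flagged on raw per-caller call counts by
`count > median + k·MAD` with k = 10 — deliberately generous so that only
extreme inflation (an order of magnitude above typical) is excluded. This
formalises what is usually an eyeball judgement; with fewer than four
samples the rule is unstable and flags nothing.

## Depth arbitration (automated visual inspection)

The evidence is the per-sample windowed mean depth (default 100 bp
windows). For a call, the diploid baseline is the **median** window depth
over 50 kb flanks on each side (median, not mean, for robustness to
residual CNVs and spikes). Flank windows overlapping any other
same-sample call are masked, so CNV-dense neighbourhoods do not bias the
baseline; fewer than 10 usable flank windows makes the call unarbitrable
and it is dropped with a log record.

State assignment uses `ratio = mean(region windows) / flank median`:
loss if ratio ≤ 0.70, gain if ratio ≥ 1.30, otherwise the call is a false
positive and removed. Expected ratios are 0.5 (one copy lost of two) and
1.5 (one gained); the midpoints 0.75/1.25 are tightened slightly to
0.70/1.30 to favour precision. Both are configurable
(`ArbitrationConfig.loss_max_ratio`, `gain_min_ratio`).

**Boundary refinement** operationalises "the initial descending (losses) /
ascending (gains) position" at window resolution. Scanning from
`start − 50 kb` toward the event, the refined start is the left edge of
the first window where depth crosses `cross_fraction × flank median`
(0.75 for losses, 1.25 for gains) and stays crossed for
`sustain_windows = 3` consecutive windows; the end is found symmetrically.
Two guards make this robust:

* a candidate crossing must also keep the *mean* depth of the next
  `lookahead_windows = 10` windows (toward the event) on the crossed side.
  At 30× and 100 bp windows, a 3-window noise run occurs about once per
  500-window flank, and without the look-ahead it would drag a boundary
  tens of kb outward; the look-ahead mean rejects such runs while leaving
  genuine boundaries within a window or two.
* scan spans never extend into other same-sample calls (their depth is
  displaced too and would fake a crossing), and a refined interval must
  still reproduce the assigned state; otherwise the original boundaries
  are kept and the call is flagged unrefined.

Refinement is idempotent on a fixed track.

**Region validation.** After cross-sample merging, each candidate CNVR is
compared with two reference samples that have no call overlapping the
region; references are chosen in sample order, preferring ones whose
in-region ratio already sits in the normal band [0.80, 1.25] (the analogue
of picking two cats with visibly normal depth). Every carrier must
reproduce its claimed member state from its own track (complex regions are
judged per member state); failing carriers are removed and a region with
no surviving carrier is discarded. All references must be normal. With
fewer than two eligible references the region is kept and flagged
unvalidatable. GC-content correction of depth is out of scope and assumed
to have happened upstream (or to be irrelevant, as for the simulator).

## CNVRs

Validated consensus CNVs of all samples merge transitively when they
overlap or are bookended (gap 0 — the default of the standard merge
tool). State is loss/gain when all member states agree, complex
otherwise; a singleton has exactly one distinct member sample. Size
classes default to <20, 20–50, 50–100, 100–500 and ≥500 kb (the published
figure enumerates only the outer classes; the inner bounds are a
configurable choice). Breed-private percentages are
`round(100 · members / breed size)` with half-up rounding over
post-exclusion breed sizes — the only rule consistent with the published
2-of-3 → 67 style entries.

## Population structure

The scoring matrix is binary presence/absence of any member CNV per
sample, restricted to CNVRs shared by ≥ 2 samples (singletons carry no
co-variation signal). The sample distance defaults to 1 − Pearson
correlation between column vectors (the default of the clustering tool
this replaces, which does not state its metric); Jaccard distance is the
alternative. Zero-variance columns get distance 1 with a warning.

UPGMA is implemented directly: join the closest pair, new distances are
size-weighted averages, heights are half the joining distance, and ties
are broken by the lexicographically smallest pair of cluster ids (a
cluster's id is the sorted tuple of its leaf labels) — fully
deterministic. The tree is ultrametric by construction; tests verify
cophenetic agreement with an independent average-linkage implementation.

Branch support is by multiscale bootstrap: CNVR **rows** are resampled
with replacement (samples fixed — the standard design when clustering
samples on features) at sizes `round(n·r)`, r ∈ {0.5, 0.6, …, 1.4}, the
tree is rebuilt per resample and each original cluster's recovery counted.
With `BP_r` the recovery frequency at scale r and
`z_r = Φ⁻¹(1 − BP_r)`, the signed-distance/curvature model
`z_r = v√r + c/√r` is fitted per cluster by maximising the binomial
likelihood of the counts (`counts_r ~ Binomial(B, Φ(−z_r))`), initialised
by weighted least squares on the usable scales and falling back to the
WLS solution if the optimiser fails. Then `AU = 1 − Φ(v − c)` and BP is
the plain frequency at r = 1. Clusters recovered always (or never) at
every scale saturate to AU = 1 (or 0); clusters with fewer than two
informative scales fall back to AU = BP with a flag. The default is
B = 10,000 resamples; scaled-down runs (B = 1,000) are used where wall
time matters and change AU by at most a few hundredths.

PCA treats samples as observations and CNVR rows as variables, centring
but not scaling (all variables are same-unit 0/1 indicators; scaling is
exposed as an option). Eigenvalue fractions report variance explained;
component signs are fixed by making each component's largest-magnitude
loading positive, so output is deterministic.

## Synthetic cohort generator

The generator emulates the study conditions end to end so every stage has
a ground-truthed input:

* **Design**: 3 geographic groups × 4 breeds × 3 samples (36 cats),
  150 planted CNVRs on 5 × 20 Mb chromosomes, ≥ 25 kb apart (room for
  flanks). Lengths are log-uniform on 5–530 kb (the observed CNVR size
  range); 84 % losses (the observed state mix). Each CNVR has a "home"
  group with carrier frequency ~Beta(2, 2) and background frequency
  ~Beta(1, 12) elsewhere, giving group-structured sharing; every planted
  region is guaranteed ≥ 1 carrier. Carrier copy numbers are 1 (or 0 with
  probability 0.2) for losses and 3 (or 4 with probability 0.2) for gains.
* **Depth**: per 100 bp window, NegativeBinomial via gamma–Poisson with
  mean `30 × cn/2` and gamma shape k = 50 (variance = μ + μ²/k, mildly
  overdispersed relative to Poisson, as real sequencing is);
  `nb_dispersion = 0` selects the exact Poisson limit.
* **Callers**: caller A detects each carried event with probability 0.97,
  jitters boundaries by ±2 windows and reports a median log fold change;
  caller B detects with probability 0.98 and splits each event into
  ~`Poisson(10)` contiguous fragments (≥ 1.5 kb each, covering ≥ ~90 %),
  with per-fragment q0 ~ Beta(1.5, 15) and log-uniform p-values; 4 % of
  fragments draw failing statistics so the filter stage does real work.
  10 % of caller-B event calls carry a flipped loss/gain label (the
  fine-window caller is the one with a known gain deficiency), feeding the
  arbitration path. False events are planted at 0.3/Mb per sample away
  from true regions; half are emitted by *both* callers — shared artifacts
  that survive consensus and can only be removed by depth validation.
* **Quality statistics carry a selection-effect shift** (0.35 in log2
  units) away from the filter boundary: callers emit a call when their
  internal evidence is strong, so the reported statistic for a true event
  is biased beyond the naive `log2(cn/2)`. Without this, a heterozygous
  deletion would sit exactly on the strict `< −1` threshold and the filter
  would reject half of all true het-deletion calls — contradicting the
  filter's role as a false-positive screen.

What passing on this cohort does **not** show: robustness to GC bias,
mappability structure, reference errors, breakpoint microhomology or
caller-specific systematic artifacts — none of which are simulated. The
synthetic genome is small and CNV-dense (regions cover ~17 % of it versus
a fraction of a percent of a real genome), so genome-fraction statistics
from synthetic runs characterise the arithmetic, not real cohorts.

## Problem sizes and determinism

Default end-to-end runs use the 36-sample / 150-region / 100 Mb cohort
(seconds to a few minutes on one CPU); bootstrap support in scripted runs
uses B = 1,000 over the full 10-scale grid. All randomness flows from
explicit seeds (`numpy.random.default_rng` with spawned child streams per
stage); reruns with the same seed are byte-identical, including file
outputs.

## Known limitations

* Arbitration thresholds are declared replacements for human judgement,
  not values recovered from the original annotators.
* The flank span (50 kb per side) follows the published description read
  as "per side"; a total-span reading would halve it (configurable).
* Bootstrap cluster recovery counts rooted leafsets (as the reference
  clustering tool does), not unrooted bipartitions.
* Depth must arrive as windowed bedGraph; computing depth from BAM/CRAM is
  out of scope.
* The breed-private percentage column reproduces the consistent published
  entries; some published entries are internally inconsistent with the
  stated breed sizes and are not targeted.
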