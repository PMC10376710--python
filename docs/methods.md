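# Methods

This note documents the models and numerical conventions behind
`spacetrend`, the defaults that matter, and what the synthetic benchmarks
do and do not demonstrate.

## The mission grid and preprocessing

All analyses operate on an 8-bin deidentified grid labeled by days relative
to launch: −180, −45 (pre-flight), 33, 82, 132 (in-flight), 165 (return),
195, 225 (post-return).  Bin edges are midpoints between adjacent labels,
extended to a study window of [−200, 240) days; a raw observation is
assigned to the bin whose half-open interval contains its day, and multiple
observations in one bin (repeat assays included) are averaged.

Each binned series is differenced against the −45 d baseline bin and scaled
to unit Euclidean norm over its present bins.  No imputation is performed:
a missing bin stays missing all the way through the spectral stage, which
tolerates gaps by construction.  Series are dropped (with a logged reason)
when the baseline bin is missing or fewer than `min_bins` (default 5 of 8)
bins are present; this threshold is a package default, chosen so that at
least one lag beyond the shortest is identifiable, not an empirical
constant from any dataset.  Series equal to their baseline at every present
bin have zero norm; they are flagged degenerate and excluded from
classification rather than divided by zero.

## Spectral classification

**Periodogram.**  The classical (tau-shifted) Lomb-Scargle periodogram is
computed after removing the sample mean of the present values.  This form
is algebraically identical to half the explained sum of squares of a
per-frequency least-squares sinusoid fit, which the test suite uses as an
independent oracle.  At a frequency where the sine basis norm vanishes
(possible at the Nyquist frequency of a complete grid), the degenerate term
is dropped; the least-squares equivalence is preserved.

**Time axis.**  The spectral stage treats the grid ordinally: bin i sits at
time i, so "lag 1" means one mission-phase step regardless of the uneven
day spacing of the bin labels.  Two reasons drive this choice.  First, with
ordinal times and the frequency grid f_k = k/(2N), k = 1..N, the inverse
cosine transform of the periodogram reproduces the direct lagged-product
autocorrelation of a complete series *exactly* (the zero-padded discrete
Wiener–Khinchin identity; verified to machine precision in the tests), so
the autocorrelations have an unambiguous meaning.  Second, on the physical
day axis the long pre-flight gap spreads a simple in-flight step across
incommensurate delays, leaving its lag-1 autocorrelation (≈ 0.08) far below
any usable threshold — the trend classes would be essentially blind to the
very shapes they are meant to catch.  Day labels still drive binning, the
visibility-graph geometry and the reporting phases.

**Autocorrelations.**  ρ_l = Σ_k P(f_k) cos(2π f_k l) / Σ_k P(f_k) for
l ∈ {0, …, N/2}.  By construction ρ₀ = 1 and |ρ_l| ≤ 1 (each ρ_l is a
convex combination of cosines).

**Bootstrap null.**  For each subject, null series are generated by
resampling the subject's pooled present normalized values i.i.d. with
replacement onto the full grid (default 10⁵ series).  Per-lag 0.95
quantiles of the null autocorrelations give the lag thresholds; the 0.95
quantile of per-series maxima and the 0.05 quantile of per-series minima
give the spike bounds (the minima test is lower-tailed so that a
sub-threshold minimum is a rare event under the null).  Pooling across the
subject's whole panel reads the resampling unit as "the subject"; per-
measurement pooling would put each series' own extremes into its null and
blind the spike tests.

**Classification.**  Lag M is assigned with M the smallest lag whose ρ_l
meets or exceeds its threshold (ties count as exceedance).  Only series
failing every lag are tested for spikes, against the normalized-scale
bounds: max Q strictly above the maxima quantile gives SpikeMax, min Q
strictly below the minima quantile gives SpikeMin; otherwise the series has
no trend.  Every series receives exactly one label.

**Empirical p-values and the FDR gate.**  Each series carries the empirical
tail probability of its *deciding* statistic — ρ at the deciding lag M, or
the spike extremum — computed with the add-one rule (1 + #{null ≥ obs}) /
(n_boot + 1).  A classed series therefore always has p < 1 − level.
Benjamini–Hochberg across each subject's measurements (default α = 0.05)
gates what downstream stages count as significant.  A power caveat at
N = 8: a noise-free persisting step attains ρ₁ ≈ 0.46 while the i.i.d.
null's lag-1 distribution reaches that value with probability ≈ 0.02, so
empirical p-values are floored near 0.01 and the BH staircase at α = 0.05
rarely fires unless trends are both strong and numerous in the panel.  The
classification rule itself (the quantile test) is the primary detector;
the gate is a conservative overlay, and the worked examples run it at
α = 0.25 to populate the cohort tables at desk scale.

## Group/subgroup clustering

Within one subject and class, agglomerative (average-linkage) clustering is
applied twice: groups G on autocorrelation vectors with 1 − Pearson r
dissimilarity, subgroups S on the normalized series with Euclidean
dissimilarity (correlation is available as an option).  Cluster counts
maximize the mean silhouette over k = 2..min(n − 1, 8), ties going to the
smaller k; sets with n < 3, or whose members are mutually identical, form a
single cluster.  Zero-variance vectors compare as identical when equal and
maximally distant otherwise.

## Visibility summaries

The per-(G, S) median signal (missing-aware median across members) is
turned into a natural visibility graph on its present bins: i and j connect
iff the chord between them passes strictly above every intermediate point,
evaluated on the bin-label day axis.  Strictness makes a constant series a
path graph and a strictly convex series a complete graph; adjacent bins are
always connected, so the graph is connected.

Temporal communities are delimited by the fewest-hops shortest path from
the first to the last bin, ties broken by the lexicographically smallest
vertex sequence.  Walking forward in time, an interior path vertex opens a
new community when it shares strictly more edges with the vertices ahead of
it (up to the next path vertex) than with the community behind it; on a tie
it stays with the earlier community.  These tie rules make the output
deterministic but deliberately time-asymmetric: a monotone step splits
cleanly walking down but ties (and therefore merges) walking up.  The
partition is always contiguous in time and covers every vertex once.

## Cohort network

Per measurement, subjects' periodograms (shared frequency grid) are
compared by Euclidean distance; pairs lacking the measurement are skipped
for that matrix.  The similarity radius d_q is the 0.99 quantile of
distances among periodograms of 50,000 bootstrap signals drawn from the
cohort's pooled normalized values; the null distance distribution is
estimated from 10⁶ seeded random pairs of those signals rather than all
~1.25 × 10⁹ — the same distribution at linear cost.  Each distance matrix
is binarized strictly below d_q and the binary matrices sum to the weighted
adjacency; subjects sharing no measurement with anyone remain isolated
nodes rather than being dropped.

The 0.99 level is deliberately permissive — it excludes only the 1% most
dissimilar null pairs — and on small, strongly blocked synthetic cohorts it
saturates the graph (every pair is "similar" on nearly every measurement).
The level is therefore a configuration knob; the planted-block recovery
benchmark runs at level 0.25, where the noise-free two-block cohort is
recovered with adjusted Rand index 1.

**Embedding and consensus.**  The adjacency (plus a small uniform
regularizer, `reg × mean(A)` on every entry) is normalized by the square
roots of its row and column degrees and decomposed by SVD; the leading
`dim = 2` left singular vectors, scaled by their singular values and the
inverse degree square roots, give the node coordinates.  k-means on this
embedding is repeated (default 1,000 runs) with fresh initializations,
re-selecting k by silhouette each run in `auto` mode or holding it fixed
(e.g. k = 5) in `fixed` mode.  Runs are aligned to a reference partition
derived from the co-association matrix (average-linkage at the consensus
k) via the Hungarian method, and each node takes its highest-frequency
aligned label.  The embedding is deterministic; all run-to-run variation
comes from the seeded k-means initializations.

## Cohort trend tables

Per measurement, subjects whose series is classed and passes the FDR gate
are counted.  Each such subject's direction triple codes the mean of the
normalized series over the Flight bins (33/82/132 d), the Return bin
(165 d) and the Post-return bins (195/225 d): ↑ above +ε, ↓ below −ε, −
inside the deadband, with ε = 0.1 on the normalized scale (unit-norm series
make a fixed deadband comparable across measurements).  The cohort trend is
the majority triple; a different triple shared by ≥ 25% of the significant
subjects is reported as secondary.  Rows sort by subject count descending,
ties by measurement id.

## The synthetic cohort generator

The generator emulates the structure of a long-duration mission biomarker
panel: by default 27 subjects × 264 measurement annotations, visits every
~15 days with ±4 days of jitter across −180..+225 d, 10% visit dropout,
additive i.i.d. Gaussian noise per raw observation, and a constant baseline
level per measurement.  Planted archetypes displace the baseline at
bin resolution: persisting rise (all six post-launch bins), reverting rise
(in-flight bins only), landing spike/dip (the 165 d bin), or flat.
Subjects are split into contiguous blocks that share archetype
assignments, so cross-subject communities are recoverable by construction,
and every planted (subject, measurement) pair carries its expected trend
family as ground truth.

What the generator does *not* emulate: assay-specific error structures,
heteroscedasticity, between-subject amplitude variation, correlated
measurements, or clinical-event covariates.  Passing benchmarks therefore
demonstrate that the pipeline recovers its own planted structure under
idealized noise, not that it would achieve the same operating
characteristics on archival mission data.

**Benchmark conditions** (frozen after calibration simulations, as the
package's own operating points): archetype amplitude/noise ratio 8 for
recovery tests (the lag classifier reaches ≈ 0.93 sensitivity there, vs
≈ 0.74 at ratio 5); spikes planted sparsely (2 in a 50-measurement panel)
because denser spikes contaminate the subject's bootstrap pool and push the
spike quantile up to the spike's own value, which the strict inequality
then never exceeds; block-recovery at radius level 0.25 as above.

## Numerical conventions and edge cases

* Bootstrap p-values use the add-one rule, so p ∈ (0, 1] always.
* Lag thresholds use ≥ (a tie is an exceedance); spike and radius
  comparisons are strict, as are the visibility inequalities.
* All randomness flows from explicit integer seeds; per-subject and
  per-stage seeds are derived from the run seed through SeedSequence, so a
  pipeline run is byte-reproducible.
* Series with fewer than 3 present bins cannot enter the spectral stage;
  the preprocessing filter (default min 5 bins) removes them earlier.
* A silhouette selection over an all-identical set, or over fewer than 3
  members, is bypassed (single cluster).
* Consensus clustering rejects k larger than the node count; duplicate
  embedding coordinates may yield fewer distinct clusters than requested,
  which the co-association consensus absorbs.

## Known limitations

* With 8 timepoints the spectral tests have limited power, and the FDR
  gate at α = 0.05 is close to inoperative on single measurements (see
  above); cohort-level counts are the more robust summary.
* The visibility community tie rules are time-asymmetric by design.
* The 0.99 similarity radius saturates small synthetic cohorts; choosing
  the level for a given cohort size remains the analyst's decision.
* Creatinine (or other) normalization of urine analytes is assumed to have
  happened upstream; measurement ids arrive already normalized.
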