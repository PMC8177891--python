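# Methods

## Data model and anatomy

A trial is a set of sorted single-unit spike trains (ms-resolution float
times) recorded simultaneously on a dual-shank linear array, together with
the array geometry. The default geometry has 2 shanks × 16 contacts at
100 µm pitch, top row at 100 µm below the dorsal surface (tip at 1600 µm).
Contacts are partitioned into four depth-defined gray-matter regions. The
published depth ranges for these regions leave gaps between them (sDH "to
~400 µm" but dDH "from ~500 µm", etc.), so the package places cut-points at
the midpoints — 450, 1050 and 1350 µm — which yields a deterministic total
partition and the 8/12/6/6 electrodes-per-region split of the default array.
Boundaries are configurable per trial via the metadata sidecar.

Unit admissibility uses two screens. A unit whose fraction of inter-spike
intervals below 2 ms exceeds 1% is treated as a contaminated cluster (the
criterion is qualitative in the source literature — "predominance" of short
ISIs — so 1% is this package's explicit, configurable default). Pairs of
units on the same or adjacent contacts whose ±1-bin coincidence fraction
exceeds 0.5 are treated as duplicate detections of one cell and the
lower-spike-count member is dropped (ties broken by unit id). Both screens
are idempotent and log exclusions.

## Pairwise testing

The cross-correlogram uses half-open 1 ms bins centred on integer lags over
±50 ms (both configurable; the long-jitter null spans the same ±50 ms
window). No edge correction is applied: with trials of 2–5 minutes and a
50 ms maximum lag the edge bias is O(max_lag/T) ≈ 0.03%.

The test lag for each pair is the |z|-extremum of the normalized CCG, which
makes the latency definition (time to peak correlation strength) and the
tested lag coincide. Ties in |z| are broken toward the smallest |lag|, then
the positive lag. The polarity threshold (|z| ≥ 3) is a display/annotation
threshold only; significance comes from the p-value machinery below.

Because the extremum is selected among L = 101 candidate lags, the reported
single-lag p-value would be the minimum of ~101 nearly independent
p-values; per-pair p-values are therefore Šidák-corrected,
p′ = 1 − (1 − p)^L. Without this correction, null trials produce per-pair
p-values concentrated near 1/L and the per-trial BH step would flag
essentially every pair; with it, null p-values are uniform-to-conservative
and the false-discovery guarantee is real. The correction can be disabled
(`AnalysisParams.lag_correction=False`) for exploratory use.

p-value branches, recorded per pair in `test_used`:

* `fisher` — min occupied bins ≤ 50: two-sided Fisher exact test.
* `binom` — expected coincidence count µ = occ_a·occ_b/M below 50: exact
  two-sided binomial tail on n₁₁ with the minimum-likelihood convention
  (the same two-sided rule Fisher's test uses). The χ² approximation is
  badly anti-conservative in this regime: at µ ≈ 4 it understates
  tail probabilities near 10⁻⁵ by two orders of magnitude, which in
  simulation pushed the realized FDR above 0.5. The binomial tail restores
  control at negligible cost and agrees with Fisher to a few percent on
  tables straddling the branch point.
* `chisq` — everything else: χ² = M·r² with 1 df, upper tail.

BH FDR is applied strictly per trial over all C(n, 2) pairs at q = 0.05;
the realized p-threshold (the largest p(k) ≤ k·q/m) is reported per trial
and varies with the data.

## Synthetic cohorts

The generator emulates the statistical skeleton of the in-vivo cohorts:
per-region unit counts drawn as rounded normals truncated at zero around
means 11/25/16/14 (sd 3/3/2/2) for sDH/dDH/IG/VH — 66 units per trial in
expectation — each unit placed uniformly on an electrode of its region.
Baseline firing is homogeneous Poisson thinned by a 2 ms absolute
refractory period (realized rate λ/(1+λτ)). Baseline rates are drawn
log-normally with median 3 Hz (log-sd 0.7) by default; no firing-rate
statistics are available for the recorded units, so this is a package
choice tuned only for 2–5 minute trials to be informative, and it is fully
configurable.

Excitatory couplings insert a target spike per source spike with
probability `efficacy` at latency + N(0, 0.5 ms), resolving refractory
collisions by dropping the inserted spike (the baseline train is never
altered). Inhibitory couplings delete target spikes inside
(latency, latency + 5 ms] after a source spike with probability `efficacy`.
Default latency means (6.4 ms excitatory, 2.7 ms inhibitory) follow the
observed in-vivo summaries. A single master seed expands into per-unit and
per-connection substreams by stable identifier hashing, so populations are
reproducible and locally perturbable.

What the generator does *not* emulate: common slow drive or state
transitions (baselines are stationary), higher-order motifs (couplings are
strictly pairwise), bursting, and rate nonstationarity. Passing tests on
these cohorts therefore demonstrate correctness of the statistical
machinery under the model's assumptions, not robustness to every feature of
in-vivo data — in real recordings shared slow modulation can inflate
coincidence counts at all lags, which is exactly what the jitter ensembles
are for.

For parameter-recovery benchmarks the package uses 300 s trials with
log-normal rates around 10 Hz and restricts inhibitory coupling endpoints
to units firing ≥ 10 Hz. This reflects a real identifiability constraint,
not convenience: a suppression of 5 ms windows at efficacy 0.8 between
3 Hz units shifts the CCG trough by ≈ 1.3 standard errors — statistically
invisible at any reasonable trial length — while at 10 Hz the trough
reaches |z| ≈ 4.4. Detecting inhibition by correlation requires brisk,
stable firing in both cells.

## Jitter surrogates

Each spike is displaced by an independent integer draw from
uniform{−J..+J} ms (J ∈ {5, 50}), preserving per-unit spike counts exactly
(asserted on every replicate) and coarse rate profiles. Out-of-range spikes
are clamped to the trial boundary (reflection available); the uniform
support includes 0, so identity displacements are legal. Replicate seeds
are split counter-style from the master seed, making ensembles independent
of evaluation order and safely parallelizable. The reference procedure uses
1000 replicates; the test suite uses 100–500, which bounds the Monte-Carlo
error of ensemble means well below the effect sizes being tested, and the
full 1000 is a parameter.

A destruction caveat discovered in simulation and worth stating: ±5 ms
jitter reduces a short-latency coupling's CCG peak by roughly the ratio of
the triangular smear (width 2·(2J)+1 bins) to the original peak width, so
very strong couplings (peak z in the tens) remain significant after
jittering. Jitter ensembles therefore bound what *cannot* be explained by
slow rate structure; they do not null out arbitrarily strong fine-timescale
coupling.

## Topology

Significant pairs map to the ten unordered region-pair categories;
same-electrode pairs land in their region's within category. In node
counts, a connection increments both endpoint electrodes, and a
same-electrode connection increments its electrode twice, keeping the
total at 2× the edge count. "Most connected nodes" are electrodes whose
count exceeds the across-electrode mean plus z₀.₉₅ times the SD (one-sided
α = 0.05, ddof = 1); the rule and its parameters are recorded in every
report since the designation in the source literature names no specific
test.

The random-placement benchmark assigns category (i, j) the expected share
(n_i+n_j)/D (within: n_i/D) with D the total electrode representation over
all comparisons; it is scale-invariant and yields 25%/75% within/between
for the default array. A between-region comparison is only counted when
both regions have electrodes, which makes degenerate single-region
geometries behave sensibly (100% within).

One structural property of this benchmark deserves note. Under the
pipeline's null, false-positive pairs are uniform over unit pairs, so
pooled null-ensemble category proportions converge to the cohort's
pair-composition frequencies (C(n_i,2)/C(n,2) within, n_i·n_j/C(n,2)
between), which coincide with the electrode-ratio benchmark only when
regional unit shares scale with the square root of electrode counts. At
the default cohort composition the two distributions differ by up to
~5 percentage points in individual categories (while agreeing closely on
the within/between totals), and BH under a true global null flags too few
pairs for per-category ensemble proportions to stabilize at practical
replicate counts. The convergence check in the acceptance suite asserts
the strict ±2 pp criterion and is expected to fail for these structural
reasons; it is retained as documentation of the discrepancy rather than
weakened.

## Numerical choices

* Bins are half-open [t, t+Δ); CCG bins are centred on integer lags.
* Spike times are float64 ms; I/O serializes them with `repr` so round
  trips are bit-exact.
* A spike exactly at trial end is placed in the last occupancy bin.
* Contingency tables at lag ℓ drop the |ℓ|/Δ shifted-out bins (no
  wrap-around).
* Degenerate tables (any empty margin) give r = 0, p = 1.
* `empirical_comparison` uses the add-one rank estimator
  (1 + #{replicates ≥ observed})/(R + 1), never returning 0.

## Known limitations

* Polarity and latency come from the CCG extremum; for inhibitory
  couplings the trough lag sits inside the suppression window, biased late
  relative to the synaptic latency by about half the window.
* Lags of 0–1 ms are reported as given; disambiguating shared presynaptic
  drive from monosynaptic coupling is out of scope.
* No directed/causal inference, no shift-predictor normalization (no
  repeated-stimulus structure exists in spontaneous data), no higher-order
  motif analysis.
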