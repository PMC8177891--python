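# spinefc

Functional-connectivity analysis for populations of spinal interneurons
recorded with dual-shank multielectrode arrays. Given sorted single-unit
spike trains from one recording trial, `spinefc` decides which unit pairs
exhibit statistically significant temporal synchrony, extracts the latency
and putative polarity (excitatory/inhibitory) of each connection, benchmarks
the observed connectivity against jitter-surrogate null ensembles, and maps
significant connections onto the array geometry and the depth-defined
regions of the spinal gray matter (superficial dorsal horn `sDH`, deep
dorsal horn `dDH`, intermediate gray `IG`, ventral horn `VH`).

It is written for electrophysiologists analyzing spontaneous (resting-state)
activity, where no stimulus structure exists to build shift predictors from,
and ships a synthetic cohort generator with known ground-truth couplings so
the whole pipeline is testable without recordings.

## The method

For every unordered pair of admissible units *(a, b)* in a trial:

1. **Cross-correlogram.** Spike-time differences *t_b − t_a* are binned at
   1 ms over ±50 ms. Under independence the expected count per bin is
   *n_a·n_b·Δ/T*; the normalized correlogram is
   *z(k) = (c(k) − e)/√e*. The |z|-extremum lag is the connection latency
   (time to peak correlation strength); *z ≥ +3* calls the pair putatively
   excitatory, *z ≤ −3* inhibitory.
2. **Correlation strength.** Trains are binarized into 1 ms occupancy bins
   and, at the extremum lag, summarized by the phi coefficient
   *r = (n₁₁n₀₀ − n₁₀n₀₁)/√((n₁₁+n₁₀)(n₀₁+n₀₀)(n₁₁+n₀₁)(n₁₀+n₀₀))* — the
   Pearson correlation of the two binary sequences.
3. **Significance.** Sparse trains (≤ 50 occupied bins) get a two-sided
   Fisher exact test; well-populated tables get *χ² = M·r²* with 1 df; in
   between, an exact binomial tail on the coincidence count keeps deep-tail
   p-values honest. The p-value is Šidák-corrected for the selection of the
   test lag among the 101 candidates, and the Benjamini–Hochberg step-up at
   *q = 0.05* is applied per trial over all *C(n, 2)* pairs; the realized
   p-threshold is data dependent and reported per trial.
4. **Null ensembles.** Every spike of every unit is jittered by an integer
   draw from uniform{−J..+J} ms (J = 5 or 50), preserving spike counts
   exactly; the full battery is re-run on ≥ 100 such replicates and the
   observed significant-pair proportion is ranked within the ensemble.
5. **Topology.** Significant pairs are tallied into the ten region-pair
   categories (sDH-sDH … VH-VH) and compared with a closed-form
   random-placement model: with *n_i* electrodes per region, category
   *(i, j)* is expected to hold *(n_i+n_j)/D* of connections (within-region:
   *n_i/D*), *D = Σ n_i + Σ_{i<j}(n_i+n_j)* = 128 for the default
   8/12/6/6 array. Per-electrode connection counts yield the trial's "most
   connected nodes" (counts above mean + z₀.₉₅·SD across electrodes).

## Worked example

`examples/01_simulate_and_detect.py` simulates a ~60-unit, 300 s trial with
5 excitatory (6 ms latency, efficacy 0.5) and 3 inhibitory (2 ms latency,
5 ms suppression window) couplings, then runs the full battery:

```
59 units -> 1711 pairs -> 8 significant (realized p-threshold 5.97e-06)

detected ground-truth couplings:
    IG_005 - dDH_003  called inhibitory latency 4 ms (truth: inhibitory, 2 ms)  peak z -5.1
    IG_005 - dDH_005  called excitatory latency 6 ms (truth: excitatory, 6 ms)  peak z +141.7
    IG_007 - VH_000   called excitatory latency 6 ms (truth: excitatory, 6 ms)  peak z +140.4
   dDH_002 - dDH_005  called inhibitory latency 3 ms (truth: inhibitory, 2 ms)  peak z -6.0
   dDH_003 - dDH_015  called inhibitory latency 3 ms (truth: inhibitory, 2 ms)  peak z -6.0
   dDH_012 - dDH_018  called excitatory latency 6 ms (truth: excitatory, 6 ms)  peak z +136.7
   dDH_013 - dDH_019  called excitatory latency 6 ms (truth: excitatory, 6 ms)  peak z +156.4
   dDH_015 - dDH_021  called excitatory latency 6 ms (truth: excitatory, 6 ms)  peak z +148.1

8/8 embedded couplings recovered; the remaining 0 significant pairs are
secondary correlations (shared endpoints) or residual false positives at q = 0.05.
```

Every embedded coupling is recovered with the right polarity; excitatory
latencies land on the embedded 6 ms, while inhibitory latencies fall inside
the suppression window (the trough lag, not the synaptic delay itself).
`examples/02_jitter_null_benchmark.py` shows the jitter null (observed
proportion 0.0184 vs ensemble mean 0.0046, exceedance p = 0.020) and
`examples/03_topology_benchmark.py` prints the random-placement table above.

A thin CLI wraps the same calls: `spinefc simulate`, `spinefc analyze`,
`spinefc null` (see `--help`).

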