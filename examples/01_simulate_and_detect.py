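"""Simulate a cohort trial with known couplings and recover them.

Builds a ~66-unit synthetic trial (regional means 11/25/16/14 across
sDH/dDH/IG/VH), embeds 5 excitatory couplings at 6 ms and 3 inhibitory
couplings at 2 ms, runs the full pairwise battery with per-trial BH FDR,
and prints what was detected against the ground truth.
"""

import numpy as np

import spinefc as sfc

params = sfc.CohortParams(
    duration_s=300.0,
    rate_distribution=sfc.RateDistribution(
        "lognormal", log_mean=float(np.log(10.0)), log_sd=0.25))
spec = sfc.ConnectionSpec(
    n_excitatory=5, excitatory_latency_ms=6.0, excitatory_efficacy=0.5,
    n_inhibitory=3, inhibitory_latency_ms=2.0, inhibitory_efficacy=0.8,
    suppression_window_ms=5.0, inhibitory_min_rate_hz=10.0)

trial, truth = sfc.simulate_trial(params, spec, seed=42)
analysis = sfc.analyze_trial(trial)

log = analysis.stage_log
print(f"{log['units_in']} units -> {log['pairs_tested']} pairs -> "
      f"{log['significant_pairs']} significant "
      f"(realized p-threshold {log['realized_p_threshold']:.3g})")

truth_by_pair = {c.pair: c for c in truth}
print("\ndetected ground-truth couplings:")
for res in analysis.significant:
    conn = truth_by_pair.get(frozenset((res.unit_a, res.unit_b)))
    if conn:
        print(f"  {res.unit_a:>8} - {res.unit_b:<8} called {res.polarity:<10} "
              f"latency {res.latency_ms:.0f} ms (truth: {conn.polarity}, "
              f"{conn.latency_ms:.0f} ms)  peak z {res.peak_z:+.1f}")
n_true = sum(1 for r in analysis.significant
             if frozenset((r.unit_a, r.unit_b)) in truth_by_pair)
print(f"\n{n_true}/{len(truth)} embedded couplings recovered; the remaining "
      f"{log['significant_pairs'] - n_true} significant pairs are secondary "
      "correlations (shared endpoints) or residual false positives at q = 0.05.")
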