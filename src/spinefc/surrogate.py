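"""Jitter-surrogate null ensembles.

A surrogate trial is built by displacing every spike of every unit
independently by an integer draw from uniform{-J, ..., +J} ms (1-ms
granularity, draws with replacement; J is 5 ms for short-latency nulls and
50 ms for long-latency nulls). Jittering preserves each unit's spike count
exactly and its rate at coarse timescales while destroying temporal
alignment finer than ~J. Re-running the full pairwise battery on many
jittered replicates yields the null distribution of any connectivity summary,
against which the observed value is ranked.

Spikes displaced beyond the trial are clamped to the boundary by default
(reflection available as a flag). Replicate seeds are split counter-style
from the master seed, so results do not depend on evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import REGION_PAIR_CATEGORIES
from .model import SpikeTrain, Trial
from .stats import AnalysisParams, bh_fdr, test_all_pairs

_CAT_INDEX = {c: i for i, c in enumerate(REGION_PAIR_CATEGORIES)}


def jitter_spike_train(train: SpikeTrain, J_ms: int, duration_s: float,
                       rng: np.random.Generator | int,
                       mode: str = "clamp") -> SpikeTrain:
    """Jitter every spike by an independent integer draw from U{-J..+J} ms.

    Spike count is always preserved; out-of-range spikes are clamped to
    [0, duration] (``mode="clamp"``) or reflected at the boundaries
    (``mode="reflect"``).
    """
    J = int(J_ms)
    if not (0 <= J <= 50):
        raise ValueError("J_ms must be an integer in 0..50")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    times = train.times
    if J == 0 or times.size == 0:
        return SpikeTrain(train.unit, times)
    disp = rng.integers(-J, J + 1, size=times.size).astype(np.float64)
    out = times + disp
    duration_ms = duration_s * 1000.0
    if mode == "clamp":
        np.clip(out, 0.0, duration_ms, out=out)
    elif mode == "reflect":
        out = np.abs(out)
        over = out > duration_ms
        out[over] = 2 * duration_ms - out[over]
    else:
        raise ValueError(f"unknown boundary mode {mode!r}")
    out.sort()
    return SpikeTrain(train.unit, out, copy=False)


def jitter_trial(trial: Trial, J_ms: int, rng: np.random.Generator,
                 mode: str = "clamp") -> Trial:
    """Jitter every train of a trial (trains processed in unit-id order)."""
    jittered = [jitter_spike_train(tr, J_ms, trial.duration_s, rng, mode)
                for tr in trial.trains]
    return trial.with_trains(jittered)


@dataclass
class NullEnsemble:
    """Connectivity summaries over jittered surrogate replicates."""

    jitter_halfwidth_ms: int
    n_replicates: int
    n_pairs: int
    seed: int
    fdr_q: float
    significant_counts: np.ndarray          # (n_replicates,) int
    category_counts: np.ndarray             # (n_replicates, 10) int
    mode: str = "clamp"

    @property
    def significant_proportions(self) -> np.ndarray:
        if self.n_pairs == 0:
            return np.zeros(self.n_replicates)
        return self.significant_counts / self.n_pairs

    @property
    def mean_significant_proportion(self) -> float:
        return float(self.significant_proportions.mean())

    def pooled_category_proportions(self) -> dict[str, float]:
        """Category proportions (%) of significant pairs pooled over replicates."""
        totals = self.category_counts.sum(axis=0)
        grand = totals.sum()
        if grand == 0:
            return {c: 0.0 for c in REGION_PAIR_CATEGORIES}
        return {c: 100.0 * totals[i] / grand
                for i, c in enumerate(REGION_PAIR_CATEGORIES)}

    def to_frame(self) -> pd.DataFrame:
        """One row per replicate: significant proportion plus category counts."""
        df = pd.DataFrame({
            "replicate": np.arange(self.n_replicates),
            "J_ms": self.jitter_halfwidth_ms,
            "significant_proportion": self.significant_proportions,
        })
        for i, c in enumerate(REGION_PAIR_CATEGORIES):
            df[c] = self.category_counts[:, i]
        return df


def build_null_ensemble(trial: Trial, J_ms: int, n_replicates: int,
                        params: AnalysisParams = AnalysisParams(),
                        seed: int = 0, mode: str = "clamp") -> NullEnsemble:
    """Jitter, re-analyze and summarize ``n_replicates`` surrogate trials.

    Each replicate re-runs the identical pairwise battery plus per-trial BH
    FDR on a freshly jittered copy of the trial. Per-unit spike counts are
    asserted unchanged on every replicate. Deterministic given ``seed``;
    replicate r uses the child seed (seed, r) regardless of execution order.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    n = trial.n_units
    n_pairs = n * (n - 1) // 2
    sig_counts = np.zeros(n_replicates, dtype=np.int64)
    cat_counts = np.zeros((n_replicates, len(REGION_PAIR_CATEGORIES)),
                          dtype=np.int64)
    pre_counts = [tr.n_spikes for tr in trial.trains]
    for rep in range(n_replicates):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed) & 0x7FFFFFFF, rep, int(J_ms)]))
        surrogate = jitter_trial(trial, J_ms, rng, mode)
        post_counts = [tr.n_spikes for tr in surrogate.trains]
        assert post_counts == pre_counts, "jitter must preserve spike counts"
        results = test_all_pairs(surrogate, params)
        results, _ = bh_fdr(results, params.fdr_q)
        for res in results:
            if res.significant:
                sig_counts[rep] += 1
                cat_counts[rep, _CAT_INDEX[res.pair_category]] += 1
    return NullEnsemble(
        jitter_halfwidth_ms=int(J_ms), n_replicates=n_replicates,
        n_pairs=n_pairs, seed=int(seed), fdr_q=params.fdr_q,
        significant_counts=sig_counts, category_counts=cat_counts, mode=mode)


def empirical_comparison(observed: float, ensemble) -> tuple[float, float]:
    """Rank an observed summary within a null ensemble.

    Returns ``(percentile, exceedance_p)`` where percentile is the share of
    replicates strictly below the observed value (in percent) and
    exceedance_p = (1 + #{replicates >= observed}) / (n_replicates + 1).
    """
    values = np.asarray(
        ensemble.significant_proportions if isinstance(ensemble, NullEnsemble)
        else ensemble, dtype=float)
    if values.size == 0:
        raise ValueError("ensemble is empty")
    percentile = 100.0 * float(np.mean(values < observed))
    exceedance_p = (1.0 + int(np.sum(values >= observed))) / (values.size + 1.0)
    return percentile, exceedance_p
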