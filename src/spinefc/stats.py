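"""Pairwise correlation strength, p-values and per-trial FDR control.

Spike trains are binarized into 1-ms occupancy bins. For a pair (a, b) tested
at lag L, the 2x2 contingency table counts bins where both fire, only a, only
b, or neither, with b shifted back by L bins (bins shifted out of range are
dropped, not wrapped). Correlation strength is the phi coefficient

    r = (n11*n00 - n10*n01) / sqrt((n11+n10)(n01+n00)(n11+n01)(n10+n00)),

the Pearson product-moment correlation of the two binary vectors. Each pair's
test lag is the |z|-extremum lag of its normalized cross-correlogram, which
matches the time-to-peak latency definition.

Three p-value branches, recorded per pair:

* ``fisher`` — two-sided Fisher exact test when either train occupies <= 50
  bins (sparse trains, exact by enumeration);
* ``binom``  — exact two-sided binomial tail on n11 when the expected
  coincidence count mu = occ_a*occ_b/M is below ~50. The chi-square
  approximation underestimates deep-tail p-values by orders of magnitude in
  this regime (Poisson skew), which would destroy false-discovery control;
* ``chisq``  — chi2 = M*r^2 with 1 df (upper tail) for well-populated tables.

Because the test lag is selected as the extremum over ~2*max_lag/binwidth + 1
candidate lags, the per-pair p-value is Sidak-corrected for that selection
(p' = 1 - (1-p)^n_lags); without it, null pairs carry min-of-many p-values
and the per-trial Benjamini-Hochberg step would flag nearly everything.
BH FDR control is applied per trial over all C(n,2) pairs; the realized
p-threshold is data dependent and reported per trial.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .correlogram import (Correlogram, PolarityCall, call_polarity_latency,
                          compute_ccg, normalize_ccg)
from .geometry import pair_category_label
from .model import SpikeTrain, Trial

logger = logging.getLogger(__name__)

#: Occupied-bin count at or below which Fisher's exact test is used.
FISHER_MAX_N = 50
#: Expected-coincidence count below which the exact binomial tail replaces chi2.
EXACT_TAIL_MIN_EXPECTED = 50.0


@dataclass(frozen=True)
class ContingencyTable:
    """Joint bin-occupancy counts of a pair at the test lag."""

    n11: int
    n10: int
    n01: int
    n00: int

    @property
    def M(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def occupied_a(self) -> int:
        return self.n11 + self.n10

    @property
    def occupied_b(self) -> int:
        return self.n11 + self.n01


@dataclass(frozen=True)
class AnalysisParams:
    """Knobs of the pairwise connectivity test battery."""

    binwidth_ms: float = 1.0
    max_lag_ms: float = 50.0
    z_threshold: float = 3.0
    fdr_q: float = 0.05
    fisher_max_n: int = FISHER_MAX_N
    exact_tail_min_expected: float = EXACT_TAIL_MIN_EXPECTED
    lag_correction: bool = True

    @property
    def n_candidate_lags(self) -> int:
        return 2 * int(round(self.max_lag_ms / self.binwidth_ms)) + 1


@dataclass
class ConnectionResult:
    """Outcome of the pairwise test for one unordered unit pair."""

    unit_a: str
    unit_b: str
    electrode_a: int
    electrode_b: int
    region_a: str
    region_b: str
    pair_category: str
    r: float
    p: float
    test_used: str
    latency_ms: Optional[float]
    polarity: str
    peak_z: float
    test_lag_ms: float
    significant: bool = False
    q_level: Optional[float] = None


def binarize(train, binwidth_ms: float, duration_s: float) -> np.ndarray:
    """Binary occupancy sequence: bin b is 1 iff >= 1 spike in [b*dt, (b+1)*dt)."""
    if binwidth_ms <= 0:
        raise ValueError("binwidth_ms must be positive")
    times = train.times if isinstance(train, SpikeTrain) else np.asarray(train)
    n_bins = int(np.ceil(duration_s * 1000.0 / binwidth_ms))
    out = np.zeros(n_bins, dtype=bool)
    if times.size:
        idx = np.floor_divide(times, binwidth_ms).astype(np.int64)
        np.clip(idx, 0, n_bins - 1, out=idx)   # spike exactly at trial end
        out[idx] = True
    return out


def _table_at_lag(occ_a: np.ndarray, occ_b: np.ndarray,
                  lag_bins: int) -> ContingencyTable:
    m = occ_a.size
    if abs(lag_bins) >= m:
        raise ValueError("lag leaves no overlapping bins")
    if lag_bins >= 0:
        a = occ_a[:m - lag_bins]
        b = occ_b[lag_bins:]
    else:
        a = occ_a[-lag_bins:]
        b = occ_b[:m + lag_bins]
    n11 = int(np.count_nonzero(a & b))
    n1a = int(np.count_nonzero(a))
    n1b = int(np.count_nonzero(b))
    total = a.size
    return ContingencyTable(n11, n1a - n11, n1b - n11, total - n1a - n1b + n11)


def phi_from_table(table: ContingencyTable) -> float:
    """Phi coefficient; 0 when any margin is empty."""
    n11, n10, n01, n00 = table.n11, table.n10, table.n01, table.n00
    denom = (float(n11 + n10) * float(n01 + n00)
             * float(n11 + n01) * float(n10 + n00))
    if denom == 0:
        return 0.0
    return (float(n11) * n00 - float(n10) * n01) / np.sqrt(denom)


def phi_at_lag(train_a: SpikeTrain, train_b: SpikeTrain, lag_ms: float,
               binwidth_ms: float, duration_s: float,
               ) -> tuple[float, ContingencyTable]:
    """Phi coefficient of the binarized pair with b shifted by the test lag."""
    occ_a = binarize(train_a, binwidth_ms, duration_s)
    occ_b = binarize(train_b, binwidth_ms, duration_s)
    lag_bins = int(round(lag_ms / binwidth_ms))
    table = _table_at_lag(occ_a, occ_b, lag_bins)
    return phi_from_table(table), table


def p_value(table: ContingencyTable, r: float,
            fisher_max_n: int = FISHER_MAX_N,
            exact_tail_min_expected: float = EXACT_TAIL_MIN_EXPECTED,
            ) -> tuple[float, str]:
    """Two-sided p-value for one contingency table (single, fixed lag).

    Branches on the sparser train's occupied-bin count N: Fisher's exact test
    when N <= fisher_max_n, otherwise a large-N branch — chi2 = M*r^2 when the
    expected coincidence count is large enough for the chi-square tail to be
    trustworthy, and an exact binomial tail on n11 below that. Degenerate
    margins give p = 1.
    """
    occ_min = min(table.occupied_a, table.occupied_b)
    m = table.M
    if m == 0:
        return 1.0, "fisher"
    margins = (table.occupied_a, table.occupied_b,
               m - table.occupied_a, m - table.occupied_b)
    if 0 in margins:
        return 1.0, "fisher" if occ_min <= fisher_max_n else "chisq"
    if occ_min <= fisher_max_n:
        _, p = sps.fisher_exact(
            [[table.n11, table.n10], [table.n01, table.n00]],
            alternative="two-sided")
        return float(min(p, 1.0)), "fisher"
    mu = table.occupied_a * table.occupied_b / m
    if mu < exact_tail_min_expected:
        p_bin = table.occupied_a / m * table.occupied_b / m
        return _binom_two_sided(table.n11, m, p_bin), "binom"
    chi2 = m * r * r
    return float(sps.chi2.sf(chi2, df=1)), "chisq"


def _binom_two_sided(n11: int, m: int, p: float) -> float:
    """Two-sided exact binomial p with the minimum-likelihood convention.

    Sums P(X = k) over all k whose point probability does not exceed that of
    the observed count (the same two-sided rule Fisher's exact test uses),
    for X ~ Binomial(m, p). Exact for the coincidence count under fixed
    occupancy probabilities.
    """
    pmf_obs = float(sps.binom.pmf(n11, m, p))
    if pmf_obs == 0.0:
        # far in a tail: the opposite tail contributes nothing at this scale
        return float(min(1.0, sps.binom.sf(n11 - 1, m, p)
                         if n11 > m * p else sps.binom.cdf(n11, m, p)))
    mode = int(np.floor((m + 1) * p))
    tol = pmf_obs * (1.0 + 1e-7)
    if n11 == mode:
        return 1.0
    if n11 > mode:
        upper = float(sps.binom.sf(n11 - 1, m, p))
        ks = np.arange(0, mode + 1)
        pmf = sps.binom.pmf(ks, m, p)          # increasing on [0, mode]
        below = np.flatnonzero(pmf <= tol)
        lower = float(sps.binom.cdf(below[-1], m, p)) if below.size else 0.0
        return min(1.0, upper + lower)
    lower = float(sps.binom.cdf(n11, m, p))
    sd = max(1.0, np.sqrt(m * p * (1 - p)))
    hi = mode + int(20 * sd) + 20
    while True:                                # pmf decreasing beyond the mode
        ks = np.arange(mode, min(m, hi) + 1)
        pmf = sps.binom.pmf(ks, m, p)
        past = np.flatnonzero(pmf <= tol)
        if past.size:
            upper = float(sps.binom.sf(int(ks[past[0]]) - 1, m, p))
            break
        if hi >= m:
            upper = 0.0
            break
        hi *= 2
    return min(1.0, lower + upper)


def sidak_correct(p: float, n_tests: int) -> float:
    """1 - (1-p)^n, computed stably for tiny p."""
    if p >= 1.0:
        return 1.0
    return float(-np.expm1(n_tests * np.log1p(-p)))


def test_all_pairs(trial: Trial, params: AnalysisParams = AnalysisParams(),
                   ) -> list[ConnectionResult]:
    """Run the pairwise battery over all C(n,2) unordered pairs of a trial.

    Per pair: CCG -> normalization -> polarity/latency call at the |z|
    extremum -> phi and p-value at that lag (Sidak-corrected for lag
    selection when enabled). Deterministic: trains are processed in unit-id
    order. Fewer than two units yields an empty list with a warning.
    """
    trains = trial.trains
    if len(trains) < 2:
        warnings.warn(f"trial {trial.trial_id}: fewer than 2 units, no pairs to test")
        return []
    occ = [binarize(tr, params.binwidth_ms, trial.duration_s) for tr in trains]
    results: list[ConnectionResult] = []
    for i in range(len(trains)):
        for j in range(i + 1, len(trains)):
            results.append(_test_pair(trial, trains[i], trains[j],
                                      occ[i], occ[j], params))
    return results


test_all_pairs.__test__ = False  # not a pytest item when imported into tests


def _test_pair(trial: Trial, tr_a: SpikeTrain, tr_b: SpikeTrain,
               occ_a: np.ndarray, occ_b: np.ndarray,
               params: AnalysisParams) -> ConnectionResult:
    ccg = compute_ccg(tr_a, tr_b, params.binwidth_ms, params.max_lag_ms)
    normalize_ccg(ccg, trial.duration_s)
    call = call_polarity_latency(ccg, params.z_threshold)

    ua, ub = tr_a.unit, tr_b.unit
    base = dict(
        unit_a=ua.unit_id, unit_b=ub.unit_id,
        electrode_a=ua.electrode_id, electrode_b=ub.electrode_id,
        region_a=ua.region, region_b=ub.region,
        pair_category=pair_category_label(ua.region, ub.region),
    )
    if ccg.z is None:   # an empty train: nothing to test
        return ConnectionResult(**base, r=0.0, p=1.0, test_used="fisher",
                                latency_ms=None, polarity="none", peak_z=0.0,
                                test_lag_ms=0.0)
    lag_ms = call.peak_lag_ms
    lag_bins = int(round(lag_ms / params.binwidth_ms))
    table = _table_at_lag(occ_a, occ_b, lag_bins)
    r = phi_from_table(table)
    p, used = p_value(table, r, params.fisher_max_n,
                      params.exact_tail_min_expected)
    if params.lag_correction:
        p = sidak_correct(p, params.n_candidate_lags)
    return ConnectionResult(**base, r=r, p=p, test_used=used,
                            latency_ms=call.latency_ms, polarity=call.polarity,
                            peak_z=call.peak_z, test_lag_ms=lag_ms)


def bh_fdr(results: Sequence[ConnectionResult], q: float = 0.05,
           ) -> tuple[list[ConnectionResult], float]:
    """Benjamini-Hochberg step-up over one trial's p-values.

    Flags every pair with p at or below the realized threshold (the largest
    p(k) <= k*q/m); returns the flagged results and that threshold (0.0 when
    nothing is significant). Applied strictly per trial, never pooled.
    """
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    results = list(results)
    if not results:
        return results, 0.0
    p = np.array([res.p for res in results])
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    threshold = float(p[reject].max()) if reject.any() else 0.0
    for res, flag in zip(results, reject):
        res.significant = bool(flag)
        res.q_level = q
    return results, threshold


def results_to_frame(results: Sequence[ConnectionResult]) -> pd.DataFrame:
    """Tidy results table (one row per unordered pair)."""
    return pd.DataFrame([
        {
            "unit_a": r.unit_a, "unit_b": r.unit_b,
            "r": r.r, "p": r.p, "test_used": r.test_used,
            "significant": r.significant,
            "latency_ms": r.latency_ms, "polarity": r.polarity,
            "pair_category": r.pair_category,
            "peak_z": r.peak_z, "test_lag_ms": r.test_lag_ms,
            "electrode_a": r.electrode_a, "electrode_b": r.electrode_b,
        }
        for r in results
    ])
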