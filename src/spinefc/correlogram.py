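"""Cross-correlograms (CCGs) and polarity/latency extraction.

For an unordered unit pair (a, b), the CCG histograms all ordered spike-time
differences t_b - t_a into half-open 1-ms bins centred on integer lags over
[-max_lag, +max_lag]. Under independent stationary firing the expected count
per bin is n_a * n_b * binwidth / duration; the normalized correlogram is the
Poisson standardization z = (count - expected) / sqrt(expected).

A CCG peak (z above threshold) marks a putative excitatory interaction and a
trough (z below -threshold) a putative inhibitory one; connection latency is
the unsigned lag of the |z| extremum — the time to peak correlation strength.
Pairs are analyzed without designating either unit as pre- or post-synaptic,
so latency is reported unsigned. No edge correction is applied: trials are
minutes long while max_lag is 50 ms, so edge bias is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .model import SpikeTrain


@dataclass
class Correlogram:
    """Lag-binned coincidence counts for one unordered unit pair."""

    unit_a: str
    unit_b: str
    binwidth_ms: float
    max_lag_ms: float
    counts: np.ndarray          # int counts per lag bin
    n_a: int
    n_b: int
    expected: Optional[float] = None   # independence expectation per bin
    z: Optional[np.ndarray] = None     # normalized correlogram

    @property
    def n_bins(self) -> int:
        return self.counts.size

    def lags(self) -> np.ndarray:
        """Bin-centre lags in ms, negative to positive."""
        k = int(round(self.max_lag_ms / self.binwidth_ms))
        return np.arange(-k, k + 1) * self.binwidth_ms

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: pair, lag_ms, count, z."""
        return pd.DataFrame({
            "unit_a": self.unit_a,
            "unit_b": self.unit_b,
            "lag_ms": self.lags(),
            "count": self.counts,
            "z": self.z if self.z is not None else np.full(self.n_bins, np.nan),
        })


@dataclass(frozen=True)
class PolarityCall:
    """Polarity and latency read off a normalized correlogram."""

    polarity: str                 # "excitatory" | "inhibitory" | "none"
    latency_ms: Optional[float]   # unsigned; None when undefined
    peak_z: float
    peak_lag_ms: float = 0.0      # signed lag of the |z| extremum


def _ccg_counts(times_a: np.ndarray, times_b: np.ndarray,
                binwidth_ms: float, max_lag_ms: float) -> np.ndarray:
    """Histogram of t_b - t_a over half-open bins [k*bw - bw/2, k*bw + bw/2)."""
    k_max = int(round(max_lag_ms / binwidth_ms))
    n_bins = 2 * k_max + 1
    counts = np.zeros(n_bins, dtype=np.int64)
    if times_a.size == 0 or times_b.size == 0:
        return counts
    half = max_lag_ms + binwidth_ms / 2.0
    lo = np.searchsorted(times_b, times_a - half, side="left")
    hi = np.searchsorted(times_b, times_a + half, side="left")
    per = hi - lo
    total = int(per.sum())
    if total == 0:
        return counts
    # flat indices of every in-window b spike, per a spike
    csum = np.cumsum(per)
    flat = (np.arange(total)
            - np.repeat(csum - per, per)
            + np.repeat(lo, per))
    diffs = times_b[flat] - np.repeat(times_a, per)
    bins = np.floor(diffs / binwidth_ms + 0.5).astype(np.int64) + k_max
    np.clip(bins, 0, n_bins - 1, out=bins)   # guards float edge rounding only
    np.add.at(counts, bins, 1)
    return counts


def compute_ccg(train_a: SpikeTrain, train_b: SpikeTrain,
                binwidth_ms: float = 1.0, max_lag_ms: float = 50.0) -> Correlogram:
    """CCG of all ordered spike pairs; ccg(a, b) is the lag-reverse of ccg(b, a)."""
    if binwidth_ms <= 0:
        raise ValueError("binwidth_ms must be positive")
    ratio = max_lag_ms / binwidth_ms
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("max_lag_ms must be a multiple of binwidth_ms")
    counts = _ccg_counts(train_a.times, train_b.times, binwidth_ms, max_lag_ms)
    return Correlogram(
        unit_a=train_a.unit.unit_id, unit_b=train_b.unit.unit_id,
        binwidth_ms=binwidth_ms, max_lag_ms=max_lag_ms,
        counts=counts, n_a=train_a.n_spikes, n_b=train_b.n_spikes)


def expected_count(train_a, train_b, binwidth_ms: float,
                   duration_s: float) -> float:
    """Expected coincidences per bin for independent stationary trains.

    Accepts :class:`SpikeTrain` objects or plain spike counts.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n_a = train_a.n_spikes if isinstance(train_a, SpikeTrain) else int(train_a)
    n_b = train_b.n_spikes if isinstance(train_b, SpikeTrain) else int(train_b)
    return n_a * n_b * (binwidth_ms / 1000.0) / duration_s


def normalize_ccg(ccg: Correlogram, duration_s: float) -> Correlogram:
    """Fill in the independence expectation and z = (c - e) / sqrt(e).

    With an empty train the expectation is zero and z stays undefined
    (``ccg.z is None``) — flagged rather than raised.
    """
    e = expected_count(ccg.n_a, ccg.n_b, ccg.binwidth_ms, duration_s)
    ccg.expected = e
    ccg.z = (ccg.counts - e) / np.sqrt(e) if e > 0 else None
    return ccg


def call_polarity_latency(ccg: Correlogram, z_threshold: float = 3.0) -> PolarityCall:
    """Polarity and latency from the |z| extremum of a normalized CCG.

    Ties in |z| are broken toward the smallest |lag| and then toward the
    positive lag. An all-zero (or unnormalizable) correlogram yields
    polarity "none" with missing latency.
    """
    if ccg.z is None or not np.any(ccg.counts):
        return PolarityCall("none", None, 0.0)
    z = ccg.z
    lags = ccg.lags()
    absz = np.abs(z)
    peak = absz.max()
    tied = np.flatnonzero(absz == peak)
    # smallest |lag|, then positive lag first
    order = sorted(tied, key=lambda i: (abs(lags[i]), lags[i] < 0))
    k = order[0]
    peak_z = float(z[k])
    if peak_z >= z_threshold:
        polarity = "excitatory"
    elif peak_z <= -z_threshold:
        polarity = "inhibitory"
    else:
        polarity = "none"
    return PolarityCall(polarity, float(abs(lags[k])), peak_z, float(lags[k]))
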