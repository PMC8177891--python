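"""Unit admissibility screening.

Two quantitative screens mirror standard sorted-unit hygiene:

* refractory violations — a physiological unit has essentially no inter-spike
  intervals below ~2 ms; a unit whose fraction of ISIs < 2 ms exceeds a
  threshold is discarded as a contaminated or multi-unit cluster;
* duplicate detection — the same cell picked up twice on the same or an
  adjacent contact produces two "units" with near-identical spike times; when
  the zero-lag (+/- 1 bin) coincidence fraction of such a pair is too high,
  the lower-spike-count member is discarded.

Both thresholds are configurable; exclusions are logged at INFO level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import SpikeTrain, Trial

logger = logging.getLogger(__name__)

#: ISIs below this bound (ms) count as refractory violations.
REFRACTORY_BOUND_MS = 2.0


@dataclass(frozen=True)
class Exclusion:
    unit_id: str
    reason: str


def isi_violation_fraction(train: SpikeTrain,
                           bound_ms: float = REFRACTORY_BOUND_MS) -> float:
    """Fraction of inter-spike intervals shorter than ``bound_ms``."""
    isi = train.isi()
    if isi.size == 0:
        return 0.0
    return float(np.mean(isi < bound_ms))


def coincidence_fraction(train_a: SpikeTrain, train_b: SpikeTrain,
                         binwidth_ms: float = 1.0) -> float:
    """Share of the sparser train's spikes with a partner within +/-1 bin.

    A spike of the sparser train counts as coincident when the other train
    has any spike within 1.5 * binwidth (the zero-lag bin plus one bin on
    either side, for 1-ms bins: |dt| < 1.5 ms).
    """
    small, large = sorted((train_a, train_b), key=lambda t: t.n_spikes)
    if small.n_spikes == 0:
        return 0.0
    window = 1.5 * binwidth_ms
    lo = np.searchsorted(large.times, small.times - window, side="left")
    hi = np.searchsorted(large.times, small.times + window, side="right")
    return float(np.mean(hi > lo))


def _are_adjacent(geometry, eid_a: int, eid_b: int) -> bool:
    if eid_a == eid_b:
        return True
    sa, sb = geometry.shank_of(eid_a), geometry.shank_of(eid_b)
    ra, rb = geometry.row_of(eid_a), geometry.row_of(eid_b)
    if sa == sb and abs(ra - rb) == 1:
        return True
    # facing contact on the neighbouring shank
    return abs(sa - sb) == 1 and ra == rb


def admissibility_report(trial: Trial,
                         isi_violation_fraction_max: float = 0.01,
                         duplicate_sync_max: float = 0.5,
                         binwidth_ms: float = 1.0) -> list[Exclusion]:
    """List the units the thresholds would exclude, with reasons."""
    if not (0 < isi_violation_fraction_max < 1) or not (0 < duplicate_sync_max < 1):
        raise ValueError("thresholds must lie in (0, 1)")

    exclusions: list[Exclusion] = []
    excluded: set[str] = set()

    for tr in trial.trains:
        frac = isi_violation_fraction(tr)
        if frac > isi_violation_fraction_max:
            excluded.add(tr.unit.unit_id)
            exclusions.append(Exclusion(
                tr.unit.unit_id,
                f"ISI<{REFRACTORY_BOUND_MS:g}ms fraction {frac:.3f} > "
                f"{isi_violation_fraction_max:g}"))

    survivors = [tr for tr in trial.trains if tr.unit.unit_id not in excluded]
    for i in range(len(survivors)):
        for j in range(i + 1, len(survivors)):
            a, b = survivors[i], survivors[j]
            if a.unit.unit_id in excluded or b.unit.unit_id in excluded:
                continue
            if not _are_adjacent(trial.geometry, a.unit.electrode_id,
                                 b.unit.electrode_id):
                continue
            frac = coincidence_fraction(a, b, binwidth_ms)
            if frac > duplicate_sync_max:
                # drop the sparser member; ties broken by unit id for determinism
                loser = min((a, b), key=lambda t: (t.n_spikes, t.unit.unit_id))
                excluded.add(loser.unit.unit_id)
                exclusions.append(Exclusion(
                    loser.unit.unit_id,
                    f"duplicate of a neighbour (coincidence {frac:.3f} > "
                    f"{duplicate_sync_max:g})"))
    return exclusions


def filter_admissible(trial: Trial,
                      isi_violation_fraction_max: float = 0.01,
                      duplicate_sync_max: float = 0.5,
                      binwidth_ms: float = 1.0) -> Trial:
    """Return a trial containing only admissible trains (idempotent)."""
    exclusions = admissibility_report(
        trial, isi_violation_fraction_max, duplicate_sync_max, binwidth_ms)
    excluded = {e.unit_id for e in exclusions}
    for e in exclusions:
        logger.info("trial %s: excluding unit %s (%s)",
                    trial.trial_id, e.unit_id, e.reason)
    kept = [tr for tr in trial.trains if tr.unit.unit_id not in excluded]
    return trial.with_trains(kept)
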