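"""Synthetic cohort generator with known ground truth.

Generates trials with the statistical structure the downstream analysis
assumes: regional unit counts drawn around the in-vivo means (sDH 11, dDH 25,
IG 16, VH 14 units per trial), spontaneous firing modelled as a homogeneous
Poisson process thinned by an absolute refractory period, and embedded
pairwise couplings with known polarity, latency and efficacy:

* excitatory couplings insert a target spike after each source spike with
  probability ``efficacy``, at ``latency + N(0, jitter_sd)`` ms;
* inhibitory couplings delete target spikes falling within a suppression
  window after each source spike, with probability ``efficacy``.

All randomness derives from a single seed, expanded into per-unit and
per-connection substreams by stable hashing of identifiers, so adding one
unit leaves every other unit's spikes unchanged.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import ConfigurationError
from .geometry import REGIONS, ArrayGeometry, default_geometry
from .model import SpikeTrain, Trial, UnitMeta, make_unit


# --------------------------------------------------------------------------
# parameters

@dataclass(frozen=True)
class RateDistribution:
    """Baseline firing-rate law for the population.

    ``lognormal`` draws exp(N(log_mean, log_sd)); ``uniform`` draws from
    [low, high). Units: Hz.
    """

    kind: Literal["lognormal", "uniform"] = "lognormal"
    log_mean: float = float(np.log(3.0))
    log_sd: float = 0.7
    low: float = 3.0
    high: float = 8.0

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "lognormal":
            return float(np.exp(rng.normal(self.log_mean, self.log_sd)))
        return float(rng.uniform(self.low, self.high))


@dataclass(frozen=True)
class CohortParams:
    """Population-level parameters of one synthetic trial."""

    regional_unit_means: dict[str, float] = field(
        default_factory=lambda: {"sDH": 11.0, "dDH": 25.0, "IG": 16.0, "VH": 14.0})
    regional_unit_sd: dict[str, float] = field(
        default_factory=lambda: {"sDH": 3.0, "dDH": 3.0, "IG": 2.0, "VH": 2.0})
    rate_distribution: RateDistribution = field(default_factory=RateDistribution)
    refractory_ms: float = 2.0
    duration_s: float = 300.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.regional_unit_means.values()):
            raise ConfigurationError("regional unit means must be >= 0")
        if any(v < 0 for v in self.regional_unit_sd.values()):
            raise ConfigurationError("regional unit sds must be >= 0")
        if self.refractory_ms < 0:
            raise ConfigurationError("refractory_ms must be >= 0")
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")


@dataclass(frozen=True)
class GroundTruthConnection:
    """One embedded coupling, the simulated counterpart of an observed link."""

    source_unit: str
    target_unit: str
    polarity: Literal["excitatory", "inhibitory"]
    latency_ms: float
    efficacy: float
    jitter_sd_ms: float = 0.0
    suppression_window_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.latency_ms < 0:
            raise ConfigurationError("latency_ms must be >= 0")
        if not (0.0 <= self.efficacy <= 1.0):
            raise ConfigurationError("efficacy must lie in [0, 1]")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.source_unit, self.target_unit))


@dataclass(frozen=True)
class ConnectionSpec:
    """How many couplings of each polarity to embed, and with what parameters.

    Endpoints are drawn at random from the population, without repeating an
    ordered (source, target) pair and without self-coupling. Inhibitory
    couplings are only statistically visible when both cells fire briskly, so
    their endpoints can be restricted to units whose baseline rate is at
    least ``inhibitory_min_rate_hz``.
    """

    n_excitatory: int = 0
    n_inhibitory: int = 0
    excitatory_latency_ms: float = 6.4
    inhibitory_latency_ms: float = 2.7
    excitatory_efficacy: float = 0.5
    inhibitory_efficacy: float = 0.8
    jitter_sd_ms: float = 0.5
    suppression_window_ms: float = 5.0
    inhibitory_min_rate_hz: float = 0.0
    explicit: tuple[GroundTruthConnection, ...] = ()

    def __post_init__(self) -> None:
        if self.n_excitatory < 0 or self.n_inhibitory < 0:
            raise ConfigurationError("connection counts must be >= 0")


# --------------------------------------------------------------------------
# seeding

def _substream(seed: int, *keys) -> np.random.Generator:
    """Child RNG keyed by stable string hashing, independent of call order."""
    tag = zlib.crc32("/".join(str(k) for k in keys).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


# --------------------------------------------------------------------------
# operations

def sample_population(params: CohortParams, geometry: ArrayGeometry,
                      seed: int) -> list[UnitMeta]:
    """Draw the units of one trial and place them on electrodes.

    Per-region counts are rounded normals truncated at zero; each unit is
    assigned uniformly at random to an electrode within its region.
    """
    units: list[UnitMeta] = []
    for region in REGIONS:
        mean = float(params.regional_unit_means.get(region, 0.0))
        sd = float(params.regional_unit_sd.get(region, 0.0))
        electrodes = geometry.electrodes_in_region(region)
        rng = _substream(seed, "population", region)
        count = max(0, int(round(rng.normal(mean, sd)))) if sd > 0 else int(round(mean))
        if count > 0 and not electrodes:
            raise ConfigurationError(
                f"region {region}: positive unit mean but no electrodes")
        for i in range(count):
            eid = int(rng.choice(electrodes))
            units.append(make_unit(f"{region}_{i:03d}", eid, geometry))
    return units


def simulate_baseline(unit: UnitMeta, rate_hz: float, duration_s: float,
                      refractory_ms: float, seed: int) -> SpikeTrain:
    """Homogeneous Poisson spiking thinned by an absolute refractory period.

    The realized rate of the thinned process is rate/(1 + rate*refractory)
    (standard non-paralyzable dead-time correction).
    """
    if rate_hz < 0:
        raise ConfigurationError("rate_hz must be >= 0")
    rng = _substream(seed, "baseline", unit.unit_id)
    duration_ms = duration_s * 1000.0
    if rate_hz == 0:
        return SpikeTrain(unit, np.empty(0))
    n = rng.poisson(rate_hz * duration_s)
    times = np.sort(rng.uniform(0.0, duration_ms, size=n))
    if refractory_ms > 0 and times.size:
        kept = _thin_refractory(times, refractory_ms)
        times = times[kept]
    return SpikeTrain(unit, times, copy=False)


def _thin_refractory(sorted_times: np.ndarray, refractory_ms: float) -> np.ndarray:
    keep = np.zeros(sorted_times.size, dtype=bool)
    last = -np.inf
    for i, t in enumerate(sorted_times):
        if t - last >= refractory_ms:
            keep[i] = True
            last = t
    return keep


def embed_excitatory(source_train: SpikeTrain, target_train: SpikeTrain,
                     latency_ms: float, efficacy: float, jitter_sd_ms: float,
                     seed: int, duration_s: float,
                     refractory_ms: float = 2.0) -> SpikeTrain:
    """Insert target spikes after source spikes; returns the modified target.

    Each source spike triggers, with probability ``efficacy``, an inserted
    target spike at ``source + latency + N(0, jitter_sd)`` ms, clipped to the
    trial. Refractory collisions are resolved by dropping the inserted spike,
    keeping the baseline train intact. Never decreases the spike count.
    """
    rng = _substream(seed, "exc", source_train.unit.unit_id,
                     target_train.unit.unit_id)
    src = source_train.times
    fired = rng.random(src.size) < efficacy
    inserted = src[fired] + latency_ms
    if jitter_sd_ms > 0:
        inserted = inserted + rng.normal(0.0, jitter_sd_ms, size=inserted.size)
    duration_ms = duration_s * 1000.0
    inserted = np.clip(inserted, 0.0, duration_ms)
    inserted.sort()

    base = target_train.times
    if refractory_ms > 0 and inserted.size:
        keep = np.ones(inserted.size, dtype=bool)
        # reject inserts within the refractory period of any baseline spike
        if base.size:
            idx = np.searchsorted(base, inserted)
            prev = np.where(idx > 0, inserted - base[np.maximum(idx - 1, 0)], np.inf)
            nxt = np.where(idx < base.size,
                           base[np.minimum(idx, base.size - 1)] - inserted, np.inf)
            keep &= (prev >= refractory_ms) & (nxt >= refractory_ms)
        # and within the refractory period of an earlier kept insert
        last = -np.inf
        for i in range(inserted.size):
            if not keep[i]:
                continue
            if inserted[i] - last < refractory_ms:
                keep[i] = False
            else:
                last = inserted[i]
        inserted = inserted[keep]
    merged = np.sort(np.concatenate([base, inserted]))
    return SpikeTrain(target_train.unit, merged, copy=False)


def embed_inhibitory(source_train: SpikeTrain, target_train: SpikeTrain,
                     latency_ms: float, suppression_window_ms: float,
                     efficacy: float, seed: int) -> SpikeTrain:
    """Delete target spikes in the suppression window after source spikes.

    A target spike at lag (latency, latency + window] after any source spike
    is removed with probability ``efficacy``. Never increases the count.
    """
    rng = _substream(seed, "inh", source_train.unit.unit_id,
                     target_train.unit.unit_id)
    src = source_train.times
    tgt = target_train.times
    if src.size == 0 or tgt.size == 0 or efficacy == 0:
        return SpikeTrain(target_train.unit, tgt)
    # target t is exposed iff some source lies in [t - latency - window, t - latency)
    lo = np.searchsorted(src, tgt - latency_ms - suppression_window_ms, side="left")
    hi = np.searchsorted(src, tgt - latency_ms, side="left")
    exposed = hi > lo
    deleted = exposed & (rng.random(tgt.size) < efficacy)
    return SpikeTrain(target_train.unit, tgt[~deleted], copy=False)


def simulate_trial(params: CohortParams, connection_spec: ConnectionSpec,
                   geometry: ArrayGeometry | None = None, seed: int = 0,
                   trial_id: str = "synthetic",
                   ) -> tuple[Trial, list[GroundTruthConnection]]:
    """Full generator: population -> baselines -> embedded couplings.

    Returns the trial together with its ground-truth connection list.
    Deterministic given the seed.
    """
    geometry = geometry or default_geometry()
    units = sample_population(params, geometry, seed)
    rates = {
        u.unit_id: params.rate_distribution.sample(_substream(seed, "rate", u.unit_id))
        for u in units
    }
    trains = {
        u.unit_id: simulate_baseline(u, rates[u.unit_id], params.duration_s,
                                     params.refractory_ms, seed)
        for u in units
    }

    truth = _draw_connections(connection_spec, units, rates, seed)
    if len(truth) != len({(c.source_unit, c.target_unit) for c in truth}):
        raise ConfigurationError("duplicate (source, target) pair in connection spec")
    for c in truth:
        for uid in (c.source_unit, c.target_unit):
            if uid not in trains:
                raise ConfigurationError(f"connection references unknown unit {uid}")

    for c in truth:
        if c.polarity == "excitatory":
            trains[c.target_unit] = embed_excitatory(
                trains[c.source_unit], trains[c.target_unit], c.latency_ms,
                c.efficacy, c.jitter_sd_ms, seed, params.duration_s,
                params.refractory_ms)
    for c in truth:
        if c.polarity == "inhibitory":
            trains[c.target_unit] = embed_inhibitory(
                trains[c.source_unit], trains[c.target_unit], c.latency_ms,
                c.suppression_window_ms, c.efficacy, seed)

    trial = Trial(trial_id, params.duration_s, geometry,
                  [trains[u.unit_id] for u in units])
    trial.validate(reject_duplicates=False)
    return trial, truth


def _draw_connections(spec: ConnectionSpec, units: Sequence[UnitMeta],
                      rates: dict[str, float], seed: int,
                      ) -> list[GroundTruthConnection]:
    truth = list(spec.explicit)
    ids = [u.unit_id for u in units]
    taken = {(c.source_unit, c.target_unit) for c in truth}

    def draw(n: int, pool: list[str], label: str) -> list[tuple[str, str]]:
        if n == 0:
            return []
        possible = len(pool) * (len(pool) - 1) - sum(
            1 for (s, t) in taken if s in pool and t in pool and s != t)
        if n > possible:
            raise ConfigurationError(
                f"cannot place {n} {label} couplings among {len(pool)} eligible units")
        rng = _substream(seed, "connections", label)
        pairs: list[tuple[str, str]] = []
        while len(pairs) < n:
            s, t = rng.choice(pool, size=2, replace=False)
            key = (str(s), str(t))
            if key in taken:
                continue
            taken.add(key)
            pairs.append(key)
        return pairs

    for s, t in draw(spec.n_excitatory, ids, "excitatory"):
        truth.append(GroundTruthConnection(
            s, t, "excitatory", spec.excitatory_latency_ms,
            spec.excitatory_efficacy, jitter_sd_ms=spec.jitter_sd_ms))
    inh_pool = [u for u in ids if rates[u] >= spec.inhibitory_min_rate_hz]
    for s, t in draw(spec.n_inhibitory, inh_pool, "inhibitory"):
        truth.append(GroundTruthConnection(
            s, t, "inhibitory", spec.inhibitory_latency_ms,
            spec.inhibitory_efficacy,
            suppression_window_ms=spec.suppression_window_ms))
    return truth
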