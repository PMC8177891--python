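"""Topology of significant connections on the array geometry.

Significant pairs are classified into the ten unordered region-pair
categories (sDH-sDH, sDH-dDH, ..., VH-VH) and summarized as percentages,
with within- vs between-region totals. The observed layout is benchmarked
against a closed-form random-placement model: if units are distributed
uniformly through the sampled gray matter, the expected share of a category
is the ratio of the number of electrodes represented in that comparison to
the total represented across all comparisons — n_i/D for within-region
categories and (n_i + n_j)/D for between-region ones, with
D = sum_i n_i + sum_{i<j} (n_i + n_j) (128 for the default 8/12/6/6 array).

Node-level summaries count, per electrode, the significant connections
touching it; the "most connected nodes" of a trial are the electrodes whose
count significantly exceeds the across-electrode mean (one-sided z rule).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError
from .geometry import (REGION_PAIR_CATEGORIES, REGIONS, WITHIN_CATEGORIES,
                       ArrayGeometry, pair_category_label)
from .model import Trial


def _round_half_up(x: float, decimals: int = 1) -> float:
    """Display rounding with halves away from zero (6.25 -> 6.3)."""
    scale = 10 ** decimals
    return float(np.floor(abs(x) * scale + 0.5) / scale * np.sign(x) if x < 0
                 else np.floor(x * scale + 0.5) / scale)


@dataclass(frozen=True)
class RegionalSummary:
    """Percent of connections per region-pair category, plus totals."""

    proportions: dict[str, float]          # category -> percent
    within_total: float
    between_total: float
    n_connections: int
    denominator: Optional[int] = None      # electrode-count denominator (theory)

    def rounded(self, decimals: int = 1) -> dict[str, float]:
        """Category percentages rounded half-up for display (full precision kept)."""
        return {c: _round_half_up(v, decimals) for c, v in self.proportions.items()}

    @property
    def is_empty(self) -> bool:
        return self.n_connections == 0 and self.denominator is None


@dataclass(frozen=True)
class NodeReport:
    """Per-electrode connection counts and the most-connected subset."""

    counts: dict[int, int]
    most_connected: frozenset[int]
    alpha: float
    mean: float
    sd: float
    threshold: float


def pair_category(connection, geometry: ArrayGeometry | None = None) -> str:
    """Unordered region-pair category of a connection.

    Works with any object carrying ``region_a``/``region_b`` (or a (region,
    region) tuple). Same-electrode pairs necessarily share a region and land
    in that region's within category.
    """
    if isinstance(connection, (tuple, list)) and len(connection) == 2:
        ra, rb = connection
    else:
        ra, rb = connection.region_a, connection.region_b
    if ra is None or rb is None:
        raise ValueError("connection lacks region annotations")
    return pair_category_label(ra, rb)


def regional_proportions(significant_connections: Sequence,
                         geometry: ArrayGeometry | None = None) -> RegionalSummary:
    """Observed percent of significant connections per category."""
    counts = {c: 0 for c in REGION_PAIR_CATEGORIES}
    n = 0
    for conn in significant_connections:
        counts[pair_category(conn, geometry)] += 1
        n += 1
    if n == 0:
        return RegionalSummary({c: 0.0 for c in REGION_PAIR_CATEGORIES},
                               0.0, 0.0, 0)
    props = {c: 100.0 * k / n for c, k in counts.items()}
    within = sum(props[c] for c in WITHIN_CATEGORIES)
    return RegionalSummary(props, within, 100.0 - within, n)


def theoretical_proportions(electrode_counts_per_region) -> RegionalSummary:
    """Random-placement benchmark from per-region electrode counts.

    ``electrode_counts_per_region`` is a mapping region -> count or a
    sequence in canonical region order. Scale-invariant in the counts.
    """
    if isinstance(electrode_counts_per_region, Mapping):
        counts = [float(electrode_counts_per_region.get(r, 0.0)) for r in REGIONS]
    else:
        counts = [float(x) for x in electrode_counts_per_region]
    if len(counts) != len(REGIONS):
        raise ConfigurationError(f"expected {len(REGIONS)} electrode counts")
    if any(c < 0 for c in counts):
        raise ConfigurationError("electrode counts must be >= 0")
    if sum(counts) == 0:
        raise ConfigurationError("at least one region must have electrodes")

    weights: dict[str, float] = {}
    for i, r in enumerate(REGIONS):
        weights[pair_category_label(r, r)] = counts[i]
    for i, j in itertools.combinations(range(len(REGIONS)), 2):
        # a between-region comparison exists only if both regions have electrodes
        w = counts[i] + counts[j] if counts[i] > 0 and counts[j] > 0 else 0.0
        weights[pair_category_label(REGIONS[i], REGIONS[j])] = w
    denom = sum(weights.values())
    props = {c: 100.0 * weights[c] / denom for c in REGION_PAIR_CATEGORIES}
    within = sum(props[c] for c in WITHIN_CATEGORIES)
    return RegionalSummary(props, within, 100.0 - within, 0,
                           denominator=int(denom) if denom == int(denom) else None)


def node_connection_counts(significant_connections: Sequence,
                           geometry: ArrayGeometry) -> dict[int, int]:
    """Significant connections touching each electrode.

    Every connection increments both endpoint electrodes; a same-electrode
    connection increments its electrode twice, so total increments are
    always 2x the number of connections.
    """
    counts = {eid: 0 for eid in geometry.electrode_ids}
    for conn in significant_connections:
        counts[int(conn.electrode_a)] += 1
        counts[int(conn.electrode_b)] += 1
    return counts


def most_connected_nodes(counts: Mapping[int, int],
                         alpha: float = 0.05) -> NodeReport:
    """Electrodes whose count exceeds mean + z_(1-alpha) * SD across electrodes.

    One-sided rule; with all-equal counts (zero variance) the set is empty.
    """
    if len(counts) < 2:
        raise ValueError("need counts for at least 2 electrodes")
    values = np.array(list(counts.values()), dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    z = float(sps.norm.ppf(1.0 - alpha))
    threshold = mean + z * sd
    selected = frozenset(eid for eid, c in counts.items() if c > threshold)
    return NodeReport(dict(counts), selected, alpha, mean, sd, threshold)


def count_unique_pairs(n_units: int) -> int:
    """Unordered pairs among n units (reciprocal connections ignored)."""
    if n_units < 0:
        raise ValueError("n_units must be >= 0")
    return n_units * (n_units - 1) // 2


# --------------------------------------------------------------------------
# connectivity map export

def connectivity_map_export(trial: Trial, results: Sequence,
                            significant_only: bool = True) -> dict:
    """Machine-readable connectivity map (nodes: electrodes; edges: pairs).

    Nodes carry shank/depth/region from the geometry; edges carry unit ids,
    strength, peak z, latency and polarity for each (significant) result.
    """
    geo = trial.geometry
    nodes = [
        {"electrode_id": int(eid), "shank": geo.shank_of(eid),
         "depth_um": geo.depth_of(eid), "region": geo.region_of(eid)}
        for eid in geo.electrode_ids
    ]
    edges = []
    for res in results:
        if significant_only and not res.significant:
            continue
        edges.append({
            "unit_a": res.unit_a, "unit_b": res.unit_b,
            "electrode_a": int(res.electrode_a), "electrode_b": int(res.electrode_b),
            "r": res.r, "z": res.peak_z,
            "latency_ms": res.latency_ms, "polarity": res.polarity,
        })
    return {"trial_id": trial.trial_id, "duration_s": trial.duration_s,
            "nodes": nodes, "edges": edges}


def write_connectivity_map(map_doc: dict, path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(map_doc, fh, indent=1)
    return path


def read_connectivity_map(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


def map_to_graph(map_doc: dict) -> nx.MultiGraph:
    """networkx view of a map document (nodes = electrodes, multi-edges = pairs)."""
    g = nx.MultiGraph()
    for node in map_doc["nodes"]:
        g.add_node(node["electrode_id"], **node)
    for edge in map_doc["edges"]:
        g.add_edge(edge["electrode_a"], edge["electrode_b"], **edge)
    return g


def plot_connectivity_map(map_doc: dict, ax=None, color_by: str = "polarity"):
    """Render a map document: electrodes as dots, connections as lines.

    Edge colour encodes polarity (red excitatory / blue inhibitory) or
    correlation strength. Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3.5, 6))
    xs = {n["electrode_id"]: n["shank"] for n in map_doc["nodes"]}
    ys = {n["electrode_id"]: n["depth_um"] for n in map_doc["nodes"]}
    ax.scatter(list(xs.values()), list(ys.values()), s=40, c="0.7", zorder=2)
    for e in map_doc["edges"]:
        a, b = e["electrode_a"], e["electrode_b"]
        if color_by == "polarity":
            color = {"excitatory": "crimson", "inhibitory": "royalblue"}.get(
                e["polarity"], "0.4")
        else:
            color = plt.cm.viridis(min(1.0, abs(e["r"]) * 10))
        ax.plot([xs[a], xs[b]], [ys[a], ys[b]], color=color, alpha=0.6,
                lw=1.0, zorder=1)
    ax.invert_yaxis()
    ax.set_xlabel("shank")
    ax.set_ylabel("depth (um)")
    ax.set_xticks(sorted(set(xs.values())))
    return ax
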