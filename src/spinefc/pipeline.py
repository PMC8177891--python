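"""End-to-end orchestration: simulate -> analyze -> null -> report.

The stages are plain library calls; this module wires them together with a
serializable configuration, stage-count logging (units in/out, pairs tested,
significant pairs, realized p-threshold) and deterministic seeding, and is
what the command-line interface drives.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import __version__
from .admissibility import filter_admissible
from .geometry import ArrayGeometry, default_geometry
from .model import Trial
from .stats import (AnalysisParams, ConnectionResult, bh_fdr, results_to_frame,
                    test_all_pairs)
from .surrogate import NullEnsemble, build_null_ensemble, empirical_comparison
from .synthetic import CohortParams, ConnectionSpec, simulate_trial
from .topology import (NodeReport, RegionalSummary, connectivity_map_export,
                       most_connected_nodes, node_connection_counts,
                       regional_proportions)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every numeric knob of a run, serializable into the run report."""

    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    isi_violation_fraction_max: float = 0.01
    duplicate_sync_max: float = 0.5
    jitter_J_ms: tuple[int, ...] = (5, 50)
    n_replicates: int = 200
    node_alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["jitter_J_ms"] = list(self.jitter_J_ms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "analysis" in d and isinstance(d["analysis"], dict):
            d["analysis"] = AnalysisParams(**d["analysis"])
        if "jitter_J_ms" in d:
            d["jitter_J_ms"] = tuple(int(x) for x in d["jitter_J_ms"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class TrialAnalysis:
    """Everything the analyze stage produces for one trial."""

    trial: Trial                      # admissible trains only
    results: list[ConnectionResult]
    p_threshold: float
    regional_summary: RegionalSummary
    node_report: NodeReport
    stage_log: dict

    @property
    def significant(self) -> list[ConnectionResult]:
        return [r for r in self.results if r.significant]

    @property
    def significant_proportion(self) -> float:
        return len(self.significant) / len(self.results) if self.results else 0.0


def analyze_trial(trial: Trial, config: RunConfig | None = None) -> TrialAnalysis:
    """Admissibility filter -> pairwise tests -> per-trial BH -> topology."""
    config = config or RunConfig()
    t0 = time.perf_counter()
    n_in = trial.n_units
    filtered = filter_admissible(
        trial, config.isi_violation_fraction_max, config.duplicate_sync_max,
        config.analysis.binwidth_ms)
    results = test_all_pairs(filtered, config.analysis)
    results, threshold = bh_fdr(results, config.analysis.fdr_q)
    significant = [r for r in results if r.significant]
    summary = regional_proportions(significant, filtered.geometry)
    counts = node_connection_counts(significant, filtered.geometry)
    report = most_connected_nodes(counts, config.node_alpha)
    log = {
        "trial_id": trial.trial_id,
        "units_in": n_in,
        "units_admissible": filtered.n_units,
        "pairs_tested": len(results),
        "significant_pairs": len(significant),
        "realized_p_threshold": threshold,
        "wall_time_s": round(time.perf_counter() - t0, 3),
    }
    logger.info("analyze %s: %d units -> %d admissible -> %d pairs -> "
                "%d significant (p <= %.3g)", trial.trial_id, n_in,
                filtered.n_units, len(results), len(significant), threshold)
    return TrialAnalysis(filtered, results, threshold, summary, report, log)


def run_null(analysis: TrialAnalysis, config: RunConfig) -> dict[int, dict]:
    """Build one jitter ensemble per J in the config and rank the observed value."""
    observed = analysis.significant_proportion
    out: dict[int, dict] = {}
    for J in config.jitter_J_ms:
        ensemble = build_null_ensemble(
            analysis.trial, J, config.n_replicates, config.analysis,
            seed=config.seed)
        percentile, exceedance = empirical_comparison(observed, ensemble)
        out[J] = {
            "ensemble": ensemble,
            "observed_significant_proportion": observed,
            "ensemble_mean_significant_proportion":
                ensemble.mean_significant_proportion,
            "observed_percentile": percentile,
            "exceedance_p": exceedance,
        }
        logger.info("null J=%d: observed %.4f vs ensemble mean %.4f "
                    "(percentile %.1f, exceedance p %.4g)", J, observed,
                    ensemble.mean_significant_proportion, percentile, exceedance)
    return out


def write_run_report(path, config: RunConfig, analysis: TrialAnalysis,
                     null_results: Optional[dict] = None) -> Path:
    """Self-contained YAML run report: config echo + all summary tables."""
    doc = {
        "software_version": __version__,
        "config": config.to_dict(),
        "stage_log": analysis.stage_log,
        "regional_proportions_pct": analysis.regional_summary.rounded(1),
        "within_total_pct": round(analysis.regional_summary.within_total, 1),
        "between_total_pct": round(analysis.regional_summary.between_total, 1),
        "most_connected_nodes": sorted(analysis.node_report.most_connected),
        "node_rule": {
            "alpha": analysis.node_report.alpha,
            "mean": analysis.node_report.mean,
            "sd": analysis.node_report.sd,
            "threshold": analysis.node_report.threshold,
        },
    }
    if null_results:
        doc["null_comparison"] = {
            int(J): {k: float(v) for k, v in res.items() if k != "ensemble"}
            for J, res in null_results.items()
        }
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path
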