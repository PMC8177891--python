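"""Reading and writing trials.

A trial on disk is a pair of files:

* a UTF-8 comma-delimited spike table with header ``unit_id,electrode_id,time_ms``,
  one row per spike, times serialized at full (round-trip) precision;
* a YAML metadata sidecar with keys ``trial_id``, ``duration_s`` and
  ``geometry: {n_shanks, contacts_per_shank, pitch_um, top_row_depth_um,
  region_boundaries_um}``.

``load_trial(write_trial(T)) == T`` holds bit-exactly for valid trials. A
unit exists in the table only through its spikes, so a train with zero
spikes has no on-disk representation and is dropped by a round trip.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SpikeTableFormatError, TrialValidationError
from .geometry import ArrayGeometry
from .model import SpikeTrain, Trial, make_unit

_COLUMNS = ("unit_id", "electrode_id", "time_ms")


def load_trial(spike_table_path, metadata_path) -> Trial:
    """Load a trial from a spike table CSV and its metadata sidecar.

    Rows are grouped by unit, times sorted ascending. Malformed rows raise
    :class:`SpikeTableFormatError`; invariant violations (times outside the
    trial, unknown electrodes, a unit spread over several electrodes) raise
    :class:`TrialValidationError` naming the offending unit.
    """
    meta = _read_sidecar(metadata_path)
    geometry = ArrayGeometry.from_dict(meta["geometry"])
    trial_id = str(meta["trial_id"])
    duration_s = float(meta["duration_s"])

    try:
        table = pd.read_csv(
            spike_table_path,
            dtype={"unit_id": str},
            float_precision="round_trip",
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as exc:
        raise SpikeTableFormatError(f"{spike_table_path}: {exc}") from exc

    missing = [c for c in _COLUMNS if c not in table.columns]
    if missing:
        raise SpikeTableFormatError(
            f"{spike_table_path}: missing columns {missing}")

    trains: list[SpikeTrain] = []
    if len(table):
        times = pd.to_numeric(table["time_ms"], errors="coerce")
        if times.isna().any():
            bad = int(times.isna().idxmax())
            raise SpikeTableFormatError(
                f"{spike_table_path}: non-numeric time_ms at row {bad}")
        electrodes = pd.to_numeric(table["electrode_id"], errors="coerce")
        if electrodes.isna().any():
            bad = int(electrodes.isna().idxmax())
            raise SpikeTableFormatError(
                f"{spike_table_path}: non-numeric electrode_id at row {bad}")
        table = table.assign(time_ms=times.astype(np.float64),
                             electrode_id=electrodes.astype(int))
        for unit_id, grp in table.groupby("unit_id", sort=True):
            eids = grp["electrode_id"].unique()
            if len(eids) > 1:
                raise TrialValidationError(
                    f"unit {unit_id}: listed on multiple electrodes {sorted(eids)}")
            eid = int(eids[0])
            if not geometry.has_electrode(eid):
                raise TrialValidationError(
                    f"unit {unit_id}: unknown electrode_id {eid}")
            unit = make_unit(unit_id, eid, geometry)
            trains.append(SpikeTrain(unit, np.sort(grp["time_ms"].to_numpy())))

    trial = Trial(trial_id, duration_s, geometry, trains)
    trial.validate()
    return trial


def write_trial(trial: Trial, spike_table_path, metadata_path) -> tuple[Path, Path]:
    """Write a trial; returns the two paths. Round-trips through load_trial."""
    spike_table_path = Path(spike_table_path)
    metadata_path = Path(metadata_path)

    with open(spike_table_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for tr in trial.trains:
            uid, eid = tr.unit.unit_id, tr.unit.electrode_id
            for t in tr.times:
                writer.writerow((uid, eid, repr(float(t))))

    sidecar = {
        "trial_id": trial.trial_id,
        "duration_s": float(trial.duration_s),
        "geometry": trial.geometry.to_dict(),
    }
    with open(metadata_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)
    return spike_table_path, metadata_path


def _read_sidecar(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict):
        raise SpikeTableFormatError(f"{path}: sidecar is not a mapping")
    for key in ("trial_id", "duration_s", "geometry"):
        if key not in meta:
            raise SpikeTableFormatError(f"{path}: sidecar missing key {key!r}")
    return meta


def write_ground_truth(connections, path) -> Path:
    """Write embedded ground-truth couplings as tidy CSV."""
    path = Path(path)
    rows = [
        {
            "source_unit": c.source_unit,
            "target_unit": c.target_unit,
            "polarity": c.polarity,
            "latency_ms": c.latency_ms,
            "efficacy": c.efficacy,
            "jitter_sd_ms": c.jitter_sd_ms,
            "suppression_window_ms": c.suppression_window_ms,
        }
        for c in connections
    ]
    pd.DataFrame(
        rows,
        columns=["source_unit", "target_unit", "polarity", "latency_ms",
                 "efficacy", "jitter_sd_ms", "suppression_window_ms"],
    ).to_csv(path, index=False)
    return path
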