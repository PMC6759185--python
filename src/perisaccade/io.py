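"""On-disk formats: trial sets, models, configuration, provenance.

A trial set is stored as a directory of plain-text files: ``header.json``
(schema version, grid geometry, time axis, saccade offsets),
``stimulus_events.csv`` (trial_id, probe_row, probe_col, onset_ms,
duration_ms) and ``spikes.csv`` (trial_id, spike_time_ms).  The event table
plus header regenerate the binary lattices bit-exactly; there is no
community format for probe-grid flash experiments, and delimited text keeps
everything diffable.  Models are stored as JSON (coefficients, masks, knot
grids, constants, seeds) with a versioned schema.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .basis import InvalidInputError
from .experiment import ProbeGrid, Trial, TrialSet
from .fmodel import FModel, SOURCES
from .smodel import Bases, SModel

SCHEMA_VERSION = 1


def write_trialset(trials: TrialSet, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    g = trials.grid
    header = {
        "schema_version": SCHEMA_VERSION,
        "grid": {"n_rows": g.n_rows, "n_cols": g.n_cols,
                 "origin": list(g.origin), "dx": g.dx, "dy": g.dy,
                 "fp": list(g.fp), "st": list(g.st)},
        "time_axis": list(trials.time_axis),
        "trials": [{"trial_id": t.trial_id,
                    "saccade_offset": t.saccade_offset}
                   for t in trials.trials],
    }
    (path / "header.json").write_text(json.dumps(header, indent=1))
    ev_rows, spk_rows = [], []
    for t in trials.trials:
        for r in range(g.n_rows):
            for c in range(g.n_cols):
                on = np.flatnonzero(t.stimulus[r, c])
                if on.size == 0:
                    continue
                starts = on[np.r_[True, np.diff(on) > 1]]
                ends = on[np.r_[np.diff(on) > 1, True]]
                for s, e in zip(starts, ends):
                    ev_rows.append((t.trial_id, r, c,
                                    int(s) + t.t_start, int(e - s) + 1))
        for s in np.flatnonzero(t.spikes):
            spk_rows.append((t.trial_id, int(s) + t.t_start))
    pd.DataFrame(ev_rows, columns=["trial_id", "probe_row", "probe_col",
                                   "onset_ms", "duration_ms"]) \
        .sort_values(["trial_id", "onset_ms"]) \
        .to_csv(path / "stimulus_events.csv", index=False)
    pd.DataFrame(spk_rows, columns=["trial_id", "spike_time_ms"]) \
        .to_csv(path / "spikes.csv", index=False)


def read_trialset(path) -> TrialSet:
    path = Path(path)
    try:
        header = json.loads((path / "header.json").read_text())
    except json.JSONDecodeError as e:
        raise InvalidInputError(f"malformed header.json: {e}") from e
    hg = header["grid"]
    grid = ProbeGrid(n_rows=hg["n_rows"], n_cols=hg["n_cols"],
                     origin=tuple(hg["origin"]), dx=hg["dx"], dy=hg["dy"],
                     fp=tuple(hg["fp"]), st=tuple(hg["st"]))
    t0, t1 = header["time_axis"]
    n_bins = t1 - t0
    events = pd.read_csv(path / "stimulus_events.csv")
    spikes = pd.read_csv(path / "spikes.csv")
    trials = []
    for meta in header["trials"]:
        tid = meta["trial_id"]
        stim = np.zeros((grid.n_rows, grid.n_cols, n_bins), dtype=np.uint8)
        for row in events[events.trial_id == tid].itertuples():
            i0 = int(row.onset_ms) - t0
            stim[int(row.probe_row), int(row.probe_col),
                 i0:i0 + int(row.duration_ms)] = 1
        spk = np.zeros(n_bins, dtype=np.uint8)
        tt = spikes[spikes.trial_id == tid].spike_time_ms.to_numpy() - t0
        spk[tt.astype(int)] = 1
        try:
            trials.append(Trial(stimulus=stim, spikes=spk, t_start=t0,
                                saccade_offset=meta["saccade_offset"],
                                trial_id=tid))
        except InvalidInputError as e:
            raise InvalidInputError(
                f"trial {tid} violates invariants: {e}") from e
    return TrialSet(grid=grid, trials=trials, time_axis=(t0, t1))


def _bases_meta(b: Bases) -> dict:
    return {
        "delay_knots": list(map(float, b.stimulus.delay_basis.knots.knots)),
        "time_knots": list(map(float, b.stimulus.time_basis.knots.knots)),
        "postspike_knots": list(map(float, b.postspike.knots.knots)),
        "offset_knots": list(map(float, b.offset.knots.knots)),
        "delay_support": [int(b.stimulus.delay_basis.grid[0]),
                          int(b.stimulus.delay_basis.grid[-1]) + 1],
        "time_support": [int(b.stimulus.time_basis.grid[0]),
                         int(b.stimulus.time_basis.grid[-1]) + 1],
    }


def _bases_from_meta(m: dict) -> Bases:
    return Bases.from_knots(m["delay_knots"], m["time_knots"],
                            m["postspike_knots"], m["offset_knots"],
                            delay_support=tuple(m["delay_support"]),
                            time_support=tuple(m["time_support"]))


def write_smodel(model: SModel, path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "kind": "smodel",
        "kappa": model.kappa.tolist(),
        "eta": model.eta.tolist(),
        "beta": model.beta.tolist(),
        "r0": model.r0,
        "rmax": model.rmax,
        "delta_ms": model.delta_ms,
        "seed": model.seed,
        "selection_mask": None if model.selection_mask is None
        else model.selection_mask.astype(int).tolist(),
        "bases": _bases_meta(model.bases),
    }
    Path(path).write_text(json.dumps(doc))


def read_smodel(path) -> SModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("kind") != "smodel":
        raise InvalidInputError(f"{path} is not an S-model file")
    mask = doc["selection_mask"]
    return SModel(kappa=np.asarray(doc["kappa"], dtype=float),
                  eta=np.asarray(doc["eta"], dtype=float),
                  beta=np.asarray(doc["beta"], dtype=float),
                  r0=doc["r0"], rmax=doc["rmax"],
                  bases=_bases_from_meta(doc["bases"]),
                  selection_mask=None if mask is None
                  else np.asarray(mask, dtype=bool),
                  delta_ms=doc["delta_ms"], seed=doc["seed"])


def write_fmodel(model: FModel, path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "kind": "fmodel",
        "sources": {sr: model.sources[sr].tolist() for sr in SOURCES},
        "baseline": model.baseline.tolist(),
        "fixation": model.fixation.tolist(),
        "bins": model.bins.tolist(),
        "time_grid": model.time_grid.tolist(),
        "delay_grid": model.delay_grid.tolist(),
        "source_locs": {k: list(v) for k, v in model.source_locs.items()},
        "smoothing_span_ms": model.smoothing_span_ms,
    }
    Path(path).write_text(json.dumps(doc))


def read_fmodel(path) -> FModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("kind") != "fmodel":
        raise InvalidInputError(f"{path} is not an F-model file")
    return FModel(
        sources={sr: np.asarray(doc["sources"][sr]) for sr in SOURCES},
        baseline=np.asarray(doc["baseline"]),
        fixation=np.asarray(doc["fixation"]),
        bins=np.asarray(doc["bins"]),
        time_grid=np.asarray(doc["time_grid"]),
        delay_grid=np.asarray(doc["delay_grid"]),
        source_locs={k: tuple(v) for k, v in doc["source_locs"].items()},
        smoothing_span_ms=doc["smoothing_span_ms"])


def load_config(path) -> dict:
    """YAML/JSON run configuration with light validation."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise InvalidInputError("config must be a mapping")
    for key in ("n_resamples", "n_ensemble", "n_sequences", "n_null"):
        if key in cfg and int(cfg[key]) < 1:
            raise InvalidInputError(f"{key} must be >= 1")
    fr = cfg.get("split_fractions")
    if fr is not None and sum(fr) > 1.0 + 1e-9:
        raise InvalidInputError("split fractions must sum to <= 1")
    return cfg


def provenance_record(stage: str, seed: int, config: Optional[dict] = None,
                      **extra) -> dict:
    """Provenance entry: stage, seed, config hash, package version."""
    from . import __version__
    blob = json.dumps(config or {}, sort_keys=True).encode()
    return {"stage": stage, "seed": seed,
            "config_sha1": hashlib.sha1(blob).hexdigest(),
            "version": __version__, **extra}


def append_provenance(path, record: dict) -> None:
    with open(path, "a") as f:
        f.write(json.dumps(record) + "\n")
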