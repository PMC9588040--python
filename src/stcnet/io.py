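"""Configuration files, raster/weight serialization and run manifests.

Conventions (stated in every file header): times are seconds as floats,
neuron ids are 0-based with the excitatory block first. Rasters and weight
tables are written as TSV for human inspection and as HDF5 for binned
matrices; configs are flat YAML/JSON keyed by the model symbol names.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .dynamics import SpikeRaster
from .params import ModelParams
from .plasticity import NMSchedule
from .protocol import ProtocolTimeline, RunRecord

_HEADER = "# times in seconds; neuron ids 0-based, excitatory block first\n"


# -- configuration -----------------------------------------------------------

def load_config(path) -> dict:
    """Read a YAML/JSON config into (params, timeline, nm_schedule, sweep).

    Unspecified keys fall back to the model defaults; unknown keys raise
    (no silently ignored typos). Returns a dict with keys ``params``,
    ``timeline``, ``nm_schedule`` and ``sweep`` (the raw grid mapping or
    None).
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    known_sections = {"params", "timeline", "nm_schedule", "sweep"}
    unknown = set(raw) - known_sections
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    params = ModelParams.from_dict(raw.get("params") or {})
    tl_raw = dict(raw.get("timeline") or {})
    if "learning_pulses" in tl_raw:
        tl_raw["learning_pulses"] = tuple(
            (float(a), float(b)) for a, b in tl_raw["learning_pulses"])
    allowed_tl = set(ProtocolTimeline.__dataclass_fields__)
    if set(tl_raw) - allowed_tl:
        raise ValueError(f"unknown timeline keys: {sorted(set(tl_raw) - allowed_tl)}")
    timeline = ProtocolTimeline(**tl_raw)
    nm_raw = dict(raw.get("nm_schedule") or {})
    allowed_nm = {"level", "onset_min", "duration_min"}
    if set(nm_raw) - allowed_nm:
        raise ValueError(f"unknown nm_schedule keys: {sorted(set(nm_raw) - allowed_nm)}")
    nm = NMSchedule(**nm_raw)
    return {"params": params, "timeline": timeline, "nm_schedule": nm,
            "sweep": raw.get("sweep")}


def save_config(cfg: dict, path) -> None:
    """Write the config mapping back to YAML (round-trips with load_config)."""
    out = {
        "params": cfg["params"].to_dict(),
        "timeline": {
            **asdict(cfg["timeline"]),
            "learning_pulses": [list(p) for p in cfg["timeline"].learning_pulses],
        },
        "nm_schedule": {
            "level": cfg["nm_schedule"].level,
            "onset_min": cfg["nm_schedule"].onset_min,
            "duration_min": cfg["nm_schedule"].duration_min,
        },
    }
    if cfg.get("sweep") is not None:
        out["sweep"] = cfg["sweep"]
    Path(path).write_text(yaml.safe_dump(out, sort_keys=True))


def config_hash(cfg: dict) -> str:
    canon = {
        "params": cfg["params"].to_dict(),
        "timeline": asdict(cfg["timeline"]),
        "nm_schedule": {"level": cfg["nm_schedule"].level,
                        "onset_min": cfg["nm_schedule"].onset_min,
                        "duration_min": cfg["nm_schedule"].duration_min},
    }
    blob = json.dumps(canon, sort_keys=True, default=list).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# -- rasters -----------------------------------------------------------------

def write_raster_tsv(raster: SpikeRaster, path) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER)
        fh.write(f"# n_neurons={raster.n_neurons}\n")
        fh.write("time_s\tneuron_id\n")
        order = np.argsort(raster.times, kind="stable")
        for t, nid in zip(raster.times[order], raster.neuron_ids[order]):
            fh.write(f"{t:.6f}\t{nid}\n")


def read_raster_tsv(path) -> SpikeRaster:
    n_neurons = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# n_neurons="):
                n_neurons = int(line.split("=", 1)[1])
            if not line.startswith("#"):
                break
    df = pd.read_csv(path, sep="\t", comment="#")
    if n_neurons is None:
        n_neurons = int(df["neuron_id"].max()) + 1 if len(df) else 0
    return SpikeRaster(df["neuron_id"].to_numpy(), df["time_s"].to_numpy(),
                       n_neurons)


def write_binned_h5(binned: np.ndarray, path, bin_width: float,
                    t0: float = 0.0, name: str = "raster") -> None:
    with h5py.File(path, "a") as fh:
        if name in fh:
            del fh[name]
        ds = fh.create_dataset(name, data=np.asarray(binned, dtype=np.int8),
                               compression="gzip")
        ds.attrs["bin_width_s"] = bin_width
        ds.attrs["t0_s"] = t0


def read_binned_h5(path, name: str = "raster") -> tuple[np.ndarray, dict]:
    with h5py.File(path, "r") as fh:
        ds = fh[name]
        return ds[...], dict(ds.attrs)


# -- weight tables -----------------------------------------------------------

def write_weights_tsv(df: pd.DataFrame, path, snapshot_time: float | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER)
        if snapshot_time is not None:
            fh.write(f"# snapshot_time_s={snapshot_time}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_weights_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def record_weight_frame(record: RunRecord, stage: str = "post_recall") -> pd.DataFrame:
    snap = record.snapshots[stage]
    return pd.DataFrame({
        "pre_id": record.ee_pre, "post_id": record.ee_post,
        "h": snap["h"], "z": snap["z"], "class": record.synapse_class,
    })


# -- manifests ---------------------------------------------------------------

def write_manifest(path, cfg: dict, seed: int, outputs: list[str],
                   phase_times: dict | None = None,
                   package_version: str | None = None) -> None:
    if package_version is None:
        from . import __version__ as package_version
    manifest = {
        "config_hash": config_hash(cfg),
        "seed": int(seed),
        "package_version": package_version,
        "created_unix": time.time(),
        "outputs": list(outputs),
        "phase_wall_times_s": phase_times or {},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def save_run(record: RunRecord, out_dir, cfg: dict,
             phase_times: dict | None = None) -> list[str]:
    """Write raster TSV, weight snapshots and the manifest for one run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    raster_path = out / "raster.tsv"
    write_raster_tsv(record.raster, raster_path)
    files.append(str(raster_path))
    for stage in ("post_learning", "pre_recall", "post_recall"):
        p = out / f"weights_{stage}.tsv"
        write_weights_tsv(record_weight_frame(record, stage), p,
                          snapshot_time=record.snapshots[stage]["t"])
        files.append(str(p))
    ids_path = out / "subpopulations.json"
    as_ids, ans_ids, ctrl_ids = record.subpopulations()
    ids_path.write_text(json.dumps({
        "as": as_ids.tolist(), "ans": ans_ids.tolist(),
        "ctrl": ctrl_ids.tolist(),
        "t_learn": record.timeline.t_learn,
        "t_recall": record.timeline.t_recall,
        "final_pulse_window": list(record.timeline.final_pulse_window),
        "recall_window": list(record.timeline.recall_window),
    }))
    files.append(str(ids_path))
    write_manifest(out / "manifest.json", cfg, record.seed, files, phase_times)
    files.append(str(out / "manifest.json"))
    return files
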