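"""File formats, run configuration, and manifests.

Canonical on-disk forms: the trial table as CSV (one row per trial),
per-trial eyelid traces as CSV (frame_index, time_s, raw_px, closure) or
one HDF5 file per session, paw tracks as wide CSV (time_s, then x/y/z per
paw, body_x) with metadata in commented header lines, split-belt protocols
as YAML, and a JSON run manifest (config hash, seed, package versions)
from which every output is regenerable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .eyelid import EyelidTrace, RawEyelidTrace
from .gait import PAWS, PawTracks
from .splitbelt import AdaptationProtocol, ProtocolTrial

#: Required trial-table columns; (mouse_id, session, trial_index) is the key.
TRIAL_TABLE_COLUMNS = [
    "mouse_id", "group", "session", "trial_index", "trial_type",
    "cs_onset_s", "isi_s", "us_present", "us_duration_s",
]
TRIAL_KEY = ["mouse_id", "session", "trial_index"]


def read_trial_table(path, check_refs: bool = True) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Raises on a missing required column (naming it), on duplicate
    (mouse_id, session, trial_index) keys, and on dangling trace_ref /
    wheel_ref paths (listing the unresolved ones).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing required column(s): {missing}")
    dup = df.duplicated(TRIAL_KEY)
    if dup.any():
        keys = df.loc[dup, TRIAL_KEY].to_records(index=False).tolist()
        raise ValueError(f"duplicate trial key(s): {keys[:5]}")
    if check_refs:
        dangling = []
        for col in ("trace_ref", "wheel_ref"):
            if col in df.columns:
                for ref in df[col].dropna().unique():
                    if not (path.parent / str(ref)).exists():
                        dangling.append(str(ref))
        if dangling:
            raise ValueError(f"unresolved trace reference(s): {dangling[:10]}")
    return df


def write_trace_csv(path, trace: EyelidTrace | RawEyelidTrace,
                    raw: RawEyelidTrace | None = None) -> None:
    """Per-trial trace CSV: frame_index, time_s, raw_px, closure."""
    n = trace.values.size
    is_norm = isinstance(trace, EyelidTrace)
    pd.DataFrame({
        "frame_index": np.arange(n),
        "time_s": trace.times,
        "raw_px": raw.values if raw is not None else (
            np.full(n, np.nan) if is_norm else trace.values),
        "closure": trace.values if is_norm else np.full(n, np.nan),
    }).to_csv(path, index=False)


def read_trace_csv(path, sampling_rate: float | None = None) -> EyelidTrace:
    df = pd.read_csv(path)
    if sampling_rate is None:
        dt = np.diff(df["time_s"].to_numpy())
        sampling_rate = 1.0 / float(np.median(dt))
    return EyelidTrace(df["closure"].to_numpy(), sampling_rate)


def write_cohort(cohort, outdir, traces: bool = True,
                 fmt: str = "csv") -> Path:
    """Write a simulated cohort: trial table, traces, and manifest.

    ``fmt='csv'`` stores one trace file per trial under ``traces/``;
    ``fmt='hdf5'`` stores one HDF5 file per (mouse, session).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = cohort.table.copy()
    if traces and cohort.eyelid:
        refs = []
        if fmt == "csv":
            tdir = outdir / "traces"
            tdir.mkdir(exist_ok=True)
            for _, row in table.iterrows():
                key = (row["mouse_id"], row["session"], row["trial_index"])
                name = f"traces/{key[0]}_s{key[1]:02d}_t{key[2]:03d}.csv"
                write_trace_csv(outdir / name, cohort.eyelid[key])
                refs.append(name)
        elif fmt == "hdf5":
            tdir = outdir / "traces"
            tdir.mkdir(exist_ok=True)
            handles: dict[tuple, h5py.File] = {}
            try:
                for _, row in table.iterrows():
                    key = (row["mouse_id"], row["session"], row["trial_index"])
                    name = f"traces/{key[0]}_s{key[1]:02d}.h5"
                    if (key[0], key[1]) not in handles:
                        handles[(key[0], key[1])] = h5py.File(
                            outdir / name, "w")
                    handles[(key[0], key[1])].create_dataset(
                        f"trial_{key[2]:03d}",
                        data=cohort.eyelid[key].values)
                    refs.append(name)
            finally:
                for h in handles.values():
                    h.close()
        else:
            raise ValueError(f"unknown format {fmt!r}")
        table["trace_ref"] = refs
    table.to_csv(outdir / "trial_table.csv", index=False)
    return outdir / "trial_table.csv"


# --------------------------------------------------------------------------
# Paw tracks
# --------------------------------------------------------------------------

def write_tracks(tracks: PawTracks, path) -> None:
    """Wide track CSV with metadata in commented header lines."""
    belt = tracks.belt_speed
    if not isinstance(belt, dict):
        belt = {"left": float(belt), "right": float(belt)}
    header = (f"#context={tracks.context}\n"
              f"#frame_rate={tracks.frame_rate}\n"
              f"#belt_left={belt['left']}\n"
              f"#belt_right={belt['right']}\n")
    cols = {"time_s": tracks.times}
    for paw in PAWS:
        for j, ax in enumerate("xyz"):
            cols[f"{paw}_{ax}"] = tracks.paws[paw][:, j]
    cols["body_x"] = tracks.body_x
    with open(path, "w") as fh:
        fh.write(header)
        pd.DataFrame(cols).to_csv(fh, index=False)


def read_tracks(path) -> PawTracks:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key] = val
    df = pd.read_csv(path, comment="#")
    paws = {
        paw: np.column_stack([df[f"{paw}_{ax}"].to_numpy() for ax in "xyz"])
        for paw in PAWS
    }
    return PawTracks(
        paws=paws,
        body_x=df["body_x"].to_numpy(),
        frame_rate=float(meta.get("frame_rate", 0) or
                         1.0 / np.median(np.diff(df["time_s"]))),
        context=meta.get("context", "overground"),
        belt_speed={"left": float(meta.get("belt_left", 0.0)),
                    "right": float(meta.get("belt_right", 0.0))},
    )


# --------------------------------------------------------------------------
# Protocols (YAML)
# --------------------------------------------------------------------------

def write_protocol(protocol: AdaptationProtocol, path) -> None:
    data = {"trials": [asdict(tr) for tr in protocol.trials]}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_protocol(path) -> AdaptationProtocol:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return AdaptationProtocol([ProtocolTrial(**tr) for tr in data["trials"]])


# --------------------------------------------------------------------------
# Run configuration and manifest
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Analysis thresholds and paths; defaults follow the study's values."""

    cr_threshold: float = 0.1  # normalized closure
    stationary_threshold: float = 0.05  # m/s
    walking_threshold: float = 0.01  # m/s
    contact_height: float = 1.0  # mm
    speed_bin_edges: list[float] = field(
        default_factory=lambda: [0.0, 0.025, 0.05, 0.075, 0.1, 0.125, 0.15,
                                 0.2, 0.3])
    activity_split_m: float = 150.0  # m/session "top runner" threshold
    seed: int = 0
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(outdir, config: dict, seed: int) -> Path:
    """Machine-readable run manifest: config (and its hash), seed, versions."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config,
        "config_sha256": config_hash(config),
        "seed": int(seed),
        "versions": {
            "locoblink": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
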