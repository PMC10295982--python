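"""Plain-text artifact formats: trial CSVs, angle CSVs, manifests.

A trial is stored as a long-format CSV (`t,sensor,x,y,z,azimuth,
elevation,roll`) with a JSON sidecar holding the metadata, the seed
and the sensor mounting rotations; synthetic ground truth goes into a
companion ``*_truth.csv``.  Every artifact carries the hash of the
configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import ANGLE_NAMES, SENSORS, TrialSeries
from .preprocessing import N_NORMALIZED, NormalizedTrial
from .synthetic import TrialMeta, TrialRecord

TRIAL_COLUMNS = ["t", "sensor", "x", "y", "z", "azimuth", "elevation", "roll"]


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def trial_basename(meta: TrialMeta) -> str:
    return (
        f"s{meta.subject}_{meta.object}_{meta.origin}-{meta.destination}"
        f"_r{meta.repetition}"
    )


def write_trial_csv(trial: TrialRecord, directory: str | Path) -> Path:
    """Write one trial (pose CSV + metadata sidecar + truth CSV)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = trial_basename(trial.meta)
    frames = []
    for sensor in SENSORS:
        df = pd.DataFrame(trial.sensors[sensor],
                          columns=["x", "y", "z", "azimuth", "elevation", "roll"])
        df.insert(0, "sensor", sensor)
        df.insert(0, "t", trial.t)
        frames.append(df)
    pd.concat(frames).to_csv(directory / f"{base}.csv", index=False)

    sidecar = {
        "subject": trial.meta.subject,
        "object": trial.meta.object,
        "origin": trial.meta.origin,
        "destination": trial.meta.destination,
        "repetition": trial.meta.repetition,
        "seed": trial.seed,
        "mounts": {k: v.tolist() for k, v in (trial.mounts or {}).items()},
    }
    (directory / f"{base}.json").write_text(json.dumps(sidecar, indent=1))

    if trial.truth_angles is not None:
        truth = pd.DataFrame(trial.truth_angles, columns=list(ANGLE_NAMES))
        truth.insert(0, "t", trial.t)
        truth["is_grasp"] = 0
        truth["is_release"] = 0
        truth.loc[trial.grasp_index, "is_grasp"] = 1
        truth.loc[trial.release_index, "is_release"] = 1
        truth.to_csv(directory / f"{base}_truth.csv", index=False)
    return directory / f"{base}.csv"


def read_trial_csv(path: str | Path) -> TrialRecord:
    """Read a trial written by :func:`write_trial_csv`."""
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    meta = TrialMeta(
        subject=int(sidecar["subject"]),
        object=sidecar["object"],
        origin=sidecar["origin"],
        destination=sidecar["destination"],
        repetition=int(sidecar["repetition"]),
    )
    sensors = {}
    t = None
    for sensor, part in df.groupby("sensor", sort=False):
        sensors[sensor] = part[["x", "y", "z", "azimuth", "elevation", "roll"]
                               ].to_numpy()
        t = part["t"].to_numpy()
    mounts = {k: np.array(v) for k, v in sidecar.get("mounts", {}).items()} or None

    truth_path = path.with_name(path.stem + "_truth.csv")
    truth_angles = grasp_index = release_index = None
    if truth_path.exists():
        truth = pd.read_csv(truth_path)
        truth_angles = truth[list(ANGLE_NAMES)].to_numpy()
        grasp_index = int(truth.index[truth["is_grasp"] == 1][0])
        release_index = int(truth.index[truth["is_release"] == 1][0])
    return TrialRecord(
        meta=meta, t=t, sensors=sensors, mounts=mounts,
        truth_angles=truth_angles, grasp_index=grasp_index,
        release_index=release_index, seed=sidecar.get("seed"),
    )


def write_study_manifest(paths: list, design: dict, directory: str | Path,
                         cfg_hash: str = "") -> Path:
    directory = Path(directory)
    manifest = {
        "config_hash": cfg_hash,
        "design": design,
        "trials": [str(Path(p).name) for p in paths],
    }
    out = directory / "manifest.json"
    out.write_text(json.dumps(manifest, indent=1))
    return out


def write_angles_csv(ts: TrialSeries, directory: str | Path,
                     cfg_hash: str = "") -> Path:
    """Angle CSV with a provenance header comment line."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = trial_basename(ts.meta)
    df = pd.DataFrame(ts.angles, columns=list(ANGLE_NAMES))
    df.insert(0, "t", ts.t)
    for i, c in enumerate(("hand_x", "hand_y", "hand_z")):
        df[c] = ts.hand_pos[:, i]
    out = directory / f"{base}.csv"
    with open(out, "w") as fh:
        fh.write(f"# provenance={','.join(ts.provenance)} config={cfg_hash}\n")
        df.to_csv(fh, index=False)
    return out


def write_normalized_csv(nt: NormalizedTrial, directory: str | Path,
                         cfg_hash: str = "") -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = trial_basename(nt.meta)
    df = pd.DataFrame(nt.angles, columns=list(ANGLE_NAMES))
    df.insert(0, "tau", nt.tau)
    for i, c in enumerate(("hand_x", "hand_y", "hand_z")):
        df[c] = nt.hand_pos[:, i]
    out = directory / f"{base}.csv"
    meta = {
        "provenance": list(nt.provenance),
        "config": cfg_hash,
        "pk": nt.pk, "pl": nt.pl,
        "true_pk": nt.true_pk, "true_pl": nt.true_pl,
        "offsets": None if nt.offsets is None else list(np.round(nt.offsets, 9)),
    }
    with open(out, "w") as fh:
        fh.write(f"# {json.dumps(meta)}\n")
        df.to_csv(fh, index=False)
    return out


def read_normalized_csv(path: str | Path, meta: TrialMeta) -> NormalizedTrial:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
        df = pd.read_csv(fh)
    info = json.loads(header)
    return NormalizedTrial(
        meta=meta,
        tau=df["tau"].to_numpy(),
        angles=df[list(ANGLE_NAMES)].to_numpy(),
        hand_pos=df[["hand_x", "hand_y", "hand_z"]].to_numpy(),
        pk=info.get("pk"), pl=info.get("pl"),
        true_pk=info.get("true_pk"), true_pl=info.get("true_pl"),
        offsets=None if info.get("offsets") is None else np.array(info["offsets"]),
        provenance=tuple(info.get("provenance", ())),
    )


def parse_trial_filename(name: str) -> TrialMeta:
    """Inverse of :func:`trial_basename`."""
    stem = Path(name).stem
    subject, obj, od, rep = stem.split("_")
    origin, destination = od.split("-")
    return TrialMeta(
        subject=int(subject[1:]), object=obj, origin=origin,
        destination=destination, repetition=int(rep[1:]),
    )
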