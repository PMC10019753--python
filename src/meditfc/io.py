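"""Reading and writing recordings.

Native on-disk dialect: one channels x samples CSV per subject plus a
JSON sidecar carrying montage, sampling rate, group label and the state
schedule. The sidecar schema is versioned. EDF files are read through
MNE's built-in reader when available; the montage/hemisphere assignment
then comes from a two-column montage CSV (label, hemisphere).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np

from .synthetic import EEGRecording

SIDECAR_SCHEMA_VERSION = 1


def save_recording(rec: EEGRecording, directory: str | Path) -> tuple[Path, Path]:
    """Write ``<subject>.csv`` (rows = channels) and ``<subject>.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / f"{rec.subject_id}.csv"
    json_path = directory / f"{rec.subject_id}.json"
    np.savetxt(csv_path, rec.data, delimiter=",", fmt="%.6e")
    sidecar = {
        "schema_version": SIDECAR_SCHEMA_VERSION,
        "subject_id": rec.subject_id,
        "group": rec.group,
        "sampling_rate": rec.sampling_rate,
        "montage": [{"label": lab, "hemisphere": h} for lab, h in rec.montage],
        "schedule": [
            {"state": s, "start": int(a), "end": int(b)} for s, a, b in rec.schedule
        ],
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    return csv_path, json_path


def load_recording(csv_path: str | Path) -> EEGRecording:
    """Load a recording from the CSV + JSON sidecar dialect."""
    csv_path = Path(csv_path)
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    version = sidecar.get("schema_version")
    if version != SIDECAR_SCHEMA_VERSION:
        raise ValueError(f"unsupported sidecar schema version: {version}")
    data = np.loadtxt(csv_path, delimiter=",", ndmin=2)
    return EEGRecording(
        subject_id=sidecar["subject_id"],
        group=sidecar["group"],
        montage=[(m["label"], m["hemisphere"]) for m in sidecar["montage"]],
        sampling_rate=float(sidecar["sampling_rate"]),
        data=data,
        schedule=[(e["state"], e["start"], e["end"]) for e in sidecar["schedule"]],
    )


def read_montage_map(path: str | Path) -> dict[str, str]:
    """Read a two-column CSV (label, hemisphere) into a montage map.

    Hemisphere values are ``left``/``right``/``drop``; a header row is
    detected and skipped.
    """
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        label, side = (part.strip() for part in line.split(",")[:2])
        if label.lower() in ("label", "channel") and side.lower() in ("hemisphere", "side"):
            continue
        if side not in ("left", "right", "drop"):
            raise ValueError(f"unknown hemisphere tag {side!r} for channel {label!r}")
        out[label] = side
    return out


def read_edf(
    path: str | Path,
    montage_map: Mapping[str, str],
    schedule: list[tuple[str, int, int]],
    *,
    group: str = "NM",
    subject_id: str | None = None,
) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording`.

    Only the channels tagged left/right in ``montage_map`` are retained;
    a state ``schedule`` (sample intervals) must be supplied because EDF
    carries no session structure of its own.
    """
    import mne  # local import: heavy, optional for the synthetic pipeline

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = raw.ch_names
    keep = [lab for lab in labels if montage_map.get(lab) in ("left", "right")]
    missing = [lab for lab, side in montage_map.items()
               if side in ("left", "right") and lab not in labels]
    if missing:
        raise ValueError(f"montage_map channels absent from EDF: {missing}")
    data = raw.get_data(picks=keep)
    montage = [(lab, montage_map[lab]) for lab in keep]
    return EEGRecording(
        subject_id=subject_id or Path(path).stem,
        group=group,
        montage=montage,
        sampling_rate=float(raw.info["sfreq"]),
        data=np.asarray(data, dtype=float),
        schedule=list(schedule),
    )
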