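"""Plain-text I/O for recordings, events, hypnograms and cohort manifests.

Recordings are stored as CSV with a small ``#``-prefixed header (rate,
reference note, optional montage) and one column per channel — adequate for
desk-scale synthetic data; a clinical EDF ingest would slot in behind
``load_recording`` without touching anything downstream.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core_signal import Recording, StageSeries

__all__ = [
    "save_recording",
    "load_recording",
    "save_events",
    "load_events",
    "save_hypnogram",
    "load_hypnogram",
    "save_montage",
    "load_montage",
    "FileCohort",
    "load_cohort",
]


def save_recording(rec: Recording, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# rate={rec.rate}\n")
        fh.write(f"# reference={rec.reference_note}\n")
        if rec.montage is not None:
            mont = ";".join(
                f"{c}:{rec.montage[c][0]}:{rec.montage[c][1]}" for c in rec.channel_labels
            )
            fh.write(f"# montage={mont}\n")
        fh.write(",".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.data.T, delimiter=",", fmt="%.6f")


def load_recording(path) -> Recording:
    path = Path(path)
    rate = None
    reference = "as recorded"
    montage = None
    n_header = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, val = line[1:].strip().partition("=")
            key = key.strip()
            if key == "rate":
                rate = float(val)
            elif key == "reference":
                reference = val
            elif key == "montage":
                montage = {}
                for item in val.split(";"):
                    c, x, y = item.split(":")
                    montage[c] = (float(x), float(y))
    if rate is None:
        raise ValueError(f"{path}: missing '# rate=' header")
    df = pd.read_csv(path, skiprows=n_header)
    return Recording(
        data=df.to_numpy().T,
        rate=rate,
        channel_labels=list(df.columns),
        montage=montage,
        reference_note=reference,
    )


def save_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def load_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "onset_s" not in df.columns or "condition" not in df.columns:
        raise ValueError(f"{path}: events need onset_s and condition columns")
    df["condition"] = df["condition"].astype(str)
    return df


def save_hypnogram(stages: StageSeries, path) -> None:
    pd.DataFrame(
        {"epoch": np.arange(len(stages)), "stage": list(stages.labels)}
    ).to_csv(path, index=False)


def load_hypnogram(path, epoch_length: float = 30.0) -> StageSeries:
    df = pd.read_csv(path)
    return StageSeries(labels=list(df["stage"].astype(str)), epoch_length=epoch_length)


def save_montage(montage: dict, path) -> None:
    rows = [{"label": c, "x": xy[0], "y": xy[1]} for c, xy in montage.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_montage(path) -> dict:
    df = pd.read_csv(path)
    return {r.label: (float(r.x), float(r.y)) for r in df.itertuples()}


class FileCohort:
    """Cohort backed by files on disk, mirroring the synthetic Cohort API.

    The manifest CSV needs per-subject columns: subject_id, group, age,
    sleep_recording, hypnogram, p50_recording, p50_events, assr_recording,
    assr_events. Referenced files are checked at load time.
    """

    def __init__(self, manifest: pd.DataFrame, root: Path):
        self.manifest = manifest
        self.root = root
        required = {"subject_id", "group", "age"}
        if not required <= set(manifest.columns):
            raise ValueError(f"manifest needs columns {sorted(required)}")
        if manifest["subject_id"].duplicated().any():
            raise ValueError("duplicate subject ids in manifest")
        file_cols = [c for c in manifest.columns if c.endswith(("recording", "events", "hypnogram"))]
        for _, row in manifest.iterrows():
            for c in file_cols:
                p = root / str(row[c])
                if not p.exists():
                    raise FileNotFoundError(f"manifest references missing file {p}")

    def iter_subjects(self):
        from .synthetic import SubjectData, SubjectSpec

        for _, row in self.manifest.iterrows():
            spec = SubjectSpec(
                subject_id=row["subject_id"], group=row["group"], age=float(row["age"])
            )
            yield SubjectData(
                spec=spec,
                sleep=(
                    load_recording(self.root / row["sleep_recording"]),
                    load_hypnogram(self.root / row["hypnogram"]),
                    pd.DataFrame(),
                ),
                p50=(
                    load_recording(self.root / row["p50_recording"]),
                    load_events(self.root / row["p50_events"]),
                ),
                assr=(
                    load_recording(self.root / row["assr_recording"]),
                    load_events(self.root / row["assr_events"]),
                ),
            )


def load_cohort(manifest_path) -> FileCohort:
    manifest_path = Path(manifest_path)
    return FileCohort(pd.read_csv(manifest_path), manifest_path.parent)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
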