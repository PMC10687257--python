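"""On-disk session format: JSON manifests + CSV recording tables.

Layout of a cohort directory::

    cohort/
      index.json                 # subject list + generation parameters
      S0000/
        manifest.json            # labels, site, recording file table
        p01_center_body.csv      # landmark table: frame,joint,x,y
        p08_center_voice.csv     # MFCC table: frame,c1..c25
      ...

CSV is the canonical interchange format; everything written here is
re-readable by :func:`read_session` / :func:`read_cohort`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import protocols as P
from .data_model import (
    Camera,
    Disease,
    LandmarkSequence,
    ProtocolLabel,
    ProtocolRecording,
    Site,
    SubjectSession,
    VoiceFeatureSequence,
)


def landmark_frame(seq: LandmarkSequence) -> pd.DataFrame:
    frames, joints = seq.frames, seq.joints
    frame_idx = np.repeat(np.arange(frames), joints)
    joint_idx = np.tile(np.arange(joints), frames)
    flat = seq.array.reshape(-1, 2)
    return pd.DataFrame(
        {"frame": frame_idx, "joint": joint_idx, "x": flat[:, 0], "y": flat[:, 1]}
    )


def landmark_from_frame(df: pd.DataFrame, part: str, fps: float = 30.0) -> LandmarkSequence:
    frames = int(df["frame"].max()) + 1
    joints = int(df["joint"].max()) + 1
    arr = np.full((frames, joints, 2), np.nan)
    arr[df["frame"].to_numpy(), df["joint"].to_numpy(), 0] = df["x"].to_numpy()
    arr[df["frame"].to_numpy(), df["joint"].to_numpy(), 1] = df["y"].to_numpy()
    return LandmarkSequence(part=part, array=arr, fps=fps)


def mfcc_frame(seq: VoiceFeatureSequence) -> pd.DataFrame:
    cols = {f"c{i + 1}": seq.array[:, i] for i in range(seq.channels)}
    return pd.DataFrame({"frame": np.arange(seq.frames), **cols})


def mfcc_from_frame(df: pd.DataFrame) -> VoiceFeatureSequence:
    cols = [c for c in df.columns if c.startswith("c")]
    cols.sort(key=lambda c: int(c[1:]))
    return VoiceFeatureSequence(df[cols].to_numpy(dtype=float))


def _recording_files(rec: ProtocolRecording) -> dict:
    stem = f"p{rec.protocol_id:02d}_{rec.camera.value}"
    files = {}
    for part in rec.landmarks:
        files[part] = f"{stem}_{part}.csv"
    if rec.voice is not None:
        files["voice"] = f"{stem}_voice.csv"
    return files


def write_session(session: SubjectSession, out_dir: Path) -> Path:
    out_dir = Path(out_dir)
    subject_dir = out_dir / session.subject_id
    subject_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subject_id": session.subject_id,
        "disease_label": session.disease_label.value,
        "site": session.site.value,
        "protocol_labels": [l.value for l in session.protocol_labels],
        "recordings": [],
    }
    for rec in session.recordings:
        files = _recording_files(rec)
        entry = {
            "protocol_id": rec.protocol_id,
            "camera": rec.camera.value,
            "files": files,
        }
        for part, seq in rec.landmarks.items():
            landmark_frame(seq).to_csv(subject_dir / files[part], index=False)
            entry["fps"] = seq.fps
        if rec.voice is not None:
            mfcc_frame(rec.voice).to_csv(subject_dir / files["voice"], index=False)
        manifest["recordings"].append(entry)
    (subject_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return subject_dir


def read_session(subject_dir: Path) -> SubjectSession:
    subject_dir = Path(subject_dir)
    manifest = json.loads((subject_dir / "manifest.json").read_text())
    recordings = []
    for entry in manifest["recordings"]:
        landmarks = {}
        voice = None
        fps = entry.get("fps", 30.0)
        for key, fname in entry["files"].items():
            df = pd.read_csv(subject_dir / fname)
            if key == "voice":
                voice = mfcc_from_frame(df)
            else:
                landmarks[key] = landmark_from_frame(df, key, fps)
        recordings.append(
            ProtocolRecording(
                entry["protocol_id"], Camera(entry["camera"]), landmarks, voice
            )
        )
    return SubjectSession(
        subject_id=manifest["subject_id"],
        disease_label=Disease(manifest["disease_label"]),
        protocol_labels=tuple(
            ProtocolLabel(l) for l in manifest["protocol_labels"]
        ),
        recordings=tuple(recordings),
        site=Site(manifest["site"]),
    )


def write_cohort(sessions, out_dir: Path, meta: dict | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for session in sessions:
        write_session(session, out_dir)
    index = {
        "subjects": [s.subject_id for s in sessions],
        "counts": {
            d.value: sum(1 for s in sessions if s.disease_label is d)
            for d in Disease
        },
        "meta": meta or {},
    }
    (out_dir / "index.json").write_text(json.dumps(index, indent=1))
    return out_dir


def read_cohort(cohort_dir: Path) -> list[SubjectSession]:
    cohort_dir = Path(cohort_dir)
    index = json.loads((cohort_dir / "index.json").read_text())
    return [read_session(cohort_dir / sid) for sid in index["subjects"]]
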