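"""File exchange: raw recordings (CSV, EDF/EDF+), label tables, preprocessed
sample tables, and run manifests.

CSV layout for raw EEG: a ``# key=value`` header line carrying the sampling
rate and subject id, then columns ``time, L1, L2, R1, R2`` (microvolts).
EDF/EDF+ reading goes through MNE when it is installed; all writing here is
plain text so datasets round-trip losslessly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Sample, Segment
from .synth import CHANNEL_NAMES, DepthTrajectory, EEGRecord, SubjectData

_EDF_SUFFIXES = {".edf", ".bdf"}


def read_eeg(path: str | Path) -> EEGRecord:
    """Load a 4-channel recording from CSV or EDF/EDF+.

    Channels are returned in L1, L2, R1, R2 order; missing channels or a
    missing sampling rate raise with the offending field named.
    """
    path = Path(path)
    if path.suffix.lower() in _EDF_SUFFIXES:
        return _read_edf(path)
    with open(path) as fh:
        first = fh.readline()
    meta = {}
    if first.startswith("#"):
        for tok in first[1:].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
    df = pd.read_csv(path, comment="#")
    missing = [c for c in CHANNEL_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"CSV is missing channel column(s): {', '.join(missing)}")
    if "fs" in meta:
        fs = float(meta["fs"])
    elif "time" in df.columns and len(df) > 1:
        fs = 1.0 / float(np.median(np.diff(df["time"].to_numpy())))
    else:
        raise ValueError("sampling rate not found: no '# fs=' header and no time column")
    data = np.vstack([df[c].to_numpy(dtype=float) for c in CHANNEL_NAMES])
    return EEGRecord(data=data, fs=fs, subject_id=meta.get("subject", path.stem))


def _read_edf(path: Path) -> EEGRecord:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    missing = [c for c in CHANNEL_NAMES if c not in raw.ch_names]
    if missing:
        raise ValueError(f"EDF is missing channel(s): {', '.join(missing)}")
    raw.pick([*CHANNEL_NAMES])
    data = raw.get_data() * 1e6  # MNE returns volts
    return EEGRecord(data=data, fs=float(raw.info["sfreq"]), subject_id=path.stem)


def write_eeg_csv(record: EEGRecord, path: str | Path) -> None:
    path = Path(path)
    t = np.arange(record.n_samples) / record.fs
    df = pd.DataFrame({"time": t})
    for i, c in enumerate(CHANNEL_NAMES):
        df[c] = record.data[i]
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs} subject={record.subject_id}\n")
        df.to_csv(fh, index=False)


def write_dataset(subjects: list[SubjectData], out_dir: str | Path) -> None:
    """One CSV per subject plus a per-segment label table and trajectories."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sub in subjects:
        rec = sub.record
        write_eeg_csv(rec, out / f"{rec.subject_id}.csv")
        traj = sub.trajectory
        pd.DataFrame(
            {"time": traj.times, "depth": traj.depth, "psi": traj.psi}
        ).to_csv(out / f"{rec.subject_id}_trajectory.csv", index=False)
        win = int(np.floor(4.0 * rec.fs))
        hop = win // 2
        for start in range(0, rec.n_samples - win + 1, hop):
            mid = (start + win / 2) / rec.fs
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "segment_start_s": start / rec.fs,
                    "psi": float(traj.psi_at(np.array([mid]))[0]),
                }
            )
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)


def load_dataset(in_dir: str | Path) -> list[SubjectData]:
    in_dir = Path(in_dir)
    subjects = []
    for traj_path in sorted(in_dir.glob("*_trajectory.csv")):
        sid = traj_path.name.replace("_trajectory.csv", "")
        rec = read_eeg(in_dir / f"{sid}.csv")
        tdf = pd.read_csv(traj_path)
        traj = DepthTrajectory(
            times=tdf["time"].to_numpy(), depth=tdf["depth"].to_numpy()
        )
        subjects.append(SubjectData(record=rec, trajectory=traj))
    if not subjects:
        raise FileNotFoundError(f"no '<subject>_trajectory.csv' files in {in_dir}")
    return subjects


def write_samples(samples: list[Sample], path: str | Path) -> None:
    """Flattened (2848-column) cleaned windows with labels, one CSV."""
    n = len(samples)
    if n == 0:
        raise ValueError("no samples to write")
    width = samples[0].segment.data.size
    mat = np.empty((n, width + 3))
    for i, s in enumerate(samples):
        mat[i, 0] = s.segment.start_time
        mat[i, 1] = s.psi
        mat[i, 2] = s.segment.fs
        mat[i, 3:] = s.segment.data.ravel()
    header = "start_time,psi,fs," + ",".join(f"x{j}" for j in range(width))
    np.savetxt(path, mat, delimiter=",", header=header, comments="")


def read_samples(path: str | Path, subject_id: str = "S00") -> list[Sample]:
    mat = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    out = []
    for row in mat:
        width = row.size - 3
        seg = Segment(
            data=row[3:].reshape(4, width // 4),
            fs=row[2],
            start_time=row[0],
            subject_id=subject_id,
        )
        out.append(Sample(segment=seg, psi=row[1]))
    return out


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(path: str | Path, config: dict, seed: int | None = None) -> None:
    import doaeeg

    manifest = {
        "config": config,
        "config_hash": config_hash(config),
        "seed": seed,
        "version": doaeeg.__version__,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
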