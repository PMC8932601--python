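"""Dataset I/O: CSV recordings with JSON sidecars, manifests, and EDF.

CSV layout: one file per recording, columns = channel names, rows = samples
(uV), plus a ``<stem>.json`` sidecar holding fs, ids, scores and (for
synthetic data) the latent ground-truth level. A dataset manifest lists every
recording pair.

EDF: a minimal single-record-per-second 16-bit EDF+ compatible writer is
implemented here (no installed package exports EDF); reading goes through
``mne`` when available.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import Recording, TrialScores


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _rec_stem(rec: Recording) -> str:
    return f"{rec.subject_id}_{rec.trial_id}"


def write_recording_csv(rec: Recording, outdir: Path) -> tuple[Path, Path]:
    """Write one recording as CSV + JSON sidecar; returns both paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"{_rec_stem(rec)}.csv"
    side_path = outdir / f"{_rec_stem(rec)}.json"
    pd.DataFrame(rec.signal.T, columns=list(rec.channels)).to_csv(
        csv_path, index=False, float_format="%.6f")
    sidecar = {
        "subject_id": rec.subject_id,
        "trial_id": rec.trial_id,
        "fs": rec.fs,
        "channels": list(rec.channels),
        "scores": {"valence": rec.scores.valence,
                   "arousal": rec.scores.arousal,
                   "ham_a": rec.scores.ham_a},
        "ground_truth_level": rec.ground_truth_level,
    }
    side_path.write_text(json.dumps(sidecar, indent=1))
    return csv_path, side_path


def write_dataset(recordings: list[Recording], outdir: Path) -> Path:
    """Write every recording plus a dataset-level manifest; returns its path."""
    outdir = Path(outdir)
    entries = []
    for rec in recordings:
        csv_path, side_path = write_recording_csv(rec, outdir)
        entries.append({"subject_id": rec.subject_id,
                        "trial_id": rec.trial_id,
                        "csv": csv_path.name,
                        "sidecar": side_path.name})
    manifest = outdir / "dataset_manifest.json"
    manifest.write_text(json.dumps({"n_recordings": len(entries),
                                    "recordings": entries}, indent=1))
    return manifest


def read_recording_csv(csv_path: Path) -> Recording:
    """Read one CSV + sidecar pair back into a Recording."""
    csv_path = Path(csv_path)
    side_path = csv_path.with_suffix(".json")
    if not side_path.exists():
        raise FileNotFoundError(f"missing sidecar {side_path}")
    meta = json.loads(side_path.read_text())
    df = pd.read_csv(csv_path)
    expected = meta["channels"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"recording {csv_path.name} is missing channel(s) {missing}")
    rec = Recording(
        subject_id=meta["subject_id"],
        trial_id=meta["trial_id"],
        signal=df[expected].to_numpy(dtype=float).T,
        fs=float(meta["fs"]),
        channels=tuple(expected),
        scores=TrialScores(**meta["scores"]),
        ground_truth_level=meta.get("ground_truth_level"),
    )
    rec.validate()
    return rec


def read_recordings(path: Path, expected_channels=None,
                    expected_fs: float | None = None) -> list[Recording]:
    """Read a dataset manifest, a directory of CSV pairs, or a single EDF file.

    Optionally verifies channel names and the declared sampling rate.
    """
    path = Path(path)
    if path.is_file() and path.suffix.lower() == ".edf":
        recs = [read_recording_edf(path)]
    elif path.is_file() and path.name.endswith(".json"):
        meta = json.loads(path.read_text())
        recs = [read_recording_csv(path.parent / e["csv"])
                for e in meta["recordings"]]
    elif path.is_dir():
        manifest = path / "dataset_manifest.json"
        if manifest.exists():
            return read_recordings(manifest, expected_channels, expected_fs)
        recs = [read_recording_csv(p) for p in sorted(path.glob("*.csv"))]
    else:
        raise FileNotFoundError(f"cannot read recordings from {path}")
    for rec in recs:
        if expected_channels is not None:
            missing = [c for c in expected_channels if c not in rec.channels]
            if missing:
                raise ValueError(
                    f"{rec.subject_id}/{rec.trial_id}: missing channel(s) {missing}")
        if expected_fs is not None and rec.fs != expected_fs:
            raise ValueError(
                f"{rec.subject_id}/{rec.trial_id}: fs {rec.fs} != declared {expected_fs}")
    return recs


# --- EDF ---------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_recording_edf(rec: Recording, path: Path) -> Path:
    """Write a recording as 16-bit EDF (one 1-s data record per second).

    Physical units are uV with a symmetric physical range derived from the
    data, so round-tripping is exact up to 16-bit quantization. Requires an
    integer sampling rate and a whole number of seconds.
    """
    path = Path(path)
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n = rec.n_samples
    if n % fs:
        raise ValueError("EDF export requires a whole number of seconds")
    n_records = n // fs
    n_sig = len(rec.channels)

    phys_max = float(np.max(np.abs(rec.signal)))
    phys_max = max(phys_max, 1e-6)
    dig_max, dig_min = 32767, -32768
    scale = dig_max / phys_max
    digital = np.clip(np.round(rec.signal * scale), dig_min, dig_max).astype("<i2")

    header = b"".join([
        _edf_field("0", 8),
        _edf_field(f"{rec.subject_id}", 80),
        _edf_field(f"{rec.subject_id} {rec.trial_id}", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (1 + n_sig), 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_field(1, 8),                      # record duration, s
        _edf_field(n_sig, 4),
    ])
    per_sig = b"".join([
        b"".join(_edf_field(ch, 16) for ch in rec.channels),
        b"".join(_edf_field("", 80) for _ in rec.channels),      # transducer
        b"".join(_edf_field("uV", 8) for _ in rec.channels),
        b"".join(_edf_field(f"{-phys_max:.6g}"[:8], 8) for _ in rec.channels),
        b"".join(_edf_field(f"{phys_max:.6g}"[:8], 8) for _ in rec.channels),
        b"".join(_edf_field(dig_min, 8) for _ in rec.channels),
        b"".join(_edf_field(dig_max, 8) for _ in rec.channels),
        b"".join(_edf_field("", 80) for _ in rec.channels),      # prefiltering
        b"".join(_edf_field(fs, 8) for _ in rec.channels),
        b"".join(_edf_field("", 32) for _ in rec.channels),
    ])
    with open(path, "wb") as f:
        f.write(header)
        f.write(per_sig)
        for r in range(n_records):
            block = digital[:, r * fs:(r + 1) * fs]
            f.write(block.tobytes())            # channel-sequential per record
    return path


def read_recording_edf(path: Path, scores: TrialScores | None = None) -> Recording:
    """Read an EDF file via mne; signals are returned in uV."""
    try:
        import mne
    except ImportError as exc:   # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    signal = raw.get_data() * 1e6    # mne loads EEG in volts
    return Recording(
        subject_id=Path(path).stem,
        trial_id="T01",
        signal=signal,
        fs=float(raw.info["sfreq"]),
        channels=tuple(raw.ch_names),
        scores=scores or TrialScores(valence=5.0, arousal=5.0, ham_a=0),
        ground_truth_level=None,
    )


def write_labels_csv(label_rows: list[dict], path: Path) -> Path:
    """Write per-trial labels (subject_id, trial_id, scheme, granularity, class)."""
    pd.DataFrame(label_rows).to_csv(path, index=False)
    return Path(path)
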