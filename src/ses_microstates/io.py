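"""Readers and writers.

Two recording formats are supported:

* **Delimited matrix + JSON sidecar** — a TSV with one column per channel
  (header row = channel names) and one row per sample, next to
  ``<stem>.json`` holding ``fs``, ``channel_names`` and the epoch table.
  Plain text, lossless for our purposes, and the canonical interchange for
  this package.
* **EDF** — read through MNE; written by a small built-in EDF writer
  (16-bit, one data record per second) so simulated cohorts can be exchanged
  with standard EEG tooling.  EDF quantizes to the stored physical range.

Units are microvolts everywhere.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Recording, Segmentation, TemplateSet


# ---------------------------------------------------------------------------
# delimited matrix + JSON sidecar


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording_tsv(rec: Recording, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=rec.ch_names)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    sidecar = {
        "fs": rec.fs,
        "channel_names": list(rec.ch_names),
        "epochs": [[int(a), int(b)] for a, b in rec.epochs],
        "unit": "uV",
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording_tsv(path: str | Path) -> Recording:
    path = Path(path)
    side_path = _sidecar_path(path)
    if not side_path.exists():
        raise FileNotFoundError(f"missing JSON sidecar {side_path}")
    side = json.loads(side_path.read_text())
    for key in ("fs", "channel_names"):
        if key not in side:
            raise ValueError(f"sidecar {side_path} missing required field '{key}'")
    if side["fs"] <= 0:
        raise ValueError(f"sidecar {side_path}: fs must be positive")
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != list(side["channel_names"]):
        raise ValueError(f"{path}: column header does not match sidecar channel_names")
    data = df.to_numpy(dtype=float).T
    epochs = [tuple(e) for e in side.get("epochs", [])]
    return Recording(data=data, fs=float(side["fs"]), ch_names=list(side["channel_names"]),
                     epochs=epochs)


# ---------------------------------------------------------------------------
# EDF


def _ascii(value, width: int) -> bytes:
    s = f"{value}"[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a recording as plain EDF (16-bit), one data record per second.

    The sampling rate must be an integer; the trailing partial second, if
    any, is zero-padded.  Epoch structure is not representable in plain EDF
    and should travel via the sidecar/TSV format when it matters.
    """
    path = Path(path)
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    C, T = rec.data.shape
    n_rec = int(np.ceil(T / fs))
    data = np.zeros((C, n_rec * fs))
    data[:, :T] = rec.data
    pmax = float(np.max(np.abs(data)))
    pmax = max(pmax, 1e-6)
    dig_max, dig_min = 32767, -32768
    scaled = np.round(data / pmax * dig_max).clip(dig_min, dig_max).astype("<i2")

    header = b"".join([
        _ascii("0", 8), _ascii("X X X X", 80), _ascii("Startdate X X X X", 80),
        _ascii("01.01.00", 8), _ascii("00.00.00", 8),
        _ascii(256 * (1 + C), 8), _ascii("", 44),
        _ascii(n_rec, 8), _ascii(1, 8), _ascii(C, 4),
    ])
    sig = b"".join([
        b"".join(_ascii(n, 16) for n in rec.ch_names),
        b"".join(_ascii("AgAgCl electrode", 80) for _ in range(C)),
        b"".join(_ascii("uV", 8) for _ in range(C)),
        b"".join(_ascii(f"{-pmax:.6g}"[:8], 8) for _ in range(C)),
        b"".join(_ascii(f"{pmax:.6g}"[:8], 8) for _ in range(C)),
        b"".join(_ascii(dig_min, 8) for _ in range(C)),
        b"".join(_ascii(dig_max, 8) for _ in range(C)),
        b"".join(_ascii("", 80) for _ in range(C)),
        b"".join(_ascii(fs, 8) for _ in range(C)),
        b"".join(_ascii("", 32) for _ in range(C)),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_rec):
            fh.write(scaled[:, r * fs:(r + 1) * fs].tobytes())
    return path


def read_recording_edf(path: str | Path, epoch_s: float | None = None) -> Recording:
    """Read an EDF file via MNE; optional fixed-length epoch table."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE returns volts
    fs = float(raw.info["sfreq"])
    epochs: list[tuple[int, int]] = []
    if epoch_s is not None:
        step = int(round(epoch_s * fs))
        epochs = [(a, min(a + step, data.shape[1]))
                  for a in range(0, data.shape[1], step)]
    return Recording(data=data, fs=fs, ch_names=list(raw.ch_names), epochs=epochs)


def read_recording(path: str | Path, epoch_s: float | None = None) -> Recording:
    """Dispatch on extension: ``.edf`` via MNE, anything else TSV + sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_recording_edf(path, epoch_s=epoch_s)
    return read_recording_tsv(path)


# ---------------------------------------------------------------------------
# templates / segmentations / tables


def write_templates(tset: TemplateSet, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(tset.to_dict(), indent=1))
    return path


def read_templates(path: str | Path) -> TemplateSet:
    return TemplateSet.from_dict(json.loads(Path(path).read_text()))


def write_segmentation(seg: Segmentation, class_names: list[str], path: str | Path,
                       subject: str = "") -> Path:
    """Run-list TSV: subject, epoch, class, start_ms, duration_ms, truncated."""
    path = Path(path)
    epoch_of = np.zeros(seg.n_samples, dtype=int)
    for i, (a, b) in enumerate(seg.epochs):
        epoch_of[a:b] = i
    rows = []
    for s in seg.segments:
        rows.append({
            "subject": subject,
            "epoch": int(epoch_of[s["start"]]),
            "class": class_names[s["label"]],
            "start_ms": s["start"] / seg.fs * 1000.0,
            "duration_ms": s["length"] / seg.fs * 1000.0,
            "truncated": bool(s["trunc_left"] or s["trunc_right"]),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.3f")
    return path


def write_label_vector(seg: Segmentation, class_names: list[str],
                       path: str | Path) -> Path:
    """Per-sample label vector, one token per line ('.' = unassigned)."""
    path = Path(path)
    names = np.array(class_names + ["."])
    path.write_text("\n".join(names[seg.labels]) + "\n")
    return path


def read_label_vector(path: str | Path, class_names: list[str], fs: float,
                      epochs: list[tuple[int, int]] | None = None) -> Segmentation:
    lookup = {name: i for i, name in enumerate(class_names)}
    lookup["."] = -1
    tokens = Path(path).read_text().split()
    labels = np.array([lookup[t] for t in tokens], dtype=int)
    return Segmentation(labels=labels, fs=fs,
                        epochs=epochs or [(0, labels.size)],
                        n_classes=len(class_names))


def read_demographics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "age", "gender",
                "parent_edu_1", "parent_edu_2", "parent_occ_1", "parent_occ_2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"demographic table missing columns: {sorted(missing)}")
    return df
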