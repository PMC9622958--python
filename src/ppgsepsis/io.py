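"""File input/output.

* A minimal WFDB reader/writer (format 16: plain-text ``.hea`` header plus
  16-bit little-endian ``.dat``), covering the subset of the format the
  pipeline needs -- single- or multi-channel records with per-signal gain,
  baseline and description.  Channel selection matches the signal
  description against a configurable list of PPG aliases.
* Subject-metadata tables as CSV.
* A per-subject segment store: stacked arrays in ``.npz`` with a CSV
  manifest and, for synthetic records, a JSON sidecar holding ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .dataset import SubjectMeta
from .preprocess import Segment
from .simulate import PPGRecord

__all__ = [
    "write_wfdb",
    "read_wfdb",
    "write_subject_table",
    "read_subject_table",
    "save_segments",
    "load_segments",
    "PPG_ALIASES",
]

PPG_ALIASES = ("PLETH",)


def write_wfdb(record: PPGRecord, out_dir, name: str,
               description: str = "PLETH", units: str = "NU") -> Path:
    """Write a single-channel record as WFDB format 16; returns the header path.

    The amplitude is digitized with a gain chosen to span the int16 range;
    physical values are recovered as ``(adc - baseline) / gain``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    x = np.asarray(record.samples, dtype=np.float64)
    scale = float(np.max(np.abs(x))) or 1.0
    gain = (2**15 - 8) / scale
    adc = np.clip(np.round(x * gain), -(2**15) + 1, 2**15 - 1).astype("<i2")
    checksum = int(np.sum(adc.astype(np.int64)) & 0xFFFF)
    if checksum >= 0x8000:
        checksum -= 0x10000

    dat = out_dir / f"{name}.dat"
    adc.tofile(dat)
    hea = out_dir / f"{name}.hea"
    fs = record.fs
    fs_str = f"{fs:g}"
    first = int(adc[0]) if adc.size else 0
    with open(hea, "w") as fh:
        fh.write(f"{name} 1 {fs_str} {adc.size}\n")
        fh.write(f"{name}.dat 16 {gain:.6f}(0)/{units} 16 0 {first} {checksum} 0 {description}\n")
    return hea


def read_wfdb(header_path, channel_names: Sequence[str] = PPG_ALIASES,
              subject_id: str = "", label: str = "unknown") -> PPGRecord:
    """Read a WFDB format-16 record and extract the PPG channel.

    Multi-channel ``.dat`` files are assumed sample-interleaved (the format's
    frame layout when all signals share the record rate).  The first signal
    whose description matches ``channel_names`` (case-insensitive) is
    returned in physical units.
    """
    header_path = Path(header_path)
    lines = [ln.strip() for ln in header_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    rec_fields = lines[0].split()
    n_sig = int(rec_fields[1])
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    sig_lines = lines[1:1 + n_sig]

    signals = []
    for ln in sig_lines:
        parts = ln.split()
        fname, fmt = parts[0], parts[1].split("x")[0]
        if fmt != "16":
            raise ValueError(f"unsupported WFDB format {fmt!r}; only format 16 is handled")
        gain_field = parts[2] if len(parts) > 2 else "200"
        gain_str = gain_field.split("/")[0]
        baseline = 0
        if "(" in gain_str:
            gain_str, base_str = gain_str.split("(")
            baseline = int(base_str.rstrip(")"))
        gain = float(gain_str) if float(gain_str) != 0 else 200.0
        # fields: file fmt gain(baseline)/units adcres adczero initval checksum blocksize description
        desc = " ".join(parts[8:]) if len(parts) > 8 else ""
        signals.append(dict(fname=fname, gain=gain, baseline=baseline, desc=desc))

    wanted = {c.upper() for c in channel_names}
    chan = next((i for i, s in enumerate(signals) if s["desc"].upper() in wanted), None)
    if chan is None:
        raise ValueError(
            f"no channel matching {sorted(wanted)} in {header_path.name}; "
            f"found {[s['desc'] for s in signals]}"
        )
    raw = np.fromfile(header_path.parent / signals[0]["fname"], dtype="<i2")
    frames = raw.size // n_sig
    adc = raw[: frames * n_sig].reshape(frames, n_sig)[:, chan].astype(np.float64)
    s = signals[chan]
    return PPGRecord(samples=(adc - s["baseline"]) / s["gain"], fs=fs,
                     subject_id=subject_id or header_path.stem, label=label)


# -- subject metadata ----------------------------------------------------

_BOOL_COLS = ("died_in_hospital", "in_matched_subset", "has_ppg")


def write_subject_table(subjects: Iterable[SubjectMeta], path) -> Path:
    rows = []
    for m in subjects:
        rows.append({
            "subject_id": m.subject_id,
            "died_in_hospital": m.died_in_hospital,
            "n_icu_stays": m.n_icu_stays,
            "n_admissions": m.n_admissions,
            "icd9_codes": ";".join(sorted(m.icd9_codes)),
            "in_matched_subset": m.in_matched_subset,
            "has_ppg": m.has_ppg,
        })
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_subject_table(path) -> List[SubjectMeta]:
    df = pd.read_csv(path, dtype={"subject_id": str, "icd9_codes": str})
    out = []
    for _, r in df.iterrows():
        codes = set() if pd.isna(r["icd9_codes"]) or not r["icd9_codes"] else set(
            str(r["icd9_codes"]).split(";"))
        out.append(SubjectMeta(
            subject_id=str(r["subject_id"]),
            died_in_hospital=bool(r["died_in_hospital"]),
            n_icu_stays=int(r["n_icu_stays"]),
            n_admissions=int(r["n_admissions"]),
            icd9_codes=codes,
            in_matched_subset=bool(r["in_matched_subset"]),
            has_ppg=bool(r["has_ppg"]),
        ))
    return out


# -- segment store -------------------------------------------------------

def save_segments(segments: Sequence[Segment], out_dir,
                  qc_verdicts: Optional[Sequence[bool]] = None) -> Path:
    """One ``.npz`` per subject plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_subject: Dict[str, List[int]] = {}
    for i, seg in enumerate(segments):
        by_subject.setdefault(seg.subject_id, []).append(i)
    rows = []
    for sid, idxs in by_subject.items():
        arr = np.stack([segments[i].samples for i in idxs]).astype(np.float32)
        np.savez_compressed(out_dir / f"{sid}.npz", samples=arr,
                            segment_index=np.array([segments[i].segment_index for i in idxs]))
        for i in idxs:
            rows.append({
                "subject_id": sid,
                "segment_index": segments[i].segment_index,
                "label": segments[i].label,
                "accepted": bool(qc_verdicts[i]) if qc_verdicts is not None else True,
            })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_segments(seg_dir, accepted_only: bool = True) -> List[Segment]:
    seg_dir = Path(seg_dir)
    manifest = pd.read_csv(seg_dir / "manifest.csv", dtype={"subject_id": str})
    out: List[Segment] = []
    for sid, sub in manifest.groupby("subject_id"):
        with np.load(seg_dir / f"{sid}.npz") as z:
            samples = z["samples"]
            seg_idx = list(z["segment_index"])
        for _, row in sub.iterrows():
            if accepted_only and not row["accepted"]:
                continue
            pos = seg_idx.index(row["segment_index"])
            out.append(Segment(samples=samples[pos].astype(np.float64), fs=125.0,
                               subject_id=str(sid),
                               segment_index=int(row["segment_index"]),
                               label=str(row["label"])))
    return out
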