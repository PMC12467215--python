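"""On-disk dataset layout: JSON manifest + one array file per record.

A dataset directory looks like::

    <dir>/manifest.json      ids, labels, folds, fs, class names, ground truth
    <dir>/labels.csv         flat label table for interoperability
    <dir>/records/<id>.npy   float32 (n_leads, T) array, millivolts
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_ecg import ECGRecord

__all__ = ["save_dataset", "load_dataset"]


def save_dataset(records: list[ECGRecord], out_dir: str | Path,
                 class_names: list[str], label_mode: str = "multilabel",
                 force: bool = False) -> Path:
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(
            f"{out_dir} exists and is not empty (pass force=True to replace)")
    rec_dir = out_dir / "records"
    rec_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "class_names": class_names,
        "label_mode": label_mode,
        "fs": int(records[0].fs),
        "n_leads": int(records[0].n_leads),
        "n_samples": int(records[0].n_samples),
        "records": [],
    }
    rows = []
    for rec in records:
        np.save(rec_dir / f"{rec.record_id}.npy", rec.signal)
        entry = {
            "id": rec.record_id,
            "labels": [int(v) for v in rec.labels],
            "fold": rec.fold,
            "true_r_peaks": ([int(p) for p in rec.true_r_peaks]
                             if rec.true_r_peaks is not None else None),
            "meta": _jsonable(rec.meta),
        }
        manifest["records"].append(entry)
        rows.append({"record_id": rec.record_id, "fold": rec.fold,
                     **{c: int(v) for c, v in zip(class_names, rec.labels)}})
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    pd.DataFrame(rows).to_csv(out_dir / "labels.csv", index=False)
    return out_dir


def load_dataset(data_dir: str | Path) -> tuple[list[ECGRecord], dict]:
    """Read a dataset directory back; returns (records, manifest)."""
    data_dir = Path(data_dir)
    with open(data_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    records = []
    for entry in manifest["records"]:
        signal = np.load(data_dir / "records" / f"{entry['id']}.npy")
        peaks = entry.get("true_r_peaks")
        records.append(ECGRecord(
            signal=signal, fs=manifest["fs"],
            labels=np.asarray(entry["labels"], dtype=np.int8),
            record_id=entry["id"],
            true_r_peaks=None if peaks is None else np.asarray(peaks),
            fold=entry["fold"], meta=entry.get("meta", {})))
    return records, manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
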