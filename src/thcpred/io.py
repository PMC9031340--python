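"""Cohort persistence: one NIfTI volume per patient plus one clinical CSV
keyed by patient ID, with a JSON manifest recording config and seed.

Real data laid out the same way (a directory of ``.nii.gz`` volumes and a
``clinical.csv`` with a ``patient_id`` column, the clinical fields and a
``label`` column) can be loaded with :func:`load_cohort` in place of a
synthetic cohort.  Volumes read from disk are min-max scaled to [0, 1]
when they fall outside it.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict
from typing import List, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import (
    QUALITATIVE_LEVELS,
    QUANTITATIVE_FIELDS,
    CohortConfig,
    PatientRecord,
)

__all__ = ["save_cohort", "load_cohort", "config_hash"]


def config_hash(obj) -> str:
    """Stable short hash of a config-like object (dataclass or dict)."""
    d = asdict(obj) if not isinstance(obj, dict) else obj
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _patient_id(i: int) -> str:
    return f"P{i:04d}"


def save_cohort(
    records: Sequence[PatientRecord],
    out_dir: str,
    config: Optional[CohortConfig] = None,
) -> str:
    """Write volumes, the clinical table and a manifest; returns ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    vol_dir = os.path.join(out_dir, "volumes")
    os.makedirs(vol_dir, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        pid = _patient_id(i)
        img = nib.Nifti1Image(np.asarray(rec.volume, dtype=np.float32), affine=np.eye(4))
        nib.save(img, os.path.join(vol_dir, f"{pid}.nii.gz"))
        row = {"patient_id": pid}
        row.update({name: rec.quantitative[name] for name, _ in QUANTITATIVE_FIELDS})
        row.update({name: rec.qualitative[name] for name in QUALITATIVE_LEVELS})
        row["label"] = rec.label
        rows.append(row)
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "clinical.csv"), index=False)
    manifest = {
        "n_patients": len(records),
        "config": asdict(config) if config is not None else None,
        "seed": config.seed if config is not None else None,
        "config_hash": config_hash(config) if config is not None else None,
        "format": "nifti+csv v1",
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out_dir


def load_cohort(in_dir: str) -> List[PatientRecord]:
    """Read a cohort written by :func:`save_cohort` (or real data in the
    same layout).  Clinical fields are taken by schema name; the volume
    for row ``patient_id`` is ``volumes/<patient_id>.nii.gz`` or ``.nii``."""
    table = pd.read_csv(os.path.join(in_dir, "clinical.csv"))
    required = {"patient_id", "label"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"clinical.csv is missing columns: {sorted(missing)}")
    records: List[PatientRecord] = []
    vol_dir = os.path.join(in_dir, "volumes")
    for _, row in table.iterrows():
        pid = row["patient_id"]
        path = os.path.join(vol_dir, f"{pid}.nii.gz")
        if not os.path.exists(path):
            path = os.path.join(vol_dir, f"{pid}.nii")
        vol = np.asarray(nib.load(path).dataobj, dtype=np.float32)
        lo, hi = float(vol.min()), float(vol.max())
        if lo < 0.0 or hi > 1.0:
            vol = (vol - lo) / (hi - lo) if hi > lo else np.zeros_like(vol)
        records.append(
            PatientRecord(
                volume=vol,
                quantitative={name: float(row[name]) for name, _ in QUANTITATIVE_FIELDS},
                qualitative={name: str(row[name]) for name in QUALITATIVE_LEVELS},
                label=int(row["label"]),
            )
        )
    return records
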