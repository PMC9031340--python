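"""Synthetic cohorts: 3-D volumes with a planted lesion signal plus a
clinical covariate table, emulating the inputs of the recurrence-prediction
pipeline (CT volume + quantitative and qualitative clinical fields +
binary recurrence label).

Generative model, per patient:

* latent risk ``z ~ N(0, 1)``;
* label ``~ Bernoulli(sigmoid(signal_strength * z + offset))`` with the
  offset solved so the marginal recurrence probability equals
  ``prevalence`` (at ``signal_strength = 0`` the label is independent of
  every feature);
* the volume holds one ellipsoidal lesion on a smooth noisy background;
  lesion radius and intensity contrast increase monotonically with ``z``;
* hemoglobin and albumin decrease linearly in ``z``; every other clinical
  field is label-independent noise in a physiologically plausible range.

The generator targets the statistical contract the pipeline needs —
volumetric and tabular features carrying a controllable amount of label
signal — not CT physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, optimize, stats

__all__ = [
    "QUANTITATIVE_FIELDS",
    "QUALITATIVE_LEVELS",
    "CohortConfig",
    "PatientRecord",
    "generate_cohort",
    "render_volume",
    "ClinicalEncoder",
    "encode_clinical",
]

#: Quantitative clinical fields and their units.
QUANTITATIVE_FIELDS: Tuple[Tuple[str, str], ...] = (
    ("hemoglobin", "g/dL"),
    ("lymphocytes", "Giga/L"),
    ("leucocytes", "Giga/L"),
    ("thrombocytes", "Giga/L"),
    ("albumin", "g/L"),
    ("treatment_duration", "days"),
    ("total_dose", "Gy"),
    ("n_fractions", "fractions"),
    ("dose_per_fraction", "Gy"),
    ("weight", "kg"),
)

#: Qualitative fields with their admissible levels.
QUALITATIVE_LEVELS: Dict[str, Tuple[str, ...]] = {
    "gender": ("M", "F"),
    "tabacology": ("smoker", "non-smoker", "former"),
    "induction_chemo": ("Y", "N"),
    "concomitant_chemo": ("Y", "N"),
    "tnm": ("I", "II", "III", "IV"),
}


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class CohortConfig:
    """Conditions under which a cohort is drawn.

    ``signal_strength`` scales the log-odds slope of the label on the
    latent risk; 0 makes the label independent of all features.
    ``noise_sd`` is the voxelwise Gaussian noise on top of the smooth
    background field.
    """

    n_patients: int = 200
    volume_shape: Tuple[int, int, int] = (32, 32, 16)
    prevalence: float = 0.5
    signal_strength: float = 5.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.volume_shape = tuple(int(v) for v in self.volume_shape)
        if self.n_patients < 10:
            raise ValueError("n_patients must be >= 10")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie strictly in (0, 1)")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")


@dataclass
class PatientRecord:
    """One synthetic patient: volume, clinical fields, label, provenance."""

    volume: np.ndarray
    quantitative: Dict[str, float]
    qualitative: Dict[str, str]
    label: int
    meta: Dict[str, float] = field(default_factory=dict)


def _prevalence_offset(signal_strength: float, prevalence: float) -> float:
    """Solve E_z[sigmoid(s z + b)] = prevalence over z ~ N(0,1)."""
    if signal_strength == 0.0:
        return float(np.log(prevalence / (1.0 - prevalence)))
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    w = weights / weights.sum()

    def marginal(b: float) -> float:
        return float(np.sum(w * _sigmoid(signal_strength * nodes + b)) - prevalence)

    lo, hi = -60.0, 60.0
    if marginal(lo) > 0 or marginal(hi) < 0:
        raise ValueError(
            f"prevalence {prevalence} infeasible at signal_strength {signal_strength}"
        )
    return float(optimize.brentq(marginal, lo, hi, xtol=1e-10))


def render_volume(
    risk: float,
    shape: Sequence[int],
    noise_sd: float,
    rng: np.random.Generator,
    base_radius: Optional[float] = None,
) -> np.ndarray:
    """Render one volume: smooth background + noise + one ellipsoidal lesion.

    The lesion sits at a uniformly random interior position with radius
    ``base_radius * (1 + 0.3 * sigmoid(risk))`` (voxels) and additive
    intensity contrast proportional to ``sigmoid(risk)``; output is
    clipped to [0, 1].
    """
    shape = tuple(int(v) for v in shape)
    if base_radius is None:
        base_radius = 0.14 * min(shape)
    radius = base_radius * (1.0 + 0.3 * float(_sigmoid(risk)))
    semi = np.array([radius, 0.85 * radius, 0.7 * radius])
    if np.any(2.0 * semi >= np.array(shape)):
        raise ValueError(f"lesion (semi-axes {semi}) does not fit volume {shape}")

    field_ = rng.standard_normal(shape)
    background = 0.15 + 0.08 * ndimage.gaussian_filter(field_, sigma=4.0)
    noise = noise_sd * rng.standard_normal(shape) if noise_sd > 0 else 0.0

    lo = np.ceil(semi).astype(int)
    hi = np.array(shape) - lo - 1
    center = np.array([rng.integers(l, h + 1) for l, h in zip(lo, hi)], dtype=float)
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    r2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    contrast = 0.55 * float(_sigmoid(risk))
    lesion = contrast * np.clip(1.0 - r2, 0.0, 1.0)  # soft-edged ellipsoid

    return np.clip(background + noise + lesion, 0.0, 1.0)


def generate_cohort(cfg: CohortConfig) -> List[PatientRecord]:
    """Draw a fully reproducible cohort under ``cfg``.

    Records carry the latent risk and true lesion radius in ``meta`` so
    tests can build oracle classifiers against the planted signal.
    """
    rng = np.random.default_rng(cfg.seed)
    offset = _prevalence_offset(cfg.signal_strength, cfg.prevalence)
    records: List[PatientRecord] = []
    base_radius = 0.14 * min(cfg.volume_shape)
    for _ in range(cfg.n_patients):
        z = float(rng.standard_normal())
        p_rec = float(_sigmoid(cfg.signal_strength * z + offset))
        label = int(rng.random() < p_rec)
        volume = render_volume(z, cfg.volume_shape, cfg.noise_sd, rng,
                               base_radius=base_radius)

        n_frac = int(np.round(rng.normal(33, 2)))
        total_dose = float(rng.normal(66, 4))
        quantitative = {
            "hemoglobin": float(rng.normal(13.5, 0.7) - 1.2 * z),
            "lymphocytes": float(rng.normal(1.8, 0.5)),
            "leucocytes": float(rng.normal(7.0, 2.0)),
            "thrombocytes": float(rng.normal(250.0, 60.0)),
            "albumin": float(rng.normal(40.0, 2.0) - 3.0 * z),
            "treatment_duration": float(rng.normal(45.0, 7.0)),
            "total_dose": total_dose,
            "n_fractions": float(n_frac),
            "dose_per_fraction": total_dose / n_frac,
            "weight": float(rng.normal(70.0, 12.0)),
        }
        qualitative = {
            name: levels[rng.integers(len(levels))]
            for name, levels in QUALITATIVE_LEVELS.items()
        }
        records.append(
            PatientRecord(
                volume=volume.astype(np.float32),
                quantitative=quantitative,
                qualitative=qualitative,
                label=label,
                meta={
                    "risk": z,
                    "lesion_radius": base_radius * (1.0 + 0.3 * float(_sigmoid(z))),
                    "p_recurrence": p_rec,
                },
            )
        )
    return records


class ClinicalEncoder:
    """Turn clinical fields into a fixed-length numeric vector.

    Quantitative fields are z-scored with statistics *fitted on training
    records only*; qualitative fields are one-hot encoded against the
    schema level sets (an unseen level raises, naming the field).
    """

    def __init__(self) -> None:
        self.means_: Optional[np.ndarray] = None
        self.sds_: Optional[np.ndarray] = None

    @property
    def width(self) -> int:
        return len(QUANTITATIVE_FIELDS) + sum(
            len(v) for v in QUALITATIVE_LEVELS.values()
        )

    def fit(self, records: Sequence[PatientRecord]) -> "ClinicalEncoder":
        mat = np.array(
            [[r.quantitative[name] for name, _ in QUANTITATIVE_FIELDS] for r in records]
        )
        self.means_ = mat.mean(axis=0)
        sds = mat.std(axis=0, ddof=0)
        self.sds_ = np.where(sds > 0, sds, 1.0)
        return self

    def transform_one(self, record: PatientRecord) -> np.ndarray:
        if self.means_ is None:
            raise RuntimeError("encoder must be fitted before transforming")
        quant = np.array(
            [record.quantitative[name] for name, _ in QUANTITATIVE_FIELDS]
        )
        parts = [(quant - self.means_) / self.sds_]
        for name, levels in QUALITATIVE_LEVELS.items():
            value = record.qualitative[name]
            if value not in levels:
                raise ValueError(
                    f"unseen level {value!r} for qualitative field {name!r}"
                )
            onehot = np.zeros(len(levels))
            onehot[levels.index(value)] = 1.0
            parts.append(onehot)
        return np.concatenate(parts)

    def transform(self, records: Sequence[PatientRecord]) -> np.ndarray:
        return np.stack([self.transform_one(r) for r in records])


def encode_clinical(record: PatientRecord, stats: ClinicalEncoder) -> np.ndarray:
    """Functional alias: encode one record with a fitted encoder."""
    return stats.transform_one(record)
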