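"""Shannon and Tsallis-Havrda-Charvat (THC) entropies, cross-entropies and
the batch losses used to train the recurrence-prediction network.

The THC family generalizes Shannon entropy with a single exponent ``alpha``:

    H_alpha(p) = (1 - sum_i p_i^alpha) / (alpha - 1),      alpha > 0,

which recovers the Shannon entropy ``-sum_i p_i log p_i`` (natural log) in
the limit ``alpha -> 1``.  The associated cross-entropy between a predicted
distribution ``q`` and a reference ``p`` is

    H_alpha(q : p) = (1 - sum_i q_i^(alpha-1) p_i) / (alpha - 1),

again reducing to ``-sum_i p_i log q_i`` at ``alpha = 1``.  Natural
logarithms are used throughout so that the alpha -> 1 limits hold exactly.

The batch losses operate on a binary classification batch (ground-truth
labels ``p_n`` in {0,1}, predicted probabilities ``q_n``) and on paired
3-D volumes (reconstruction target / output).  Predicted probabilities are
clamped to ``[EPS, 1 - EPS]`` before any power or logarithm: for
``alpha < 1`` the term ``q^(alpha-1)`` diverges at 0, and the log loss
diverges at both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "EPS",
    "ALPHA_DISPATCH_TOL",
    "ProbabilityVector",
    "AlphaParam",
    "BinaryBatch",
    "VolumePair",
    "LossBreakdown",
    "InvalidDistributionError",
    "ParameterError",
    "shannon_entropy",
    "shannon_cross_entropy",
    "h_alpha",
    "thc_entropy",
    "thc_cross_entropy",
    "binary_shannon_loss",
    "binary_thc_loss",
    "binary_thc_loss_gradient",
    "mse_reconstruction_loss",
    "total_loss",
]

#: Clamp for predicted probabilities before powers/logarithms.
EPS = 1e-7

#: |alpha - 1| below this routes every THC expression to its Shannon form.
ALPHA_DISPATCH_TOL = 1e-6

_SUM_TOL = 1e-9


class InvalidDistributionError(ValueError):
    """A probability vector violates its invariants."""


class ParameterError(ValueError):
    """An entropy-order parameter violates ``alpha > 0``."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbabilityVector:
    """A finite discrete distribution ``(p_1, ..., p_k)``.

    Entries must lie in ``[0, 1]`` and sum to 1 within ``1e-9``.
    """

    probs: np.ndarray

    def __init__(self, probs: Sequence[float] | np.ndarray):
        arr = np.asarray(probs, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise InvalidDistributionError(
                f"probability vector must be 1-D and non-empty, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise InvalidDistributionError("probability vector contains non-finite entries")
        if np.any(arr < 0.0) or np.any(arr > 1.0):
            raise InvalidDistributionError(
                f"entries must lie in [0, 1], got range [{arr.min()}, {arr.max()}]"
            )
        total = float(arr.sum())
        if abs(total - 1.0) > _SUM_TOL:
            raise InvalidDistributionError(f"entries must sum to 1, got {total!r}")
        object.__setattr__(self, "probs", arr)

    @property
    def k(self) -> int:
        return int(self.probs.size)

    def __len__(self) -> int:
        return self.k


@dataclass(frozen=True)
class AlphaParam:
    """Order of the THC entropy; must be strictly positive."""

    alpha: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha <= 0.0:
            raise ParameterError(f"alpha must be a positive real, got {self.alpha!r}")

    @property
    def is_shannon(self) -> bool:
        """True when alpha is within the dispatch tolerance of 1."""
        return abs(self.alpha - 1.0) < ALPHA_DISPATCH_TOL


@dataclass(frozen=True)
class BinaryBatch:
    """Paired ground-truth labels ``p_n`` in {0,1} and predictions ``q_n``.

    Predictions are clamped to ``[EPS, 1-EPS]`` on construction so every
    downstream power/log is finite.
    """

    labels: np.ndarray
    predictions: np.ndarray

    def __init__(self, labels: Sequence[float], predictions: Sequence[float]):
        lab = np.asarray(labels, dtype=float)
        pred = np.asarray(predictions, dtype=float)
        if lab.ndim != 1 or pred.ndim != 1 or lab.shape != pred.shape:
            raise ValueError(
                f"labels and predictions must be 1-D of equal length, "
                f"got {lab.shape} and {pred.shape}"
            )
        if lab.size < 1:
            raise ValueError("empty batch")
        if not np.all(np.isin(lab, (0.0, 1.0))):
            raise ValueError("labels must all be 0 or 1")
        if not np.all(np.isfinite(pred)) or np.any(pred < 0.0) or np.any(pred > 1.0):
            raise ValueError("predictions must be probabilities in [0, 1]")
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "predictions", np.clip(pred, EPS, 1.0 - EPS))

    @property
    def n(self) -> int:
        return int(self.labels.size)


@dataclass(frozen=True)
class VolumePair:
    """A reconstruction target and the network output, identical shapes."""

    target: np.ndarray
    reconstruction: np.ndarray

    def __init__(self, target: np.ndarray, reconstruction: np.ndarray):
        t = np.asarray(target, dtype=float)
        r = np.asarray(reconstruction, dtype=float)
        if t.shape != r.shape:
            raise ValueError(f"shape mismatch: target {t.shape} vs reconstruction {r.shape}")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
            raise ValueError("volumes must be finite")
        object.__setattr__(self, "target", t)
        object.__setattr__(self, "reconstruction", r)


@dataclass(frozen=True)
class LossBreakdown:
    """Reconstruction, prediction and total loss for one batch.

    ``total`` is always exactly ``rec + pred``.
    """

    rec: float
    pred: float
    total: float = field(init=False)

    def __post_init__(self) -> None:
        if self.rec < 0 or self.pred < 0:
            raise ValueError("loss terms must be nonnegative")
        object.__setattr__(self, "total", self.rec + self.pred)


# ---------------------------------------------------------------------------
# Entropies and cross-entropies
# ---------------------------------------------------------------------------


def _as_pv(p) -> ProbabilityVector:
    return p if isinstance(p, ProbabilityVector) else ProbabilityVector(p)


def _as_alpha(a) -> AlphaParam:
    return a if isinstance(a, AlphaParam) else AlphaParam(float(a))


def shannon_entropy(p) -> float:
    """Shannon entropy ``-sum_i p_i log p_i`` (natural log, 0 log 0 := 0)."""
    pv = _as_pv(p).probs
    nz = pv[pv > 0.0]
    return float(-(nz * np.log(nz)).sum())


def shannon_cross_entropy(q, p) -> float:
    """Shannon cross-entropy ``-sum_i p_i log q_i``.

    ``q`` is the predicted distribution (clamped away from 0 before the
    logarithm), ``p`` the reference.  When ``p`` is a Dirac at ``i0`` this
    is ``-log q_{i0}``.
    """
    qv, pv = _as_pv(q).probs, _as_pv(p).probs
    if qv.size != pv.size:
        raise ValueError(f"dimension mismatch: q has k={qv.size}, p has k={pv.size}")
    qc = np.clip(qv, EPS, 1.0 - EPS)
    return float(-(pv * np.log(qc)).sum())


def h_alpha(u: float, a) -> float:
    """THC generator ``h_alpha(u) = (u^alpha - u)/(alpha - 1)`` on [0, 1].

    Convex, with ``h_alpha(0) = h_alpha(1) = 0``.  Within the dispatch
    tolerance of ``alpha = 1`` this returns the Shannon generator
    ``u log u`` (its alpha -> 1 limit), so ``-sum_i h_alpha(p_i)`` equals
    the matching entropy at every alpha.
    """
    ap = _as_alpha(a)
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"u must lie in [0, 1], got {u!r}")
    if ap.is_shannon:
        return float(u * np.log(u)) if u > 0.0 else 0.0
    return float((u ** ap.alpha - u) / (ap.alpha - 1.0))


def thc_entropy(p, a) -> float:
    """THC entropy ``(1 - sum_i p_i^alpha)/(alpha - 1)``.

    Dispatches to :func:`shannon_entropy` within the alpha = 1 tolerance.
    Nonnegative for every valid distribution; zero iff ``p`` is a Dirac.
    """
    ap = _as_alpha(a)
    pv = _as_pv(p).probs
    if ap.is_shannon:
        return shannon_entropy(pv)
    return float((1.0 - (pv ** ap.alpha).sum()) / (ap.alpha - 1.0))


def thc_cross_entropy(q, p, a) -> float:
    """THC cross-entropy ``(1 - sum_i q_i^(alpha-1) p_i)/(alpha - 1)``.

    ``q`` is clamped to ``[EPS, 1-EPS]`` first (``q^(alpha-1)`` diverges at
    0 for alpha < 1).  Dispatches to :func:`shannon_cross_entropy` near
    alpha = 1.
    """
    ap = _as_alpha(a)
    qv, pv = _as_pv(q).probs, _as_pv(p).probs
    if qv.size != pv.size:
        raise ValueError(f"dimension mismatch: q has k={qv.size}, p has k={pv.size}")
    if ap.is_shannon:
        return shannon_cross_entropy(qv, pv)
    qc = np.clip(qv, EPS, 1.0 - EPS)
    return float((1.0 - (qc ** (ap.alpha - 1.0) * pv).sum()) / (ap.alpha - 1.0))


# ---------------------------------------------------------------------------
# Batch losses
# ---------------------------------------------------------------------------


def _as_batch(b) -> BinaryBatch:
    return b if isinstance(b, BinaryBatch) else BinaryBatch(*b)


def binary_shannon_loss(b) -> float:
    """Binary cross-entropy ``-(1/N) sum_n [p_n log q_n + (1-p_n) log(1-q_n)]``."""
    bb = _as_batch(b)
    p, q = bb.labels, bb.predictions
    return float(-np.mean(p * np.log(q) + (1.0 - p) * np.log(1.0 - q)))


def binary_thc_loss(b, a) -> float:
    """Binary THC loss
    ``(1/(alpha-1)) (1 - (1/N) sum_n [q_n^(a-1) p_n + (1-q_n)^(a-1) (1-p_n)])``.

    Dispatches to :func:`binary_shannon_loss` within the alpha = 1 tolerance
    (the closed form is undefined at alpha = 1).
    """
    ap = _as_alpha(a)
    bb = _as_batch(b)
    if ap.is_shannon:
        return binary_shannon_loss(bb)
    p, q = bb.labels, bb.predictions
    e = ap.alpha - 1.0
    inner = np.mean(q**e * p + (1.0 - q) ** e * (1.0 - p))
    return float((1.0 - inner) / e)


def binary_thc_loss_gradient(b, a) -> np.ndarray:
    """Per-sample gradient ``dL/dq_n`` of :func:`binary_thc_loss`.

    For alpha != 1: ``-(1/N) [q_n^(a-2) p_n - (1-q_n)^(a-2) (1-p_n)]``;
    at alpha ~ 1 the Shannon gradient
    ``-(1/N) [p_n/q_n - (1-p_n)/(1-q_n)]``.  Evaluated at the clamped
    predictions, matching the loss itself.
    """
    ap = _as_alpha(a)
    bb = _as_batch(b)
    p, q = bb.labels, bb.predictions
    n = bb.n
    if ap.is_shannon:
        return -(p / q - (1.0 - p) / (1.0 - q)) / n
    e = ap.alpha - 2.0
    return -(q**e * p - (1.0 - q) ** e * (1.0 - p)) / n


def mse_reconstruction_loss(pairs: Sequence[VolumePair]) -> float:
    """Mean over patients of the squared Euclidean norm of the voxelwise
    reconstruction error, ``(1/N) sum_n ||y_n - yhat_n||^2``.

    Note the inner norm is a *sum* over voxels, not a voxel mean.
    """
    items = [p if isinstance(p, VolumePair) else VolumePair(*p) for p in pairs]
    if not items:
        raise ValueError("empty batch of volume pairs")
    shape = items[0].target.shape
    for it in items:
        if it.target.shape != shape:
            raise ValueError("all volume pairs must share one shape")
    per_patient = [((it.target - it.reconstruction) ** 2).sum() for it in items]
    return float(np.mean(per_patient))


def total_loss(rec: float, pred: float) -> LossBreakdown:
    """Combine the two task losses with unit weights: ``total = rec + pred``."""
    return LossBreakdown(rec=float(rec), pred=float(pred))
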