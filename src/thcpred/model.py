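"""Model/Results interface over the multitask network.

:class:`RecurrenceModel` holds the data (volumes, encoded clinical
covariates, labels) and configuration; :meth:`RecurrenceModel.fit` trains
the network and returns a :class:`RecurrenceResults` carrying the trained
parameters, the per-epoch loss log, prediction methods and a ``summary()``
table.  ``from_cohort`` builds the model straight from a list of patient
records, fitting the clinical encoder on those records (so in
cross-validation the encoder never sees the held-out fold).
"""

from __future__ import annotations

import json
from dataclasses import replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .cohort import ClinicalEncoder, PatientRecord
from .entropy import EPS, LossBreakdown
from .network import MultitaskNet, NetworkConfig, TrainedModel, train_model

__all__ = ["RecurrenceModel", "RecurrenceResults"]


class RecurrenceModel:
    """Multitask recurrence model bound to a training cohort."""

    def __init__(
        self,
        volumes: np.ndarray,
        clinical: np.ndarray,
        labels: np.ndarray,
        config: Optional[NetworkConfig] = None,
        encoder: Optional[ClinicalEncoder] = None,
    ):
        volumes = np.asarray(volumes)
        clinical = np.asarray(clinical, dtype=float)
        labels = np.asarray(labels, dtype=float)
        if volumes.shape[0] != clinical.shape[0] or volumes.shape[0] != labels.shape[0]:
            raise ValueError("volumes, clinical and labels must align on patients")
        if config is None:
            config = NetworkConfig(
                volume_shape=tuple(volumes.shape[1:]), clinical_dim=clinical.shape[1]
            )
        if config.clinical_dim != clinical.shape[1]:
            config = replace(config, clinical_dim=clinical.shape[1])
        self.volumes = volumes
        self.clinical = clinical
        self.labels = labels
        self.config = config
        self.encoder = encoder

    @classmethod
    def from_cohort(
        cls,
        records: Sequence[PatientRecord],
        config: Optional[NetworkConfig] = None,
        encoder: Optional[ClinicalEncoder] = None,
    ) -> "RecurrenceModel":
        """Build from patient records; fits the clinical encoder on them
        unless a pre-fitted one is supplied."""
        if not records:
            raise ValueError("empty cohort")
        if encoder is None:
            encoder = ClinicalEncoder().fit(records)
        volumes = np.stack([r.volume for r in records])
        clinical = encoder.transform(records)
        labels = np.array([r.label for r in records], dtype=float)
        return cls(volumes, clinical, labels, config=config, encoder=encoder)

    def fit(self, callback=None) -> "RecurrenceResults":
        net = MultitaskNet(self.config)
        trained = train_model(
            net, self.volumes, self.clinical, self.labels, self.config, callback=callback
        )
        return RecurrenceResults(self, trained)


class RecurrenceResults:
    """Fitted parameters, training log and prediction interface."""

    def __init__(self, model: RecurrenceModel, trained: TrainedModel):
        self.model = model
        self.net = trained.net
        self.config = trained.config
        self.training_log: List[LossBreakdown] = trained.training_log
        self.encoder = model.encoder

    # -- prediction --------------------------------------------------------

    def predict_proba(self, volumes: np.ndarray, clinical: np.ndarray) -> np.ndarray:
        volumes = np.asarray(volumes)
        clinical = np.asarray(clinical, dtype=float)
        probs = []
        step = max(1, self.config.batch_size)
        for start in range(0, volumes.shape[0], step):
            _, _, q = self.net.forward_batch(
                volumes[start : start + step], clinical[start : start + step]
            )
            probs.append(q)
        return np.clip(np.concatenate(probs), EPS, 1.0 - EPS)

    def predict(
        self, volumes: np.ndarray, clinical: np.ndarray, threshold: float = 0.5
    ) -> np.ndarray:
        """Hard labels: 1 iff predicted probability >= threshold."""
        return (self.predict_proba(volumes, clinical) >= threshold).astype(int)

    def predict_records(
        self, records: Sequence[PatientRecord], threshold: float = 0.5
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Predict on raw records using the training-time clinical encoder."""
        if self.encoder is None:
            raise RuntimeError("results carry no clinical encoder; pass arrays instead")
        volumes = np.stack([r.volume for r in records])
        clinical = self.encoder.transform(records)
        probs = self.predict_proba(volumes, clinical)
        return (probs >= threshold).astype(int), probs

    # -- reporting ---------------------------------------------------------

    def training_accuracy(self, threshold: float = 0.5) -> float:
        preds = self.predict(self.model.volumes, self.model.clinical, threshold)
        return float(np.mean(preds == self.model.labels))

    def summary(self) -> str:
        cfg = self.config
        first, last = self.training_log[0], self.training_log[-1]
        lines = [
            "Multitask recurrence model results",
            "=" * 50,
            f"volume shape        : {cfg.volume_shape}",
            f"encoder channels    : {cfg.encoder_channels}",
            f"alpha (loss order)  : {cfg.alpha}" + ("  [Shannon]" if cfg.loss == "shannon" or abs(cfg.alpha - 1) < 1e-6 else ""),
            f"epochs / batch / lr : {cfg.epochs} / {cfg.batch_size} / {cfg.learning_rate}",
            f"patients            : {self.model.volumes.shape[0]}",
            "-" * 50,
            f"loss (epoch 1)      : rec {first.rec:.4f}  pred {first.pred:.4f}  total {first.total:.4f}",
            f"loss (final)        : rec {last.rec:.4f}  pred {last.pred:.4f}  total {last.total:.4f}",
            f"training accuracy   : {self.training_accuracy():.3f}",
            "=" * 50,
        ]
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        """Serialize parameters + config to one ``.npz`` file."""
        params = self.net.parameters()
        arrays = {f"param_{i}": p for i, p in enumerate(params)}
        arrays["config_json"] = np.array(json.dumps(self.config.to_dict()))
        log = np.array([[e.rec, e.pred, e.total] for e in self.training_log])
        arrays["training_log"] = log
        if self.encoder is not None and self.encoder.means_ is not None:
            arrays["encoder_means"] = self.encoder.means_
            arrays["encoder_sds"] = self.encoder.sds_
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "RecurrenceResults":
        data = np.load(path, allow_pickle=False)
        cfg = NetworkConfig.from_dict(json.loads(str(data["config_json"])))
        net = MultitaskNet(cfg)
        n_params = len(net.parameters())
        net.set_parameters([data[f"param_{i}"] for i in range(n_params)])
        from .entropy import total_loss

        log = [total_loss(r, p) for r, p, _ in data["training_log"]]
        encoder = None
        if "encoder_means" in data:
            encoder = ClinicalEncoder()
            encoder.means_ = data["encoder_means"]
            encoder.sds_ = data["encoder_sds"]
        dummy_model = RecurrenceModel.__new__(RecurrenceModel)
        dummy_model.volumes = np.zeros((0,) + cfg.volume_shape)
        dummy_model.clinical = np.zeros((0, cfg.clinical_dim))
        dummy_model.labels = np.zeros(0)
        dummy_model.config = cfg
        dummy_model.encoder = encoder
        trained = TrainedModel(net=net, config=cfg, training_log=log)
        return cls(dummy_model, trained)
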