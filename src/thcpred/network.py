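"""Multitask 3-D network: encoder-decoder reconstruction plus a fully
connected recurrence-prediction branch read off the bottleneck.

The backbone has three convolutional stages on the way down (conv + ReLU +
2x max-pool each) and a mirrored way up (x2 nearest upsampling, channel
concatenation with the matching encoder stage, conv + ReLU), ending in a
single-channel linear reconstruction.  The flattened bottleneck is
projected to ``bottleneck_dim``, concatenated with the encoded clinical
covariate vector, and passed through fully connected ReLU layers to one
sigmoid unit giving the recurrence probability.

Training minimizes ``L_total = L_rec + L_pred`` where ``L_rec`` is the
per-patient summed squared voxel error (mean over the batch) against the
input volume itself, and ``L_pred`` is the binary THC loss at the
configured ``alpha`` (its Shannon form at ``alpha = 1``).  The two unit
weights are exposed as ``loss_weights`` for experimentation.  All
arithmetic is NumPy; runs are bit-reproducible from ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import entropy as ent
from .layers import Adam, Conv3d, Dense, MaxPool3d, ReLU, Upsample3d, sigmoid, DT

__all__ = [
    "NetworkConfig",
    "MultitaskOutput",
    "MultitaskNet",
    "TrainedModel",
    "build_model",
    "forward",
    "train_model",
    "predict",
]


@dataclass
class NetworkConfig:
    """Architecture and optimization settings.

    ``volume_shape`` must be divisible by 8 in every dimension so three
    pool/upsample rounds return to the input resolution.  ``alpha`` is the
    THC order of the prediction loss; ``loss`` may force the explicit
    Shannon form regardless of alpha.
    """

    volume_shape: Tuple[int, int, int] = (32, 32, 16)
    encoder_channels: Tuple[int, int, int] = (8, 16, 32)
    bottleneck_dim: int = 64
    fc_widths: Tuple[int, ...] = (64, 16)
    clinical_dim: int = 23
    alpha: float = 1.0
    loss: str = "thc"  # "thc" dispatches to Shannon at alpha ~ 1; "shannon" forces it
    loss_weights: Tuple[float, float] = (1.0, 1.0)
    learning_rate: float = 1e-3
    batch_size: int = 4
    epochs: int = 6
    polyak_tail: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.volume_shape = tuple(int(v) for v in self.volume_shape)
        self.encoder_channels = tuple(int(c) for c in self.encoder_channels)
        self.fc_widths = tuple(int(w) for w in self.fc_widths)
        self.loss_weights = tuple(float(x) for x in self.loss_weights)
        if len(self.volume_shape) != 3:
            raise ValueError("volume_shape must have three dimensions")
        if any(v % 8 != 0 or v < 8 for v in self.volume_shape):
            raise ValueError(
                f"volume_shape {self.volume_shape} must be divisible by 8 in every "
                "dimension (three pooling stages)"
            )
        if len(self.encoder_channels) != 3:
            raise ValueError("exactly three encoder stages are required")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.polyak_tail < 0:
            raise ValueError("polyak_tail must be >= 0")
        if self.loss not in ("thc", "shannon"):
            raise ValueError(f"loss must be 'thc' or 'shannon', got {self.loss!r}")
        ent.AlphaParam(self.alpha)  # validates alpha > 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


@dataclass(frozen=True)
class MultitaskOutput:
    """Outputs of one forward pass: reconstruction and recurrence probability."""

    reconstruction: np.ndarray
    recurrence_prob: float


class MultitaskNet:
    """The raw network: layers, forward pass and hand-written backward pass."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c1, c2, c3 = cfg.encoder_channels
        d, h, w = cfg.volume_shape
        self.conv1, self.relu1, self.pool1 = Conv3d(1, c1, rng), ReLU(), MaxPool3d()
        self.conv2, self.relu2, self.pool2 = Conv3d(c1, c2, rng), ReLU(), MaxPool3d()
        self.conv3, self.relu3, self.pool3 = Conv3d(c2, c3, rng), ReLU(), MaxPool3d()
        self.up3, self.convd3, self.relud3 = Upsample3d(), Conv3d(2 * c3, c2, rng), ReLU()
        self.up2, self.convd2, self.relud2 = Upsample3d(), Conv3d(2 * c2, c1, rng), ReLU()
        self.up1, self.convd1 = Upsample3d(), Conv3d(2 * c1, 1, rng)
        self.flat_dim = c3 * (d // 8) * (h // 8) * (w // 8)
        self.dense_b, self.relu_b = Dense(self.flat_dim, cfg.bottleneck_dim, rng), ReLU()
        widths = [cfg.bottleneck_dim + cfg.clinical_dim, *cfg.fc_widths]
        self.fcs: List[Dense] = []
        self.fc_relus: List[ReLU] = []
        for a, b in zip(widths[:-1], widths[1:]):
            self.fcs.append(Dense(a, b, rng))
            self.fc_relus.append(ReLU())
        self.fc_out = Dense(widths[-1], 1, rng)

    # -- plumbing ----------------------------------------------------------

    def layers(self):
        return [
            self.conv1, self.conv2, self.conv3,
            self.convd3, self.convd2, self.convd1,
            self.dense_b, *self.fcs, self.fc_out,
        ]

    def parameters(self) -> List[np.ndarray]:
        return [p for l in self.layers() for p in l.params()]

    def set_parameters(self, values: Sequence[np.ndarray]) -> None:
        own = self.parameters()
        if len(own) != len(values):
            raise ValueError("parameter count mismatch")
        for p, v in zip(own, values):
            p[...] = v

    # -- forward / backward ------------------------------------------------

    def _check_shapes(self, vol: np.ndarray, clin: np.ndarray) -> None:
        if vol.shape[1:] != self.cfg.volume_shape:
            raise ValueError(
                f"volume batch shape {vol.shape[1:]} != configured {self.cfg.volume_shape}"
            )
        if clin.shape[1] != self.cfg.clinical_dim:
            raise ValueError(
                f"clinical vector length {clin.shape[1]} != configured {self.cfg.clinical_dim}"
            )

    def forward_batch(self, vol: np.ndarray, clin: np.ndarray):
        """Forward a batch; returns (reconstruction, logits, probabilities)."""
        vol = np.asarray(vol, dtype=DT)
        clin = np.asarray(clin, dtype=DT)
        if vol.ndim != 4 or clin.ndim != 2 or vol.shape[0] != clin.shape[0]:
            raise ValueError("expected vol (B, D, H, W) and clin (B, F) with equal B")
        self._check_shapes(vol, clin)
        x = vol[..., None]
        s1 = self.relu1.forward(self.conv1.forward(x))
        p1 = self.pool1.forward(s1)
        s2 = self.relu2.forward(self.conv2.forward(p1))
        p2 = self.pool2.forward(s2)
        s3 = self.relu3.forward(self.conv3.forward(p2))
        p3 = self.pool3.forward(s3)

        flat = p3.reshape(p3.shape[0], -1)
        bneck = self.relu_b.forward(self.dense_b.forward(flat))
        hid = np.concatenate([bneck, clin], axis=1)
        for fc, relu in zip(self.fcs, self.fc_relus):
            hid = relu.forward(fc.forward(hid))
        logit = self.fc_out.forward(hid)[:, 0]

        u3 = self.up3.forward(p3)
        d3 = self.relud3.forward(self.convd3.forward(np.concatenate([u3, s3], axis=-1)))
        u2 = self.up2.forward(d3)
        d2 = self.relud2.forward(self.convd2.forward(np.concatenate([u2, s2], axis=-1)))
        u1 = self.up1.forward(d2)
        recon = self.convd1.forward(np.concatenate([u1, s1], axis=-1))[..., 0]

        self._p3_shape = p3.shape
        return recon, logit, sigmoid(logit)

    def backward_batch(self, drecon: np.ndarray, dlogit: np.ndarray) -> None:
        """Backpropagate gradients of the scalar loss w.r.t. recon and logit."""
        c1, c2, c3 = self.cfg.encoder_channels
        dcat1 = self.convd1.backward(drecon[..., None].astype(DT))
        du1, ds1_skip = dcat1[..., :c1], dcat1[..., c1:]
        dd2 = self.up1.backward(du1)
        dcat2 = self.convd2.backward(self.relud2.backward(dd2))
        du2, ds2_skip = dcat2[..., :c2], dcat2[..., c2:]
        dd3 = self.up2.backward(du2)
        dcat3 = self.convd3.backward(self.relud3.backward(dd3))
        du3, ds3_skip = dcat3[..., :c3], dcat3[..., c3:]
        dp3_dec = self.up3.backward(du3)

        dh = self.fc_out.backward(dlogit[:, None].astype(DT))
        for fc, relu in zip(reversed(self.fcs), reversed(self.fc_relus)):
            dh = fc.backward(relu.backward(dh))
        dbneck = dh[:, : self.cfg.bottleneck_dim]
        dflat = self.dense_b.backward(self.relu_b.backward(dbneck))
        dp3 = dp3_dec + dflat.reshape(self._p3_shape)

        ds3 = self.pool3.backward(dp3) + ds3_skip
        dp2 = self.conv3.backward(self.relu3.backward(ds3))
        ds2 = self.pool2.backward(dp2) + ds2_skip
        dp1 = self.conv2.backward(self.relu2.backward(ds2))
        ds1 = self.pool1.backward(dp1) + ds1_skip
        self.conv1.backward(self.relu1.backward(ds1))


@dataclass
class TrainedModel:
    """A trained network plus its config and per-epoch loss log."""

    net: MultitaskNet
    config: NetworkConfig
    training_log: List[ent.LossBreakdown] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Functional interface
# ---------------------------------------------------------------------------


def build_model(cfg: NetworkConfig) -> MultitaskNet:
    """Instantiate an untrained network from a validated config."""
    return MultitaskNet(cfg)


def forward(model: MultitaskNet, volume: np.ndarray, clinical: np.ndarray) -> MultitaskOutput:
    """Run one patient through the network (deterministic evaluation)."""
    recon, _, prob = model.forward_batch(
        np.asarray(volume)[None], np.asarray(clinical)[None]
    )
    p = float(np.clip(prob[0], ent.EPS, 1.0 - ent.EPS))
    return MultitaskOutput(reconstruction=recon[0], recurrence_prob=p)


def _prediction_loss_and_grad(labels: np.ndarray, q: np.ndarray, cfg: NetworkConfig):
    batch = ent.BinaryBatch(labels, q)
    if cfg.loss == "shannon":
        loss = ent.binary_shannon_loss(batch)
        grad = ent.binary_thc_loss_gradient(batch, 1.0)
    else:
        loss = ent.binary_thc_loss(batch, cfg.alpha)
        grad = ent.binary_thc_loss_gradient(batch, cfg.alpha)
    return loss, grad


def train_model(
    model: MultitaskNet,
    volumes: np.ndarray,
    clinical: np.ndarray,
    labels: np.ndarray,
    cfg: Optional[NetworkConfig] = None,
    callback=None,
) -> TrainedModel:
    """Train on a cohort, minimizing ``w_rec * L_rec + w_pred * L_pred``.

    ``volumes`` is (N, D, H, W), ``clinical`` (N, F), ``labels`` (N,) in
    {0, 1}.  The per-epoch log records the weighted loss terms averaged
    over patients, with ``total = rec + pred`` exactly.  A non-finite loss
    aborts with a diagnostic naming the offending term.
    """
    cfg = cfg or model.cfg
    n = volumes.shape[0]
    if n < 1:
        raise ValueError("empty cohort")
    labels = np.asarray(labels, dtype=float)
    if not np.all(np.isin(labels, (0.0, 1.0))):
        raise ValueError("labels must be binary")
    w_rec, w_pred = cfg.loss_weights
    rng = np.random.default_rng(cfg.seed + 1)  # training shuffles; init used cfg.seed
    opt = Adam(model.layers(), lr=cfg.learning_rate)
    log: List[ent.LossBreakdown] = []
    tail: List[List[np.ndarray]] = []  # end-of-epoch snapshots for averaging
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        rec_sum = pred_sum = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            vol = volumes[idx].astype(DT)
            clin = clinical[idx].astype(DT)
            lab = labels[idx]
            b = len(idx)

            recon, logit, q = model.forward_batch(vol, clin)
            err = recon - vol
            l_rec = float((err**2).sum() / b)
            if not math.isfinite(l_rec):
                raise RuntimeError(
                    f"reconstruction loss became non-finite at epoch {epoch + 1}"
                )
            l_pred, dq = _prediction_loss_and_grad(lab, q, cfg)
            if not math.isfinite(l_pred):
                raise RuntimeError(
                    f"prediction loss became non-finite at epoch {epoch + 1}"
                )
            drecon = w_rec * 2.0 * err / b
            dlogit = w_pred * dq * q * (1.0 - q)
            model.backward_batch(drecon, dlogit)
            opt.step()
            rec_sum += w_rec * l_rec * b
            pred_sum += w_pred * l_pred * b
        entry = ent.total_loss(rec_sum / n, pred_sum / n)
        log.append(entry)
        if min(cfg.polyak_tail, cfg.epochs) > 1 and epoch >= cfg.epochs - cfg.polyak_tail:
            tail.append([p.copy() for p in model.parameters()])
        if callback is not None:
            callback(epoch, entry)
    if len(tail) > 1:
        # Polyak-style tail averaging damps end-of-training oscillation
        model.set_parameters(
            [np.mean(stack, axis=0) for stack in zip(*tail)]
        )
    return TrainedModel(net=model, config=cfg, training_log=log)


def predict(model: MultitaskNet, volume: np.ndarray, clinical: np.ndarray,
            threshold: float = 0.5) -> Tuple[int, float]:
    """Hard decision and probability; label 1 iff probability >= threshold."""
    out = forward(model, volume, clinical)
    return int(out.recurrence_prob >= threshold), out.recurrence_prob
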