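"""The 1D-CNN prediction head and joint gate+CNN training.

Each sample's combined feature vector (fused expert block followed by the
statistics block) is reshaped into a one-channel 1-D signal and passed
through convolutional blocks (conv -> ReLU -> batch-norm -> max-pool), a
global average pool, and fully connected layers ending in two logits.  The
positive-class probability is the softmax of the logits,

    p_i = exp(z_i1) / (exp(z_i0) + exp(z_i1)),

trained with mean binary cross-entropy; the predicted label is 1 when
p >= 0.5.  Gradients flow through the fusion step into the gating network,
so one Adam step updates the gate and the CNN jointly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .gating import (GateOutput, GateParams, gate_backward, gate_forward,
                     concat_combined, fuse, init_gate, softmax)
from .nn import (Adam, BatchNorm1D, Conv1D, Dense, Dropout, GlobalAvgPool,
                 MaxPool1D, ReLU, Sequential)

_EPS = 1e-12


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimization settings for the prediction head."""

    channels: tuple[int, ...] = (32, 64)
    kernel_size: int = 3
    pool_width: int = 2
    fc_width: int = 64
    dropout: float = 0.3
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 50
    gate_hidden: int = 64
    patience: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass(frozen=True)
class PredictionRecord:
    """Logits, positive probability, predicted label and gate weights."""

    sample_id: str
    z0: float
    z1: float
    p_hat: float
    y_hat: int
    alpha1: float
    alpha2: float


def build_cnn(config: ModelConfig, input_width: int,
              rng: np.random.Generator) -> Sequential:
    """Assemble the convolutional head for a given combined-feature width.

    Raises if the width is too small for the convolution or for any
    pooling stage, naming the offending stage.
    """
    if input_width < config.kernel_size:
        raise ValueError(
            f"input width {input_width} smaller than kernel size {config.kernel_size}"
        )
    layers = []
    c_in, length = 1, input_width
    for i, c_out in enumerate(config.channels):
        layers += [
            Conv1D(c_in, c_out, config.kernel_size, rng),
            ReLU(),
            BatchNorm1D(c_out),
            MaxPool1D(config.pool_width),
        ]
        length //= config.pool_width
        if length < 1:
            raise ValueError(
                f"conv block {i + 1}: max-pool reduces length below 1 "
                f"(input width {input_width} too small for {len(config.channels)} blocks)"
            )
        c_in = c_out
    layers += [
        GlobalAvgPool(),
        Dense(c_in, config.fc_width, rng),
        ReLU(),
        Dropout(config.dropout, rng),
        Dense(config.fc_width, 2, rng),
    ]
    return Sequential(layers)


def cross_entropy(labels: np.ndarray, probabilities: np.ndarray) -> float:
    """Mean binary cross-entropy from positive-class probabilities.

    Probabilities are clamped at 1e-12 before the logarithm.  Computing the
    loss from probabilities (rather than a fused log-softmax) mirrors the
    probability-space definition exactly; the fused form is numerically
    preferable in general and the two are asserted equivalent in tests away
    from the clamp region.
    """
    y = np.asarray(labels, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} probabilities")
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _loss_and_dlogits(labels: np.ndarray, logits: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss plus dL/dlogits; the clamp zeroes the gradient where it binds."""
    y = np.asarray(labels, dtype=float)
    p1 = softmax(logits)[:, 1]
    loss = cross_entropy(y, p1)
    active = (p1 > _EPS) & (p1 < 1.0 - _EPS)
    dz1 = np.where(active, (p1 - y) / len(y), 0.0)
    return loss, np.stack([-dz1, dz1], axis=1)


class MoEClassifier:
    """Gating network + 1D-CNN trained jointly on labeled pairs."""

    def __init__(self, s: int, d: int, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.s, self.d = s, d
        rng = np.random.default_rng(self.config.seed)
        self.gate = init_gate(s, hidden=self.config.gate_hidden,
                              seed=int(rng.integers(2**31)))
        self.cnn = build_cnn(self.config, input_width=d + s, rng=rng)
        self._train_rng = rng
        self.loss_history: list[float] = []

    # ---------------------------------------------------------------- forward

    def _check_widths(self, stats: np.ndarray, e1: np.ndarray, e2: np.ndarray) -> None:
        if stats.shape[1] != self.s:
            raise ValueError(f"stats width {stats.shape[1]} != model s={self.s}")
        if e1.shape[1] != self.d or e2.shape[1] != self.d:
            raise ValueError(
                f"expert widths ({e1.shape[1]}, {e2.shape[1]}) != model d={self.d}"
            )

    def forward(self, stats: np.ndarray, e1: np.ndarray, e2: np.ndarray,
                train: bool) -> tuple[GateOutput, np.ndarray, np.ndarray]:
        """Gate -> fuse -> concat -> CNN; returns (gate_out, combined, logits)."""
        self._check_widths(stats, e1, e2)
        gate_out = gate_forward(self.gate, stats)
        fused = fuse(gate_out.alpha, e1, e2)
        combined = concat_combined(fused, stats)
        logits = self.cnn.forward(combined[:, None, :], train)
        return gate_out, combined, logits

    def n_parameters(self) -> int:
        return self.cnn.n_parameters() + sum(
            p.size for p in (self.gate.W1, self.gate.b1, self.gate.W2, self.gate.b2)
        )

    # ----------------------------------------------------------------- training

    def fit(self, stats: np.ndarray, e1: np.ndarray, e2: np.ndarray,
            labels: np.ndarray, freeze_gate: bool = False) -> list[float]:
        """Train jointly with Adam; returns the per-epoch mean-loss trajectory.

        ``freeze_gate`` excludes the gating parameters from the update (used
        to probe gradient flow); by default gate and CNN move in one step.
        """
        stats = np.asarray(stats, dtype=float)
        e1 = np.asarray(e1, dtype=float)
        e2 = np.asarray(e2, dtype=float)
        labels = np.asarray(labels, dtype=int)
        self._check_widths(stats, e1, e2)
        if len(set(np.unique(labels))) < 2:
            raise ValueError("training set must contain both classes")

        cfg = self.config
        gate_arrays = [self.gate.W1, self.gate.b1, self.gate.W2, self.gate.b2]
        params = self.cnn.params + ([] if freeze_gate else gate_arrays)
        opt = Adam(params, lr=cfg.learning_rate)
        n = len(labels)
        best, since_best = np.inf, 0

        for epoch in range(cfg.epochs):
            order = self._train_rng.permutation(n)
            losses, weights = [], []
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                bs = stats[idx]
                be1, be2, by = e1[idx], e2[idx], labels[idx]

                gate_out, _, logits = self.forward(bs, be1, be2, train=True)
                loss, dlogits = _loss_and_dlogits(by, logits)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch + 1} "
                        f"(batch starting {start}); check inputs/learning rate"
                    )
                dcombined = self.cnn.backward(dlogits)[:, 0, :]
                dfused = dcombined[:, :self.d]
                dalpha = np.stack([(dfused * be1).sum(axis=1),
                                   (dfused * be2).sum(axis=1)], axis=1)
                ggrads = gate_backward(self.gate, bs, gate_out, dalpha)
                grads = self.cnn.grads + (
                    [] if freeze_gate
                    else [ggrads["W1"], ggrads["b1"], ggrads["W2"], ggrads["b2"]]
                )
                opt.step(grads)
                losses.append(loss)
                weights.append(len(idx))

            epoch_loss = float(np.average(losses, weights=weights))
            self.loss_history.append(epoch_loss)
            if cfg.patience is not None:
                if epoch_loss < best - 1e-6:
                    best, since_best = epoch_loss, 0
                else:
                    since_best += 1
                    if since_best >= cfg.patience:
                        break
        return self.loss_history

    # ---------------------------------------------------------------- predict

    def predict(self, stats: np.ndarray, e1: np.ndarray, e2: np.ndarray,
                sample_ids: list[str] | None = None,
                batch_size: int = 256) -> list[PredictionRecord]:
        """Deterministic inference (dropout off, batch-norm running stats)."""
        stats = np.atleast_2d(np.asarray(stats, dtype=float))
        e1 = np.atleast_2d(np.asarray(e1, dtype=float))
        e2 = np.atleast_2d(np.asarray(e2, dtype=float))
        self._check_widths(stats, e1, e2)
        ids = sample_ids or [f"sample_{i}" for i in range(len(stats))]
        records = []
        for start in range(0, len(stats), batch_size):
            sl = slice(start, start + batch_size)
            gate_out, _, logits = self.forward(stats[sl], e1[sl], e2[sl], train=False)
            p1 = softmax(logits)[:, 1]
            for i, sid in enumerate(ids[sl]):
                records.append(PredictionRecord(
                    sample_id=sid,
                    z0=float(logits[i, 0]), z1=float(logits[i, 1]),
                    p_hat=float(p1[i]), y_hat=int(p1[i] >= 0.5),
                    alpha1=float(gate_out.alpha[i, 0]),
                    alpha2=float(gate_out.alpha[i, 1]),
                ))
        return records

    # -------------------------------------------------------------- checkpoint

    def save(self, path: str | Path, extra_meta: dict | None = None) -> None:
        """Single-archive checkpoint: all parameters + running stats + metadata."""
        arrays: dict[str, np.ndarray] = {
            "gate_W1": self.gate.W1, "gate_b1": self.gate.b1,
            "gate_W2": self.gate.W2, "gate_b2": self.gate.b2,
        }
        for i, layer in enumerate(self.cnn.layers):
            for j, p in enumerate(layer.params):
                arrays[f"layer{i}_p{j}"] = p
            if isinstance(layer, BatchNorm1D):
                arrays[f"layer{i}_rmean"] = layer.running_mean
                arrays[f"layer{i}_rvar"] = layer.running_var
        meta = {
            "s": self.s, "d": self.d,
            "config": asdict(self.config),
            "package_version": __version__,
            "numpy_version": np.__version__,
        }
        if extra_meta:
            meta.update(extra_meta)
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> tuple["MoEClassifier", dict]:
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta_json"]).decode())
            cfg = dict(meta["config"])
            cfg["channels"] = tuple(cfg["channels"])
            model = cls(s=meta["s"], d=meta["d"], config=ModelConfig(**cfg))
            model.gate = GateParams(
                W1=data["gate_W1"].copy(), b1=data["gate_b1"].copy(),
                W2=data["gate_W2"].copy(), b2=data["gate_b2"].copy(),
            )
            for i, layer in enumerate(model.cnn.layers):
                for j in range(len(layer.params)):
                    layer.params[j][...] = data[f"layer{i}_p{j}"]
                if isinstance(layer, BatchNorm1D):
                    layer.running_mean = data[f"layer{i}_rmean"].copy()
                    layer.running_var = data[f"layer{i}_rvar"].copy()
        return model, meta
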