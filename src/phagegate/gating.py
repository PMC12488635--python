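"""The mixture-of-experts gating layer.

A two-layer feed-forward gating network maps each sample's statistics
vector to a pair of non-negative expert weights summing to one:

    H = ReLU(X_stats W1 + b1)        H in R^{N x hidden}
    G = H W2 + b2                    G in R^{N x 2}
    alpha = softmax(G)               alpha in R^{N x 2}

The weights form a per-sample convex combination of the two expert
embedding streams,

    X_fused,i = alpha_i1 * expert1_i + alpha_i2 * expert2_i,

and the fused vector is concatenated with the statistics block to give the
combined representation the classifier sees (widths d + s, 1024 + 26 =
1050 under the reference configuration).  Gating is strictly per sample:
two samples with identical statistics always receive identical weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_HIDDEN = 64
N_EXPERTS = 2


@dataclass
class GateParams:
    """Trainable parameters of the gating network."""

    W1: np.ndarray  # (s, hidden)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (hidden, 2)
    b2: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        s, hidden = self.W1.shape
        if self.b1.shape != (hidden,) or self.W2.shape != (hidden, N_EXPERTS) \
                or self.b2.shape != (N_EXPERTS,):
            raise ValueError("inconsistent gate parameter shapes")
        for arr in (self.W1, self.b1, self.W2, self.b2):
            if not np.all(np.isfinite(arr)):
                raise ValueError("gate parameters must be finite")

    @property
    def s(self) -> int:
        return self.W1.shape[0]

    @property
    def hidden(self) -> int:
        return self.W1.shape[1]

    def copy(self) -> "GateParams":
        return GateParams(self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy())


@dataclass(frozen=True)
class GateOutput:
    """Per-sample gate intermediates: hidden H, logits G and weights alpha."""

    hidden: np.ndarray  # (N, hidden)
    logits: np.ndarray  # (N, 2)
    alpha: np.ndarray   # (N, 2), rows on the probability simplex


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction for numerical stability."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def init_gate(s: int, hidden: int = DEFAULT_HIDDEN, seed: int = 0) -> GateParams:
    """Glorot-uniform weights, zero biases, fully seeded."""
    if s < 1:
        raise ValueError("stats width s must be >= 1")
    rng = np.random.default_rng(seed)

    def glorot(fan_in: int, fan_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    return GateParams(
        W1=glorot(s, hidden),
        b1=np.zeros(hidden),
        W2=glorot(hidden, N_EXPERTS),
        b2=np.zeros(N_EXPERTS),
    )


def gate_forward(params: GateParams, stats: np.ndarray) -> GateOutput:
    """Forward pass of the gating network over a batch of statistics rows."""
    stats = np.atleast_2d(np.asarray(stats, dtype=float))
    if stats.shape[1] != params.s:
        raise ValueError(f"stats width {stats.shape[1]} != gate s={params.s}")
    H = np.maximum(stats @ params.W1 + params.b1, 0.0)
    G = H @ params.W2 + params.b2
    return GateOutput(hidden=H, logits=G, alpha=softmax(G))


def gate_backward(
    params: GateParams,
    stats: np.ndarray,
    out: GateOutput,
    dalpha: np.ndarray,
) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss w.r.t. the gate parameters.

    ``dalpha`` is dL/dalpha, (N, 2).  Returns gradients keyed like the
    parameter fields.
    """
    stats = np.atleast_2d(np.asarray(stats, dtype=float))
    alpha = out.alpha
    # softmax Jacobian: dL/dG = alpha * (dalpha - sum(dalpha * alpha))
    dG = alpha * (dalpha - (dalpha * alpha).sum(axis=1, keepdims=True))
    dW2 = out.hidden.T @ dG
    db2 = dG.sum(axis=0)
    dH = dG @ params.W2.T
    dH *= out.hidden > 0  # ReLU mask
    dW1 = stats.T @ dH
    db1 = dH.sum(axis=0)
    return {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2}


def fuse(alpha: np.ndarray, expert1: np.ndarray, expert2: np.ndarray) -> np.ndarray:
    """Element-wise convex combination of the two expert streams.

    Works on one sample (alpha (2,), experts (d,)) or a batch (alpha
    (N, 2), experts (N, d)).
    """
    alpha = np.asarray(alpha, dtype=float)
    e1 = np.asarray(expert1, dtype=float)
    e2 = np.asarray(expert2, dtype=float)
    if e1.shape != e2.shape:
        raise ValueError(f"expert width mismatch: {e1.shape} vs {e2.shape}")
    if alpha.ndim == 1:
        return alpha[0] * e1 + alpha[1] * e2
    return alpha[:, [0]] * e1 + alpha[:, [1]] * e2


def concat_combined(fused: np.ndarray, stats: np.ndarray) -> np.ndarray:
    """Concatenate fused block first, then statistics: width d + s."""
    fused = np.asarray(fused, dtype=float)
    stats = np.asarray(stats, dtype=float)
    return np.concatenate([fused, stats], axis=-1)
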