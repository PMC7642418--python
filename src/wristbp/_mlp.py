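"""Minimal fully-connected regression network with batch normalization.

Numpy-only, full-batch Adam.  Hidden layers are linear -> batch norm ->
activation; the output layer is a plain affine map (two nodes for SBP and
DBP), so the final prediction is an exact linear read-out of the last
hidden activations — the property per-subject calibration relies on.

Training is deterministic given the seed: weights are initialized from a
seeded Generator and optimization is full-batch (no shuffling).  Inference
uses batch-norm statistics captured over the full training set after the
last update.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["MLPParams", "init_mlp", "forward", "fit_mlp", "predict_with_hidden"]

_BN_EPS = 1e-5


@dataclass
class MLPParams:
    """All learnable parameters plus the frozen inference-time BN stats."""

    hidden_sizes: tuple[int, ...]
    activation: str  # "relu" | "tanh"
    W: list = field(default_factory=list)        # per hidden layer, (n_out, n_in)
    gamma: list = field(default_factory=list)    # BN scale, (n_out,)
    beta: list = field(default_factory=list)     # BN shift, (n_out,)
    bn_mean: list = field(default_factory=list)  # inference stats, (n_out,)
    bn_var: list = field(default_factory=list)
    W_out: Optional[np.ndarray] = None           # (2, n_last)
    b_out: Optional[np.ndarray] = None           # (2,)

    def copy(self) -> "MLPParams":
        return MLPParams(
            hidden_sizes=self.hidden_sizes,
            activation=self.activation,
            W=[w.copy() for w in self.W],
            gamma=[g.copy() for g in self.gamma],
            beta=[b.copy() for b in self.beta],
            bn_mean=[m.copy() for m in self.bn_mean],
            bn_var=[v.copy() for v in self.bn_var],
            W_out=self.W_out.copy(),
            b_out=self.b_out.copy(),
        )


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "tanh":
        return np.tanh(z)
    raise ValueError(f"unknown activation {kind!r}")


def _act_grad(z: np.ndarray, h: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (z > 0.0).astype(float)
    return 1.0 - h**2  # tanh


def init_mlp(
    input_dim: int,
    hidden_sizes: tuple[int, ...],
    activation: str,
    n_outputs: int = 2,
    seed: int | np.random.SeedSequence = 0,
    y_mean: Optional[np.ndarray] = None,
) -> MLPParams:
    """He/Glorot-initialized network; output bias starts at the target mean."""
    if len(hidden_sizes) == 0:
        raise ValueError("need at least one hidden layer")
    rng = np.random.default_rng(seed)
    p = MLPParams(hidden_sizes=tuple(hidden_sizes), activation=activation)
    n_in = input_dim
    for n_out in hidden_sizes:
        scale = np.sqrt(2.0 / n_in) if activation == "relu" else np.sqrt(1.0 / n_in)
        p.W.append(rng.normal(0.0, scale, size=(n_out, n_in)))
        p.gamma.append(np.ones(n_out))
        p.beta.append(np.zeros(n_out))
        p.bn_mean.append(np.zeros(n_out))
        p.bn_var.append(np.ones(n_out))
        n_in = n_out
    p.W_out = rng.normal(0.0, 0.01, size=(n_outputs, n_in))
    p.b_out = np.zeros(n_outputs) if y_mean is None else np.asarray(y_mean, dtype=float).copy()
    return p


def forward(
    p: MLPParams, X: np.ndarray, training: bool = False
) -> tuple[np.ndarray, np.ndarray, Optional[list]]:
    """Return (predictions (m,2), final hidden activations (m,k), cache).

    ``training=True`` uses batch statistics for the normalization (and
    returns the cache needed for backprop); inference uses the stored
    statistics so single rows predict identically to batches.
    """
    h = X
    cache = [] if training else None
    for l in range(len(p.W)):
        a = h @ p.W[l].T
        if training:
            mu = a.mean(axis=0)
            var = a.var(axis=0)
        else:
            mu, var = p.bn_mean[l], p.bn_var[l]
        inv_sd = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (a - mu) * inv_sd
        z = p.gamma[l] * xhat + p.beta[l]
        h_new = _act(z, p.activation)
        if training:
            cache.append((h, xhat, inv_sd, z, h_new))
        h = h_new
    out = h @ p.W_out.T + p.b_out
    return out, h, cache


def _adam_state(p: MLPParams) -> list:
    return [
        (np.zeros_like(t), np.zeros_like(t))
        for t in (*p.W, *p.gamma, *p.beta, p.W_out, p.b_out)
    ]


def fit_mlp(
    p: MLPParams,
    X: np.ndarray,
    y: np.ndarray,
    lr: float = 0.01,
    max_epochs: int = 500,
    tol: float = 1e-6,
    X_val: Optional[np.ndarray] = None,
    y_val: Optional[np.ndarray] = None,
    patience: int = 15,
) -> tuple[MLPParams, dict]:
    """Full-batch Adam on the summed-over-outputs MSE.

    Stops on a relative training-loss plateau (``tol`` over 10 consecutive
    epochs) or, when a validation split is supplied, by early stopping with
    the given ``patience`` (best-validation parameters are restored).
    Returns the fitted params and a history dict.
    """
    m = X.shape[0]
    nL = len(p.W)
    adam = _adam_state(p)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    prev_loss = np.inf
    plateau = 0
    best_val = np.inf
    best_params: Optional[MLPParams] = None
    best_epoch = 0
    bad_checks = 0
    history = {"loss": [], "val_loss": []}

    for epoch in range(max_epochs):
        out, h_last, cache = forward(p, X, training=True)
        err = out - y
        loss = float((err**2).sum(axis=1).mean())
        history["loss"].append(loss)

        # Backward pass.
        grads_W = [None] * nL
        grads_gamma = [None] * nL
        grads_beta = [None] * nL
        d_out = 2.0 * err / m                      # (m, 2)
        gW_out = d_out.T @ h_last                  # (2, k)
        gb_out = d_out.sum(axis=0)
        dh = d_out @ p.W_out                       # (m, k)
        for l in range(nL - 1, -1, -1):
            h_in, xhat, inv_sd, z, h_out = cache[l]
            dz = dh * _act_grad(z, h_out, p.activation)
            grads_gamma[l] = (dz * xhat).sum(axis=0)
            grads_beta[l] = dz.sum(axis=0)
            dxhat = dz * p.gamma[l]
            da = (
                dxhat
                - dxhat.mean(axis=0)
                - xhat * (dxhat * xhat).mean(axis=0)
            ) * inv_sd
            grads_W[l] = da.T @ h_in
            dh = da @ p.W[l]

        # Adam update over the flattened parameter list.
        step += 1
        params = [*p.W, *p.gamma, *p.beta, p.W_out, p.b_out]
        grads = [*grads_W, *grads_gamma, *grads_beta, gW_out, gb_out]
        corr1 = 1.0 - beta1**step
        corr2 = 1.0 - beta2**step
        for t, g, (mom, vel) in zip(params, grads, adam):
            mom *= beta1
            mom += (1 - beta1) * g
            vel *= beta2
            vel += (1 - beta2) * g**2
            t -= lr * (mom / corr1) / (np.sqrt(vel / corr2) + eps)

        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss; aborting fit")

        if X_val is not None:
            _freeze_bn_stats(p, X)
            val_out, _, _ = forward(p, X_val, training=False)
            val_loss = float(((val_out - y_val) ** 2).sum(axis=1).mean())
            history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_params = p.copy()
                best_epoch = epoch
                bad_checks = 0
            else:
                bad_checks += 1
                if bad_checks >= patience:
                    break

        rel = abs(prev_loss - loss) / max(prev_loss, 1e-12)
        plateau = plateau + 1 if rel < tol else 0
        if plateau >= 10:
            break
        prev_loss = loss

    if best_params is not None:
        p = best_params
        history["best_epoch"] = best_epoch
    _freeze_bn_stats(p, X)
    return p, history


def _freeze_bn_stats(p: MLPParams, X: np.ndarray) -> None:
    """Capture full-training-set BN statistics for inference."""
    h = X
    for l in range(len(p.W)):
        a = h @ p.W[l].T
        p.bn_mean[l] = a.mean(axis=0)
        p.bn_var[l] = a.var(axis=0)
        inv_sd = 1.0 / np.sqrt(p.bn_var[l] + _BN_EPS)
        z = p.gamma[l] * (a - p.bn_mean[l]) * inv_sd + p.beta[l]
        h = _act(z, p.activation)


def predict_with_hidden(p: MLPParams, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    out, hidden, _ = forward(p, X, training=False)
    return out, hidden
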