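"""Minimal feed-forward neural-network core in NumPy.

Implements exactly the building blocks the synergy-regression architecture
needs -- affine layers, ReLU, FiLM conditioning, a symmetric bilinear pairing
tensor, dropout, Adam with L2 regularisation, and an early-stopping training
loop -- with hand-derived backpropagation.  Everything is float64 and batch
oriented; parameter containers are plain dicts of ndarrays so checkpointing
is a ``dict`` copy.
"""

from __future__ import annotations

import copy
from typing import Callable

import numpy as np

__all__ = [
    "init_mlp",
    "mlp_forward",
    "mlp_backward",
    "init_film",
    "sym_bilinear_forward",
    "sym_bilinear_backward",
    "Adam",
    "train_loop",
]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_mlp(rng: np.random.Generator, dims: list[int]) -> dict[str, np.ndarray]:
    """Affine stack ``dims[0] -> ... -> dims[-1]``; ReLU between layers only."""
    params: dict[str, np.ndarray] = {}
    for i in range(len(dims) - 1):
        params[f"W{i}"] = _glorot(rng, dims[i], dims[i + 1])
        params[f"b{i}"] = np.zeros(dims[i + 1])
    return params


def init_film(rng: np.random.Generator, l_c: int, widths: list[int]) -> dict[str, np.ndarray]:
    """Linear FiLM maps (cell features -> per-unit scale gamma and shift beta).

    Initialised at the neutral transform: gamma(c) = 1, beta(c) = 0 for all c.
    """
    params: dict[str, np.ndarray] = {}
    for i, w in enumerate(widths):
        params[f"Wg{i}"] = np.zeros((l_c, w))
        params[f"bg{i}"] = np.ones(w)
        params[f"Wb{i}"] = np.zeros((l_c, w))
        params[f"bb{i}"] = np.zeros(w)
    return params


def mlp_forward(
    params: dict[str, np.ndarray],
    n_layers: int,
    x: np.ndarray,
    film: dict[str, np.ndarray] | None = None,
    cell: np.ndarray | None = None,
    dropout: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
):
    """Forward pass; returns (output, cache).

    Hidden layers apply affine -> (FiLM) -> ReLU; the final layer is affine
    only.  ``dropout=(p_in, p_hidden)`` applies inverted dropout to the input
    and each hidden activation (training mode; pass None at evaluation).
    """
    cache: dict = {"inputs": [], "pre": [], "film": [], "masks": []}
    h = x
    if dropout is not None and dropout[0] > 0:
        mask = (rng.random(h.shape) >= dropout[0]) / (1 - dropout[0])
        h = h * mask
        cache["in_mask"] = mask
    for i in range(n_layers):
        cache["inputs"].append(h)
        a = h @ params[f"W{i}"] + params[f"b{i}"]
        last = i == n_layers - 1
        if last:
            h = a
            cache["pre"].append(a)
            cache["film"].append(None)
            cache["masks"].append(None)
            continue
        if film is not None and cell is not None and f"Wg{i}" in film:
            g = cell @ film[f"Wg{i}"] + film[f"bg{i}"]
            be = cell @ film[f"Wb{i}"] + film[f"bb{i}"]
            m = g * a + be
            cache["film"].append((a, g))
        else:
            m = a
            cache["film"].append(None)
        cache["pre"].append(m)
        h = np.maximum(m, 0.0)
        if dropout is not None and dropout[1] > 0:
            mask = (rng.random(h.shape) >= dropout[1]) / (1 - dropout[1])
            h = h * mask
            cache["masks"].append(mask)
        else:
            cache["masks"].append(None)
    return h, cache


def mlp_backward(
    params: dict[str, np.ndarray],
    n_layers: int,
    cache: dict,
    dout: np.ndarray,
    grads: dict[str, np.ndarray],
    film: dict[str, np.ndarray] | None = None,
    film_grads: dict[str, np.ndarray] | None = None,
    cell: np.ndarray | None = None,
) -> np.ndarray:
    """Backprop through :func:`mlp_forward`; accumulates into ``grads`` and
    returns the gradient w.r.t. the input."""
    dh = dout
    for i in reversed(range(n_layers)):
        last = i == n_layers - 1
        if not last:
            if cache["masks"][i] is not None:
                dh = dh * cache["masks"][i]
            dm = dh * (cache["pre"][i] > 0)
            if cache["film"][i] is not None:
                a, g = cache["film"][i]
                dg = dm * a
                dbe = dm
                film_grads[f"Wg{i}"] = film_grads.get(f"Wg{i}", 0) + cell.T @ dg
                film_grads[f"bg{i}"] = film_grads.get(f"bg{i}", 0) + dg.sum(0)
                film_grads[f"Wb{i}"] = film_grads.get(f"Wb{i}", 0) + cell.T @ dbe
                film_grads[f"bb{i}"] = film_grads.get(f"bb{i}", 0) + dbe.sum(0)
                da = dm * g
            else:
                da = dm
        else:
            da = dh
        x = cache["inputs"][i]
        grads[f"W{i}"] = grads.get(f"W{i}", 0) + x.T @ da
        grads[f"b{i}"] = grads.get(f"b{i}", 0) + da.sum(0)
        dh = da @ params[f"W{i}"].T
    if "in_mask" in cache:
        dh = dh * cache["in_mask"]
    return dh


def sym_bilinear_forward(W: np.ndarray, e1: np.ndarray, e2: np.ndarray) -> np.ndarray:
    """z[n, i] = e1[n] @ sym(W[i]) @ e2[n], with sym(A) = (A + A.T)/2.

    Symmetrising every slice at evaluation time makes the pairing exactly
    order-invariant while keeping the stored tensor unconstrained.
    """
    S = 0.5 * (W + W.transpose(0, 2, 1))
    return np.einsum("ni,kij,nj->nk", e1, S, e2, optimize=True)


def sym_bilinear_backward(
    W: np.ndarray, e1: np.ndarray, e2: np.ndarray, dz: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    S = 0.5 * (W + W.transpose(0, 2, 1))
    dS = np.einsum("nk,ni,nj->kij", dz, e1, e2, optimize=True)
    dW = 0.5 * (dS + dS.transpose(0, 2, 1))
    de1 = np.einsum("nk,kij,nj->ni", dz, S, e2, optimize=True)
    de2 = np.einsum("nk,kij,ni->nj", dz, S, e1, optimize=True)
    return dW, de1, de2


class Adam:
    """Adam with additive L2 weight decay on matrix parameters."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 weight_decay: float = 0.0, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in params.items():
            g = grads.get(k)
            if g is None:
                continue
            g = np.asarray(g, dtype=float)
            if self.wd > 0 and p.ndim > 1:  # decay weights, not biases/gains
                g = g + self.wd * p
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_loop(
    params: dict[str, np.ndarray],
    step_fn: Callable[[np.ndarray], float],
    val_fn: Callable[[], float],
    n_train: int,
    batch_size: int,
    max_epochs: int,
    patience: int,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], dict]:
    """Generic minibatch loop with early stopping on a validation criterion.

    ``step_fn(idx)`` performs one optimisation step on the rows ``idx`` and
    returns the minibatch loss; ``val_fn()`` returns the current validation
    loss.  Weights are restored to the best-validation checkpoint.
    """
    best_val = np.inf
    best_params = copy.deepcopy(params)
    wait = 0
    trace: list[float] = []
    epochs_run = 0
    for epoch in range(max_epochs):
        epochs_run = epoch + 1
        order = rng.permutation(n_train)
        losses = []
        for start in range(0, n_train, batch_size):
            idx = order[start:start + batch_size]
            loss = step_fn(idx)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            losses.append(loss)
        trace.append(float(np.mean(losses)))
        val = val_fn()
        if val < best_val - 1e-12:
            best_val = val
            best_params = copy.deepcopy(params)
            wait = 0
        else:
            wait += 1
            if wait >= patience:
                break
    params.update(best_params)
    report = {
        "epochs_run": epochs_run,
        "best_validation_mse": float(best_val),
        "train_loss_trace": trace,
    }
    return params, report
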