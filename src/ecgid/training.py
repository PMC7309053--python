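"""Training harness: stratified splitting, cross-entropy + Adam with full
backpropagation through time, and evaluation with the multi-class metric
suite.

The loss is the mean cross-entropy between softmax(fused window score) and
the one-hot subject label. Gradients flow through the fusion average, the
output projection, and every LSTM track (forward and backward) of every
layer. Optimization is Adam with the standard moment defaults
(beta1=0.9, beta2=0.999, eps=1e-8) and learning rate 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import EvalReport, report_from_predictions
from .model import BiDRNNModel, LSTMCellParams, _scan_forward, fuse_scores, softmax
from .records import ConfigurationError
from .segmentation import SegmentSet

__all__ = ["TrainConfig", "split_dataset", "train", "evaluate", "encode_labels"]


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    Defaults follow the standard recipe for this classifier family:
    cross-entropy loss, Adam, learning rate 0.001, 80/20 train/test split.
    Epochs default to 50 with early stopping on a loss plateau.
    """

    learning_rate: float = 0.001
    batch_size: int = 100
    epochs: int = 50
    split_fraction: float = 0.8
    seed: int = 0
    keep_prob: float = 1.0
    split_mode: str = "stratified"  # or "temporal" (chronological per class)
    early_stop_tol: float = 5e-3  # stop once training loss falls below this
    early_stop_patience: int = 16  # or after this many epochs without improvement
    max_grad_norm: float = 5.0  # global-norm gradient clipping (0 disables)
    lr_decay_patience: int = 5  # halve the learning rate after this many
    lr_decay_factor: float = 0.5  # epochs without improvement (0 disables)
    min_learning_rate: float = 1e-4
    compute_dtype: str = "float64"  # forward/backward precision during
    # training; "float32" runs ~1.6x faster with master weights and Adam
    # state kept in float64

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ConfigurationError("split_fraction must be in (0, 1)")
        if not 0 < self.keep_prob <= 1:
            raise ConfigurationError("keep_prob must be in (0, 1]")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ConfigurationError("learning_rate, batch_size, epochs must be positive")
        if self.split_mode not in ("stratified", "temporal"):
            raise ConfigurationError(f"unknown split_mode {self.split_mode!r}")
        if self.compute_dtype not in ("float32", "float64"):
            raise ConfigurationError(f"unknown compute_dtype {self.compute_dtype!r}")


def encode_labels(labels: list[str], class_names: list[str]) -> np.ndarray:
    index = {name: k for k, name in enumerate(class_names)}
    try:
        return np.asarray([index[lab] for lab in labels], dtype=np.int64)
    except KeyError as exc:
        raise ConfigurationError(f"label {exc.args[0]!r} not in class set") from exc


def split_dataset(segments: SegmentSet, config: TrainConfig) -> tuple[SegmentSet, SegmentSet]:
    """Per-class split at `split_fraction`; every class lands in both halves.

    Stratified mode shuffles within each class with the config seed;
    temporal mode assigns the chronologically first fraction of each
    class's windows to training. The test half always gets at least one
    window per class.
    """
    labels = np.asarray(segments.labels)
    rng = np.random.default_rng(config.seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in sorted(set(segments.labels)):
        idx = np.flatnonzero(labels == cls)
        n_c = idx.size
        if n_c < 2:
            raise ConfigurationError(
                f"class {cls!r} has only {n_c} window(s); need at least 2 to split"
            )
        n_test = n_c - int(round(config.split_fraction * n_c))
        n_test = min(max(1, n_test), n_c - 1)
        if config.split_mode == "stratified":
            idx = rng.permutation(idx)
            test_part, train_part = idx[:n_test], idx[n_test:]
        else:
            train_part, test_part = idx[: n_c - n_test], idx[n_c - n_test :]
        train_idx.extend(train_part.tolist())
        test_idx.extend(test_part.tolist())
    train_idx.sort()
    test_idx.sort()

    def subset(which: list[int]) -> SegmentSet:
        return SegmentSet(
            segments.windows[which],
            [segments.labels[i] for i in which],
            segments.source_rate_hz,
            segments.mode,
        )

    return subset(train_idx), subset(test_idx)


# --------------------------------------------------------------------------
# backpropagation through time
# --------------------------------------------------------------------------


def _lstm_backward(dH: np.ndarray, cache: dict, cell: LSTMCellParams):
    """BPTT through one left-to-right track. Returns dX and (dU, dW, db).

    Only the recurrent coupling dh_{t-1} = dz_t @ W.T has to run inside the
    time loop; the weight gradients and dX are single large products over
    the accumulated pre-activation gradients dz.
    """
    B, T, Hd = dH.shape
    X = cache["X"]
    dZ = np.empty((B, T, 4 * Hd), dtype=dH.dtype)
    dh_next = np.zeros((B, Hd), dtype=dH.dtype)
    dc_next = np.zeros((B, Hd), dtype=dH.dtype)
    tanh_g = cell.activation_g == "tanh"
    W_T = cell.W.T
    for t in range(T - 1, -1, -1):
        i = cache["i"][:, t]
        f = cache["f"][:, t]
        g = cache["g"][:, t]
        o = cache["o"][:, t]
        c = cache["c"][:, t]
        c_prev = cache["c_prev"][:, t]
        dh = dH[:, t] + dh_next
        tanh_c = np.tanh(c)
        do = dh * tanh_c
        dc = dh * o * (1.0 - tanh_c * tanh_c) + dc_next
        dc_next = dc * f
        dz = dZ[:, t]
        dz[:, 0 * Hd : 1 * Hd] = dc * g * i * (1.0 - i)
        dz[:, 1 * Hd : 2 * Hd] = dc * c_prev * f * (1.0 - f)
        dg = dc * i
        dz[:, 2 * Hd : 3 * Hd] = dg * (1.0 - g * g) if tanh_g else dg * g * (1.0 - g)
        dz[:, 3 * Hd : 4 * Hd] = do * o * (1.0 - o)
        dh_next = dz @ W_T
    dZ_flat = dZ.reshape(-1, 4 * Hd)
    dU = X.reshape(-1, X.shape[-1]).T @ dZ_flat
    dW = cache["h_prev"].reshape(-1, Hd).T @ dZ_flat
    db = dZ_flat.sum(axis=0)
    dX = dZ @ cell.U.T
    return dX, (dU, dW, db)


def _cast_model(model: BiDRNNModel, dtype) -> BiDRNNModel:
    """Shallow compute copy of the model with weights cast to `dtype`."""
    from .model import LayerParams

    layers = []
    for layer in model.layers:
        fwd = LSTMCellParams(
            layer.forward_cell.U.astype(dtype),
            layer.forward_cell.W.astype(dtype),
            layer.forward_cell.b.astype(dtype),
            layer.forward_cell.activation_g,
        )
        bwd = None
        if layer.backward_cell is not None:
            bwd = LSTMCellParams(
                layer.backward_cell.U.astype(dtype),
                layer.backward_cell.W.astype(dtype),
                layer.backward_cell.b.astype(dtype),
                layer.backward_cell.activation_g,
            )
        layers.append(LayerParams(fwd, bwd))
    return BiDRNNModel(
        layers,
        model.output_weight.astype(dtype),
        model.output_bias.astype(dtype),
        fusion=model.fusion,
        arch_id=model.arch_id,
        class_names=model.class_names,
    )


def loss_and_grads(
    model: BiDRNNModel,
    X: np.ndarray,
    y: np.ndarray,
    keep_prob: float = 1.0,
    rng: np.random.Generator | None = None,
    dtype=None,
):
    """Mean cross-entropy and gradients in `model.parameters()` order.

    X is (B, T, D); y is (B,) integer class indices. Inverted dropout with
    the given keep probability is applied between stacked layers when
    keep_prob < 1 (training only). With ``dtype=np.float32`` the forward
    and backward passes run in single precision on a cast copy of the
    weights (the caller's master weights are untouched).
    """
    if dtype is not None and model.parameters()[0].dtype != dtype:
        model = _cast_model(model, dtype)
        X = X.astype(dtype, copy=False)
    B = X.shape[0]
    A = X
    layer_caches = []
    for layer in model.layers:
        Hf, cf = _scan_forward(A, layer.forward_cell, want_cache=True)
        if layer.backward_cell is not None:
            Hb_rev, cb = _scan_forward(A[:, ::-1], layer.backward_cell, want_cache=True)
            out = np.concatenate([Hf, Hb_rev[:, ::-1]], axis=-1)
        else:
            cb = None
            out = Hf
        mask = None
        if keep_prob < 1.0 and layer is not model.layers[-1]:
            if rng is None:
                raise ValueError("dropout requires an rng")
            mask = ((rng.random(out.shape) < keep_prob) / keep_prob).astype(out.dtype)
            out = out * mask
        layer_caches.append({"cf": cf, "cb": cb, "mask": mask})
        A = out

    scores = A @ model.output_weight + model.output_bias  # (B, T, C)
    Y = fuse_scores(model, scores)  # (B, C)
    P = softmax(Y, axis=1)
    eps = 1e-12
    loss = float(-np.mean(np.log(P[np.arange(B), y] + eps)))

    dY = P.copy()
    dY[np.arange(B), y] -= 1.0
    dY /= B
    T = scores.shape[1]
    dScores = np.zeros_like(scores)
    if model.fusion == "late_sum":
        dScores[:] = dY[:, None, :] / T
    else:
        dScores[:, -1] = dY

    top_dim = model.output_weight.shape[0]
    dWp = A.reshape(-1, top_dim).T @ dScores.reshape(-1, model.num_classes)
    dbp = dScores.sum(axis=(0, 1))
    dA = dScores @ model.output_weight.T

    grads_per_layer = []
    for layer, cache in zip(reversed(model.layers), reversed(layer_caches)):
        if cache["mask"] is not None:
            dA = dA * cache["mask"]
        if layer.backward_cell is not None:
            Hd = layer.forward_cell.hidden_dim
            dHf, dHb = dA[..., :Hd], dA[..., Hd:]
            dXf, gf = _lstm_backward(dHf, cache["cf"], layer.forward_cell)
            dXb_rev, gb = _lstm_backward(
                dHb[:, ::-1], cache["cb"], layer.backward_cell
            )
            dA = dXf + dXb_rev[:, ::-1]
            grads_per_layer.append(list(gf) + list(gb))
        else:
            dXf, gf = _lstm_backward(dA, cache["cf"], layer.forward_cell)
            dA = dXf
            grads_per_layer.append(list(gf))

    grads: list[np.ndarray] = []
    for layer_grads in reversed(grads_per_layer):
        grads.extend(layer_grads)
    grads += [dWp, dbp]
    return loss, grads


class Adam:
    """Standard Adam; updates the parameter arrays of a model in place."""

    def __init__(self, params: list[np.ndarray], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def train(
    model: BiDRNNModel, train_set: SegmentSet, config: TrainConfig
) -> tuple[BiDRNNModel, list[float]]:
    """Fit the model on the training windows; returns (model, loss trace).

    Labels are one-hot encoded against the model's class set (taken from
    ``model.class_names`` or, if unset, the sorted unique training labels).
    Mini-batches are reshuffled each epoch with the config seed, so the
    loss trace is fully reproducible. When training stops (cap, loss
    tolerance, or plateau patience), the parameters of the best-loss epoch
    are restored, so a late instability spike cannot be the final state.
    """
    if len(train_set) == 0:
        raise ConfigurationError("empty training set")
    class_names = model.class_names or sorted(set(train_set.labels))
    if len(class_names) != model.num_classes:
        raise ConfigurationError(
            f"model has {model.num_classes} outputs but {len(class_names)} classes found"
        )
    model.class_names = list(class_names)
    y = encode_labels(train_set.labels, class_names)
    compute_dtype = np.float32 if config.compute_dtype == "float32" else np.float64
    X = train_set.windows[:, :, None].astype(compute_dtype)
    n = X.shape[0]
    rng = np.random.default_rng(config.seed)
    params = model.parameters()
    opt = Adam(params, lr=config.learning_rate)
    trace: list[float] = []
    best = np.inf
    best_params = [p.copy() for p in params]
    stale = 0
    for _ in range(config.epochs):
        perm = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            loss, grads = loss_and_grads(
                model, X[idx], y[idx], keep_prob=config.keep_prob, rng=rng,
                dtype=compute_dtype,
            )
            if config.max_grad_norm > 0:
                gnorm = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
                if gnorm > config.max_grad_norm:
                    scale = config.max_grad_norm / gnorm
                    grads = [g * scale for g in grads]
            opt.step(grads)
            total += loss * idx.size
        epoch_loss = total / n
        trace.append(epoch_loss)
        if epoch_loss < best - 1e-4:
            best = epoch_loss
            for snap, p in zip(best_params, params):
                snap[...] = p
            stale = 0
        else:
            stale += 1
        if epoch_loss < config.early_stop_tol or stale >= config.early_stop_patience:
            break
        # plateau learning-rate decay: smaller steps stop the late-phase
        # instability spikes that a fixed rate produces on long windows
        if (
            config.lr_decay_patience > 0
            and stale > 0
            and stale % config.lr_decay_patience == 0
            and opt.lr > config.min_learning_rate
        ):
            opt.lr = max(opt.lr * config.lr_decay_factor, config.min_learning_rate)
    for p, snap in zip(params, best_params):
        p[...] = snap
    return model, trace


def evaluate(
    model: BiDRNNModel, test_set: SegmentSet, batch_size: int = 64
) -> EvalReport:
    """Score the model on held-out windows with the full metric suite."""
    if len(test_set) == 0:
        raise ConfigurationError("cannot evaluate on an empty test set")
    class_names = model.class_names or sorted(set(test_set.labels))
    y_true = encode_labels(test_set.labels, class_names)
    X = test_set.windows[:, :, None]
    preds = []
    from .model import model_forward_batch, fuse_scores as _fuse

    for start in range(0, X.shape[0], batch_size):
        scores = model_forward_batch(model, X[start : start + batch_size])
        preds.append(np.argmax(_fuse(model, scores), axis=1))
    y_pred = np.concatenate(preds)
    return report_from_predictions(y_true, y_pred, model.num_classes, list(class_names))
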