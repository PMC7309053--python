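"""Bidirectional deep-LSTM classifier with late score fusion.

The recurrent unit is a standard LSTM memory cell with four gates acting on
the current input x_t and the previous hidden state h_{t-1}:

    i_t = sigmoid(U_i x_t + W_i h_{t-1} + b_i)        (input gate)
    f_t = sigmoid(U_f x_t + W_f h_{t-1} + b_f)        (forget gate)
    g_t = tanh   (U_g x_t + W_g h_{t-1} + b_g)        (input modulation)
    o_t = sigmoid(U_o x_t + W_o h_{t-1} + b_o)        (output gate)
    c_t = f_t * c_{t-1} + g_t * i_t                   (internal state)
    h_t = tanh(c_t) * o_t                             (hidden state)

Layers can run unidirectionally (left to right) or bidirectionally (a
forward and a backward track whose hidden states are concatenated per time
step before the next layer). A linear output projection maps each top-layer
time step to a class-score vector; the window-level prediction is either
the mean of those per-step scores (late fusion, "sum rule") or the last
step's score, followed by a softmax.

Six registry architectures are provided: 1-3 layers of unidirectional LSTM
with last-step readout (Arch 1-3) and 1-3 bidirectional layers with late
fusion (Arch 4-6).

Everything is plain NumPy (float64); training-time backpropagation lives in
:mod:`ecgid.training`.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LSTMCellParams",
    "CellState",
    "BiDRNNModel",
    "LayerParams",
    "lstm_cell_step",
    "run_layer",
    "forward_pass",
    "late_fusion",
    "softmax",
    "classify",
    "build_architecture",
    "ARCHITECTURES",
    "save_checkpoint",
    "load_checkpoint",
]

# gate column order inside the fused weight matrices
_GATES = ("i", "f", "g", "o")


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(scores: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically safe softmax (max-subtracted)."""
    z = scores - np.max(scores, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


@dataclass
class LSTMCellParams:
    """Fused parameters of one LSTM cell.

    ``U`` is (input_dim, 4*hidden), ``W`` is (hidden, 4*hidden), ``b`` is
    (4*hidden,), with gate columns ordered (input, forget, modulation,
    output). Per-gate views are exposed as ``U_i``, ``W_f``, ``b_g`` etc.
    ``activation_g`` selects the modulation-gate nonlinearity: ``"tanh"``
    (default) or ``"sigmoid"``.
    """

    U: np.ndarray
    W: np.ndarray
    b: np.ndarray
    activation_g: str = "tanh"

    def __post_init__(self) -> None:
        # float32 is accepted so training can run in reduced precision;
        # anything else is promoted to float64
        def _as_float(a):
            arr = np.asarray(a)
            return arr if arr.dtype in (np.float32, np.float64) else arr.astype(float)

        self.U = _as_float(self.U)
        self.W = _as_float(self.W)
        self.b = _as_float(self.b)
        h = self.hidden_dim
        if self.U.shape[1] != 4 * h or self.b.shape != (4 * h,):
            raise ValueError("inconsistent gate dimensions")
        if self.W.shape != (h, 4 * h):
            raise ValueError("W must be (hidden, 4*hidden)")
        for arr in (self.U, self.W, self.b):
            if not np.all(np.isfinite(arr)):
                raise ValueError("cell parameters must be finite")
        if self.activation_g not in ("tanh", "sigmoid"):
            raise ValueError(f"unknown activation_g {self.activation_g!r}")

    @property
    def input_dim(self) -> int:
        return int(self.U.shape[0])

    @property
    def hidden_dim(self) -> int:
        return int(self.W.shape[0]) if self.W.ndim == 2 else int(self.b.size // 4)

    def _gate_slice(self, gate: str) -> slice:
        k = _GATES.index(gate)
        h = self.hidden_dim
        return slice(k * h, (k + 1) * h)

    def __getattr__(self, name: str):
        # U_i, W_f, b_g, ... views into the fused arrays
        if len(name) == 3 and name[1] == "_" and name[0] in "UWb" and name[2] in "ifgo":
            arr = object.__getattribute__(self, name[0])
            sl = self._gate_slice(name[2])
            return arr[..., sl]
        raise AttributeError(name)

    @classmethod
    def from_gates(cls, gates: dict, activation_g: str = "tanh") -> "LSTMCellParams":
        """Build from per-gate (U, W, b) triples keyed 'i', 'f', 'g', 'o'."""
        U = np.concatenate([np.atleast_2d(gates[g][0]) for g in _GATES], axis=1)
        W = np.concatenate([np.atleast_2d(gates[g][1]) for g in _GATES], axis=1)
        b = np.concatenate([np.atleast_1d(gates[g][2]) for g in _GATES])
        return cls(U, W, b, activation_g)

    @classmethod
    def glorot_init(
        cls,
        input_dim: int,
        hidden_dim: int,
        rng: np.random.Generator,
        activation_g: str = "tanh",
        forget_bias: float = 1.0,
    ) -> "LSTMCellParams":
        """Uniform fan-based initialization; forget-gate bias set positive."""
        su = np.sqrt(6.0 / (input_dim + hidden_dim))
        sw = np.sqrt(6.0 / (2 * hidden_dim))
        U = rng.uniform(-su, su, size=(input_dim, 4 * hidden_dim))
        W = rng.uniform(-sw, sw, size=(hidden_dim, 4 * hidden_dim))
        b = np.zeros(4 * hidden_dim)
        b[hidden_dim : 2 * hidden_dim] = forget_bias
        return cls(U, W, b, activation_g)


@dataclass
class CellState:
    """Hidden state h and internal state c of one cell (or a batch)."""

    h: np.ndarray
    c: np.ndarray

    @classmethod
    def zeros(cls, hidden_dim: int, batch: int | None = None, dtype=np.float64) -> "CellState":
        shape = (hidden_dim,) if batch is None else (batch, hidden_dim)
        return cls(np.zeros(shape, dtype=dtype), np.zeros(shape, dtype=dtype))


def _gate_activations(x_t, h_prev, params: LSTMCellParams):
    h = params.hidden_dim
    z = x_t @ params.U + h_prev @ params.W + params.b
    i = sigmoid(z[..., 0 * h : 1 * h])
    f = sigmoid(z[..., 1 * h : 2 * h])
    zg = z[..., 2 * h : 3 * h]
    g = np.tanh(zg) if params.activation_g == "tanh" else sigmoid(zg)
    o = sigmoid(z[..., 3 * h : 4 * h])
    return i, f, g, o


def lstm_cell_step(x_t: np.ndarray, prev: CellState, params: LSTMCellParams) -> CellState:
    """One LSTM time step; works on single vectors or leading batch axes."""
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape[-1] != params.input_dim:
        raise ValueError(
            f"input dim {x_t.shape[-1]} != cell input dim {params.input_dim}"
        )
    i, f, g, o = _gate_activations(x_t, prev.h, params)
    c = f * prev.c + g * i
    h = np.tanh(c) * o
    return CellState(h=h, c=c)


def run_layer(
    inputs: np.ndarray, cell: LSTMCellParams, direction: str = "forward"
) -> np.ndarray:
    """Run one LSTM track over a sequence from zero initial state.

    `inputs` is (T, input_dim) or (B, T, input_dim). The backward direction
    consumes the sequence right-to-left and returns hidden states re-aligned
    to input order. Output has shape (..., T, hidden_dim).
    """
    if direction not in ("forward", "backward"):
        raise ValueError(f"unknown direction {direction!r}")
    inputs = np.asarray(inputs, dtype=float)
    single = inputs.ndim == 2
    X = inputs[None] if single else inputs
    if X.shape[1] == 0:
        raise ValueError("run_layer requires a non-empty sequence")
    if direction == "backward":
        X = X[:, ::-1]
    H, _ = _scan_forward(X, cell)
    if direction == "backward":
        H = H[:, ::-1]
    return H[0] if single else H


def _scan_forward(X: np.ndarray, cell: LSTMCellParams, want_cache: bool = False):
    """Left-to-right scan over X (B, T, D). Returns H (B, T, hidden), cache.

    The input-to-gate projection X @ U + b has no recurrence, so it is
    computed for all time steps in one matrix product before the loop.
    """
    B, T, _ = X.shape
    Hd = cell.hidden_dim
    tanh_g = cell.activation_g == "tanh"
    ZX = X @ cell.U + cell.b  # (B, T, 4H): input contribution to all gates
    dt = ZX.dtype
    H = np.empty((B, T, Hd), dtype=dt)
    state = CellState.zeros(Hd, batch=B, dtype=dt)
    cache = None
    if want_cache:
        cache = {
            "i": np.empty((B, T, Hd), dtype=dt),
            "f": np.empty((B, T, Hd), dtype=dt),
            "g": np.empty((B, T, Hd), dtype=dt),
            "o": np.empty((B, T, Hd), dtype=dt),
            "c": np.empty((B, T, Hd), dtype=dt),
            "h_prev": np.empty((B, T, Hd), dtype=dt),
            "c_prev": np.empty((B, T, Hd), dtype=dt),
            "X": X,
        }
    for t in range(T):
        z = ZX[:, t] + state.h @ cell.W
        i = sigmoid(z[:, 0 * Hd : 1 * Hd])
        f = sigmoid(z[:, 1 * Hd : 2 * Hd])
        zg = z[:, 2 * Hd : 3 * Hd]
        g = np.tanh(zg) if tanh_g else sigmoid(zg)
        o = sigmoid(z[:, 3 * Hd : 4 * Hd])
        c = f * state.c + g * i
        h = np.tanh(c) * o
        if want_cache:
            cache["i"][:, t] = i
            cache["f"][:, t] = f
            cache["g"][:, t] = g
            cache["o"][:, t] = o
            cache["c"][:, t] = c
            cache["h_prev"][:, t] = state.h
            cache["c_prev"][:, t] = state.c
        state = CellState(h=h, c=c)
        H[:, t] = h
    return H, cache


@dataclass
class LayerParams:
    """One stacked layer: a forward cell and (if bidirectional) a backward cell."""

    forward_cell: LSTMCellParams
    backward_cell: LSTMCellParams | None = None

    @property
    def bidirectional(self) -> bool:
        return self.backward_cell is not None

    @property
    def output_dim(self) -> int:
        h = self.forward_cell.hidden_dim
        return 2 * h if self.bidirectional else h


@dataclass
class BiDRNNModel:
    """Stacked (bi)directional LSTM classifier with a linear score head.

    fusion
        ``"late_sum"`` — average the per-step class scores over the window
        (sum-rule late fusion); ``"last_step"`` — use the final step's score.
    """

    layers: list[LayerParams]
    output_weight: np.ndarray  # (top_dim, num_classes)
    output_bias: np.ndarray  # (num_classes,)
    fusion: str = "late_sum"
    arch_id: int | None = None
    class_names: list[str] | None = None  # label for each output index, if known

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("model needs at least one layer")
        bi = [layer.bidirectional for layer in self.layers]
        if any(bi) and not all(bi):
            raise ValueError("architecture must be uniformly uni- or bidirectional")
        if self.fusion not in ("late_sum", "last_step"):
            raise ValueError(f"unknown fusion {self.fusion!r}")
        ow = np.asarray(self.output_weight)
        ob = np.asarray(self.output_bias)
        self.output_weight = ow if ow.dtype in (np.float32, np.float64) else ow.astype(float)
        self.output_bias = ob if ob.dtype in (np.float32, np.float64) else ob.astype(float)
        if self.output_weight.shape[0] != self.layers[-1].output_dim:
            raise ValueError("output projection does not match top-layer width")

    @property
    def num_classes(self) -> int:
        return int(self.output_bias.size)

    @property
    def bidirectional(self) -> bool:
        return self.layers[0].bidirectional

    @property
    def hidden_dim(self) -> int:
        return self.layers[0].forward_cell.hidden_dim

    def parameters(self) -> list[np.ndarray]:
        """Flat list of all trainable arrays (views, mutated in place by Adam)."""
        out: list[np.ndarray] = []
        for layer in self.layers:
            out += [layer.forward_cell.U, layer.forward_cell.W, layer.forward_cell.b]
            if layer.backward_cell is not None:
                out += [
                    layer.backward_cell.U,
                    layer.backward_cell.W,
                    layer.backward_cell.b,
                ]
        out += [self.output_weight, self.output_bias]
        return out


def _as_batch_input(window: np.ndarray) -> np.ndarray:
    """Scalar sample sequence (T,) -> (1, T, 1); (T, D) -> (1, T, D)."""
    w = np.asarray(window, dtype=float)
    if w.ndim == 1:
        w = w[:, None]
    if w.ndim != 2 or w.shape[0] < 1:
        raise ValueError("window must be a non-empty sample sequence")
    return w[None]


def model_forward_batch(model: BiDRNNModel, X: np.ndarray) -> np.ndarray:
    """Per-step class scores for a batch: X (B, T, D) -> (B, T, C)."""
    A = X
    for layer in model.layers:
        Hf, _ = _scan_forward(A, layer.forward_cell)
        if layer.backward_cell is not None:
            Hb, _ = _scan_forward(A[:, ::-1], layer.backward_cell)
            A = np.concatenate([Hf, Hb[:, ::-1]], axis=-1)
        else:
            A = Hf
    return A @ model.output_weight + model.output_bias


def forward_pass(model: BiDRNNModel, window: np.ndarray) -> np.ndarray:
    """Per-timestep score sequence (T, num_classes) for one window.

    In bidirectional layers the next layer receives the concatenated
    forward and backward hidden states; the per-step score of a
    bidirectional top layer is the sum of the projected forward and
    backward contributions (realised as one projection of the
    concatenated state).
    """
    X = _as_batch_input(window)
    return model_forward_batch(model, X)[0]


def late_fusion(scores: np.ndarray) -> np.ndarray:
    """Sum-rule fusion: the arithmetic mean of per-step score vectors."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] == 0:
        raise ValueError("late_fusion requires a non-empty (T, C) score sequence")
    return scores.mean(axis=0)


def fuse_scores(model: BiDRNNModel, step_scores: np.ndarray) -> np.ndarray:
    """Window-level score according to the model's fusion mode. (B,T,C)->(B,C)."""
    if model.fusion == "late_sum":
        return step_scores.mean(axis=1)
    return step_scores[:, -1]


def classify(model: BiDRNNModel, window: np.ndarray) -> tuple[np.ndarray, int]:
    """Class probabilities and the argmax class for one window.

    Ties break toward the lowest class index (np.argmax convention).
    """
    step_scores = forward_pass(model, window)
    Y = late_fusion(step_scores) if model.fusion == "late_sum" else step_scores[-1]
    probs = softmax(Y)
    return probs, int(np.argmax(probs))


def predict_batch(model: BiDRNNModel, X: np.ndarray) -> np.ndarray:
    """Predicted class indices for X (B, T) or (B, T, D)."""
    if X.ndim == 2:
        X = X[:, :, None]
    fused = fuse_scores(model, model_forward_batch(model, X))
    return np.argmax(fused, axis=1)


# --------------------------------------------------------------------------
# architecture registry
# --------------------------------------------------------------------------

#: registry id -> (number of layers, bidirectional?, fusion mode)
ARCHITECTURES: dict[int, tuple[int, bool, str]] = {
    1: (1, False, "last_step"),
    2: (2, False, "last_step"),
    3: (3, False, "last_step"),
    4: (1, True, "late_sum"),
    5: (2, True, "late_sum"),
    6: (3, True, "late_sum"),
}


def build_architecture(
    arch_id: int,
    num_classes: int,
    hidden_dim: int = 128,
    input_dim: int = 1,
    seed: int = 0,
    activation_g: str = "tanh",
) -> BiDRNNModel:
    """Construct a registry architecture with seeded Glorot initialization."""
    if arch_id not in ARCHITECTURES:
        raise ValueError(f"unknown architecture id {arch_id}; valid: 1-6")
    n_layers, bidirectional, fusion = ARCHITECTURES[arch_id]
    rng = np.random.default_rng(seed)
    layers: list[LayerParams] = []
    in_dim = input_dim
    for _ in range(n_layers):
        fwd = LSTMCellParams.glorot_init(in_dim, hidden_dim, rng, activation_g)
        bwd = (
            LSTMCellParams.glorot_init(in_dim, hidden_dim, rng, activation_g)
            if bidirectional
            else None
        )
        layers.append(LayerParams(fwd, bwd))
        in_dim = layers[-1].output_dim
    top = layers[-1].output_dim
    s = np.sqrt(6.0 / (top + num_classes))
    Wp = rng.uniform(-s, s, size=(top, num_classes))
    bp = np.zeros(num_classes)
    return BiDRNNModel(layers, Wp, bp, fusion=fusion, arch_id=arch_id)


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

_CHECKPOINT_VERSION = 1


def save_checkpoint(model: BiDRNNModel, path) -> None:
    """Persist architecture descriptor + all weights; round-trips bit-exact."""
    desc = {
        "format_version": _CHECKPOINT_VERSION,
        "arch_id": model.arch_id,
        "fusion": model.fusion,
        "num_classes": model.num_classes,
        "bidirectional": model.bidirectional,
        "activation_g": model.layers[0].forward_cell.activation_g,
        "num_layers": len(model.layers),
        "class_names": model.class_names,
    }
    arrays = {"descriptor": np.frombuffer(json.dumps(desc).encode(), dtype=np.uint8)}
    for li, layer in enumerate(model.layers):
        for tag, cell in (("f", layer.forward_cell), ("b", layer.backward_cell)):
            if cell is None:
                continue
            arrays[f"layer{li}_{tag}_U"] = cell.U
            arrays[f"layer{li}_{tag}_W"] = cell.W
            arrays[f"layer{li}_{tag}_b"] = cell.b
    arrays["output_weight"] = model.output_weight
    arrays["output_bias"] = model.output_bias
    np.savez(path, **arrays)


def load_checkpoint(path) -> BiDRNNModel:
    with np.load(path) as data:
        desc = json.loads(bytes(data["descriptor"]).decode())
        if desc["format_version"] != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {desc['format_version']}")
        act = desc["activation_g"]
        layers = []
        for li in range(desc["num_layers"]):
            fwd = LSTMCellParams(
                data[f"layer{li}_f_U"], data[f"layer{li}_f_W"], data[f"layer{li}_f_b"], act
            )
            bwd = None
            if desc["bidirectional"]:
                bwd = LSTMCellParams(
                    data[f"layer{li}_b_U"],
                    data[f"layer{li}_b_W"],
                    data[f"layer{li}_b_b"],
                    act,
                )
            layers.append(LayerParams(fwd, bwd))
        return BiDRNNModel(
            layers,
            data["output_weight"],
            data["output_bias"],
            fusion=desc["fusion"],
            arch_id=desc["arch_id"],
            class_names=desc.get("class_names"),
        )
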