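"""The four screening classifiers: GRU (proposed), LSTM, FCN and an SVM hook.

The recurrent cells follow the printed screening recipe exactly:

GRU:   z = sigma(b_z + U_z x + W_z h_prev)
       r = sigma(b_r + U_r x + W_r h_prev)
       h~ = tanh(b_h + U_h x + W_h (r * h_prev))
       h  = z * h_prev + (1 - z) * h~          (z gates the PREVIOUS state)

LSTM:  g, f, o = sigma(gate pre-activations)
       s = f * s_prev + g * sigma(b + U x + W h_prev)   (candidate through
       sigma as printed; a tanh variant is available via ``candidate``)
       h = tanh(s) * o

Note both conventions differ from the most common library forms: many GRU
implementations use ``(1 - z) * h_prev + z * h~`` and virtually all LSTMs
squash the cell candidate with tanh.  The forms above are kept verbatim.

Classification head: the final hidden state of the last layer feeds a
fully connected layer of 3 units with a softmax.  Training minimizes
softmax cross-entropy plus an L2 penalty on weight matrices (not biases)
with Adam.  The reference architecture is 2 layers x 64 units; frames are
consumed one scalar sample per timestep by default, with a chunked-input
option (e.g. 96 steps x 10 samples) for speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import (Adam, Tensor, blend, conv1d, fma2, softmax_cross_entropy,
                       stack_rows)

N_CLASSES = 3


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def softmax(scores: np.ndarray) -> np.ndarray:
    """Exp-normalized scores along the last axis, with the max-shift trick."""
    scores = np.asarray(scores, dtype=np.float64)
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# plain-numpy single-step cells (the reference equations, vector in/out)
# ---------------------------------------------------------------------------

@dataclass
class GruLayerParams:
    """GRU gate parameters; U: (input_dim, hidden), W: (hidden, hidden)."""

    U_z: np.ndarray
    W_z: np.ndarray
    b_z: np.ndarray
    U_r: np.ndarray
    W_r: np.ndarray
    b_r: np.ndarray
    U_h: np.ndarray
    W_h: np.ndarray
    b_h: np.ndarray


@dataclass
class LstmLayerParams:
    """LSTM gate/cell parameters; subscripts g/f/o/c = input, forget, output, candidate."""

    U_g: np.ndarray
    W_g: np.ndarray
    b_g: np.ndarray
    U_f: np.ndarray
    W_f: np.ndarray
    b_f: np.ndarray
    U_o: np.ndarray
    W_o: np.ndarray
    b_o: np.ndarray
    U_c: np.ndarray
    W_c: np.ndarray
    b_c: np.ndarray


def gru_step(x_t: np.ndarray, h_prev: np.ndarray, params: GruLayerParams) -> np.ndarray:
    """One GRU update; works on single vectors or batched (N, dim) rows."""
    z = sigmoid(params.b_z + x_t @ params.U_z + h_prev @ params.W_z)
    r = sigmoid(params.b_r + x_t @ params.U_r + h_prev @ params.W_r)
    h_tilde = np.tanh(params.b_h + x_t @ params.U_h + (r * h_prev) @ params.W_h)
    return z * h_prev + (1.0 - z) * h_tilde


def lstm_step(x_t: np.ndarray, h_prev: np.ndarray, s_prev: np.ndarray,
              params: LstmLayerParams, candidate: str = "sigmoid",
              ) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM update returning (h_t, s_t)."""
    g = sigmoid(params.b_g + x_t @ params.U_g + h_prev @ params.W_g)
    f = sigmoid(params.b_f + x_t @ params.U_f + h_prev @ params.W_f)
    o = sigmoid(params.b_o + x_t @ params.U_o + h_prev @ params.W_o)
    pre = params.b_c + x_t @ params.U_c + h_prev @ params.W_c
    cand = sigmoid(pre) if candidate == "sigmoid" else np.tanh(pre)
    s_t = f * s_prev + g * cand
    h_t = np.tanh(s_t) * o
    return h_t, s_t


# ---------------------------------------------------------------------------
# trainable classifiers (autograd)
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Training regime; defaults are the screening recipe's exact settings."""

    learning_rate: float = 0.001
    l2_lambda: float = 0.0001
    batch_size: int = 64
    epochs: int = 50
    n_layers: int = 2
    units: int = 64
    rng_seed: int = 0
    chunk_size: int = 1          # samples consumed per timestep
    lstm_candidate: str = "sigmoid"

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.epochs,
               self.n_layers, self.units, self.chunk_size) <= 0:
            raise ValueError("all training settings must be positive")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")


def _uniform_init(rng: np.random.Generator, shape: tuple[int, ...],
                  fan_in: int) -> Tensor:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class _Classifier:
    """Shared surface: parameters(), weights(), predict_proba()."""

    n_classes = N_CLASSES

    def parameters(self) -> list[Tensor]:
        raise NotImplementedError

    def weights(self) -> list[Tensor]:
        """Weight matrices subject to L2 (biases and BN scales excluded)."""
        raise NotImplementedError

    def forward(self, X: np.ndarray, train: bool = False) -> Tensor:
        raise NotImplementedError

    @property
    def n_output_units(self) -> int:
        return int(self._W_out.data.shape[1])

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(X), batch_size):
            logits = self.forward(np.asarray(X[i:i + batch_size]), train=False)
            out.append(softmax(logits.data))
        return np.vstack(out)


class _Recurrent(_Classifier):
    """Stacked recurrent layers feeding a 3-unit softmax head.

    Gate weights are stored fused (one input matrix and one recurrent
    matrix per layer) so each timestep costs a couple of matmuls; the
    input projections of every layer are computed for the whole sequence
    in a single matmul.  The arithmetic is identical to the per-gate
    reference equations above.
    """

    n_gates: int  # columns blocks in the fused matrices

    def __init__(self, n_layers: int, units: int, chunk_size: int, seed: int):
        self.n_layers, self.units, self.chunk_size = n_layers, units, chunk_size
        self.rng = np.random.default_rng(seed)
        self.layers: list[dict[str, Tensor]] = []
        for k in range(n_layers):
            d_in = chunk_size if k == 0 else units
            self.layers.append(self._make_layer(d_in, units))
        self._W_out = _uniform_init(self.rng, (units, N_CLASSES), units)
        self._b_out = Tensor(np.zeros(N_CLASSES), requires_grad=True)

    def _chunk(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            n, L = X.shape
            if L % self.chunk_size:
                raise ValueError(
                    f"frame length {L} not divisible by chunk size {self.chunk_size}")
            X = X.reshape(n, L // self.chunk_size, self.chunk_size)
        if X.shape[2] != self.chunk_size:
            raise ValueError(
                f"expected input dimension {self.chunk_size}, got {X.shape[2]}")
        return X

    def parameters(self) -> list[Tensor]:
        out = []
        for layer in self.layers:
            out.extend(layer.values())
        out += [self._W_out, self._b_out]
        return out

    def weights(self) -> list[Tensor]:
        out = []
        for layer in self.layers:
            out.extend(v for k, v in layer.items() if not k.startswith("b"))
        out.append(self._W_out)
        return out

    def _input_projection(self, layer: dict[str, Tensor], seq: Tensor) -> Tensor:
        """(T*N, n_gates*H) biased input pre-activations for a whole sequence."""
        return seq @ layer["U"] + layer["b"]


class GruClassifier(_Recurrent):
    n_gates = 3  # update z, reset r, candidate

    def _make_layer(self, d_in: int, units: int) -> dict[str, Tensor]:
        return {"U": _uniform_init(self.rng, (d_in, 3 * units), d_in),
                "W_zr": _uniform_init(self.rng, (units, 2 * units), units),
                "W_h": _uniform_init(self.rng, (units, units), units),
                "b": Tensor(np.zeros(3 * units), requires_grad=True)}

    def forward(self, X: np.ndarray, train: bool = False) -> Tensor:
        X = self._chunk(X)
        n, T, _ = X.shape
        H = self.units
        seq: Tensor = Tensor(np.ascontiguousarray(X.transpose(1, 0, 2)).reshape(T * n, -1))
        h_last = None
        for layer in self.layers:
            xu = self._input_projection(layer, seq)
            h = Tensor(np.zeros((n, H)))
            outs = []
            for t in range(T):
                pre = xu.rows(t * n, n)
                hw = h @ layer["W_zr"]
                z = (pre.narrow(0, H) + hw.narrow(0, H)).sigmoid()
                r = (pre.narrow(H, H) + hw.narrow(H, H)).sigmoid()
                h_tilde = (pre.narrow(2 * H, H) + (r * h) @ layer["W_h"]).tanh()
                h = blend(z, h, h_tilde)  # z * h + (1 - z) * h~
                outs.append(h)
            seq = stack_rows(outs)
            h_last = h
        return h_last @ self._W_out + self._b_out


class LstmClassifier(_Recurrent):
    n_gates = 4  # input g, forget f, output o, cell candidate

    def __init__(self, n_layers: int, units: int, chunk_size: int, seed: int,
                 candidate: str = "sigmoid"):
        self.candidate = candidate
        super().__init__(n_layers, units, chunk_size, seed)

    def _make_layer(self, d_in: int, units: int) -> dict[str, Tensor]:
        return {"U": _uniform_init(self.rng, (d_in, 4 * units), d_in),
                "W": _uniform_init(self.rng, (units, 4 * units), units),
                "b": Tensor(np.zeros(4 * units), requires_grad=True)}

    def forward(self, X: np.ndarray, train: bool = False) -> Tensor:
        X = self._chunk(X)
        n, T, _ = X.shape
        H = self.units
        seq: Tensor = Tensor(np.ascontiguousarray(X.transpose(1, 0, 2)).reshape(T * n, -1))
        h_last = None
        for layer in self.layers:
            h = Tensor(np.zeros((n, H)))
            s = Tensor(np.zeros((n, H)))
            xu = self._input_projection(layer, seq)
            outs = []
            for t in range(T):
                pre = xu.rows(t * n, n) + h @ layer["W"]
                g = pre.narrow(0, H).sigmoid()
                f = pre.narrow(H, H).sigmoid()
                o = pre.narrow(2 * H, H).sigmoid()
                raw = pre.narrow(3 * H, H)
                cand = raw.sigmoid() if self.candidate == "sigmoid" else raw.tanh()
                s = fma2(f, s, g, cand)  # f * s_prev + g * candidate
                h = s.tanh() * o
                outs.append(h)
            seq = stack_rows(outs)
            h_last = h
        return h_last @ self._W_out + self._b_out


@dataclass
class FcnConfig:
    """Fully convolutional baseline: conv blocks + BN + ReLU, then GAP."""

    filters: tuple[int, ...] = (128, 256, 128)
    kernels: tuple[int, ...] = (8, 5, 3)
    bn_eps: float = 1e-5
    bn_momentum: float = 0.9


class FcnClassifier(_Classifier):
    def __init__(self, config: FcnConfig | None = None, seed: int = 0):
        self.config = config or FcnConfig()
        rng = np.random.default_rng(seed)
        self.blocks = []
        c_in = 1
        for c_out, k in zip(self.config.filters, self.config.kernels):
            self.blocks.append({
                "w": _uniform_init(rng, (k, c_in, c_out), k * c_in),
                "b": Tensor(np.zeros(c_out), requires_grad=True),
                "gamma": Tensor(np.ones(c_out), requires_grad=True),
                "beta": Tensor(np.zeros(c_out), requires_grad=True),
                "run_mean": np.zeros(c_out),
                "run_var": np.ones(c_out),
            })
            c_in = c_out
        self._W_out = _uniform_init(rng, (c_in, N_CLASSES), c_in)
        self._b_out = Tensor(np.zeros(N_CLASSES), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        out = []
        for blk in self.blocks:
            out += [blk["w"], blk["b"], blk["gamma"], blk["beta"]]
        return out + [self._W_out, self._b_out]

    def weights(self) -> list[Tensor]:
        return [blk["w"] for blk in self.blocks] + [self._W_out]

    def forward(self, X: np.ndarray, train: bool = False) -> Tensor:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[:, :, None]
        x = Tensor(X)
        mom, eps = self.config.bn_momentum, self.config.bn_eps
        for blk in self.blocks:
            x = conv1d(x, blk["w"], blk["b"])
            if train:
                mu = x.mean(axis=0).mean(axis=0)
                var = ((x - mu) ** 2).mean(axis=0).mean(axis=0)
                blk["run_mean"] = mom * blk["run_mean"] + (1 - mom) * mu.data
                blk["run_var"] = mom * blk["run_var"] + (1 - mom) * var.data
            else:
                mu, var = Tensor(blk["run_mean"]), Tensor(blk["run_var"])
            xhat = (x - mu) * ((var + eps) ** -0.5)
            x = (blk["gamma"] * xhat + blk["beta"]).relu()
        pooled = x.mean(axis=1)  # global average pooling over time
        return pooled @ self._W_out + self._b_out


def build_model(name: str, config: TrainConfig | None = None,
                fcn_config: FcnConfig | None = None) -> _Classifier:
    config = config or TrainConfig()
    if name == "gru":
        return GruClassifier(config.n_layers, config.units, config.chunk_size,
                             config.rng_seed)
    if name == "lstm":
        return LstmClassifier(config.n_layers, config.units, config.chunk_size,
                              config.rng_seed, config.lstm_candidate)
    if name == "fcn":
        return FcnClassifier(fcn_config, seed=config.rng_seed)
    raise ValueError(f"unknown model name {name!r}; expected gru, lstm or fcn")


def train(model: _Classifier, X_train: np.ndarray, y_train: np.ndarray,
          X_val: np.ndarray | None, y_val: np.ndarray | None,
          config: TrainConfig) -> dict[str, list[float]]:
    """Adam / cross-entropy / L2 training loop with per-epoch metric curves."""
    X_train = np.asarray(X_train, dtype=np.float64)
    y_train = np.asarray(y_train)
    if len(X_train) == 0:
        raise ValueError("empty training set")
    if y_train.min() < 0 or y_train.max() >= N_CLASSES:
        raise ValueError(f"labels must lie in [0, {N_CLASSES})")
    rng = np.random.default_rng(config.rng_seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history: dict[str, list[float]] = {"loss": [], "train_acc": [], "val_acc": []}
    n = len(X_train)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, correct = 0.0, 0
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            logits = model.forward(X_train[idx], train=True)
            loss = softmax_cross_entropy(logits, y_train[idx])
            if config.l2_lambda > 0:
                reg = None
                for w in model.weights():
                    term = (w * w).sum()
                    reg = term if reg is None else reg + term
                loss = loss + config.l2_lambda * reg
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
            correct += int((logits.data.argmax(axis=1) == y_train[idx]).sum())
        history["loss"].append(epoch_loss / n)
        history["train_acc"].append(correct / n)
        if X_val is not None and len(X_val):
            preds = model.predict_proba(X_val).argmax(axis=1)
            history["val_acc"].append(float((preds == y_val).mean()))
    return history


def predict(model: _Classifier, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels for a batch of frames."""
    probs = model.predict_proba(np.asarray(X, dtype=np.float64))
    return probs, probs.argmax(axis=1)
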