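"""LSTM binary classifier over the multivariate recovery sequences.

Two code paths implement the same recurrence and cross-check each other:

* :func:`cell_step` — the literal gating equations, one gate at a time::

      f_t = sigmoid(W_f [h_{t-1}, x_t] + b_f)
      i_t = sigmoid(W_i [h_{t-1}, x_t] + b_i)
      g_t = tanh(W_C [h_{t-1}, x_t] + b_C)
      C_t = f_t * C_{t-1} + i_t * g_t
      o_t = sigmoid(W_o [h_{t-1}, x_t] + b_o)
      h_t = o_t * tanh(C_t)

* :class:`LSTMLayer` — a batched, fused-matrix implementation of the same
  recurrence used by the trainable network, with full backpropagation
  through time.

The default network mirrors the study architecture: two stacked LSTM
layers (64 and 32 units), batch normalization and dropout, a 16-unit ReLU
dense layer and a sigmoid output trained with binary cross-entropy and
Adam, with early stopping on validation loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellState",
    "GateWeights",
    "LSTMConfig",
    "LSTMLayer",
    "LSTMClassifier",
    "TrainingError",
    "cell_step",
    "build_network",
    "lstm_parameter_count",
]


class TrainingError(RuntimeError):
    """Training diverged (non-finite loss); carries the epoch index."""

    def __init__(self, message: str, epoch: int):
        super().__init__(message)
        self.epoch = epoch


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# reference cell


@dataclass(frozen=True)
class CellState:
    """Gate activations and states after one step of the recurrence."""

    f: np.ndarray
    i: np.ndarray
    c_tilde: np.ndarray
    c: np.ndarray
    o: np.ndarray
    h: np.ndarray


@dataclass(frozen=True)
class GateWeights:
    """Separate per-gate weights W_(f|i|c|o): (H, H+D), biases: (H,)."""

    wf: np.ndarray
    wi: np.ndarray
    wc: np.ndarray
    wo: np.ndarray
    bf: np.ndarray
    bi: np.ndarray
    bc: np.ndarray
    bo: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.wf.shape[0]

    @property
    def input_size(self) -> int:
        return self.wf.shape[1] - self.wf.shape[0]


def cell_step(x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, w: GateWeights) -> CellState:
    """One step of the literal gating equations on a single input vector."""
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    c_prev = np.asarray(c_prev, dtype=float)
    hsz = w.hidden_size
    if x_t.shape != (w.input_size,) or h_prev.shape != (hsz,) or c_prev.shape != (hsz,):
        raise ValueError(
            f"dimension mismatch: x {x_t.shape}, h {h_prev.shape}, c {c_prev.shape} "
            f"for hidden {hsz}, input {w.input_size}"
        )
    z = np.concatenate([h_prev, x_t])
    f = _sigmoid(w.wf @ z + w.bf)
    i = _sigmoid(w.wi @ z + w.bi)
    c_tilde = np.tanh(w.wc @ z + w.bc)
    c = f * c_prev + i * c_tilde
    o = _sigmoid(w.wo @ z + w.bo)
    h = o * np.tanh(c)
    return CellState(f=f, i=i, c_tilde=c_tilde, c=c, o=o, h=h)


# ---------------------------------------------------------------------------
# trainable network


class LSTMLayer:
    """Batched LSTM layer with a fused (4H, H+D) weight matrix.

    Gate row order is (f, i, c, o).  Holds no parameters itself; the
    classifier owns them and passes views in.
    """

    @staticmethod
    def init_params(hidden: int, inputs: int, rng: np.random.Generator):
        lim = math.sqrt(6.0 / (hidden + inputs + hidden))
        w = rng.uniform(-lim, lim, size=(4 * hidden, hidden + inputs))
        b = np.zeros(4 * hidden)
        b[:hidden] = 1.0  # forget-gate bias: remember by default
        return w, b

    @staticmethod
    def from_gate_weights(gw: GateWeights):
        w = np.concatenate([gw.wf, gw.wi, gw.wc, gw.wo], axis=0)
        b = np.concatenate([gw.bf, gw.bi, gw.bc, gw.bo])
        return w, b

    @staticmethod
    def forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
        """Run the recurrence over an (B, M, D) batch.

        Returns the (B, M, H) hidden sequence and the cache for backward.
        """
        bsz, m, _ = x.shape
        hsz = w.shape[0] // 4
        h = np.zeros((bsz, hsz))
        c = np.zeros((bsz, hsz))
        h_seq = np.empty((bsz, m, hsz))
        cache = []
        for t in range(m):
            z = np.concatenate([h, x[:, t]], axis=1)
            a = z @ w.T + b
            f = _sigmoid(a[:, :hsz])
            i = _sigmoid(a[:, hsz : 2 * hsz])
            g = np.tanh(a[:, 2 * hsz : 3 * hsz])
            o = _sigmoid(a[:, 3 * hsz :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            h_seq[:, t] = h
            cache.append((z, f, i, g, o, c_prev, tc))
        return h_seq, cache

    @staticmethod
    def backward(dh_seq: np.ndarray, cache, w: np.ndarray):
        """Backpropagate through time.

        ``dh_seq`` holds the external gradient w.r.t. each hidden output
        (zeros everywhere but the last step for a last-state readout).
        Returns (dW, db, dx_seq).
        """
        bsz, m, hsz = dh_seq.shape
        d_in = w.shape[1] - hsz
        dw = np.zeros_like(w)
        db = np.zeros(4 * hsz)
        dx_seq = np.empty((bsz, m, d_in))
        dh_next = np.zeros((bsz, hsz))
        dc_next = np.zeros((bsz, hsz))
        for t in range(m - 1, -1, -1):
            z, f, i, g, o, c_prev, tc = cache[t]
            dh = dh_seq[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc**2)
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            da = np.concatenate(
                [
                    df * f * (1.0 - f),
                    di * i * (1.0 - i),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dw += da.T @ z
            db += da.sum(axis=0)
            dz = da @ w
            dh_next = dz[:, :hsz]
            dx_seq[:, t] = dz[:, hsz:]
            dc_next = dc * f
        return dw, db, dx_seq


@dataclass(frozen=True)
class LSTMConfig:
    """Architecture and training hyperparameters.

    Layer sizes, the dense width, dropout and batch-norm follow the study
    architecture; learning rate, batch size, epoch budget and patience are
    conventional defaults (the protocol leaves them open) and are all
    configurable.
    """

    hidden: tuple[int, ...] = (64, 32)
    dense: int = 16
    dropout: float = 0.5
    batch_norm: bool = True
    learning_rate: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 200
    patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hidden or any(h < 1 for h in self.hidden):
            raise ValueError("hidden sizes must all be >= 1")
        if self.dense < 1:
            raise ValueError("dense size must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")


def lstm_parameter_count(config: LSTMConfig, n_features: int) -> int:
    """Closed-form trainable parameter count: 4*(u*(u+v)+u) per LSTM layer
    plus batch-norm scale/shift and the dense head."""
    total = 0
    v = n_features
    for u in config.hidden:
        total += 4 * (u * (u + v) + u)
        v = u
    if config.batch_norm:
        total += 2 * config.hidden[-1]
    total += config.hidden[-1] * config.dense + config.dense
    total += config.dense * 1 + 1
    return total


class LSTMClassifier:
    """Stacked-LSTM binary classifier trained with Adam on BCE loss."""

    def __init__(self, config: LSTMConfig, n_features: int):
        self.config = config
        self.n_features = n_features
        self._rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        self.bn_running: dict[str, np.ndarray] = {}
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        self._build()

    # -- construction ------------------------------------------------------

    def _build(self) -> None:
        rng = self._rng
        d = self.n_features
        for li, h in enumerate(self.config.hidden):
            w, b = LSTMLayer.init_params(h, d, rng)
            self.params[f"l{li}_W"] = w
            self.params[f"l{li}_b"] = b
            d = h
        last = self.config.hidden[-1]
        if self.config.batch_norm:
            self.params["bn_gamma"] = np.ones(last)
            self.params["bn_beta"] = np.zeros(last)
            self.bn_running = {"mean": np.zeros(last), "var": np.ones(last)}
        lim = math.sqrt(6.0 / (last + self.config.dense))
        self.params["d1_W"] = rng.uniform(-lim, lim, size=(last, self.config.dense))
        self.params["d1_b"] = np.zeros(self.config.dense)
        lim = math.sqrt(6.0 / (self.config.dense + 1))
        self.params["out_W"] = rng.uniform(-lim, lim, size=(self.config.dense, 1))
        self.params["out_b"] = np.zeros(1)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -- forward -----------------------------------------------------------

    def _forward(self, x: np.ndarray, training: bool, rng=None):
        cfg = self.config
        cache: dict = {"lstm": [], "drop_masks": []}
        h = x
        for li in range(len(cfg.hidden)):
            h_seq, lcache = LSTMLayer.forward(
                h, self.params[f"l{li}_W"], self.params[f"l{li}_b"]
            )
            cache["lstm"].append(lcache)
            if li < len(cfg.hidden) - 1 and cfg.dropout > 0 and training:
                mask = (rng.random(h_seq.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
                h_seq = h_seq * mask
                cache["drop_masks"].append(mask)
            else:
                cache["drop_masks"].append(None)
            h = h_seq
        last = h[:, -1]
        cache["last_shape"] = h.shape

        if cfg.batch_norm:
            eps = 1e-5
            if training:
                mu = last.mean(axis=0)
                var = last.var(axis=0)
                mom = 0.9
                self.bn_running["mean"] = mom * self.bn_running["mean"] + (1 - mom) * mu
                self.bn_running["var"] = mom * self.bn_running["var"] + (1 - mom) * var
            else:
                mu, var = self.bn_running["mean"], self.bn_running["var"]
            istd = 1.0 / np.sqrt(var + eps)
            xhat = (last - mu) * istd
            bn_out = self.params["bn_gamma"] * xhat + self.params["bn_beta"]
            cache["bn"] = (xhat, istd)
        else:
            bn_out = last
            cache["bn"] = None

        if cfg.dropout > 0 and training:
            mask = (rng.random(bn_out.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            bn_out = bn_out * mask
            cache["head_mask"] = mask
        else:
            cache["head_mask"] = None

        z1 = bn_out @ self.params["d1_W"] + self.params["d1_b"]
        a1 = np.maximum(z1, 0.0)
        logits = (a1 @ self.params["out_W"] + self.params["out_b"]).ravel()
        p = _sigmoid(logits)
        cache.update(bn_in=last, bn_out=bn_out, z1=z1, a1=a1, p=p)
        return p, cache

    # -- backward ----------------------------------------------------------

    def _backward(self, x: np.ndarray, y: np.ndarray, cache) -> dict[str, np.ndarray]:
        cfg = self.config
        bsz = x.shape[0]
        grads: dict[str, np.ndarray] = {}
        dlogits = (cache["p"] - y) / bsz  # sigmoid + BCE
        grads["out_W"] = cache["a1"].T @ dlogits[:, None]
        grads["out_b"] = np.array([dlogits.sum()])
        da1 = dlogits[:, None] @ self.params["out_W"].T
        dz1 = da1 * (cache["z1"] > 0)
        grads["d1_W"] = cache["bn_out"].T @ dz1
        grads["d1_b"] = dz1.sum(axis=0)
        dbn_out = dz1 @ self.params["d1_W"].T

        if cache["head_mask"] is not None:
            dbn_out = dbn_out * cache["head_mask"]

        if cfg.batch_norm:
            xhat, istd = cache["bn"]
            gamma = self.params["bn_gamma"]
            grads["bn_gamma"] = (dbn_out * xhat).sum(axis=0)
            grads["bn_beta"] = dbn_out.sum(axis=0)
            dlast = (
                gamma
                * istd
                / bsz
                * (
                    bsz * dbn_out
                    - dbn_out.sum(axis=0)
                    - xhat * (dbn_out * xhat).sum(axis=0)
                )
            )
        else:
            dlast = dbn_out

        # last-state readout: external gradient only at the final step
        b_, m_, h_ = cache["last_shape"]
        dh_seq = np.zeros((b_, m_, h_))
        dh_seq[:, -1] = dlast

        for li in range(len(cfg.hidden) - 1, -1, -1):
            dw, db, dx_seq = LSTMLayer.backward(
                dh_seq, cache["lstm"][li], self.params[f"l{li}_W"]
            )
            grads[f"l{li}_W"] = dw
            grads[f"l{li}_b"] = db
            if li > 0:
                mask = cache["drop_masks"][li - 1]
                dh_seq = dx_seq * mask if mask is not None else dx_seq
        return grads

    @staticmethod
    def _bce(p: np.ndarray, y: np.ndarray) -> float:
        eps = 1e-12
        return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))

    # -- training ----------------------------------------------------------

    def fit(
        self,
        x_train: np.ndarray,
        y_train: np.ndarray,
        x_val: np.ndarray,
        y_val: np.ndarray,
    ) -> "LSTMClassifier":
        """Mini-batch Adam with early stopping on validation loss.

        Stops when the validation loss has not improved for more than
        ``patience`` consecutive epochs (patience 0: first non-improving
        epoch) or at the epoch budget; the best-validation weights are
        restored.  Deterministic given the config seed.
        """
        cfg = self.config
        x_train = np.asarray(x_train, dtype=float)
        y_train = np.asarray(y_train, dtype=float)
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
        adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_val = math.inf
        best_params = {k: v.copy() for k, v in self.params.items()}
        best_running = {k: v.copy() for k, v in self.bn_running.items()}
        stall = 0
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(y_train))
            epoch_loss = 0.0
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = x_train[idx], y_train[idx]
                p, cache = self._forward(xb, training=True, rng=rng)
                loss = self._bce(p, yb)
                if not math.isfinite(loss):
                    raise TrainingError(f"non-finite loss at epoch {epoch}", epoch)
                epoch_loss += loss * len(idx)
                grads = self._backward(xb, yb, cache)
                step += 1
                for k, g in grads.items():
                    adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * g
                    adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * g**2
                    m_hat = adam_m[k] / (1 - beta1**step)
                    v_hat = adam_v[k] / (1 - beta2**step)
                    self.params[k] -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
            self.history["train_loss"].append(epoch_loss / len(y_train))
            val_p, _ = self._forward(np.asarray(x_val, dtype=float), training=False)
            val_loss = self._bce(val_p, np.asarray(y_val, dtype=float))
            self.history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in self.params.items()}
                best_running = {k: v.copy() for k, v in self.bn_running.items()}
                stall = 0
            else:
                stall += 1
                if stall > cfg.patience:
                    break
        self.params = best_params
        self.bn_running = best_running
        return self

    # -- inference ---------------------------------------------------------

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-subject positive-class (cancer) probability in (0, 1)."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 3 or x.shape[2] != self.n_features:
            raise ValueError(f"expected shape (*, M, {self.n_features}), got {x.shape}")
        p, _ = self._forward(x, training=False)
        return p

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Labels at probability threshold 0.5."""
        return (self.predict_proba(x) >= 0.5).astype(int)


def build_network(config: LSTMConfig, n_features: int) -> LSTMClassifier:
    """Construct the (untrained) classifier for V input features."""
    return LSTMClassifier(config, n_features)
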