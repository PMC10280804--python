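"""Per-sequence LSTM forecasting of affine transformation parameters.

The predictor is deliberately small and patient-specific: one recurrent
network is trained from scratch on the first part of a single sequence's
normalized TP vectors and forecasts that same sequence's future motion.
The many-to-many model reads a window of W six-dimensional TP vectors and
emits the next P vectors through a linear regression head; the
many-to-one baseline treats the six parameters as independent univariate
series and predicts a single next value for each.

The network and its training loop are implemented directly on numpy:
standard LSTM cell (input, forget, output gates and a tanh candidate,
unit forget-gate bias), truncated-to-window backpropagation through time,
mean-squared-error (or mean-absolute-error) loss, and RMSProp updates.
Gradients are exercised against numerical differentiation in the test
suite.  Everything is seeded, so a fit is reproducible bit for bit on one
machine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .features import WindowedDataset

__all__ = ["ModelConfig", "LSTMForecaster", "build_model", "train", "predict",
           "save_model", "load_model"]


@dataclass
class ModelConfig:
    """Forecaster hyperparameters.

    ``hidden_units`` is the LSTM state width (default 500);
    ``epochs`` defaults to 200, appropriate for ~75-frame sequences —
    use ~500 for sequences around 150 frames.  RMSProp with learning
    rate 1e-3 and a linear output layer; loss is mean squared error by
    default (evaluation is MAE, selectable here as ``"mae"``).
    """

    hidden_units: int = 500
    n_lstm_layers: int = 1
    epochs: int = 200
    learning_rate: float = 1e-3
    rho: float = 0.9
    epsilon: float = 1e-7
    batch_size: int | None = 32  # None = full batch
    loss: str = "mse"  # or "mae"
    mode: str = "many_to_many"  # or "many_to_one"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1 or self.n_lstm_layers < 1 or self.epochs < 1:
            raise ValueError("hidden_units, n_lstm_layers and epochs must be >= 1")
        if self.loss not in ("mse", "mae"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.mode not in ("many_to_many", "many_to_one"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal_recurrent(rng: np.random.Generator, h: int) -> np.ndarray:
    """Per-gate orthogonal initialization of the H x 4H recurrent kernel."""
    blocks = []
    for _ in range(4):
        a = rng.standard_normal((h, h))
        q, r = np.linalg.qr(a)
        q *= np.sign(np.diag(r))
        blocks.append(q)
    return np.concatenate(blocks, axis=1)


class _LSTMNet:
    """One stacked-LSTM + dense-head network on raw numpy arrays.

    Parameter layout per layer l: ``Wx[l]`` (F_in x 4H), ``Wh[l]`` (H x 4H),
    ``b[l]`` (4H); gate order along the 4H axis is (i, f, g, o).  The dense
    head maps the final hidden state to ``P * F_out`` linear outputs.
    """

    def __init__(self, n_features: int, n_out_steps: int, n_out_features: int,
                 hidden: int, n_layers: int, rng: np.random.Generator):
        self.F = n_features
        self.P = n_out_steps
        self.Fo = n_out_features
        self.H = hidden
        self.L = n_layers
        self.params: dict[str, np.ndarray] = {}
        f_in = n_features
        for layer in range(n_layers):
            self.params[f"Wx{layer}"] = _glorot(rng, (f_in, 4 * hidden))
            self.params[f"Wh{layer}"] = _orthogonal_recurrent(rng, hidden)
            b = np.zeros(4 * hidden)
            b[hidden:2 * hidden] = 1.0  # unit forget-gate bias
            self.params[f"b{layer}"] = b
            f_in = hidden
        self.params["Wd"] = _glorot(rng, (hidden, n_out_steps * n_out_features))
        self.params["bd"] = np.zeros(n_out_steps * n_out_features)

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def forward(self, X: np.ndarray, want_cache: bool = False):
        """X: (B, W, F) -> outputs (B, P, Fo), plus BPTT cache if asked."""
        B, W, _ = X.shape
        H, L = self.H, self.L
        h = [np.zeros((B, H)) for _ in range(L)]
        c = [np.zeros((B, H)) for _ in range(L)]
        cache = [] if want_cache else None
        for t in range(W):
            x = X[:, t, :]
            step_cache = []
            for layer in range(L):
                Wx = self.params[f"Wx{layer}"]
                Wh = self.params[f"Wh{layer}"]
                b = self.params[f"b{layer}"]
                z = x @ Wx + h[layer] @ Wh + b
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H:2 * H])
                g = np.tanh(z[:, 2 * H:3 * H])
                o = _sigmoid(z[:, 3 * H:])
                c_new = f * c[layer] + i * g
                tanh_c = np.tanh(c_new)
                h_new = o * tanh_c
                if want_cache:
                    step_cache.append((x, h[layer], c[layer], i, f, g, o,
                                       c_new, tanh_c))
                h[layer], c[layer] = h_new, c_new
                x = h_new
            if want_cache:
                cache.append(step_cache)
        flat = h[-1] @ self.params["Wd"] + self.params["bd"]
        out = flat.reshape(B, self.P, self.Fo)
        return (out, cache) if want_cache else out

    def backward(self, X: np.ndarray, cache, d_out: np.ndarray) -> dict[str, np.ndarray]:
        """BPTT; ``d_out`` is dLoss/d(outputs), shape (B, P, Fo)."""
        B, W, _ = X.shape
        H, L = self.H, self.L
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        d_flat = d_out.reshape(B, self.P * self.Fo)
        h_last = cache[W - 1][L - 1][6] * cache[W - 1][L - 1][8]  # o * tanh(c)
        grads["Wd"] = h_last.T @ d_flat
        grads["bd"] = d_flat.sum(axis=0)

        dh = [np.zeros((B, H)) for _ in range(L)]
        dc = [np.zeros((B, H)) for _ in range(L)]
        dh[L - 1] = d_flat @ self.params["Wd"].T
        for t in range(W - 1, -1, -1):
            dx_up = None  # gradient flowing into lower layer's h at time t
            for layer in range(L - 1, -1, -1):
                x, h_prev, c_prev, i, f, g, o, c_new, tanh_c = cache[t][layer]
                dh_l = dh[layer] if dx_up is None else dh[layer] + dx_up
                do = dh_l * tanh_c
                dc_l = dc[layer] + dh_l * o * (1.0 - tanh_c ** 2)
                di = dc_l * g
                df = dc_l * c_prev
                dg = dc_l * i
                dz = np.concatenate([
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g ** 2),
                    do * o * (1.0 - o),
                ], axis=1)
                grads[f"Wx{layer}"] += x.T @ dz
                grads[f"Wh{layer}"] += h_prev.T @ dz
                grads[f"b{layer}"] += dz.sum(axis=0)
                dh[layer] = dz @ self.params[f"Wh{layer}"].T
                dc[layer] = dc_l * f
                dx_up = dz @ self.params[f"Wx{layer}"].T if layer > 0 else None
        return grads


class LSTMForecaster(BaseEstimator, RegressorMixin):
    """Window-to-horizon TP forecaster (scikit-learn estimator API).

    ``fit(X, y)`` expects normalized arrays ``X`` of shape (M, W, F) and
    ``y`` of shape (M, P, F); ``predict(X)`` returns (M, P, F) on the same
    normalized scale.  In ``many_to_one`` mode the six parameters are fit
    as independent univariate streams (P is forced to 1).

    Fitted attributes: ``loss_history_`` (one value per epoch), ``net_``
    (or ``nets_`` in many-to-one mode), ``n_parameters_``, ``W_``, ``P_``,
    ``n_features_in_``.
    """

    def __init__(self, hidden_units: int = 500, n_lstm_layers: int = 1,
                 epochs: int = 200, learning_rate: float = 1e-3,
                 rho: float = 0.9, epsilon: float = 1e-7,
                 batch_size: int | None = 32, loss: str = "mse",
                 mode: str = "many_to_many", random_state: int = 0):
        self.hidden_units = hidden_units
        self.n_lstm_layers = n_lstm_layers
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.rho = rho
        self.epsilon = epsilon
        self.batch_size = batch_size
        self.loss = loss
        self.mode = mode
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _loss_and_grad(self, pred: np.ndarray, y: np.ndarray):
        diff = pred - y
        if self.loss == "mse":
            return float(np.mean(diff ** 2)), 2.0 * diff / diff.size
        return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size

    def _fit_net(self, net: _LSTMNet, X: np.ndarray, y: np.ndarray,
                 rng: np.random.Generator) -> list[float]:
        # Start the linear head at the per-output training-target mean so
        # the recurrent part only has to learn fluctuations: several TP
        # components (the linear-part entries) sit at a large offset from
        # zero that gradient steps alone would take many epochs to reach.
        net.params["bd"] = y.reshape(y.shape[0], -1).mean(axis=0).copy()
        ms = {k: np.zeros_like(v) for k, v in net.params.items()}
        M = X.shape[0]
        bs = self.batch_size or M
        history: list[float] = []
        for epoch in range(self.epochs):
            order = rng.permutation(M) if bs < M else np.arange(M)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, M, bs):
                idx = order[start:start + bs]
                pred, cache = net.forward(X[idx], want_cache=True)
                loss, d_out = self._loss_and_grad(pred, y[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch + 1} "
                        f"(lr={self.learning_rate}, batch={bs}); reduce the "
                        "learning rate or check input normalization"
                    )
                grads = net.backward(X[idx], cache, d_out)
                for k, g in grads.items():
                    ms[k] = self.rho * ms[k] + (1.0 - self.rho) * g * g
                    net.params[k] -= self.learning_rate * g / (
                        np.sqrt(ms[k]) + self.epsilon)
                epoch_loss += loss
                n_batches += 1
            history.append(epoch_loss / n_batches)
        return history

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        cfg_check = ModelConfig(self.hidden_units, self.n_lstm_layers,
                                self.epochs, self.learning_rate, self.rho,
                                self.epsilon, self.batch_size, self.loss,
                                self.mode, self.random_state)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 3 or y.ndim != 3 or X.shape[0] != y.shape[0]:
            raise ValueError(
                f"expected X (M, W, F) and y (M, P, F); got {X.shape}, {y.shape}"
            )
        if X.shape[0] == 0:
            raise ValueError("training set is empty")
        M, W, F = X.shape
        _, P, Fo = y.shape
        self.W_, self.P_, self.n_features_in_ = W, P, F
        rng = np.random.default_rng(self.random_state)

        if self.mode == "many_to_one":
            if P != 1:
                raise ValueError("many_to_one mode predicts a single step (P=1)")
            self.nets_ = []
            self.loss_history_ = np.zeros(self.epochs)
            for j in range(Fo):
                net = _LSTMNet(1, 1, 1, self.hidden_units,
                               self.n_lstm_layers, rng)
                hist = self._fit_net(net, X[:, :, j:j + 1], y[:, :, j:j + 1], rng)
                self.nets_.append(net)
                self.loss_history_ += np.array(hist)
            self.loss_history_ = list(self.loss_history_ / Fo)
            self.n_parameters_ = sum(n.n_parameters() for n in self.nets_)
        else:
            if Fo != F:
                raise ValueError("many_to_many mode needs matching feature counts")
            self.net_ = _LSTMNet(F, P, Fo, self.hidden_units,
                                 self.n_lstm_layers, rng)
            self.loss_history_ = self._fit_net(self.net_, X, y, rng)
            self.n_parameters_ = self.net_.n_parameters()
        del cfg_check
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3 or X.shape[1] != self.W_:
            raise ValueError(
                f"expected windows of shape (M, {self.W_}, {self.n_features_in_}), "
                f"got {X.shape}"
            )
        if self.mode == "many_to_one":
            cols = [net.forward(X[:, :, j:j + 1]) for j, net in enumerate(self.nets_)]
            return np.concatenate(cols, axis=2)
        return self.net_.forward(X)


# -- functional wrappers mirroring the pipeline stage boundaries -----------

def build_model(cfg: ModelConfig, W: int, P: int) -> LSTMForecaster:
    """Instantiate an untrained forecaster for a W-in / P-out problem."""
    if cfg.mode == "many_to_one" and P != 1:
        raise ValueError("many_to_one mode requires P=1")
    est = LSTMForecaster(hidden_units=cfg.hidden_units,
                         n_lstm_layers=cfg.n_lstm_layers, epochs=cfg.epochs,
                         learning_rate=cfg.learning_rate, rho=cfg.rho,
                         epsilon=cfg.epsilon, batch_size=cfg.batch_size,
                         loss=cfg.loss, mode=cfg.mode,
                         random_state=cfg.rng_seed)
    est._expected_W = W
    est._expected_P = P
    return est


def train(model: LSTMForecaster, train_set: WindowedDataset,
          cfg: ModelConfig | None = None) -> LSTMForecaster:
    """Fit on a windowed (normalized) dataset; returns the fitted model."""
    return model.fit(train_set.inputs, train_set.targets)


def save_model(model: LSTMForecaster, path,
               norm_factors: np.ndarray | None = None) -> None:
    """Checkpoint a fitted forecaster (weights + config + factors)."""
    import json

    payload: dict[str, np.ndarray] = {}
    if model.mode == "many_to_one":
        for j, net in enumerate(model.nets_):
            for k, v in net.params.items():
                payload[f"net{j}/{k}"] = v
    else:
        for k, v in model.net_.params.items():
            payload[f"net/{k}"] = v
    meta = {"params": model.get_params(), "W": model.W_, "P": model.P_,
            "F": model.n_features_in_,
            "loss_history": list(map(float, model.loss_history_))}
    payload["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    if norm_factors is not None:
        payload["__norm_factors__"] = np.asarray(norm_factors, dtype=float)
    np.savez(path, **payload)


def load_model(path) -> tuple[LSTMForecaster, np.ndarray | None]:
    """Restore a checkpointed forecaster and its normalization factors."""
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = LSTMForecaster(**meta["params"])
        model.W_, model.P_ = meta["W"], meta["P"]
        model.n_features_in_ = meta["F"]
        model.loss_history_ = meta["loss_history"]
        rng = np.random.default_rng(0)
        if model.mode == "many_to_one":
            model.nets_ = []
            for j in range(meta["F"]):
                net = _LSTMNet(1, 1, 1, model.hidden_units,
                               model.n_lstm_layers, rng)
                net.params = {k.split("/", 1)[1]: data[k] for k in data.files
                              if k.startswith(f"net{j}/")}
                model.nets_.append(net)
            model.n_parameters_ = sum(n.n_parameters() for n in model.nets_)
        else:
            net = _LSTMNet(meta["F"], meta["P"], meta["F"],
                           model.hidden_units, model.n_lstm_layers, rng)
            net.params = {k.split("/", 1)[1]: data[k] for k in data.files
                          if k.startswith("net/")}
            model.net_ = net
            model.n_parameters_ = net.n_parameters()
        factors = data["__norm_factors__"] if "__norm_factors__" in data else None
    return model, factors


def predict(model: LSTMForecaster, window: np.ndarray,
            norm_factors: np.ndarray | None = None) -> np.ndarray:
    """Forecast from one W x 6 window, denormalizing if factors are given."""
    out = model.predict(np.asarray(window, dtype=float)[None] if
                        np.asarray(window).ndim == 2 else window)
    if norm_factors is not None:
        out = out * np.asarray(norm_factors, dtype=float)
    return out[0] if np.asarray(window).ndim == 2 else out
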