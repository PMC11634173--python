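"""Sequence classifier: a five-layer bidirectional LSTM network in numpy.

The architecture follows the compact recurrent design that works well for
per-coordinate labelling of short feature sequences: sequence input (4
milestone features per line coordinate) -> bidirectional LSTM with 200
hidden units per direction -> fully connected layer -> soft-max ->
classification output. Training uses Adam on a class-weighted, padding-
masked cross-entropy over variable-length sequences, with early stopping
on validation loss to avoid overfitting.

The implementation is plain numpy (forward pass + backpropagation through
time + Adam); a finite-difference gradient check in the test suite pins
down its correctness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import ConfigError, LSTMConfig
from .containers import CLASSES, ContractError, Dataset, LineSample
from .knn import TrainingError

__all__ = ["SequenceModel", "train_bilstm", "predict_bilstm",
           "save_model", "load_model", "BiLSTMNet"]

LAYER_SPEC = ("sequence_input", "bilstm", "fully_connected", "softmax",
              "classification_output")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _glorot(rng, fan_in, fan_out, shape):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


class BiLSTMNet:
    """Parameter container and forward/backward engine."""

    def __init__(self, n_features: int, hidden: int, n_classes: int,
                 seed: int = 0):
        self.n_features = n_features
        self.hidden = hidden
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)
        H, F = hidden, n_features
        self.params: dict[str, np.ndarray] = {}
        for d in ("f", "b"):
            self.params[f"Wx_{d}"] = _glorot(rng, F, H, (F, 4 * H))
            self.params[f"Wh_{d}"] = _glorot(rng, H, H, (H, 4 * H))
            bias = np.zeros(4 * H)
            bias[H:2 * H] = 1.0      # forget-gate bias
            self.params[f"b_{d}"] = bias
        self.params["Wo"] = _glorot(rng, 2 * H, n_classes,
                                    (2 * H, n_classes))
        self.params["bo"] = np.zeros(n_classes)

    # -- one LSTM direction -------------------------------------------------

    def _run_direction(self, x, mask, d):
        """x (T, B, F), mask (T, B); masked steps carry state unchanged."""
        T, B, _ = x.shape
        H = self.hidden
        Wx, Wh, b = (self.params[f"Wx_{d}"], self.params[f"Wh_{d}"],
                     self.params[f"b_{d}"])
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((T, B, H))
        cache = []
        for t in range(T):
            m = mask[t][:, None]
            z = x[t] @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            h_next = m * h_new + (1 - m) * h
            c_next = m * c_new + (1 - m) * c
            cache.append((x[t], h, c, i, f, g, o, tc, m))
            h, c = h_next, c_next
            hs[t] = h
        return hs, cache

    def _back_direction(self, dh_out, cache, d, grads):
        """dh_out (T, B, H): gradient w.r.t. each step's (masked) output."""
        T, B, H = dh_out.shape
        Wx, Wh = self.params[f"Wx_{d}"], self.params[f"Wh_{d}"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H)
        dh = np.zeros((B, H))
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tc, m = cache[t]
            dh_total = dh + dh_out[t]
            dh_new = dh_total * m
            dh_carry = dh_total * (1 - m)
            dc_new = dc * m + dh_new * o * (1 - tc * tc)
            do = dh_new * tc
            di = dc_new * g
            df = dc_new * c_prev
            dg = dc_new * i
            dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - g * g), do * o * (1 - o)], axis=1)
            dWx += x_t.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dh = dh_carry + dz @ Wh.T
            dc = dc_new * f + dc * (1 - m)
        grads[f"Wx_{d}"] = dWx
        grads[f"Wh_{d}"] = dWh
        grads[f"b_{d}"] = db

    # -- full network -------------------------------------------------------

    def forward(self, x, mask):
        """Posteriors (T, B, C) and a cache for the backward pass."""
        hs_f, cache_f = self._run_direction(x, mask, "f")
        hs_b, cache_b = self._run_direction(x[::-1], mask[::-1], "b")
        hs_b = hs_b[::-1]
        concat = np.concatenate([hs_f, hs_b], axis=-1)
        logits = concat @ self.params["Wo"] + self.params["bo"]
        shifted = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        probs = e / e.sum(axis=-1, keepdims=True)
        return probs, (cache_f, cache_b, concat)

    def loss_and_grads(self, x, mask, targets, class_weights):
        """Masked, class-weighted cross-entropy and all parameter grads.

        ``targets`` is (T, B) int with arbitrary values at masked steps.
        """
        probs, (cache_f, cache_b, concat) = self.forward(x, mask)
        T, B, C = probs.shape
        onehot = np.eye(C)[targets]
        w = class_weights[targets] * mask
        norm = max(w.sum(), 1e-12)
        eps = 1e-12
        loss = -(w * np.log(probs[np.arange(T)[:, None],
                                  np.arange(B)[None, :], targets] + eps)
                 ).sum() / norm
        dlogits = (probs - onehot) * w[..., None] / norm
        grads: dict[str, np.ndarray] = {}
        grads["Wo"] = np.tensordot(concat, dlogits, axes=((0, 1), (0, 1)))
        grads["bo"] = dlogits.sum(axis=(0, 1))
        dconcat = dlogits @ self.params["Wo"].T
        H = self.hidden
        self._back_direction(dconcat[..., :H], cache_f, "f", grads)
        self._back_direction(dconcat[::-1, :, H:], cache_b, "b", grads)
        return loss, grads

    def loss(self, x, mask, targets, class_weights):
        probs, _ = self.forward(x, mask)
        T, B, _ = probs.shape
        w = class_weights[targets] * mask
        norm = max(w.sum(), 1e-12)
        return -(w * np.log(probs[np.arange(T)[:, None],
                                  np.arange(B)[None, :], targets] + 1e-12)
                 ).sum() / norm


@dataclass
class SequenceModel:
    """Trained sequence classifier (weights + config + training log)."""

    net: BiLSTMNet
    config: LSTMConfig
    classes: tuple[str, ...] = CLASSES
    layer_spec: tuple[str, ...] = LAYER_SPEC
    training_log: list = field(default_factory=list)
    stop_epoch: int = 0
    class_weights: np.ndarray | None = None

    @property
    def hidden_units(self) -> int:
        return self.net.hidden


def _pack(seqs: list[np.ndarray], labels: list[np.ndarray] | None):
    """Pad a batch of variable-length sequences to (T, B, F) + mask."""
    T = max(len(s) for s in seqs)
    B = len(seqs)
    F = seqs[0].shape[1]
    x = np.zeros((T, B, F))
    mask = np.zeros((T, B))
    y = np.zeros((T, B), dtype=np.int64)
    for b, s in enumerate(seqs):
        x[:len(s), b] = s
        mask[:len(s), b] = 1.0
        if labels is not None:
            y[:len(s), b] = labels[b]
    return x, mask, y


def _adam_step(params, grads, state, lr, t, beta1=0.9, beta2=0.999,
               eps=1e-8):
    for k, g in grads.items():
        m, v = state[k]
        m = beta1 * m + (1 - beta1) * g
        v = beta2 * v + (1 - beta2) * g * g
        state[k] = (m, v)
        mhat = m / (1 - beta1 ** t)
        vhat = v / (1 - beta2 ** t)
        params[k] -= lr * mhat / (np.sqrt(vhat) + eps)


def train_bilstm(dataset: Dataset, config: LSTMConfig | None = None
                 ) -> SequenceModel:
    """Train the sequence model on the dataset's train split.

    Early stopping monitors the validation-split loss: training stops when
    it has not improved for ``patience`` epochs (or at ``max_epochs``), and
    the weights of the best validation epoch are kept. Raises
    :class:`ConfigError` when the validation split is empty and
    :class:`TrainingError` for fewer than two training sequences.
    """
    config = config or LSTMConfig()
    train = dataset.subset("train")
    val = dataset.subset("validation")
    if not train:
        train = [s for s in dataset.samples if s not in val]
    if len(train) < 2:
        raise TrainingError("need at least 2 training sequences")
    if not val:
        raise ConfigError("validation split empty: early stopping impossible")
    for s in train + val:
        if s.labels is None:
            raise TrainingError("all training sequences must be labelled")

    rng = np.random.default_rng(config.seed)
    net = BiLSTMNet(train[0].features.shape[1], config.hidden_units,
                    len(CLASSES), seed=config.seed)
    all_labels = np.concatenate([s.labels for s in train])
    if config.class_weighting:
        counts = np.bincount(all_labels, minlength=len(CLASSES)).astype(float)
        weights = counts.sum() / np.maximum(counts, 1.0) / len(CLASSES)
    else:
        weights = np.ones(len(CLASSES))

    state = {k: (np.zeros_like(v), np.zeros_like(v))
             for k, v in net.params.items()}
    x_val, m_val, y_val = _pack([s.features for s in val],
                                [s.labels for s in val])
    best_val = np.inf
    best_params = {k: v.copy() for k, v in net.params.items()}
    best_epoch = 0
    log = []
    step = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train))
        train_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [train[i] for i in order[start:start + config.batch_size]]
            x, m, y = _pack([s.features for s in batch],
                            [s.labels for s in batch])
            loss, grads = net.loss_and_grads(x, m, y, weights)
            step += 1
            _adam_step(net.params, grads, state, config.learning_rate, step)
            train_losses.append(loss)
        val_loss = net.loss(x_val, m_val, y_val, weights)
        log.append({"epoch": epoch, "train_loss": float(np.mean(train_losses)),
                    "val_loss": float(val_loss)})
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in net.params.items()}
            best_epoch = epoch
        elif epoch - best_epoch >= config.patience:
            break
    net.params = best_params
    return SequenceModel(net=net, config=config, training_log=log,
                         stop_epoch=len(log), class_weights=weights)


def predict_bilstm(model: SequenceModel, sample: LineSample):
    """Per-coordinate soft-max posteriors and arg-max labels for one line.

    Returns (labels (n,), posteriors (n, 3)); posterior rows sum to 1.
    """
    feats = np.asarray(sample.features, dtype=float)
    if feats.ndim != 2 or feats.shape[1] != model.net.n_features:
        raise ContractError(
            f"expected (n, {model.net.n_features}) features")
    if len(feats) < 2:
        raise ContractError("sequence length must be >= 2")
    x, mask, _ = _pack([feats], None)
    probs, _ = model.net.forward(x, mask)
    posteriors = probs[:, 0, :]
    return posteriors.argmax(axis=1), posteriors


def save_model(model: SequenceModel, directory) -> None:
    """Checkpoint: weights as .npz plus a JSON sidecar with architecture,
    classes, training log and config."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", **model.net.params)
    sidecar = {
        "layer_spec": list(model.layer_spec),
        "classes": list(model.classes),
        "n_features": model.net.n_features,
        "hidden_units": model.net.hidden,
        "n_classes": model.net.n_classes,
        "config": {k: (v.item() if hasattr(v, "item") else v)
                   for k, v in vars(model.config).items()},
        "stop_epoch": model.stop_epoch,
        "training_log": model.training_log,
        "class_weights": None if model.class_weights is None
        else list(map(float, model.class_weights)),
    }
    with open(directory / "model.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_model(directory) -> SequenceModel:
    directory = Path(directory)
    with open(directory / "model.json") as fh:
        sidecar = json.load(fh)
    config = LSTMConfig(**sidecar["config"])
    net = BiLSTMNet(sidecar["n_features"], sidecar["hidden_units"],
                    sidecar["n_classes"])
    with np.load(directory / "weights.npz") as data:
        net.params = {k: data[k] for k in data.files}
    cw = sidecar.get("class_weights")
    return SequenceModel(net=net, config=config,
                         classes=tuple(sidecar["classes"]),
                         layer_spec=tuple(sidecar["layer_spec"]),
                         training_log=sidecar["training_log"],
                         stop_epoch=sidecar["stop_epoch"],
                         class_weights=None if cw is None else np.array(cw))
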