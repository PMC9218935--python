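"""Execution and training of network graphs.

A :class:`Model` compiles a :class:`~halfunet.architectures.NetworkSpec`
into engine layers with Kaiming-initialized weights and runs forward and
backward passes. :func:`train` implements the training recipe used
throughout this package: Adam, soft Dice loss, an initial learning rate of
1e-3 dropped to 1/2 at epoch 30 and to 1/10 at epoch 50, a seeded 0.2
validation split, L2 weight regularization, and best-validation
checkpointing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from . import metrics
from .architectures import NetworkSpec
from .engine import (
    AddLayer,
    BilinearLayer,
    ConcatLayer,
    ConvLayer,
    DeconvLayer,
    GhostLayer,
    MaxPoolLayer,
    ShapeError,
    SigmoidLayer,
)

__all__ = ["TrainConfig", "TrainingRecord", "Model", "forward", "train",
           "evaluate", "lr_for_epoch"]


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    initial_lr: float = 1e-3
    lr_drops: tuple = ((30, 2.0), (50, 10.0))  # (epoch, divide initial by)
    lr_mode: str = "factor_of_initial"  # or "cumulative"
    epochs: int = 60
    batch_size: int = 14
    loss_smoothing: float = 1.0
    validation_fraction: float = 0.2
    weight_decay: float = 1e-5
    adam_betas: tuple = (0.9, 0.999)
    threshold: float = 0.5
    seed: int = 0
    repeats: int = 1

    def __post_init__(self):
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def lr_for_epoch(epoch: int, config: TrainConfig) -> float:
    """Learning rate for a 1-based epoch index. ``factor_of_initial``
    divides the initial rate by each drop's factor (1e-3 -> 5e-4 -> 1e-4);
    ``cumulative`` compounds the factors instead."""
    lr = config.initial_lr
    factor = 1.0
    for at, div in sorted(config.lr_drops):
        if epoch >= at:
            factor = factor * div if config.lr_mode == "cumulative" else div
    return lr / factor


@dataclass
class TrainingRecord:
    seed: int
    lr_trace: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    train_dice: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_dice: list = field(default_factory=list)
    best_epoch: int = 0
    train_indices: np.ndarray | None = None
    val_indices: np.ndarray | None = None
    model: "Model | None" = None

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "lr", "train_loss", "train_dice",
                        "val_loss", "val_dice"])
            for e in range(len(self.lr_trace)):
                w.writerow([e + 1, self.lr_trace[e], self.train_loss[e],
                            self.train_dice[e], self.val_loss[e],
                            self.val_dice[e]])


# ---------------------------------------------------------------------------
# model


def _make_layer(node, rng):
    c = node.cfg
    if node.kind == "conv":
        return ConvLayer(c["k"], c["cin"], c["cout"], rng,
                         bias=c.get("bias", True),
                         batchnorm=c.get("batchnorm", False),
                         relu=c.get("relu", False))
    if node.kind == "ghost":
        return GhostLayer(c["k"], c["cin"], c["cout"], rng,
                          s=c.get("s", 2), d=c.get("d", 3),
                          batchnorm=c.get("batchnorm", True),
                          relu=c.get("relu", True))
    if node.kind == "deconv":
        return DeconvLayer(c["k"], c["cin"], c["cout"], rng)
    if node.kind == "maxpool":
        return MaxPoolLayer()
    if node.kind == "bilinear":
        return BilinearLayer(c["factor"])
    if node.kind == "add":
        return AddLayer()
    if node.kind == "concat":
        return ConcatLayer()
    if node.kind == "sigmoid":
        return SigmoidLayer()
    raise ValueError(f"unknown layer kind {node.kind!r}")


class Model:
    """A compiled network: engine layers bound to the nodes of a graph."""

    def __init__(self, network: NetworkSpec, seed: int = 0):
        network.validate()
        self.net = network
        rng = np.random.default_rng(seed)
        self.layers = {
            n.name: _make_layer(n, rng)
            for n in network.nodes if n.kind != "input"
        }
        self._values: dict[str, np.ndarray] = {}

    def forward(self, x, training: bool = False) -> np.ndarray:
        """Run the graph on a batch (N, C, H, W); a (C, H, W) array is
        promoted to a batch of one."""
        x = np.asarray(x, dtype=np.float32)
        squeeze = x.ndim == 3
        if squeeze:
            x = x[None]
        values: dict[str, np.ndarray] = {}
        expected = self.net.input_shape[0]
        for node in self.net.nodes:
            if node.kind == "input":
                if x.shape[1] != expected:
                    raise ShapeError(
                        f"expected {expected} input channels, got {x.shape[1]}"
                    )
                values[node.name] = x
                continue
            layer = self.layers[node.name]
            values[node.name] = layer.forward(
                [values[i] for i in node.inputs], training
            )
        self._values = values
        out = values[self.net.output_name]
        return out[0] if squeeze else out

    def backward(self, dout: np.ndarray) -> None:
        """Backpropagate a gradient of the loss w.r.t. the output,
        accumulating parameter gradients in each layer. Auxiliary branches
        that do not feed the output receive no gradient."""
        dvals: dict[str, np.ndarray] = {self.net.output_name: dout}
        for node in reversed(self.net.nodes):
            if node.kind == "input" or node.name not in dvals:
                continue
            dxs = self.layers[node.name].backward(dvals.pop(node.name))
            for iname, dx in zip(node.inputs, dxs):
                if iname in dvals:
                    dvals[iname] = dvals[iname] + dx
                else:
                    dvals[iname] = dx

    def parameters(self):
        for node in self.net.nodes:
            if node.kind == "input":
                continue
            layer = self.layers[node.name]
            for pname, arr in layer.params.items():
                yield node.name, layer, pname, arr

    def n_params(self) -> int:
        return sum(int(a.size) for _, _, _, a in self.parameters())

    def weight_norm(self) -> float:
        return float(np.sqrt(sum(
            float((a.astype(np.float64) ** 2).sum())
            for _, _, pname, a in self.parameters() if pname.startswith("w")
        )))

    # -- serialization ------------------------------------------------
    def state_dict(self) -> dict:
        state = {}
        for name, layer in self.layers.items():
            for pname, arr in layer.params.items():
                state[f"{name}/{pname}"] = arr.copy()
            for bname, arr in layer.buffers.items():
                state[f"{name}/buf:{bname}"] = arr.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for name, layer in self.layers.items():
            for pname in layer.params:
                layer.params[pname][...] = state[f"{name}/{pname}"]
            for bname in layer.buffers:
                layer.buffers[bname][...] = state[f"{name}/buf:{bname}"]

    def save(self, path) -> None:
        np.savez_compressed(path, __network__=np.array(self.net.name),
                            **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files
                                  if k != "__network__"})


def forward(network_or_model, batch, training: bool = False) -> np.ndarray:
    """Convenience single-call forward pass (compiles the network first if
    given a spec)."""
    model = network_or_model if isinstance(network_or_model, Model) \
        else Model(network_or_model)
    return model.forward(batch, training)


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    def __init__(self, model: Model, betas=(0.9, 0.999), eps=1e-8):
        self.model = model
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m: dict[tuple, np.ndarray] = {}
        self.v: dict[tuple, np.ndarray] = {}

    def step(self, lr: float, weight_decay: float = 0.0) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for node, layer, pname, arr in self.model.parameters():
            g = layer.grads.get(pname)
            if g is None:
                continue
            if weight_decay and pname.startswith("w"):
                g = g + weight_decay * arr
            key = (node, pname)
            m = self.m.setdefault(key, np.zeros_like(arr))
            v = self.v.setdefault(key, np.zeros_like(arr))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            arr -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(arr.dtype)
        for layer in self.model.layers.values():
            layer.grads.clear()


# ---------------------------------------------------------------------------
# training / evaluation


def _as_arrays(data, split="train", target=None):
    """Accept (images, masks) arrays or a DatasetManifest."""
    if isinstance(data, tuple):
        x, y = data
        return np.asarray(x, np.float32), np.asarray(y, np.float32)
    from .synthetic import load_arrays

    return load_arrays(data, split=split, target=target)


def _batched_eval(model, x, y, config):
    losses, dices = [], []
    for at in range(0, len(x), config.batch_size):
        xb = x[at: at + config.batch_size]
        yb = y[at: at + config.batch_size]
        p = model.forward(xb, training=False)
        loss, _ = metrics.dice_loss_grad(p, yb, config.loss_smoothing)
        losses.append(loss * len(xb))
        dices.extend(metrics.dice(p[i, 0], yb[i, 0], config.threshold)
                     for i in range(len(xb)))
    return sum(losses) / len(x), float(np.mean(dices))


def train(network: NetworkSpec, data, config: TrainConfig | None = None,
          target=None, verbose=False) -> TrainingRecord:
    """Train a network and return the full per-epoch record; the returned
    record's ``model`` carries the best-validation weights."""
    config = config or TrainConfig()
    x, y = _as_arrays(data, "train", target)
    if len(x) == 0:
        raise ValueError("empty training split")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(x))
    n_val = max(1, int(round(len(x) * config.validation_fraction)))
    if n_val >= len(x):
        raise ValueError("validation split leaves no training images")
    val_idx, tr_idx = order[:n_val], order[n_val:]
    model = Model(network, seed=config.seed)
    opt = Adam(model, betas=config.adam_betas)
    rec = TrainingRecord(seed=config.seed, train_indices=tr_idx,
                         val_indices=val_idx, model=model)
    best = (-1.0, None)
    for epoch in range(1, config.epochs + 1):
        lr = lr_for_epoch(epoch, config)
        rec.lr_trace.append(lr)
        perm = tr_idx[rng.permutation(len(tr_idx))]
        ep_loss, ep_dice, seen = 0.0, [], 0
        for at in range(0, len(perm), config.batch_size):
            idx = perm[at: at + config.batch_size]
            xb, yb = x[idx], y[idx]
            p = model.forward(xb, training=True)
            loss, dp = metrics.dice_loss_grad(p, yb, config.loss_smoothing)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {at // config.batch_size}"
                )
            model.backward(dp)
            opt.step(lr, config.weight_decay)
            ep_loss += loss * len(idx)
            seen += len(idx)
            ep_dice.extend(metrics.dice(p[i, 0], yb[i, 0], config.threshold)
                           for i in range(len(idx)))
        rec.train_loss.append(ep_loss / seen)
        rec.train_dice.append(float(np.mean(ep_dice)))
        vl, vd = _batched_eval(model, x[val_idx], y[val_idx], config)
        rec.val_loss.append(vl)
        rec.val_dice.append(vd)
        if vd > best[0]:
            best = (vd, model.state_dict())
            rec.best_epoch = epoch
        if verbose:
            print(f"epoch {epoch:3d}  lr {lr:.5f}  train loss {rec.train_loss[-1]:.4f}"
                  f"  train dice {rec.train_dice[-1]:.4f}  val dice {vd:.4f}")
    if best[1] is not None:
        model.load_state_dict(best[1])
    return rec


def evaluate(model: Model, data, split="test", target=None,
             threshold: float = 0.5, batch_size: int = 8) -> dict:
    """Per-image Dice/sensitivity/specificity on a held-out split,
    averaged per image (nan-skipping for undefined cases)."""
    x, y = _as_arrays(data, split, target)
    per_image = []
    for at in range(0, len(x), batch_size):
        p = model.forward(x[at: at + batch_size], training=False)
        for i in range(len(p)):
            per_image.append({
                "dice": metrics.dice(p[i, 0], y[at + i, 0], threshold),
                "sensitivity": metrics.sensitivity(p[i, 0], y[at + i, 0], threshold),
                "specificity": metrics.specificity(p[i, 0], y[at + i, 0], threshold),
            })
    agg = {
        k: float(np.nanmean([r[k] for r in per_image]))
        for k in ("dice", "sensitivity", "specificity")
    }
    agg["n_images"] = len(per_image)
    agg["per_image"] = per_image
    return agg


def evaluation_to_csv(result: dict, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image", "dice", "sensitivity", "specificity"])
        for i, r in enumerate(result["per_image"]):
            w.writerow([i, r["dice"], r["sensitivity"], r["specificity"]])
        w.writerow(["mean", result["dice"], result["sensitivity"],
                    result["specificity"]])
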