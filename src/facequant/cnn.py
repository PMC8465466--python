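"""Small convolutional classifiers with explicit forward/backward passes.

The harness trains compact binary image classifiers in three families —
VGG-like plain stacks, ResNet-like residual blocks and Inception-like
parallel branches — under a transfer-learning experiment grid: learning
rate, batch normalization, pretrained initialization (a checkpoint saved
from a prior run), an explicit weight re-initialization scheme, SGD vs
Adam, and layer-freezing schemes (train everything, only the final
fully-connected head, or only the last five weight-bearing layers).

Every layer implements its own backward pass in numpy.  Besides making
training self-contained, this exposes the gradient of a class score with
respect to any intermediate convolutional activation, which is exactly
what Grad-CAM needs (see :mod:`facequant.gradcam`).

Data layout is NCHW throughout; images enter as (H, W) grayscale floats.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .screenstats import ConfusionMatrix

BACKBONES = ("small-vgg-like", "small-resnet-like", "small-inception-like")
FREEZING_SCHEMES = ("from-scratch", "last-fc-only", "last-five-layers")
OPTIMIZERS = ("SGD", "Adam")


# ---------------------------------------------------------------------------
# layers

def _im2col(x, k, stride, pad):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
    return cols.reshape(n, c * k * k, oh * ow), oh, ow


def _col2im(dcols, x_shape, k, stride, pad):
    n, c, h, w = x_shape
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, k, k, oh, ow)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += dcols[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Layer:
    has_params = False

    def __init__(self, name=""):
        self.name = name
        self.trainable = True
        self.params: dict = {}
        self.grads: dict = {}

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def param_layers(self):
        return [self] if self.has_params else []

    def zero_grad(self):
        for l in self.param_layers():
            l.grads = {k: np.zeros_like(v) for k, v in l.params.items()}


class Conv2D(Layer):
    has_params = True

    def __init__(self, in_ch, out_ch, k=3, stride=1, pad=None, name=""):
        super().__init__(name)
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        self.pad = (k // 2) if pad is None else pad
        self.params = {"W": np.zeros((out_ch, in_ch * k * k)), "b": np.zeros(out_ch)}

    def init_weights(self, rng, scheme="he"):
        fan_in = self.in_ch * self.k * self.k
        if scheme == "he":
            self.params["W"] = rng.normal(0, np.sqrt(2.0 / fan_in), self.params["W"].shape)
        else:  # xavier-uniform
            fan_out = self.out_ch * self.k * self.k
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            self.params["W"] = rng.uniform(-lim, lim, self.params["W"].shape)
        self.params["b"] = np.zeros(self.out_ch)

    def forward(self, x, train=False):
        cols, oh, ow = _im2col(x, self.k, self.stride, self.pad)
        self._cache = (x.shape, cols)
        out = np.einsum("oc,ncl->nol", self.params["W"], cols, optimize=True)
        out += self.params["b"][None, :, None]
        return out.reshape(x.shape[0], self.out_ch, oh, ow)

    def backward(self, dy):
        x_shape, cols = self._cache
        n = dy.shape[0]
        dyf = dy.reshape(n, self.out_ch, -1)
        self.grads["W"] = np.einsum("nol,ncl->oc", dyf, cols, optimize=True)
        self.grads["b"] = dyf.sum(axis=(0, 2))
        dcols = np.einsum("oc,nol->ncl", self.params["W"], dyf, optimize=True)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad)


class BatchNorm2D(Layer):
    has_params = True

    def __init__(self, ch, momentum=0.1, eps=1e-5, name=""):
        super().__init__(name)
        self.ch, self.momentum, self.eps = ch, momentum, eps
        self.params = {"gamma": np.ones(ch), "beta": np.zeros(ch)}
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            if getattr(self, "_collect", None) is not None:
                self._collect.append((mean, var))
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]

    def backward(self, dy):
        xhat, inv, train, shape = self._cache
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dy.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        if not train:
            return dy * g * inv[None, :, None, None]
        m = shape[0] * shape[2] * shape[3]
        dxhat = dy * g
        dx = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
        return dx * inv[None, :, None, None]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2x2(Layer):
    def forward(self, x, train=False):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4)
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return xr.max(axis=-1)

    def backward(self, dy):
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, self._arg[..., None], dy[..., None], axis=-1)
        return dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w), self._shape).copy()


class GlobalSumPool(Layer):
    """Spatial sum head; used by analytically constructed test networks."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.sum(axis=(2, 3))

    def backward(self, dy):
        return np.broadcast_to(dy[:, :, None, None], self._shape).copy()


class Linear(Layer):
    has_params = True

    def __init__(self, in_f, out_f, name=""):
        super().__init__(name)
        self.in_f, self.out_f = in_f, out_f
        self.params = {"W": np.zeros((out_f, in_f)), "b": np.zeros(out_f)}

    def init_weights(self, rng, scheme="he"):
        if scheme == "he":
            self.params["W"] = rng.normal(0, np.sqrt(2.0 / self.in_f), (self.out_f, self.in_f))
        else:
            lim = np.sqrt(6.0 / (self.in_f + self.out_f))
            self.params["W"] = rng.uniform(-lim, lim, (self.out_f, self.in_f))
        self.params["b"] = np.zeros(self.out_f)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = dy.T @ self._x
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"]


class ResBlock(Layer):
    """y = relu(f(x) + shortcut(x)) with f = conv-[bn]-relu-conv-[bn]."""

    def __init__(self, in_ch, out_ch, stride=1, batch_norm=True, name=""):
        super().__init__(name)
        self.branch = [Conv2D(in_ch, out_ch, 3, stride, name=f"{name}.conv1")]
        if batch_norm:
            self.branch.append(BatchNorm2D(out_ch, name=f"{name}.bn1"))
        self.branch.append(ReLU(name=f"{name}.relu1"))
        self.branch.append(Conv2D(out_ch, out_ch, 3, 1, name=f"{name}.conv2"))
        if batch_norm:
            self.branch.append(BatchNorm2D(out_ch, name=f"{name}.bn2"))
        self.proj = None
        if stride != 1 or in_ch != out_ch:
            self.proj = Conv2D(in_ch, out_ch, 1, stride, pad=0, name=f"{name}.proj")

    def param_layers(self):
        out = []
        for l in self.branch:
            out.extend(l.param_layers())
        if self.proj is not None:
            out.extend(self.proj.param_layers())
        return out

    def forward(self, x, train=False):
        y = x
        for l in self.branch:
            y = l.forward(y, train)
        s = self.proj.forward(x, train) if self.proj is not None else x
        z = y + s
        self._mask = z > 0
        return z * self._mask

    def backward(self, dy):
        dz = dy * self._mask
        db = dz
        for l in reversed(self.branch):
            db = l.backward(db)
        ds = self.proj.backward(dz) if self.proj is not None else dz
        return db + ds


class InceptionBlock(Layer):
    """Parallel 1x1 and 3x3 convolutions, channel-concatenated, relu'd."""

    def __init__(self, in_ch, out1, out3, batch_norm=True, name=""):
        super().__init__(name)
        self.b1 = [Conv2D(in_ch, out1, 1, pad=0, name=f"{name}.conv1x1")]
        self.b3 = [Conv2D(in_ch, out3, 3, name=f"{name}.conv3x3")]
        if batch_norm:
            self.b1.append(BatchNorm2D(out1, name=f"{name}.bn1x1"))
            self.b3.append(BatchNorm2D(out3, name=f"{name}.bn3x3"))
        self.out1 = out1

    def param_layers(self):
        out = []
        for l in self.b1 + self.b3:
            out.extend(l.param_layers())
        return out

    def forward(self, x, train=False):
        y1, y3 = x, x
        for l in self.b1:
            y1 = l.forward(y1, train)
        for l in self.b3:
            y3 = l.forward(y3, train)
        z = np.concatenate([y1, y3], axis=1)
        self._mask = z > 0
        return z * self._mask

    def backward(self, dy):
        dz = dy * self._mask
        d1, d3 = dz[:, :self.out1], dz[:, self.out1:]
        for l in reversed(self.b1):
            d1 = l.backward(d1)
        for l in reversed(self.b3):
            d3 = l.backward(d3)
        return d1 + d3


# ---------------------------------------------------------------------------
# model

class Model:
    """Ordered stack of named layers with cached activations."""

    def __init__(self, layers, input_size, tag=""):
        self.layers = layers
        self.input_size = input_size
        self.tag = tag
        self.input_mean = 0.0
        self.input_std = 1.0
        names = [l.name for l in layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")

    def layer_names(self):
        return [l.name for l in self.layers]

    def conv_layer_names(self):
        return [l.name for l in self.layers
                if isinstance(l, (Conv2D, ResBlock, InceptionBlock))]

    def param_layers(self):
        out = []
        for l in self.layers:
            out.extend(l.param_layers())
        return out

    def prepare(self, images):
        """(H,W) or (N,H,W) grayscale floats -> standardized (N,1,H,W)."""
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        x = (x - self.input_mean) / self.input_std
        return x[:, None, :, :]

    def forward(self, x, train=False, keep_activations=False):
        acts = []
        for l in self.layers:
            x = l.forward(x, train)
            if keep_activations:
                acts.append(x)
        if keep_activations:
            self._activations = acts
        return x

    def backward(self, dout, to_layer=None):
        """Propagate ``dout`` (grad at the logits) backward.

        With ``to_layer`` set, stop once the gradient with respect to
        that layer's *output* is available and return it; otherwise
        propagate to the input and return the input gradient.
        """
        idx = None
        if to_layer is not None:
            names = self.layer_names()
            if to_layer not in names:
                raise KeyError(f"unknown layer: {to_layer!r}")
            idx = names.index(to_layer)
        g = dout
        for i in range(len(self.layers) - 1, -1, -1):
            if idx is not None and i == idx:
                return g
            g = self.layers[i].backward(g)
        return g

    def activation(self, name):
        return self._activations[self.layer_names().index(name)]

    def zero_grad(self):
        for l in self.layers:
            l.zero_grad()

    def calibrate_bn(self, x_all, batch_size=64):
        """Recompute batch-norm population statistics over a dataset.

        Exponential running averages lag behind fast-moving weights at
        high learning rates; a final full pass ("precise BN") replaces
        them with the mean of per-batch statistics under the trained
        weights, so eval-mode behavior matches the trained network.
        """
        bns = [l for l in self.param_layers() if isinstance(l, BatchNorm2D)]
        if not bns:
            return
        for bn in bns:
            bn._collect = []
        for start in range(0, len(x_all), batch_size):
            self.forward(x_all[start:start + batch_size], train=True)
        for bn in bns:
            means = np.stack([m for m, _ in bn._collect])
            varis = np.stack([v for _, v in bn._collect])
            bn.running_mean = means.mean(axis=0)
            # total variance = within-batch + between-batch spread
            bn.running_var = varis.mean(axis=0) + means.var(axis=0)
            bn._collect = None

    # -- serialization ------------------------------------------------------
    def state_dict(self):
        state = {"__input_mean__": np.array(self.input_mean),
                 "__input_std__": np.array(self.input_std)}
        for l in self.param_layers():
            for k, v in l.params.items():
                state[f"{l.name}/{k}"] = v
            if isinstance(l, BatchNorm2D):
                state[f"{l.name}/running_mean"] = l.running_mean
                state[f"{l.name}/running_var"] = l.running_var
        return state

    def load_state_dict(self, state):
        self.input_mean = float(state["__input_mean__"])
        self.input_std = float(state["__input_std__"])
        for l in self.param_layers():
            for k in l.params:
                l.params[k] = np.asarray(state[f"{l.name}/{k}"]).copy()
            if isinstance(l, BatchNorm2D):
                l.running_mean = np.asarray(state[f"{l.name}/running_mean"]).copy()
                l.running_var = np.asarray(state[f"{l.name}/running_var"]).copy()

    def save(self, path):
        np.savez(path, **self.state_dict())

    def load(self, path):
        with np.load(path) as f:
            self.load_state_dict(dict(f.items()))


# ---------------------------------------------------------------------------
# experiment configuration

@dataclass
class ExperimentConfig:
    backbone: str = "small-resnet-like"
    learning_rate: float = 0.1
    batch_norm: bool = True
    pretrained: bool = False
    checkpoint: str | None = None  # stub weights from a prior run
    weight_init: bool = False  # explicit Xavier re-init instead of the default He scheme
    optimizer: str = "SGD"
    freezing: str = "from-scratch"
    epochs_max: int = 30
    batch_size: int = 32
    momentum: float = 0.9
    adam_betas: tuple = (0.9, 0.999)
    seed: int = 0
    input_size: int = 64
    name: str = ""

    def __post_init__(self):
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.freezing not in FREEZING_SCHEMES:
            raise ValueError(f"unknown freezing scheme {self.freezing!r}")
        if self.freezing != "from-scratch" and not self.pretrained:
            raise ValueError("freezing layers requires pretrained (stub) weights")
        if self.pretrained and not self.checkpoint:
            raise ValueError("pretrained=True requires a checkpoint path")


def _make_backbone(cfg: ExperimentConfig) -> Model:
    bn = cfg.batch_norm
    if cfg.backbone == "small-vgg-like":
        layers = [Conv2D(1, 8, name="conv1")]
        if bn:
            layers.append(BatchNorm2D(8, name="bn1"))
        layers += [ReLU(name="relu1"), MaxPool2x2(name="pool1"), Conv2D(8, 16, name="conv2")]
        if bn:
            layers.append(BatchNorm2D(16, name="bn2"))
        layers += [ReLU(name="relu2"), MaxPool2x2(name="pool2"), Conv2D(16, 32, name="conv3")]
        if bn:
            layers.append(BatchNorm2D(32, name="bn3"))
        layers += [ReLU(name="relu3"), GlobalAvgPool(name="gap"), Linear(32, 2, name="fc")]
    elif cfg.backbone == "small-resnet-like":
        layers = [Conv2D(1, 8, name="stem")]
        if bn:
            layers.append(BatchNorm2D(8, name="stem_bn"))
        layers += [
            ReLU(name="stem_relu"),
            MaxPool2x2(name="pool1"),
            ResBlock(8, 16, stride=2, batch_norm=bn, name="block1"),
            ResBlock(16, 32, stride=2, batch_norm=bn, name="block2"),
            GlobalAvgPool(name="gap"),
            Linear(32, 2, name="fc"),
        ]
    else:  # small-inception-like
        layers = [Conv2D(1, 8, name="stem")]
        if bn:
            layers.append(BatchNorm2D(8, name="stem_bn"))
        layers += [
            ReLU(name="stem_relu"),
            MaxPool2x2(name="pool1"),
            InceptionBlock(8, 8, 8, batch_norm=bn, name="incept1"),
            MaxPool2x2(name="pool2"),
            InceptionBlock(16, 16, 16, batch_norm=bn, name="incept2"),
            GlobalAvgPool(name="gap"),
            Linear(32, 2, name="fc"),
        ]
    return Model(layers, input_size=cfg.input_size, tag=cfg.backbone)


def build_model(config: ExperimentConfig) -> Model:
    """Untrained model per config; deterministic given (config, seed)."""
    model = _make_backbone(config)
    rng = np.random.default_rng(config.seed)
    scheme = "xavier" if config.weight_init else "he"
    for l in model.param_layers():
        if hasattr(l, "init_weights"):
            l.init_weights(rng, scheme)
    if config.pretrained:
        path = Path(config.checkpoint)
        if not path.exists():
            raise FileNotFoundError(f"pretrained checkpoint not found: {path}")
        model.load(path)
    return model


def apply_freezing(model: Model, scheme: str) -> Model:
    if scheme not in FREEZING_SCHEMES:
        raise ValueError(f"unknown freezing scheme {scheme!r}")
    plist = model.param_layers()
    if scheme == "from-scratch":
        trainables = set(range(len(plist)))
    elif scheme == "last-fc-only":
        trainables = {len(plist) - 1}
    else:  # last-five-layers: the last five weight-bearing layers
        trainables = set(range(max(0, len(plist) - 5), len(plist)))
    for i, l in enumerate(plist):
        l.trainable = i in trainables
    return model


# ---------------------------------------------------------------------------
# optimizers and training

class _SGD:
    def __init__(self, layers, lr, momentum=0.9):
        self.layers, self.lr, self.momentum = layers, lr, momentum
        self.vel = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in layers]

    def step(self):
        for l, vel in zip(self.layers, self.vel):
            if not l.trainable:
                continue
            for k in l.params:
                vel[k] = self.momentum * vel[k] - self.lr * l.grads[k]
                l.params[k] += vel[k]


class _Adam:
    def __init__(self, layers, lr, betas=(0.9, 0.999), eps=1e-8):
        self.layers, self.lr, self.betas, self.eps = layers, lr, betas, eps
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in layers]
        self.t = 0

    def step(self):
        b1, b2 = self.betas
        self.t += 1
        for l, m, v in zip(self.layers, self.m, self.v):
            if not l.trainable:
                continue
            for k in l.params:
                g = l.grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                mhat = m[k] / (1 - b1**self.t)
                vhat = v[k] / (1 - b2**self.t)
                l.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax_xent(logits, labels):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = -np.log(p[np.arange(n), labels] + 1e-12).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


def train(model: Model, train_set, config: ExperimentConfig, eval_set=None) -> dict:
    """Train in place; returns the history dict.

    Stopping rule: training ends at ``epochs_max`` or once the
    moving-average (window 3) epoch loss has failed to improve by at
    least 1e-4 for 5 consecutive epochs.
    """
    images = np.asarray(train_set.images, dtype=np.float64)
    labels = train_set.label_array()
    if len(images) == 0:
        raise ValueError("empty training set")
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    model.input_mean = float(images.mean())
    model.input_std = float(images.std()) or 1.0
    x_all = model.prepare(images)

    rng = np.random.default_rng(config.seed)
    opt_layers = model.param_layers()
    if config.optimizer == "SGD":
        opt = _SGD(opt_layers, config.learning_rate, config.momentum)
    else:
        opt = _Adam(opt_layers, config.learning_rate, config.adam_betas)

    history = {"loss": [], "eval_accuracy": []}
    best_ma = np.inf
    stall = 0
    for _ in range(config.epochs_max):
        order = rng.permutation(len(x_all))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            model.zero_grad()
            logits = model.forward(x_all[idx], train=True)
            loss, dlogits = softmax_xent(logits, labels[idx])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history["loss"].append(float(np.mean(losses)))
        if eval_set is not None:
            cm = evaluate(model, eval_set)
            history["eval_accuracy"].append((cm.TP + cm.TN) / cm.total)
        ma = float(np.mean(history["loss"][-3:]))
        if ma < best_ma - 1e-4:
            best_ma = ma
            stall = 0
        else:
            stall += 1
            if stall >= 5:
                break
    model.calibrate_bn(x_all, config.batch_size)
    model.history = history
    return history


def predict(model: Model, images, batch_size=64) -> np.ndarray:
    x = model.prepare(np.asarray(images, dtype=np.float64))
    preds = []
    for start in range(0, len(x), batch_size):
        logits = model.forward(x[start:start + batch_size], train=False)
        preds.append(logits.argmax(axis=1))
    return np.concatenate(preds)


def evaluate(model: Model, test_set) -> ConfusionMatrix:
    """Confusion counts on a dataset; positive class = case."""
    if len(test_set) == 0:
        raise ValueError("empty test set")
    y = test_set.label_array()
    yhat = predict(model, np.asarray(test_set.images, dtype=np.float64))
    return ConfusionMatrix(
        TP=int(np.sum((y == 1) & (yhat == 1))),
        FN=int(np.sum((y == 1) & (yhat == 0))),
        FP=int(np.sum((y == 0) & (yhat == 1))),
        TN=int(np.sum((y == 0) & (yhat == 0))),
    )


def run_experiment_grid(grid, train_set, test_set) -> "pd.DataFrame":
    """One row per config: confusion counts plus ACC/SEN/SPE in percent.

    The best row (highest accuracy, ties to the earliest config) is
    flagged in the ``best`` column.
    """
    import pandas as pd

    from .screenstats import confusion_metrics

    rows = []
    for i, cfg in enumerate(grid):
        model = build_model(cfg)
        apply_freezing(model, cfg.freezing)
        train(model, train_set, cfg)
        cm = evaluate(model, test_set)
        met = confusion_metrics(cm)
        rows.append({
            "experiment": cfg.name or f"exp-{i + 1}",
            "backbone": cfg.backbone,
            "learning_rate": cfg.learning_rate,
            "batch_norm": cfg.batch_norm,
            "pretrained": cfg.pretrained,
            "weight_init": cfg.weight_init,
            "optimizer": cfg.optimizer,
            "freezing": cfg.freezing,
            "TP": cm.TP, "FN": cm.FN, "FP": cm.FP, "TN": cm.TN,
            "ACC": met.accuracy, "SEN": met.sensitivity, "SPE": met.specificity,
        })
    report = pd.DataFrame(rows)
    best = int(report["ACC"].idxmax())  # idxmax takes the first maximum
    report["best"] = [i == best for i in range(len(report))]
    return report
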