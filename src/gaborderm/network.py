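"""Compact CNN branches: build, retrain with SGD-momentum, extract features.

A *branch* is one CNN trained on one input stream (the original image or
one Gabor subband rendering); an *ensemble* is the five branches of one
backbone.  The classification head of every backbone is a 7-unit fully
connected layer, and the deep feature extracted per image is that head's
pre-softmax activation vector, so the feature length always equals the
class count.

The ``tiny-test`` backbone — three 3x3 conv/ReLU/maxpool blocks (8, 16,
32 channels) on 32x32x3 input, followed by the 7-unit head — is a pure
numpy implementation trained here with minibatch stochastic gradient
descent with momentum (SGDM).  Being numpy end-to-end it is exactly
reproducible on CPU for a fixed seed.  The ImageNet-family backbones
(resnet18, shufflenet, mobilenet) are registered as optional heavyweight
plugins: they require the ``torch``/``torchvision`` stack and raise
:class:`BackboneUnavailableError` when that stack is not installed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gaborderm.data import CLASSES, DatasetTable, TrainConfig, resize_image
from gaborderm.features import STREAMS, FeatureMatrix

__all__ = [
    "BackboneSpec",
    "BranchModel",
    "BranchEnsemble",
    "BackboneUnavailableError",
    "BACKBONE_REGISTRY",
    "build_branch",
    "retrain_branch",
    "extract_features",
    "train_ensemble",
]


class BackboneUnavailableError(RuntimeError):
    """A registered backbone whose optional dependency is not installed."""


#: registry name -> (input side, available flag)
BACKBONE_REGISTRY = {
    "tiny-test": {"input_side": 32, "available": True},
    "resnet18": {"input_side": 224, "available": False},
    "shufflenet": {"input_side": 224, "available": False},
    "mobilenet": {"input_side": 224, "available": False},
}


@dataclass(frozen=True)
class BackboneSpec:
    name: str
    input_side: int | None = None
    pretrained: bool = False

    def __post_init__(self):
        if self.name not in BACKBONE_REGISTRY:
            raise ValueError(
                f"unknown backbone {self.name!r}; registered backbones: "
                f"{sorted(BACKBONE_REGISTRY)}"
            )
        if self.input_side is None:
            object.__setattr__(
                self, "input_side", BACKBONE_REGISTRY[self.name]["input_side"]
            )


@dataclass
class BranchModel:
    """One CNN branch: a backbone body plus a 7-unit class head."""

    backbone: BackboneSpec
    stream: str
    n_classes: int = 7
    params: dict = field(default_factory=dict, repr=False)
    stats: dict = field(default_factory=dict, repr=False)
    training_log: list = field(default_factory=list, repr=False)
    seed: int = 0

    def __post_init__(self):
        if self.stream not in STREAMS:
            raise ValueError(
                f"unknown stream {self.stream!r}; expected one of {STREAMS}"
            )


@dataclass
class BranchEnsemble:
    """The five branches (original, GW1..GW4) of one backbone."""

    backbone: BackboneSpec
    branches: dict  # stream -> BranchModel

    def __post_init__(self):
        if set(self.branches) != set(STREAMS):
            raise ValueError(
                f"ensemble must cover streams {STREAMS}, "
                f"got {sorted(self.branches)}"
            )


# ---------------------------------------------------------------------------
# numpy tiny CNN
# ---------------------------------------------------------------------------

_TINY_CHANNELS = (8, 16, 32)
_KSIZE = 3
_CLIP_NORM = 1.0  # global gradient-norm ceiling during SGDM


def _tiny_init(n_classes: int, input_side: int, seed: int) -> dict:
    """He-initialised weights for the tiny-test architecture."""
    rng = np.random.default_rng(seed)
    params = {}
    c_in = 3
    side = input_side
    for i, c_out in enumerate(_TINY_CHANNELS):
        fan_in = c_in * _KSIZE * _KSIZE
        params[f"W{i}"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in)
        )
        params[f"g{i}"] = np.ones(c_out)   # batch-norm scale
        params[f"be{i}"] = np.zeros(c_out)  # batch-norm shift
        c_in = c_out
        side //= 2
    flat = _TINY_CHANNELS[-1] * side * side
    params["Wf"] = rng.normal(0.0, np.sqrt(2.0 / flat), size=(n_classes, flat))
    params["bf"] = np.zeros(n_classes)
    return params


def _init_stats() -> dict:
    """Running batch-norm statistics (inference-time mean/variance)."""
    stats = {}
    for i, c in enumerate(_TINY_CHANNELS):
        stats[f"rm{i}"] = np.zeros(c)
        stats[f"rv{i}"] = np.ones(c)
    return stats


def _im2col(x: np.ndarray) -> np.ndarray:
    # x: (N, C, H, W) -> (N, C*9, H*W), 3x3 kernel, pad 1, stride 1
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((n, c, _KSIZE, _KSIZE, h, w), dtype=x.dtype)
    for i in range(_KSIZE):
        for j in range(_KSIZE):
            cols[:, :, i, j] = xp[:, :, i : i + h, j : j + w]
    return cols.reshape(n, c * _KSIZE * _KSIZE, h * w)


def _col2im(dcols: np.ndarray, shape) -> np.ndarray:
    n, c, h, w = shape
    dcols = dcols.reshape(n, c, _KSIZE, _KSIZE, h, w)
    dxp = np.zeros((n, c, h + 2, w + 2), dtype=dcols.dtype)
    for i in range(_KSIZE):
        for j in range(_KSIZE):
            dxp[:, :, i : i + h, j : j + w] += dcols[:, :, i, j]
    return dxp[:, :, 1:-1, 1:-1]


_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


def _forward(
    params: dict,
    x: np.ndarray,
    stats: dict | None = None,
    train: bool = False,
    want_cache: bool = False,
):
    """Forward pass; x is (N, 3, S, S) float. Returns logits (N, n_classes).

    Each block is conv(3x3, pad 1) -> batch norm -> ReLU -> 2x2 max pool.
    In training mode batch statistics are used and the running ``stats``
    are updated in place; otherwise the running statistics are used.
    """
    cache = {"x": []}
    h = x
    for i in range(len(_TINY_CHANNELS)):
        n, c, hh, ww = h.shape
        cols = _im2col(h)
        conv = np.einsum("fk,nkp->nfp", params[f"W{i}"], cols)
        f = conv.shape[1]
        if train:
            mean = conv.mean(axis=(0, 2))
            var = conv.var(axis=(0, 2))
            if stats is not None:
                m = _BN_MOMENTUM
                stats[f"rm{i}"] = (1 - m) * stats[f"rm{i}"] + m * mean
                stats[f"rv{i}"] = (1 - m) * stats[f"rv{i}"] + m * var
        else:
            mean = stats[f"rm{i}"] if stats is not None else np.zeros(f)
            var = stats[f"rv{i}"] if stats is not None else np.ones(f)
        invstd = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (conv - mean[None, :, None]) * invstd[None, :, None]
        bn = params[f"g{i}"][None, :, None] * xhat
        bn += params[f"be{i}"][None, :, None]
        bn = bn.reshape(n, f, hh, ww)
        relu = np.maximum(bn, 0.0)
        # 2x2 max pooling, stride 2
        r = relu.reshape(n, f, hh // 2, 2, ww // 2, 2)
        pooled = r.max(axis=(3, 5))
        if want_cache:
            cache["x"].append(
                (h.shape, cols, bn, relu, pooled, xhat, invstd)
            )
        h = pooled
    n = h.shape[0]
    flat = h.reshape(n, -1)
    logits = flat @ params["Wf"].T + params["bf"]
    if want_cache:
        cache["flat"] = flat
        cache["pooled_shape"] = h.shape
        return logits, cache
    return logits


def _backward(params: dict, cache: dict, dlogits: np.ndarray) -> dict:
    grads = {}
    grads["Wf"] = dlogits.T @ cache["flat"]
    grads["bf"] = dlogits.sum(axis=0)
    dh = (dlogits @ params["Wf"]).reshape(cache["pooled_shape"])
    for i in reversed(range(len(_TINY_CHANNELS))):
        in_shape, cols, bn, relu, pooled, xhat, invstd = cache["x"][i]
        n, c, hh, ww = relu.shape
        # unpool: route gradient to a single argmax per 2x2 window
        r4 = (
            relu.reshape(n, c, hh // 2, 2, ww // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, hh // 2, ww // 2, 4)
        )
        onehot = np.eye(4)[r4.argmax(axis=-1)]
        drelu = (
            (onehot * dh[..., None])
            .reshape(n, c, hh // 2, ww // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, hh, ww)
        )
        dbn = (drelu * (bn > 0)).reshape(n, c, hh * ww)
        # batch-norm backward (batch statistics; m = n * spatial per channel)
        grads[f"g{i}"] = np.einsum("nfp,nfp->f", dbn, xhat)
        grads[f"be{i}"] = dbn.sum(axis=(0, 2))
        dxhat = dbn * params[f"g{i}"][None, :, None]
        m = n * hh * ww
        sum_dxhat = dxhat.sum(axis=(0, 2))
        sum_dxhat_xhat = np.einsum("nfp,nfp->f", dxhat, xhat)
        dconv = (
            invstd[None, :, None]
            / m
            * (
                m * dxhat
                - sum_dxhat[None, :, None]
                - xhat * sum_dxhat_xhat[None, :, None]
            )
        )
        grads[f"W{i}"] = np.einsum("nfp,nkp->fk", dconv, cols)
        dcols = np.einsum("fk,nfp->nkp", params[f"W{i}"], dconv)
        dh = _col2im(dcols, (in_shape[0], in_shape[1], hh, ww))
    return grads


def _recalibrate_stats(params: dict, stats: dict, x: np.ndarray,
                       batch: int = 256) -> None:
    """Set batch-norm running stats to exact dataset statistics.

    After the last SGDM step the exponential running averages still lag
    the final weights; one frozen-weight pass over the training images
    replaces them with the exact per-channel mean/variance.
    """
    def block(h, i):
        n, _, hh, ww = h.shape
        cols = _im2col(h)
        conv = np.einsum("fk,nkp->nfp", params[f"W{i}"], cols)
        return conv, (n, conv.shape[1], hh, ww)

    # layer by layer: stats for layer i are computed with layers < i
    # already using their recalibrated statistics
    for layer in range(len(_TINY_CHANNELS)):
        s1 = s2 = 0.0
        count = 0
        for start in range(0, len(x), batch):
            h = x[start : start + batch]
            for i in range(layer + 1):
                conv, (n, f, hh, ww) = block(h, i)
                if i == layer:
                    s1 = s1 + conv.sum(axis=(0, 2))
                    s2 = s2 + (conv**2).sum(axis=(0, 2))
                    count += n * hh * ww
                    break
                invstd = 1.0 / np.sqrt(stats[f"rv{i}"] + _BN_EPS)
                xhat = (conv - stats[f"rm{i}"][None, :, None])
                xhat *= invstd[None, :, None]
                bn = params[f"g{i}"][None, :, None] * xhat
                bn += params[f"be{i}"][None, :, None]
                relu = np.maximum(bn.reshape(n, f, hh, ww), 0.0)
                h = relu.reshape(n, f, hh // 2, 2, ww // 2, 2).max(axis=(3, 5))
        mean = s1 / count
        stats[f"rm{layer}"] = mean
        stats[f"rv{layer}"] = np.maximum(s2 / count - mean**2, 0.0)


def _softmax_xent(logits: np.ndarray, y: np.ndarray):
    z = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(z)
    p = expz / expz.sum(axis=1, keepdims=True)
    n = len(y)
    loss = -np.mean(np.log(p[np.arange(n), y] + 1e-300))
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


def _table_to_arrays(table: DatasetTable, side: int):
    """Resize records to the backbone side and stack as (N,3,S,S) in [-0.5,0.5]."""
    imgs, labels = [], []
    for rec in table:
        px = resize_image(rec, side).pixels
        imgs.append(px.transpose(2, 0, 1))
        labels.append(CLASSES.index(rec.label))
    x = np.stack(imgs).astype(np.float64) / 255.0 - 0.5
    return x, np.array(labels)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def build_branch(
    spec: BackboneSpec, stream: str, n_classes: int = 7, seed: int = 0
) -> BranchModel:
    """Instantiate a branch with its head replaced by an n-class FC layer.

    The tiny-test backbone is initialised from a seeded random draw; the
    ImageNet-family backbones require the optional torch plugin stack.
    """
    entry = BACKBONE_REGISTRY[spec.name]
    if not entry["available"]:
        raise BackboneUnavailableError(
            f"backbone {spec.name!r} is an optional heavyweight plugin "
            "requiring the torch/torchvision stack, which is not installed; "
            "use the 'tiny-test' backbone for CPU-only work"
        )
    params = _tiny_init(n_classes, spec.input_side, seed)
    return BranchModel(
        backbone=spec, stream=stream, n_classes=n_classes,
        params=params, stats=_init_stats(), seed=seed,
    )


def retrain_branch(
    branch: BranchModel, train: DatasetTable, config: TrainConfig
) -> BranchModel:
    """Fixed-epoch SGDM training of one branch on its stream imagery.

    Minibatches are reshuffled each epoch from a generator seeded by
    ``config.seed``; a held-out tenth of the training rows serves as the
    validation set, scored every ``validation_frequency`` iterations.
    Per-epoch mean loss and training accuracy go to ``training_log``.
    Returns the same model object with updated weights (epochs=0 is a
    no-op with an empty log).
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    if config.epochs == 0:
        return branch
    x, y = _table_to_arrays(train, branch.backbone.input_side)
    rng = np.random.default_rng(config.seed)

    # held-out validation tenth (at least 1 row when possible)
    n = len(y)
    n_val = max(1, n // 10) if n >= 10 else 0
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    xv, yv = x[val_idx], y[val_idx]
    xt, yt = x[tr_idx], y[tr_idx]

    params = branch.params
    velocity = {k: np.zeros_like(v) for k, v in params.items()}
    mu, lr = config.momentum, config.learning_rate
    iteration = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(yt))
        losses, correct = [], 0
        for start in range(0, len(order), config.mini_batch):
            idx = order[start : start + config.mini_batch]
            logits, cache = _forward(
                params, xt[idx], stats=branch.stats, train=True,
                want_cache=True,
            )
            loss, dlogits = _softmax_xent(logits, yt[idx])
            grads = _backward(params, cache, dlogits)
            # global-norm gradient clipping keeps SGDM stable on small batches
            gnorm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
            if gnorm > _CLIP_NORM:
                scale = _CLIP_NORM / gnorm
                grads = {k: g * scale for k, g in grads.items()}
            for k in params:
                velocity[k] = mu * velocity[k] - lr * grads[k]
                params[k] += velocity[k]
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == yt[idx]).sum())
            iteration += 1
            if n_val and iteration % config.validation_frequency == 0:
                vl = _forward(params, xv, stats=branch.stats)
                val_acc = float((vl.argmax(axis=1) == yv).mean())
                branch.training_log.append(
                    {"epoch": epoch, "iteration": iteration,
                     "val_accuracy": val_acc}
                )
        branch.training_log.append(
            {
                "epoch": epoch,
                "loss": float(np.mean(losses)),
                "accuracy": correct / len(yt),
            }
        )
    _recalibrate_stats(params, branch.stats, xt)
    return branch


def extract_features(
    branch: BranchModel, images: DatasetTable, batch: int = 64
) -> FeatureMatrix:
    """Pre-softmax activations of the class head, one row per image."""
    x, _ = _table_to_arrays(images, branch.backbone.input_side)
    chunks = [
        _forward(branch.params, x[i : i + batch], stats=branch.stats)
        for i in range(0, len(x), batch)
    ]
    values = np.vstack(chunks)
    prov = [
        (branch.backbone.name, branch.stream, j)
        for j in range(branch.n_classes)
    ]
    return FeatureMatrix(
        values=values, row_ids=images.image_ids, column_provenance=prov
    )


def train_ensemble(
    spec: BackboneSpec, stream_tables: dict, config: TrainConfig
) -> BranchEnsemble:
    """Train the five branches of one backbone on their stream datasets.

    ``stream_tables`` maps each stream tag to a DatasetTable; all five
    tables must share image ids and labels row-for-row.  Each branch gets
    an independent deterministic seed derived from ``config.seed``.
    """
    missing = set(STREAMS) - set(stream_tables)
    if missing:
        raise ValueError(f"missing stream dataset(s): {sorted(missing)}")
    ref = stream_tables[STREAMS[0]]
    for s in STREAMS[1:]:
        t = stream_tables[s]
        if t.image_ids != ref.image_ids or t.labels != ref.labels:
            raise ValueError(
                f"stream {s!r} dataset does not match the reference stream's "
                "image ids/labels"
            )
    branches = {}
    for i, s in enumerate(STREAMS):
        branch_seed = (config.seed * 1000 + i) % (2**31)
        branch = build_branch(spec, s, seed=branch_seed)
        cfg = TrainConfig(
            mini_batch=config.mini_batch,
            epochs=config.epochs,
            learning_rate=config.learning_rate,
            validation_frequency=config.validation_frequency,
            momentum=config.momentum,
            seed=branch_seed,
        )
        branches[s] = retrain_branch(branch, stream_tables[s], cfg)
    return BranchEnsemble(backbone=spec, branches=branches)
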