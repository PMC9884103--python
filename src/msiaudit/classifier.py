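"""Patch classifier: a compact dense-connectivity CNN trained on 32 x 32 patches.

The network follows the DenseNet idea: inside each block, every 3 x 3
convolution receives the concatenation of the block input and all previous
layer outputs, and contributes ``growth`` new feature maps.  Blocks are
joined by 1 x 1 compression convolutions with 2 x 2 average pooling; a
global average pool and a fully-connected layer produce K-way class
probabilities through a softmax.  Training minimizes multiclass
cross-entropy with Adam (initial learning rate 0.001) and L2 regularization
0.001, for 40 epochs in batches of 128, with post-hoc selection of the epoch
that maximizes validation micro-accuracy.  The implementation is pure NumPy
and exactly reproducible from its seeds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._nn import (
    DTYPE,
    Adam,
    AvgPool2d,
    Conv2d,
    Dense,
    GlobalAvgPool,
    ReLU,
    cross_entropy,
    softmax,
    softmax_ce_grad,
)
from .patchwork import PatchDataset


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters of the dense-connectivity classifier."""

    input_channels: int
    n_classes: int
    input_size: int = 32
    n_blocks: int = 3
    layers_per_block: int = 4
    growth: int = 12
    stem_channels: int = 16
    stem_stride: int = 2
    stem_pool: bool = True  # extra 2x2 average pool after the stem
    compression: float = 0.5
    seed: int = 0


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol; the defaults are the reference protocol."""

    learning_rate: float = 0.001
    l2_weight: float = 0.001
    epochs: int = 40
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.l2_weight) < 0 or \
           min(self.epochs, self.batch_size) <= 0:
            raise ValueError("TrainConfig values must be positive")


class DenseNetClassifier:
    """The network itself; ``build_model`` is the public constructor."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        g = spec.growth
        c = spec.stem_channels
        self.stem = Conv2d(spec.input_channels, c, 3, spec.stem_stride, 1, rng, "stem")
        self.stem_pool = AvgPool2d() if spec.stem_pool else None
        self.blocks: list[dict] = []
        for b in range(spec.n_blocks):
            layers = []
            for l in range(spec.layers_per_block):
                layers.append({"relu": ReLU(),
                               "conv": Conv2d(c + l * g, g, 3, 1, 1, rng, f"b{b}l{l}")})
            c = c + spec.layers_per_block * g
            trans = None
            if b < spec.n_blocks - 1:
                cout = max(1, int(c * spec.compression))
                trans = {"relu": ReLU(), "conv": Conv2d(c, cout, 1, 1, 0, rng, f"t{b}"),
                         "pool": AvgPool2d()}
                c = cout
            self.blocks.append({"layers": layers, "trans": trans})
        self.head_relu = ReLU()
        self.gap = GlobalAvgPool()
        self.fc = Dense(c, spec.n_classes, rng, "fc")
        self.feature_channels = c

    # -- parameter plumbing -------------------------------------------------
    def params(self):
        out = list(self.stem.params())
        for blk in self.blocks:
            for lay in blk["layers"]:
                out.extend(lay["conv"].params())
            if blk["trans"] is not None:
                out.extend(blk["trans"]["conv"].params())
        out.extend(self.fc.params())
        return out

    def n_parameters(self) -> int:
        return int(sum(v.size for _, v, _ in self.params()))

    def get_state(self) -> dict[str, np.ndarray]:
        return {name: v.copy() for name, v, _ in self.params()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for name, v, _ in self.params():
            v[...] = state[name]

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        """x: (N, C, H, W) float32 -> class probabilities (N, K)."""
        h = self.stem.forward(x, cache)
        if self.stem_pool is not None:
            h = self.stem_pool.forward(h, cache)
        for blk in self.blocks:
            feats = [h]
            for lay in blk["layers"]:
                inp = feats[0] if len(feats) == 1 else np.concatenate(feats, axis=1)
                y = lay["conv"].forward(lay["relu"].forward(inp, cache), cache)
                feats.append(y)
            h = np.concatenate(feats, axis=1)
            t = blk["trans"]
            if t is not None:
                h = t["pool"].forward(t["conv"].forward(t["relu"].forward(h, cache),
                                                        cache), cache)
        h = self.head_relu.forward(h, cache)
        z = self.fc.forward(self.gap.forward(h, cache), cache)
        return softmax(z)

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.gap.backward(self.fc.backward(dlogits))
        dh = self.head_relu.backward(dh)
        for blk in reversed(self.blocks):
            t = blk["trans"]
            if t is not None:
                dh = t["relu"].backward(t["conv"].backward(t["pool"].backward(dh)))
            # split the concat gradient into per-feature slices
            g = self.spec.growth
            c0 = dh.shape[1] - g * len(blk["layers"])
            bounds = [0, c0] + [c0 + g * (i + 1) for i in range(len(blk["layers"]))]
            d_feats = [dh[:, bounds[i]:bounds[i + 1]].copy()
                       for i in range(len(bounds) - 1)]
            for l in range(len(blk["layers"]) - 1, -1, -1):
                lay = blk["layers"][l]
                dinp = lay["relu"].backward(lay["conv"].backward(d_feats[l + 1]))
                for i in range(l + 1):
                    d_feats[i] += dinp[:, bounds[i]:bounds[i + 1]]
            dh = d_feats[0]
        if self.stem_pool is not None:
            dh = self.stem_pool.backward(dh)
        self.stem.backward(dh)

    def loss_and_grad(self, x: np.ndarray, labels: np.ndarray) -> float:
        probs = self.forward(x, cache=True)
        loss = cross_entropy(probs, labels)
        self.backward(softmax_ce_grad(probs, labels))
        return loss

    def predict_proba_array(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        out = np.empty((x.shape[0], self.spec.n_classes))
        for i in range(0, x.shape[0], batch_size):
            out[i:i + batch_size] = self.forward(x[i:i + batch_size], cache=False)
        return out


def build_model(spec: ModelSpec) -> DenseNetClassifier:
    """Construct an untrained dense-connectivity classifier from its spec."""
    if spec.input_channels < 1 or spec.n_classes < 2:
        raise ValueError("need >= 1 input channel and >= 2 classes")
    return DenseNetClassifier(spec)


@dataclass
class PredictionBatch:
    """Per-patch probability vectors plus provenance.

    ``predicted`` is the argmax label (ties resolve to the lowest class
    index); each probability row sums to 1.
    """

    probs: np.ndarray
    labels: np.ndarray
    class_names: tuple[str, ...]
    specimen_ids: np.ndarray | None = None
    scene_ids: np.ndarray | None = None
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.probs.ndim != 2 or self.probs.shape[0] != self.labels.size:
            raise ValueError("probs must be (N, K) matching labels")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")

    @property
    def predicted(self) -> np.ndarray:
        return np.argmax(self.probs, axis=1)

    @property
    def n_classes(self) -> int:
        return self.probs.shape[1]

    def correct_probs(self) -> np.ndarray:
        return self.probs[np.arange(self.labels.size), self.labels]

    def micro_accuracy(self) -> float:
        return float(np.mean(self.predicted == self.labels))


@dataclass
class TrainedModel:
    """A trained network with its per-epoch history and selected epoch."""

    net: DenseNetClassifier
    spec: ModelSpec
    config: TrainConfig
    history: pd.DataFrame
    selected_epoch: int
    view: str | tuple = "msi21"

    @property
    def validation_accuracy(self) -> float:
        return float(self.history["val_micro_acc"].iloc[self.selected_epoch])


def _to_nchw(patches: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(patches.transpose(0, 3, 1, 2).astype(DTYPE))


def train(model: DenseNetClassifier, dataset: PatchDataset,
          config: TrainConfig) -> TrainedModel:
    """Train with Adam on cross-entropy + L2; keep the best-epoch checkpoint.

    The best epoch maximizes validation micro-accuracy (ties resolve to the
    earliest epoch).  Fully reproducible from (ModelSpec.seed, config.seed).
    """
    if model.spec.input_channels != dataset.n_channels:
        raise ValueError(f"model expects {model.spec.input_channels} channels, "
                         f"dataset has {dataset.n_channels}")
    x_train, y_train = dataset.model_inputs("train")
    x_val, y_val = dataset.model_inputs("validation")
    if y_train.size == 0 or y_val.size == 0:
        raise ValueError("train and validation splits must be non-empty")
    x_train = _to_nchw(x_train)
    x_val = _to_nchw(x_val)

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.learning_rate, weight_decay=config.l2_weight)
    hist = []
    best_state = model.get_state()
    best_acc, best_epoch = -1.0, 0
    n = y_train.size
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = perm[i:i + config.batch_size]
            loss = model.loss_and_grad(x_train[idx], y_train[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, step {i // config.batch_size}")
            opt.step()
            losses.append(loss)
        val_probs = model.predict_proba_array(x_val)
        val_acc = float(np.mean(np.argmax(val_probs, axis=1) == y_val))
        hist.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_micro_acc": val_acc})
        if val_acc > best_acc:
            best_acc, best_epoch = val_acc, epoch
            best_state = model.get_state()
    model.set_state(best_state)
    return TrainedModel(net=model, spec=model.spec, config=config,
                        history=pd.DataFrame(hist), selected_epoch=best_epoch,
                        view=dataset.view)


def predict_proba(trained: TrainedModel | DenseNetClassifier,
                  patches: np.ndarray,
                  labels: np.ndarray | None = None,
                  class_names: Sequence[str] | None = None,
                  specimen_ids: np.ndarray | None = None,
                  scene_ids: np.ndarray | None = None,
                  coords: np.ndarray | None = None) -> PredictionBatch:
    """Apply the model to normalized patches (N, 32, 32, C), order preserved."""
    net = trained.net if isinstance(trained, TrainedModel) else trained
    if patches.ndim != 4 or patches.shape[-1] != net.spec.input_channels:
        raise ValueError(f"patches must be (N, H, W, {net.spec.input_channels})")
    probs = net.predict_proba_array(_to_nchw(patches))
    if labels is None:
        labels = np.full(patches.shape[0], -1, dtype=np.int64)
    if class_names is None:
        class_names = tuple(f"class{i}" for i in range(net.spec.n_classes))
    return PredictionBatch(probs=probs, labels=labels, class_names=tuple(class_names),
                           specimen_ids=specimen_ids, scene_ids=scene_ids, coords=coords)


def predict_split(trained: TrainedModel, dataset: PatchDataset,
                  split: str = "test") -> PredictionBatch:
    """Predict a whole dataset split with provenance carried through."""
    x, y = dataset.model_inputs(split)
    s = dataset.splits[split]
    return predict_proba(trained, x, labels=y, class_names=dataset.class_names,
                         specimen_ids=s.specimen_ids, scene_ids=s.scene_ids,
                         coords=s.coords)


def select_best(candidates: Sequence[TrainedModel]) -> TrainedModel:
    """The candidate with the highest validation micro-accuracy (ties: first)."""
    if len(candidates) == 0:
        raise ValueError("no candidate models")
    best = candidates[0]
    for c in candidates[1:]:
        if c.validation_accuracy > best.validation_accuracy:
            best = c
    return best


def save_checkpoint(trained: TrainedModel, path: str | Path) -> None:
    """Checkpoint: .npz of parameters + embedded spec/config/history JSON."""
    path = Path(path)
    meta = {
        "spec": asdict(trained.spec),
        "config": asdict(trained.config),
        "selected_epoch": trained.selected_epoch,
        "view": trained.view if isinstance(trained.view, str) else list(trained.view),
        "history": trained.history.to_dict(orient="list"),
    }
    state = trained.net.get_state()
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path) -> TrainedModel:
    z = np.load(path, allow_pickle=False)
    meta = json.loads(bytes(z["__meta__"]).decode())
    spec = ModelSpec(**meta["spec"])
    net = build_model(spec)
    net.set_state({k: z[k] for k in z.files if k != "__meta__"})
    view = meta["view"]
    return TrainedModel(net=net, spec=spec, config=TrainConfig(**meta["config"]),
                        history=pd.DataFrame(meta["history"]),
                        selected_epoch=meta["selected_epoch"],
                        view=view if isinstance(view, str) else tuple(view))
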