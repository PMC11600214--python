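"""Residual-CNN distance-matrix models for transition-state prediction.

The high-energy-state model maps the two endpoint sigmoid distance matrices
(stacked as a 2-channel L x L input) through an 8-block residual CNN
(64 channels, 3x3 kernels) and a per-position 64-cell head to a single
L x L matrix, which is symmetrized by averaging with its transpose.  The
pathway variant shares the backbone and adds two more heads so the three
anchor states along the pathway (pre-transition, transition, post-
transition) are predicted simultaneously; intermediate states are linear
interpolations through the anchors.

Training minimizes a weighted squared error that up-weights unique-contact
pairs 5:1 over all other pairs, with plain SGD at learning rate 0.001.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from ..featurize import CONTACT_THRESHOLD, ContactMasks, DistanceFeature
from .nn import Conv1x1, Conv3x3, Relu, ResidualBlock, Sequential

__all__ = [
    "HesConfig",
    "TrainingExample",
    "PathPrediction",
    "DistanceMatrixModel",
    "TrainResult",
    "predict_transition_state",
    "weighted_loss",
    "train",
    "evaluate_unique",
    "predict_pathway",
]

_D_MAX = 1.0 - 1.0 / (1.0 + np.e)


@dataclass(frozen=True)
class HesConfig:
    """Architecture and optimization settings."""

    n_res_blocks: int = 8
    channels: int = 64
    kernel: int = 3
    head_cells: int = 64
    learning_rate: float = 0.001
    unique_weight: float = 5.0
    seed: int = 0
    mode: str = "hes"             # "hes" (1 head) or "path" (3 heads)
    n_steps: int = 2000           # SGD steps (one example per step)
    max_grad_norm: float = 1.0    # global gradient-norm clip
    momentum: float = 0.9         # SGD momentum
    val_every: int = 100
    target_train_loss: float | None = None   # optional early stop

    def __post_init__(self):
        if min(self.n_res_blocks, self.channels, self.head_cells) <= 0:
            raise ValueError("architecture sizes must be positive")
        if self.kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        if self.kernel != 3:
            raise NotImplementedError("only 3x3 kernels are implemented")
        if self.mode not in ("hes", "path"):
            raise ValueError("mode must be 'hes' or 'path'")

    @property
    def n_heads(self) -> int:
        return 1 if self.mode == "hes" else 3


@dataclass(frozen=True)
class TrainingExample:
    """Input features, target(s) and masks for one protein."""

    da: DistanceFeature
    db: DistanceFeature
    target_ts: DistanceFeature
    masks: ContactMasks
    targets_s2_s4: tuple | None = None     # (pre, post) anchors, optional

    def __post_init__(self):
        L = self.da.n
        if self.db.n != L or self.target_ts.n != L:
            raise ValueError("all matrices must share the same size")

    @property
    def n(self) -> int:
        return self.da.n

    def input_tensor(self) -> np.ndarray:
        return np.stack([self.da.D, self.db.D]).astype(np.float32)

    def targets(self, mode: str):
        if mode == "hes":
            return [self.target_ts.D]
        if self.targets_s2_s4 is None:
            raise ValueError("path mode requires targets_s2_s4")
        s2, s4 = self.targets_s2_s4
        return [s2.D, self.target_ts.D, s4.D]


@dataclass(frozen=True)
class PathPrediction:
    """Predicted anchors plus the interpolated pathway series."""

    anchors: tuple                 # (s2, s3, s4) DistanceFeatures
    interpolated: tuple            # DistanceFeatures from state A to B


class DistanceMatrixModel:
    """Residual CNN over 2-channel distance features; 1 or 3 output heads."""

    def __init__(self, config: HesConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.channels
        self.trunk = Sequential(
            Conv3x3(2, c, rng),
            *[ResidualBlock(c, rng) for _ in range(config.n_res_blocks)],
        )
        self.heads = [
            Sequential(Conv1x1(c, config.head_cells, rng), Relu(),
                       Conv1x1(config.head_cells, 1, rng, std=0.01))
            for _ in range(config.n_heads)
        ]
        self.trained = False

    # ---- forward ------------------------------------------------------
    def forward(self, da, db):
        """Symmetric raw head outputs (list of L x L float32 arrays)."""
        Da = da.D if isinstance(da, DistanceFeature) else np.asarray(da)
        Db = db.D if isinstance(db, DistanceFeature) else np.asarray(db)
        if Da.shape != Db.shape:
            raise ValueError("the two feature matrices must share a shape")
        if Da.shape[0] < self.config.kernel:
            raise ValueError("input smaller than the kernel size")
        x = np.stack([Da, Db]).astype(np.float32)
        # the network predicts the deviation from the endpoint average:
        # common contacts barely change along the pathway, so the mean of
        # the two endpoint matrices is the natural baseline
        baseline = 0.5 * (x[0] + x[1])
        h = self.trunk.forward(x)
        outs = []
        for head in self.heads:
            y = head.forward(h)[0]
            outs.append(baseline + 0.5 * (y + y.T))
        return outs

    def _backward(self, dheads):
        dtrunk = None
        for head, dy in zip(self.heads, dheads):
            if dy is None:
                continue
            g = head.backward(dy[None].astype(np.float32))
            dtrunk = g if dtrunk is None else dtrunk + g
        if dtrunk is not None:
            self.trunk.backward(dtrunk)

    def predict(self, da, db):
        """Clamped predictions in [0, D_max]; list of L x L arrays."""
        if not self.trained:
            import warnings
            warnings.warn("predicting with an untrained model")
        return [np.clip(o, 0.0, _D_MAX).astype(float)
                for o in self.forward(da, db)]

    # ---- parameters ---------------------------------------------------
    def _layers(self):
        out = [*self.trunk.layers]
        for head in self.heads:
            out.extend(head.layers)
        return out

    def state(self):
        return [getattr(owner, name).copy()
                for layer in self._layers()
                for owner, name, _ in layer.params()]

    def load_state(self, st):
        k = 0
        for layer in self._layers():
            for owner, name, _ in layer.params():
                getattr(owner, name)[...] = st[k]
                k += 1

    def grad_norm(self) -> float:
        sq = 0.0
        for layer in self._layers():
            for owner, _, gname in layer.params():
                sq += float(np.sum(getattr(owner, gname) ** 2))
        return float(np.sqrt(sq))

    def sgd_step(self, lr: float, max_grad_norm: float | None = None,
                 momentum: float = 0.0):
        scale = 1.0
        if max_grad_norm is not None:
            gn = self.grad_norm()
            if gn > max_grad_norm:
                scale = max_grad_norm / gn
        if momentum > 0.0 and not hasattr(self, "_velocity"):
            self._velocity = [np.zeros_like(getattr(owner, name))
                              for layer in self._layers()
                              for owner, name, _ in layer.params()]
        k = 0
        for layer in self._layers():
            for owner, name, gname in layer.params():
                g = scale * getattr(owner, gname)
                if momentum > 0.0:
                    v = self._velocity[k]
                    v *= momentum
                    v += g
                    g = v
                getattr(owner, name)[...] -= lr * g
                k += 1

    # ---- persistence --------------------------------------------------
    def save(self, path):
        arrays = {f"p{k}": a for k, a in enumerate(self.state())}
        cfg = json.dumps(self.config.__dict__)
        np.savez(path, _config=np.frombuffer(cfg.encode(), dtype=np.uint8),
                 _trained=np.array([self.trained]), **arrays)

    @classmethod
    def load(cls, path) -> "DistanceMatrixModel":
        data = np.load(path)
        cfg = json.loads(bytes(data["_config"]).decode())
        model = cls(HesConfig(**cfg))
        n = len([k for k in data.files if k.startswith("p")])
        model.load_state([data[f"p{k}"] for k in range(n)])
        model.trained = bool(data["_trained"][0])
        return model


def predict_transition_state(model: DistanceMatrixModel, da, db) -> np.ndarray:
    """Transition-state prediction (first head), clamped and symmetric."""
    return model.predict(da, db)[0]


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def weighted_loss(pred: np.ndarray, target: np.ndarray,
                  masks: ContactMasks, unique_weight: float = 5.0) -> float:
    """Weighted squared error: unique-contact pairs count 5:1.

    L = w * sum_unique (pred - target)^2 + sum_non_unique (pred - target)^2,
    summed over all matrix entries.
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError("prediction/target shape mismatch")
    err2 = (pred - target) ** 2
    return float(unique_weight * err2[masks.unique].sum()
                 + err2[masks.non_unique].sum())


def _loss_weights(masks: ContactMasks, unique_weight: float) -> np.ndarray:
    return np.where(masks.unique, unique_weight, 1.0).astype(np.float32)


def _mean_loss_and_grad(pred, target, weights):
    """Weight-normalized mean loss; gradient of the weighted *sum*.

    The reported loss is the weighted mean (comparable across matrix
    sizes); the training gradient is that of the raw weighted sum, whose
    scale is tamed by the global gradient-norm clip.
    """
    diff = pred - target
    loss = float((weights * diff * diff).sum() / weights.sum())
    grad = 2.0 * weights * diff
    return loss, grad


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    model: DistanceMatrixModel
    history: list                  # rows: (step, train_loss, val_loss)
    best_val_loss: float
    train_indices: np.ndarray = field(default_factory=lambda: np.zeros(0))
    val_indices: np.ndarray = field(default_factory=lambda: np.zeros(0))


def _epoch_loss(model, examples):
    cfg = model.config
    total = 0.0
    for ex in examples:
        preds = model.forward(ex.da, ex.db)
        for pred, target in zip(preds, ex.targets(cfg.mode)):
            w = _loss_weights(ex.masks, cfg.unique_weight)
            loss, _ = _mean_loss_and_grad(pred, target.astype(np.float32), w)
            total += loss
    return total / max(len(examples), 1)


def train(corpus, config: HesConfig, split=(0.9, 0.1)) -> TrainResult:
    """Train with plain SGD (one example per step, shuffled epochs).

    ``split`` is either a (train, validation) fraction pair — resolved with
    the config seed — or a pair of explicit index arrays.  The returned
    model carries the best-validation checkpoint.  Training loss reported
    in the history is the weight-normalized mean over the most recent
    window; validation loss is the full-validation mean.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("empty corpus")
    targets_flat = np.concatenate(
        [t.ravel() for ex in corpus for t in ex.targets(config.mode)])
    if np.allclose(targets_flat, targets_flat[0]):
        import warnings
        warnings.warn("degenerate corpus: all target entries identical")

    rng = np.random.default_rng(config.seed)
    if isinstance(split, tuple) and len(split) == 2 \
            and np.isscalar(split[0]) and 0 < split[0] <= 1:
        idx = rng.permutation(len(corpus))
        n_train = max(int(round(split[0] * len(corpus))), 1)
        train_idx, val_idx = idx[:n_train], idx[n_train:]
    else:
        train_idx = np.asarray(split[0], dtype=int)
        val_idx = np.asarray(split[1], dtype=int)
    train_set = [corpus[i] for i in train_idx]
    val_set = [corpus[i] for i in val_idx]

    model = DistanceMatrixModel(config)
    weights = [_loss_weights(ex.masks, config.unique_weight)
               for ex in train_set]
    targets = [[t.astype(np.float32) for t in ex.targets(config.mode)]
               for ex in train_set]

    history = []
    best_val = np.inf
    best_state = model.state()
    window: list[float] = []
    order = rng.permutation(len(train_set))
    pos = 0

    for step in range(1, config.n_steps + 1):
        if pos >= len(order):
            order = rng.permutation(len(train_set))
            pos = 0
        k = order[pos]
        pos += 1
        ex = train_set[k]

        preds = model.forward(ex.da, ex.db)
        grads = []
        loss_ex = 0.0
        for pred, target in zip(preds, targets[k]):
            loss, grad = _mean_loss_and_grad(pred, target, weights[k])
            loss_ex += loss
            grads.append(grad)
        model._backward(grads)
        model.sgd_step(config.learning_rate, config.max_grad_norm,
                       config.momentum)

        window.append(loss_ex)
        if len(window) > max(len(train_set), 20):
            window.pop(0)

        if step % config.val_every == 0 or step == config.n_steps:
            train_loss = float(np.mean(window))
            val_loss = (_epoch_loss(model, val_set) if val_set
                        else float("nan"))
            history.append((step, train_loss, val_loss))
            if val_set and val_loss < best_val:
                best_val = val_loss
                best_state = model.state()
            if (config.target_train_loss is not None
                    and train_loss < config.target_train_loss):
                break

    if val_set:
        model.load_state(best_state)
    else:
        best_val = float(np.mean(window))
    model.trained = True
    return TrainResult(model=model, history=history, best_val_loss=best_val,
                       train_indices=train_idx, val_indices=val_idx)


# ---------------------------------------------------------------------------
# evaluation / pathway prediction
# ---------------------------------------------------------------------------

def evaluate_unique(pred: np.ndarray, sim_target: np.ndarray,
                    masks: ContactMasks):
    """Pearson r and MAE restricted to unique-contact pairs (upper triangle)."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(sim_target, dtype=float)
    sel = np.triu(masks.unique, k=1)
    p = pred[sel]
    t = target[sel]
    if p.size < 2:
        raise ValueError("need at least 2 unique pairs to evaluate")
    r = float(stats.pearsonr(p, t).statistic)
    mae = float(np.mean(np.abs(p - t)))
    return r, mae


def predict_pathway(model: DistanceMatrixModel, da: DistanceFeature,
                    db: DistanceFeature, n_points: int = 5) -> PathPrediction:
    """Predict the three pathway anchors and interpolate a full series.

    The series runs from state A's feature through the anchors (s2, s3, s4
    at pathway fractions 1/4, 1/2, 3/4) to state B's feature, resampled to
    ``n_points`` by elementwise linear interpolation.
    """
    if model.config.mode != "path":
        raise ValueError("pathway prediction needs a model in 'path' mode")
    if n_points < 5:
        raise ValueError("n_points must be >= 5")
    s2, s3, s4 = model.predict(da, db)
    knots = np.stack([da.D, s2, s3, s4, db.D])
    t_knots = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    t_out = np.linspace(0.0, 1.0, n_points)
    seg = np.clip(np.searchsorted(t_knots, t_out, side="right") - 1, 0, 3)
    frac = (t_out - t_knots[seg]) / 0.25
    series = ((1 - frac)[:, None, None] * knots[seg]
              + frac[:, None, None] * knots[seg + 1])
    feats = tuple(
        DistanceFeature(D=0.5 * (m + m.T), source="predicted")
        for m in series
    )
    anchors = tuple(DistanceFeature(D=m, source="predicted")
                    for m in (s2, s3, s4))
    return PathPrediction(anchors=anchors, interpolated=feats)
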