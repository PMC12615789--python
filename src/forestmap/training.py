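"""Loss, augmentation, block-wise splitting, and ensemble training.

Training minimizes a masked cross-entropy (pixels labelled unknown carry no
gradient) with Adam, a linear warmup over the first 10% of steps followed
by cosine decay to zero, and clipping of the global gradient norm at 1.0.
An ensemble is a set of members differing only in their initialization
seed; prediction averages their softmax outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, masked_cross_entropy_node
from .model import Model, ModelConfig
from .types import SceneSample

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization schedule.

    Full-scale values: batch 512, 10 epochs on hundreds of thousands of
    scenes; the desk default keeps the same schedule shape at batch 8.
    """

    lr: float = 1e-3
    weight_decay: float = 3e-5
    epochs: int = 10
    batch_size: int = 8          # full-scale: 512
    warmup_fraction: float = 0.10
    grad_clip: float = 1.0
    ensemble_size: int = 5
    seed: int = 0
    adam_beta1: float = 0.9      # library-default moments, pinned
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def validate(self) -> None:
        if min(self.lr, self.weight_decay, self.epochs, self.batch_size, self.grad_clip,
               self.ensemble_size) <= 0:
            raise ValueError("all TrainConfig magnitudes must be positive")
        if not 0.0 <= self.warmup_fraction < 1.0:
            raise ValueError("warmup fraction must lie in [0, 1)")


# ---------------------------------------------------------------------------
# loss

def masked_cross_entropy(logits: Tensor | np.ndarray, labels: np.ndarray) -> Tensor:
    """Mean negative log-softmax over pixels with label != 0.

    ``logits`` is (..., H, W, C); ``labels`` (..., H, W) with values 0..C,
    class k > 0 mapping to logit index k - 1. Returns 0 (with zero
    gradient) when every pixel is unknown.
    """
    if not isinstance(logits, Tensor):
        logits = Tensor(logits)
    n_classes = logits.shape[-1]
    flat = logits.reshape(-1, n_classes)
    idx = labels.reshape(-1).astype(np.int64) - 1  # unknown -> -1, ignored
    if (idx >= n_classes).any():
        raise ValueError("labels exceed the number of classes")
    if (idx < 0).all():
        log.warning("degenerate batch: every pixel is labelled unknown")
    return masked_cross_entropy_node(flat, idx)


# ---------------------------------------------------------------------------
# augmentation

def augment(sample: SceneSample, seed: int) -> SceneSample:
    """Random right-angle rotation plus independent horizontal/vertical flips.

    The same draw is applied to every modality, every time step, and the
    label raster; the location vector is unchanged. Aspect values are moved
    geometrically but their angular meaning is not recomputed.
    """
    rng = np.random.default_rng(seed)
    k = int(rng.integers(4))
    flip_h = bool(rng.integers(2))
    flip_v = bool(rng.integers(2))

    def tf(arr: np.ndarray, row_axis: int) -> np.ndarray:
        axes = (row_axis, row_axis + 1)
        out = np.rot90(arr, k, axes=axes)
        if flip_h:
            out = np.flip(out, axis=row_axis + 1)
        if flip_v:
            out = np.flip(out, axis=row_axis)
        return np.ascontiguousarray(out)

    return SceneSample(
        s2=tf(sample.s2, 1),
        topo=tf(sample.topo, 1),
        loc=sample.loc,
        labels=tf(sample.labels, 0),
        transform=sample.transform,
        crs=sample.crs,
    )


# ---------------------------------------------------------------------------
# block-wise split

def split_blocks(
    locations: np.ndarray,
    test_fraction: float = 0.10,
    block_size: float = 100_000.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Split scene indices at the granularity of square map-coordinate blocks.

    ``locations`` is (n, 2) scene-centre map coordinates (m); each scene
    belongs to exactly one ``block_size``-sided block and no block ever
    contributes to both sides of the split.
    """
    locations = np.asarray(locations, float)
    blocks = np.floor_divide(locations, block_size).astype(np.int64)
    keys = blocks[:, 0] * 2**31 + blocks[:, 1]
    unique = np.unique(keys)
    if unique.size < 2:
        raise ValueError("need at least 2 distinct blocks to split")
    rng = np.random.default_rng(seed)
    n_test = max(1, int(round(test_fraction * unique.size)))
    test_blocks = set(rng.choice(unique, size=n_test, replace=False).tolist())
    is_test = np.array([k in test_blocks for k in keys])
    return np.flatnonzero(~is_test), np.flatnonzero(is_test)


# ---------------------------------------------------------------------------
# schedule and optimizer

def learning_rate(step: int, total_steps: int, cfg: TrainConfig) -> float:
    """Linear warmup to ``cfg.lr`` then cosine decay to 0 at the last step."""
    warmup = max(1, int(round(cfg.warmup_fraction * total_steps)))
    if step < warmup:
        return cfg.lr * step / warmup
    T = max(1, total_steps - 1 - warmup)
    return cfg.lr * 0.5 * (1.0 + np.cos(np.pi * min(step - warmup, T) / T))


class Adam:
    def __init__(self, params: dict[str, Tensor], cfg: TrainConfig):
        self.params = params
        self.cfg = cfg
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self, lr: float) -> float:
        """Clip the global gradient norm, apply one update; returns the norm."""
        cfg = self.cfg
        grads = {k: p.grad for k, p in self.params.items() if p.grad is not None}
        gnorm = float(np.sqrt(sum(float((g * g).sum()) for g in grads.values())))
        scale = cfg.grad_clip / gnorm if gnorm > cfg.grad_clip else 1.0
        self.t += 1
        b1, b2 = cfg.adam_beta1, cfg.adam_beta2
        for k, g in grads.items():
            g = g * scale + cfg.weight_decay * self.params[k].data
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            self.params[k].data -= lr * mhat / (np.sqrt(vhat) + cfg.adam_eps)
        return gnorm

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


# ---------------------------------------------------------------------------
# fitting

def compute_norm_stats(scenes: list[SceneSample]) -> dict[str, np.ndarray]:
    """Per-band mean/std over the training split, for input standardization."""
    s2 = np.stack([s.s2 for s in scenes])
    topo = np.stack([s.topo for s in scenes])
    return {
        "s2_mean": s2.mean(axis=(0, 1, 2, 3)).astype(np.float32),
        "s2_std": (s2.std(axis=(0, 1, 2, 3)) + 1e-6).astype(np.float32),
        "topo_mean": topo.mean(axis=(0, 1, 2, 3)).astype(np.float32),
        "topo_std": (topo.std(axis=(0, 1, 2, 3)) + 1e-6).astype(np.float32),
    }


def _train_member(
    scenes: list[SceneSample],
    cfg: TrainConfig,
    model_cfg: ModelConfig,
    member_seed: int,
    norm: dict[str, np.ndarray],
    loss_log: list[float],
) -> Model:
    model = Model(model_cfg, seed=member_seed)
    model.norm = dict(norm)
    opt = Adam(model.params, cfg)
    rng = np.random.default_rng(member_seed + 1)
    n = len(scenes)
    steps_per_epoch = max(1, n // cfg.batch_size)
    total_steps = cfg.epochs * steps_per_epoch
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for b in range(steps_per_epoch):
            batch_ids = order[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            batch = [
                augment(scenes[i], seed=int(rng.integers(2**31))) for i in batch_ids
            ]
            s2 = np.stack([s.s2 for s in batch])
            topo = np.stack([s.topo for s in batch])
            loc = np.stack([s.loc for s in batch])
            labels = np.stack([s.labels for s in batch])
            logits = model.forward_batch(s2, topo, loc)
            loss = masked_cross_entropy(logits, labels)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at step {step} (epoch {epoch}); aborting"
                )
            opt.zero_grad()
            loss.backward()
            opt.step(learning_rate(step, total_steps, cfg))
            loss_log.append(float(loss.data))
            step += 1
    return model


def fit(
    scenes: list[SceneSample],
    cfg: TrainConfig | None = None,
    model_cfg: ModelConfig | None = None,
    loss_log: list[float] | None = None,
) -> list[Model]:
    """Train an ensemble of independently initialized members.

    Members share the training data, schedule and normalization statistics
    and differ only in their initialization/shuffling seed (derived from
    ``cfg.seed``). Per-step losses are appended to ``loss_log`` if given.
    """
    cfg = cfg or TrainConfig()
    cfg.validate()
    model_cfg = model_cfg or ModelConfig()
    if not scenes:
        raise ValueError("at least one training scene is required")
    norm = compute_norm_stats(scenes)
    members = []
    for member in range(cfg.ensemble_size):
        members.append(
            _train_member(
                scenes, cfg, model_cfg, cfg.seed + 1000 * member, norm,
                loss_log if loss_log is not None else [],
            )
        )
    return members


# ---------------------------------------------------------------------------
# desk-scale preset: one CPU, minutes not TPU-hours. 32-px scenes keep the
# patch grid at 8x8 patches per scene (patch 4), the embedding shrinks to 48
# with the MLP width held at 4x the embedding, and three ensemble members
# stand in for the full-scale five.

def desk_model_config(image_size: int = 32) -> ModelConfig:
    return ModelConfig(
        image_size=image_size, spatial_patch=4, embed_dim=48, heads=4, mlp_dim=192
    )


def desk_train_config(seed: int = 0, epochs: int = 80, ensemble_size: int = 3) -> TrainConfig:
    return TrainConfig(epochs=epochs, batch_size=8, ensemble_size=ensemble_size, seed=seed)


def pixel_accuracy(models: list[Model], scenes: list[SceneSample]) -> float:
    """Overall accuracy of the ensemble argmax over labelled (non-unknown) pixels."""
    from .model import ensemble_predict

    correct = total = 0
    for scene in scenes:
        probs = ensemble_predict(models, scene)
        pred = probs.argmax(axis=-1) + 1
        mask = scene.labels > 0
        correct += int((pred[mask] == scene.labels[mask]).sum())
        total += int(mask.sum())
    return correct / total if total else float("nan")
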