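"""Multi-modal temporal-spatial vision transformer for land-cover segmentation.

The network tokenizes each seasonal spectral composite and the topography
raster into 8x8-pixel patches, runs a shared spatial encoder over the patch
sequence of every (modality, time step), a shared temporal encoder over the
time axis of every (modality, spatial token), mean-pools the temporal axis,
fuses both modalities plus a projected location token in a self-attention
decoder, and maps each decoded spatial token back to per-pixel class logits
through an MLP head.

Weights live in a flat name -> Tensor dict so the Adam trainer and the
checkpoint format stay trivial.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import Tensor, concat, gelu as _gelu_node, layernorm as _layernorm_node
from .autodiff import softmax as softmax_t
from .types import N_CLASSES, SceneSample


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are the full-scale configuration (192-dim embeddings, 6 heads,
    encoder depths 2/2, decoder depth 4, MLP width 768, 8x8 spatial patches,
    temporal patch 1); tests and desk-scale runs shrink ``image_size`` and
    ``embed_dim``.
    """

    image_size: int = 128
    spatial_patch: int = 8
    temporal_patch: int = 1
    embed_dim: int = 192
    heads: int = 6
    spatial_depth: int = 2
    temporal_depth: int = 2
    decoder_depth: int = 4
    mlp_dim: int = 768
    n_classes: int = N_CLASSES
    s2_bands: int = 10
    topo_bands: int = 3
    n_seasons: int = 4
    use_location: bool = True

    def __post_init__(self) -> None:
        if self.image_size % self.spatial_patch:
            raise ValueError("image_size must be divisible by spatial_patch")
        if self.embed_dim % self.heads:
            raise ValueError("embed_dim must be divisible by heads")

    @property
    def n_tokens(self) -> int:
        side = self.image_size // self.spatial_patch
        return side * side


def patchify(image: np.ndarray, patch: int) -> np.ndarray:
    """Split (rows, cols, bands) into row-major patch tokens.

    Returns (n_tokens, patch*patch*bands) with
    n_tokens = (rows/patch) * (cols/patch).
    """
    rows, cols, bands = image.shape
    if rows % patch or cols % patch:
        raise ValueError(f"image shape {image.shape} not divisible by patch {patch}")
    gr, gc = rows // patch, cols // patch
    x = image.reshape(gr, patch, gc, patch, bands)
    return x.transpose(0, 2, 1, 3, 4).reshape(gr * gc, patch * patch * bands)


def unpatchify(tokens: np.ndarray, patch: int, rows: int, cols: int) -> np.ndarray:
    """Inverse of :func:`patchify`; exact reconstruction."""
    gr, gc = rows // patch, cols // patch
    bands = tokens.shape[1] // (patch * patch)
    x = tokens.reshape(gr, gc, patch, patch, bands)
    return x.transpose(0, 2, 1, 3, 4).reshape(rows, cols, bands)


def _patchify_batch(x: np.ndarray, patch: int) -> np.ndarray:
    """(B, T, H, W, C) -> (B, T, N, patch*patch*C), row-major patches."""
    b, t, h, w, c = x.shape
    gr, gc = h // patch, w // patch
    y = x.reshape(b, t, gr, patch, gc, patch, c)
    return y.transpose(0, 1, 2, 4, 3, 5, 6).reshape(b, t, gr * gc, patch * patch * c)


def _gelu(x: Tensor) -> Tensor:
    return _gelu_node(x)


class Model:
    """A transformer with parameters in ``self.params`` (name -> Tensor)."""

    _LN_EPS = 1e-5

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.params: dict[str, Tensor] = {}
        # per-band normalization statistics, set from the training split
        self.norm: dict[str, np.ndarray] = {
            "s2_mean": np.zeros(config.s2_bands, np.float32),
            "s2_std": np.ones(config.s2_bands, np.float32),
            "topo_mean": np.zeros(config.topo_bands, np.float32),
            "topo_std": np.ones(config.topo_bands, np.float32),
        }
        self._init_params(np.random.default_rng(seed))

    # -- parameter construction -------------------------------------------

    def _param(self, name: str, shape: tuple[int, ...], rng, std: float = 0.02) -> None:
        if std == 0.0:
            data = np.zeros(shape, np.float32)
        elif std == -1.0:  # layer-norm gain
            data = np.ones(shape, np.float32)
        else:
            data = rng.normal(0.0, std, size=shape).astype(np.float32)
        self.params[name] = Tensor(data, requires_grad=True)

    def _init_block(self, prefix: str, rng) -> None:
        d, m = self.config.embed_dim, self.config.mlp_dim
        self._param(f"{prefix}/ln1/g", (d,), rng, std=-1.0)
        self._param(f"{prefix}/ln1/b", (d,), rng, std=0.0)
        for nm in ("Wq", "Wk", "Wv", "Wo"):
            self._param(f"{prefix}/attn/{nm}", (d, d), rng)
        for nm in ("bq", "bk", "bv", "bo"):
            self._param(f"{prefix}/attn/{nm}", (d,), rng, std=0.0)
        self._param(f"{prefix}/ln2/g", (d,), rng, std=-1.0)
        self._param(f"{prefix}/ln2/b", (d,), rng, std=0.0)
        self._param(f"{prefix}/mlp/W1", (d, m), rng)
        self._param(f"{prefix}/mlp/b1", (m,), rng, std=0.0)
        self._param(f"{prefix}/mlp/W2", (m, d), rng)
        self._param(f"{prefix}/mlp/b2", (d,), rng, std=0.0)

    def _init_params(self, rng) -> None:
        c = self.config
        p2 = c.spatial_patch * c.spatial_patch
        d = c.embed_dim
        self._param("embed/s2/W", (p2 * c.s2_bands, d), rng)
        self._param("embed/s2/b", (d,), rng, std=0.0)
        self._param("embed/topo/W", (p2 * c.topo_bands, d), rng)
        self._param("embed/topo/b", (d,), rng, std=0.0)
        self._param("pos", (c.n_tokens, d), rng)
        self._param("temb", (c.n_seasons, d), rng)
        if c.use_location:
            self._param("loc/W", (3, d), rng)
            self._param("loc/b", (d,), rng, std=0.0)
        for i in range(c.spatial_depth):
            self._init_block(f"spatial/{i}", rng)
        for i in range(c.temporal_depth):
            self._init_block(f"temporal/{i}", rng)
        for i in range(c.decoder_depth):
            self._init_block(f"decoder/{i}", rng)
        self._param("head/ln/g", (d,), rng, std=-1.0)
        self._param("head/ln/b", (d,), rng, std=0.0)
        self._param("head/W1", (d, c.mlp_dim), rng)
        self._param("head/b1", (c.mlp_dim,), rng, std=0.0)
        self._param("head/W2", (c.mlp_dim, p2 * c.n_classes), rng)
        self._param("head/b2", (p2 * c.n_classes,), rng, std=0.0)

    @property
    def n_params(self) -> int:
        return sum(int(t.data.size) for t in self.params.values())

    # -- layers ------------------------------------------------------------

    def _layernorm(self, x: Tensor, prefix: str) -> Tensor:
        return _layernorm_node(
            x, self.params[f"{prefix}/g"], self.params[f"{prefix}/b"], self._LN_EPS
        )

    def _attention(self, x: Tensor, prefix: str) -> Tensor:
        c = self.config
        m, t, d = x.shape
        dh = d // c.heads
        p = self.params

        def heads_of(w: str, b: str) -> Tensor:
            y = x @ p[f"{prefix}/{w}"] + p[f"{prefix}/{b}"]
            return y.reshape(m, t, c.heads, dh).transpose((0, 2, 1, 3))

        q = heads_of("Wq", "bq")
        k = heads_of("Wk", "bk")
        v = heads_of("Wv", "bv")
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(dh))
        att = softmax_t(scores, axis=-1)
        out = (att @ v).transpose((0, 2, 1, 3)).reshape(m, t, d)
        return out @ p[f"{prefix}/Wo"] + p[f"{prefix}/bo"]

    def _block(self, x: Tensor, prefix: str) -> Tensor:
        x = x + self._attention(self._layernorm(x, f"{prefix}/ln1"), f"{prefix}/attn")
        h = self._layernorm(x, f"{prefix}/ln2")
        h = _gelu(h @ self.params[f"{prefix}/mlp/W1"] + self.params[f"{prefix}/mlp/b1"])
        return x + h @ self.params[f"{prefix}/mlp/W2"] + self.params[f"{prefix}/mlp/b2"]

    def _encode(self, x: Tensor, stage: str, depth: int) -> Tensor:
        for i in range(depth):
            x = self._block(x, f"{stage}/{i}")
        return x

    # -- forward -----------------------------------------------------------

    def _validate_inputs(self, s2: np.ndarray, topo: np.ndarray, loc: np.ndarray) -> None:
        c = self.config
        b = s2.shape[0]
        if s2.shape != (b, c.n_seasons, c.image_size, c.image_size, c.s2_bands):
            raise ValueError(f"s2 shape {s2.shape} does not match config")
        if topo.shape != (b, 1, c.image_size, c.image_size, c.topo_bands):
            raise ValueError(f"topo shape {topo.shape} does not match config")
        if loc.shape != (b, 3):
            raise ValueError(f"loc shape {loc.shape} does not match config")
        for name, arr in (("s2", s2), ("topo", topo), ("loc", loc)):
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite values in {name} input")

    def forward_batch(self, s2: np.ndarray, topo: np.ndarray, loc: np.ndarray) -> Tensor:
        """Per-pixel logits (B, H, W, n_classes) for a batch of scenes."""
        self._validate_inputs(s2, topo, loc)
        c = self.config
        p = self.params
        b, nt, n = s2.shape[0], c.n_seasons, c.n_tokens

        s2n = (s2 - self.norm["s2_mean"]) / self.norm["s2_std"]
        topon = (topo - self.norm["topo_mean"]) / self.norm["topo_std"]

        tok_s2 = Tensor(_patchify_batch(s2n.astype(np.float32), c.spatial_patch))
        tok_topo = Tensor(_patchify_batch(topon.astype(np.float32), c.spatial_patch))
        e_s2 = tok_s2 @ p["embed/s2/W"] + p["embed/s2/b"]          # (B,4,N,D)
        e_topo = tok_topo @ p["embed/topo/W"] + p["embed/topo/b"]  # (B,1,N,D)
        e_s2 = e_s2 + p["pos"] + p["temb"].reshape(1, nt, 1, c.embed_dim)
        e_topo = e_topo + p["pos"] + p["temb"][0:1].reshape(1, 1, 1, c.embed_dim)

        # shared spatial encoder over every (modality, time) patch sequence
        x = concat(
            [e_s2.reshape(b * nt, n, c.embed_dim), e_topo.reshape(b, n, c.embed_dim)],
            axis=0,
        )
        x = self._encode(x, "spatial", c.spatial_depth)
        x_s2 = x[: b * nt].reshape(b, nt, n, c.embed_dim)
        x_topo = x[b * nt :].reshape(b, 1, n, c.embed_dim)

        # shared temporal encoder over the time axis of every spatial token
        t_s2 = x_s2.transpose((0, 2, 1, 3)).reshape(b * n, nt, c.embed_dim)
        t_s2 = self._encode(t_s2, "temporal", c.temporal_depth)
        z_s2 = t_s2.reshape(b, n, nt, c.embed_dim).mean(axis=2)
        t_topo = x_topo.transpose((0, 2, 1, 3)).reshape(b * n, 1, c.embed_dim)
        t_topo = self._encode(t_topo, "temporal", c.temporal_depth)
        z_topo = t_topo.reshape(b, n, c.embed_dim)

        # multi-modal decoder over fused token set (+ one location token)
        parts = [z_s2, z_topo]
        if c.use_location:
            loc_tok = Tensor(loc.astype(np.float32)) @ p["loc/W"] + p["loc/b"]
            parts.append(loc_tok.reshape(b, 1, c.embed_dim))
        x = concat(parts, axis=1)
        x = self._encode(x, "decoder", c.decoder_depth)
        dec = x[:, :n]

        h = self._layernorm(dec, "head/ln")
        h = _gelu(h @ p["head/W1"] + p["head/b1"])
        out = h @ p["head/W2"] + p["head/b2"]  # (B, N, p^2 * K)

        gr = c.image_size // c.spatial_patch
        out = out.reshape(b, gr, gr, c.spatial_patch, c.spatial_patch, c.n_classes)
        out = out.transpose((0, 1, 3, 2, 4, 5))
        return out.reshape(b, c.image_size, c.image_size, c.n_classes)

    def forward(self, sample: SceneSample) -> np.ndarray:
        """Logits (H, W, n_classes) for one scene; never consumes labels."""
        out = self.forward_batch(
            sample.s2[None], sample.topo[None], sample.loc[None].astype(np.float32)
        )
        return out.data[0]

    def predict_proba(self, sample: SceneSample) -> np.ndarray:
        """Per-pixel softmax probabilities (H, W, n_classes)."""
        logits = self.forward(sample)
        z = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint: one archive embedding config, norm stats and weights."""
        arrays = {f"param:{k}": v.data for k, v in self.params.items()}
        arrays.update({f"norm:{k}": v for k, v in self.norm.items()})
        meta = json.dumps(asdict(self.config))
        np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "Model":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__config__"]).decode())
            model = cls(ModelConfig(**meta), seed=0)
            for k in z.files:
                if k.startswith("param:"):
                    model.params[k[6:]] = Tensor(z[k], requires_grad=True)
                elif k.startswith("norm:"):
                    model.norm[k[5:]] = z[k]
        return model


def ensemble_predict(models: list[Model], sample: SceneSample) -> np.ndarray:
    """Arithmetic mean of per-member softmax outputs, (H, W, n_classes).

    The mean is taken over probabilities, not logits, so a single sharp
    member cannot dominate the ensemble the way it would under logit
    averaging.
    """
    if not models:
        raise ValueError("ensemble requires at least one model")
    cfg0 = models[0].config
    for m in models[1:]:
        if m.config != cfg0:
            raise ValueError("ensemble members must share an identical config")
    probs = [m.predict_proba(sample) for m in models]
    return np.mean(probs, axis=0)
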