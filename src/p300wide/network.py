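"""The wide-and-deep P300 network.

Two branches share a single bias and a sigmoid head:

* **wide (memorizing) branch** — a logistic-regression logit ``w . x`` over
  the assembled input ``x = [flattened 30x90 epoch, one-hot participant
  features, cross products]``;
* **deep (generalizing) branch** — the one-hot participant vector is embedded
  into a 90-sample row, stacked under the 30 EEG channels to form a 31x90
  tensor, and passed through three 1-D convolutions along time (kernel 7,
  LeakyReLU) applied identically to each of the 31 rows; the flattened
  activations feed a dense unit.

Combined prediction: ``P(y=1|x) = sigmoid(wide_logit + deep_logit + b)``.

Convolution geometry is defined by the feature-map time widths 42, 18 and 13
(strides 2, 2, 1 with a single left zero-pad on the third layer), which makes
the flattened activation length 31*13*16 = 6448.

Everything here is plain numpy with hand-written backprop: the FTRL trainer
needs per-coordinate gradient access, and at ~16k parameters an autodiff
framework would be overkill.
"""

from __future__ import annotations

import io as _stdio
import json
import zipfile
from dataclasses import dataclass, field

import numpy as np

from .features import (
    CrossSpec,
    SparseFeatureSpec,
    assemble_wide_input,
    cross_products,
    one_hot_encode,
)

__all__ = [
    "sigmoid",
    "logistic_loss",
    "WideModel",
    "ConvLayer",
    "DeepModel",
    "CombinedModel",
    "wide_logit",
    "deep_forward",
    "combined_predict",
    "count_parameters",
    "save_model",
    "load_model",
]

#: Probabilities are clipped to [EPS, 1-EPS] so the logistic loss stays finite.
PROB_EPS = 1e-7


def sigmoid(z):
    """Numerically stable logistic function, elementwise."""
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    if out.ndim == 0:
        return float(out)
    return out


def logistic_loss(probs, labels) -> float:
    """Mean binary cross-entropy, probabilities clipped away from {0, 1}."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if probs.shape != labels.shape:
        raise ValueError(f"length mismatch: {probs.shape} probs vs {labels.shape} labels")
    p = np.clip(probs, PROB_EPS, 1.0 - PROB_EPS)
    return float(-np.mean(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p)))


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class WideModel:
    """Wide-branch weights; ``b`` is the bias shared by both branches."""

    w: np.ndarray
    b: float = 0.0


@dataclass
class ConvLayer:
    """1-D convolution along time, shared across the 31 rows.

    ``weights`` is (out_channels, in_channels, kernel); ``pad_left`` zeros are
    prepended to the time axis before the (valid, strided) convolution.
    """

    weights: np.ndarray
    bias: np.ndarray
    stride: int = 1
    pad_left: int = 0

    def out_width(self, in_width: int) -> int:
        return (in_width + self.pad_left - self.weights.shape[2]) // self.stride + 1

    @property
    def n_params(self) -> int:
        return self.weights.size + self.bias.size


@dataclass
class DeepModel:
    embedding: np.ndarray  # (T, n_samples)
    convs: list[ConvLayer]
    dense: np.ndarray  # flattened-activation weights, no separate bias
    leaky_slope: float = 0.01


@dataclass
class CombinedModel:
    """Both branches plus the feature specification they were built for."""

    wide: WideModel | None
    deep: DeepModel | None
    feature_spec: SparseFeatureSpec
    cross_spec: CrossSpec
    n_channels: int = 30
    n_samples: int = 90
    bias: float = 0.0  # used when the wide branch is absent
    _embed_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def b(self) -> float:
        return self.wide.b if self.wide is not None else self.bias

    @b.setter
    def b(self, value: float) -> None:
        if self.wide is not None:
            self.wide.b = float(value)
        else:
            self.bias = float(value)

    def encode_profile(self, profile) -> tuple[np.ndarray, np.ndarray]:
        d2 = one_hot_encode(profile, self.feature_spec)
        return d2, cross_products(d2, self.cross_spec)

    def embed(self, d2: np.ndarray, cache_key=None) -> np.ndarray:
        """Embedding row for a one-hot vector; cached per participant since
        it never changes between that participant's predictions."""
        if cache_key is not None and cache_key in self._embed_cache:
            return self._embed_cache[cache_key]
        if self.deep is None:
            row = np.zeros(self.n_samples)
        else:
            row = d2 @ self.deep.embedding
        if cache_key is not None:
            self._embed_cache[cache_key] = row
        return row

    def clear_cache(self) -> None:
        self._embed_cache.clear()


def initialize_model(
    feature_spec: SparseFeatureSpec,
    cross_spec: CrossSpec | None = None,
    seed: int = 0,
    n_channels: int = 30,
    n_samples: int = 90,
    conv_channels: tuple[int, ...] = (16, 32, 16),
    kernel: int = 7,
    strides: tuple[int, ...] = (2, 2, 1),
    pads: tuple[int, ...] = (0, 0, 1),
    leaky_slope: float = 0.01,
    use_wide: bool = True,
    use_deep: bool = True,
) -> CombinedModel:
    """Seeded initialization: wide weights start at zero (the FTRL
    convention); deep weights are uniform scaled by fan-in."""
    cross_spec = cross_spec if cross_spec is not None else CrossSpec.pairwise(feature_spec)
    rng = np.random.default_rng(seed)
    T = feature_spec.total_length

    wide = None
    if use_wide:
        d = n_channels * n_samples + T + cross_spec.n_features
        wide = WideModel(w=np.zeros(d), b=0.0)

    deep = None
    if use_deep:
        def u(shape, fan_in):
            lim = 1.0 / np.sqrt(max(fan_in, 1))
            return rng.uniform(-lim, lim, size=shape)

        embedding = u((T, n_samples), fan_in=max(T, 1))
        convs = []
        c_in = 1
        for c_out, s, p in zip(conv_channels, strides, pads):
            convs.append(
                ConvLayer(
                    weights=u((c_out, c_in, kernel), fan_in=c_in * kernel),
                    bias=np.zeros(c_out),
                    stride=s,
                    pad_left=p,
                )
            )
            c_in = c_out
        w = n_samples
        for layer in convs:
            w = layer.out_width(w)
        flat = (n_channels + 1) * w * conv_channels[-1]
        deep = DeepModel(
            embedding=embedding,
            convs=convs,
            dense=u(flat, fan_in=flat),
            leaky_slope=leaky_slope,
        )
    return CombinedModel(
        wide=wide,
        deep=deep,
        feature_spec=feature_spec,
        cross_spec=cross_spec,
        n_channels=n_channels,
        n_samples=n_samples,
    )


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------


def wide_logit(x: np.ndarray, m: WideModel) -> float:
    """``w . x + b`` (the sigmoid is applied by the combined head)."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != m.w.shape[0]:
        raise ValueError(f"input length {x.shape[-1]} != weight length {m.w.shape[0]}")
    out = x @ m.w + m.b
    return float(out) if out.ndim == 0 else out


def _conv_forward(x: np.ndarray, layer: ConvLayer):
    """x: (N, R, C_in, W_in) -> y: (N, R, C_out, W_out), plus the im2col cache.

    Computation runs in the dtype of the layer weights (the trainer keeps the
    deep branch in float32 for speed; a freshly initialized model is float64).
    """
    c_out, c_in, k = layer.weights.shape
    dtype = layer.weights.dtype
    x = np.ascontiguousarray(x, dtype=dtype)
    if layer.pad_left:
        x = np.pad(x, ((0, 0), (0, 0), (0, 0), (layer.pad_left, 0)))
    win = np.lib.stride_tricks.sliding_window_view(x, k, axis=3)[:, :, :, :: layer.stride, :]
    n, r, _, w_out, _ = win.shape
    cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2, 4)).reshape(n * r * w_out, c_in * k)
    y = cols @ layer.weights.reshape(c_out, c_in * k).T + layer.bias.astype(dtype)
    y = y.reshape(n, r, w_out, c_out).transpose(0, 1, 3, 2)
    return y, (cols, x.shape, w_out)


def _conv_backward(dy: np.ndarray, cache, layer: ConvLayer):
    """Returns (dx, dW, db); dy is (N, R, C_out, W_out).

    dx is accumulated per kernel offset through basic strided slices of the
    padded input-gradient buffer (positions are unique within one offset).
    """
    cols, x_padded_shape, w_out = cache
    c_out, c_in, k = layer.weights.shape
    n, r = dy.shape[0], dy.shape[1]
    dy2 = np.ascontiguousarray(dy.transpose(0, 1, 3, 2)).reshape(n * r * w_out, c_out)
    db = dy2.sum(axis=0)
    dw = (dy2.T @ cols).reshape(c_out, c_in, k)
    dcols = (dy2 @ layer.weights.reshape(c_out, c_in * k)).reshape(n, r, w_out, c_in, k)
    dcols = np.ascontiguousarray(dcols.transpose(0, 1, 3, 4, 2))  # (N, R, C_in, K, W_out)
    dxp = np.zeros((n, r, c_in, x_padded_shape[3]), dtype=dy.dtype)
    span = (w_out - 1) * layer.stride + 1
    for kk in range(k):
        dxp[:, :, :, kk : kk + span : layer.stride] += dcols[:, :, :, kk, :]
    dx = dxp[:, :, :, layer.pad_left:] if layer.pad_left else dxp
    return dx, dw, db


def deep_forward_batch(epochs: np.ndarray, embed_rows: np.ndarray, deep: DeepModel):
    """Forward pass for a batch.

    epochs: (N, 30, 90); embed_rows: (N, 90). Returns (a_lf (N, F),
    logits (N,), caches for backprop).
    """
    dtype = deep.convs[0].weights.dtype
    epochs = np.asarray(epochs, dtype=dtype)
    embed_rows = np.asarray(embed_rows, dtype=dtype)
    x = np.concatenate([epochs, embed_rows[:, None, :]], axis=1)  # (N, 31, 90)
    act = x[:, :, None, :]  # (N, R, 1, W)
    caches = []
    for layer in deep.convs:
        z, cache = _conv_forward(act, layer)
        act = np.where(z > 0, z, deep.leaky_slope * z)
        caches.append((cache, z))
    n = act.shape[0]
    a_lf = act.reshape(n, -1)
    logits = a_lf @ deep.dense
    return a_lf, logits, (caches, act.shape)


def deep_backward_batch(dlogits: np.ndarray, a_lf: np.ndarray, ctx, deep: DeepModel):
    """Backprop to all deep parameters and to the embedding row.

    Returns (grads dict with 'dense', 'conv{i}_w', 'conv{i}_b', and
    d_embed_rows (N, 90)).
    """
    caches, act_shape = ctx
    dtype = deep.dense.dtype
    dlogits = np.asarray(dlogits, dtype=dtype)
    grads = {"dense": a_lf.T @ dlogits}
    dact = np.outer(dlogits, deep.dense).reshape(act_shape)
    for i in range(len(deep.convs) - 1, -1, -1):
        cache, z = caches[i]
        dz = dact * np.where(z > 0, z.dtype.type(1.0), z.dtype.type(deep.leaky_slope))
        dact, dw, db = _conv_backward(dz, cache, deep.convs[i])
        grads[f"conv{i}_w"] = dw
        grads[f"conv{i}_b"] = db
    dx = dact[:, :, 0, :]  # (N, 31, 90)
    d_embed_rows = dx[:, -1, :]
    return grads, d_embed_rows


def deep_forward(epoch: np.ndarray, d2: np.ndarray, m: DeepModel):
    """Single-epoch forward: returns (flattened activations, deep logit)."""
    epoch = np.asarray(epoch, dtype=np.float64)
    d2 = np.asarray(d2, dtype=np.float64)
    if d2.shape[0] != m.embedding.shape[0]:
        raise ValueError(
            f"one-hot length {d2.shape[0]} != embedding vocabulary {m.embedding.shape[0]}"
        )
    embed_row = d2 @ m.embedding
    a_lf, logits, _ = deep_forward_batch(epoch[None], embed_row[None], m)
    return a_lf[0], float(logits[0])


def combined_predict(epoch: np.ndarray, profile, model: CombinedModel) -> float:
    """P(target | epoch, participant) through both branches.

    The participant's embedding row is computed once and cached under the
    subject id; repeated predictions reuse it.
    """
    d2, dphi = model.encode_profile(profile)
    logit = model.b
    if model.wide is not None:
        x = assemble_wide_input(epoch, d2, dphi, (model.n_channels, model.n_samples))
        logit += float(x @ model.wide.w)
    if model.deep is not None:
        embed_row = model.embed(d2, cache_key=getattr(profile, "subject_id", None))
        _, dl, _ = deep_forward_batch(np.asarray(epoch, dtype=np.float64)[None], embed_row[None], model.deep)
        logit += float(dl[0])
    return float(sigmoid(logit))


def count_parameters(model: CombinedModel) -> dict[str, int]:
    """Trainable-scalar counts per component."""
    counts: dict[str, int] = {}
    if model.wide is not None:
        counts["wide"] = model.wide.w.size + 1  # weights + shared bias
    if model.deep is not None:
        counts["embedding"] = model.deep.embedding.size
        for i, layer in enumerate(model.deep.convs, start=1):
            counts[f"conv{i}"] = layer.n_params
        counts["dense"] = model.deep.dense.size
        counts["deep"] = sum(
            v for k, v in counts.items() if k.startswith(("embedding", "conv", "dense"))
        )
    counts["total"] = counts.get("wide", 0 if model.wide is None else 1) + counts.get("deep", 0)
    if model.wide is None:
        counts["total"] += 1  # the shared bias still exists
    return counts


# ---------------------------------------------------------------------------
# serialization: zip of .npy arrays + a JSON architecture block
# ---------------------------------------------------------------------------


def save_model(model: CombinedModel, path) -> None:
    arch = {
        "n_channels": model.n_channels,
        "n_samples": model.n_samples,
        "bias": model.b,
        "use_wide": model.wide is not None,
        "use_deep": model.deep is not None,
        "feature_spec": {
            "subjects": list(model.feature_spec.subjects),
            "sexes": list(model.feature_spec.sexes),
            "age_groups": list(model.feature_spec.age_groups),
        },
    }
    arrays: dict[str, np.ndarray] = {"cross_mask": model.cross_spec.mask}
    if model.wide is not None:
        arrays["wide_w"] = model.wide.w
    if model.deep is not None:
        arch["leaky_slope"] = model.deep.leaky_slope
        arch["conv_meta"] = [
            {"stride": c.stride, "pad_left": c.pad_left} for c in model.deep.convs
        ]
        arrays["embedding"] = model.deep.embedding
        for i, c in enumerate(model.deep.convs):
            arrays[f"conv{i}_w"] = c.weights
            arrays[f"conv{i}_b"] = c.bias
        arrays["dense"] = model.deep.dense
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("arch.json", json.dumps(arch))
        for name, arr in arrays.items():
            buf = _stdio.BytesIO()
            np.save(buf, np.ascontiguousarray(arr))
            zf.writestr(f"{name}.npy", buf.getvalue())


def load_model(path) -> CombinedModel:
    with zipfile.ZipFile(path) as zf:
        arch = json.loads(zf.read("arch.json"))

        def arr(name):
            return np.load(_stdio.BytesIO(zf.read(f"{name}.npy")))

        spec = SparseFeatureSpec(
            subjects=tuple(arch["feature_spec"]["subjects"]),
            sexes=tuple(arch["feature_spec"]["sexes"]),
            age_groups=tuple(arch["feature_spec"]["age_groups"]),
        )
        cross = CrossSpec(arr("cross_mask"))
        wide = WideModel(w=arr("wide_w"), b=arch["bias"]) if arch["use_wide"] else None
        deep = None
        if arch["use_deep"]:
            convs = [
                ConvLayer(
                    weights=arr(f"conv{i}_w"),
                    bias=arr(f"conv{i}_b"),
                    stride=m["stride"],
                    pad_left=m["pad_left"],
                )
                for i, m in enumerate(arch["conv_meta"])
            ]
            deep = DeepModel(
                embedding=arr("embedding"),
                convs=convs,
                dense=arr("dense"),
                leaky_slope=arch["leaky_slope"],
            )
    model = CombinedModel(
        wide=wide,
        deep=deep,
        feature_spec=spec,
        cross_spec=cross,
        n_channels=arch["n_channels"],
        n_samples=arch["n_samples"],
    )
    model.b = arch["bias"]
    return model
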