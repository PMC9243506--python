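"""FTRL-Proximal: per-coordinate online optimization with L1/L2 regularization.

Each coordinate i keeps an accumulator ``z_i`` and a sum of squared gradients
``q_i``. One step with gradient ``g``:

    sigma_i = (sqrt(q_i + g_i^2) - sqrt(q_i)) / alpha
    q_i    <- q_i + g_i^2
    z_i    <- z_i + g_i - sigma_i * w_i
    w_i     = 0                                           if |z_i| <= lambda1
            = -(lambda2 + (beta + sqrt(q_i)) / alpha)^-1
               * (z_i - lambda1 * sign(z_i))              otherwise

which is the closed-form argmin of the proximal objective
``G_{1:t} . w + 1/2 sum_s sigma_s (w - w_s)^2 + lambda1 |w| + lambda2/2 w^2``
(with the beta term acting as an extra quadratic stabilizer centered at the
origin). The effective learning rate alpha/(beta + sqrt(q_i)) is
per-coordinate: rarely active features keep a large rate. The L1 truncation
zeroes any weight whose accumulator stays within lambda1, which is what
produces sparse wide weights.

The trainer below applies FTRL to *every* trainable parameter of the
combined model — wide weights, embedding, convolution filters and the dense
head — feeding it the per-coordinate gradients of the logistic loss.
A conventional Adagrad update for the deep branch is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import cross_products, one_hot_encode
from .network import (
    CombinedModel,
    deep_backward_batch,
    deep_forward_batch,
    logistic_loss,
    sigmoid,
)

__all__ = ["FtrlConfig", "FtrlState", "ftrl_step", "FtrlOptimizer", "fit_model", "wide_sparsity"]


@dataclass(frozen=True)
class FtrlConfig:
    """alpha/beta shape the per-coordinate learning rate
    alpha/(beta + sqrt(q)); lambda1/lambda2 are the L1/L2 strengths."""

    alpha: float = 0.05
    beta: float = 1.0
    lambda1: float = 1e-5
    lambda2: float = 1e-4

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if min(self.beta, self.lambda1, self.lambda2) < 0:
            raise ValueError("beta, lambda1, lambda2 must be >= 0")


@dataclass(frozen=True)
class FtrlState:
    """Per-coordinate optimizer state; immutable (steps return new states)."""

    z: np.ndarray
    q: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        if not (self.z.shape == self.q.shape == self.w.shape):
            raise ValueError("z, q, w must share one shape")

    @classmethod
    def zeros(cls, shape) -> "FtrlState":
        return cls(np.zeros(shape), np.zeros(shape), np.zeros(shape))

    @classmethod
    def from_weights(cls, w: np.ndarray, cfg: "FtrlConfig") -> "FtrlState":
        """State whose proximal argmin at q = 0 equals ``w``.

        z is set to -w (lambda2 + beta/alpha) (minus the L1 shift), so a
        nonzero initialization (e.g. the deep branch's random init) is the
        optimizer's starting point rather than being pulled to the origin on
        the first step.
        """
        w = np.array(w, dtype=float)
        z = -w * (cfg.lambda2 + cfg.beta / cfg.alpha)
        z += np.where(w != 0.0, cfg.lambda1 * np.sign(z), 0.0)
        return cls(z, np.zeros_like(w, dtype=float), w)


def ftrl_step(state: FtrlState, g: np.ndarray, cfg: FtrlConfig) -> FtrlState:
    """One FTRL-Proximal update; elementwise over any array shape.

    Pure: the input state is not mutated. Ties |z| == lambda1 truncate to 0.
    """
    g = np.asarray(g, dtype=float)
    if g.shape != state.w.shape:
        raise ValueError(f"gradient shape {g.shape} != weight shape {state.w.shape}")
    if not np.all(np.isfinite(g)):
        bad = np.argwhere(~np.isfinite(g))[0]
        raise ValueError(f"non-finite gradient at coordinate {tuple(bad)}")
    sigma = (np.sqrt(state.q + g * g) - np.sqrt(state.q)) / cfg.alpha
    q = state.q + g * g
    z = state.z + g - sigma * state.w
    with np.errstate(divide="ignore", invalid="ignore"):
        # the else-branch may be 0/0 where |z| <= lambda1; np.where discards it
        w = np.where(
            np.abs(z) <= cfg.lambda1,
            0.0,
            -(z - cfg.lambda1 * np.sign(z))
            / (cfg.lambda2 + (cfg.beta + np.sqrt(q)) / cfg.alpha),
        )
    return FtrlState(z=z, q=q, w=w)


class FtrlOptimizer:
    """FTRL state for a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], cfg: FtrlConfig):
        self.cfg = cfg
        self.states = {name: FtrlState.from_weights(p, cfg) for name, p in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        """Update every named parameter; returns the new weight arrays."""
        out = {}
        for name, g in grads.items():
            self.states[name] = ftrl_step(self.states[name], g, self.cfg)
            out[name] = self.states[name].w
        return out


class _AdagradOptimizer:
    """Plain Adagrad, offered for the deep branch as an alternative."""

    def __init__(self, params: dict[str, np.ndarray], cfg: FtrlConfig):
        self.cfg = cfg
        self.weights = {k: np.array(v, dtype=float) for k, v in params.items()}
        self.q = {k: np.zeros_like(v, dtype=float) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        out = {}
        for name, g in grads.items():
            self.q[name] += g * g
            self.weights[name] -= self.cfg.alpha * g / (self.cfg.beta + np.sqrt(self.q[name]))
            out[name] = self.weights[name]
        return out


def wide_sparsity(model: CombinedModel) -> float:
    """Fraction of wide weights that are exactly zero."""
    if model.wide is None or model.wide.w.size == 0:
        return 0.0
    return float(np.mean(model.wide.w == 0.0))


def _encode_subjects(model: CombinedModel, subject_ids, profiles) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch one-hot and cross-product matrices from the profile map."""
    T = model.feature_spec.total_length
    k = model.cross_spec.n_features
    n = len(subject_ids)
    d2 = np.zeros((n, T))
    dphi = np.zeros((n, k))
    cache: dict = {}
    for i, sid in enumerate(subject_ids):
        if sid not in cache:
            if sid in profiles:
                v = one_hot_encode(profiles[sid], model.feature_spec)
            elif T == 0:
                v = np.zeros(0)  # no sparse features configured at all
            else:
                raise KeyError(f"no profile supplied for subject {sid!r}")
            cache[sid] = (v, cross_products(v, model.cross_spec))
        d2[i], dphi[i] = cache[sid]
    return d2, dphi


def fit_model(
    model: CombinedModel,
    X: np.ndarray,
    y: np.ndarray,
    subject_ids,
    profiles,
    cfg: FtrlConfig | None = None,
    n_passes: int = 3,
    batch_size: int = 64,
    seed: int = 0,
    deep_optimizer: str = "ftrl",
) -> tuple[CombinedModel, list[float]]:
    """Train the combined model in place with mini-batch FTRL.

    X is (n, channels, samples) in uV, y binary; ``profiles`` maps each id in
    ``subject_ids`` to its participant attributes. Gradients of the mean
    logistic loss w.r.t. *all* trainable parameters are fed per coordinate to
    the optimizer. Returns the model and the per-pass mean training loss.
    """
    cfg = cfg or FtrlConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 3 or len(X) == 0:
        raise ValueError("X must be a non-empty (n, channels, samples) array")
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    if deep_optimizer not in ("ftrl", "adaptive"):
        raise ValueError("deep_optimizer must be 'ftrl' or 'adaptive'")
    n = len(X)
    subject_ids = list(subject_ids) if subject_ids is not None else [""] * n
    d2_all, dphi_all = _encode_subjects(model, subject_ids, profiles or {})
    flat = X.reshape(n, -1)

    wide_params: dict[str, np.ndarray] = {"bias": np.array([model.b])}
    if model.wide is not None:
        wide_params["wide_w"] = model.wide.w
    deep_params: dict[str, np.ndarray] = {}
    if model.deep is not None:
        # deep branch computes in float32 during training (speed); the
        # optimizer state itself stays float64
        model.deep.embedding = model.deep.embedding.astype(np.float32)
        for layer in model.deep.convs:
            layer.weights = layer.weights.astype(np.float32)
            layer.bias = layer.bias.astype(np.float32)
        model.deep.dense = model.deep.dense.astype(np.float32)
        deep_params["embedding"] = model.deep.embedding
        for i, layer in enumerate(model.deep.convs):
            deep_params[f"conv{i}_w"] = layer.weights
            deep_params[f"conv{i}_b"] = layer.bias
        deep_params["dense"] = model.deep.dense

    wide_opt = FtrlOptimizer(wide_params, cfg)
    deep_opt = (
        FtrlOptimizer(deep_params, cfg)
        if deep_optimizer == "ftrl"
        else _AdagradOptimizer(deep_params, cfg)
    )

    rng = np.random.default_rng(seed)
    losses: list[float] = []
    for _ in range(n_passes):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = flat[idx], y[idx]
            d2b, dphib = d2_all[idx], dphi_all[idx]
            m = len(idx)

            logits = np.full(m, model.b)
            if model.wide is not None:
                xw = np.concatenate([xb, d2b, dphib], axis=1)
                logits = logits + xw @ model.wide.w
            if model.deep is not None:
                embed_rows = d2b @ model.deep.embedding
                a_lf, dl, ctx = deep_forward_batch(X[idx], embed_rows, model.deep)
                logits = logits + dl
            p = sigmoid(logits)
            total += logistic_loss(p, yb) * m

            dlogit = (p - yb) / m
            new_w = wide_opt.step(
                {"bias": np.array([dlogit.sum()])}
                | ({"wide_w": xw.T @ dlogit} if model.wide is not None else {})
            )
            model.b = float(new_w["bias"][0])
            if model.wide is not None:
                model.wide.w = new_w["wide_w"]
            if model.deep is not None:
                grads, d_embed = deep_backward_batch(dlogit, a_lf, ctx, model.deep)
                grads = {
                    "embedding": d2b.T @ d_embed,
                    "conv0_w": grads["conv0_w"],
                    "conv0_b": grads["conv0_b"],
                    "conv1_w": grads["conv1_w"],
                    "conv1_b": grads["conv1_b"],
                    "conv2_w": grads["conv2_w"],
                    "conv2_b": grads["conv2_b"],
                    "dense": grads["dense"],
                }
                updated = deep_opt.step(grads)
                model.deep.embedding = updated["embedding"].astype(np.float32)
                for i, layer in enumerate(model.deep.convs):
                    layer.weights = updated[f"conv{i}_w"].astype(np.float32)
                    layer.bias = updated[f"conv{i}_b"].astype(np.float32)
                model.deep.dense = updated["dense"].astype(np.float32)
        losses.append(total / n)
    model.clear_cache()
    return model, losses
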