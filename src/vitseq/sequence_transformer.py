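"""Time-series transformer classifier over ordered slice-feature sequences.

The model receives one feature vector per slice, in anatomical order, and
classifies the whole volume: sinusoidal positional encodings are added to
the inputs, a stack of pre-layer-norm transformer blocks (multi-head scaled
dot-product self-attention + position-wise feed-forward, both residual)
mixes information across slices, the sequence axis is pooled (global
average by default, attention pooling optionally), and a dense softmax head
produces class probabilities. Training minimizes categorical cross-entropy
with an Adam optimizer and early stopping on validation loss.

Everything — forward pass, analytic gradients, optimizer — is implemented
directly on NumPy arrays, so the model is deterministic under a fixed seed
and its gradients can be verified against finite differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .errors import DataError, ParameterError, ShapeError

_LN_EPS = 1e-5
_POOLING_MODES = ("global_average", "attention")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyper-parameters.

    The block width equals ``feature_dim`` unless ``model_dim`` is set, in
    which case a single linear map projects the inputs first. One seed
    governs parameter initialization, minibatch shuffling and dropout.
    """

    feature_dim: int
    seq_len: int = 50
    n_classes: int = 3
    n_blocks: int = 2
    n_heads: int = 4
    head_dim: int = 32
    ff_dim: int = 128
    dropout: float = 0.1
    pooling: str = "global_average"
    model_dim: int | None = None
    use_positional_encoding: bool = True
    learning_rate: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_dim < 1 or self.seq_len < 1:
            raise ParameterError("feature_dim and seq_len must be positive")
        if self.n_classes < 2:
            raise ParameterError("n_classes must be >= 2")
        if self.n_heads < 1 or self.head_dim < 1 or self.ff_dim < 1 or self.n_blocks < 0:
            raise ParameterError("invalid transformer dimensions")
        if not (0.0 <= self.dropout < 1.0):
            raise ParameterError("dropout must be in [0, 1)")
        if self.pooling not in _POOLING_MODES:
            raise ParameterError(
                f"pooling must be one of {_POOLING_MODES}, got {self.pooling!r}"
            )
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ParameterError("learning_rate must be > 0 and batch_size >= 1")
        if self.max_epochs < 0 or self.patience < 0:
            raise ParameterError("max_epochs and patience must be >= 0")

    @property
    def width(self) -> int:
        return self.model_dim if self.model_dim is not None else self.feature_dim


# ---------------------------------------------------------------------------
# Positional encoding
# ---------------------------------------------------------------------------

def positional_encoding(seq_len: int, dim: int) -> np.ndarray:
    """Sinusoidal position code: ``pe[p, 2i] = sin(p / 10000^(2i/dim))`` and
    ``pe[p, 2i+1] = cos`` of the same angle. Shape (seq_len, dim)."""
    if seq_len < 1 or dim < 1:
        raise ParameterError("seq_len and dim must be >= 1")
    pos = np.arange(seq_len, dtype=np.float64)[:, None]
    i = np.arange(0, dim, 2, dtype=np.float64)
    angles = pos / np.power(10000.0, i / dim)[None, :]
    pe = np.zeros((seq_len, dim))
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)[:, : dim // 2]
    return pe


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, scale, size=(fan_in, fan_out))


def init_params(config: ModelConfig, rng: np.random.Generator | None = None) -> dict:
    """Seeded parameter initialization (Glorot-scaled Gaussians, unit norms)."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    d, hd = config.width, config.n_heads * config.head_dim
    p: dict[str, np.ndarray] = {}
    if config.model_dim is not None and config.model_dim != config.feature_dim:
        p["Win"] = _glorot(rng, config.feature_dim, d)
        p["bin"] = np.zeros(d)
    for k in range(config.n_blocks):
        pre = f"blk{k}_"
        p[pre + "ln1_g"] = np.ones(d)
        p[pre + "ln1_b"] = np.zeros(d)
        for name in ("Wq", "Wk", "Wv"):
            p[pre + name] = _glorot(rng, d, hd)
            p[pre + name.replace("W", "b")] = np.zeros(hd)
        p[pre + "Wo"] = _glorot(rng, hd, d)
        p[pre + "bo"] = np.zeros(d)
        p[pre + "ln2_g"] = np.ones(d)
        p[pre + "ln2_b"] = np.zeros(d)
        p[pre + "W1"] = _glorot(rng, d, config.ff_dim)
        p[pre + "b1"] = np.zeros(config.ff_dim)
        p[pre + "W2"] = _glorot(rng, config.ff_dim, d)
        p[pre + "b2"] = np.zeros(d)
    p["lnf_g"] = np.ones(d)
    p["lnf_b"] = np.zeros(d)
    if config.pooling == "attention":
        p["pool_v"] = rng.normal(0.0, 1.0 / np.sqrt(d), size=d)
    p["Wout"] = _glorot(rng, d, config.n_classes)
    p["bout"] = np.zeros(config.n_classes)
    return p


# ---------------------------------------------------------------------------
# Primitive layers (forward + analytic backward)
# ---------------------------------------------------------------------------

def _layer_norm(x, g, b):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv_std
    return g * xhat + b, (xhat, inv_std, g)


def _layer_norm_backward(dy, cache):
    xhat, inv_std, g = cache
    dxhat = dy * g
    dx = inv_std * (
        dxhat
        - dxhat.mean(-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(-1, keepdims=True)
    )
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    return dx, dg, db


def _softmax(x, axis=-1):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _softmax_backward(dA, A, axis=-1):
    return A * (dA - (dA * A).sum(axis=axis, keepdims=True))


def _split_heads(x, n_heads, head_dim):
    b, l, _ = x.shape
    return x.reshape(b, l, n_heads, head_dim).transpose(0, 2, 1, 3)


def _merge_heads(x):
    b, h, l, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, l, h * dh)


def _mha(xn, params, prefix, config):
    """Multi-head scaled dot-product self-attention on the normed input."""
    H, dh = config.n_heads, config.head_dim
    q = _split_heads(xn @ params[prefix + "Wq"] + params[prefix + "bq"], H, dh)
    k = _split_heads(xn @ params[prefix + "Wk"] + params[prefix + "bk"], H, dh)
    v = _split_heads(xn @ params[prefix + "Wv"] + params[prefix + "bv"], H, dh)
    scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(dh)
    attn = _softmax(scores, axis=-1)  # rows sum to 1
    ctx = _merge_heads(attn @ v)
    out = ctx @ params[prefix + "Wo"] + params[prefix + "bo"]
    return out, (xn, q, k, v, attn, ctx)


def _mha_backward(dout, cache, params, prefix, config, grads):
    xn, q, k, v, attn, ctx = cache
    H, dh = config.n_heads, config.head_dim
    grads[prefix + "Wo"] = np.einsum("blh,bld->hd", ctx, dout)
    grads[prefix + "bo"] = dout.sum((0, 1))
    dctx = _split_heads(dout @ params[prefix + "Wo"].T, H, dh)
    dattn = dctx @ v.transpose(0, 1, 3, 2)
    dv = attn.transpose(0, 1, 3, 2) @ dctx
    dscores = _softmax_backward(dattn, attn) / np.sqrt(dh)
    dq = dscores @ k
    dk = dscores.transpose(0, 1, 3, 2) @ q
    dxn = np.zeros_like(xn)
    for name, dmat in (("Wq", dq), ("Wk", dk), ("Wv", dv)):
        flat = _merge_heads(dmat)
        grads[prefix + name] = np.einsum("bld,blh->dh", xn, flat)
        grads[prefix + name.replace("W", "b")] = flat.sum((0, 1))
        dxn += flat @ params[prefix + name].T
    return dxn


def _dropout_mask(shape, p, rng):
    return (rng.random(shape) >= p) / (1.0 - p)


# ---------------------------------------------------------------------------
# Full forward / backward
# ---------------------------------------------------------------------------

def _check_inputs(X: np.ndarray, config: ModelConfig) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 3 or X.shape[1] != config.seq_len or X.shape[2] != config.feature_dim:
        raise ShapeError(
            f"expected sequences of shape (n, {config.seq_len}, "
            f"{config.feature_dim}), got {X.shape}"
        )
    return X


def _forward(params, X, config, train=False, rng=None):
    """Returns (probs, logits, cache). Dropout is active only when training."""
    B = X.shape[0]
    use_drop = train and config.dropout > 0.0
    if "Win" in params:
        x = X @ params["Win"] + params["bin"]
    else:
        x = X.copy()
    if config.use_positional_encoding:
        x = x + positional_encoding(config.seq_len, config.width)[None]
    block_caches = []
    for k in range(config.n_blocks):
        pre = f"blk{k}_"
        xn1, ln1_cache = _layer_norm(x, params[pre + "ln1_g"], params[pre + "ln1_b"])
        attn_out, mha_cache = _mha(xn1, params, pre, config)
        m1 = _dropout_mask(attn_out.shape, config.dropout, rng) if use_drop else None
        if m1 is not None:
            attn_out = attn_out * m1
        y = x + attn_out
        xn2, ln2_cache = _layer_norm(y, params[pre + "ln2_g"], params[pre + "ln2_b"])
        h1 = xn2 @ params[pre + "W1"] + params[pre + "b1"]
        a = np.maximum(h1, 0.0)
        ff_out = a @ params[pre + "W2"] + params[pre + "b2"]
        m2 = _dropout_mask(ff_out.shape, config.dropout, rng) if use_drop else None
        if m2 is not None:
            ff_out = ff_out * m2
        x_next = y + ff_out
        block_caches.append((ln1_cache, mha_cache, m1, ln2_cache, xn2, h1, a, m2))
        x = x_next
    xf, lnf_cache = _layer_norm(x, params["lnf_g"], params["lnf_b"])
    if config.pooling == "attention":
        s = xf @ params["pool_v"]  # (B, L)
        alpha = _softmax(s, axis=-1)
        pooled = (alpha[:, :, None] * xf).sum(1)
        pool_cache = (xf, alpha)
    else:
        pooled = xf.mean(1)
        pool_cache = (xf, None)
    logits = pooled @ params["Wout"] + params["bout"]
    probs = _softmax(logits, axis=-1)
    cache = (X, block_caches, lnf_cache, pool_cache, pooled, B)
    return probs, logits, cache


def _backward(params, dlogits, cache, config):
    X, block_caches, lnf_cache, pool_cache, pooled, B = cache
    L = config.seq_len
    grads: dict[str, np.ndarray] = {}
    grads["Wout"] = pooled.T @ dlogits
    grads["bout"] = dlogits.sum(0)
    dpooled = dlogits @ params["Wout"].T
    xf, alpha = pool_cache
    if config.pooling == "attention":
        dalpha = (dpooled[:, None, :] * xf).sum(-1)
        ds = _softmax_backward(dalpha, alpha, axis=-1)
        dxf = alpha[:, :, None] * dpooled[:, None, :]
        dxf += ds[:, :, None] * params["pool_v"][None, None, :]
        grads["pool_v"] = np.einsum("bld,bl->d", xf, ds)
    else:
        dxf = np.broadcast_to(dpooled[:, None, :] / L, xf.shape).copy()
    dx, grads["lnf_g"], grads["lnf_b"] = _layer_norm_backward(dxf, lnf_cache)
    for k in reversed(range(config.n_blocks)):
        pre = f"blk{k}_"
        ln1_cache, mha_cache, m1, ln2_cache, xn2, h1, a, m2 = block_caches[k]
        # feed-forward branch
        dff = dx * m2 if m2 is not None else dx
        grads[pre + "W2"] = np.einsum("blf,bld->fd", a, dff)
        grads[pre + "b2"] = dff.sum((0, 1))
        da = dff @ params[pre + "W2"].T
        dh1 = da * (h1 > 0)
        grads[pre + "W1"] = np.einsum("bld,blf->df", xn2, dh1)
        grads[pre + "b1"] = dh1.sum((0, 1))
        dxn2 = dh1 @ params[pre + "W1"].T
        dy_ln, grads[pre + "ln2_g"], grads[pre + "ln2_b"] = _layer_norm_backward(
            dxn2, ln2_cache
        )
        dy = dx + dy_ln  # residual
        # attention branch
        dattn_out = dy * m1 if m1 is not None else dy
        dxn1 = _mha_backward(dattn_out, mha_cache, params, pre, config, grads)
        dx_ln, grads[pre + "ln1_g"], grads[pre + "ln1_b"] = _layer_norm_backward(
            dxn1, ln1_cache
        )
        dx = dy + dx_ln  # residual
    if "Win" in params:
        grads["Win"] = np.einsum("blf,bld->fd", X, dx)
        grads["bin"] = dx.sum((0, 1))
    return grads


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    B = logits.shape[0]
    z = logits - logits.max(-1, keepdims=True)
    log_probs = z - np.log(np.exp(z).sum(-1, keepdims=True))
    loss = -log_probs[np.arange(B), y].mean()
    probs = np.exp(log_probs)
    onehot = np.zeros_like(probs)
    onehot[np.arange(B), y] = 1.0
    return float(loss), (probs - onehot) / B


def transformer_block(
    x: np.ndarray,
    config: ModelConfig,
    params: dict | None = None,
    block_index: int = 0,
    return_attention: bool = False,
):
    """Apply one pre-LN transformer block to a single (seq_len x width) matrix.

    ``y = x + MHA(LN(x))`` followed by ``y + FF(LN(y))``; no dropout. If
    ``params`` is omitted a seeded fresh set is initialized from the config.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != config.width:
        raise ShapeError(
            f"expected (seq_len, {config.width}) input, got shape {x.shape}"
        )
    if params is None:
        params = init_params(replace(config, n_blocks=max(config.n_blocks, 1)))
    pre = f"blk{block_index}_"
    xb = x[None]
    xn1, _ = _layer_norm(xb, params[pre + "ln1_g"], params[pre + "ln1_b"])
    attn_out, mha_cache = _mha(xn1, params, pre, config)
    y = xb + attn_out
    xn2, _ = _layer_norm(y, params[pre + "ln2_g"], params[pre + "ln2_b"])
    ff = np.maximum(xn2 @ params[pre + "W1"] + params[pre + "b1"], 0.0)
    out = (y + ff @ params[pre + "W2"] + params[pre + "b2"])[0]
    if return_attention:
        return out, mha_cache[4][0]  # (n_heads, L, L)
    return out


# ---------------------------------------------------------------------------
# Model container, training loop, prediction
# ---------------------------------------------------------------------------

@dataclass
class TransformerClassifier:
    """A (possibly trained) sequence classifier: config + parameters + history."""

    config: ModelConfig
    params: dict
    history: list = field(default_factory=list)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = _check_inputs(X, self.config)
        probs, _, _ = _forward(self.params, X, self.config, train=False)
        return probs

    def logits(self, X: np.ndarray) -> np.ndarray:
        X = _check_inputs(X, self.config)
        _, logits, _ = _forward(self.params, X, self.config, train=False)
        return logits


def build_model(config: ModelConfig) -> TransformerClassifier:
    """Fresh model with seeded parameter initialization."""
    return TransformerClassifier(config=config, params=init_params(config))


def _validate_labels(y: np.ndarray, n_classes: int) -> np.ndarray:
    y = np.asarray(y)
    if y.size and (y.min() < 0 or y.max() >= n_classes):
        raise DataError(
            f"labels must lie in [0, {n_classes}), got range "
            f"[{y.min()}, {y.max()}]"
        )
    return y.astype(np.int64)


def evaluate_loss(model: TransformerClassifier, X, y) -> tuple[float, float]:
    """(cross-entropy, accuracy) of a model on a labelled set, no dropout."""
    X = _check_inputs(X, model.config)
    y = _validate_labels(y, model.config.n_classes)
    _, logits, _ = _forward(model.params, X, model.config, train=False)
    loss, _ = cross_entropy(logits, y)
    acc = float((logits.argmax(-1) == y).mean())
    return loss, acc


def train_fold(
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    config: ModelConfig,
) -> TransformerClassifier:
    """Train one fold's model with Adam + early stopping on validation loss.

    The parameters with the best validation loss are restored at the end;
    with ``max_epochs=0`` the freshly initialized model is returned with an
    empty history.
    """
    X_tr = _check_inputs(train[0], config)
    y_tr = _validate_labels(train[1], config.n_classes)
    X_val = _check_inputs(val[0], config)
    y_val = _validate_labels(val[1], config.n_classes)
    if X_tr.shape[0] == 0 or X_val.shape[0] == 0:
        raise DataError("training and validation sets must be nonempty")

    ss = np.random.SeedSequence(config.seed).spawn(2)
    model = TransformerClassifier(
        config=config, params=init_params(config, np.random.default_rng(ss[0]))
    )
    if config.max_epochs == 0:
        return model
    rng = np.random.default_rng(ss[1])

    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(vv) for k, vv in model.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    best_val = np.inf
    best_params = {k: p.copy() for k, p in model.params.items()}
    wait = 0
    n = X_tr.shape[0]
    for epoch in range(1, config.max_epochs + 1):
        perm = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            probs, logits, cache = _forward(
                model.params, X_tr[idx], config, train=True, rng=rng
            )
            loss, dlogits = cross_entropy(logits, y_tr[idx])
            grads = _backward(model.params, dlogits, cache, config)
            step += 1
            lr_t = config.learning_rate * np.sqrt(1 - b2**step) / (1 - b1**step)
            for key, g in grads.items():
                m[key] = b1 * m[key] + (1 - b1) * g
                v[key] = b2 * v[key] + (1 - b2) * g * g
                model.params[key] -= lr_t * m[key] / (np.sqrt(v[key]) + eps)
            batch_losses.append(loss)
        val_loss, val_acc = evaluate_loss(model, X_val, y_val)
        model.history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(batch_losses)),
                "val_loss": val_loss,
                "val_accuracy": val_acc,
            }
        )
        if val_loss < best_val:
            best_val = val_loss
            best_params = {k: p.copy() for k, p in model.params.items()}
            wait = 0
        else:
            wait += 1
            if wait >= config.patience > 0:
                break
    model.params = best_params
    return model


def predict(
    model: TransformerClassifier, sequences: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels (ties go to the lower index)."""
    probs = model.predict_proba(sequences)
    return probs, probs.argmax(-1)


def order_sensitivity_fraction(
    model: TransformerClassifier,
    sequences: np.ndarray,
    rng: np.random.Generator,
    tol: float = 1e-6,
) -> float:
    """Fraction of sequences whose predicted probability vector changes when
    their slice order is randomly shuffled (a measure of how much the model
    uses slice position)."""
    X = _check_inputs(sequences, model.config)
    probs = model.predict_proba(X)
    shuffled = np.stack([x[rng.permutation(x.shape[0])] for x in X])
    probs_shuf = model.predict_proba(shuffled)
    changed = np.abs(probs - probs_shuf).max(-1) > tol
    return float(changed.mean())


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_model(model: TransformerClassifier, path_prefix: str | Path) -> list[Path]:
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    npz = prefix.with_suffix(".npz")
    meta = prefix.with_suffix(".json")
    np.savez(npz, **model.params)
    meta.write_text(
        json.dumps({"config": asdict(model.config), "history": model.history}, indent=2)
    )
    return [npz, meta]


def load_model(path_prefix: str | Path) -> TransformerClassifier:
    prefix = Path(path_prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    with np.load(prefix.with_suffix(".npz")) as data:
        params = {k: data[k].copy() for k in data.files}
    return TransformerClassifier(
        config=ModelConfig(**meta["config"]), params=params, history=meta["history"]
    )
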