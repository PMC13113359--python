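"""Hierarchical local/global-attention transformer encoder.

The encoder turns a sequence of flattened image patches into a single
global representation.  Each of the L layers computes, per head, both a
*global* attention distribution (softmax over all N tokens) and a *local*
one (softmax restricted to a Chebyshev neighbourhood on the 2-D patch
grid), and mixes them convexly with a depth-increasing coefficient
alpha(l).  Because both operands are row-stochastic, the mixture is
row-stochastic without renormalisation.  Mean-pooled token summaries are
taken at selected depths l_1 < ... < l_K and fused with softmax-normalised
weights beta_k into the final vector h.

Everything is plain numpy.  Forward passes optionally cache the
intermediates needed by the analytic backward pass used for training; the
gradients are validated against finite differences in the test suite.

Two residual structures are supported:

* literal (default): a single residual around the whole
  attention -> feed-forward block, t^(l) = t^(l-1) + W2 phi(W1 s), with no
  layer normalisation;
* ``stabilized``: pre-layer-norm around each sub-block with a residual per
  sub-block, the conventional trainable variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import special
from scipy.stats import truncnorm

from .preprocessing import PatchGrid

Params = dict  # str -> np.ndarray

_SQRT2PI = np.sqrt(2.0 * np.pi)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class EncoderConfig:
    patch_grid: PatchGrid
    n_layers: int = 4
    embed_dim: int = 64
    n_heads: int = 4
    neighborhood_radius: int = 1
    alpha_mode: str = "fixed_linear"  # fixed_linear | learnable_monotone | fixed_constant
    alpha_constant: float = 1.0
    fusion_depths: tuple[int, ...] = (2, 4)
    hidden_mult: int = 4
    activation: str = "gelu"
    stabilized: bool = False
    use_positional: bool = True
    init_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        fd = tuple(self.fusion_depths)
        if not fd or any(b <= a for a, b in zip(fd, fd[1:])):
            raise ValueError("fusion_depths must be strictly increasing")
        if fd[0] < 1 or fd[-1] > self.n_layers:
            raise ValueError("fusion_depths must lie in 1..n_layers")
        if self.alpha_mode not in ("fixed_linear", "learnable_monotone",
                                   "fixed_constant"):
            raise ValueError(f"unknown alpha_mode {self.alpha_mode!r}")
        if self.neighborhood_radius < 0:
            raise ValueError("neighborhood_radius must be >= 0")

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.n_heads

    @property
    def hidden_dim(self) -> int:
        return self.hidden_mult * self.embed_dim

    @property
    def n_levels(self) -> int:
        return len(self.fusion_depths)


# ---------------------------------------------------------------------------
# small numerics


def _softplus(x):
    return np.logaddexp(0.0, x)


def _sigmoid(x):
    return special.expit(x)


def softmax(x, axis=-1):
    m = np.max(x, axis=axis, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(axis=axis, keepdims=True)


def gelu(x):
    """Exact Gaussian-error linear unit x * Phi(x)."""
    return x * special.ndtr(x)


def gelu_grad(x):
    return special.ndtr(x) + x * np.exp(-0.5 * x * x) / _SQRT2PI


def _layer_norm_forward(x, gain, bias, eps=1e-6):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return gain * xhat + bias, (xhat, inv)

def _layer_norm_backward(dy, cache, gain):
    xhat, inv = cache
    E = xhat.shape[-1]
    dgain = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    dbias = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * gain
    dx = inv / E * (E * dxhat - dxhat.sum(-1, keepdims=True)
                    - xhat * (dxhat * xhat).sum(-1, keepdims=True))
    return dx, dgain, dbias


# ---------------------------------------------------------------------------
# attention geometry


@lru_cache(maxsize=32)
def _neighborhood_mask_cached(rows: int, cols: int, radius: int) -> np.ndarray:
    r = np.arange(rows)
    c = np.arange(cols)
    ri, ci = np.meshgrid(r, c, indexing="ij")
    ri = ri.ravel()
    ci = ci.ravel()
    cheb = np.maximum(np.abs(ri[:, None] - ri[None, :]),
                      np.abs(ci[:, None] - ci[None, :]))
    mask = cheb <= radius
    mask.setflags(write=False)
    return mask


def neighborhood_mask(grid: PatchGrid, radius: int) -> np.ndarray:
    """(N, N) boolean support of local attention (Chebyshev distance on the
    patch grid, truncated at image borders, token i always included)."""
    return _neighborhood_mask_cached(grid.grid_rows, grid.grid_cols, radius)


def neighborhood_indices(i: int, grid: PatchGrid, radius: int) -> np.ndarray:
    """Indices of the local neighbourhood of token ``i`` (including i)."""
    if not 0 <= i < grid.n_patches:
        raise IndexError(f"token index {i} out of range")
    return np.flatnonzero(neighborhood_mask(grid, radius)[i])


def attention_rows(queries: np.ndarray, keys: np.ndarray,
                   support_mask: np.ndarray | None = None) -> np.ndarray:
    """Row-stochastic scaled dot-product attention.

    ``a_ij = exp(q_i . k_j / sqrt(d))`` normalised over each row's support;
    entries off support are exactly zero.
    """
    d = queries.shape[-1]
    if d <= 0:
        raise ValueError("query/key dimension must be positive")
    logits = np.einsum("...nd,...md->...nm", queries, keys) / np.sqrt(d)
    if support_mask is not None:
        if not support_mask.any(axis=-1).all():
            raise ValueError("every attention row needs a non-empty support")
        logits = np.where(support_mask, logits, -np.inf)
    m = logits.max(axis=-1, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=-1, keepdims=True)


def mixed_attention(a_local: np.ndarray, a_global: np.ndarray,
                    alpha: float) -> np.ndarray:
    """Convex mixture alpha * global + (1 - alpha) * local.

    Both operands are row-stochastic, so the result is row-stochastic with
    no renormalisation; the endpoints are bit-exact.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0,1], got {alpha}")
    if a_local.shape != a_global.shape:
        raise ValueError("local and global attention shapes differ")
    return alpha * a_global + (1.0 - alpha) * a_local


# ---------------------------------------------------------------------------
# alpha schedule


def alpha_values(config: EncoderConfig, params: Params | None = None) -> np.ndarray:
    """Per-layer mixing coefficients alpha(l), monotone non-decreasing.

    fixed_linear: alpha(l) = l / L.
    fixed_constant: a constant (alpha == 1 recovers a plain global ViT).
    learnable_monotone: sigmoid of a base logit plus a cumulative sum of
    softplus-mapped increments (monotone by construction).
    """
    L = config.n_layers
    if config.alpha_mode == "fixed_linear":
        return np.arange(1, L + 1, dtype=float) / L
    if config.alpha_mode == "fixed_constant":
        return np.full(L, float(config.alpha_constant))
    z = params["alpha_base"] + np.concatenate(
        [[0.0], np.cumsum(_softplus(params["alpha_incr"]))])
    return _sigmoid(z)


def _alpha_backward(d_alpha: np.ndarray, config: EncoderConfig,
                    params: Params, grads: Params) -> None:
    if config.alpha_mode != "learnable_monotone":
        return
    z = params["alpha_base"] + np.concatenate(
        [[0.0], np.cumsum(_softplus(params["alpha_incr"]))])
    a = _sigmoid(z)
    dz = d_alpha * a * (1.0 - a)
    grads["alpha_base"] = grads.get("alpha_base", 0.0) + dz.sum()
    # layer l depends on increments j < l
    tail = np.cumsum(dz[::-1])[::-1]  # tail[j] = sum_{l >= j} dz_l
    dincr = tail[1:] * _sigmoid(params["alpha_incr"])
    grads["alpha_incr"] = grads.get("alpha_incr", 0.0) + dincr


# ---------------------------------------------------------------------------
# parameters


def _trunc_normal(rng, shape, sd=0.02):
    return truncnorm.rvs(-2.0, 2.0, scale=sd, size=shape, random_state=rng)


def init_encoder_params(config: EncoderConfig, seed: int = 0,
                        rng: np.random.Generator | None = None) -> Params:
    """Truncated-normal projections (sd ``config.init_sd``), zero
    positional table, zero fusion logits (equal beta at initialisation).

    The desk-scale default sd is 0.1: at small embedding widths the
    conventional 0.02 leaves initial features too weak for lesion
    detectors to form within short training budgets; the GPU-scale preset
    keeps 0.02.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    sd = config.init_sd
    E, H, d = config.embed_dim, config.n_heads, config.head_dim
    Pd = config.patch_grid.patch_dim
    params: Params = {
        "patch_proj": _trunc_normal(rng, (E, Pd), sd),
        "pos": np.zeros((config.patch_grid.n_patches, E)),
        "fusion_logits": np.zeros(config.n_levels),
    }
    for l in range(1, config.n_layers + 1):
        p = f"layers.{l}."
        params[p + "wq"] = _trunc_normal(rng, (H, d, E), sd)
        params[p + "wk"] = _trunc_normal(rng, (H, d, E), sd)
        params[p + "wv"] = _trunc_normal(rng, (H, d, E), sd)
        params[p + "wo"] = _trunc_normal(rng, (E, E), sd)
        params[p + "w1"] = _trunc_normal(rng, (config.hidden_dim, E), sd)
        params[p + "w2"] = _trunc_normal(rng, (E, config.hidden_dim), sd)
        if config.stabilized:
            params[p + "ln1_gain"] = np.ones(E)
            params[p + "ln1_bias"] = np.zeros(E)
            params[p + "ln2_gain"] = np.ones(E)
            params[p + "ln2_bias"] = np.zeros(E)
    if config.alpha_mode == "learnable_monotone":
        params["alpha_base"] = np.array(-1.0)
        params["alpha_incr"] = np.zeros(max(config.n_layers - 1, 0))
    return params


# ---------------------------------------------------------------------------
# forward


def embed_tokens(patches: np.ndarray, params: Params,
                 use_positional: bool = True) -> np.ndarray:
    """t_i = W_p z_i + p_i for every patch (works batched or single)."""
    pos = params["pos"]
    if patches.shape[-2] != pos.shape[0]:
        raise ValueError("patch count does not match the positional table")
    e = patches @ params["patch_proj"].T
    return e + pos if use_positional else e


def _project_heads(u, w):
    """(B,N,E) x (H,d,E) -> (B,H,N,d) via one gemm."""
    B, N, E = u.shape
    H, d, _ = w.shape
    flat = u.reshape(B * N, E) @ w.reshape(H * d, E).T
    return flat.reshape(B, N, H, d).transpose(0, 2, 1, 3)


def _project_heads_grad(dq, u, w, grads, key):
    """Accumulate dW for q = _project_heads(u, w); return du contribution."""
    B, H, N, d = dq.shape
    E = u.shape[-1]
    dq_flat = dq.transpose(0, 2, 1, 3).reshape(B * N, H * d)
    grads[key] = grads.get(key, 0.0) + (
        dq_flat.T @ u.reshape(B * N, E)).reshape(H, d, E)
    return (dq_flat @ w.reshape(H * d, E)).reshape(B, N, E)


def _local_rows_from_exp(e, nb_mask, logits):
    """Local softmax sharing the globally shifted exponentials; falls back
    to an independently shifted computation if the shared shift underflows
    a whole support row."""
    el = e * nb_mask
    denom = el.sum(axis=-1, keepdims=True)
    bad = denom == 0.0
    if bad.any():
        masked = np.where(nb_mask, logits, -np.inf)
        ml = masked.max(axis=-1, keepdims=True)
        el2 = np.exp(masked - ml)
        el = np.where(bad, el2, el)
        denom = el.sum(axis=-1, keepdims=True)
    return el / denom


def _attention_block(u, params, prefix, alpha, nb_mask, config,
                     keep_all_maps: bool = True):
    """Multi-head mixed attention + head merge.  Returns (merged, cache).

    With ``keep_all_maps`` False, the branch that gets zero convex weight
    at an alpha endpoint is skipped (its map is cached as None).
    """
    B, N, E = u.shape
    H, d = config.n_heads, config.head_dim
    q = _project_heads(u, params[prefix + "wq"])
    k = _project_heads(u, params[prefix + "wk"])
    v = _project_heads(u, params[prefix + "wv"])
    logits = (q @ k.transpose(0, 1, 3, 2)) / np.sqrt(d)  # (B,H,N,N)
    m = logits.max(axis=-1, keepdims=True)
    e = np.exp(logits - m)
    need_global = keep_all_maps or alpha > 0.0
    need_local = keep_all_maps or alpha < 1.0
    a_global = e / e.sum(axis=-1, keepdims=True) if need_global else None
    a_local = (_local_rows_from_exp(e, nb_mask, logits)
               if need_local else None)
    if a_local is None:
        a_mix = a_global
    elif a_global is None:
        a_mix = a_local
    else:
        a_mix = mixed_attention(a_local, a_global, alpha)
    s = a_mix @ v
    s_concat = s.transpose(0, 2, 1, 3).reshape(B, N, E)
    merged = s_concat.reshape(B * N, E) @ params[prefix + "wo"].T
    merged = merged.reshape(B, N, E)
    cache = {"u": u, "q": q, "k": k, "v": v, "a_global": a_global,
             "a_local": a_local, "a_mix": a_mix, "s_concat": s_concat,
             "alpha": alpha}
    return merged, cache


def _attention_block_backward(d_merged, cache, params, prefix, grads, config):
    u, q, k, v = cache["u"], cache["q"], cache["k"], cache["v"]
    a_g, a_l, a_mix = cache["a_global"], cache["a_local"], cache["a_mix"]
    alpha = cache["alpha"]
    B, N, E = u.shape
    H, d = config.n_heads, config.head_dim
    wo = params[prefix + "wo"]
    dm_flat = d_merged.reshape(B * N, E)
    grads[prefix + "wo"] = grads.get(prefix + "wo", 0.0) + (
        dm_flat.T @ cache["s_concat"].reshape(B * N, E))
    ds_concat = dm_flat @ wo
    ds = ds_concat.reshape(B, N, H, d).transpose(0, 2, 1, 3)  # (B,H,N,d)

    dA = ds @ v.transpose(0, 1, 3, 2)              # (B,H,N,N)
    dv = a_mix.transpose(0, 1, 3, 2) @ ds          # (B,H,N,d)
    d_alpha = (float(np.sum(dA * (a_g - a_l)))
               if a_g is not None and a_l is not None else 0.0)
    dlog = 0.0
    if a_g is not None and alpha > 0.0:
        da_g = alpha * dA
        dlog = a_g * (da_g - (da_g * a_g).sum(-1, keepdims=True))
    if a_l is not None and alpha < 1.0:
        da_l = (1.0 - alpha) * dA
        dlog = dlog + a_l * (da_l - (da_l * a_l).sum(-1, keepdims=True))
    scale = 1.0 / np.sqrt(d)
    dq = (dlog @ k) * scale
    dk = (dlog.transpose(0, 1, 3, 2) @ q) * scale

    du = _project_heads_grad(dq, u, params[prefix + "wq"], grads, prefix + "wq")
    du += _project_heads_grad(dk, u, params[prefix + "wk"], grads, prefix + "wk")
    du += _project_heads_grad(dv, u, params[prefix + "wv"], grads, prefix + "wv")
    return du, d_alpha


def _ffn_forward(x, params, prefix):
    B, N, E = x.shape
    pre = (x.reshape(B * N, E) @ params[prefix + "w1"].T).reshape(B, N, -1)
    phi = special.ndtr(pre)   # cached so the backward pass reuses it
    act = pre * phi
    out = (act.reshape(B * N, -1) @ params[prefix + "w2"].T).reshape(B, N, E)
    return out, (x, pre, phi, act)


def _ffn_backward(dout, cache, params, prefix, grads):
    x, pre, phi, act = cache
    B, N, E = x.shape
    hid = pre.shape[-1]
    dout_flat = dout.reshape(B * N, E)
    grads[prefix + "w2"] = grads.get(prefix + "w2", 0.0) + (
        dout_flat.T @ act.reshape(B * N, hid))
    dact = dout_flat @ params[prefix + "w2"]
    dgelu = phi + pre * np.exp(-0.5 * pre * pre) / _SQRT2PI
    dpre = dact.reshape(B, N, hid) * dgelu
    dpre_flat = dpre.reshape(B * N, hid)
    grads[prefix + "w1"] = grads.get(prefix + "w1", 0.0) + (
        dpre_flat.T @ x.reshape(B * N, E))
    return (dpre_flat @ params[prefix + "w1"]).reshape(B, N, E)


def _layer_forward(x, params, layer: int, alpha: float, nb_mask, config,
                   keep_all_maps: bool = True):
    prefix = f"layers.{layer}."
    cache = {"x_in": x}
    if config.stabilized:
        u, cache["ln1"] = _layer_norm_forward(
            x, params[prefix + "ln1_gain"], params[prefix + "ln1_bias"])
        merged, cache["attn"] = _attention_block(u, params, prefix, alpha,
                                                 nb_mask, config, keep_all_maps)
        x2 = x + merged
        w, cache["ln2"] = _layer_norm_forward(
            x2, params[prefix + "ln2_gain"], params[prefix + "ln2_bias"])
        f, cache["ffn"] = _ffn_forward(w, params, prefix)
        out = x2 + f
        cache["x2"] = x2
    else:
        merged, cache["attn"] = _attention_block(x, params, prefix, alpha,
                                                 nb_mask, config, keep_all_maps)
        f, cache["ffn"] = _ffn_forward(merged, params, prefix)
        out = x + f
    return out, cache


def _layer_backward(dout, cache, params, layer: int, grads, config):
    prefix = f"layers.{layer}."
    if config.stabilized:
        dx2 = dout.copy()
        dw = _ffn_backward(dout, cache["ffn"], params, prefix, grads)
        dx2_ln, dg, db = _layer_norm_backward(dw, cache["ln2"],
                                              params[prefix + "ln2_gain"])
        grads[prefix + "ln2_gain"] = grads.get(prefix + "ln2_gain", 0.0) + dg
        grads[prefix + "ln2_bias"] = grads.get(prefix + "ln2_bias", 0.0) + db
        dx2 = dx2 + dx2_ln
        dx = dx2.copy()
        du, d_alpha = _attention_block_backward(dx2, cache["attn"], params,
                                                prefix, grads, config)
        dx_ln, dg, db = _layer_norm_backward(du, cache["ln1"],
                                             params[prefix + "ln1_gain"])
        grads[prefix + "ln1_gain"] = grads.get(prefix + "ln1_gain", 0.0) + dg
        grads[prefix + "ln1_bias"] = grads.get(prefix + "ln1_bias", 0.0) + db
        dx = dx + dx_ln
        return dx, d_alpha
    dx = dout.copy()
    dmerged = _ffn_backward(dout, cache["ffn"], params, prefix, grads)
    du, d_alpha = _attention_block_backward(dmerged, cache["attn"], params,
                                            prefix, grads, config)
    return dx + du, d_alpha


def encoder_layer(tokens: np.ndarray, params: Params, layer: int,
                  alpha: float, config: EncoderConfig):
    """One encoder layer on a single (N, E) token sequence.

    Returns (new_tokens, attention) where ``attention`` holds the per-head
    local/global/mixed row-stochastic matrices of this layer.
    """
    nb = neighborhood_mask(config.patch_grid, config.neighborhood_radius)
    out, cache = _layer_forward(tokens[None], params, layer, alpha, nb, config)
    attn = {k: cache["attn"][k][0] for k in ("a_local", "a_global", "a_mix")}
    return out[0], attn


def pool_level(tokens: np.ndarray) -> np.ndarray:
    """Arithmetic mean over the token axis (h^(k))."""
    tokens = np.asarray(tokens)
    if tokens.shape[-2] < 1:
        raise ValueError("need at least one token")
    return tokens.mean(axis=-2)


def fuse_levels(level_pools: np.ndarray, fusion_logits: np.ndarray):
    """h = sum_k beta_k h^(k) with beta = softmax(fusion_logits).

    Returns (fused, beta); beta is non-negative and sums to one by
    construction.
    """
    beta = softmax(np.asarray(fusion_logits, dtype=float))
    level_pools = np.asarray(level_pools)
    fused = np.tensordot(beta, level_pools, axes=([0], [level_pools.ndim - 2]))
    return fused, beta


@dataclass
class GlobalRepresentation:
    """Output of the full encoder on one image."""

    fused: np.ndarray                 # (E,)
    level_pools: np.ndarray           # (K, E)
    beta: np.ndarray                  # (K,)
    final_tokens: np.ndarray          # (N, E)
    attention: list = field(default_factory=list)  # per layer dicts of (H,N,N)


def encoder_forward(patches: np.ndarray, params: Params, config: EncoderConfig,
                    want_cache: bool = False, store_attention: bool = True) -> dict:
    """Batched forward pass: patches (B, N, P^2 C) -> fused (B, E).

    With ``want_cache`` the returned dict also carries everything the
    backward pass needs.
    """
    nb = neighborhood_mask(config.patch_grid, config.neighborhood_radius)
    alphas = alpha_values(config, params)
    t = embed_tokens(patches, params, config.use_positional)
    layer_caches = []
    attention = []
    pools = {}
    x = t
    for l in range(1, config.n_layers + 1):
        x, cache = _layer_forward(x, params, l, alphas[l - 1], nb, config,
                                  keep_all_maps=store_attention)
        if l in config.fusion_depths:
            pools[l] = x.mean(axis=1)
        if store_attention:
            attention.append({k: cache["attn"][k]
                              for k in ("a_local", "a_global", "a_mix")})
        layer_caches.append(cache)
    level = np.stack([pools[l] for l in config.fusion_depths], axis=1)  # (B,K,E)
    fused, beta = fuse_levels(level, params["fusion_logits"])
    out = {"fused": fused, "level_pools": level, "beta": beta,
           "final_tokens": x, "attention": attention, "alphas": alphas}
    if want_cache:
        out["cache"] = {"patches": patches, "layers": layer_caches}
    return out


def encoder_backward(d_fused: np.ndarray, fwd: dict, params: Params,
                     config: EncoderConfig) -> Params:
    """Analytic gradients of a scalar loss w.r.t. every encoder parameter,
    given dL/dh (B, E) and the cached forward pass."""
    cache = fwd["cache"]
    level, beta = fwd["level_pools"], fwd["beta"]
    grads: Params = {}

    # fusion: h = sum_k beta_k h^(k), beta = softmax(logits)
    dlevel = beta[None, :, None] * d_fused[:, None, :]          # (B,K,E)
    dbeta = np.einsum("be,bke->k", d_fused, level)
    grads["fusion_logits"] = beta * (dbeta - np.dot(beta, dbeta))

    B, _, E = level.shape
    N = config.patch_grid.n_patches
    pool_grad = {l: dlevel[:, k, :] / N
                 for k, l in enumerate(config.fusion_depths)}

    dx = np.zeros((B, N, E))
    d_alpha = np.zeros(config.n_layers)
    for l in range(config.n_layers, 0, -1):
        if l in pool_grad:
            dx = dx + pool_grad[l][:, None, :]
        dx, da = _layer_backward(dx, cache["layers"][l - 1], params, l,
                                 grads, config)
        d_alpha[l - 1] = da
    _alpha_backward(d_alpha, config, params, grads)

    # embedding: t = Z W_p^T + pos
    grads["patch_proj"] = np.einsum("bne,bnd->ed", dx, cache["patches"])
    if config.use_positional:
        grads["pos"] = dx.sum(axis=0)
    else:
        grads["pos"] = np.zeros_like(params["pos"])
    return grads


def encode(image: np.ndarray, stats, grid: PatchGrid, config: EncoderConfig,
           params: Params, fov_mask: np.ndarray | None = None) -> GlobalRepresentation:
    """Full single-image path: preprocessing -> embedding -> L layers ->
    multi-depth pooling -> beta-fusion."""
    from .preprocessing import preprocess

    patches, _ = preprocess(image, stats, grid, fov_mask)
    out = encoder_forward(patches[None], params, config)
    return GlobalRepresentation(
        fused=out["fused"][0],
        level_pools=out["level_pools"][0],
        beta=out["beta"],
        final_tokens=out["final_tokens"][0],
        attention=[{k: a[k][0] for k in a} for a in out["attention"]],
    )
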