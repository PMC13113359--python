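"""Naive nested-loop reference encoder used as an independent oracle.

Implements the token embedding, the L mixed local/global attention layers
(literal single-residual form, no layer norm), the multi-depth mean
pooling and the softmax-weighted fusion entirely with explicit Python
loops over tokens, heads and channels.  Deliberately shares no array code
with the package implementation.
"""

import math

import numpy as np


def _phi(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def _gelu(x: float) -> float:
    return x * _phi(x)


def _neighbors(i: int, rows: int, cols: int, radius: int) -> list[int]:
    ri, ci = divmod(i, cols)
    out = []
    for j in range(rows * cols):
        rj, cj = divmod(j, cols)
        if max(abs(ri - rj), abs(ci - cj)) <= radius:
            out.append(j)
    return out


def _softmax_over(logit_row, support):
    m = max(logit_row[j] for j in support)
    exps = {j: math.exp(logit_row[j] - m) for j in support}
    z = sum(exps.values())
    return {j: exps[j] / z for j in support}


def naive_encoder(patches, params, config):
    """Forward pass on one (N, Pd) patch array; returns a dict with the
    fused vector, per-level pools, final tokens and per-layer mixed
    attention (averaged over nothing -- kept per head)."""
    assert not config.stabilized, "reference covers the literal form only"
    N, Pd = patches.shape
    E = config.embed_dim
    H = config.n_heads
    d = config.head_dim
    rows, cols = config.patch_grid.grid_rows, config.patch_grid.grid_cols
    radius = config.neighborhood_radius
    L = config.n_layers

    if config.alpha_mode == "fixed_linear":
        alphas = [(l + 1) / L for l in range(L)]
    elif config.alpha_mode == "fixed_constant":
        alphas = [config.alpha_constant] * L
    else:
        raise NotImplementedError

    # embedding: t_i = W_p z_i + p_i
    Wp = params["patch_proj"]
    tokens = []
    for i in range(N):
        t = [sum(Wp[e][p] * patches[i][p] for p in range(Pd))
             + (params["pos"][i][e] if config.use_positional else 0.0)
             for e in range(E)]
        tokens.append(t)

    attention_layers = []
    pools = {}
    for l in range(1, L + 1):
        pref = f"layers.{l}."
        wq, wk, wv = params[pref + "wq"], params[pref + "wk"], params[pref + "wv"]
        alpha = alphas[l - 1]
        s_cat = [[0.0] * E for _ in range(N)]
        attn_heads = []
        for h in range(H):
            q = [[sum(wq[h][a][e] * tokens[i][e] for e in range(E))
                  for a in range(d)] for i in range(N)]
            k = [[sum(wk[h][a][e] * tokens[i][e] for e in range(E))
                  for a in range(d)] for i in range(N)]
            v = [[sum(wv[h][a][e] * tokens[i][e] for e in range(E))
                  for a in range(d)] for i in range(N)]
            logits = [[sum(q[i][a] * k[j][a] for a in range(d)) / math.sqrt(d)
                       for j in range(N)] for i in range(N)]
            amix = np.zeros((N, N))
            for i in range(N):
                glob = _softmax_over(logits[i], range(N))
                loc = _softmax_over(logits[i], _neighbors(i, rows, cols, radius))
                for j in range(N):
                    amix[i][j] = (alpha * glob[j]
                                  + (1 - alpha) * loc.get(j, 0.0))
            for i in range(N):
                for a in range(d):
                    s_cat[i][h * d + a] = sum(amix[i][j] * v[j][a]
                                              for j in range(N))
            attn_heads.append(amix)
        attention_layers.append(np.stack(attn_heads))
        wo, w1, w2 = params[pref + "wo"], params[pref + "w1"], params[pref + "w2"]
        hid = w1.shape[0]
        new_tokens = []
        for i in range(N):
            merged = [sum(wo[e][f] * s_cat[i][f] for f in range(E))
                      for e in range(E)]
            act = [_gelu(sum(w1[g][e] * merged[e] for e in range(E)))
                   for g in range(hid)]
            ffn = [sum(w2[e][g] * act[g] for g in range(hid))
                   for e in range(E)]
            new_tokens.append([tokens[i][e] + ffn[e] for e in range(E)])
        tokens = new_tokens
        if l in config.fusion_depths:
            pools[l] = [sum(tokens[i][e] for i in range(N)) / N
                        for e in range(E)]

    logits_b = params["fusion_logits"]
    mx = max(logits_b)
    exps = [math.exp(b - mx) for b in logits_b]
    z = sum(exps)
    beta = [e / z for e in exps]
    fused = [sum(beta[kk] * pools[dep][e]
                 for kk, dep in enumerate(config.fusion_depths))
             for e in range(E)]
    return {
        "fused": np.array(fused),
        "level_pools": np.array([pools[dep] for dep in config.fusion_depths]),
        "beta": np.array(beta),
        "final_tokens": np.array(tokens),
        "attention": attention_layers,
    }
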