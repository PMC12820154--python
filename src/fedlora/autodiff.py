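"""Forward and backward passes for the transformer, written against the flat
parameter dictionary.

There is a single source of truth for the forward computation: eval-mode
inference (`fedlora.vit.forward_logits`) and training both route through
:func:`model_forward`.  The backward pass is hand-derived and verified in the
test suite against central finite differences on a small configuration.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy.special import erf

from .errors import ShapeError

_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)
_LN_EPS = 1e-6


# ---------------------------------------------------------------------------
# primitives


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def gelu(u: np.ndarray) -> np.ndarray:
    return 0.5 * u * (1.0 + erf(u / _SQRT2))


def gelu_grad(u: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(u / _SQRT2)) + u * _INV_SQRT_2PI * np.exp(-0.5 * u * u)


def layernorm_forward(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    rstd = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * rstd
    return xhat * g + b, (xhat, rstd, g)


def layernorm_backward(dy, cache):
    xhat, rstd, g = cache
    dxhat = dy * g
    axes = tuple(range(dy.ndim - 1))
    dg = (dy * xhat).sum(axis=axes)
    db = dy.sum(axis=axes)
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = rstd * (dxhat - m1 - xhat * m2)
    return dx, dg, db


def _dropout(x, p, train, rng):
    """Inverted dropout; returns (output, mask) with mask already scaled."""
    if not train or p <= 0.0:
        return x, None
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * mask, mask


def lora_scaling(cfg) -> float:
    if cfg.scaling_convention == "alpha_over_r":
        return cfg.alpha / cfg.rank
    return float(cfg.alpha)


# ---------------------------------------------------------------------------
# encoder block


def block_forward(x, params, i, cfg, lora_cfg, train=False, rng=None):
    """One pre-norm block: x + MHSA(LN(x)), then x + MLP(LN(x)).

    Returns (output, cache); cache carries everything backward needs plus the
    per-head attention weights (B, H, T, T) for explainability.
    """
    p = f"blocks.{i}"
    d, H, dh = cfg.embed_dim, cfg.num_heads, cfg.head_dim
    B, T, _ = x.shape

    h, ln1c = layernorm_forward(x, params[f"{p}.ln1.weight"], params[f"{p}.ln1.bias"])
    qkv = h @ params[f"{p}.attn.qkv.weight"] + params[f"{p}.attn.qkv.bias"]
    q, k, v = qkv[..., :d], qkv[..., d : 2 * d], qkv[..., 2 * d :]

    adapters = {}
    for name, sl in (("query", 0), ("value", 2)):
        a_key = f"{p}.attn.{name}.lora_A"
        if a_key in params:
            A, Bm = params[a_key], params[f"{p}.attn.{name}.lora_B"]
            s = lora_scaling(lora_cfg)
            hd, mask = _dropout(h, lora_cfg.dropout, train, rng)
            low = hd @ A  # (B, T, r)
            delta = s * (low @ Bm)
            if name == "query":
                q = q + delta
            else:
                v = v + delta
            adapters[name] = {"A": A, "B": Bm, "s": s, "hd": hd, "low": low, "mask": mask}

    def split_heads(t):
        return t.reshape(B, T, H, dh).transpose(0, 2, 1, 3)

    qh, kh, vh = split_heads(q), split_heads(k), split_heads(v)
    scale = 1.0 / math.sqrt(dh)
    scores = (qh @ kh.swapaxes(-1, -2)) * scale
    attn = softmax(scores, axis=-1)
    o = attn @ vh  # (B, H, T, dh)
    om = o.transpose(0, 2, 1, 3).reshape(B, T, d)
    attn_out = om @ params[f"{p}.attn.proj.weight"] + params[f"{p}.attn.proj.bias"]
    x1 = x + attn_out

    h2, ln2c = layernorm_forward(x1, params[f"{p}.ln2.weight"], params[f"{p}.ln2.bias"])
    u = h2 @ params[f"{p}.mlp.fc1.weight"] + params[f"{p}.mlp.fc1.bias"]
    gu = gelu(u)
    m = gu @ params[f"{p}.mlp.fc2.weight"] + params[f"{p}.mlp.fc2.bias"]
    out = x1 + m

    cache = {
        "h": h,
        "ln1c": ln1c,
        "qh": qh,
        "kh": kh,
        "vh": vh,
        "attn_weights": attn,
        "om": om,
        "h2": h2,
        "ln2c": ln2c,
        "u": u,
        "gu": gu,
        "adapters": adapters,
        "scale": scale,
    }
    return out, cache


def block_backward(dout, cache, params, i, cfg, grads):
    p = f"blocks.{i}"
    d, H, dh = cfg.embed_dim, cfg.num_heads, cfg.head_dim
    h, h2, gu, u = cache["h"], cache["h2"], cache["gu"], cache["u"]
    B, T, _ = h.shape

    def flat(t):
        return t.reshape(-1, t.shape[-1])

    # MLP branch (dout hits both m and the residual x1)
    W2 = params[f"{p}.mlp.fc2.weight"]
    W1 = params[f"{p}.mlp.fc1.weight"]
    grads[f"{p}.mlp.fc2.weight"] = flat(gu).T @ flat(dout)
    grads[f"{p}.mlp.fc2.bias"] = dout.sum(axis=(0, 1))
    dgu = dout @ W2.T
    du = dgu * gelu_grad(u)
    grads[f"{p}.mlp.fc1.weight"] = flat(h2).T @ flat(du)
    grads[f"{p}.mlp.fc1.bias"] = du.sum(axis=(0, 1))
    dh2 = du @ W1.T
    dx1, dg2, db2 = layernorm_backward(dh2, cache["ln2c"])
    grads[f"{p}.ln2.weight"] = dg2
    grads[f"{p}.ln2.bias"] = db2
    dx1 = dx1 + dout

    # attention output projection
    Wproj = params[f"{p}.attn.proj.weight"]
    grads[f"{p}.attn.proj.weight"] = flat(cache["om"]).T @ flat(dx1)
    grads[f"{p}.attn.proj.bias"] = dx1.sum(axis=(0, 1))
    dom = dx1 @ Wproj.T
    do = dom.reshape(B, T, H, dh).transpose(0, 2, 1, 3)

    attn, qh, kh, vh = cache["attn_weights"], cache["qh"], cache["kh"], cache["vh"]
    dattn = do @ vh.swapaxes(-1, -2)
    dvh = attn.swapaxes(-1, -2) @ do
    ds = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
    scale = cache["scale"]
    dqh = (ds @ kh) * scale
    dkh = (ds.swapaxes(-1, -2) @ qh) * scale

    def merge_heads(t):
        return t.transpose(0, 2, 1, 3).reshape(B, T, d)

    dq, dk, dv = merge_heads(dqh), merge_heads(dkh), merge_heads(dvh)

    dh_extra = np.zeros_like(h)
    for name, dslice in (("query", dq), ("value", dv)):
        ad = cache["adapters"].get(name)
        if ad is None:
            continue
        s, A, Bm, hd, low, mask = ad["s"], ad["A"], ad["B"], ad["hd"], ad["low"], ad["mask"]
        dlow = s * (dslice @ Bm.T)  # (B, T, r)
        grads[f"{p}.attn.{name}.lora_B"] = s * (flat(low).T @ flat(dslice))
        grads[f"{p}.attn.{name}.lora_A"] = flat(hd).T @ flat(dlow)
        dhd = dlow @ A.T
        dh_extra += dhd if mask is None else dhd * mask

    dqkv = np.concatenate([dq, dk, dv], axis=-1)
    Wqkv = params[f"{p}.attn.qkv.weight"]
    grads[f"{p}.attn.qkv.weight"] = flat(h).T @ flat(dqkv)
    grads[f"{p}.attn.qkv.bias"] = dqkv.sum(axis=(0, 1))
    dh_total = dqkv @ Wqkv.T + dh_extra
    dx0, dg1, db1 = layernorm_backward(dh_total, cache["ln1c"])
    grads[f"{p}.ln1.weight"] = dg1
    grads[f"{p}.ln1.bias"] = db1
    return dx1 + dx0


# ---------------------------------------------------------------------------
# full model


def model_forward(model, images, train=False, rng=None, need_cache=False):
    """Returns (logits, aux).  aux carries caches and per-block attention."""
    from .vit import patchify

    cfg = model.config
    params = model.params
    xp = patchify(images, cfg)
    z = xp @ params["patch_embed.weight"] + params["patch_embed.bias"]
    cls = np.broadcast_to(params["cls_token"], (z.shape[0], 1, cfg.embed_dim))
    z = np.concatenate([cls, z], axis=1) + params["pos_embed"]
    caches = []
    for i in range(cfg.depth):
        z, c = block_forward(z, params, i, cfg, model.lora, train=train, rng=rng)
        caches.append(c)
    zf, lnfc = layernorm_forward(z, params["norm.weight"], params["norm.bias"])
    logits = zf[:, 0] @ params["head.weight"] + params["head.bias"]
    aux = {"attn": [c["attn_weights"] for c in caches]}
    if need_cache:
        aux.update({"xp": xp, "caches": caches, "lnfc": lnfc, "cls_out": zf[:, 0], "zf_shape": zf.shape})
    return logits, aux


def model_backward(model, dlogits, aux):
    """Gradients for every parameter given d(loss)/d(logits)."""
    cfg = model.config
    params = model.params
    grads: dict[str, np.ndarray] = {}
    grads["head.weight"] = aux["cls_out"].T @ dlogits
    grads["head.bias"] = dlogits.sum(axis=0)
    dzf = np.zeros(aux["zf_shape"], dtype=dlogits.dtype)
    dzf[:, 0] = dlogits @ params["head.weight"].T
    dz, dgf, dbf = layernorm_backward(dzf, aux["lnfc"])
    grads["norm.weight"] = dgf
    grads["norm.bias"] = dbf
    for i in reversed(range(cfg.depth)):
        dz = block_backward(dz, aux["caches"][i], params, i, cfg, grads)
    grads["pos_embed"] = dz.sum(axis=0)
    grads["cls_token"] = dz[:, 0].sum(axis=0)
    dzp = dz[:, 1:]
    xp = aux["xp"]
    grads["patch_embed.weight"] = xp.reshape(-1, xp.shape[-1]).T @ dzp.reshape(
        -1, cfg.embed_dim
    )
    grads["patch_embed.bias"] = dzp.sum(axis=(0, 1))
    return grads


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. logits."""
    labels = np.asarray(labels)
    if logits.shape[0] != labels.shape[0]:
        raise ShapeError("logits/labels length mismatch")
    z = logits - logits.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - lse
    n = logits.shape[0]
    ce = -logp[np.arange(n), labels].mean()
    dlogits = (np.exp(logp) - np.eye(logits.shape[1])[labels]) / n
    return float(ce), dlogits


def loss_and_grads(
    model,
    images,
    labels,
    mu: float = 0.0,
    anchor: Optional[dict] = None,
    train: bool = True,
    rng: Optional[np.random.Generator] = None,
):
    """Cross-entropy (+ proximal term) and gradients for trainable tensors.

    The proximal part follows the FedProx objective: mu/2 * ||w - w_anchor||^2
    over the trainable tensors, with gradient mu * (w - w_anchor).
    """
    logits, aux = model_forward(model, images, train=train, rng=rng, need_cache=True)
    ce, dlogits = softmax_cross_entropy(logits, labels)
    grads = model_backward(model, dlogits, aux)
    grads = {k: g for k, g in grads.items() if model.trainable.get(k, False)}
    loss = ce
    if mu > 0.0 and anchor is not None:
        sq = 0.0
        for k in grads:
            diff = model.params[k] - anchor[k]
            grads[k] = grads[k] + mu * diff
            sq += float((diff * diff).sum())
        loss = ce + 0.5 * mu * sq
    return ce, loss, grads
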