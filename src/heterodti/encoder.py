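"""Multi-relational graph-convolutional encoder with edge attention.

Per layer, drug and target embeddings are updated simultaneously by

    Z_D <- relu(M_DD Z_D W_DD + M_DT Z_T W_DT + B_D)
    Z_T <- relu(M_TT Z_T W_TT + M_TD Z_D W_TD + B_T)

where M is the row-softmax-normalized block adjacency, optionally modulated
elementwise by a learned per-edge attention weight in (0, 1) and then
renormalized over the structural support so each connected node still
distributes unit weight over its neighbours.  Raw drug/target features enter
through a learned linear projection to the embedding width, and two decoder
MLPs map embeddings back to feature space for the reconstruction loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .graph import UnifiedGraph

__all__ = ["EncoderParams", "init_encoder_params", "attention_scores",
           "conv_layer", "encode", "reconstruction_loss"]

_BLOCKS = ("DD", "TT", "DT", "TD")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape=None) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


@dataclass
class AttentionMLP:
    """One hidden layer of width `hidden` with relu, scalar sigmoid output.

    The concatenation MLP([z_i || z_j]) is evaluated with the first-layer
    weight split into a source half and a destination half, which lets the
    dense (rows x cols) attention map be built by broadcasting.
    """

    W_src: Tensor
    W_dst: Tensor
    b1: Tensor
    w2: Tensor
    b2: Tensor

    def dense(self, Z_rows: Tensor, Z_cols: Tensor) -> Tensor:
        m = Z_rows.shape[0]
        n = Z_cols.shape[0]
        hid = self.W_src.shape[1]
        h_rows = (Z_rows @ self.W_src).reshape(m, 1, hid)
        h_cols = (Z_cols @ self.W_dst).reshape(1, n, hid)
        hidden = (h_rows + h_cols + self.b1).relu()
        pre = (hidden * self.w2).sum(axis=2) + self.b2
        return pre.sigmoid()

    def parameters(self):
        return [self.W_src, self.W_dst, self.b1, self.w2, self.b2]


@dataclass
class DecoderMLP:
    """Embedding -> feature decoder: one relu hidden layer then linear out."""

    W1: Tensor
    b1: Tensor
    W2: Tensor
    b2: Tensor

    def __call__(self, Z: Tensor) -> Tensor:
        return (Z @ self.W1 + self.b1).relu() @ self.W2 + self.b2

    def parameters(self):
        return [self.W1, self.b1, self.W2, self.b2]


@dataclass
class EncoderParams:
    """All trainable parameters of the encoder.

    Layer weights are per-layer; attention MLPs and decoders are shared
    across layers (one per block / entity class).
    """

    h: int
    L: int
    W_in_D: Tensor
    b_in_D: Tensor
    W_in_T: Tensor
    b_in_T: Tensor
    layers: list[dict] = field(default_factory=list)  # keys W_DD..W_TD, B_D, B_T
    attention: dict[str, AttentionMLP] = field(default_factory=dict)
    decoder_D: DecoderMLP | None = None
    decoder_T: DecoderMLP | None = None

    def parameters(self) -> list[Tensor]:
        params = [self.W_in_D, self.b_in_D, self.W_in_T, self.b_in_T]
        for layer in self.layers:
            params.extend(layer.values())
        for mlp in self.attention.values():
            params.extend(mlp.parameters())
        for dec in (self.decoder_D, self.decoder_T):
            if dec is not None:
                params.extend(dec.parameters())
        return params


def init_encoder_params(d: int, t: int, h: int, L: int,
                        rng: np.random.Generator) -> EncoderParams:
    """Glorot-uniform initialization of every weight; biases start at zero."""
    if h <= 0 or L < 1:
        raise ValueError("need embedding width h > 0 and L >= 1 layers")
    params = EncoderParams(
        h=h, L=L,
        W_in_D=_glorot(rng, d, h), b_in_D=Tensor(np.zeros((1, h)), True),
        W_in_T=_glorot(rng, t, h), b_in_T=Tensor(np.zeros((1, h)), True),
    )
    for _ in range(L):
        params.layers.append({
            "W_DD": _glorot(rng, h, h), "W_TT": _glorot(rng, h, h),
            "W_DT": _glorot(rng, h, h), "W_TD": _glorot(rng, h, h),
            "B_D": Tensor(np.zeros((1, h)), True),
            "B_T": Tensor(np.zeros((1, h)), True),
        })
    for block in _BLOCKS:
        params.attention[block] = AttentionMLP(
            W_src=_glorot(rng, h, h), W_dst=_glorot(rng, h, h),
            b1=Tensor(np.zeros(h), True),
            w2=_glorot(rng, h, 1, shape=(h,)),
            b2=Tensor(np.zeros(()), True),
        )
    params.decoder_D = DecoderMLP(
        W1=_glorot(rng, h, h), b1=Tensor(np.zeros((1, h)), True),
        W2=_glorot(rng, h, d), b2=Tensor(np.zeros((1, d)), True))
    params.decoder_T = DecoderMLP(
        W1=_glorot(rng, h, h), b1=Tensor(np.zeros((1, h)), True),
        W2=_glorot(rng, h, t), b2=Tensor(np.zeros((1, t)), True))
    return params


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def attention_scores(Z_D: Tensor | np.ndarray, Z_T: Tensor | np.ndarray,
                     graph: UnifiedGraph, params: EncoderParams,
                     block: str) -> np.ndarray:
    """Dense attention map for one block; entries off the structural support
    are exactly 0, supported entries lie in (0, 1)."""
    Z_D, Z_T = _as_tensor(Z_D), _as_tensor(Z_T)
    rows, cols = {"DD": (Z_D, Z_D), "TT": (Z_T, Z_T),
                  "DT": (Z_D, Z_T), "TD": (Z_T, Z_D)}[block]
    alpha = params.attention[block].dense(rows, cols).data
    return alpha * graph.support(block)


def _message_matrix(N_block: np.ndarray, alpha: Tensor | None,
                    support: np.ndarray, renormalize: bool) -> Tensor:
    """Effective message operator M for one block.

    Without attention M is the (constant) normalized adjacency.  With
    attention M = N ⊙ alpha; applied literally this leaves rows
    sub-stochastic, so by default rows are renormalized over the support
    (empty-support rows stay zero).
    """
    N = Tensor(N_block)
    if alpha is None:
        return N
    M_raw = N * alpha
    if not renormalize:
        return M_raw
    row_sum = M_raw.sum(axis=1, keepdims=True)
    empty = (~support.any(axis=1)).astype(float).reshape(-1, 1)
    return M_raw / (row_sum + Tensor(empty))  # empty rows: 0 / 1 = 0


def conv_layer(Z_D: Tensor | np.ndarray, Z_T: Tensor | np.ndarray,
               graph: UnifiedGraph, params: EncoderParams, layer: int,
               use_attention: bool = True,
               renormalize: bool = True) -> tuple[Tensor, Tensor]:
    """One simultaneous block message-passing update of (Z_D, Z_T)."""
    Z_D, Z_T = _as_tensor(Z_D), _as_tensor(Z_T)
    if Z_D.shape != (graph.m, params.h) or Z_T.shape != (graph.n, params.h):
        raise ValueError(
            f"embedding shapes {Z_D.shape}/{Z_T.shape} do not match graph "
            f"({graph.m}, {params.h})/({graph.n}, {params.h})")
    lw = params.layers[layer]
    src = {"DD": (Z_D, Z_D), "TT": (Z_T, Z_T),
           "DT": (Z_D, Z_T), "TD": (Z_T, Z_D)}
    M = {}
    for block in _BLOCKS:
        alpha = None
        if use_attention:
            rows, cols = src[block]
            alpha = params.attention[block].dense(rows, cols)
        M[block] = _message_matrix(
            getattr(graph, f"N_{block}"), alpha, graph.support(block),
            renormalize)
    Z_D_new = (M["DD"] @ Z_D @ lw["W_DD"] + M["DT"] @ Z_T @ lw["W_DT"]
               + lw["B_D"]).relu()
    Z_T_new = (M["TT"] @ Z_T @ lw["W_TT"] + M["TD"] @ Z_D @ lw["W_TD"]
               + lw["B_T"]).relu()
    return Z_D_new, Z_T_new


def encode(X_D, X_T, graph: UnifiedGraph, params: EncoderParams,
           use_attention: bool = True,
           renormalize: bool = True) -> tuple[Tensor, Tensor]:
    """Project raw features to width h, then apply all L conv layers."""
    Z_D = _as_tensor(X_D) @ params.W_in_D + params.b_in_D
    Z_T = _as_tensor(X_T) @ params.W_in_T + params.b_in_T
    for layer in range(params.L):
        Z_D, Z_T = conv_layer(Z_D, Z_T, graph, params, layer,
                              use_attention=use_attention,
                              renormalize=renormalize)
        if not (np.all(np.isfinite(Z_D.data)) and
                np.all(np.isfinite(Z_T.data))):
            raise FloatingPointError(
                f"non-finite activations after encoder layer {layer}")
    return Z_D, Z_T


def save_checkpoint(params: EncoderParams, path_prefix, drug_ids=None,
                    target_ids=None, extras: dict | None = None):
    """Write parameters as a flat .npz blob plus a JSON manifest
    (entity ids, width, layer count, blob names)."""
    import json
    from pathlib import Path

    blobs: dict[str, np.ndarray] = {
        "W_in_D": params.W_in_D.data, "b_in_D": params.b_in_D.data,
        "W_in_T": params.W_in_T.data, "b_in_T": params.b_in_T.data,
    }
    for l, layer in enumerate(params.layers):
        for key, tensor in layer.items():
            blobs[f"layer{l}_{key}"] = tensor.data
    for block, mlp in params.attention.items():
        for i, p in enumerate(mlp.parameters()):
            blobs[f"att_{block}_{i}"] = p.data
    for tag, dec in (("D", params.decoder_D), ("T", params.decoder_T)):
        for i, p in enumerate(dec.parameters()):
            blobs[f"dec_{tag}_{i}"] = p.data
    if extras:
        for name, arr in extras.items():
            blobs[f"extra_{name}"] = np.asarray(arr)
    prefix = Path(path_prefix)
    np.savez(prefix.with_suffix(".npz"), **blobs)
    manifest = {
        "h": params.h, "L": params.L,
        "drug_ids": list(drug_ids or []),
        "target_ids": list(target_ids or []),
        "blobs": sorted(blobs),
    }
    prefix.with_suffix(".json").write_text(json.dumps(manifest, indent=1))
    return prefix.with_suffix(".npz"), prefix.with_suffix(".json")


def load_checkpoint(path_prefix) -> tuple[EncoderParams, dict]:
    """Inverse of `save_checkpoint`; returns (params, manifest)."""
    import json
    from pathlib import Path

    prefix = Path(path_prefix)
    manifest = json.loads(prefix.with_suffix(".json").read_text())
    blobs = np.load(prefix.with_suffix(".npz"))
    h, L = manifest["h"], manifest["L"]

    def t(name):
        return Tensor(blobs[name], requires_grad=True)

    params = EncoderParams(h=h, L=L, W_in_D=t("W_in_D"), b_in_D=t("b_in_D"),
                           W_in_T=t("W_in_T"), b_in_T=t("b_in_T"))
    for l in range(L):
        params.layers.append({
            key: t(f"layer{l}_{key}")
            for key in ("W_DD", "W_TT", "W_DT", "W_TD", "B_D", "B_T")
        })
    for block in _BLOCKS:
        names = [f"att_{block}_{i}" for i in range(5)]
        params.attention[block] = AttentionMLP(*(t(n) for n in names))
    params.decoder_D = DecoderMLP(*(t(f"dec_D_{i}") for i in range(4)))
    params.decoder_T = DecoderMLP(*(t(f"dec_T_{i}") for i in range(4)))
    return params, manifest


def reconstruction_loss(Z_D: Tensor, Z_T: Tensor, X_D, X_T,
                        params: EncoderParams) -> Tensor:
    """Sum of squared errors of the decoded embeddings against the inputs."""
    err_D = params.decoder_D(Z_D) - Tensor(np.asarray(X_D, float))
    err_T = params.decoder_T(Z_T) - Tensor(np.asarray(X_T, float))
    return (err_D * err_D).sum() + (err_T * err_T).sum()
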