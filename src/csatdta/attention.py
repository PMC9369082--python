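"""Self-attention, attention-augmented convolution and parameter accounting.

A sequence of length W is treated as a feature map of height 1 and width W,
so the two-dimensional formulation degenerates cleanly to one dimension:
relative-position logits run along the width only.  For a single head h,

    O_h = Softmax( (X W_q)(X W_k)^T / sqrt(d_kh) ) (X W_v)

optionally with a relative-position term Q_i . r_{j-i} added to the
pre-softmax logits.  Multi-head attention concatenates the head outputs in
fixed head order and applies the learned projection W_o.  The
attention-augmented convolution concatenates, channel-wise, an ordinary
'same'-padded convolution with F_out - d_v filters and the d_v attention
channels, so the total output width is F_out.

These are reference forward-pass implementations on plain numpy arrays; the
trainable network wraps the same arithmetic in differentiable form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AttentionSpec",
    "AttentionWeights",
    "LayerParamDelta",
    "single_head_attention",
    "multi_head_attention",
    "relative_logits",
    "aaconv",
    "count_params_delta",
    "init_attention_weights",
    "softmax",
]


@dataclass(frozen=True)
class AttentionSpec:
    """Hyperparameters of one attention-augmented convolution layer.

    ``d_k`` and ``d_v`` are the TOTAL key/query and value depths summed over
    the ``n_heads`` heads; both must divide evenly.  ``kappa = d_k / f_out``
    and ``v_ratio = d_v / f_out`` express the depths as fractions of the
    reference output channel count of the convolution being augmented.
    """

    f_in: int
    f_out: int
    d_k: int
    d_v: int
    n_heads: int
    kernel_size: int
    use_relative: bool = True

    def __post_init__(self) -> None:
        for name in ("f_in", "f_out", "d_k", "d_v", "n_heads", "kernel_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.d_k % self.n_heads or self.d_v % self.n_heads:
            raise ValueError(
                f"d_k={self.d_k} and d_v={self.d_v} must be divisible by "
                f"n_heads={self.n_heads}"
            )

    @property
    def d_k_head(self) -> int:
        return self.d_k // self.n_heads

    @property
    def d_v_head(self) -> int:
        return self.d_v // self.n_heads

    @property
    def kappa(self) -> float:
        """Key depth as a fraction of the reference output channels."""
        return self.d_k / self.f_out

    @property
    def v_ratio(self) -> float:
        """Value (attentional channel) depth as a fraction of f_out."""
        return self.d_v / self.f_out

    @classmethod
    def from_ratios(
        cls,
        f_in: int,
        f_out: int,
        kappa: float,
        v_ratio: float,
        n_heads: int,
        kernel_size: int,
        use_relative: bool = True,
    ) -> "AttentionSpec":
        d_k, d_v = kappa * f_out, v_ratio * f_out
        if abs(d_k - round(d_k)) > 1e-9 or abs(d_v - round(d_v)) > 1e-9:
            raise ValueError("kappa*f_out and v_ratio*f_out must be integers")
        return cls(f_in, f_out, int(round(d_k)), int(round(d_v)),
                   n_heads, kernel_size, use_relative)


@dataclass
class AttentionWeights:
    """Learned linear maps for one multi-head attention layer.

    ``w_q``/``w_k`` have shape (n_heads, f_in, d_k_head), ``w_v`` shape
    (n_heads, f_in, d_v_head) and ``w_o`` shape (d_v, d_v).  When relative
    positions are used, ``relative_embeddings`` holds one depth-d_k_head
    vector per offset -(W-1)..(W-1), shared across heads.
    """

    w_q: np.ndarray
    w_k: np.ndarray
    w_v: np.ndarray
    w_o: np.ndarray
    relative_embeddings: np.ndarray | None = None

    def validate(self, spec: AttentionSpec) -> None:
        nh, dkh, dvh = spec.n_heads, spec.d_k_head, spec.d_v_head
        if self.w_q.shape != (nh, spec.f_in, dkh):
            raise ValueError(f"w_q shape {self.w_q.shape} mismatches spec")
        if self.w_k.shape != (nh, spec.f_in, dkh):
            raise ValueError(f"w_k shape {self.w_k.shape} mismatches spec")
        if self.w_v.shape != (nh, spec.f_in, dvh):
            raise ValueError(f"w_v shape {self.w_v.shape} mismatches spec")
        if self.w_o.shape != (spec.d_v, spec.d_v):
            raise ValueError(f"w_o shape {self.w_o.shape} mismatches spec")


@dataclass(frozen=True)
class LayerParamDelta:
    """Signed weight-count change from augmenting one convolution layer."""

    delta: int


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax (max-subtracted); finite for |logit|<=1e4."""
    z = logits - np.max(logits, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def _as_2d(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Accept (W, C) or (1, W, C); return (W, C) and whether input was 3-D."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 3:
        if x.shape[0] != 1:
            raise ValueError("feature maps with height > 1 are not supported")
        return x[0], True
    if x.ndim != 2:
        raise ValueError(f"expected a 2-D or (1, W, C) array, got {x.shape}")
    return x, False


def relative_logits(
    q: np.ndarray, embeddings: np.ndarray, spec: AttentionSpec
) -> np.ndarray:
    """Relative-position logits L[i, j] = q_i . r_{j-i} for one head.

    ``q`` has shape (W, d_k_head); ``embeddings`` has one row per offset
    -(W-1)..(W-1), i.e. at least 2W-1 rows, centred on offset zero.  The
    result depends only on offsets j - i, so it is invariant to shifting
    all positions by a constant.
    """
    if not spec.use_relative:
        raise ValueError("relative logits requested but use_relative is off")
    q = np.asarray(q, dtype=np.float64)
    w = q.shape[0]
    emb = np.asarray(embeddings, dtype=np.float64)
    if emb.ndim != 2 or emb.shape[1] != spec.d_k_head:
        raise ValueError("embeddings must be (n_offsets, d_k_head)")
    if emb.shape[0] < 2 * w - 1:
        raise ValueError(
            f"need embeddings for offsets -{w - 1}..{w - 1} "
            f"({2 * w - 1} rows), got {emb.shape[0]}"
        )
    centre = emb.shape[0] // 2
    offsets = np.arange(w)[None, :] - np.arange(w)[:, None]  # j - i
    return np.einsum("id,ijd->ij", q, emb[offsets + centre])


def single_head_attention(
    x: np.ndarray,
    w_q: np.ndarray,
    w_k: np.ndarray,
    w_v: np.ndarray,
    spec: AttentionSpec,
    relative_embeddings: np.ndarray | None = None,
    return_attention: bool = False,
):
    """Scaled dot-product self-attention output of one head.

    ``x`` is the flattened feature map (W, f_in).  Returns (W, d_v_head),
    or a ``(output, attention_matrix)`` pair when ``return_attention`` is
    set.  The full pre-softmax logit, including any relative term, is
    scaled by 1/sqrt(d_k_head).
    """
    x, _ = _as_2d(x)
    if not np.isfinite(x).all():
        raise ValueError("non-finite entries in attention input")
    if x.shape[1] != spec.f_in:
        raise ValueError(f"input has {x.shape[1]} channels, spec.f_in={spec.f_in}")
    q, k, v = x @ w_q, x @ w_k, x @ w_v
    logits = q @ k.T
    if spec.use_relative and relative_embeddings is not None:
        logits = logits + relative_logits(q, relative_embeddings, spec)
    attn = softmax(logits / np.sqrt(spec.d_k_head), axis=-1)
    out = attn @ v
    return (out, attn) if return_attention else out


def multi_head_attention(
    x: np.ndarray, weights: AttentionWeights, spec: AttentionSpec
) -> np.ndarray:
    """MHA(X) = Concat[O_1, ..., O_Nh] W_o, reshaped to (H, W, d_v).

    Head outputs are concatenated in fixed head-index order.  The output
    has the same number of dimensions as the input ((W, d_v) for 2-D input,
    (1, W, d_v) for a 3-D feature map).
    """
    x2, was_3d = _as_2d(x)
    weights.validate(spec)
    rel = weights.relative_embeddings if spec.use_relative else None
    heads = [
        single_head_attention(
            x2, weights.w_q[h], weights.w_k[h], weights.w_v[h], spec, rel
        )
        for h in range(spec.n_heads)
    ]
    out = np.concatenate(heads, axis=-1) @ weights.w_o
    return out[None, :, :] if was_3d else out


def aaconv(
    x: np.ndarray,
    conv_kernel: np.ndarray,
    weights: AttentionWeights,
    spec: AttentionSpec,
) -> np.ndarray:
    """Attention-augmented convolution: Concat[Conv(X), MHA(X)].

    ``conv_kernel`` has shape (kernel_size, f_in, f_out - d_v) and is applied
    with 'same' padding so the spatial width is preserved; the d_v attention
    channels are appended, giving f_out output channels in total.
    """
    n_conv = spec.f_out - spec.d_v
    if n_conv < 0:
        raise ValueError(
            f"d_v={spec.d_v} exceeds f_out={spec.f_out}: no room for conv filters"
        )
    x2, was_3d = _as_2d(x)
    if n_conv > 0:
        kernel = np.asarray(conv_kernel, dtype=np.float64)
        if kernel.shape != (spec.kernel_size, spec.f_in, n_conv):
            raise ValueError(
                f"conv kernel shape {kernel.shape} != "
                f"{(spec.kernel_size, spec.f_in, n_conv)}"
            )
        conv_out = _conv1d_same(x2, kernel)
        parts = [conv_out]
    else:
        parts = []
    parts.append(multi_head_attention(x2, weights, spec))
    out = np.concatenate(parts, axis=-1)
    return out[None, :, :] if was_3d else out


def _conv1d_same(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """'same'-padded 1-D convolution; x (W, C_in), kernel (k, C_in, C_out)."""
    k = kernel.shape[0]
    left = (k - 1) // 2
    xp = np.pad(x, ((left, k - 1 - left), (0, 0)))
    w = x.shape[0]
    out = np.zeros((w, kernel.shape[2]))
    for t in range(k):
        out += xp[t : t + w] @ kernel[t]
    return out


def count_params_delta(spec: AttentionSpec, spatial_dims: int = 2) -> LayerParamDelta:
    """Exact weight-count change from augmenting a convolution layer.

    Attention adds f_in * (2 d_k + d_v) weights for the query/key/value maps
    plus d_v^2 for the output projection, while the convolutional part drops
    from f_out to f_out - d_v filters, losing kernel_size**spatial_dims *
    f_in * d_v weights.  Biases and relative-position embeddings are
    excluded from the count.  ``spatial_dims=2`` corresponds to square k x k
    kernels; use 1 for the sequence convolutions in this package.
    """
    if spatial_dims not in (1, 2):
        raise ValueError("spatial_dims must be 1 or 2")
    taps = spec.kernel_size**spatial_dims
    added = spec.f_in * (2 * spec.d_k + spec.d_v) + spec.d_v**2
    removed = taps * spec.f_in * spec.d_v
    return LayerParamDelta(delta=int(added - removed))


def init_attention_weights(
    spec: AttentionSpec,
    rng: np.random.Generator,
    max_width: int | None = None,
) -> AttentionWeights:
    """Glorot-normal initialisation of all attention maps.

    ``max_width`` sizes the relative-embedding table (offsets up to
    +/-(max_width-1)); required when ``spec.use_relative`` is set.
    """
    def glorot(shape: tuple[int, ...]) -> np.ndarray:
        fan_in, fan_out = shape[-2], shape[-1]
        sd = np.sqrt(2.0 / (fan_in + fan_out))
        return rng.normal(0.0, sd, size=shape)

    nh, dkh, dvh = spec.n_heads, spec.d_k_head, spec.d_v_head
    rel = None
    if spec.use_relative:
        if max_width is None:
            raise ValueError("max_width required when use_relative is set")
        rel = rng.normal(0.0, spec.d_k_head**-0.5, size=(2 * max_width - 1, dkh))
    return AttentionWeights(
        w_q=glorot((nh, spec.f_in, dkh)),
        w_k=glorot((nh, spec.f_in, dkh)),
        w_v=glorot((nh, spec.f_in, dvh)),
        w_o=glorot((spec.d_v, spec.d_v)),
        relative_embeddings=rel,
    )
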