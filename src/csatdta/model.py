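"""The two-branch attention-augmented convolutional affinity regressor.

One branch reads the drug SMILES tokens, the other the protein sequence
tokens.  Each branch is: token embedding -> four 'same'-padded 1-D
convolutions with widths F, 2F, 3F, 3F -> a terminal attention-augmented
convolution whose concatenated (conv + multi-head attention) output is
again 3F channels -> batch normalisation -> ReLU -> global max pooling.
The two pooled 3F vectors are concatenated and passed through dense layers
1024 -> dropout -> 1024 -> dropout -> 512 -> a single linear output, the
predicted binding affinity.

Weights are Glorot-normal initialised from the configured seed; inference
is deterministic (dropout off, batch norm on running statistics).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np

from ._autodiff import Tensor, concat
from .attention import AttentionSpec

__all__ = ["BranchConfig", "ModelConfig", "AffinityModel", "build_model", "predict"]


@dataclass(frozen=True)
class BranchConfig:
    """Configuration of one encoder branch (drug or protein)."""

    vocab_size: int
    max_len: int
    kernel_size: int
    n_heads: int
    head_depth: int  # per-head key/query and value depth
    embed_dim: int = 128
    base_filters: int = 32
    use_relative: bool = True
    downsample_attention: bool = False
    batchnorm_everywhere: bool = False

    def attention_spec(self) -> AttentionSpec:
        f = 3 * self.base_filters
        return AttentionSpec(
            f_in=f,
            f_out=f,
            d_k=self.n_heads * self.head_depth,
            d_v=self.n_heads * self.head_depth,
            n_heads=self.n_heads,
            kernel_size=self.kernel_size,
            use_relative=self.use_relative,
        )

    def validate(self) -> None:
        if self.vocab_size < 1 or self.max_len < 1:
            raise ValueError("vocab_size and max_len must be positive")
        if self.embed_dim < 1 or self.base_filters < 1:
            raise ValueError("embed_dim and base_filters must be positive")
        spec = self.attention_spec()
        if spec.d_v >= spec.f_out:
            raise ValueError(
                f"attention value depth {spec.d_v} must leave at least one "
                f"conv filter in the {spec.f_out}-channel terminal layer"
            )
        if self.downsample_attention and self.max_len % 2:
            raise ValueError("downsampled attention requires an even max_len")


def _default_drug_branch() -> BranchConfig:
    return BranchConfig(vocab_size=64, max_len=100, kernel_size=4,
                        n_heads=4, head_depth=2)


def _default_protein_branch() -> BranchConfig:
    return BranchConfig(vocab_size=25, max_len=1000, kernel_size=8,
                        n_heads=10, head_depth=5)


@dataclass(frozen=True)
class ModelConfig:
    """Full hyperparameter set of the regressor and its training loop."""

    drug_branch: BranchConfig = field(default_factory=_default_drug_branch)
    protein_branch: BranchConfig = field(default_factory=_default_protein_branch)
    dense_sizes: tuple[int, ...] = (1024, 1024, 512)
    dropout_rate: float = 0.1
    learning_rate: float = 0.001
    batch_size: int = 64
    optimizer_name: str = "adadelta"
    initializer_name: str = "glorot_normal"
    epochs: int = 100
    early_stop_patience: int = 15
    seed: int = 0

    def validate(self) -> None:
        self.drug_branch.validate()
        self.protein_branch.validate()
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if self.optimizer_name not in ("adadelta", "adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer_name!r}")
        if self.initializer_name != "glorot_normal":
            raise ValueError(f"unknown initializer {self.initializer_name!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dense_sizes"] = list(self.dense_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["drug_branch"] = BranchConfig(**d["drug_branch"])
        d["protein_branch"] = BranchConfig(**d["protein_branch"])
        d["dense_sizes"] = tuple(d["dense_sizes"])
        return cls(**d)

    def with_seed(self, seed: int) -> "ModelConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    sd = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, sd, size=shape)


class _BatchNorm:
    """Per-channel batch normalisation over (batch, width)."""

    EPS = 1e-3
    MOMENTUM = 0.9

    def __init__(self, channels: int):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True).mean(axis=1, keepdims=True)
            centred = x - mu
            var = (centred**2.0).mean(axis=0, keepdims=True).mean(axis=1, keepdims=True)
            m = self.MOMENTUM
            self.running_mean = m * self.running_mean + (1 - m) * mu.data.ravel()
            self.running_var = m * self.running_var + (1 - m) * var.data.ravel()
            xhat = centred * ((var + self.EPS) ** -0.5)
        else:
            xhat = (x - self.running_mean) * (self.running_var + self.EPS) ** -0.5
        return xhat * self.gamma + self.beta


class _MultiHeadAttention:
    """Differentiable MHA over (B, W, F) with optional relative positions."""

    def __init__(self, spec: AttentionSpec, width: int, rng: np.random.Generator):
        self.spec = spec
        self.width = width
        f, dkh, dvh = spec.f_in, spec.d_k_head, spec.d_v_head
        self.w_q = [Tensor(_glorot(rng, (f, dkh), f, dkh), True)
                    for _ in range(spec.n_heads)]
        self.w_k = [Tensor(_glorot(rng, (f, dkh), f, dkh), True)
                    for _ in range(spec.n_heads)]
        self.w_v = [Tensor(_glorot(rng, (f, dvh), f, dvh), True)
                    for _ in range(spec.n_heads)]
        self.w_o = Tensor(_glorot(rng, (spec.d_v, spec.d_v), spec.d_v, spec.d_v), True)
        if spec.use_relative:
            self.rel = Tensor(
                rng.normal(0.0, dkh**-0.5, size=(2 * width - 1, dkh)), True
            )
            # offset index table: idx[i, j] = (j - i) + (width - 1)
            off = np.arange(width)[None, :] - np.arange(width)[:, None]
            self._offset_idx = off + width - 1
        else:
            self.rel = None

    def __call__(self, x: Tensor) -> Tensor:
        spec = self.spec
        scale = 1.0 / np.sqrt(spec.d_k_head)
        heads = []
        for h in range(spec.n_heads):
            q = x @ self.w_q[h]
            k = x @ self.w_k[h]
            v = x @ self.w_v[h]
            logits = q @ k.transpose((0, 2, 1))
            if self.rel is not None:
                w = x.shape[1]
                if w != self.width:
                    raise ValueError(
                        f"attention built for width {self.width}, got {w}"
                    )
                all_off = q @ self.rel.transpose((1, 0))  # (B, W, 2W-1)
                logits = logits + all_off.gather_last(self._offset_idx)
            attn = (logits * scale).softmax(axis=-1)
            heads.append(attn @ v)
        return concat(heads, axis=-1) @ self.w_o


class _Branch:
    """One encoder branch: embedding, conv stack, AA-conv, BN, max pool."""

    def __init__(self, cfg: BranchConfig, rng: np.random.Generator):
        cfg.validate()
        self.cfg = cfg
        f, e, k = cfg.base_filters, cfg.embed_dim, cfg.kernel_size
        v, spec = 3 * f, cfg.attention_spec()
        self.embed = Tensor(
            _glorot(rng, (cfg.vocab_size + 1, e), cfg.vocab_size + 1, e), True
        )
        widths = [(e, f), (f, 2 * f), (2 * f, 3 * f), (3 * f, 3 * f)]
        self.convs = []
        for cin, cout in widths:
            kern = Tensor(_glorot(rng, (k, cin, cout), k * cin, k * cout), True)
            bias = Tensor(np.zeros(cout), True)
            self.convs.append((kern, bias))
        # terminal attention-augmented convolution: conv part has 3F - d_v filters
        n_conv = v - spec.d_v
        self.aa_kernel = Tensor(
            _glorot(rng, (k, v, n_conv), k * v, k * n_conv), True
        )
        self.aa_bias = Tensor(np.zeros(n_conv), True)
        attn_width = cfg.max_len // 2 if cfg.downsample_attention else cfg.max_len
        self.mha = _MultiHeadAttention(spec, attn_width, rng)
        self.bn = _BatchNorm(v)
        self.bn_inner = (
            [_BatchNorm(cout) for _, cout in widths]
            if cfg.batchnorm_everywhere
            else None
        )

    def __call__(self, tokens: np.ndarray, training: bool,
                 bn_training: bool) -> Tensor:
        x = self.embed.gather_rows(tokens)  # (B, W, E)
        for i, (kern, bias) in enumerate(self.convs):
            x = x.conv1d_same(kern) + bias
            if self.bn_inner is not None:
                x = self.bn_inner[i](x, bn_training)
            x = x.relu()
        attn_in = x
        if self.cfg.downsample_attention:
            b, w, c = x.shape
            attn_in = x.reshape(b, w // 2, 2, c).mean(axis=2)
        attn_out = self.mha(attn_in)
        if self.cfg.downsample_attention:
            b, w2, c = attn_out.shape
            attn_out = concat(
                [attn_out.reshape(b, w2, 1, c)] * 2, axis=2
            ).reshape(b, 2 * w2, c)
        conv_out = x.conv1d_same(self.aa_kernel) + self.aa_bias
        x = concat([conv_out, attn_out], axis=-1)
        x = self.bn(x, bn_training)
        x = x.relu()
        return x.max(axis=1)  # global max pool -> (B, 3F)

    def parameters(self) -> dict[str, Tensor]:
        params = {"embed": self.embed}
        for i, (kern, bias) in enumerate(self.convs, 1):
            params[f"conv{i}.kernel"] = kern
            params[f"conv{i}.bias"] = bias
        params["aaconv.kernel"] = self.aa_kernel
        params["aaconv.bias"] = self.aa_bias
        for h in range(self.mha.spec.n_heads):
            params[f"attn.w_q.{h}"] = self.mha.w_q[h]
            params[f"attn.w_k.{h}"] = self.mha.w_k[h]
            params[f"attn.w_v.{h}"] = self.mha.w_v[h]
        params["attn.w_o"] = self.mha.w_o
        if self.mha.rel is not None:
            params["attn.rel"] = self.mha.rel
        params["bn.gamma"] = self.bn.gamma
        params["bn.beta"] = self.bn.beta
        if self.bn_inner is not None:
            for i, bn in enumerate(self.bn_inner, 1):
                params[f"bn{i}.gamma"] = bn.gamma
                params[f"bn{i}.beta"] = bn.beta
        return params

    def batchnorms(self) -> dict[str, _BatchNorm]:
        bns = {"bn": self.bn}
        if self.bn_inner is not None:
            for i, bn in enumerate(self.bn_inner, 1):
                bns[f"bn{i}"] = bn
        return bns


class AffinityModel:
    """The assembled two-branch regressor.

    Use :func:`build_model` rather than constructing directly.
    """

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.drug = _Branch(config.drug_branch, rng)
        self.protein = _Branch(config.protein_branch, rng)
        head_in = 3 * (config.drug_branch.base_filters
                       + config.protein_branch.base_filters)
        self.dense = []
        prev = head_in
        for width in config.dense_sizes:
            w = Tensor(_glorot(rng, (prev, width), prev, width), True)
            b = Tensor(np.zeros(width), True)
            self.dense.append((w, b))
            prev = width
        self.out_w = Tensor(_glorot(rng, (prev, 1), prev, 1), True)
        self.out_b = Tensor(np.zeros(1), True)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 0xD0]).generate_state(1)[0]
        )
        self.epochs_trained = 0
        self.best_validation_loss: float | None = None
        # affine de-standardisation of the raw network output; set by the
        # training loop so the network learns on zero-mean unit-variance
        # targets while predictions stay on the affinity scale
        self.target_center = 0.0
        self.target_scale = 1.0
        # provenance of the affinities the model was fitted to
        self.affinity_scale = "unknown"

    # -- forward -----------------------------------------------------------

    def forward(
        self,
        drug_tokens: np.ndarray,
        protein_tokens: np.ndarray,
        training: bool = False,
        bn_training: bool | None = None,
    ) -> Tensor:
        """Predict affinities for a batch; returns a (B,) tensor."""
        drug_tokens = np.asarray(drug_tokens, dtype=np.int64)
        protein_tokens = np.asarray(protein_tokens, dtype=np.int64)
        self._check_tokens(drug_tokens, self.config.drug_branch, "drug")
        self._check_tokens(protein_tokens, self.config.protein_branch, "protein")
        if bn_training is None:
            bn_training = training
        d = self.drug(drug_tokens, training, bn_training)
        p = self.protein(protein_tokens, training, bn_training)
        x = concat([d, p], axis=-1)
        rate = self.config.dropout_rate
        for i, (w, b) in enumerate(self.dense):
            x = (x @ w + b).relu()
            if training and rate > 0.0 and i < 2:
                mask = (
                    self._dropout_rng.random(x.shape) >= rate
                ) / (1.0 - rate)
                x = x * Tensor(mask)
        out = x @ self.out_w + self.out_b
        return out.reshape(out.shape[0])

    @staticmethod
    def _check_tokens(tokens: np.ndarray, branch: BranchConfig, name: str) -> None:
        if tokens.ndim != 2 or tokens.shape[1] != branch.max_len:
            raise ValueError(
                f"{name} tokens must have shape (batch, {branch.max_len}), "
                f"got {tokens.shape}"
            )
        if tokens.min() < 0 or tokens.max() > branch.vocab_size:
            raise ValueError(
                f"{name} token codes must lie in [0, {branch.vocab_size}]"
            )

    def predict_batch(
        self, drug_tokens: np.ndarray, protein_tokens: np.ndarray
    ) -> np.ndarray:
        """Deterministic inference (dropout off, batch-norm running stats)."""
        raw = self.forward(drug_tokens, protein_tokens, training=False).data
        return raw * self.target_scale + self.target_center

    # -- parameter access --------------------------------------------------

    def parameters(self) -> dict[str, Tensor]:
        params = {}
        for prefix, branch in (("drug", self.drug), ("protein", self.protein)):
            for k, v in branch.parameters().items():
                params[f"{prefix}.{k}"] = v
        for i, (w, b) in enumerate(self.dense, 1):
            params[f"head.dense{i}.w"] = w
            params[f"head.dense{i}.b"] = b
        params["head.out.w"] = self.out_w
        params["head.out.b"] = self.out_b
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.parameters().items()}
        state["target_affine"] = np.array([self.target_center, self.target_scale])
        for prefix, branch in (("drug", self.drug), ("protein", self.protein)):
            for k, bn in branch.batchnorms().items():
                state[f"{prefix}.{k}.running_mean"] = bn.running_mean.copy()
                state[f"{prefix}.{k}.running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        if "target_affine" in state:
            self.target_center, self.target_scale = (
                float(x) for x in state["target_affine"]
            )
        params = self.parameters()
        for k, v in params.items():
            if k not in state:
                raise KeyError(f"checkpoint missing parameter {k}")
            if state[k].shape != v.data.shape:
                raise ValueError(
                    f"shape mismatch for {k}: {state[k].shape} vs {v.data.shape}"
                )
            v.data = np.asarray(state[k], dtype=np.float64).copy()
        for prefix, branch in (("drug", self.drug), ("protein", self.protein)):
            for k, bn in branch.batchnorms().items():
                bn.running_mean = np.asarray(
                    state[f"{prefix}.{k}.running_mean"], dtype=np.float64
                ).copy()
                bn.running_var = np.asarray(
                    state[f"{prefix}.{k}.running_var"], dtype=np.float64
                ).copy()

    def n_parameters(self) -> int:
        return sum(v.data.size for v in self.parameters().values())


def build_model(config: ModelConfig) -> AffinityModel:
    """Validate the configuration and allocate a seeded model."""
    config.validate()
    return AffinityModel(config)


def predict(model: AffinityModel, drug_encoded, protein_encoded) -> float:
    """Affinity score for one (drug, protein) pair of encoded sequences."""
    d = np.asarray(getattr(drug_encoded, "tokens", drug_encoded))[None, :]
    p = np.asarray(getattr(protein_encoded, "tokens", protein_encoded))[None, :]
    return float(model.predict_batch(d, p)[0])
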