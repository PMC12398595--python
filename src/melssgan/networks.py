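"""Generator and discriminator: attention-prefixed multilayer perceptrons.

The generator maps a Gaussian noise vector z ∈ R^noise_size to a
synthetic feature vector in R^d.  The discriminator maps a feature
vector to three class probabilities — non-melanoma (column 0), melanoma
(column 1) and fake (column 2) — and exposes a penultimate feature map
``D_F``.  Because the generator must be able to reconstruct a sample
from its discriminator features (G(D_F(x))), the discriminator ends in
a linear projection to exactly ``noise_size`` units before the 3-logit
head; that projection is the one architectural addition needed to make
the composition well-typed.

Both networks start with a residual self-attention block with d_k equal
to the input width, so disabling attention (zero weights) reproduces
the plain MLP path exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from ._autodiff import Tensor, constant
from .attention import AttentionWeights, self_attention_t

CLASS_NON_MELANOMA = 0
CLASS_MELANOMA = 1
CLASS_FAKE = 2

ACTIVATIONS = ("relu", "leaky_relu", "linear", "tanh", "sigmoid")

__all__ = [
    "CLASS_NON_MELANOMA",
    "CLASS_MELANOMA",
    "CLASS_FAKE",
    "ACTIVATIONS",
    "MLPSpec",
    "GeneratorNet",
    "DiscriminatorNet",
    "generator_forward",
    "discriminator_forward",
    "discriminator_features",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class MLPSpec:
    """Hidden-stack shape shared by both networks.

    ``n_layers`` counts hidden layers (search range [1, 10]); all hidden
    layers use one configurable ``hidden_width``.
    """

    n_layers: int = 2
    hidden_width: int = 64
    activation: str = "relu"
    dropout_rate: float = 0.0

    def __post_init__(self):
        if not 1 <= self.n_layers <= 10:
            raise ValueError("n_layers must lie in [1, 10]")
        if self.hidden_width < 1:
            raise ValueError("hidden_width must be positive")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


def _activate(t: Tensor, activation: str) -> Tensor:
    if activation == "relu":
        return t.relu()
    if activation == "leaky_relu":
        return t.leaky_relu(0.01)
    if activation == "tanh":
        return t.tanh()
    if activation == "sigmoid":
        return t.sigmoid()
    return t  # linear


def _init_linear(rng, fan_in: int, fan_out: int):
    bound = 1.0 / np.sqrt(fan_in)
    W = rng.uniform(-bound, bound, size=(fan_in, fan_out))
    b = np.zeros(fan_out)
    return W, b


def _dropout(t: Tensor, rate: float, rng) -> Tensor:
    if rate <= 0.0:
        return t
    mask = (rng.random(t.shape) >= rate) / (1.0 - rate)
    return t * constant(mask)


class _AttentionMLP:
    """Shared attention-residual + hidden-stack machinery."""

    def __init__(self, in_dim: int, spec: MLPSpec, rng, use_attention: bool):
        self.in_dim = in_dim
        self.spec = spec
        self.use_attention = use_attention
        self.params: dict[str, Tensor] = {}
        if use_attention:
            bound = 1.0 / np.sqrt(in_dim)
            for name in ("W_Q", "W_K", "W_V"):
                self.params[name] = Tensor(
                    rng.uniform(-bound, bound, size=(in_dim, in_dim))
                )
        else:
            for name in ("W_Q", "W_K", "W_V"):
                self.params[name] = Tensor(np.zeros((in_dim, in_dim)))
        width_in = in_dim
        for layer in range(spec.n_layers):
            W, b = _init_linear(rng, width_in, spec.hidden_width)
            self.params[f"W{layer}"] = Tensor(W)
            self.params[f"b{layer}"] = Tensor(b)
            width_in = spec.hidden_width
        self.hidden_out = width_in

    def trainable(self) -> dict[str, Tensor]:
        if self.use_attention:
            return dict(self.params)
        return {k: v for k, v in self.params.items() if not k.startswith("W_")}

    def forward(self, X: Tensor, train_mode: bool, rng) -> Tensor:
        h = X + self_attention_t(
            X, self.params["W_Q"], self.params["W_K"], self.params["W_V"]
        )
        for layer in range(self.spec.n_layers):
            h = h @ self.params[f"W{layer}"] + self.params[f"b{layer}"]
            h = _activate(h, self.spec.activation)
            if train_mode and rng is not None:
                h = _dropout(h, self.spec.dropout_rate, rng)
        return h

    @property
    def attention(self) -> AttentionWeights:
        return AttentionWeights(
            self.params["W_Q"].value, self.params["W_K"].value, self.params["W_V"].value
        )


class GeneratorNet:
    """z (m × noise_size) → synthetic features (m × d)."""

    def __init__(
        self,
        noise_size: int,
        out_dim: int,
        spec: MLPSpec,
        seed: int = 0,
        use_attention: bool = True,
    ):
        if noise_size < 1 or out_dim < 1:
            raise ValueError("noise_size and out_dim must be positive")
        self.noise_size = noise_size
        self.out_dim = out_dim
        self.spec = spec
        self.use_attention = use_attention
        rng = np.random.default_rng(seed)
        self.core = _AttentionMLP(noise_size, spec, rng, use_attention)
        W, b = _init_linear(rng, self.core.hidden_out, out_dim)
        self.params = dict(self.core.params)
        self.params["W_out"] = Tensor(W)
        self.params["b_out"] = Tensor(b)

    def trainable(self) -> dict[str, Tensor]:
        out = self.core.trainable()
        out["W_out"] = self.params["W_out"]
        out["b_out"] = self.params["b_out"]
        return out

    def forward_t(self, z: Tensor, train_mode: bool = False, rng=None) -> Tensor:
        h = self.core.forward(z, train_mode, rng)
        return h @ self.params["W_out"] + self.params["b_out"]

    def forward(self, z: np.ndarray, train_mode: bool = False, seed: int = 0) -> np.ndarray:
        z = np.asarray(z, dtype=np.float64)
        if z.ndim != 2 or z.shape[1] != self.noise_size:
            raise ValueError(
                f"z must be m × {self.noise_size}; got shape {z.shape}"
            )
        if not np.isfinite(z).all():
            raise ValueError("z must be finite")
        rng = np.random.default_rng(seed) if train_mode else None
        return self.forward_t(constant(z), train_mode, rng).value


class DiscriminatorNet:
    """Features (m × d) → 3-class probabilities; D_F is the penultimate map."""

    def __init__(
        self,
        in_dim: int,
        feature_dim: int,
        spec: MLPSpec,
        seed: int = 0,
        use_attention: bool = True,
    ):
        if in_dim < 1 or feature_dim < 1:
            raise ValueError("in_dim and feature_dim must be positive")
        self.in_dim = in_dim
        self.feature_dim = feature_dim  # = generator noise_size
        self.spec = spec
        self.use_attention = use_attention
        rng = np.random.default_rng(seed)
        self.core = _AttentionMLP(in_dim, spec, rng, use_attention)
        W_p, b_p = _init_linear(rng, self.core.hidden_out, feature_dim)
        W_h, b_h = _init_linear(rng, feature_dim, 3)
        self.params = dict(self.core.params)
        self.params.update(
            W_proj=Tensor(W_p), b_proj=Tensor(b_p), W_head=Tensor(W_h), b_head=Tensor(b_h)
        )

    def trainable(self) -> dict[str, Tensor]:
        out = self.core.trainable()
        for name in ("W_proj", "b_proj", "W_head", "b_head"):
            out[name] = self.params[name]
        return out

    def _check(self, f: np.ndarray) -> np.ndarray:
        f = np.asarray(f, dtype=np.float64)
        if f.ndim != 2 or f.shape[1] != self.in_dim:
            raise ValueError(f"input must be m × {self.in_dim}; got shape {f.shape}")
        if not np.isfinite(f).all():
            raise ValueError("input must be finite")
        return f

    def features_t(self, f: Tensor, train_mode: bool = False, rng=None) -> Tensor:
        h = self.core.forward(f, train_mode, rng)
        return h @ self.params["W_proj"] + self.params["b_proj"]

    def forward_t(self, f: Tensor, train_mode: bool = False, rng=None) -> Tensor:
        feats = self.features_t(f, train_mode, rng)
        logits = feats @ self.params["W_head"] + self.params["b_head"]
        return logits.softmax_rows()

    def forward(self, f: np.ndarray, train_mode: bool = False, seed: int = 0) -> np.ndarray:
        f = self._check(f)
        rng = np.random.default_rng(seed) if train_mode else None
        return self.forward_t(constant(f), train_mode, rng).value

    def features(self, f: np.ndarray) -> np.ndarray:
        return self.features_t(constant(self._check(f))).value


# -- module-level wrappers (spec surface) --------------------------------


def generator_forward(g: GeneratorNet, z, train_mode: bool = False, seed: int = 0):
    return g.forward(z, train_mode=train_mode, seed=seed)


def discriminator_forward(dsc: DiscriminatorNet, f, train_mode: bool = False, seed: int = 0):
    return dsc.forward(f, train_mode=train_mode, seed=seed)


def discriminator_features(dsc: DiscriminatorNet, f):
    return dsc.features(f)


# -- checkpointing -------------------------------------------------------


def _net_state(net) -> dict:
    return {name: t.value.tolist() for name, t in net.params.items()}


def _load_state(net, state: dict) -> None:
    for name, values in state.items():
        net.params[name].value = np.asarray(values, dtype=np.float64)


def save_checkpoint(path, generator: GeneratorNet, discriminator: DiscriminatorNet,
                    extra: dict | None = None) -> None:
    """Self-describing JSON archive; floats round-trip bit-exactly."""
    payload = {
        "generator": {
            "noise_size": generator.noise_size,
            "out_dim": generator.out_dim,
            "spec": asdict(generator.spec),
            "use_attention": generator.use_attention,
            "params": _net_state(generator),
        },
        "discriminator": {
            "in_dim": discriminator.in_dim,
            "feature_dim": discriminator.feature_dim,
            "spec": asdict(discriminator.spec),
            "use_attention": discriminator.use_attention,
            "params": _net_state(discriminator),
        },
        "extra": extra or {},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path):
    with open(path) as fh:
        payload = json.load(fh)
    gsec, dsec = payload["generator"], payload["discriminator"]
    gen = GeneratorNet(
        gsec["noise_size"], gsec["out_dim"], MLPSpec(**gsec["spec"]),
        use_attention=gsec["use_attention"],
    )
    dsc = DiscriminatorNet(
        dsec["in_dim"], dsec["feature_dim"], MLPSpec(**dsec["spec"]),
        use_attention=dsec["use_attention"],
    )
    _load_state(gen, gsec["params"])
    _load_state(dsc, dsec["params"])
    return gen, dsc, payload.get("extra", {})
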