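"""Random-key encoding of mixed hyperparameter spaces.

Every hyperparameter c gets a sub-vector of length D_c inside a genome
in [0,1]^D: continuous and integer parameters use one gene mapped
affinely onto [lo, hi] (integers round half-up); categorical parameters
use one gene per option, the argmax position selecting the option.  The
argmax rule is permutation-sensitive and invariant under strictly
increasing transforms of the sub-vector, so colony updates that
preserve order preserve the decoded choice.  Decoding is total: every
point of the unit cube yields a valid configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .networks import ACTIVATIONS

__all__ = [
    "HyperparamSpec",
    "SearchSpace",
    "Genome",
    "space_dimension",
    "decode_genome",
    "random_genome",
    "generator_space",
    "discriminator_space",
    "PRESETS",
]


@dataclass(frozen=True)
class HyperparamSpec:
    """One tunable: continuous / integer range or categorical options."""

    name: str
    kind: str
    lo: float | None = None
    hi: float | None = None
    options: tuple | None = None

    def __post_init__(self):
        if self.kind not in ("continuous", "integer", "categorical"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.options or len(self.options) < 2:
                raise ValueError(f"{self.name}: categorical needs >= 2 options")
        else:
            if self.lo is None or self.hi is None or not self.lo < self.hi:
                raise ValueError(f"{self.name}: need lo < hi")

    @property
    def width(self) -> int:
        """Sub-vector length D_c: 1 for ranged kinds, |options| otherwise."""
        return len(self.options) if self.kind == "categorical" else 1

    def decode(self, genes: np.ndarray):
        if self.kind == "categorical":
            return self.options[int(np.argmax(genes))]
        value = self.lo + float(genes[0]) * (self.hi - self.lo)
        if self.kind == "integer":
            return int(min(max(math.floor(value + 0.5), self.lo), self.hi))
        return value


@dataclass(frozen=True)
class SearchSpace:
    specs: tuple

    def __post_init__(self):
        if not self.specs:
            raise ValueError("SearchSpace must contain at least one parameter")
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate hyperparameter names")

    @property
    def dimension(self) -> int:
        return sum(s.width for s in self.specs)


@dataclass(frozen=True)
class Genome:
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 1:
            raise ValueError("genome must be a flat vector")
        if ((v < 0) | (v > 1)).any():
            raise ValueError("genome entries must lie in [0, 1]")


def space_dimension(space: SearchSpace) -> int:
    """Total genome length D = Σ_c D_c."""
    return space.dimension


def decode_genome(g: Genome, space: SearchSpace) -> dict:
    """Map a genome to a name → value configuration."""
    if len(g.values) != space.dimension:
        raise ValueError(
            f"genome length {len(g.values)} != space dimension {space.dimension}"
        )
    out = {}
    cursor = 0
    for spec in space.specs:
        out[spec.name] = spec.decode(g.values[cursor:cursor + spec.width])
        cursor += spec.width
    return out


def random_genome(space: SearchSpace, rng) -> Genome:
    return Genome(rng.random(space.dimension))


def generator_space() -> SearchSpace:
    """Generator search ranges (learning-rate low end and dropout high end
    nudged off the degenerate bounds so decoding is always valid)."""
    return SearchSpace(specs=(
        HyperparamSpec("batch_size", "integer", 16, 512),
        HyperparamSpec("epochs", "integer", 64, 1024),
        HyperparamSpec("lr", "continuous", 1e-5, 1.0),
        HyperparamSpec("activation", "categorical", options=ACTIVATIONS),
        HyperparamSpec("dropout_rate", "continuous", 0.0, 0.95),
        HyperparamSpec("n_layers", "integer", 1, 10),
        HyperparamSpec("noise_size", "integer", 16, 1024),
        HyperparamSpec("lambda_r", "continuous", 0.0, 1.0),
    ))


def discriminator_space() -> SearchSpace:
    return SearchSpace(specs=(
        HyperparamSpec("batch_size", "integer", 16, 512),
        HyperparamSpec("epochs", "integer", 64, 1024),
        HyperparamSpec("lr", "continuous", 1e-5, 1.0),
        HyperparamSpec("activation", "categorical", options=ACTIVATIONS),
        HyperparamSpec("dropout_rate", "continuous", 0.0, 0.95),
        HyperparamSpec("n_layers", "integer", 1, 10),
        HyperparamSpec("lambda_consistency", "continuous", 0.0, 1.0),
        HyperparamSpec("lambda_pseudo", "continuous", 0.0, 1.0),
        HyperparamSpec("tau", "continuous", 0.5, 1.0),
    ))


PRESETS = {
    "generator": generator_space,
    "discriminator": discriminator_space,
}
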