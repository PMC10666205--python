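"""Model hyper-parameters and the branch shape arithmetic."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from typing import Any

import yaml


@dataclass
class ModelConfig:
    """Hyper-parameters of the pathway-CNN ensemble.

    The architecture is fixed at two conv+pool stages, each pooling halving
    the spatial length; ``stride`` and ``pool_factor`` are kept as explicit
    (validated) constants so a config file states the full architecture.
    """

    n_filters: int = 32
    kernel_size: int = 3
    stride: int = 1
    pool_factor: int = 2
    n_conv_blocks: int = 2
    cca_dim: int = 8
    cca_ridge: float = 1e-3
    lambda_cca: float = 0.1
    learning_rate: float = 0.001
    epochs: int = 400
    batch_size: int = 5
    seed: int = 0
    activation: str = "relu"
    min_genes: int = 5
    aggregate: str = "geometric"

    def __post_init__(self) -> None:
        if self.pool_factor != 2:
            raise ValueError("pool_factor is fixed at 2")
        if self.n_conv_blocks != 2:
            raise ValueError("n_conv_blocks is fixed at 2")
        if self.stride != 1:
            raise ValueError("stride is fixed at 1")
        if self.lambda_cca < 0:
            raise ValueError("lambda_cca must be non-negative")
        if self.cca_ridge <= 0:
            raise ValueError("cca_ridge must be positive")
        if self.activation != "relu":
            raise ValueError("only the rectified-linear activation is supported")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "ModelConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc.get("model", doc))


def branch_output_length(g: int, config: ModelConfig | None = None, n_filters: int | None = None) -> int:
    """Flattened feature dimension of one branch for input length ``g``:
    conv (same padding) preserves length, each of the two pools floors a
    halving, and the channel axis multiplies by the filter count."""
    config = config or ModelConfig()
    nf = n_filters if n_filters is not None else config.n_filters
    if g < 4:
        raise ValueError(
            f"input length {g} is below the minimum spatial length 4; "
            "right-pad the pathway block with zero columns"
        )
    spatial = (g // config.pool_factor) // config.pool_factor
    return spatial * nf
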