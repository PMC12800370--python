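"""Run configuration: schema-validated YAML + command-line overrides.

One global seed expands deterministically into per-stage seeds so any stage
can be rerun in isolation and still agree with a full run.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PathsConfig(_Strict):
    pdb_dir: str
    fasta: str
    ppi: str
    sl_pairs: str
    gene_map: str


class Node2VecConfig(_Strict):
    p: float = 1.0
    q: float = 1.0
    walks_per_node: int = 10
    walk_length: int = 80
    window: int = 10
    epochs: int = 5
    negative: int = 5


class FeaturesConfig(_Strict):
    cmap_thresh: float = 10.0
    min_ppi_score: float = 0.0
    seq_dim: int = 1024
    ppi_dim: int = 128
    struct_dim: int = 128
    kmer_k: int = 3
    embedder_layers: int = 2
    node2vec: Node2VecConfig = Field(default_factory=Node2VecConfig)


class DatasetConfig(_Strict):
    ratio: str = "1:1"
    folds: int = 5


class MLPSection(_Strict):
    hidden_sizes: list[int] = [256, 128, 64]
    dropout_rate: float = 0.5
    learning_rate: float = 0.004
    l2_lambda: float = 1e-4
    max_epochs: int = 200
    patience: int = 10
    batch_size: int = 256


class RunConfig(_Strict):
    paths: PathsConfig
    features: FeaturesConfig = Field(default_factory=FeaturesConfig)
    dataset: DatasetConfig = Field(default_factory=DatasetConfig)
    mlp: MLPSection = Field(default_factory=MLPSection)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, overrides: list[str] = ()) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for item in overrides:
            key, _, raw = item.partition("=")
            if not _:
                raise ValueError(f"override {item!r} is not key=value")
            node = data
            parts = key.split(".")
            for part in parts[:-1]:
                node = node.setdefault(part, {})
            node[parts[-1]] = yaml.safe_load(raw)
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(), sort_keys=True)
        )

    def parse_ratio(self) -> tuple[int, int]:
        m, _, n = self.dataset.ratio.partition(":")
        return int(m), int(n)
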