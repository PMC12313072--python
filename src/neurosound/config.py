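"""Run configuration.

One YAML file describes a full run: per-stage seeds derived from a master
seed by fixed offsets, design sizes, noise level, pipeline and evaluation
choices, and the output directory. A run is reproducible from its config
alone; every artifact embeds the config hash.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .benchmark import DEFAULT_NOISE_SD, DEFAULT_TEST_COUNTS


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/default"
    # design sizes (the packaged mini-benchmark shape)
    n_train: int = 120
    test_counts: dict = field(default_factory=lambda: dict(DEFAULT_TEST_COUNTS))
    n_voxels: int = 400
    k_voxels: int = 200
    n_train_reps: int = 1
    noise_sd: float = DEFAULT_NOISE_SD
    channels: tuple = (16, 32, 64, 64, 64)
    layer: str = "L5"
    roi: str = "AC"
    # generator
    translator_corpus: int = 240
    # attention
    n_attention_exemplars: int = 2
    attention_leak: float = 0.3
    # evaluation
    pipeline: str = "full"            # full | brain_to_codebook | pixel_opt
    metric: str = "pearson"           # pearson | spearman
    scope: str = "all"                # all | within_category
    render_audio: bool = True

    def stage_seed(self, offset: int) -> int:
        return (self.seed + offset) % (2 ** 31)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channels"] = list(self.channels)
        return d

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        data = {}
        if path is not None:
            data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "channels" in data:
            data["channels"] = tuple(data["channels"])
        return cls(**data)

    def save(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict()))
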