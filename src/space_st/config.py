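"""Run configuration: one dataclass per pipeline stage, loadable from YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class KernelConfig:
    n_each: int = 5
    quantiles: tuple[float, ...] | None = None
    families: tuple[str, ...] = ("gaussian", "cosine")


@dataclass
class TestConfig:
    fdr: float = 0.05
    combine: str = "cauchy"  # or "minp"


@dataclass
class Step2Config:
    alpha: float = 0.05
    selection: str = "cor_test"  # or "abs_r", "spearman"
    var_threshold: float = 0.8
    min_size: int = 5
    resolution: float = 1.0
    seed: int = 0


@dataclass
class EmbedConfig:
    method: str = "smoothed_pca"  # or "pca", "external"
    n_pcs: int = 5
    bandwidth_quantile: float | None = None
    external_paths: dict = field(default_factory=dict)  # cluster -> file
    include_singletons: bool = False


@dataclass
class DomainConfig:
    method: str = "leiden"  # or "louvain", "walktrap"
    mode: str = "unknown_k"  # or "known_k"
    k_d: int | None = None
    resolution: float = 1.0
    n_neighbors: int = 20
    seed: int = 0


@dataclass
class PreprocessConfig:
    min_frac: float = 0.01
    normalize: str = "lognorm"  # or "none" for pre-normalized input


@dataclass
class BaselineConfig:
    n_top_svgs: int = 3000
    n_pcs: int = 20


@dataclass
class SpaceConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    kernel: KernelConfig = field(default_factory=KernelConfig)
    test: TestConfig = field(default_factory=TestConfig)
    step2: Step2Config = field(default_factory=Step2Config)
    embed: EmbedConfig = field(default_factory=EmbedConfig)
    domains: DomainConfig = field(default_factory=DomainConfig)
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "SpaceConfig":
        kwargs = {}
        for f in fields(cls):
            if f.name not in data:
                continue
            sub = data[f.name]
            if f.name == "seed":
                kwargs["seed"] = int(sub)
            else:
                kwargs[f.name] = f.default_factory().__class__(**sub)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "SpaceConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
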