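"""Run configuration: explicit seeds everywhere, lossless YAML round-trip."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "profile_config", "load_config"]


@dataclass
class RunConfig:
    profile: str = "tiny"
    seeds: dict = field(default_factory=dict)
    database: dict = field(default_factory=dict)
    experiment: dict = field(default_factory=dict)
    observers: dict = field(default_factory=dict)
    embeddings: list = field(default_factory=list)
    cv: dict = field(default_factory=dict)
    infotheory: dict = field(default_factory=dict)
    revcor: dict = field(default_factory=dict)
    generalization: dict = field(default_factory=dict)

    REQUIRED_SEEDS = ("database", "stimuli", "observers", "embeddings", "permutation", "generalization")

    def validate(self) -> None:
        missing = [k for k in self.REQUIRED_SEEDS if k not in self.seeds]
        if missing:
            raise ValueError(f"config is missing seeds for stages: {missing}")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def with_seed(self, seed: int) -> "RunConfig":
        """Rebase every stage seed on a single master seed."""
        cfg = RunConfig.from_dict(self.to_dict())
        for i, k in enumerate(self.REQUIRED_SEEDS):
            cfg.seeds[k] = seed * 1000 + i
        return cfg


def profile_config(profile: str = "tiny") -> RunConfig:
    """Built-in profiles: ``tiny`` (test default) and ``paper-scale``."""
    if profile == "tiny":
        return RunConfig(
            profile="tiny",
            seeds={k: i for i, k in enumerate(RunConfig.REQUIRED_SEEDS)},
            database=dict(n_exemplars=60, n_vertices=60, rank=8, factor_effect_sd=1.0,
                          residual_sd=1.0, texture_pixels=48, texture_rank=6, K=8, K_tex=6),
            experiment=dict(n_targets=2, blocks_per_session=9, trials_per_block=20, array_size=6),
            observers=dict(n_observers=4, kind="distance", noise_sd=0.5, component_sd=1.0,
                           template_jitter=0.3),
            embeddings=[
                dict(name="emb_shape", dim=64, shape_fidelity=0.9, texture_fidelity=0.0,
                     nonlinearity="none", noise_sd=0.1),
                dict(name="emb_texture", dim=64, shape_fidelity=0.0, texture_fidelity=0.9,
                     nonlinearity="none", noise_sd=0.1),
            ],
            cv=dict(fold_len=20),
            infotheory=dict(n_bins=3, n_perm=25, percentile=95.0),
            revcor=dict(estimator="ols", amp_max=50.0, amp_step=0.5),
            generalization=dict(k=8, loading_threshold=0.1,
                                amps=[0.33, 0.67, 1.0, 1.33, 1.67],
                                conditions=["view_-30", "view_0", "view_+30", "age_80", "sex_swap"]),
        )
    if profile == "paper-scale":
        cfg = profile_config("tiny")
        cfg.profile = "paper-scale"
        cfg.database.update(n_exemplars=355, n_vertices=4735, rank=100, texture_pixels=512,
                            texture_rank=50, K=50, K_tex=50)
        cfg.experiment.update(n_targets=4, blocks_per_session=90, trials_per_block=20)
        cfg.observers.update(n_observers=14)
        for e in cfg.embeddings:
            e["dim"] = 512
        cfg.cv.update(fold_len=200)
        cfg.infotheory.update(n_perm=100)
        return cfg
    raise ValueError(f"unknown profile {profile!r}")


def load_config(path) -> RunConfig:
    cfg = RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))
    cfg.validate()
    return cfg
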