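"""Run configuration: hyperparameters, cohort sizes, replicate counts, seeds.

A :class:`RunConfig` round-trips through YAML byte-identically (keys are
sorted and values normalized on write), and the master seed is stamped into
every artifact the pipeline emits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .intergm import Hyperparameters

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    hyper: Hyperparameters = field(default_factory=Hyperparameters)
    datasets: tuple[str, ...] = ("hard", "easy")
    n_items: int = 15
    n_pairs: int = 10
    n_passes: int = 3  # per role; 15 items x 3 = 45 listener decisions each
    model: str = "mh"
    model_a: float = 1.0
    model_b: float = 0.0
    n_null: int = 1000
    n_model_reps: int = 100
    alpha_level: float = 0.001
    seed: int = 0
    out_dir: str = "mhng-run"
    # column mapping for importing externally deposited logs
    import_columns: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, v in (("n_items", self.n_items), ("n_pairs", self.n_pairs),
                        ("n_null", self.n_null), ("n_model_reps", self.n_model_reps)):
            if v < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_passes < 0:
            raise ValueError("n_passes must be non-negative")
        if not 0 < self.alpha_level < 1:
            raise ValueError("significance level must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "datasets", "n_items", "n_pairs", "n_passes", "model", "model_a",
            "model_b", "n_null", "n_model_reps", "alpha_level", "seed", "out_dir",
            "import_columns",
        )}
        d["datasets"] = list(self.datasets)
        d["hyper"] = self.hyper.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        hyper = Hyperparameters.from_dict(d.pop("hyper", {}))
        if "datasets" in d:
            d["datasets"] = tuple(d["datasets"])
        return cls(hyper=hyper, **d)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True, default_flow_style=False)


def load_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))
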