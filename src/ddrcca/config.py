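"""Pipeline configuration."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class PipelineConfig:
    """All tunable parameters of the analysis pipeline, with defaults.

    Defaults mirror the standard analysis: 5 CV folds, 50 dimension-
    estimation repeats, wide-block compression to 100 components, 10,000
    permutations, top-20 loadings with an occurrence threshold of 2.
    """

    # preprocessing
    benchmark: str | None = None
    manual_flips: tuple[str, ...] = ()
    confound_squares: tuple[str, ...] = ()
    # dimension reduction
    n_folds: int = 5
    n_repeats: int = 50
    center_folds: bool = False
    # CCA
    bm_target_dim: int | None = 100
    n_perm: int = 10000
    alpha: float = 0.05
    block_permutation: bool = False
    # stability
    top_t: int = 20
    min_occurrence: int = 2
    foldwise_deconfound: bool = False
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_folds", "n_repeats", "n_perm", "top_t", "min_occurrence"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.bm_target_dim is not None and self.bm_target_dim < 1:
            raise ValueError("bm_target_dim must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.manual_flips = tuple(self.manual_flips)
        self.confound_squares = tuple(self.confound_squares)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["manual_flips"] = list(self.manual_flips)
        d["confound_squares"] = list(self.confound_squares)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def replace(self, **kwargs) -> "PipelineConfig":
        d = asdict(self)
        d.update(kwargs)
        return PipelineConfig(**d)
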