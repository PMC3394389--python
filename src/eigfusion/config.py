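"""Run configuration with flat key=value file serialization."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path


@dataclass
class RunConfig:
    """Tunable parameters shared across scoring, permutation and evaluation.

    Parameters
    ----------
    n_permutations
        Label permutations used for the pooled permutation null.
    p_threshold
        Significance cut applied to permutation p-values.
    top_n
        Ranking cut used for top-list calls (true/false positives); the same
        length is used for the bottom of the list when calling false negatives.
    copa_percentile
        Percentile of standardized cancer-group values used by the COPA statistic.
    fence_multiplier
        Tukey fence multiplier f in q75 + f*IQR for outlier-sample calls and the
        GTI outlier definition.
    seed
        Base seed for all randomness.
    """

    n_permutations: int = 100
    p_threshold: float = 0.001
    top_n: int = 10
    copa_percentile: float = 80.0
    fence_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if not 0.0 < self.copa_percentile < 100.0:
            raise ValueError("copa_percentile must be in (0, 100)")
        if self.fence_multiplier < 0.0:
            raise ValueError("fence_multiplier must be >= 0")

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load key=value text; keyword arguments override file values."""
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"n_permutations": int, "top_n": int, "seed": int,
                 "p_threshold": float, "copa_percentile": float,
                 "fence_multiplier": float}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in types:
                    raise ValueError(f"unknown config key {key!r}")
                kwargs[key] = casts[key](value.strip())
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)
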