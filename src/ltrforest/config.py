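"""Run configuration shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .errors import ConfigurationError

DEFAULT_EVALUE_GRID: tuple[float, ...] = (
    1e-50, 1e-40, 1e-30, 1e-20, 1e-10, 1e-05, 1e-02, 1e-01,
)
DEFAULT_LENGTH_GRID: tuple[int, ...] = (20, 50, 100, 200, 500, 700)
DEFAULT_COUNT_GRID: tuple[int, ...] = (1, 2, 3, 4, 5)

SUPERFAMILIES: tuple[str, ...] = ("Copia", "Gypsy", "Bel-Pao")

#: Key subdomain whose mere presence defines the baseline prediction.
KEY_DOMAINS: dict[str, str] = {
    "Copia": "RNase_HI_RT_Ty1",
    "Gypsy": "RNase_HI_RT_Ty3",
    "Bel-Pao": "RT_pepA17",
}


@dataclass(frozen=True)
class RunConfig:
    """Parameters controlling windowing, test enumeration and forest training.

    Defaults are the published operating point: 10 kb windows with 1 kb
    overlap, the 8-entry e-value grid, the 6-entry length grid, count
    thresholds 1..5, 100 trees and a minimum leaf size of 5.
    """

    window_length: int = 10_000
    window_overlap: int = 1_000
    evalue_grid: tuple[float, ...] = DEFAULT_EVALUE_GRID
    length_grid: tuple[int, ...] = DEFAULT_LENGTH_GRID
    count_grid: tuple[int, ...] = DEFAULT_COUNT_GRID
    n_trees: int = 100
    min_leaf: int = 5
    none_threshold: float = 0.5
    rng_seed: int = 0
    bootstrap: bool = True
    feature_sampling: bool = True

    def __post_init__(self) -> None:
        if self.window_length <= 0:
            raise ConfigurationError("window_length must be positive")
        if not 0 <= self.window_overlap < self.window_length:
            raise ConfigurationError(
                "window_overlap must satisfy 0 <= overlap < window_length"
            )
        for name in ("evalue_grid", "length_grid", "count_grid"):
            grid = getattr(self, name)
            object.__setattr__(self, name, tuple(grid))
            grid = getattr(self, name)
            if list(grid) != sorted(set(grid)):
                raise ConfigurationError(f"{name} must be strictly sorted")
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if self.min_leaf < 1:
            raise ConfigurationError("min_leaf must be >= 1")
        if not 0.0 <= self.none_threshold <= 1.0:
            raise ConfigurationError("none_threshold must lie in [0, 1]")

    @property
    def window_step(self) -> int:
        return self.window_length - self.window_overlap

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("evalue_grid", "length_grid", "count_grid"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**{
            k: tuple(v) if k in ("evalue_grid", "length_grid", "count_grid") else v
            for k, v in d.items()
        })
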