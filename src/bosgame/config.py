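"""Analysis configuration with the study's default constants."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Defaults for the full session analysis.

    last_n: steady-state window (final trials analyzed).  w: running-
    window length for FCO/FCL/psee smoothing.  mi_alpha/n_surrogates:
    surrogate MI test.  dcr_z: normal quantile for the DCR confidence
    box (1.96 = 95%).  dcr_threshold: minimum DCR amplitude for the
    dynamic-coordination label.  psee_k (1/ms) and psee_dt0 (ms):
    logistic visibility model.  seed: surrogate/shuffle RNG seed.
    """

    last_n: int = 200
    w: int = 8
    mi_alpha: float = 0.01
    n_surrogates: int = 1000
    dcr_z: float = 1.96
    dcr_threshold: float = 0.2
    psee_k: float = 0.04
    psee_dt0: float = 50.0
    min_length: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.last_n < 1 or self.w < 1 or self.n_surrogates < 1:
            raise ValueError("last_n, w and n_surrogates must be positive")
        if not 0 < self.mi_alpha < 1:
            raise ValueError("mi_alpha must be in (0, 1)")
        if self.psee_k <= 0:
            raise ValueError("psee_k must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8")
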