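"""Observation containers: (stimulation frequency, RoMaR) pairs with provenance."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError

__all__ = ["Observation", "ObservationSet", "SOURCES"]

SOURCES = ("seed", "bayesopt", "brute_force", "clinical_repeat")


@dataclass(frozen=True)
class Observation:
    """One rigidity measurement at a stimulation frequency."""

    x: float  # stimulation frequency, Hz
    y: float  # RoMaR value
    order_index: int = 0  # acquisition order within the session
    source: str = "brute_force"

    def __post_init__(self):
        if self.source not in SOURCES:
            raise InvalidParameterError(
                f"source must be one of {SOURCES}, got {self.source!r}"
            )


@dataclass
class ObservationSet:
    """Ordered collection of observations with array views for fitting."""

    observations: list[Observation] = field(default_factory=list)

    def append(self, obs: Observation) -> None:
        self.observations.append(obs)

    def add(self, x: float, y: float, source: str = "brute_force") -> Observation:
        obs = Observation(float(x), float(y), len(self.observations), source)
        self.observations.append(obs)
        return obs

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self):
        return iter(self.observations)

    @property
    def x(self) -> np.ndarray:
        return np.array([o.x for o in self.observations], dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.array([o.y for o in self.observations], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_hz": self.x,
                "romar": self.y,
                "source": [o.source for o in self.observations],
                "order_index": [o.order_index for o in self.observations],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ObservationSet":
        missing = {"frequency_hz", "romar"} - set(df.columns)
        if missing:
            raise InvalidParameterError(f"observations missing columns: {sorted(missing)}")
        obs = []
        for i, row in enumerate(df.itertuples(index=False)):
            obs.append(
                Observation(
                    float(row.frequency_hz),
                    float(row.romar),
                    int(getattr(row, "order_index", i)),
                    str(getattr(row, "source", "brute_force")),
                )
            )
        return cls(obs)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ObservationSet":
        return cls.from_dataframe(pd.read_csv(path))
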