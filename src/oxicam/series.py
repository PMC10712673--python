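"""Time-stamped SpO2 series shared by the simulator, pipeline and evaluator."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpO2Series"]


@dataclass
class SpO2Series:
    """Per-second SpO2 values with timestamps (seconds from record start).

    Used both for estimates (one value per window step; missing windows are
    ``nan``) and for the 1 Hz reference.
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def n_missing(self) -> int:
        return int(np.sum(~np.isfinite(self.values)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "spo2": self.values})

    def clipped(self, lo: float = 0.0, hi: float = 100.0) -> "SpO2Series":
        return SpO2Series(self.times, np.clip(self.values, lo, hi), self.label)
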