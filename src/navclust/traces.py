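"""Containers for whole-cell voltage-clamp current families."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["Sweep", "TraceSet"]


@dataclass
class Sweep:
    """One clamp sweep: the current response to a single command step.

    ``voltage`` is the test (or conditioning pre-pulse) potential in mV;
    ``interval_ms`` is set only for recovery-protocol sweeps and gives the
    P1-P2 inter-pulse interval.
    """

    voltage: float
    time_ms: np.ndarray
    current_pa: np.ndarray
    interval_ms: Optional[float] = None

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.current_pa = np.asarray(self.current_pa, dtype=float)
        if self.time_ms.shape != self.current_pa.shape:
            raise ValueError("time and current arrays must have equal length")
        if self.time_ms.size >= 3:
            dt = np.diff(self.time_ms)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("non-uniform sampling within sweep")

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0]) if self.time_ms.size > 1 else float("nan")


@dataclass
class TraceSet:
    """A family of sweeps from one protocol on one cell.

    ``protocol`` is one of ``activation``, ``inactivation``, ``recovery``.
    ``c_m`` is the whole-cell capacitance (pF) used for current-density
    normalization.  ``meta`` carries protocol metadata (holding voltage,
    P1 reference trace for recovery, generator seed, ...).
    """

    sweeps: list[Sweep]
    c_m: float
    protocol: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.c_m > 0:
            raise ValueError(f"capacitance must be positive, got {self.c_m}")

    def __len__(self) -> int:
        return len(self.sweeps)

    def voltages(self) -> np.ndarray:
        return np.array([s.voltage for s in self.sweeps], dtype=float)
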