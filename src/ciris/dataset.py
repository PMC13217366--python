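"""In-memory representation of a raw paired laser-on/off acquisition.

A scan steps the laser over a wavenumber grid; at each grid point the trap
cycle is repeated ``cycles_per_wn`` times and every cycle produces one
laser-off and one laser-on transient.  All transients share one uniform
time axis, so the record block is stored as a single (n_records, n_samples)
float32 array -- the same layout the binary container on disk uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .tof import TofTrace

__all__ = ["RawDataset"]


@dataclass
class RawDataset:
    """Raw transients plus the scan geometry needed to interpret them."""

    t_start: float
    dt: float
    n_samples: int
    wn_start: float
    wn_step: float
    n_wn: int
    cycles_per_wn: int
    wn_index: np.ndarray = field(repr=False)
    cycle_index: np.ndarray = field(repr=False)
    laser_on: np.ndarray = field(repr=False)
    intensities: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.wn_index = np.asarray(self.wn_index, dtype=np.uint32)
        self.cycle_index = np.asarray(self.cycle_index, dtype=np.uint32)
        self.laser_on = np.asarray(self.laser_on, dtype=np.uint8)
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        n = self.intensities.shape[0]
        if self.intensities.ndim != 2 or self.intensities.shape[1] != self.n_samples:
            raise ValueError("intensities must have shape (n_records, n_samples)")
        if not (self.wn_index.shape == self.cycle_index.shape == self.laser_on.shape == (n,)):
            raise ValueError("per-record metadata arrays must match the record count")
        if self.dt <= 0 or self.n_samples < 1:
            raise ValueError("invalid time axis")

    @property
    def n_records(self) -> int:
        return self.intensities.shape[0]

    @property
    def wn_grid(self) -> np.ndarray:
        return self.wn_start + self.wn_step * np.arange(self.n_wn)

    def time(self) -> np.ndarray:
        return self.t_start + self.dt * np.arange(self.n_samples)

    def wavenumbers(self) -> np.ndarray:
        """Per-record wavenumber values."""
        return self.wn_start + self.wn_step * self.wn_index.astype(float)

    def is_complete(self) -> bool:
        return self.n_records == self.n_wn * self.cycles_per_wn * 2

    def trace(self, i: int) -> TofTrace:
        return TofTrace(
            t_start=self.t_start,
            dt=self.dt,
            counts=self.intensities[i].astype(float),
            meta={
                "wavenumber": float(self.wn_start + self.wn_step * int(self.wn_index[i])),
                "laser_state": "on" if self.laser_on[i] else "off",
                "cycle_index": int(self.cycle_index[i]),
            },
        )

    def traces(self) -> Iterator[TofTrace]:
        for i in range(self.n_records):
            yield self.trace(i)

    def scaled(self, c: float) -> "RawDataset":
        """A copy with every intensity multiplied by ``c`` (diagnostics aid)."""
        return RawDataset(
            t_start=self.t_start,
            dt=self.dt,
            n_samples=self.n_samples,
            wn_start=self.wn_start,
            wn_step=self.wn_step,
            n_wn=self.n_wn,
            cycles_per_wn=self.cycles_per_wn,
            wn_index=self.wn_index.copy(),
            cycle_index=self.cycle_index.copy(),
            laser_on=self.laser_on.copy(),
            intensities=(self.intensities.astype(np.float64) * c).astype(np.float32),
        )
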