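"""Core data containers shared across the analysis modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "VoltageTrace",
    "SpikeRaster",
    "Burst",
    "VCSweepSet",
    "RawMEASignal",
]


@dataclass
class VoltageTrace:
    """One current-clamp sweep: sampled membrane potential plus the stimulus
    waveform, sample-aligned.

    voltage_mv and stimulus_pa have equal length; time of sample i is
    i / sampling_rate_hz.
    """

    sampling_rate_hz: float
    voltage_mv: np.ndarray
    stimulus_pa: np.ndarray
    holding_potential_mv: float = -65.0
    ljp_corrected: bool = False
    ljp_mv: float = 0.0
    series_resistance_mohm: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voltage_mv = np.asarray(self.voltage_mv, dtype=float)
        self.stimulus_pa = np.asarray(self.stimulus_pa, dtype=float)
        if self.voltage_mv.shape != self.stimulus_pa.shape:
            raise ValueError("voltage and stimulus must be the same length")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.ljp_corrected and self.ljp_mv == 0.0:
            raise ValueError("ljp_corrected traces must record ljp_mv")

    @property
    def n_samples(self) -> int:
        return self.voltage_mv.size

    @property
    def dt_ms(self) -> float:
        return 1e3 / self.sampling_rate_hz

    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass
class SpikeRaster:
    """Per-electrode sorted spike times (s) for one MEA well."""

    well_id: str
    electrodes: dict[str, np.ndarray]
    duration_s: float = 300.0

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for eid, times in self.electrodes.items():
            t = np.asarray(times, dtype=float)
            if t.size and (t.min() < 0 or t.max() > self.duration_s):
                raise ValueError(
                    f"electrode {eid}: spike times outside [0, duration]")
            if t.size > 1 and not np.all(np.diff(t) > 0):
                t = np.unique(t)
            clean[eid] = t
        self.electrodes = clean

    @property
    def n_electrodes(self) -> int:
        return len(self.electrodes)

    def total_spikes(self) -> int:
        return int(sum(t.size for t in self.electrodes.values()))

    def shifted(self, offset_s: float) -> "SpikeRaster":
        """Uniform time translation (spikes clipped to the new window)."""
        return SpikeRaster(
            self.well_id,
            {e: t + offset_s for e, t in self.electrodes.items()},
            self.duration_s + offset_s,
        )


@dataclass(frozen=True)
class Burst:
    """A detected (or planted) burst on one electrode."""

    start_s: float
    end_s: float
    first_spike_index: int
    n_spikes: int
    surprise: float

    def __post_init__(self) -> None:
        if self.end_s < self.start_s:
            raise ValueError("burst end before start")
        if self.n_spikes < 2:
            raise ValueError("a burst needs at least 2 spikes")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class VCSweepSet:
    """Voltage-clamp sweep family for one cell and one drug condition.

    currents_pa has shape (n_steps, n_samples); row i is the current trace
    for step potential step_mv[i].  The protocol timing (step duration, tail
    potential/duration) is carried in ``protocol``.
    """

    cell_id: str
    condition: str  # pre_drug | post_drug | subtracted
    capacitance_pf: float
    step_mv: np.ndarray
    currents_pa: np.ndarray
    sampling_rate_hz: float
    seal_resistance_gohm: Optional[float] = None
    series_resistance_mohm: Optional[float] = None
    protocol: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.step_mv = np.asarray(self.step_mv, dtype=float)
        self.currents_pa = np.atleast_2d(
            np.asarray(self.currents_pa, dtype=float))
        if self.capacitance_pf <= 0:
            raise ValueError("capacitance must be positive")
        if self.currents_pa.shape[0] != self.step_mv.size:
            raise ValueError("one current trace per voltage step required")

    @property
    def n_steps(self) -> int:
        return self.step_mv.size


@dataclass
class RawMEASignal:
    """Continuous extracellular signals: one row per electrode, with the
    ground-truth spike times retained for detector benchmarking."""

    signals: dict[str, np.ndarray]
    sampling_rate_hz: float
    ground_truth: dict[str, np.ndarray] = field(default_factory=dict)
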