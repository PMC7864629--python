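"""Passive and active membrane properties from current-clamp sweeps.

Operational definitions:

- RMP: mean voltage over the first window (default 100 ms) of a
  stimulus-free sweep.
- Input resistance R_N: ordinary least-squares slope of steady-state
  voltage (mean over the last 100 ms of each 500 ms step) against injected
  current, from subthreshold steps; sweeps containing APs in the
  measurement window are excluded.
- AP threshold: voltage where the rising-phase dV/dt first crosses
  5 mV/ms (searching backward from the peak; linear interpolation between
  the bracketing samples).
- AP amplitude: peak voltage minus the holding potential V_h; half-width:
  time between the rising and falling crossings of V_h + amplitude/2.
- fAHP: voltage at the first post-peak sample where the 1 ms sliding mean
  of dV/dt enters the band [-0.5, +0.5] mV/ms after repolarization
  (i.e. where the falling phase flattens out).
- mAHP / sAHP: minimum voltage within 1 s after the offset of the last
  pulse of a 50 Hz, 25-pulse train, and the voltage exactly 1 s after that
  offset, both relative to V_h (negative values = hyperpolarized).
- QC: R_S < 30 MOhm, R_N > 200 MOhm, V_rest < -45 mV, AP amplitude
  > 80 mV (all strict).

dV/dt uses central differences (one-sided at the edges), scaled to mV/ms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ephyskit.types import VoltageTrace

__all__ = [
    "PassiveProperties", "APFeatures", "AHPFeatures", "QCLimits", "QCResult",
    "measure_rmp", "input_resistance", "detect_aps", "ap_threshold",
    "ap_amplitude_halfwidth", "fahp", "post_burst_ahp", "apply_qc", "dvdt",
    "NoThresholdError",
]

log = logging.getLogger(__name__)


class NoThresholdError(ValueError):
    """The dV/dt criterion is never reached on the rising phase."""


@dataclass
class PassiveProperties:
    rmp_mv: float
    input_resistance_mohm: float
    series_resistance_mohm: Optional[float] = None


@dataclass
class APFeatures:
    threshold_mv: float
    amplitude_mv: float
    half_width_ms: float
    fahp_mv: Optional[float]
    peak_time_ms: float


@dataclass
class AHPFeatures:
    mahp_mv: float
    sahp_mv: float


@dataclass
class QCLimits:
    """Inclusion gates; pass requires all four strict inequalities."""

    max_series_resistance_mohm: float = 30.0
    min_input_resistance_mohm: float = 200.0
    max_resting_potential_mv: float = -45.0
    min_ap_amplitude_mv: float = 80.0


@dataclass
class QCResult:
    passed: bool
    reasons: list[str]
    indeterminate: bool = False


def dvdt(trace: VoltageTrace) -> np.ndarray:
    """First derivative of voltage in mV/ms (central differences)."""
    return np.gradient(trace.voltage_mv) * trace.sampling_rate_hz / 1e3


def measure_rmp(trace: VoltageTrace, window_ms: float = 100.0) -> float:
    """Resting membrane potential: mean voltage over the first ``window_ms``
    of a zero-current sweep.  Raises if the stimulus is nonzero anywhere in
    the window."""
    n = max(int(round(window_ms * 1e-3 * trace.sampling_rate_hz)), 1)
    n = min(n, trace.n_samples)
    if np.any(trace.stimulus_pa[:n] != 0):
        raise ValueError("nonzero stimulus inside the RMP window")
    return float(trace.voltage_mv[:n].mean())


def _step_extent(stim: np.ndarray) -> tuple[int, int]:
    nz = np.nonzero(stim)[0]
    if nz.size == 0:
        raise ValueError("sweep has no current step")
    return int(nz[0]), int(nz[-1]) + 1  # [onset, offset)


def input_resistance(step_sweeps: Sequence[VoltageTrace],
                     steady_window_ms: float = 100.0,
                     exclude_spiking: bool = True) -> float:
    """Input resistance (MOhm): OLS slope of steady-state V against step
    current.

    Steady state is the mean voltage over the last ``steady_window_ms`` of
    each step.  Sweeps with APs (samples > 0 mV) during the measurement
    window are excluded with a warning; fewer than 3 usable amplitudes
    raise, except that exactly 2 amplitudes are accepted when nothing was
    excluded (a line through two points).
    """
    points = []
    n_excluded = 0
    for tr in step_sweeps:
        onset, offset = _step_extent(tr.stimulus_pa)
        amp = float(tr.stimulus_pa[onset:offset].mean())
        nw = max(int(round(steady_window_ms * 1e-3 * tr.sampling_rate_hz)), 1)
        seg = tr.voltage_mv[max(offset - nw, onset):offset]
        if exclude_spiking and np.any(seg > 0.0):
            n_excluded += 1
            log.warning("excluding %+.0f pA sweep: APs in the steady-state "
                        "window", amp)
            continue
        points.append((amp, float(seg.mean())))
    amps = np.array([a for a, _ in points])
    if np.unique(amps).size < 3 and not (np.unique(amps).size == 2
                                         and n_excluded == 0):
        raise ValueError(f"only {np.unique(amps).size} usable step "
                         "amplitudes; need >= 3")
    volts = np.array([v for _, v in points])
    slope_mv_per_pa = np.polyfit(amps, volts, 1)[0]
    return float(slope_mv_per_pa * 1e3)  # mV/pA -> MOhm


def detect_aps(trace: VoltageTrace, min_peak_mv: float = 0.0,
               min_dvdt_mv_per_ms: float = 10.0,
               min_separation_ms: float = 2.0) -> list[int]:
    """AP peak sample indices: local maxima above ``min_peak_mv`` preceded
    (within 2 ms) by dV/dt >= ``min_dvdt_mv_per_ms``, at least
    ``min_separation_ms`` apart.  An empty list is a valid result."""
    v = trace.voltage_mv
    if trace.sampling_rate_hz < 10000.0:
        raise ValueError("AP detection requires >= 10 kHz sampling")
    d = dvdt(trace)
    fs = trace.sampling_rate_hz
    look = max(int(round(2.0e-3 * fs)), 1)
    sep = max(int(round(min_separation_ms * 1e-3 * fs)), 1)
    cand = np.nonzero((v[1:-1] > min_peak_mv) & (v[1:-1] >= v[:-2])
                      & (v[1:-1] > v[2:]))[0] + 1
    peaks: list[int] = []
    for i in cand:
        if d[max(i - look, 0):i + 1].max() < min_dvdt_mv_per_ms:
            continue
        if peaks and i - peaks[-1] < sep:
            if v[i] > v[peaks[-1]]:
                peaks[-1] = int(i)
            continue
        peaks.append(int(i))
    return peaks


def ap_threshold(trace: VoltageTrace, peak_index: int,
                 criterion_dvdt: float = 5.0) -> float:
    """Threshold voltage: where dV/dt last crosses ``criterion_dvdt`` from
    below on the rising phase before the peak (linear interpolation
    between the bracketing samples)."""
    d = dvdt(trace)
    v = trace.voltage_mv
    # rising phase: walk back from the peak while the trace is ascending
    start = peak_index
    while start > 0 and v[start - 1] <= v[start]:
        start -= 1
    seg = d[start:peak_index + 1]
    if seg.size < 2:
        raise NoThresholdError("rising phase too short to locate threshold")
    if np.all(seg < criterion_dvdt):
        raise NoThresholdError(
            f"dV/dt never reaches {criterion_dvdt} mV/ms before the peak")
    up = np.nonzero((seg[:-1] < criterion_dvdt)
                    & (seg[1:] >= criterion_dvdt))[0]
    if up.size == 0:
        # criterion already exceeded at the foot of the rising phase
        return float(v[start])
    i = start + int(up[-1])  # last upward crossing before the peak
    d0, d1 = d[i], d[i + 1]
    frac = 0.0 if d1 == d0 else (criterion_dvdt - d0) / (d1 - d0)
    return float(v[i] + frac * (v[i + 1] - v[i]))


def _interp_crossing(t0: float, t1: float, v0: float, v1: float,
                     level: float) -> float:
    if v1 == v0:
        return t0
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def ap_amplitude_halfwidth(trace: VoltageTrace, peak_index: int,
                           v_h: Optional[float] = None,
                           max_fall_ms: float = 20.0
                           ) -> tuple[float, float]:
    """AP amplitude (peak minus V_h, mV) and half-width (ms) at half the
    amplitude relative to V_h, with linear interpolation at both
    crossings.  Raises if the falling crossing is not found within
    ``max_fall_ms`` of the peak."""
    if v_h is None:
        v_h = trace.holding_potential_mv
    v = trace.voltage_mv
    dt_ms = trace.dt_ms
    peak_v = float(v[peak_index])
    amplitude = peak_v - v_h
    if amplitude <= 0:
        raise ValueError("non-positive AP amplitude")
    half = v_h + amplitude / 2.0
    i = peak_index
    while i > 0 and v[i - 1] >= half:
        i -= 1
    if i == 0 and v[0] >= half:
        raise ValueError("rising half-amplitude crossing not found")
    t_rise = _interp_crossing((i - 1) * dt_ms, i * dt_ms, v[i - 1], v[i],
                              half)
    j = peak_index
    limit = min(peak_index + int(round(max_fall_ms / dt_ms)), v.size - 1)
    while j < limit and v[j + 1] > half:
        j += 1
    if j == limit and v[j] > half:
        raise ValueError("falling half-amplitude crossing not found within "
                         f"{max_fall_ms} ms of the peak")
    t_fall = _interp_crossing(j * dt_ms, (j + 1) * dt_ms, v[j], v[j + 1],
                              half)
    return float(amplitude), float(t_fall - t_rise)


def fahp(trace: VoltageTrace, peak_index: int,
         band_mv_per_ms: float = 0.5,
         search_window_ms: float = 10.0) -> Optional[float]:
    """Fast AHP: voltage at the first post-peak sample where the 1 ms
    sliding mean of dV/dt enters [-band, +band] mV/ms after having been
    below -band (repolarization flattening out).  Returns ``None`` (logged)
    if the band is never entered inside the search window."""
    fs = trace.sampling_rate_hz
    d = dvdt(trace)
    n_smooth = max(int(round(1.0e-3 * fs)), 1)
    kernel = np.ones(n_smooth) / n_smooth
    end = min(peak_index + int(round(search_window_ms * 1e-3 * fs)),
              trace.n_samples)
    seg = d[peak_index:end]
    if seg.size < n_smooth:
        log.warning("fAHP window shorter than the smoothing kernel")
        return None
    smooth = np.convolve(seg, kernel, mode="valid")
    # smooth[i] = mean of dV/dt over the 1 ms starting i samples post-peak
    was_falling = False
    for i, s in enumerate(smooth):
        if was_falling and abs(s) <= band_mv_per_ms:
            return float(trace.voltage_mv[peak_index + i
                                          + (n_smooth - 1) // 2])
        if s < -band_mv_per_ms:
            was_falling = True
    log.warning("fAHP derivative band never entered within %.1f ms of the "
                "peak", search_window_ms)
    return None


def post_burst_ahp(trace: VoltageTrace,
                   v_h: Optional[float] = None) -> AHPFeatures:
    """Medium and slow AHP after a pulse train.

    mAHP = min V over (offset, offset + 1 s] minus V_h; sAHP = V at
    offset + 1 s minus V_h, where offset is the end of the last stimulus
    pulse (from the stimulus channel).  Requires the recording to extend
    at least 1.2 s past the offset.
    """
    if v_h is None:
        v_h = trace.holding_potential_mv
    fs = trace.sampling_rate_hz
    _, offset = _step_extent(trace.stimulus_pa)
    n_1s = int(round(1.0 * fs))
    if trace.n_samples < offset + int(round(1.2 * fs)):
        raise ValueError("recording must extend >= 1.2 s past the last "
                         "pulse offset")
    seg = trace.voltage_mv[offset + 1:offset + n_1s + 1]
    mahp = float(seg.min() - v_h)
    sahp = float(trace.voltage_mv[offset + n_1s] - v_h)
    return AHPFeatures(mahp_mv=mahp, sahp_mv=sahp)


def apply_qc(rmp_mv: Optional[float],
             input_resistance_mohm: Optional[float],
             series_resistance_mohm: Optional[float],
             ap_amplitude_mv: Optional[float],
             limits: QCLimits | None = None) -> QCResult:
    """Apply the four inclusion gates; fail lists every violated gate.

    Any missing quantity makes the result indeterminate (flagged, not
    passed)."""
    if limits is None:
        limits = QCLimits()
    fields = {"V_rest": rmp_mv, "R_N": input_resistance_mohm,
              "R_S": series_resistance_mohm, "AP amplitude": ap_amplitude_mv}
    missing = [k for k, val in fields.items()
               if val is None or not np.isfinite(val)]
    if missing:
        return QCResult(False, [f"missing: {m}" for m in missing],
                        indeterminate=True)
    reasons = []
    if not series_resistance_mohm < limits.max_series_resistance_mohm:
        reasons.append(
            f"R_S {series_resistance_mohm:g} MOhm not < "
            f"{limits.max_series_resistance_mohm:g}")
    if not input_resistance_mohm > limits.min_input_resistance_mohm:
        reasons.append(f"R_N {input_resistance_mohm:g} MOhm not > "
                       f"{limits.min_input_resistance_mohm:g}")
    if not rmp_mv < limits.max_resting_potential_mv:
        reasons.append(f"V_rest {rmp_mv:g} mV not < "
                       f"{limits.max_resting_potential_mv:g}")
    if not ap_amplitude_mv > limits.min_ap_amplitude_mv:
        reasons.append(f"AP amplitude {ap_amplitude_mv:g} mV not > "
                       f"{limits.min_ap_amplitude_mv:g}")
    return QCResult(len(reasons) == 0, reasons)
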