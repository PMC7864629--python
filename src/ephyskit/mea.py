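"""Well-level MEA activity and bursting metrics from spike rasters.

Metric definitions:

- active electrode: >= 1 spike/min over the recording (>= 5 spikes in
  300 s; count-based, inclusive);
- mean firing frequency (Hz): total spikes on active electrodes divided by
  (number of active electrodes x duration);
- ISI CoV: per active electrode with >= 3 spikes, SD/mean of the
  inter-spike intervals; well value is the unweighted mean across
  qualifying electrodes (a pooled variant is available by flag);
- bursts: Poisson-surprise maximization in the style of Legendy & Salcman
  — candidate runs of short ISIs are grown and trimmed to maximize the
  surprise S = -ln P(N >= n | Poisson at the electrode's mean rate), and
  accepted when S >= min_surprise (natural log, default 10) with >= 3
  spikes;
- burst frequency (Hz): total bursts / (bursting electrodes x duration);
  IBI CoV: SD/mean of gaps between consecutive burst starts, averaged
  across electrodes with >= 3 bursts; burst %: percentage of all spikes on
  active electrodes that fall inside bursts.

Raw-signal spike detection: 300-5000 Hz Butterworth band-pass, robust
noise RMS (median absolute signal / 0.6745 over rolling windows), and
threshold crossings at 6x RMS of either polarity with 1 ms dead time,
timed at the extremum of each crossing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as spsig
from scipy import stats as sps

from ephyskit.types import Burst, RawMEASignal, SpikeRaster

__all__ = [
    "WellMetrics", "poisson_surprise", "detect_bursts", "active_electrodes",
    "mean_firing_frequency", "isi_cov", "burst_summary", "well_metrics",
    "drug_delta", "detect_spikes_raw", "match_bursts",
]

log = logging.getLogger(__name__)


@dataclass
class WellMetrics:
    """Per-well summary; burst metrics are None when nothing bursts."""

    well_id: str
    n_active_electrodes: int
    mean_firing_frequency_hz: Optional[float]
    isi_cov: Optional[float]
    n_bursting_electrodes: int
    n_bursts: int
    burst_frequency_hz: Optional[float]
    ibi_cov: Optional[float]
    spikes_per_burst: Optional[float]
    burst_percent: Optional[float]

    def as_dict(self) -> dict:
        return {
            "well_id": self.well_id,
            "n_active_electrodes": self.n_active_electrodes,
            "mean_firing_frequency_hz": self.mean_firing_frequency_hz,
            "isi_cov": self.isi_cov,
            "n_bursting_electrodes": self.n_bursting_electrodes,
            "n_bursts": self.n_bursts,
            "burst_frequency_hz": self.burst_frequency_hz,
            "ibi_cov": self.ibi_cov,
            "spikes_per_burst": self.spikes_per_burst,
            "burst_percent": self.burst_percent,
        }


# ---------------------------------------------------------------------------
# surprise and burst detection

def poisson_surprise(n: int, rate_hz: float, span_s: float) -> float:
    """S = -ln P(N >= n) for a Poisson count at ``rate_hz`` over ``span_s``.

    Computed from the regularized upper incomplete gamma function, which
    equals the Poisson tail sum exactly.
    """
    if n <= 0:
        return 0.0
    mu = rate_hz * span_s
    logp = sps.poisson.logsf(n - 1, mu)
    return float(-logp)


def detect_bursts(spike_times: np.ndarray, duration_s: float,
                  min_surprise: float = 10.0, seed_factor: float = 0.5,
                  min_spikes: int = 3) -> list[Burst]:
    """Poisson-surprise burst detection on one electrode.

    The electrode's mean rate r = n_total/duration sets the null Poisson
    model.  (1) Candidate runs are maximal stretches where consecutive
    ISIs are below ``seed_factor`` times the mean ISI; (2) each run is
    extended forward spike-by-spike while the surprise increases; (3)
    spikes are trimmed from the start while the surprise increases; (4)
    the run is accepted if S >= ``min_surprise`` and it contains at least
    ``min_spikes`` spikes.  Accepted bursts are non-overlapping, taken
    greedily in time order.
    """
    t = np.asarray(spike_times, dtype=float)
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n_total = t.size
    if n_total < max(min_spikes, 2):
        return []
    rate = n_total / duration_s
    isi = np.diff(t)
    mean_isi = isi.mean()
    if mean_isi <= 0:
        return []
    short = isi < seed_factor * mean_isi

    def surprise_of(i: int, j: int) -> float:
        # spikes i..j inclusive
        return poisson_surprise(j - i + 1, rate, max(t[j] - t[i], 1e-12))

    bursts: list[Burst] = []
    next_free = 0  # first spike index not yet covered by an accepted burst
    k = 0
    while k < short.size:
        if not short[k]:
            k += 1
            continue
        i = k          # short[i..j-1] all True -> spikes i..j are the run
        j = k
        while j < short.size and short[j]:
            j += 1
        k = j + 1
        i = max(i, next_free)
        if j <= i:
            continue
        # extend forward while surprise increases
        s = surprise_of(i, j)
        while j + 1 < n_total:
            s_new = surprise_of(i, j + 1)
            if s_new > s:
                j += 1
                s = s_new
            else:
                break
        # trim from the start while surprise increases
        while j - i + 1 > 2:
            s_new = surprise_of(i + 1, j)
            if s_new > s:
                i += 1
                s = s_new
            else:
                break
        if s >= min_surprise and j - i + 1 >= min_spikes:
            bursts.append(Burst(float(t[i]), float(t[j]), int(i),
                                int(j - i + 1), float(s)))
            next_free = j + 1
            k = max(k, j + 1)
    return bursts


def match_bursts(detected: Sequence[Burst], truth: Sequence[Burst],
                 min_overlap: float = 0.5) -> tuple[int, int, int]:
    """Greedy interval matching: a detected burst matches a ground-truth
    burst when their overlap covers >= ``min_overlap`` of the shorter
    interval.  Returns (n_matched, n_detected, n_truth)."""
    used = [False] * len(truth)
    matched = 0
    for d in detected:
        for i, g in enumerate(truth):
            if used[i]:
                continue
            lo = max(d.start_s, g.start_s)
            hi = min(d.end_s, g.end_s)
            shorter = max(min(d.duration_s, g.duration_s), 1e-9)
            if hi - lo >= min_overlap * shorter:
                used[i] = True
                matched += 1
                break
    return matched, len(detected), len(truth)


# ---------------------------------------------------------------------------
# well metrics

def active_electrodes(raster: SpikeRaster,
                      min_rate_per_min: float = 1.0) -> list[str]:
    """Electrodes with >= 1 spike/min (count-based, threshold inclusive)."""
    need = min_rate_per_min * raster.duration_s / 60.0
    return [e for e, t in raster.electrodes.items() if t.size >= need]


def mean_firing_frequency(raster: SpikeRaster,
                          include_inactive: bool = False
                          ) -> Optional[float]:
    """Total spikes divided by (active electrodes x duration), Hz.

    Spikes on inactive electrodes are excluded by default (the denominator
    counts active electrodes only); ``include_inactive`` pools all spikes.
    Returns None when no electrode is active.
    """
    active = active_electrodes(raster)
    if not active:
        return None
    if include_inactive:
        total = raster.total_spikes()
    else:
        total = sum(raster.electrodes[e].size for e in active)
    return total / (len(active) * raster.duration_s)


def isi_cov(raster: SpikeRaster, min_spikes: int = 3,
            pooled: bool = False) -> Optional[float]:
    """Inter-spike-interval coefficient of variation.

    Default: per-electrode CoV (SD/mean of ISIs, electrodes with >=
    ``min_spikes`` spikes among the active set), averaged unweighted across
    electrodes.  ``pooled=True`` computes one CoV over all ISIs pooled.
    """
    active = set(active_electrodes(raster))
    covs, pooled_isis = [], []
    for e in active:
        t = raster.electrodes[e]
        if t.size < min_spikes:
            continue
        isis = np.diff(t)
        m = isis.mean()
        if m > 0:
            covs.append(isis.std(ddof=0) / m)
            pooled_isis.append(isis)
    if not covs:
        return None
    if pooled:
        allisi = np.concatenate(pooled_isis)
        return float(allisi.std(ddof=0) / allisi.mean())
    return float(np.mean(covs))


def burst_summary(raster: SpikeRaster,
                  bursts_per_electrode: dict[str, list[Burst]],
                  min_bursts_for_ibi: int = 3) -> dict:
    """Well-level burst metrics from per-electrode burst lists.

    burst_frequency = total bursts / (bursting electrodes x duration);
    IBI = gaps between consecutive burst starts per electrode, CoV averaged
    over electrodes with >= ``min_bursts_for_ibi`` bursts; spikes_per_burst
    = mean over all bursts; burst_percent = 100 x spikes inside bursts /
    all spikes on active electrodes.
    """
    active = active_electrodes(raster)
    bursting = [e for e, bl in bursts_per_electrode.items() if bl]
    n_bursts = sum(len(bl) for bl in bursts_per_electrode.values())
    total_active_spikes = sum(raster.electrodes[e].size for e in active)
    spikes_in_bursts = sum(b.n_spikes for bl in bursts_per_electrode.values()
                           for b in bl)
    out = {
        "n_bursting_electrodes": len(bursting),
        "n_bursts": n_bursts,
        "burst_frequency_hz": None,
        "ibi_cov": None,
        "spikes_per_burst": None,
        "burst_percent": (100.0 * spikes_in_bursts / total_active_spikes
                          if total_active_spikes else None),
    }
    if n_bursts == 0:
        if total_active_spikes:
            out["burst_percent"] = 0.0
        return out
    out["burst_frequency_hz"] = n_bursts / (len(bursting)
                                            * raster.duration_s)
    out["spikes_per_burst"] = spikes_in_bursts / n_bursts
    ibi_covs = []
    for e in bursting:
        starts = np.array([b.start_s for b in bursts_per_electrode[e]])
        if starts.size >= min_bursts_for_ibi:
            ibis = np.diff(np.sort(starts))
            if ibis.size and ibis.mean() > 0:
                ibi_covs.append(ibis.std(ddof=0) / ibis.mean())
    if ibi_covs:
        out["ibi_cov"] = float(np.mean(ibi_covs))
    return out


def well_metrics(raster: SpikeRaster, min_surprise: float = 10.0,
                 seed_factor: float = 0.5, min_spikes: int = 3
                 ) -> tuple[WellMetrics, dict[str, list[Burst]]]:
    """Run burst detection on every active electrode and assemble the
    well-level metric set."""
    active = active_electrodes(raster)
    bursts = {e: detect_bursts(raster.electrodes[e], raster.duration_s,
                               min_surprise, seed_factor, min_spikes)
              for e in active}
    bs = burst_summary(raster, bursts)
    wm = WellMetrics(
        well_id=raster.well_id,
        n_active_electrodes=len(active),
        mean_firing_frequency_hz=mean_firing_frequency(raster),
        isi_cov=isi_cov(raster),
        **bs)
    return wm, bursts


def drug_delta(pre: WellMetrics, post: WellMetrics) -> dict:
    """Per-metric post-minus-pre differences for one well (paired design).

    Raises when the two measurements are from different wells; a delta is
    None when either side is missing.
    """
    if pre.well_id != post.well_id:
        raise ValueError(f"well mismatch: {pre.well_id!r} vs "
                         f"{post.well_id!r}")
    out = {"well_id": pre.well_id}
    for key, a in pre.as_dict().items():
        if key == "well_id":
            continue
        b = post.as_dict()[key]
        out[f"delta_{key}"] = None if a is None or b is None else b - a
    return out


# ---------------------------------------------------------------------------
# raw-signal spike detection

def detect_spikes_raw(signal: np.ndarray, sampling_rate_hz: float,
                      band_hz: tuple[float, float] = (300.0, 5000.0),
                      k_rms: float = 6.0, dead_time_ms: float = 1.0,
                      rms_window_s: float = 10.0) -> np.ndarray:
    """Threshold-crossing spike times (s) from one electrode's raw signal.

    Butterworth band-pass (2nd order, zero-phase), noise RMS estimated
    robustly as median(|x|)/0.6745 per ``rms_window_s`` window, events at
    crossings of +-``k_rms`` x local RMS with ``dead_time_ms`` dead time,
    each timed at the extremum of its crossing.
    """
    x = np.asarray(signal, dtype=float)
    nyq = sampling_rate_hz / 2.0
    if band_hz[1] >= nyq:
        band_hz = (band_hz[0], 0.99 * nyq)
    sos = spsig.butter(2, [band_hz[0] / nyq, band_hz[1] / nyq],
                       btype="band", output="sos")
    pad = int(3 * sampling_rate_hz / band_hz[0])
    if x.size <= pad:
        raise ValueError("signal shorter than the filter warm-up")
    y = spsig.sosfiltfilt(sos, x)
    if not np.any(y):
        return np.array([])
    # robust rolling RMS
    win = max(int(round(rms_window_s * sampling_rate_hz)), 1)
    n_win = max(int(np.ceil(y.size / win)), 1)
    rms = np.empty(y.size)
    for w in range(n_win):
        seg = y[w * win:(w + 1) * win]
        r = np.median(np.abs(seg)) / 0.6745
        rms[w * win:(w + 1) * win] = r
    global_r = np.median(np.abs(y)) / 0.6745
    rms[rms <= 0] = global_r if global_r > 0 else 1e-12
    over = np.abs(y) > k_rms * rms
    if not over.any():
        return np.array([])
    dead = max(int(round(dead_time_ms * 1e-3 * sampling_rate_hz)), 1)
    idx = np.nonzero(over)[0]
    times = []
    i = 0
    while i < idx.size:
        start = idx[i]
        stop = start
        j = i
        while j + 1 < idx.size and idx[j + 1] - idx[j] <= dead:
            j += 1
            stop = idx[j]
        seg = np.abs(y[start:stop + 1])
        times.append((start + int(np.argmax(seg))) / sampling_rate_hz)
        i = j + 1
    return np.asarray(times)


def detect_spikes_raw_well(raw: RawMEASignal, **kwargs
                           ) -> SpikeRaster:
    """Apply :func:`detect_spikes_raw` to every electrode of a raw MEA
    recording and return the resulting raster."""
    n = len(next(iter(raw.signals.values())))
    duration = (n - 1) / raw.sampling_rate_hz
    electrodes = {e: detect_spikes_raw(sig, raw.sampling_rate_hz, **kwargs)
                  for e, sig in raw.signals.items()}
    return SpikeRaster("raw", electrodes, duration)
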