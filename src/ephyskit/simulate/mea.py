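"""Synthetic MEA spike rasters and continuous extracellular signals.

The raster generator is a two-state renewal model per electrode: a tonic
homogeneous Poisson background, plus compound bursts whose onsets form an
independent Poisson process.  Each burst contains a Poisson-dispersed
number of spikes (minimum 2) at a jittered intra-burst inter-spike
interval.  The planted burst intervals are returned as ground truth so a
burst detector can be benchmarked against them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ephyskit.types import Burst, RawMEASignal, SpikeRaster

__all__ = ["SpikeTrainGenParams", "simulate_mea_well",
           "simulate_extracellular", "biphasic_template"]

log = logging.getLogger(__name__)


@dataclass
class SpikeTrainGenParams:
    """Parameters of the two-state raster generator.

    Rates are per electrode.  ``active_fraction`` of electrodes receive the
    stated rates; the remainder fire at ``inactive_rate_per_min`` (< 1
    spike/min, so they fall below the active-electrode rule).
    """

    n_electrodes: int = 64
    duration_s: float = 300.0
    active_fraction: float = 1.0
    tonic_rate_hz: float = 0.5
    burst_rate_per_min: float = 6.0
    spikes_per_burst_mean: float = 10.0
    spikes_per_burst_dispersion: float = 1.0  # 1 = Poisson; >1 = gamma-Poisson
    intra_burst_isi_ms: float = 10.0
    intra_burst_jitter_ms: float = 2.0
    refractory_ms: float = 2.0
    inactive_rate_per_min: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.tonic_rate_hz, self.burst_rate_per_min,
               self.duration_s) < 0:
            raise ValueError("rates and duration must be non-negative")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError("active_fraction must be in [0, 1]")
        if self.tonic_rate_hz > 0 and self.intra_burst_isi_ms >= \
                1000.0 / self.tonic_rate_hz:
            raise ValueError("intra-burst ISI must be shorter than the "
                             "tonic mean ISI")


def _burst_spikes(onset: float, n: int, p: SpikeTrainGenParams,
                  rng: np.random.Generator) -> np.ndarray:
    isis = rng.normal(p.intra_burst_isi_ms, p.intra_burst_jitter_ms,
                      size=n - 1) / 1e3
    isis = np.maximum(isis, p.refractory_ms / 1e3)
    return onset + np.concatenate([[0.0], np.cumsum(isis)])


def simulate_mea_well(params: SpikeTrainGenParams,
                      well_id: str = "W1"
                      ) -> tuple[SpikeRaster, dict[str, list[Burst]]]:
    """Generate one well's raster plus planted ground-truth bursts.

    Returns ``(raster, ground_truth)`` where ``ground_truth`` maps electrode
    id to the list of planted bursts (surprise set to NaN — it is a
    detector quantity).  Spikes violating the refractory period after
    merging the tonic and burst streams are thinned with a logged warning.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n_active = int(round(p.active_fraction * p.n_electrodes))
    electrodes: dict[str, np.ndarray] = {}
    ground_truth: dict[str, list[Burst]] = {}
    n_thinned = 0
    for e in range(p.n_electrodes):
        eid = f"E{e + 1:02d}"
        active = e < n_active
        tonic_rate = p.tonic_rate_hz if active \
            else p.inactive_rate_per_min / 60.0
        n_tonic = rng.poisson(tonic_rate * p.duration_s)
        spikes = [np.sort(rng.uniform(0.0, p.duration_s, size=n_tonic))]
        bursts: list[Burst] = []
        if active and p.burst_rate_per_min > 0:
            n_bursts = rng.poisson(p.burst_rate_per_min / 60.0 * p.duration_s)
            onsets = np.sort(rng.uniform(0.0, p.duration_s, size=n_bursts))
            for onset in onsets:
                if p.spikes_per_burst_dispersion > 1.0:
                    # gamma-Poisson mixture for overdispersed counts
                    shape = p.spikes_per_burst_mean / \
                        (p.spikes_per_burst_dispersion - 1.0)
                    lam = rng.gamma(shape,
                                    p.spikes_per_burst_dispersion - 1.0)
                    n_sp = rng.poisson(lam)
                else:
                    n_sp = rng.poisson(p.spikes_per_burst_mean)
                n_sp = max(int(n_sp), 2)
                times = _burst_spikes(onset, n_sp, p, rng)
                times = times[times <= p.duration_s]
                if times.size >= 2:
                    spikes.append(times)
                    bursts.append(Burst(times[0], times[-1], -1,
                                        times.size, float("nan")))
        merged = np.sort(np.concatenate(spikes))
        if merged.size > 1:
            keep = np.concatenate(
                [[True], np.diff(merged) >= p.refractory_ms / 1e3])
            n_thinned += int((~keep).sum())
            merged = merged[keep]
        electrodes[eid] = merged
        ground_truth[eid] = bursts
    if n_thinned:
        log.warning("thinned %d spikes violating the %.1f ms refractory "
                    "period", n_thinned, p.refractory_ms)
    return SpikeRaster(well_id, electrodes, p.duration_s), ground_truth


def biphasic_template(sampling_rate_hz: float = 12500.0,
                      width_ms: float = 1.0) -> np.ndarray:
    """Biphasic extracellular spike template, unit negative peak.

    A sharp negative deflection followed by a slower positive overshoot,
    ~1 ms total, as seen by a planar electrode near a firing soma.
    """
    n = max(int(round(width_ms * 1e-3 * sampling_rate_hz)), 5)
    t = np.linspace(0.0, width_ms, n)
    neg = -np.exp(-((t - 0.25 * width_ms) ** 2) / (2 * (0.08 * width_ms) ** 2))
    pos = 0.45 * np.exp(-((t - 0.55 * width_ms) ** 2)
                        / (2 * (0.15 * width_ms) ** 2))
    w = neg + pos
    return w / np.abs(w).max()


def simulate_extracellular(raster: SpikeRaster,
                           amplitude_rms: float = 8.0,
                           noise_sd: float = 1.0,
                           sampling_rate_hz: float = 12500.0,
                           template: np.ndarray | None = None,
                           seed: int | np.random.Generator = 0
                           ) -> RawMEASignal:
    """Continuous extracellular signal per electrode: white Gaussian noise
    plus a biphasic template at every raster spike time.

    ``amplitude_rms`` scales the template peak in multiples of the noise
    RMS (``noise_sd``); when ``noise_sd`` is 0 it is interpreted against a
    unit RMS so noiseless signals remain well-defined.  Spikes closer than
    the template width superpose linearly (logged).  Ground-truth spike
    times are carried on the returned object.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if template is None:
        template = biphasic_template(sampling_rate_hz)
    amp = amplitude_rms * (noise_sd if noise_sd > 0 else 1.0)
    n_samples = int(round(raster.duration_s * sampling_rate_hz)) + 1
    signals: dict[str, np.ndarray] = {}
    overlaps = 0
    for eid, times in raster.electrodes.items():
        sig = (rng.normal(0.0, noise_sd, size=n_samples) if noise_sd > 0
               else np.zeros(n_samples))
        idx = np.round(times * sampling_rate_hz).astype(int)
        idx = idx[(idx >= 0) & (idx + template.size <= n_samples)]
        if idx.size > 1:
            overlaps += int((np.diff(idx) < template.size).sum())
        for i in idx:
            sig[i:i + template.size] += amp * template
        signals[eid] = sig
    if overlaps:
        log.warning("%d spike pairs closer than the template width were "
                    "superposed linearly", overlaps)
    return RawMEASignal(signals, sampling_rate_hz,
                        ground_truth={e: t.copy()
                                      for e, t in raster.electrodes.items()})
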