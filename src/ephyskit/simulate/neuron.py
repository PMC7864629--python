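"""Single-compartment conductance-based neuron for current-clamp protocols.

The model is Hodgkin-Huxley-style with instantaneous Na+ activation
(Wang-Buzsaki kinetics rescaled to whole-cell units: nS, pF, mV, ms, pA),
a delayed-rectifier K+ current, and three K+ conductances that shape the
afterhyperpolarizations the analysis quantifies:

- M-type (``g_m_ns``): non-inactivating, slowly activating (tau ~ 100 ms),
  half-activation near threshold; dampens repetitive firing.
- BK-type (``g_bk_ns``): fast, requires both depolarization and Ca2+;
  contributes to spike repolarization and the fast AHP.
- SK-type (``g_sk_ns``): Ca2+-gated, voltage-independent; its activation by
  Ca2+ accumulated over a spike train produces the medium/slow AHP.

Ca2+ is a single dimensionless pool: an increment per spike (upward
crossing of 0 mV) with first-order decay.  Integration is fixed-step
exponential Euler with an internal step of at most 0.025 ms, substepped to
align with the requested sampling rate; with ``noise_sd_mv = 0`` a given
(params, protocol, seed) triple is bit-reproducible.  ``noise_sd_mv``
models measurement noise added to the recorded voltage, so the underlying
dynamics stay deterministic.

All sweeps of a protocol are integrated as one vectorized batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ephyskit.types import VoltageTrace

__all__ = ["NeuronModelParams", "StimulusProtocol", "simulate_neuron",
           "simulate_stimulus", "build_stimulus", "SimulationUnstableError"]

E_NA_MV = 55.0
MAX_INTERNAL_DT_MS = 0.025


class SimulationUnstableError(RuntimeError):
    """Raised when integration produces non-finite voltages."""


@dataclass
class NeuronModelParams:
    """Whole-cell model parameters (nS, pF, mV, ms)."""

    membrane_capacitance_pf: float = 20.0
    leak_conductance_ns: float = 1.1
    leak_reversal_mv: float = -55.0
    g_na_ns: float = 700.0
    g_kdr_ns: float = 180.0
    g_m_ns: float = 2.0
    g_bk_ns: float = 2.0
    g_sk_ns: float = 0.3
    k_reversal_mv: float = -90.0
    m_v_half_mv: float = -35.0
    m_slope_mv: float = 10.0
    m_tau_ms: float = 100.0
    ca_influx_per_spike: float = 0.2
    ca_decay_tau_ms: float = 800.0
    ca_half_sk: float = 0.4
    ca_half_bk: float = 1.0
    noise_sd_mv: float = 0.0

    def __post_init__(self) -> None:
        for name in ("leak_conductance_ns", "g_na_ns", "g_kdr_ns", "g_m_ns",
                     "g_bk_ns", "g_sk_ns"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be non-negative")
        if np.any(np.asarray(self.membrane_capacitance_pf) <= 0):
            raise ValueError("capacitance must be positive")
        if np.any(np.asarray(self.ca_decay_tau_ms) <= 0):
            raise ValueError("ca_decay_tau_ms must be positive")

    def batch_size(self) -> int:
        """Largest array length among parameter fields (1 if all scalar).

        Conductance/kinetic fields may be 1-d arrays to integrate a grid of
        cells as one vectorized batch against a tiled single-sweep stimulus.
        """
        n = 1
        for name in ("leak_conductance_ns", "leak_reversal_mv", "g_na_ns",
                     "g_kdr_ns", "g_m_ns", "g_bk_ns", "g_sk_ns",
                     "membrane_capacitance_pf", "ca_influx_per_spike",
                     "ca_decay_tau_ms", "g_sk_ns"):
            n = max(n, np.size(getattr(self, name)))
        return n


@dataclass
class StimulusProtocol:
    """Current-injection protocol; one of ramp, step_family, pulse_train.

    ramp:        linear current ramp ramp_start->ramp_stop pA over
                 ramp_duration_ms (one sweep).
    step_family: rectangular steps step_start->step_stop pA in
                 step_increment pA increments, step_duration_ms each
                 (one sweep per amplitude).
    pulse_train: n_pulses rectangular pulses of pulse_width_ms at
                 pulse_amplitude_pa, at train_rate_hz, followed by at least
                 post_train_window_s of silence (one sweep).
    """

    kind: str = "step_family"
    sampling_rate_hz: float = 25000.0
    holding_potential_mv: float = -65.0
    baseline_ms: float = 100.0
    # ramp
    ramp_start_pa: float = 10.0
    ramp_stop_pa: float = 80.0
    ramp_duration_ms: float = 500.0
    # step family
    step_start_pa: float = -50.0
    step_stop_pa: float = 30.0
    step_increment_pa: float = 10.0
    step_duration_ms: float = 500.0
    post_step_ms: float = 300.0
    # pulse train
    n_pulses: int = 25
    pulse_width_ms: float = 2.0
    pulse_amplitude_pa: float = 1200.0
    train_rate_hz: float = 50.0
    post_train_window_s: float = 1.2

    def __post_init__(self) -> None:
        if self.kind not in ("ramp", "step_family", "pulse_train"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.sampling_rate_hz < 10000.0:
            raise ValueError("sampling rate must be >= 10 kHz")
        if self.kind == "pulse_train" and self.post_train_window_s < 1.2:
            raise ValueError("post-train window must be >= 1.2 s")

    def step_amplitudes_pa(self) -> np.ndarray:
        n = int(round((self.step_stop_pa - self.step_start_pa)
                      / self.step_increment_pa)) + 1
        return self.step_start_pa + self.step_increment_pa * np.arange(n)


def build_stimulus(protocol: StimulusProtocol) -> np.ndarray:
    """Stimulus waveforms (pA), shape (n_sweeps, n_samples)."""
    fs = protocol.sampling_rate_hz
    dt_ms = 1e3 / fs
    base = int(round(protocol.baseline_ms / dt_ms))
    if protocol.kind == "ramp":
        n_ramp = int(round(protocol.ramp_duration_ms / dt_ms))
        tail = int(round(200.0 / dt_ms))
        ramp = np.linspace(protocol.ramp_start_pa, protocol.ramp_stop_pa,
                           n_ramp)
        stim = np.concatenate([np.zeros(base), ramp, np.zeros(tail)])
        return stim[None, :]
    if protocol.kind == "step_family":
        n_step = int(round(protocol.step_duration_ms / dt_ms))
        tail = int(round(protocol.post_step_ms / dt_ms))
        amps = protocol.step_amplitudes_pa()
        out = np.zeros((amps.size, base + n_step + tail))
        out[:, base:base + n_step] = amps[:, None]
        return out
    # pulse train
    period_ms = 1e3 / protocol.train_rate_hz
    n_total = int(round((protocol.baseline_ms
                         + protocol.n_pulses * period_ms
                         + protocol.post_train_window_s * 1e3 + 100.0)
                        / dt_ms))
    stim = np.zeros(n_total)
    n_width = max(int(round(protocol.pulse_width_ms / dt_ms)), 1)
    for k in range(protocol.n_pulses):
        i0 = base + int(round(k * period_ms / dt_ms))
        stim[i0:i0 + n_width] = protocol.pulse_amplitude_pa
    return stim[None, :]


def _wb_minf(v):
    vv = v + 35.0
    am = np.where(np.abs(vv) < 1e-7, 1.0,
                  0.1 * vv / (1.0 - np.exp(-vv / 10.0)))
    bm = 4.0 * np.exp(-(v + 60.0) / 18.0)
    return am / (am + bm)


def _wb_h_rates(v):
    ah = 0.35 * np.exp(-(v + 58.0) / 20.0)
    bh = 5.0 / (1.0 + np.exp(-(v + 28.0) / 10.0))
    return ah, bh


def _wb_n_rates(v):
    vv = v + 34.0
    an = np.where(np.abs(vv) < 1e-7, 0.5,
                  0.05 * vv / (1.0 - np.exp(-vv / 10.0)))
    bn = 0.625 * np.exp(-(v + 44.0) / 80.0)
    return an, bn


def simulate_neuron(params: NeuronModelParams,
                    protocol: StimulusProtocol,
                    seed: int | np.random.Generator = 0
                    ) -> list[VoltageTrace]:
    """Integrate the model under a protocol; one VoltageTrace per sweep.

    The cell is held at the protocol holding potential by a constant bias
    current solved from the steady-state current balance at that potential;
    gating states start at their steady-state values there.  Raises
    :class:`SimulationUnstableError` (naming the parameter set) if the
    voltage becomes non-finite.
    """
    stim = build_stimulus(protocol)
    nb = params.batch_size()
    if nb > 1:
        if stim.shape[0] == 1:
            stim = np.tile(stim, (nb, 1))
        elif stim.shape[0] != nb:
            raise ValueError("parameter batch size does not match the "
                             "number of protocol sweeps")
    return simulate_stimulus(params, stim, protocol.sampling_rate_hz,
                             protocol.holding_potential_mv, seed=seed,
                             protocol_kind=protocol.kind)


def simulate_stimulus(params: NeuronModelParams,
                      stimulus_pa: np.ndarray,
                      sampling_rate_hz: float,
                      holding_potential_mv: float = -65.0,
                      seed: int | np.random.Generator = 0,
                      protocol_kind: str = "custom") -> list[VoltageTrace]:
    """Integrate the model under an explicit stimulus array (pA).

    ``stimulus_pa`` has shape (n_sweeps, n_samples); parameter fields given
    as length-n_sweeps arrays are broadcast across sweeps, which is how a
    whole cohort of distinct cells is integrated as one vectorized batch.
    """
    p = params
    stim = np.atleast_2d(np.asarray(stimulus_pa, dtype=float))
    n_sweeps, n_samples = stim.shape
    fs = sampling_rate_hz
    sample_dt = 1e3 / fs
    n_sub = max(int(np.ceil(sample_dt / MAX_INTERNAL_DT_MS)), 1)
    dt = sample_dt / n_sub
    e_k = p.k_reversal_mv
    vh = holding_potential_mv

    # steady states at the holding potential
    ah, bh = _wb_h_rates(vh)
    an, bn = _wb_n_rates(vh)
    h0 = ah / (ah + bh)
    n0 = an / (an + bn)
    w0 = 1.0 / (1.0 + np.exp(-(vh - p.m_v_half_mv) / p.m_slope_mv))
    m0 = _wb_minf(np.array([vh]))[0]
    # bias current holding the cell at vh (Ca = 0 at rest)
    i_hold = (p.leak_conductance_ns * (vh - p.leak_reversal_mv)
              + p.g_na_ns * m0 ** 3 * h0 * (vh - E_NA_MV)
              + p.g_kdr_ns * n0 ** 4 * (vh - e_k)
              + p.g_m_ns * w0 * (vh - e_k))

    V = np.full(n_sweeps, float(vh))
    h = np.full(n_sweeps, float(h0))
    n = np.full(n_sweeps, float(n0))
    w = np.full(n_sweeps, float(w0))
    ca = np.zeros(n_sweeps)
    above = V > 0.0

    out = np.empty((n_sweeps, n_samples))
    out[:, 0] = V
    ca_decay = np.exp(-dt / p.ca_decay_tau_ms)
    for i in range(1, n_samples):
        i_stim = stim[:, i] + i_hold
        for _ in range(n_sub):
            minf = _wb_minf(V)
            ah, bh = _wb_h_rates(V)
            an, bn = _wb_n_rates(V)
            winf = 1.0 / (1.0 + np.exp(-(V - p.m_v_half_mv) / p.m_slope_mv))
            sk_gate = ca * ca / (ca * ca + p.ca_half_sk ** 2)
            bk_gate = (ca / (ca + p.ca_half_bk)
                       * 1.0 / (1.0 + np.exp(-(V + 10.0) / 10.0)))
            g_na = p.g_na_ns * minf ** 3 * h
            g_k = (p.g_kdr_ns * n ** 4 + p.g_m_ns * w
                   + p.g_sk_ns * sk_gate + p.g_bk_ns * bk_gate)
            g_tot = g_na + g_k + p.leak_conductance_ns
            v_target = (g_na * E_NA_MV + g_k * e_k
                        + p.leak_conductance_ns * p.leak_reversal_mv
                        + i_stim) / g_tot
            V = v_target + (V - v_target) * np.exp(
                -dt * g_tot / p.membrane_capacitance_pf)
            # exponential Euler on the gates
            h = h + (ah / (ah + bh) - h) * (1.0 - np.exp(-dt * (ah + bh)))
            n = n + (an / (an + bn) - n) * (1.0 - np.exp(-dt * (an + bn)))
            w = w + (winf - w) * (1.0 - np.exp(-dt / p.m_tau_ms))
            ca = ca * ca_decay
            now_above = V > 0.0
            crossed = now_above & ~above
            if crossed.any():
                ca = ca + p.ca_influx_per_spike * crossed
            above = now_above
        out[:, i] = V
        if not np.all(np.isfinite(V)):
            raise SimulationUnstableError(
                f"non-finite voltage at sample {i}; params={p!r}")

    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    traces = []
    for s in range(n_sweeps):
        v = out[s]
        if p.noise_sd_mv > 0:
            v = v + rng.normal(0.0, p.noise_sd_mv, size=v.size)
        traces.append(VoltageTrace(
            sampling_rate_hz=fs, voltage_mv=v, stimulus_pa=stim[s],
            holding_potential_mv=vh,
            meta={"protocol": protocol_kind, "sweep": s,
                  "i_hold_pa": float(np.broadcast_to(i_hold, (n_sweeps,))[s])}))
    return traces
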