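"""Synthetic voltage-clamp sweeps: a Boltzmann-gated, non-inactivating K+
conductance with single-exponential activation, ohmic leak, Gaussian
current noise, and a drug-blockable fraction of the channel.

The generator emulates a slowly activating M-like current studied by drug
subtraction: the pre-drug condition carries the full channel current, the
post-drug condition carries ``(1 - drug_block_fraction)`` of it, and the
leak and noise statistics are common to both, so pre minus post isolates
the blocked fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ephyskit.types import VCSweepSet

__all__ = ["ChannelSimParams", "VCProtocol", "simulate_voltage_clamp",
           "boltzmann"]


def boltzmann(v_mv, v_half_mv: float, slope_mv: float):
    """Steady-state activation 1 / (1 + exp(-(V - V1/2)/k))."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(v_mv, dtype=float) - v_half_mv)
                               / slope_mv))


@dataclass
class VCProtocol:
    """Step protocol: hold at -80 mV, 1000 ms depolarizing steps from -80 to
    +40 mV in +10 mV increments, then a 300 ms tail step to 0 mV."""

    holding_mv: float = -80.0
    step_start_mv: float = -80.0
    step_stop_mv: float = 40.0
    step_increment_mv: float = 10.0
    step_duration_ms: float = 1000.0
    tail_potential_mv: float = 0.0
    tail_duration_ms: float = 300.0
    inter_sweep_interval_s: float = 20.0
    sampling_rate_hz: float = 10000.0

    def steps_mv(self) -> np.ndarray:
        n = int(round((self.step_stop_mv - self.step_start_mv)
                      / self.step_increment_mv)) + 1
        return self.step_start_mv + self.step_increment_mv * np.arange(n)


@dataclass
class ChannelSimParams:
    """Boltzmann-gated channel plus leak.

    ``tau_activation_ms`` may be a constant or a callable tau(V_mv) for
    voltage-dependent kinetics.  ``drug_block_fraction`` is the fraction of
    the channel conductance removed in the post-drug condition.
    """

    g_max_ns: float = 5.0
    v_half_mv: float = -20.0
    slope_mv: float = 10.0
    tau_activation_ms: float | Callable[[float], float] = 100.0
    reversal_mv: float = -90.0
    leak_conductance_ns: float = 1.0
    leak_reversal_mv: float = 0.0
    capacitance_pf: float = 15.0
    drug_block_fraction: float = 1.0
    current_noise_sd_pa: float = 0.0
    seal_resistance_gohm: float = 2.0
    series_resistance_mohm: float = 8.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.slope_mv == 0:
            raise ValueError("Boltzmann slope must be nonzero")
        if not 0.0 <= self.drug_block_fraction <= 1.0:
            raise ValueError("drug_block_fraction must be in [0, 1]")

    def tau_at(self, v_mv: float) -> float:
        if callable(self.tau_activation_ms):
            return float(self.tau_activation_ms(v_mv))
        return float(self.tau_activation_ms)


def _channel_gate(params: ChannelSimParams, protocol: VCProtocol,
                  v_step: float) -> np.ndarray:
    """Open probability over step + tail, single-exponential relaxation."""
    dt_ms = 1e3 / protocol.sampling_rate_hz
    n_step = int(round(protocol.step_duration_ms / dt_ms))
    n_tail = int(round(protocol.tail_duration_ms / dt_ms))
    t_step = np.arange(n_step) * dt_ms
    t_tail = np.arange(n_tail) * dt_ms
    x0 = boltzmann(protocol.holding_mv, params.v_half_mv, params.slope_mv)
    x_inf = boltzmann(v_step, params.v_half_mv, params.slope_mv)
    tau = params.tau_at(v_step)
    x_during = x_inf + (x0 - x_inf) * np.exp(-t_step / tau)
    x_end = x_during[-1] if n_step else x0
    x_inf_tail = boltzmann(protocol.tail_potential_mv, params.v_half_mv,
                           params.slope_mv)
    tau_tail = params.tau_at(protocol.tail_potential_mv)
    x_tail = x_inf_tail + (x_end - x_inf_tail) * np.exp(-t_tail / tau_tail)
    return np.concatenate([x_during, x_tail])


def simulate_voltage_clamp(params: ChannelSimParams,
                           protocol: VCProtocol | None = None,
                           seed: int | np.random.Generator = 0,
                           cell_id: str = "cell1"
                           ) -> tuple[VCSweepSet, VCSweepSet]:
    """Simulate matched pre-drug and post-drug sweep families for one cell.

    Pre-drug current per step: g_max * x(t) * (V - E_rev) + leak + noise.
    Post-drug: channel conductance scaled by (1 - drug_block_fraction);
    leak unchanged; independent noise.  The tail segment at the tail
    potential is appended to every step trace.
    """
    if protocol is None:
        protocol = VCProtocol()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    steps = protocol.steps_mv()
    sweeps = {"pre_drug": [], "post_drug": []}
    for v in steps:
        gate = _channel_gate(params, protocol, v)
        n_step = int(round(protocol.step_duration_ms * 1e-3
                           * protocol.sampling_rate_hz))
        v_wave = np.full(gate.size, protocol.tail_potential_mv)
        v_wave[:n_step] = v
        # nS * mV = pA
        i_channel = params.g_max_ns * gate * (v_wave - params.reversal_mv)
        i_leak = params.leak_conductance_ns * (v_wave
                                               - params.leak_reversal_mv)
        for cond, g_scale in (("pre_drug", 1.0),
                              ("post_drug",
                               1.0 - params.drug_block_fraction)):
            i = g_scale * i_channel + i_leak
            if params.current_noise_sd_pa > 0:
                i = i + rng.normal(0.0, params.current_noise_sd_pa,
                                   size=i.size)
            sweeps[cond].append(i)
    proto_meta = {
        "step_duration_ms": protocol.step_duration_ms,
        "tail_potential_mv": protocol.tail_potential_mv,
        "tail_duration_ms": protocol.tail_duration_ms,
        "holding_mv": protocol.holding_mv,
    }
    out = []
    for cond in ("pre_drug", "post_drug"):
        out.append(VCSweepSet(
            cell_id=cell_id, condition=cond,
            capacitance_pf=params.capacitance_pf,
            step_mv=steps, currents_pa=np.vstack(sweeps[cond]),
            sampling_rate_hz=protocol.sampling_rate_hz,
            seal_resistance_gohm=params.seal_resistance_gohm,
            series_resistance_mohm=params.series_resistance_mohm,
            protocol=dict(proto_meta)))
    return out[0], out[1]
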