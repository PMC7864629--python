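"""Drug-subtraction voltage-clamp analysis.

The background-current removal is pharmacological: sweeps recorded before
and after blocker application are subtracted sample-wise, and only the
drug-sensitive difference current is analyzed.  From the subtracted
sweeps the module measures step currents at 999 ms, tail currents 5 ms
after the switch to the tail potential, current densities (pA/pF),
percent-of-WT group summaries, single-exponential activation time
constants over 50-1000 ms, and a normalized conductance-voltage curve
from the tails with an optional Boltzmann fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize as spopt

from ephyskit.simulate.vclamp import boltzmann
from ephyskit.types import VCSweepSet

__all__ = [
    "ActivationFit", "subtract_drug", "measure_currents", "current_density",
    "percent_of_wt", "fit_activation_tau", "qc_voltage_clamp",
    "gv_from_tails",
]


@dataclass
class ActivationFit:
    voltage_mv: float
    tau_ms: float
    amplitude_pa: float
    offset_pa: float
    rss: float
    converged: bool


def subtract_drug(pre: VCSweepSet, post: VCSweepSet) -> VCSweepSet:
    """Sample-wise pre minus post: the drug-sensitive current.

    Requires matched cells, identical step sets and trace lengths.
    """
    if pre.cell_id != post.cell_id:
        raise ValueError("pre/post sweep sets are from different cells")
    if pre.step_mv.shape != post.step_mv.shape or \
            not np.allclose(pre.step_mv, post.step_mv):
        raise ValueError("step sets differ between conditions")
    if pre.currents_pa.shape != post.currents_pa.shape:
        raise ValueError("trace lengths differ between conditions")
    return VCSweepSet(
        cell_id=pre.cell_id, condition="subtracted",
        capacitance_pf=pre.capacitance_pf, step_mv=pre.step_mv.copy(),
        currents_pa=pre.currents_pa - post.currents_pa,
        sampling_rate_hz=pre.sampling_rate_hz,
        seal_resistance_gohm=pre.seal_resistance_gohm,
        series_resistance_mohm=pre.series_resistance_mohm,
        protocol=dict(pre.protocol))


def measure_currents(sweeps: VCSweepSet,
                     peak_latency_ms: float = 999.0,
                     tail_latency_ms: float = 5.0,
                     window_ms: float = 0.0) -> dict:
    """Step and tail currents per voltage step.

    The step current is read at the sample nearest ``peak_latency_ms``
    after step onset; the tail current at the sample nearest
    ``tail_latency_ms`` after the switch to the tail potential.
    ``window_ms`` > 0 averages over a centered window instead of a single
    sample.  Returns {'step_mv', 'peak_pa', 'tail_pa'} arrays.
    """
    fs = sweeps.sampling_rate_hz
    step_ms = float(sweeps.protocol.get("step_duration_ms", 1000.0))
    n_step = int(round(step_ms * 1e-3 * fs))
    i_peak = int(round(peak_latency_ms * 1e-3 * fs))
    i_tail = n_step + int(round(tail_latency_ms * 1e-3 * fs))
    n = sweeps.currents_pa.shape[1]
    if i_peak >= n or i_tail >= n:
        raise ValueError("trace shorter than the required latency")
    half = int(round(window_ms / 2 * 1e-3 * fs))

    def read(idx: int) -> np.ndarray:
        if half:
            lo, hi = max(idx - half, 0), min(idx + half + 1, n)
            return sweeps.currents_pa[:, lo:hi].mean(axis=1)
        return sweeps.currents_pa[:, idx]

    return {"step_mv": sweeps.step_mv.copy(),
            "peak_pa": np.asarray(read(i_peak), dtype=float),
            "tail_pa": np.asarray(read(i_tail), dtype=float)}


def current_density(peak_pa, capacitance_pf: float):
    """Current density pA/pF."""
    if capacitance_pf <= 0:
        raise ValueError("capacitance must be positive")
    return np.asarray(peak_pa, dtype=float) / capacitance_pf


def percent_of_wt(variant_densities, wt_densities) -> dict:
    """Group summary: variant mean density as % of the WT mean.

    percent_of_wt = 100 x mean(variant) / mean(WT); percent_smaller is the
    complement.  The SEM of the ratio uses first-order (delta-method)
    propagation from the two group means and SEMs.  Scale-invariant:
    multiplying every density by a constant leaves the result unchanged.
    """
    v = np.asarray(variant_densities, dtype=float)
    w = np.asarray(wt_densities, dtype=float)
    if v.size < 2 or w.size < 2:
        raise ValueError("need >= 2 cells per group")
    mw = w.mean()
    if mw == 0:
        raise ValueError("WT mean density is zero")
    mv = v.mean()
    sem_v = v.std(ddof=1) / np.sqrt(v.size)
    sem_w = w.std(ddof=1) / np.sqrt(w.size)
    ratio = mv / mw
    sem_ratio = abs(ratio) * np.sqrt((sem_v / mv) ** 2 + (sem_w / mw) ** 2) \
        if mv != 0 else sem_v / abs(mw)
    return {"percent_of_wt": 100.0 * ratio,
            "percent_smaller": 100.0 * (1.0 - ratio),
            "sem_percent": 100.0 * sem_ratio,
            "n_variant": int(v.size), "n_wt": int(w.size)}


def fit_activation_tau(sweeps: VCSweepSet, voltage_mv: float,
                       window_ms: tuple[float, float] = (50.0, 1000.0),
                       tau_bounds_ms: tuple[float, float] = (1.0, 5000.0)
                       ) -> ActivationFit:
    """Single-exponential activation fit I(t) = A (1 - exp(-t/tau)) + C
    over ``window_ms`` after step onset, for one step voltage.

    Valid for steps between -30 and +40 mV (where the channel activates).
    Initial guesses from the data: C = mean of the first 5 ms of the
    window, A = I(end) - C, tau = time to 63% of the span.  Fits that do
    not converge, hit the tau bounds, or have no resolvable kinetics
    return ``converged=False``.
    """
    if not -30.0 <= voltage_mv <= 40.0:
        raise ValueError("activation fits are valid for steps in "
                         "[-30, +40] mV")
    idx = np.nonzero(np.isclose(sweeps.step_mv, voltage_mv))[0]
    if idx.size == 0:
        raise ValueError(f"no sweep at {voltage_mv} mV")
    fs = sweeps.sampling_rate_hz
    i0 = int(round(window_ms[0] * 1e-3 * fs))
    i1 = int(round(window_ms[1] * 1e-3 * fs))
    trace = sweeps.currents_pa[idx[0]]
    if i1 > trace.size:
        raise ValueError("fit window extends past the trace")
    t_ms = (np.arange(i0, i1) / fs) * 1e3  # time from step onset
    y = trace[i0:i1]

    n5 = max(int(round(5.0e-3 * fs)), 1)
    c0 = float(y[:n5].mean())
    a0 = float(y[-1] - c0)
    if abs(a0) < 1e-9 or np.ptp(y) < 1e-9:
        return ActivationFit(voltage_mv, np.nan, 0.0, c0,
                             float(((y - y.mean()) ** 2).sum()), False)
    target = c0 + 0.632 * a0
    crossing = np.nonzero((y - target) * np.sign(a0) >= 0)[0]
    tau0 = float(t_ms[crossing[0]] - t_ms[0]) if crossing.size else \
        (window_ms[1] - window_ms[0]) / 3.0
    tau0 = float(np.clip(tau0, *tau_bounds_ms))

    def model(t, a, tau, c):
        return a * (1.0 - np.exp(-t / tau)) + c

    try:
        popt, _ = spopt.curve_fit(
            model, t_ms, y, p0=[a0, tau0, c0],
            bounds=([-np.inf, tau_bounds_ms[0], -np.inf],
                    [np.inf, tau_bounds_ms[1], np.inf]),
            maxfev=10000)
    except (RuntimeError, ValueError):
        return ActivationFit(voltage_mv, np.nan, np.nan, np.nan, np.inf,
                             False)
    a, tau, c = popt
    resid = y - model(t_ms, *popt)
    rss = float(resid @ resid)
    at_bound = np.isclose(tau, tau_bounds_ms[0]) or \
        np.isclose(tau, tau_bounds_ms[1])
    return ActivationFit(voltage_mv, float(tau), float(a), float(c), rss,
                         converged=not at_bound)


def qc_voltage_clamp(sweeps: VCSweepSet) -> dict:
    """Inclusion gates: seal >= 0.5 GOhm and R_S <= 20 MOhm (inclusive).

    Missing metadata gives an indeterminate result.
    """
    seal, rs = sweeps.seal_resistance_gohm, sweeps.series_resistance_mohm
    if seal is None or rs is None:
        return {"passed": False, "indeterminate": True, "reasons":
                ["missing seal or series resistance"]}
    reasons = []
    if not seal >= 0.5:
        reasons.append(f"seal {seal:g} GOhm < 0.5")
    if not rs <= 20.0:
        reasons.append(f"R_S {rs:g} MOhm > 20")
    return {"passed": not reasons, "indeterminate": False,
            "reasons": reasons}


def gv_from_tails(step_mv, tail_pa, fit: bool = True) -> dict:
    """Normalized conductance-voltage curve from tail currents.

    Tails are measured at a fixed potential, so their magnitude is
    proportional to the open probability reached at each preceding step;
    G/Gmax(V) = |tail(V)| / max |tail|.  Optionally fits a Boltzmann
    1/(1 + exp(-(V - V1/2)/k)).  The tail sign (inward/outward) is
    recorded; magnitudes are used for normalization.
    """
    v = np.asarray(step_mv, dtype=float)
    tails = np.asarray(tail_pa, dtype=float)
    mags = np.abs(tails)
    if mags.max() <= 0:
        raise ValueError("maximum tail current is zero")
    g_norm = mags / mags.max()
    out = {"step_mv": v, "g_norm": g_norm,
           "tail_sign": float(np.sign(tails[np.argmax(mags)]))}
    if fit:
        try:
            popt, _ = spopt.curve_fit(
                lambda vv, vh, k: boltzmann(vv, vh, k), v, g_norm,
                p0=[float(v[np.argmin(np.abs(g_norm - 0.5))]), 10.0],
                maxfev=10000)
            out["v_half_mv"], out["slope_mv"] = float(popt[0]), float(popt[1])
            out["fit_converged"] = True
        except (RuntimeError, ValueError):
            out["fit_converged"] = False
    return out
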