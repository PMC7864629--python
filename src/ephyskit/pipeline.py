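"""End-to-end pipeline: simulate a cohort, extract features, compute well
metrics, run the statistics, and write tables with a provenance manifest.

The run is deterministic given (config, seed): every random stream is a
child of one seeded generator.  Output goes to a fresh directory; a
directory containing a completed run manifest is never overwritten (the
rerun policy is a full clean rerun into a new directory).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

import ephyskit
from ephyskit import currentclamp as cc
from ephyskit import mea, qpcr, stats, vclamp
from ephyskit.config import RunConfig
from ephyskit.simulate import (ChannelSimParams, NeuronModelParams,
                               SpikeTrainGenParams, StimulusProtocol,
                               simulate_mea_well, simulate_neuron,
                               simulate_qpcr, simulate_voltage_clamp)
from ephyskit.simulate.neuron import build_stimulus, simulate_stimulus

__all__ = ["run_pipeline"]

log = logging.getLogger(__name__)


def _cell_params(config: RunConfig, rng: np.random.Generator,
                 group: str, week: int, n_cells: int) -> NeuronModelParams:
    """Batched per-cell model parameters for one group/week.

    The synthetic variant phenotype scales the SK conductance (deeper
    post-train AHPs) and all cells gain conductance with week in culture
    (maturation); per-cell jitter makes every cell distinct.
    """
    week_scale = 1.0 + 0.25 * (week - 3)
    gsk = 0.3 * week_scale
    if group != config.groups[0]:
        gsk *= config.variant_gsk_scale
    jitter = rng.lognormal(0.0, 0.15, size=(5, n_cells))
    return NeuronModelParams(
        leak_conductance_ns=1.1 * jitter[0],
        g_na_ns=700.0 * week_scale * jitter[1],
        g_kdr_ns=180.0 * week_scale * jitter[2],
        g_m_ns=2.0 * jitter[3],
        g_sk_ns=gsk * jitter[4],
        noise_sd_mv=0.2,
    )


def _extract_cell_features(config: RunConfig, rng: np.random.Generator,
                           group: str, week: int) -> list[dict]:
    n = config.n_cells_per_group
    params = _cell_params(config, rng, group, week, n)
    fs = 25000.0
    ramp = StimulusProtocol(kind="ramp", sampling_rate_hz=fs)
    train = StimulusProtocol(
        kind="pulse_train", sampling_rate_hz=fs,
        pulse_amplitude_pa=config.train_pulse_amplitude_pa)
    seed_child = int(rng.integers(2 ** 31))
    ramp_traces = simulate_neuron(params, ramp, seed=seed_child)
    train_traces = simulate_neuron(params, train, seed=seed_child + 1)
    # step family: all amplitudes x cells integrated as one batch
    steps_proto = StimulusProtocol(kind="step_family", sampling_rate_hz=fs)
    step_stim = build_stimulus(steps_proto)  # (n_amps, T)
    amps = steps_proto.step_amplitudes_pa()
    n_amps = amps.size
    tiled_stim = np.repeat(step_stim, n, axis=0)  # amp-major, cell-minor
    tiled = NeuronModelParams(
        leak_conductance_ns=np.tile(params.leak_conductance_ns, n_amps),
        g_na_ns=np.tile(params.g_na_ns, n_amps),
        g_kdr_ns=np.tile(params.g_kdr_ns, n_amps),
        g_m_ns=np.tile(params.g_m_ns, n_amps),
        g_sk_ns=np.tile(params.g_sk_ns, n_amps),
        noise_sd_mv=params.noise_sd_mv)
    all_steps = simulate_stimulus(tiled, tiled_stim, fs,
                                  seed=seed_child + 2,
                                  protocol_kind="step_family")
    step_traces_by_cell: list[list] = [[] for _ in range(n)]
    rmp_by_cell = [np.nan] * n
    for ai, a in enumerate(amps):
        for c in range(n):
            tr = all_steps[ai * n + c]
            if a == 0.0:
                rmp_by_cell[c] = cc.measure_rmp(tr)
            else:
                step_traces_by_cell[c].append(tr)
    rows = []
    for c in range(n):
        row = {"group": group, "week": week, "cell_id":
               f"{group}_w{week}_c{c + 1}"}
        row["rmp_mv"] = rmp_by_cell[c]
        try:
            row["input_resistance_mohm"] = cc.input_resistance(
                step_traces_by_cell[c])
        except ValueError:
            row["input_resistance_mohm"] = np.nan
        row["series_resistance_mohm"] = float(rng.uniform(8.0, 22.0))
        tr = ramp_traces[c]
        peaks = cc.detect_aps(tr)
        if peaks:
            p0 = peaks[0]
            try:
                row["ap_threshold_mv"] = cc.ap_threshold(tr, p0)
            except cc.NoThresholdError:
                row["ap_threshold_mv"] = np.nan
            try:
                amp, hw = cc.ap_amplitude_halfwidth(tr, p0)
                row["ap_amplitude_mv"], row["half_width_ms"] = amp, hw
            except ValueError:
                row["ap_amplitude_mv"] = row["half_width_ms"] = np.nan
            f = cc.fahp(tr, p0)
            row["fahp_mv"] = np.nan if f is None else f
        else:
            for k in ("ap_threshold_mv", "ap_amplitude_mv",
                      "half_width_ms", "fahp_mv"):
                row[k] = np.nan
        ahp = cc.post_burst_ahp(train_traces[c])
        row["mahp_mv"], row["sahp_mv"] = ahp.mahp_mv, ahp.sahp_mv
        qc = cc.apply_qc(row["rmp_mv"], row["input_resistance_mohm"],
                         row["series_resistance_mohm"],
                         row.get("ap_amplitude_mv"))
        row["qc_pass"] = qc.passed
        rows.append(row)
    return rows


def _mea_stage(config: RunConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for group in config.groups:
        burst_rate = 4.0
        if group != config.groups[0]:
            burst_rate *= config.variant_burst_rate_scale
        for w in range(config.n_wells_per_group):
            well_id = f"{group}_well{w + 1}"
            for week in config.weeks:
                p = SpikeTrainGenParams(
                    n_electrodes=config.n_mea_electrodes,
                    duration_s=config.mea_duration_s,
                    active_fraction=0.8,
                    tonic_rate_hz=0.5,
                    burst_rate_per_min=burst_rate * (1 + 0.2 * (week - 3)),
                    seed=int(rng.integers(2 ** 31)))
                raster, _ = simulate_mea_well(p, well_id=well_id)
                wm, _ = mea.well_metrics(
                    raster, min_surprise=config.burst_min_surprise,
                    seed_factor=config.burst_seed_factor,
                    min_spikes=config.burst_min_spikes)
                row = wm.as_dict()
                row.update({"group": group, "week": week})
                rows.append(row)
    return pd.DataFrame(rows)


def _vclamp_stage(config: RunConfig, rng: np.random.Generator
                  ) -> tuple[pd.DataFrame, dict]:
    rows = []
    for group, gmax_scale in ((config.groups[0], 1.0),
                              (config.groups[1], 0.2)):
        for c in range(max(config.n_cells_per_group, 2)):
            params = ChannelSimParams(
                g_max_ns=5.0 * gmax_scale * rng.lognormal(0, 0.2),
                capacitance_pf=float(rng.uniform(10, 20)),
                current_noise_sd_pa=5.0)
            pre, post = simulate_voltage_clamp(
                params, seed=int(rng.integers(2 ** 31)),
                cell_id=f"{group}_vc{c + 1}")
            sub = vclamp.subtract_drug(pre, post)
            meas = vclamp.measure_currents(sub)
            dens = vclamp.current_density(meas["peak_pa"],
                                          sub.capacitance_pf)
            i30 = int(np.argmin(np.abs(sub.step_mv - 30.0)))
            fit = vclamp.fit_activation_tau(
                sub, 30.0, window_ms=tuple(config.tau_fit_window_ms))
            rows.append({"group": group, "cell_id": sub.cell_id,
                         "density_30mv_pa_pf": float(dens[i30]),
                         "tau_30mv_ms": fit.tau_ms,
                         "qc_pass": vclamp.qc_voltage_clamp(pre)["passed"]})
    df = pd.DataFrame(rows)
    wt = df[df["group"] == config.groups[0]]["density_30mv_pa_pf"]
    var = df[df["group"] == config.groups[1]]["density_30mv_pa_pf"]
    summary = vclamp.percent_of_wt(var.to_numpy(), wt.to_numpy())
    return df, summary


def _stats_stage(cc_table: pd.DataFrame, mea_table: pd.DataFrame,
                 config: RunConfig) -> list[str]:
    lines = []
    ok = cc_table.dropna(subset=["half_width_ms"])
    if ok["group"].nunique() == 2 and ok["week"].nunique() >= 2:
        res = stats.two_way_anova(ok, "half_width_ms", "group", "week")
        lines.append("half-width two-way ANOVA genotype: "
                     + res.f_string("group"))
        lines.append("half-width two-way ANOVA genotype x week: "
                     + res.f_string("group:week"))
    ok = cc_table.dropna(subset=["mahp_mv"])
    g0, g1 = config.groups
    if (ok.group == g0).sum() >= 2 and (ok.group == g1).sum() >= 2:
        t = stats.t_test(ok[ok.group == g0]["mahp_mv"],
                         ok[ok.group == g1]["mahp_mv"])
        lines.append(f"mAHP t-test {g0} vs {g1}: t = {t.t:.2f}, "
                     f"df = {t.df:.0f}, p = {t.p:.4g}")
    if mea_table["week"].nunique() >= 2 and \
            mea_table["group"].nunique() == 2:
        sub = mea_table.dropna(subset=["burst_percent"])
        try:
            res = stats.rm_anova(sub, "burst_percent", "group", "week",
                                 "well_id")
            lines.append("burst %% RM-ANOVA genotype: "
                         + res.f_string("group"))
        except ValueError as e:
            lines.append(f"burst % RM-ANOVA skipped: {e}")
    return lines


def run_pipeline(config: RunConfig) -> Path:
    """Run simulate -> extract -> metrics -> stats; returns the output dir."""
    out = Path(config.output_dir)
    if (out / "manifest.json").exists():
        raise FileExistsError(
            f"{out} already contains a completed run; choose a new "
            "output_dir (rerun policy is a full clean rerun)")
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    log.info("current-clamp stage")
    cc_rows = []
    for group in config.groups:
        for week in config.weeks:
            cc_rows.extend(_extract_cell_features(config, rng, group, week))
    cc_table = pd.DataFrame(cc_rows)
    cc_table.to_csv(out / "cell_features.csv", index=False)

    log.info("MEA stage")
    mea_table = _mea_stage(config, rng)
    mea_table.to_csv(out / "well_metrics.csv", index=False)

    log.info("voltage-clamp stage")
    vc_table, vc_summary = _vclamp_stage(config, rng)
    vc_table.to_csv(out / "vc_summary.csv", index=False)

    log.info("qPCR stage")
    ct = simulate_qpcr(n_samples=3, genes=["KCNQ2"],
                       true_log2_fold_changes=[1.0],
                       seed=int(rng.integers(2 ** 31)))
    expr = qpcr.delta_ct(ct)
    expr = qpcr.normalize_to_reference(expr, expr["sample_id"].iloc[0])
    expr.to_csv(out / "expression.csv", index=False)

    log.info("statistics stage")
    lines = _stats_stage(cc_table, mea_table, config)
    lines.append(f"variant current density: "
                 f"{vc_summary['percent_of_wt']:.1f}% of WT "
                 f"({vc_summary['percent_smaller']:.1f}% smaller, "
                 f"SEM {vc_summary['sem_percent']:.1f}%)")
    (out / "stats_report.txt").write_text("\n".join(lines) + "\n")

    tables = ["cell_features.csv", "well_metrics.csv", "vc_summary.csv",
              "expression.csv", "stats_report.txt"]
    manifest = {
        "package_version": ephyskit.__version__,
        "seed": config.seed,
        "config": config.as_dict(),
        "outputs": {t: hashlib.sha256((out / t).read_bytes()).hexdigest()
                    for t in tables},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
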