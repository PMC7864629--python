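# Data dictionary

Units are carried in column names.  Missing values are empty cells
(pandas NaN); a missing burst metric means no electrode of the well
burst.

## cell_features.csv (one row per cell)

| column | meaning |
| --- | --- |
| group | cohort group (e.g. control / variant) |
| week | week in culture of the recording |
| cell_id | unique cell identifier |
| rmp_mv | resting potential: mean of first 100 ms of the 0 pA sweep (mV) |
| input_resistance_mohm | OLS slope of steady-state V–I over the step family (MΩ) |
| series_resistance_mohm | series resistance from acquisition metadata (MΩ) |
| ap_threshold_mv | voltage at the 5 mV/ms upward dV/dt crossing of the first ramp AP (mV) |
| ap_amplitude_mv | first ramp AP peak minus V_h (mV) |
| half_width_ms | AP width at half amplitude relative to V_h (ms) |
| fahp_mv | voltage where the 1 ms sliding mean of dV/dt re-enters ±0.5 mV/ms post-peak (mV) |
| mahp_mv | post-train negative peak within 1 s of offset, minus V_h (mV; negative = hyperpolarized) |
| sahp_mv | V at 1 s after train offset, minus V_h (mV) |
| qc_pass | all four inclusion gates satisfied (bool) |

## well_metrics.csv (one row per well × timepoint)

| column | meaning |
| --- | --- |
| well_id | well identifier (constant across timepoints of one well) |
| group, week | cohort group and timepoint |
| n_active_electrodes | electrodes with ≥ 1 spike/min |
| mean_firing_frequency_hz | spikes on active electrodes / (n_active × duration) |
| isi_cov | mean per-electrode SD/mean of inter-spike intervals |
| n_bursting_electrodes | electrodes with ≥ 1 detected burst |
| n_bursts | total bursts in the well |
| burst_frequency_hz | n_bursts / (n_bursting_electrodes × duration) |
| ibi_cov | mean per-electrode SD/mean of inter-burst intervals (≥ 3 bursts) |
| spikes_per_burst | mean spike count over all bursts |
| burst_percent | 100 × spikes inside bursts / spikes on active electrodes |

## vc_summary.csv (one row per cell)

| column | meaning |
| --- | --- |
| group, cell_id | expression group and cell |
| density_30mv_pa_pf | drug-sensitive current at +30 mV, 999 ms, per pF (pA/pF) |
| tau_30mv_ms | single-exponential activation time constant at +30 mV (ms) |
| qc_pass | seal ≥ 0.5 GΩ and R_S ≤ 20 MΩ |

## expression.csv (one row per sample × gene)

| column | meaning |
| --- | --- |
| sample_id, gene | sample and target gene |
| delta_ct | mean Ct(gene) − mean housekeeping Ct (cycles) |
| rel_expr | 2^−ΔCt |
| rel_to_reference | rel_expr scaled so the reference sample reads 1 |

## Per-burst table (optional CLI output)

well, electrode, start_s, end_s, n_spikes, surprise (−ln Poisson tail
probability, natural log).
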