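# ephyskit

Analysis pipeline for phenotyping induced-pluripotent-stem-cell-derived
cortical neurons by electrophysiology, aimed at studies of K⁺-channel
(e.g. KCNQ2/M-current) loss- and gain-of-function: current-clamp action
potential and afterhyperpolarization (AHP) feature extraction,
multi-electrode-array (MEA) activity and bursting metrics with
Poisson-surprise burst detection, drug-subtraction voltage-clamp analysis
of heterologously expressed channels, comparative-Ct (2^−ΔCt) qPCR
quantification, and the statistics used to compare genotypes over
development.  Seeded synthetic-data generators (a conductance-based
neuron, a two-state burst raster model, Boltzmann-gated channel currents,
Ct tables) make every stage testable without recordings.

## What it computes

**Current clamp** (per cell, with the operational definitions used in
whole-cell studies of excitability):

- Resting potential (mean of the first 100 ms of a zero-current sweep)
  and input resistance R_N, the OLS slope of steady-state ΔV vs I over
  500 ms current steps (−50 → +30 pA), in MΩ.
- AP threshold: the voltage where the rising-phase dV/dt crosses
  5 mV/ms; amplitude from the holding potential V_h (−65 mV) to the
  peak; half-width at half amplitude relative to V_h; fast AHP at the
  point where the 1 ms sliding mean of dV/dt re-enters 0.0 ± 0.5 mV/ms
  after the spike.
- Post-train medium and slow AHP after a 50 Hz train of 25 × 2 ms
  suprathreshold pulses: mAHP = negative peak within 1 s of train offset
  − V_h; sAHP = V(offset + 1 s) − V_h.
- Inclusion QC: R_S < 30 MΩ, R_N > 200 MΩ, V_rest < −45 mV, AP
  amplitude > 80 mV.
- Liquid junction potential by the stationary Henderson equation,

  V_LJ = (RT/F) · [Σ zᵢuᵢΔcᵢ / Σ zᵢ²uᵢΔcᵢ] · ln(Σ zᵢ²uᵢcᵢᵖ / Σ zᵢ²uᵢcᵢᵇ),

  with a packaged relative-mobility table (uᵢ = λᵢ/zᵢ²λ_K).

**MEA** (per 64-electrode well, 300 s): active electrodes (≥ 1
spike/min), mean firing frequency, ISI coefficient of variation, and
burst metrics from Poisson-surprise detection in the style of Legendy &
Salcman — a burst is a spike run whose surprise
S = −ln P(N ≥ n | Poisson at the electrode's mean rate) exceeds 10 after
grow/trim maximization — yielding bursts/electrode, burst frequency, IBI
CoV, spikes/burst and burst %.

**Voltage clamp**: sample-wise subtraction of post-blocker from
pre-blocker sweeps isolates the drug-sensitive current; step currents at
999 ms, tails 5 ms into a 0 mV tail step, current density (pA/pF),
percent-of-WT group summaries, and single-exponential activation fits
I(t) = A(1 − e^(−t/τ)) + C over 50–1000 ms.

**Statistics**: pooled-variance t-test, one-way and two-way ANOVA with
interaction (Type III), univariate mixed-design repeated-measures ANOVA,
and Fisher's protected LSD — all implemented self-contained and verified
against brute-force decompositions and independent packages.

## Worked example

```python
from ephyskit.ljp import compute_ljp, kmeso4_internal, bicarbonate_acsf
from ephyskit.simulate import NeuronModelParams, StimulusProtocol, simulate_neuron
from ephyskit import currentclamp as cc

print(round(compute_ljp(kmeso4_internal(), bicarbonate_acsf()), 2))
# -8.21   <- mV added once to every pipette-referenced potential

trace = simulate_neuron(NeuronModelParams(),
                        StimulusProtocol(kind="ramp"), seed=0)[0]
peak = cc.detect_aps(trace)[0]
print(round(cc.ap_threshold(trace, peak), 1))          # -50.4  (mV)
amp, hw = cc.ap_amplitude_halfwidth(trace, peak)
print(round(amp, 1), round(hw, 2))                     # 93.2  0.58  (mV, ms)
```

The threshold is where the simulated AP's upstroke first exceeds
5 mV/ms; the 93 mV amplitude (from V_h = −65 mV) clears the 80 mV QC
gate; the 0.58 ms half-width is typical of a mature fast spike.

The numbered scripts under `analysis/` run the full synthetic study:
`01_ljp_correction.py`, `02_patch_phenotype.py`, `03_mea_phenotype.py`,
`04_vclamp_percent_wt.py`, `05_qpcr_expression.py`, `06_full_pipeline.py`
write their tables to `results/`.  A `ephyskit` console command exposes
the same stages (`simulate`, `cc-extract`, `mea-metrics`, `vc-analyze`,
`qpcr`, `ljp`, `stats`, `run`).

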