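# Methods

This note documents the models, operational definitions, numerical
choices and limitations behind `ephyskit`.  Nothing here states an
empirical result the test suite or `scripts/acceptance.py` does not
itself compute.

## Conductance-based neuron model

The current-clamp generator is a single-compartment Hodgkin–Huxley-style
model in whole-cell units (pF, nS, mV, ms, pA):

C dV/dt = −g_L(V−E_L) − g_Na m∞(V)³h(V−E_Na) − g_K n⁴(V−E_K)
          − g_M w(V−E_K) − g_BK p_BK(V,Ca)(V−E_K)
          − g_SK p_SK(Ca)(V−E_K) + I_stim(t) + I_hold

The fast Na⁺ and delayed-rectifier kinetics are the Wang–Buzsáki
rate functions (instantaneous Na⁺ activation m∞; h and n first-order,
temperature factor 5), chosen because they fire robustly with realistic
upstroke velocities (> 300 mV/ms) — a full spike waveform is needed so
the threshold/half-width/fAHP extractors have something real to measure;
an integrate-and-fire reset would have no repolarization phase.  The
three slower K⁺ conductances give the model its AHP phenotypes:

- **M-type** (`g_m_ns`, default 2 nS): non-inactivating,
  w∞ = 1/(1+exp(−(V+35)/10)), τ_w = 100 ms.  Dampens repetitive firing
  near threshold.
- **BK-type** (`g_bk_ns`, 2 nS): instantaneous gate requiring both
  depolarization (half-activation −10 mV) and Ca²⁺ (half-saturation
  1 a.u.); shapes repolarization/fAHP.
- **SK-type** (`g_sk_ns`, 0.3 nS): voltage-independent Hill gate
  Ca²/(Ca²+0.4²); activated by Ca²⁺ accumulated over a train, it
  produces the medium/slow AHP.  The gSK grid {0, 1, 2, 4} nS
  monotonically deepens the post-train minimum (tested).

Ca²⁺ is a single dimensionless pool: +0.2 per spike (upward crossing of
0 mV), exponential decay with τ = 800 ms — long enough that the sAHP
read 1 s after train offset is still nonzero.  Default passives
(C = 20 pF, g_L = 1.1 nS, E_L = −55 mV) give R_N ≈ 900 MΩ and
τ_m ≈ 18 ms, typical of young iPSC-derived neurons and inside the QC
gates.  Channel densities are illustrative, not fitted: no quantitative
densities are available for these cells, so simulation defaults are
chosen to reproduce phenotype *directions* (burst-proneness, AHP
deepening with SK), and group-level tables from live recordings are not
reproduction targets.

**Integration**: fixed-step exponential Euler (unconditionally stable
for the gating updates and for V given the instantaneous conductances),
internal step ≤ 0.025 ms, substepped to align exactly with the requested
sampling grid (≥ 10 kHz).  All sweeps of a protocol — and, via the
batch interface, whole cohorts of distinct cells — are integrated as one
vectorized batch.  Reproducibility is prioritized over speed: given
(params, protocol, seed) the output is bit-identical.  `noise_sd_mv`
is *measurement* noise added to the recorded voltage after integration,
so the dynamics stay deterministic and the passive-membrane closed-form
checks are exact.  Non-finite voltages raise a diagnostic error naming
the parameter set.

**Protocols**: ramp (10→80 pA over 500 ms), step family (−50→+30 pA in
10 pA, 500 ms), pulse train (25 × 2 ms pulses at 50 Hz).  The train
amplitude is configurable and defaults to 1.2 nA; some protocols in the
literature use 1.4 nA, so no single value is hard-coded.  The holding
bias current is solved from the steady-state current balance at V_h
(−65 mV), and gating states start at their V_h steady states.

## Current-clamp feature extraction

Definitions (dV/dt by central differences, mV/ms):

- **RMP**: mean of the first 100 ms of a zero-current sweep ("immediately
  after break-in" is not a quantified window, so 100 ms is fixed here).
- **R_N**: OLS slope of steady-state voltage (last 100 ms of each step)
  against current, ×1000 → MΩ; sweeps with spikes in the window are
  excluded; ≥ 3 usable amplitudes required (2 accepted when none were
  excluded — a line through two points).
- **Threshold**: voltage at the last upward crossing of dV/dt = 5 mV/ms
  on the rising phase before the peak, linearly interpolated.  (The
  sample at the peak always has dV/dt ≈ 0, so the search is for the
  *upward* crossing, not the last sub-criterion sample.)
- **Amplitude/half-width**: peak − V_h; width between the interpolated
  crossings of V_h + amplitude/2.
- **fAHP**: after the peak, the first point where the 1 ms sliding mean
  of dV/dt enters [−0.5, +0.5] after having been < −0.5; the band is
  interpreted in mV/ms (the criterion is dimensionally a slope although
  often quoted unitless) and the search window capped at 10 ms.
- **mAHP/sAHP**: min V over (offset, offset+1 s] − V_h and
  V(offset+1 s) − V_h, with the train offset taken from the stimulus
  channel.
- **QC**: strict inequalities R_S < 30 MΩ, R_N > 200 MΩ,
  V_rest < −45 mV, amplitude > 80 mV; a missing quantity makes the
  result indeterminate rather than failed.

Extractor outputs are stable from 10 to 50 kHz sampling (tested against
closed-form spikes) and agree with brute-force scans of 10×-oversampled
simulations within 1 mV.

## Liquid junction potential

`compute_ljp` evaluates the stationary Henderson equation and returns
the **additive correction** for pipette-referenced potentials
(V_true = V_meas + LJP), i.e. minus the bath-minus-pipette junction
potential; antisymmetry under solution swap is tested.  Relative
mobilities follow the convention of the junction-potential calculators
used with patch-clamp software, uᵢ = λᵢ°/(zᵢ²·λ_K°) with λ° the limiting
molar conductivity at 25 °C (so z²u is the conductivity weight): K⁺ 1.0,
Na⁺ 0.682, Cl⁻ 1.0388, HCO₃⁻ 0.6053, H₂PO₄⁻ 0.4898, Mg²⁺ 0.361, Ca²⁺
0.4048, SO₄²⁻ 0.5443, methylsulfate 0.737, HEPES⁻ 0.30, gluconate 0.33,
phosphocreatine²⁻ 0.33, MgATP²⁻ 0.25, GTP³⁻ 0.20.  The low-millimolar
organic polyanions move the result by < 0.25 mV across plausible
mobility choices.  The packaged K-MeSO₄ internal includes the
pH-titration ions explicitly: HEPES⁻ at its ionized fraction at pH 7.35
(pKa 7.5) with matching K⁺ from KOH; Mg-ATP is modelled as the MgATP²⁻
complex, which leaves a small (< 10 mM) formal charge residual — an
accepted approximation of nucleotide speciation.  Temperature defaults
to 306.15 K (33 °C, the midpoint of a 32–35 °C bath) with any other
temperature available; the correction changes by ~0.3 mV over
22 → 33 °C.  Correction is applied exactly once per trace, guarded by
an `ljp_corrected` flag.

## MEA metrics and burst detection

The raster generator is a two-state renewal model chosen for analytic
tractability of its oracles: a homogeneous Poisson tonic stream (rate
`tonic_rate_hz`) superposed with compound bursts whose onsets are
Poisson (`burst_rate_per_min`); burst size is Poisson (or gamma-Poisson
when overdispersed) with minimum 2, intra-burst ISIs normal around 10 ms
(floored at the refractory period).  Merged spikes violating the 2 ms
refractory period are thinned with a warning — so realized tonic counts
run ~rate×refractory below the Poisson expectation.  Inactive electrodes
fire at 0.1 spikes/min, safely below the 1/min activity rule.  Planted
burst intervals are returned as ground truth.

Analysis definitions: active electrode = count ≥ duration/60 (inclusive);
mean firing frequency = spikes on active electrodes / (n_active ×
duration) — the inactive electrodes' spikes are excluded to keep the
numerator consistent with the stated denominator (a pooled variant is a
flag); ISI CoV = per-electrode SD/mean of ISIs (≥ 3 spikes), averaged
unweighted across active electrodes — averaging matches the
per-electrode adaptivity of the burst detector; a pooled variant exists
behind a flag.

**Burst detection** follows the published description of
surprise-maximization: with the electrode's mean rate r = n/duration as
the null, seed runs where consecutive ISIs < 0.5× the mean ISI, extend
forward while S = −ln P(N ≥ n | rate r, span T) increases, trim from the
start while S increases, accept at S ≥ 10 (natural log) with ≥ 3
spikes; accepted bursts are non-overlapping in time order.  The
commercial detector's exact parameters are unpublished, so all three
knobs are config options; surprise values agree with brute-force Poisson
tail sums to 1e−9 relative error (tested), and on the reference
synthetic well (6 bursts/min, 10 spikes/burst, 0.5 Hz tonic) recall and
precision against planted bursts exceed 0.95 with matching defined as
interval overlap ≥ 50 % of the shorter interval.  Burst % uses all
active-electrode spikes in the denominator (whether non-bursting
electrodes' spikes belong there is a convention; documented here).
Electrodes with ≥ 1 burst count as bursting.

Raw-signal spike detection: 2nd-order Butterworth band-pass 300–5000 Hz
(zero-phase), noise RMS = median(|x|)/0.6745 per 10 s window (robust to
spikes), ±6×RMS threshold crossings with 1 ms dead time, timed at the
crossing extremum.  The extracellular generator places a ~1 ms biphasic
template (amplitude in multiples of noise RMS; against unit RMS when
noiseless) on white Gaussian noise.

## Voltage clamp

The channel generator is Boltzmann-gated with single-exponential
activation: x(t) relaxes from x∞(−80 mV) toward x∞(V) with τ(V)
(constant by default, a callable for voltage dependence);
I = g_max·x·(V−E_rev) + g_leak(V−E_leak) + noise, with a 300 ms tail at
0 mV.  The post-drug condition scales the channel by
(1 − drug_block_fraction); subtraction of matched sweeps is the only
background removal, as in pharmacological isolation.

Analysis: step current at the sample nearest 999 ms, tail at 5 ms after
the tail switch (single-sample by default; an averaging window is an
option since the published convention is not explicit).  Activation fits
use I(t) = A(1−e^(−t/τ)) + C over 50–1000 ms for steps in [−30, +40] mV;
initialization C = first 5 ms mean, A = I(end)−C, τ = time to 63 % of
the span; bounds τ ∈ [1, 5000] ms; τ at a bound or a flat trace returns
`converged=False`.  Percent-of-WT = 100·mean(variant densities)/
mean(WT densities), SEM by first-order (delta-method) propagation of the
two group SEMs; scale-invariance is tested.  G-V curves normalize tail
magnitudes (sign recorded); note that with fast kinetics the 5 ms tail
latency lets the gate relax toward x∞(0 mV) and biases the fitted V½ by
~1 mV at τ = 100 ms — parameter-recovery tests therefore use slow
kinetics where the bias is negligible.  QC gates are inclusive as
printed: seal ≥ 0.5 GΩ, R_S ≤ 20 MΩ.

## qPCR

Technical replicates are averaged on the Ct scale (standard practice);
ΔCt = mean Ct(target) − mean of the two housekeeping genes' mean Cts;
relative expression 2^−ΔCt, optionally rescaled gene-wise to a reference
sample.  No amplification-efficiency correction is applied (the pure
2^−ΔCt form).  The generator draws housekeeping Cts around 20 cycles,
targets around 25 with −log2(fold) offsets, duplicate replicates, and a
shared per-sample offset that cancels in ΔCt (tested as an invariance).

## Statistics

All tests are implemented self-contained over scipy distributions —
statsmodels and pingouin appear only as independent cross-checks in the
test suite:

- t-test: pooled-variance Student by default (the classic default of
  legacy stats packages), Welch and paired variants by flag; zero
  variance with equal means returns p = 1.
- Two-way ANOVA: sum-to-zero coding; Type III partial SS by explicit
  least-squares model comparison (Type II by flag); empty cells raise.
- Repeated-measures (mixed) ANOVA: between effect = one-way ANOVA on
  subject means (×t); within/interaction effects from within-subject
  deviations with partial SS against the subject×within residual;
  incomplete subjects dropped and counted; no sphericity correction by
  default (uncorrected dfs match the reporting convention of the field),
  Greenhouse–Geisser optional.  The within factor is treated as
  categorical.
- Fisher's protected LSD: pairwise pooled-error t tests run only when
  the omnibus p < α; criterion t₍₁₋α/₂,df₎·√(MS_e(1/nᵢ+1/nⱼ)).
- No multiple-testing correction beyond LSD protection.

Type-I error calibration (rejection rate 0.05 ± 0.007 at 10⁴ null
replicates for t-test, one-way and two-way ANOVA), the exact F = t²
identity, and agreement of the RM decomposition with brute-force cell
means to 1e−6 are asserted in the acceptance suite.

## Pipeline, formats, provenance

Interchange is CSV (traces, rasters, sweep families, Ct and feature
tables) with JSON sidecars for acquisition metadata; units are carried
in column names (`half_width_ms`, `mahp_mv`, …, see
`docs/data_dictionary.md`).  Configs are YAML/JSON with unknown keys
rejected by name.  `run_pipeline` is deterministic given (config, seed)
— all randomness derives from one seeded generator — and writes a
manifest with the package version, the full config echo and SHA-256
hashes of every output; a directory holding a completed manifest is
never overwritten (rerun policy: full clean rerun into a fresh
directory).

Problem sizes in the shipped analysis scripts and tests (cells per
group, wells, electrodes, recording durations) are chosen as the
smallest cohorts at which the tested effects are unambiguous; all scale
up by config.

## What the synthetic data do and do not show

The generators emulate the *statistical structure* each analysis stage
assumes — spike waveforms with realistic upstrokes, Poisson/burst
mixtures, exponential channel activation, duplicate-well Ct tables —
so passing tests demonstrate that the extraction and statistics recover
known ground truth under those assumptions.  They do not emulate
electrode drift, seal instability, multi-unit contamination,
cross-electrode synchrony (network bursts), synaptic activity, glial
contributions, or amplification-efficiency differences between qPCR
assays; agreement on synthetic data therefore bounds algorithmic
correctness, not robustness to every artifact of live recordings.
Network-burst detection, spike sorting and evoked-response analysis are
out of scope.
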