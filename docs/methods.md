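# Methods

This note documents the models, conventions and numerical choices behind
`gpephys`, and what the synthetic cohorts do and do not establish about
real recordings.

## Synthetic membrane model

Sweeps are generated from a single-compartment equation

    C_m dV/dt = −(V − E_L)/R_in − g_h·m·(V − E_h) + I_hold + I(t)
    τ_h dm/dt = m_∞(V) − m,   m_∞(V) = 1/(1 + exp((V + 80)/6))

integrated by explicit Euler at the sample period (0.05 ms at 20 kHz; the
simulator rejects steps above 0.1 ms). `m_∞` is a decreasing sigmoid
(half-activation −80 mV, slope 6 mV), so the `g_h` term behaves like an
h-current: it activates on hyperpolarization and produces the sag-and-
rebound trajectory of a −200 pA step. A holding current pins the resting
potential to `E_L`, mimicking the experimenter holding cells near −70 mV.

Action potentials are not generated by spike conductances. When V crosses
the threshold `V_T`, a piecewise-linear template (rise to `V_peak` over
`t_rise`, fall back to threshold over `t_fall`, descent to the fAHP trough
over `t_fAHP`) is pasted into the trace and integration resumes from the
trough. Template breakpoints are quantized to the sample grid and the
*effective* (pasted) parameters are recorded as ground truth, so waveform
recovery can be checked sub-sample-exactly by interpolation. This is a
deliberate trade: waveform ground truth is exact, at the cost of spike
initiation realism (no biophysical threshold dynamics). Spontaneous firing
at 0 pA is realized as a jittered periodic train (5% CV of the interspike
interval) pasted on a flat baseline — simple ground truth for rate
recovery, not a pacemaker model.

### Population parameters

The three recorded populations are emulated by group-specific parameter
distributions: log-normal (CV ≈ 15%, 30% for `g_h`, 40% for rates) for
positive scale parameters, normal (SD 2 mV) for voltages. Published
sources give the *orderings* of these features but not population
means/SDs, so the defaults are the package's own choices of realistic
magnitudes:

| parameter | arkypallidal | prototypic (PV / Nkx2.1) |
|---|---|---|
| R_in (MΩ) | 350 | 120 |
| C_m (pF) | 60 | 100 |
| V_T (mV) | −50 | −42 |
| g_h (nS) | 1.5 | 0.4 |
| AP rise / fall (ms) | 0.45 / 1.4 | 0.25 / 0.7 (Nkx 0.235 / 0.7) |
| V_peak (mV) | 25 | 14 (Nkx 15.5) |
| fAHP depth (mV) | 18 | 22 (Nkx 23.5) |
| spont. rate (Hz, silent frac.) | 2 (40%) | 15 (5%) |
| soma radius (μm) | 5 | 7 |

Two calibration points deserve comment. First, the sag conductance scale:
with `g_h` much above ~2 nS the h-current dominates the steady-state I-V
slope and the *measured* input resistance no longer reflects `R_in`,
erasing the characteristic high-IR arkypallidal phenotype; 1.5/0.4 nS
keeps the sag prominent (sag ratio ≈ 1.1 vs ≈ 1.02) without flattening
the I-V curve. Second, the PV-vs-Nkx differences are intentionally
sub-sigma (≈ 0.4–0.75 within-group SD): both populations show small,
statistically detectable AP-shape differences at the study's sample sizes,
yet form a single mixed cluster under Ward linkage — which is exactly the
two-level structure the downstream clustering analysis is meant to expose.
Dendritic geometry (branching probability 0.30, exponential segment
lengths of 90–110 μm, up to 6 branch orders, linear diameter taper) gives
total dendritic lengths around 0.8–1.4 mm and Sholl profiles peaking near
6 intersections.

Note that for cells with `g_h > 0` the *extracted* input resistance is a
chord resistance (e.g. ≈ 165 MΩ for an arkypallidal cell with
`R_in = 350 MΩ`): this is a property of the steady-state measurement
itself, shared with real recordings, not an extraction error. Exact-recovery
tests therefore use ohmic (`g_h = 0`) cells.

## IPSP trains and short-term depression

Each IPSP is a rise-saturating double-exponential decay, normalized to
unit peak and scaled by the pulse amplitude; events superpose linearly on
the holding baseline. (IPSPs are *depolarizing* here: the recordings use a
high-chloride internal solution.) Per-pulse amplitudes follow a
depleting-resource recursion

    R_1 = 1,  a_n = A1·U·R_n,  R_{n+1} = 1 − (1 − R_n(1−U))·exp(−Δt/τ_rec)

with release fraction `U` and recovery constant `τ_rec`; `τ_rec → 0` gives
a flat train, `U = 1` with slow recovery gives full depletion after the
first pulse.

The analysis-side decomposition fits the decay with a double exponential
whose time constants are shared across pulses within a train (a single
kinetic class per connection — this stabilizes fits on the small late
pulses). The taus are estimated once on the post-train tail, where the
decay is longest and best constrained; for each pulse the compound decay
of everything preceding is then a two-term linear model in those basis
exponentials, fitted by linear least squares from the pulse's peak to the
next pulse and extrapolated exactly one inter-pulse interval forward. This
keeps extrapolation error from accumulating across the train. Peaks and
baselines are measured on a lightly smoothed trace (~1 ms local quadratic)
because the maximum of a raw noisy trace is biased upward by extreme-value
statistics of the noise; the smoothing changes noiseless amplitudes by
< 0.1%. Non-convergent tail fits fall back to a single exponential, with a
flag; negative amplitudes are floored at zero, with a flag.

## Connection detection and electrical coupling

A chemical connection requires the spike-triggered average deflection of
the averaged follower trace, in a 1–6 ms causal window after the driver
AP, to exceed both 3× the baseline SD of the averaged trace and an
absolute 0.2 mV floor; the latency is the 10%-rise point and must be
causal (≥ 0.3 ms). The thresholds are configuration, not published
values: the floor sits far below the smallest reported IPSP in this
preparation (1.2 mV), and the measured operating characteristics under
20-sweep averaging of 0.2 mV noise are a false-positive rate ≤ 1% and
power ≥ 95% at 1 mV.

Electrical coupling divides the follower's steady-state deflection by the
driver's during a −150 pA / 500 ms step (final 100 ms minus pre-step
baseline). `coupled` requires a coefficient ≥ 0.01 with a hyperpolarizing
follower deflection above 3× its baseline SD; a driver deflection under
1 mV invalidates the test. Since the emulated preparation contains no
coupling, the relevant performance surface is specificity, which the
uncoupled-pair tests exercise; a two-compartment resistively coupled model
(`g_c = cc·G₂/(1−cc)`) provides the positive control.

## Morphometrics

SWC trees are validated structurally (single soma root, parents precede
children, positive radii, 7 columns; errors carry line numbers). Axon
nodes (type 2) are ignored — slice experiments truncate long-range axons.
Conventions the field leaves open, chosen and fixed here: soma area is the
projected disc π·r² of the largest soma node (confocal reconstructions
report a 2D-like extent); total surface is the soma sphere 4π·r² plus the
lateral frustum area of every dendritic segment, where soma-attached
segments use the child radius at both ends (a dendrite emerges at its own
caliber, not the soma's); a trifurcation counts as two bifurcations in the
Euler identity `terminations = bifurcations + primaries`. Sholl spheres
are centered on the radius-weighted soma centroid with a 10 μm default
step; a segment with endpoints straddling a sphere counts one crossing, a
segment that dips inside and exits counts two, tangency resolves to the
smaller radius. Branch-order diameters are length-weighted means of node
diameters, orders incrementing at each bifurcation.

## Population analysis

The 15-feature matrix (AP amplitude, duration, half-width, rise/fall
times, AHP time, rise/fall rates, fAHP, rectification index, threshold,
input resistance, rheobase, maximum discharge frequency, f-I slope) drops
any row with a missing feature — missingness is flagged upstream, never
imputed — and z-scores columns (sample SD, ddof 1). PCA decomposes the
correlation matrix; components are retained while the eigenvalue exceeds
1, with the scree-plot elbow reported as a diagnostic only. Clustering is
Ward's method on squared Euclidean distances over the z-scored features
(not PC scores — the conservative reading where the published procedure is
ambiguous; both are exposed via configuration, and the two-population
separation is robust to either). The comparison dispatcher tests each
group with Shapiro-Wilk at α = 0.05: all normal → one-way ANOVA with
Tukey's post hoc; otherwise Kruskal-Wallis with Dunn's rank test,
Bonferroni-adjusted (the adjustment choice is ours; Dunn's test is
implemented in-package with the standard tie correction). A constant group
forces the non-parametric branch.

## Numerical conventions and edge cases

- **Spike threshold**: dV/dt criterion 10 mV/ms on a 5-point
  Savitzky-Golay derivative, then refined forward to the last sample whose
  raw one-sample slope is still below the criterion. The refinement
  removes the smoothing-window bias (2 samples ≈ 0.1 ms) that would
  otherwise make rise times unrecoverable at their 3% tolerance. Under
  noise the refinement can stop a couple of samples early, biasing rise
  times up by ~0.1–0.2 ms uniformly across groups.
- **Half-width** is the time from threshold to the decay crossing of
  threshold + amplitude/2 — per the feature definitions used here, *not*
  the conventional FWHM. Flagged because the two differ by the rise-side
  half-crossing.
- **Steady-state window** for I-V fits is 0.8–0.9 s into the step; steps
  shorter than 0.9 s use their final 10%.
- **Sag windows**: trough over the first 150 ms of the step, steady state
  over the final 100 ms. For slow membranes (τ_m ≈ 25 ms) relaxation is
  not quite complete inside the trough window, so a sag-free cell's ratio
  is 1 within ~5·10⁻³ rather than machine precision.
- **Capacitance** is τ_m/R_in with τ_m from a bounded single-exponential
  fit 2–100 ms after onset of the largest hyperpolarizing step ≤ 50 pA;
  a large sag conductance biases it (documented, only positivity is
  guaranteed there).
- **Degenerate inputs**: empty spike lists, all-zero traces, subthreshold
  ramps, < 3 usable I-V sweeps, and empty pair lists all return flagged
  missing values, never exceptions.

## Problem sizes

Test-suite and acceptance-script runs use cohorts of 60 arkypallidal + 60
prototypic cells per seed for clustering (20 seeds in the test suite, 5 in
the acceptance script), 10 kHz sampling for cohort batteries and 20 kHz
for exact-recovery checks (both inside the 10–20 kHz digitization range
the analyses expect), 600–1000 unconnected and 200–300 connected pairs for
detector operating characteristics, and 100–200 random trees for the
Sholl/Euler checks. These sizes were chosen to make the Monte-Carlo
estimates stable at the tolerances asserted.

## Limitations

The generator's cells are single compartments with template APs: passing
recovery tests demonstrates that the *extraction pipeline* is correct and
unbiased under the stated noise model, not that it is robust to
electrode artifacts, bridge imbalance, slow drift, seal instability or
dendritic filtering, none of which are emulated. White Gaussian voltage
noise understates the 1/f and line components of real rigs. Connectivity
simulation treats pairs independently (no common-input correlations), and
the distance field is annotation only — connection probability is not
distance-dependent within the sampled envelope. The depression model is a
single depleting resource; facilitation and stochastic release are out of
scope.
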