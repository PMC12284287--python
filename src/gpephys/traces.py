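"""Intrinsic electrophysiological features from current-clamp sweeps.

Implements the per-cell feature set used to characterise GPe neurons:
AP detection and waveform metrics, ramp-defined spike threshold, rheobase,
input resistance and rectification, membrane capacitance, sag amplitude and
ratio, spontaneous rate, discharge frequency and the f-I slope, plus phase
plots.  Missing values are returned as NaN (and flagged), never imputed, so
that population-level analyses can drop incomplete recordings explicitly.

Conventions
-----------
* Spike threshold uses a dV/dt criterion of 10 mV/ms by default, applied to
  a 5-point Savitzky-Golay smoothed derivative.
* AP duration here is rise time + fall time (threshold -> peak -> threshold
  re-crossing); half-width is the time from threshold to the decay crossing
  of threshold + amplitude/2 — note this is measured from threshold, not the
  conventional full width at half maximum.
* fAHP amplitude is reported as a positive depth below threshold.
* Sag ratio divides absolute membrane potentials (trough / steady state),
  so it is >= 1 and equals 1 without a sag conductance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

from gpephys.sweep import Sweep

DVDT_CRITERION = 10.0  # mV/ms
PEAK_SEARCH_MS = 5.0  # window after a dV/dt crossing in which a peak must occur
REFRACTORY_MS = 2.0  # peaks closer than this merge into one detection
PEAK_FLOOR_MV = 0.0  # a real AP peak must exceed this voltage


def _smoothed_dvdt(sweep: Sweep) -> np.ndarray:
    """5-point local-quadratic (Savitzky-Golay) derivative, mV/ms."""
    if len(sweep) < 5:
        return np.gradient(sweep.voltage, sweep.dt)
    return signal.savgol_filter(sweep.voltage, 5, 2, deriv=1, delta=sweep.dt)


def phase_plot(sweep: Sweep) -> tuple[np.ndarray, np.ndarray]:
    """(V, dV/dt) pairs using the raw centered-difference derivative.

    Output length equals the input length; the boundary samples use
    one-sided differences.  No resampling or smoothing is applied.
    """
    dvdt = np.gradient(sweep.voltage, sweep.dt)
    return sweep.voltage.copy(), dvdt


def detect_aps(sweep: Sweep, dvdt_criterion: float = DVDT_CRITERION) -> np.ndarray:
    """Indices of AP peaks in a sweep.

    A detection requires an upward crossing of ``dvdt_criterion`` by the
    smoothed derivative followed within 5 ms by a voltage maximum above
    0 mV; peaks within a 2 ms refractory window merge into one.
    """
    v = sweep.voltage
    dvdt = _smoothed_dvdt(sweep)
    above = dvdt >= dvdt_criterion
    ups = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if ups.size == 0:
        return np.array([], dtype=int)
    w = max(1, int(round(PEAK_SEARCH_MS / sweep.dt)))
    peaks: list[int] = []
    for i in ups:
        seg = v[i:i + w]
        if seg.size == 0:
            continue
        p = i + int(np.argmax(seg))
        if v[p] > PEAK_FLOOR_MV:
            peaks.append(p)
    if not peaks:
        return np.array([], dtype=int)
    peaks_arr = np.unique(np.array(peaks))
    merged = [int(peaks_arr[0])]
    gap = REFRACTORY_MS / sweep.dt
    for p in peaks_arr[1:]:
        if p - merged[-1] <= gap:
            if v[p] > v[merged[-1]]:
                merged[-1] = int(p)
        else:
            merged.append(int(p))
    return np.array(merged, dtype=int)


def _takeoff_index(sweep: Sweep, peak_idx: int, dvdt_criterion: float,
                   lo: int = 0) -> int:
    """Last sample before ``peak_idx`` where dV/dt is still below the criterion.

    The smoothed derivative locates the crossing; because smoothing spreads
    the take-off over its window, the index is then advanced while the raw
    one-sample slope stays below the criterion, landing on the true take-off
    sample.
    """
    v = sweep.voltage
    dvdt = _smoothed_dvdt(sweep)
    below = np.flatnonzero(dvdt[lo:peak_idx] < dvdt_criterion)
    j = lo + int(below[-1]) if below.size else lo
    while j + 1 < peak_idx and (v[j + 1] - v[j]) / sweep.dt < dvdt_criterion:
        j += 1
    return j


def threshold_from_ramp(sweep: Sweep, dvdt_criterion: float = DVDT_CRITERION) -> float:
    """Spike threshold (mV): voltage where dV/dt crosses the criterion on a ramp.

    Returns the voltage at the last sample before the first AP at which the
    derivative is still below the criterion (and stays above it from there
    to the peak).  NaN if the sweep contains no AP.
    """
    peaks = detect_aps(sweep, dvdt_criterion)
    if peaks.size == 0:
        return float("nan")
    return float(sweep.voltage[_takeoff_index(sweep, int(peaks[0]), dvdt_criterion)])


# ---------------------------------------------------------------------------
# Step-family helpers
# ---------------------------------------------------------------------------

def step_window(sweep: Sweep) -> tuple[int, int, float]:
    """Locate the current step: (onset index, offset index, amplitude pA).

    The amplitude is measured relative to the pre-step baseline current.
    Returns (0, len, 0.0) when no step is present.
    """
    i = sweep.current
    base = float(np.median(i[: max(2, len(i) // 20)]))
    dev = i - base
    mag = float(np.max(np.abs(dev)))
    if mag < 1.0:  # pA; nothing injected
        return 0, len(i), 0.0
    active = np.abs(dev) > 0.5 * mag
    onset = int(np.flatnonzero(active)[0])
    offset = int(np.flatnonzero(active)[-1]) + 1
    amp = float(np.median(dev[active]))
    return onset, offset, amp


def _steady_window(sweep: Sweep, onset: int, offset: int) -> tuple[int, int]:
    """Steady-state averaging window: 0.8-0.9 s into the step for steps of
    >= 0.9 s, otherwise the final 10% of the step."""
    dur_ms = (offset - onset) * sweep.dt
    if dur_ms >= 900.0:
        a = onset + int(round(800.0 / sweep.dt))
        b = onset + int(round(900.0 / sweep.dt))
    else:
        a = offset - max(1, int(round(0.10 * (offset - onset))))
        b = offset
    return a, b


def _steady_voltage(sweep: Sweep) -> tuple[float, float]:
    onset, offset, amp = step_window(sweep)
    a, b = _steady_window(sweep, onset, offset)
    return float(np.mean(sweep.voltage[a:b])), amp


def rheobase_from_steps(step_sweeps: list[Sweep],
                        dvdt_criterion: float = DVDT_CRITERION) -> float:
    """Smallest step amplitude (pA) whose sweep contains at least one AP."""
    spiking = [step_window(s)[2] for s in step_sweeps
               if detect_aps(s, dvdt_criterion).size > 0]
    return float(min(spiking)) if spiking else float("nan")


def input_resistance(step_sweeps: list[Sweep],
                     dvdt_criterion: float = DVDT_CRITERION) -> tuple[float, float]:
    """Input resistance (MOhm) and fit R^2 from subthreshold steps.

    Least-squares slope of the steady-state mean voltage against injected
    current; sweeps containing APs are excluded.  NaN with R^2 NaN when
    fewer than 3 usable sweeps remain.
    """
    pts = [(amp, v) for s in step_sweeps
           if detect_aps(s, dvdt_criterion).size == 0
           for v, amp in [_steady_voltage(s)]]
    if len(pts) < 3:
        return float("nan"), float("nan")
    amps, volts = map(np.array, zip(*pts))
    fit = stats.linregress(amps, volts)
    return float(fit.slope * 1000.0), float(fit.rvalue**2)


def rectification_index(step_sweeps: list[Sweep],
                        dvdt_criterion: float = DVDT_CRITERION) -> float:
    """Ratio of hyperpolarized to near-holding input resistance.

    Slope over the two most hyperpolarizing steps divided by the slope over
    the two steps bracketing 0 pA.  < 1 indicates inward rectification (a
    sag conductance flattens the I-V curve at hyperpolarized potentials).
    """
    pts = sorted(
        (amp, v) for s in step_sweeps
        if detect_aps(s, dvdt_criterion).size == 0
        for v, amp in [_steady_voltage(s)]
    )
    if len(pts) < 4:
        return float("nan")
    amps = np.array([p[0] for p in pts])
    volts = np.array([p[1] for p in pts])
    hyper = (volts[1] - volts[0]) / (amps[1] - amps[0])
    neg = np.flatnonzero(amps <= 0)
    pos = np.flatnonzero(amps > 0)
    if pos.size and neg.size:
        i, j = neg[-1], pos[0]
    else:
        order = np.argsort(np.abs(amps))
        i, j = sorted(order[:2])
    holding = (volts[j] - volts[i]) / (amps[j] - amps[i])
    if holding == 0:
        return float("nan")
    return float(hyper / holding)


def capacitance(step_sweeps: list[Sweep], R_in: float | None = None,
                dvdt_criterion: float = DVDT_CRITERION) -> float:
    """Membrane capacitance (pF) as tau_m / R_in.

    tau_m comes from a single-exponential fit to the voltage relaxation
    2-100 ms after the onset of a small (|I| <= 50 pA) hyperpolarizing step;
    R_in is computed from the step family unless supplied.  Biased by a
    large sag conductance (the fit window overlaps sag activation).
    """
    candidates = [(s, amp) for s in step_sweeps
                  for _, _, amp in [step_window(s)]
                  if -50.0 <= amp < 0.0 and detect_aps(s, dvdt_criterion).size == 0]
    if not candidates:
        return float("nan")
    sweep, _ = max(candidates, key=lambda sa: abs(sa[1]))
    if R_in is None:
        R_in, _ = input_resistance(step_sweeps, dvdt_criterion)
    if not np.isfinite(R_in) or R_in <= 0:
        return float("nan")
    onset, offset, _ = step_window(sweep)
    a = onset + int(round(2.0 / sweep.dt))
    b = min(offset, onset + int(round(100.0 / sweep.dt)))
    t = sweep.time[a:b] - sweep.time[onset]
    v = sweep.voltage[a:b]

    def model(tt, v_inf, dv, tau):
        return v_inf + dv * np.exp(-tt / tau)

    try:
        p0 = (float(v[-1]), float(v[0] - v[-1]), 10.0)
        popt, _ = optimize.curve_fit(
            model, t, v, p0=p0, maxfev=5000,
            bounds=([-150.0, -100.0, 0.05], [0.0, 100.0, 500.0]))
    except (RuntimeError, ValueError):
        return float("nan")
    tau = float(popt[2])
    return 1000.0 * tau / R_in


# ---------------------------------------------------------------------------
# AP waveform
# ---------------------------------------------------------------------------

@dataclass
class ApFeatures:
    threshold: float  # mV
    amplitude: float  # mV, threshold to peak
    duration: float  # ms, rise + fall
    half_width: float  # ms, threshold to decay crossing of 50% amplitude
    rise_time: float  # ms
    fall_time: float  # ms
    rise_rate: float  # mV/ms, amplitude / rise_time
    fall_rate: float  # mV/ms, amplitude / fall_time
    fAHP_amplitude: float  # mV below threshold (positive depth)
    fAHP_time: float  # ms from the fall point to the trough
    AHP_time: float  # ms, as fAHP_time but with a 50 ms search window
    truncated: bool = False


def _interp_crossing(t0: float, t1: float, v0: float, v1: float, level: float) -> float:
    if v1 == v0:
        return t1
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def ap_waveform(sweep: Sweep, spike_idx: int, threshold: float | None = None,
                next_spike_idx: int | None = None,
                dvdt_criterion: float = DVDT_CRITERION) -> ApFeatures:
    """Waveform features of a single AP (peak at ``spike_idx``).

    ``threshold`` may be supplied (e.g. the ramp-derived cell threshold); by
    default it is derived per spike from the local dV/dt criterion crossing.
    Crossing times are linearly interpolated between samples.  When the
    decay never re-crosses the threshold before the next spike the
    fall-dependent features are NaN and ``truncated`` is set.
    """
    v = sweep.voltage
    t = sweep.time
    p = int(spike_idx)
    limit = int(next_spike_idx) if next_spike_idx is not None else len(v)
    if threshold is None:
        lo = max(0, p - int(round(10.0 / sweep.dt)))
        threshold = float(v[_takeoff_index(sweep, p, dvdt_criterion, lo=lo)])
    amplitude = float(v[p] - threshold)

    # threshold crossing on the rise
    pre = np.flatnonzero(v[:p] < threshold)
    if pre.size:
        i = int(pre[-1])
        t_thr = _interp_crossing(t[i], t[i + 1], v[i], v[i + 1], threshold)
    else:
        t_thr = float(t[0])
    rise_time = float(t[p] - t_thr)

    # decay crossings of threshold and of the half-amplitude level
    seg = v[p:limit]
    below_thr = np.flatnonzero(seg <= threshold)
    half_level = threshold + amplitude / 2.0
    below_half = np.flatnonzero(seg <= half_level)
    if below_thr.size == 0:
        return ApFeatures(threshold, amplitude, float("nan"), float("nan"),
                          rise_time, float("nan"),
                          amplitude / rise_time if rise_time > 0 else float("nan"),
                          float("nan"), float("nan"), float("nan"), float("nan"),
                          truncated=True)
    j = p + int(below_thr[0])
    t_fall = _interp_crossing(t[j - 1], t[j], v[j - 1], v[j], threshold)
    fall_time = float(t_fall - t[p])
    k = p + int(below_half[0])
    t_half = _interp_crossing(t[k - 1], t[k], v[k - 1], v[k], half_level)
    half_width = float(t_half - t_thr)

    def trough(window_ms: float) -> tuple[float, float]:
        end = min(limit, j + int(round(window_ms / sweep.dt)))
        if end <= j:
            return float("nan"), float("nan")
        w = v[j:end]
        m = int(np.argmin(w))
        return float(threshold - w[m]), float(t[j + m] - t_fall)

    fahp_amp, fahp_t = trough(10.0)
    _, ahp_t = trough(50.0)
    return ApFeatures(
        threshold=float(threshold), amplitude=amplitude,
        duration=rise_time + fall_time, half_width=half_width,
        rise_time=rise_time, fall_time=fall_time,
        rise_rate=amplitude / rise_time if rise_time > 0 else float("nan"),
        fall_rate=amplitude / fall_time if fall_time > 0 else float("nan"),
        fAHP_amplitude=fahp_amp, fAHP_time=fahp_t, AHP_time=ahp_t,
    )


def mean_ap_features(sweep: Sweep, dvdt_criterion: float = DVDT_CRITERION,
                     max_spikes: int = 10) -> ApFeatures | None:
    """Average waveform features over up to ``max_spikes`` APs of a sweep."""
    peaks = detect_aps(sweep, dvdt_criterion)
    if peaks.size == 0:
        return None
    feats = []
    for n, p in enumerate(peaks[:max_spikes]):
        nxt = int(peaks[n + 1]) if n + 1 < peaks.size else None
        f = ap_waveform(sweep, p, next_spike_idx=nxt, dvdt_criterion=dvdt_criterion)
        if not f.truncated:
            feats.append(f)
    if not feats:
        return None
    mean = {
        fld.name: float(np.nanmean([getattr(f, fld.name) for f in feats]))
        for fld in dc_fields(ApFeatures) if fld.name != "truncated"
    }
    return ApFeatures(**mean, truncated=False)


# ---------------------------------------------------------------------------
# Sag, spontaneous rate, discharge
# ---------------------------------------------------------------------------

@dataclass
class SagMetrics:
    sag_amplitude: float  # mV, steady minus trough (positive when sag present)
    sag_ratio: float  # trough / steady on absolute potentials, >= 1
    v_min: float
    v_steady: float


def sag_metrics(sweep: Sweep, trough_window_ms: float = 150.0,
                steady_window_ms: float = 100.0) -> SagMetrics:
    """Sag amplitude and ratio from a -200 pA / >= 500 ms step.

    The trough is the minimum voltage over the first 150 ms of the step; the
    steady state is the mean over its final 100 ms.  The ratio divides the
    absolute potentials (both negative), so no sag gives exactly 1.
    """
    onset, offset, amp = step_window(sweep)
    if amp >= 0:
        return SagMetrics(float("nan"), float("nan"), float("nan"), float("nan"))
    a = onset + max(1, int(round(trough_window_ms / sweep.dt)))
    v_min = float(np.min(sweep.voltage[onset:a]))
    b = offset - int(round(steady_window_ms / sweep.dt))
    v_steady = float(np.mean(sweep.voltage[b:offset]))
    return SagMetrics(v_steady - v_min, v_min / v_steady, v_min, v_steady)


def spontaneous_rate(zero_current_sweeps: list[Sweep],
                     dvdt_criterion: float = DVDT_CRITERION) -> tuple[float, bool]:
    """Mean firing rate (Hz) at 0 pA holding over the supplied sweeps."""
    total_aps = sum(detect_aps(s, dvdt_criterion).size for s in zero_current_sweeps)
    total_s = sum(s.duration for s in zero_current_sweeps) / 1000.0
    rate = total_aps / total_s if total_s > 0 else float("nan")
    return rate, rate > 0


def discharge_frequencies(step_sweeps: list[Sweep],
                          dvdt_criterion: float = DVDT_CRITERION) -> pd.DataFrame:
    """Per-step injected amplitude (pA) and discharge frequency (Hz)."""
    rows = []
    for s in step_sweeps:
        onset, offset, amp = step_window(s)
        dur_s = (offset - onset) * s.dt / 1000.0
        n_aps = detect_aps(s, dvdt_criterion).size
        rows.append({"amplitude_pA": amp, "n_aps": n_aps,
                     "frequency_Hz": n_aps / dur_s if dur_s > 0 else np.nan})
    return pd.DataFrame(rows).sort_values("amplitude_pA", ignore_index=True)


def highest_discharge_frequency(step_sweeps: list[Sweep],
                                dvdt_criterion: float = DVDT_CRITERION) -> float:
    """Discharge frequency (Hz) at the largest injected step; NaN if silent."""
    df = discharge_frequencies(step_sweeps, dvdt_criterion)
    spiking = df[df.n_aps > 0]
    if spiking.empty:
        return float("nan")
    return float(df.iloc[-1].frequency_Hz)


def fI_slope(step_sweeps: list[Sweep],
             dvdt_criterion: float = DVDT_CRITERION) -> float:
    """Least-squares slope (Hz/pA) of frequency vs current over spiking steps."""
    df = discharge_frequencies(step_sweeps, dvdt_criterion)
    spiking = df[df.n_aps > 0]
    if len(spiking) < 2:
        return float("nan")
    fit = stats.linregress(spiking.amplitude_pA, spiking.frequency_Hz)
    return float(fit.slope)


# ---------------------------------------------------------------------------
# Per-cell profile
# ---------------------------------------------------------------------------

PROFILE_COLUMNS = [
    "cell_id", "group",
    "input_resistance", "ir_r_squared", "rectification_index", "capacitance",
    "threshold", "rheobase", "max_discharge_freq", "fi_slope",
    "spont_rate", "is_firing", "sag_amplitude", "sag_ratio",
    "ap_amplitude", "ap_duration", "ap_half_width", "ap_rise_time",
    "ap_fall_time", "ap_rise_rate", "ap_fall_rate",
    "fahp_amplitude", "fahp_time", "ahp_time",
]


@dataclass
class IntrinsicProfile:
    """The per-cell electrophysiological feature vector."""

    cell_id: str = ""
    group: str = ""
    input_resistance: float = np.nan  # MOhm
    ir_r_squared: float = np.nan
    rectification_index: float = np.nan
    capacitance: float = np.nan  # pF
    threshold: float = np.nan  # mV (ramp-defined)
    rheobase: float = np.nan  # pA
    max_discharge_freq: float = np.nan  # Hz
    fi_slope: float = np.nan  # Hz/pA
    spont_rate: float = np.nan  # Hz
    is_firing: bool = False
    sag_amplitude: float = np.nan  # mV
    sag_ratio: float = np.nan
    ap_amplitude: float = np.nan  # mV
    ap_duration: float = np.nan  # ms
    ap_half_width: float = np.nan  # ms
    ap_rise_time: float = np.nan  # ms
    ap_fall_time: float = np.nan  # ms
    ap_rise_rate: float = np.nan  # mV/ms
    ap_fall_rate: float = np.nan  # mV/ms
    fahp_amplitude: float = np.nan  # mV
    fahp_time: float = np.nan  # ms
    ahp_time: float = np.nan  # ms
    flags: list = field(default_factory=list)

    def to_row(self) -> dict:
        return {c: getattr(self, c) for c in PROFILE_COLUMNS}


def extract_profile(cell_id: str, group: str,
                    ramp_sweep: Sweep | None = None,
                    step_sweeps: list[Sweep] | None = None,
                    sag_sweep: Sweep | None = None,
                    zero_sweeps: list[Sweep] | None = None,
                    dvdt_criterion: float = DVDT_CRITERION) -> IntrinsicProfile:
    """Assemble the full IntrinsicProfile for one cell from its sweeps.

    Any protocol may be absent; the corresponding features stay NaN and a
    flag records what was missing.
    """
    prof = IntrinsicProfile(cell_id=cell_id, group=group)
    if ramp_sweep is not None:
        prof.threshold = threshold_from_ramp(ramp_sweep, dvdt_criterion)
        if np.isnan(prof.threshold):
            prof.flags.append("no_ap_on_ramp")
    else:
        prof.flags.append("no_ramp")
    if step_sweeps:
        prof.input_resistance, prof.ir_r_squared = input_resistance(step_sweeps, dvdt_criterion)
        prof.rectification_index = rectification_index(step_sweeps, dvdt_criterion)
        prof.capacitance = capacitance(step_sweeps, prof.input_resistance, dvdt_criterion)
        prof.rheobase = rheobase_from_steps(step_sweeps, dvdt_criterion)
        prof.max_discharge_freq = highest_discharge_frequency(step_sweeps, dvdt_criterion)
        prof.fi_slope = fI_slope(step_sweeps, dvdt_criterion)
        # waveform from the first spiking (lowest suprathreshold) step
        spiking = [s for s in step_sweeps if detect_aps(s, dvdt_criterion).size > 0]
        if spiking:
            spiking.sort(key=lambda s: step_window(s)[2])
            feats = mean_ap_features(spiking[0], dvdt_criterion)
            if feats is not None:
                prof.ap_amplitude = feats.amplitude
                prof.ap_duration = feats.duration
                prof.ap_half_width = feats.half_width
                prof.ap_rise_time = feats.rise_time
                prof.ap_fall_time = feats.fall_time
                prof.ap_rise_rate = feats.rise_rate
                prof.ap_fall_rate = feats.fall_rate
                prof.fahp_amplitude = feats.fAHP_amplitude
                prof.fahp_time = feats.fAHP_time
                prof.ahp_time = feats.AHP_time
        else:
            prof.flags.append("no_suprathreshold_step")
    else:
        prof.flags.append("no_steps")
    if sag_sweep is not None:
        sm = sag_metrics(sag_sweep)
        prof.sag_amplitude = sm.sag_amplitude
        prof.sag_ratio = sm.sag_ratio
    else:
        prof.flags.append("no_sag_step")
    if zero_sweeps:
        prof.spont_rate, prof.is_firing = spontaneous_rate(zero_sweeps, dvdt_criterion)
    else:
        prof.flags.append("no_zero_current")
    return prof


def profiles_to_frame(profiles: list[IntrinsicProfile]) -> pd.DataFrame:
    """Stack profiles into a DataFrame with the documented column order."""
    return pd.DataFrame([p.to_row() for p in profiles], columns=PROFILE_COLUMNS)
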