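"""Single-compartment sweep simulation with sag and template action potentials.

The membrane equation is

    C_m dV/dt = -(V - E_L)/R_in - g_h * m * (V - E_h) + I_hold + I(t)

with first-order sag-current activation

    tau_h dm/dt = m_inf(V) - m,    m_inf(V) = 1 / (1 + exp((V + 80)/6))

(a decreasing sigmoid: half-activation -80 mV, slope 6 mV).  A holding
current pins the resting potential to E_L, mimicking the experimenter's
holding at ~-70 mV.  When V crosses the threshold V_T an action-potential
template (piecewise-linear rise/fall/fast-AHP) is pasted into the trace and
integration resumes from the fAHP trough; the template breakpoints are
quantized to the sample grid and the effective (pasted) parameters are
recorded as ground truth.

Integration is explicit Euler at the sample period; steps above 0.1 ms are
rejected (accuracy contract).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from gpephys.sweep import Sweep
from gpephys.synth.cells import ApShape, CellParams

MAX_DT_MS = 0.1


@dataclass
class StimulusProtocol:
    """One sweep's injected-current waveform (relative to holding)."""

    kind: str  # ramp | step | zero_current | sag_step | gap_step | ap_train
    sampling_rate: float = 20_000.0  # Hz
    pre_ms: float = 100.0  # baseline before stimulus onset
    post_ms: float = 100.0  # baseline after stimulus end
    amplitude_pA: float = 0.0  # step amplitude / ramp final amplitude / pulse amplitude
    duration_ms: float = 500.0  # step or ramp duration
    ramp_slope_pA_per_ms: float = 0.0
    n_pulses: int = 8
    pulse_width_ms: float = 30.0
    pulse_rate_hz: float = 20.0

    # --- constructors -----------------------------------------------------
    @classmethod
    def step(cls, amplitude_pA: float, duration_ms: float = 1000.0,
             sampling_rate: float = 20_000.0, pre_ms: float = 100.0,
             post_ms: float = 100.0) -> "StimulusProtocol":
        return cls("step", sampling_rate, pre_ms, post_ms,
                   amplitude_pA=amplitude_pA, duration_ms=duration_ms)

    @classmethod
    def ramp(cls, slope_pA_per_ms: float, duration_ms: float = 1000.0,
             sampling_rate: float = 20_000.0, pre_ms: float = 100.0,
             post_ms: float = 100.0) -> "StimulusProtocol":
        return cls("ramp", sampling_rate, pre_ms, post_ms,
                   duration_ms=duration_ms, ramp_slope_pA_per_ms=slope_pA_per_ms)

    @classmethod
    def zero_current(cls, duration_ms: float = 30_000.0,
                     sampling_rate: float = 10_000.0) -> "StimulusProtocol":
        return cls("zero_current", sampling_rate, 0.0, 0.0, duration_ms=duration_ms)

    @classmethod
    def sag_step(cls, amplitude_pA: float = -200.0, duration_ms: float = 500.0,
                 sampling_rate: float = 20_000.0) -> "StimulusProtocol":
        p = cls.step(amplitude_pA, duration_ms, sampling_rate, pre_ms=100.0, post_ms=200.0)
        p.kind = "sag_step"
        return p

    @classmethod
    def gap_step(cls, amplitude_pA: float = -150.0, duration_ms: float = 500.0,
                 sampling_rate: float = 20_000.0) -> "StimulusProtocol":
        p = cls.step(amplitude_pA, duration_ms, sampling_rate, pre_ms=100.0, post_ms=100.0)
        p.kind = "gap_step"
        return p

    @classmethod
    def ap_train(cls, amplitude_pA: float = 2000.0, pulse_width_ms: float = 30.0,
                 rate_hz: float = 20.0, n_pulses: int = 8,
                 sampling_rate: float = 20_000.0) -> "StimulusProtocol":
        p = cls("ap_train", sampling_rate, 100.0, 200.0, amplitude_pA=amplitude_pA)
        p.n_pulses = n_pulses
        p.pulse_width_ms = pulse_width_ms
        p.pulse_rate_hz = rate_hz
        return p

    # --- waveform ---------------------------------------------------------
    def build(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (time ms, current pA) arrays for this protocol."""
        dt = 1000.0 / self.sampling_rate
        if self.kind == "zero_current":
            total = self.duration_ms
        elif self.kind == "ap_train":
            train_span = (self.n_pulses - 1) * 1000.0 / self.pulse_rate_hz + self.pulse_width_ms
            total = self.pre_ms + train_span + self.post_ms
        else:
            total = self.pre_ms + self.duration_ms + self.post_ms
        n = int(round(total / dt))
        t = np.arange(n) * dt
        i = np.zeros(n)
        if self.kind in ("step", "sag_step", "gap_step"):
            on = int(round(self.pre_ms / dt))
            off = int(round((self.pre_ms + self.duration_ms) / dt))
            i[on:off] = self.amplitude_pA
        elif self.kind == "ramp":
            on = int(round(self.pre_ms / dt))
            off = int(round((self.pre_ms + self.duration_ms) / dt))
            i[on:off] = self.ramp_slope_pA_per_ms * (t[on:off] - t[on])
        elif self.kind == "ap_train":
            isi = 1000.0 / self.pulse_rate_hz
            for k in range(self.n_pulses):
                on = int(round((self.pre_ms + k * isi) / dt))
                off = int(round((self.pre_ms + k * isi + self.pulse_width_ms) / dt))
                i[on:off] = self.amplitude_pA
        elif self.kind != "zero_current":
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        return t, i


@dataclass
class GroundTruth:
    """What the generator actually put into a sweep."""

    cell_params: CellParams | None = None
    spike_times: list = field(default_factory=list)  # ms, AP peak times
    threshold: float = float("nan")  # mV, pasted template anchor
    ap_shape_effective: ApShape | None = None  # grid-quantized template
    ipsp_amplitudes: list = field(default_factory=list)  # mV per pulse
    pulse_times: list = field(default_factory=list)  # ms
    coupling_coefficient: float = 0.0
    connection_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.ipsp_amplitudes):
            raise ValueError("IPSP amplitudes must be non-negative")
        if not 0.0 <= self.coupling_coefficient < 1.0:
            raise ValueError("coupling coefficient must lie in [0, 1)")


@njit(cache=True)
def _euler_to_spike(V, m, I, start, dt, C, R, E_L, g_h, tau_h, E_h, V_T, I_hold, spiking):
    """Fill V/m from ``start``; return crossing index of V_T or -1."""
    n = V.size
    for k in range(start, n - 1):
        v = V[k]
        m_inf = 1.0 / (1.0 + np.exp((v + 80.0) / 6.0))
        m[k + 1] = m[k] + dt * (m_inf - m[k]) / tau_h
        i_total = (E_L - v) / R * 1000.0 - g_h * m[k] * (v - E_h) + I_hold + I[k]
        V[k + 1] = v + dt * i_total / C
        if spiking and V[k + 1] >= V_T:
            return k + 1
    return -1


def _m_inf(v: float) -> float:
    return 1.0 / (1.0 + np.exp((v + 80.0) / 6.0))


def _quantized_shape(shape: ApShape, dt: float) -> tuple[ApShape, int, int, int]:
    n_rise = max(1, int(round(shape.t_rise / dt)))
    n_fall = max(1, int(round(shape.t_fall / dt)))
    n_ahp = max(1, int(round(shape.t_fAHP / dt)))
    eff = ApShape(
        t_rise=n_rise * dt,
        t_fall=n_fall * dt,
        V_peak=shape.V_peak,
        fAHP_depth=shape.fAHP_depth,
        t_fAHP=n_ahp * dt,
    )
    return eff, n_rise, n_fall, n_ahp


def _paste_template(V: np.ndarray, k: int, V_T: float, eff: ApShape,
                    n_rise: int, n_fall: int, n_ahp: int) -> int:
    """Paste a template anchored at index k (voltage V_T); return resume index."""
    n = V.size
    peak = min(k + n_rise, n - 1)
    V[k:peak + 1] = np.linspace(V_T, eff.V_peak, peak - k + 1)
    fall_end = min(peak + n_fall, n - 1)
    V[peak:fall_end + 1] = np.linspace(eff.V_peak, V_T, fall_end - peak + 1)
    ahp_end = min(fall_end + n_ahp, n - 1)
    V[fall_end:ahp_end + 1] = np.linspace(V_T, V_T - eff.fAHP_depth, ahp_end - fall_end + 1)
    return ahp_end


def simulate_sweep(params: CellParams, stimulus: StimulusProtocol,
                   noise_sd: float = 0.0, rng_seed=0) -> tuple[Sweep, GroundTruth]:
    """Simulate one current-clamp sweep for a synthetic cell.

    Returns the sweep plus the ground truth actually realised (spike peak
    times, pasted threshold and effective template shape).  ``noise_sd`` is
    the SD of white Gaussian voltage noise in mV.  Zero-current protocols
    realise spontaneous firing as a jittered periodic spike train (5% CV)
    pasted on a flat baseline at E_L rather than integrating a pacemaker
    current.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    dt = 1000.0 / stimulus.sampling_rate
    if dt > MAX_DT_MS:
        raise ValueError(
            f"sample period {dt:g} ms exceeds the {MAX_DT_MS} ms integration "
            "accuracy contract; use a sampling rate >= 10 kHz"
        )
    t, current = stimulus.build()
    n = t.size
    eff, n_rise, n_fall, n_ahp = _quantized_shape(params.ap_shape, dt)
    gt = GroundTruth(cell_params=params, threshold=params.V_T, ap_shape_effective=eff)

    if stimulus.kind == "zero_current":
        V = np.full(n, params.E_L)
        if params.spont_rate > 0:
            isi = 1000.0 / params.spont_rate
            times = []
            tt = float(rng.uniform(0, isi))
            while tt < t[-1]:
                times.append(tt)
                tt += isi * max(0.05, 1.0 + 0.05 * rng.standard_normal())
            starts = [int(round(x / dt)) for x in times]
            for si, k in enumerate(starts):
                if k >= n - 2:
                    break
                end = _paste_template(V, k, params.V_T, eff, n_rise, n_fall, n_ahp)
                gt.spike_times.append(t[min(k + n_rise, n - 1)])
                # relax back toward rest until the next spike
                seg_end = starts[si + 1] if si + 1 < len(starts) else n
                seg_end = min(seg_end, n)
                if end < seg_end:
                    tseg = (np.arange(end, seg_end) - end) * dt
                    V[end:seg_end] = params.E_L + (V[end] - params.E_L) * np.exp(-tseg / params.tau_m)
    else:
        V = np.full(n, params.E_L)
        m = np.full(n, _m_inf(params.E_L))
        I_hold = params.g_h * _m_inf(params.E_L) * (params.E_L - params.E_h)
        start = 0
        while True:
            k = _euler_to_spike(V, m, current, start, dt, params.C_m, params.R_in,
                                params.E_L, params.g_h, params.tau_h, params.E_h,
                                params.V_T, I_hold, True)
            if k < 0:
                break
            V[k] = params.V_T
            end = _paste_template(V, k, params.V_T, eff, n_rise, n_fall, n_ahp)
            gt.spike_times.append(t[min(k + n_rise, n - 1)])
            m[k:end + 1] = m[k]  # sag gating held during the pasted AP
            if end >= n - 2:
                break
            start = end

    if noise_sd > 0:
        V = V + rng.normal(0.0, noise_sd, size=n)

    sweep = Sweep(time=t, voltage=V, current=current,
                  sampling_rate=stimulus.sampling_rate,
                  holding_mV=params.E_L, protocol_id=stimulus.kind,
                  group=params.group)
    return sweep, gt


# ---------------------------------------------------------------------------
# IPSP trains with short-term depression
# ---------------------------------------------------------------------------

@dataclass
class IpspKernel:
    """Shape of a single IPSP: rise-saturating double-exponential decay."""

    A1: float = 2.0  # mV, first-pulse amplitude
    tau_rise: float = 1.5  # ms
    tau1: float = 15.0  # ms, fast decay
    tau2: float = 80.0  # ms, slow decay
    w2: float = 0.3  # weight of the slow component

    def __post_init__(self) -> None:
        if min(self.tau_rise, self.tau1, self.tau2) <= 0:
            raise ValueError("all time constants must be positive")


@dataclass
class Depression:
    """Depleting-resource short-term depression parameters."""

    U: float = 0.5  # release fraction per pulse
    tau_rec: float = 200.0  # ms recovery

    def __post_init__(self) -> None:
        if not 0.0 < self.U <= 1.0:
            raise ValueError("U must lie in (0, 1]")
        if self.tau_rec < 0:
            raise ValueError("tau_rec must be non-negative")


def ipsp_amplitude_recursion(A1: float, U: float, tau_rec: float,
                             n_pulses: int, rate_hz: float) -> np.ndarray:
    """Per-pulse amplitudes of a depressing train.

    R_1 = 1;  a_n = A1 * U * R_n;
    R_{n+1} = 1 - (1 - R_n * (1 - U)) * exp(-dt / tau_rec).
    """
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    dt = 1000.0 / rate_hz
    decay = 0.0 if tau_rec == 0 else np.exp(-dt / tau_rec)
    # tau_rec == 0 means instant recovery: R stays 1
    a = np.empty(n_pulses)
    R = 1.0
    for i in range(n_pulses):
        a[i] = A1 * U * R
        R = 1.0 - (1.0 - R * (1.0 - U)) * (decay if tau_rec > 0 else 0.0)
        if tau_rec == 0:
            R = 1.0
    return a


def _event_shape(t: np.ndarray, kernel: IpspKernel) -> np.ndarray:
    """Unit-peak IPSP shape evaluated at times t (ms, 0 at event onset)."""
    shape = np.where(
        t >= 0,
        (1.0 - np.exp(-np.clip(t, 0, None) / kernel.tau_rise))
        * ((1.0 - kernel.w2) * np.exp(-np.clip(t, 0, None) / kernel.tau1)
           + kernel.w2 * np.exp(-np.clip(t, 0, None) / kernel.tau2)),
        0.0,
    )
    # normalise to unit peak so amplitudes are true peak amplitudes
    tp = np.linspace(0, 10 * kernel.tau_rise + 3 * kernel.tau1, 4000)
    peak = np.max(
        (1.0 - np.exp(-tp / kernel.tau_rise))
        * ((1.0 - kernel.w2) * np.exp(-tp / kernel.tau1) + kernel.w2 * np.exp(-tp / kernel.tau2))
    )
    return shape / peak


def simulate_ipsp_train(kernel: IpspKernel, depression: Depression,
                        n_pulses: int = 8, rate: float = 20.0,
                        noise_sd: float = 0.0, rng_seed=0,
                        sampling_rate: float = 20_000.0,
                        pre_ms: float = 100.0, post_ms: float = 300.0,
                        holding_mV: float = -70.0,
                        pulse_times: np.ndarray | None = None,
                        ) -> tuple[Sweep, GroundTruth]:
    """Simulate the averaged follower response to a 20 Hz presynaptic train.

    Events superpose linearly on a flat baseline; per-pulse peak amplitudes
    follow the depleting-resource recursion.  IPSPs are depolarizing (the
    high-chloride internal makes GABAergic events positive-going at -70 mV).
    ``pulse_times`` overrides the regular train (e.g. driver AP times).
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    dt = 1000.0 / sampling_rate
    if pulse_times is None:
        pulse_times = pre_ms + np.arange(n_pulses) * 1000.0 / rate
    else:
        pulse_times = np.asarray(pulse_times, dtype=float)
        n_pulses = pulse_times.size
    amps = ipsp_amplitude_recursion(kernel.A1, depression.U, depression.tau_rec,
                                    n_pulses, rate)
    total = pulse_times[-1] + post_ms
    n = int(round(total / dt))
    t = np.arange(n) * dt
    V = np.full(n, holding_mV)
    for a, tp in zip(amps, pulse_times):
        V += a * _event_shape(t - tp, kernel)
    if noise_sd > 0:
        V = V + rng.normal(0.0, noise_sd, size=n)
    sweep = Sweep(time=t, voltage=V, current=np.zeros(n),
                  sampling_rate=sampling_rate, holding_mV=holding_mV,
                  protocol_id="ipsp_train")
    gt = GroundTruth(ipsp_amplitudes=list(amps), pulse_times=list(pulse_times))
    return sweep, gt


# ---------------------------------------------------------------------------
# Electrically coupled pair (gap-junction test sweeps)
# ---------------------------------------------------------------------------

def coupling_conductance_for(coefficient: float, follower: CellParams) -> float:
    """Gap conductance (nS) giving a steady-state coupling coefficient."""
    if not 0.0 <= coefficient < 1.0:
        raise ValueError("coefficient must lie in [0, 1)")
    G2 = 1000.0 / follower.R_in  # nS
    return coefficient * G2 / (1.0 - coefficient)


def simulate_gap_pair(driver: CellParams, follower: CellParams,
                      coupling_coefficient: float = 0.0,
                      stimulus: StimulusProtocol | None = None,
                      noise_sd: float = 0.0, rng_seed=0,
                      ) -> tuple[Sweep, Sweep, GroundTruth]:
    """Simulate simultaneous driver/follower sweeps of a gap-junction test.

    Two passive compartments coupled by a resistive conductance chosen to
    realise the requested steady-state coupling coefficient; the driver
    receives a -150 pA / 500 ms step by default.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    if stimulus is None:
        stimulus = StimulusProtocol.gap_step()
    dt = 1000.0 / stimulus.sampling_rate
    if dt > MAX_DT_MS:
        raise ValueError("sample period exceeds the 0.1 ms integration contract")
    t, current = stimulus.build()
    n = t.size
    gc = coupling_conductance_for(coupling_coefficient, follower)
    V1 = np.full(n, driver.E_L)
    V2 = np.full(n, follower.E_L)
    for k in range(n - 1):
        i1 = (driver.E_L - V1[k]) / driver.R_in * 1000.0 + gc * (V2[k] - V1[k]) + current[k]
        i2 = (follower.E_L - V2[k]) / follower.R_in * 1000.0 + gc * (V1[k] - V2[k])
        V1[k + 1] = V1[k] + dt * i1 / driver.C_m
        V2[k + 1] = V2[k] + dt * i2 / follower.C_m
    if noise_sd > 0:
        V1 = V1 + rng.normal(0.0, noise_sd, n)
        V2 = V2 + rng.normal(0.0, noise_sd, n)
    d_sweep = Sweep(t, V1, current, stimulus.sampling_rate, driver.E_L,
                    "gap_step", group=driver.group)
    f_sweep = Sweep(t, V2, np.zeros(n), stimulus.sampling_rate, follower.E_L,
                    "gap_follower", group=follower.group)
    gt = GroundTruth(coupling_coefficient=coupling_coefficient)
    return d_sweep, f_sweep, gt
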