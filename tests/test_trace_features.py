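"""Feature extraction: definitional identities and generator recovery."""

import numpy as np
import pytest

import gpephys.traces as T
from gpephys.sweep import Sweep
from gpephys.synth.cells import CellParams
from gpephys.synth.sweeps import StimulusProtocol, simulate_sweep


def _flat_sweep(v=-70.0, ms=200.0, rate=20_000.0):
    n = int(ms * rate / 1000.0)
    t = np.arange(n) / rate * 1000.0
    return Sweep(t, np.full(n, v), np.zeros(n), rate)


def _step_family(params, amps, noise=0.0, seed=0, dur=1000.0):
    return [simulate_sweep(params, StimulusProtocol.step(a, dur), noise, seed + i)[0]
            for i, a in enumerate(amps)]


# ---------------------------------------------------------------------------
# AP detection
# ---------------------------------------------------------------------------

def test_flat_trace_has_no_aps():
    assert T.detect_aps(_flat_sweep()).size == 0


def test_detects_every_pasted_ap_at_ground_truth_time(ohmic_params):
    sweep, gt = simulate_sweep(ohmic_params, StimulusProtocol.step(500.0, 600.0), 0.0, 1)
    peaks = T.detect_aps(sweep)
    assert peaks.size == len(gt.spike_times) >= 12
    detected_t = sweep.time[peaks]
    assert np.allclose(detected_t, gt.spike_times, atol=0.2)


def test_refractory_merge_of_close_peaks():
    """Two voltage maxima 1 ms apart merge into a single detection."""
    rate = 20_000.0
    n = int(0.05 * rate)
    t = np.arange(n) / rate * 1000.0
    v = np.full(n, -70.0)

    def bump(t0):
        k = int(t0 / 1000 * rate)
        w = int(0.0005 * rate)
        v[k - w:k + w] += 90.0 * np.hanning(2 * w)

    bump(20.0)
    bump(21.0)
    sweep = Sweep(t, v, np.zeros(n), rate)
    assert T.detect_aps(sweep).size == 1


def test_noise_does_not_create_false_aps(arky_params):
    arky_params.spont_rate = 0.0
    sweep, _ = simulate_sweep(arky_params, StimulusProtocol.zero_current(10_000.0), 0.5, 7)
    assert T.detect_aps(sweep).size == 0


# ---------------------------------------------------------------------------
# Ramp threshold
# ---------------------------------------------------------------------------

def test_ramp_threshold_recovers_ground_truth(arky_params):
    ramp = StimulusProtocol.ramp(2 * arky_params.rheobase / 1000.0, 1000.0)
    sweep, _ = simulate_sweep(arky_params, ramp, 0.0, 0)
    thr = T.threshold_from_ramp(sweep)
    assert thr == pytest.approx(arky_params.V_T, abs=0.5)


def test_subthreshold_ramp_gives_missing_value(ohmic_params):
    ramp = StimulusProtocol.ramp(0.5 * ohmic_params.rheobase / 1000.0, 1000.0)
    sweep, _ = simulate_sweep(ohmic_params, ramp, 0.0, 0)
    assert np.isnan(T.threshold_from_ramp(sweep))


def test_threshold_monotone_in_criterion(arky_params):
    """Doubling the dV/dt criterion cannot lower the reported threshold."""
    ramp = StimulusProtocol.ramp(2 * arky_params.rheobase / 1000.0, 1000.0)
    sweep, _ = simulate_sweep(arky_params, ramp, 0.2, 5)
    assert T.threshold_from_ramp(sweep, 20.0) >= T.threshold_from_ramp(sweep, 10.0) - 1e-9


# ---------------------------------------------------------------------------
# Rheobase / input resistance / rectification / capacitance
# ---------------------------------------------------------------------------

def test_rheobase_definition(ohmic_params):
    sweeps = _step_family(ohmic_params, [80, 100, 120, 140], dur=500.0)
    # analytic rheobase 300 pA; nothing spikes yet
    assert np.isnan(T.rheobase_from_steps(sweeps))
    sweeps = _step_family(ohmic_params, list(range(260, 381, 20)), dur=1000.0)
    rb = T.rheobase_from_steps(sweeps)
    assert abs(rb - ohmic_params.rheobase) <= 20.0  # within one increment


def test_input_resistance_exact_on_ohmic_cell(ohmic_params):
    sweeps = _step_family(ohmic_params, [-100, -50, -25, 25, 50])
    R, r2 = T.input_resistance(sweeps)
    assert R == pytest.approx(100.0, rel=1e-3)
    assert r2 == pytest.approx(1.0, abs=1e-6)


def test_input_resistance_noisy_recovery(ohmic_params):
    sweeps = _step_family(ohmic_params, [-150, -100, -50, -25, 25, 50, 75],
                          noise=0.5, seed=3)
    R, _ = T.input_resistance(sweeps)
    assert R == pytest.approx(100.0, rel=0.05)


def test_spiking_sweeps_excluded_from_ir_fit(ohmic_params):
    sub = _step_family(ohmic_params, [-100, -50, -25, 25, 50])
    supra = _step_family(ohmic_params, [400.0])
    assert T.input_resistance(sub + supra) == T.input_resistance(sub)


def test_input_resistance_missing_below_three_sweeps(ohmic_params):
    sweeps = _step_family(ohmic_params, [-100, -50])
    R, r2 = T.input_resistance(sweeps)
    assert np.isnan(R) and np.isnan(r2)


def test_rectification_ohmic_is_one_and_order_invariant(ohmic_params):
    sweeps = _step_family(ohmic_params, [-200, -150, -100, -50, 25, 50])
    ri = T.rectification_index(sweeps)
    assert ri == pytest.approx(1.0, abs=1e-3)
    assert T.rectification_index(sweeps[::-1]) == pytest.approx(ri, abs=1e-12)


def test_rectification_below_one_with_sag(arky_params):
    amps = np.array([-200, -150, -100, -50, 25, 50]) * 1.0
    sweeps = _step_family(arky_params, amps)
    assert T.rectification_index(sweeps) < 1.0


def test_capacitance_rc_recovery(ohmic_params):
    sweeps = _step_family(ohmic_params, [-100, -50, -25, 25, 50])
    C = T.capacitance(sweeps)
    assert C == pytest.approx(100.0, abs=2.0)


def test_capacitance_tau_over_r_arithmetic():
    # R = 100 MOhm, tau = 10 ms  ->  C = 100 pF
    p = CellParams(group="prototypic_PV", R_in=100.0, C_m=100.0, E_L=-70.0,
                   V_T=-40.0, g_h=0.0, tau_h=50.0, E_h=-30.0)
    assert p.tau_m == pytest.approx(10.0)
    sweeps = _step_family(p, [-50, -25, -10, 10, 25])
    assert T.capacitance(sweeps, R_in=100.0) == pytest.approx(100.0, abs=2.0)


def test_capacitance_positive_under_heavy_sag(arky_params):
    heavy = CellParams(**{**arky_params.__dict__, "g_h": 6.0})
    sweeps = _step_family(heavy, [-40, -20, -10, 10, 20])
    C = T.capacitance(sweeps)
    assert np.isnan(C) or C > 0  # documented bias; only positivity asserted


# ---------------------------------------------------------------------------
# AP waveform
# ---------------------------------------------------------------------------

def test_triangle_ap_geometry():
    """Piecewise-linear AP: threshold -40, peak +20, 1 ms rise, 2 ms fall."""
    rate = 20_000.0
    dt = 1000.0 / rate
    pieces = [np.full(int(5 / dt), -70.0)]
    pieces.append(np.linspace(-70, -40, int(3 / dt), endpoint=False))
    pieces.append(np.linspace(-40, 20, int(1 / dt), endpoint=False))
    pieces.append(np.linspace(20, -40, int(2 / dt), endpoint=False))
    pieces.append(np.linspace(-40, -50, int(1 / dt), endpoint=False))
    pieces.append(np.full(int(20 / dt), -50.0))
    v = np.concatenate(pieces)
    t = np.arange(v.size) * dt
    sweep = Sweep(t, v, np.zeros(v.size), rate)
    peak = int(np.argmax(v))
    f = T.ap_waveform(sweep, peak, threshold=-40.0)
    assert f.amplitude == pytest.approx(60.0, abs=0.1)
    assert f.rise_time == pytest.approx(1.0, abs=dt)
    assert f.fall_time == pytest.approx(2.0, abs=dt)
    assert f.duration == pytest.approx(3.0, abs=2 * dt)
    assert f.half_width == pytest.approx(2.0, abs=2 * dt)
    assert f.rise_rate == pytest.approx(60.0, rel=0.01)
    assert f.fall_rate == pytest.approx(30.0, rel=0.01)
    assert f.fAHP_amplitude == pytest.approx(10.0, abs=0.1)


@pytest.mark.parametrize("group_seed", [("arkypallidal", 3), ("prototypic_PV", 4),
                                        ("prototypic_Nkx", 5)])
def test_waveform_recovers_template_parameters(group_seed):
    """Every waveform field within 3% (or one sample) of the pasted template."""
    from gpephys.synth.cells import sample_cell
    group, seed = group_seed
    cell = sample_cell(group, seed)
    sweep, gt = simulate_sweep(cell, StimulusProtocol.step(cell.rheobase * 1.3, 800.0), 0.0, 0)
    eff = gt.ap_shape_effective
    peaks = T.detect_aps(sweep)
    f = T.ap_waveform(sweep, int(peaks[0]),
                      next_spike_idx=int(peaks[1]) if peaks.size > 1 else None)
    tol = max(0.03, sweep.dt / eff.t_rise)
    assert f.threshold == pytest.approx(cell.V_T, abs=0.5)
    assert f.amplitude == pytest.approx(eff.V_peak - cell.V_T, rel=0.03)
    assert f.rise_time == pytest.approx(eff.t_rise, rel=tol)
    assert f.fall_time == pytest.approx(eff.t_fall, rel=0.03)
    assert f.half_width == pytest.approx(eff.t_rise + eff.t_fall / 2.0, rel=0.03)
    assert f.fAHP_amplitude == pytest.approx(eff.fAHP_depth, rel=0.03)
    assert f.fAHP_time == pytest.approx(eff.t_fAHP, rel=0.03, abs=sweep.dt)


def test_waveform_definitional_identities(arky_params):
    sweep, _ = simulate_sweep(arky_params, StimulusProtocol.step(
        arky_params.rheobase * 1.5, 800.0), 0.2, 2)
    peaks = T.detect_aps(sweep)
    for i, p in enumerate(peaks[:5]):
        nxt = int(peaks[i + 1]) if i + 1 < peaks.size else None
        f = T.ap_waveform(sweep, int(p), next_spike_idx=nxt)
        assert f.duration == pytest.approx(f.rise_time + f.fall_time, abs=1e-9)
        assert f.rise_rate * f.rise_time == pytest.approx(f.amplitude, rel=1e-9)
        assert f.fall_rate * f.fall_time == pytest.approx(f.amplitude, rel=1e-9)
        assert f.half_width <= f.duration + 1e-9


def test_truncated_ap_flagged():
    """A decay that never re-crosses threshold marks the features truncated."""
    rate = 20_000.0
    n = int(0.02 * rate)
    t = np.arange(n) / rate * 1000.0
    v = np.full(n, -70.0)
    k = n // 2
    v[k:] = 10.0  # rises and stays up
    v[k - 4:k] = np.linspace(-70, 10, 4)
    sweep = Sweep(t, v, np.zeros(n), rate)
    f = T.ap_waveform(sweep, k, threshold=-40.0)
    assert f.truncated
    assert np.isnan(f.fall_time)


# ---------------------------------------------------------------------------
# Sag
# ---------------------------------------------------------------------------

def test_sag_formula_arithmetic():
    """V_min = -110, V_steady = -95 -> amplitude 15 mV, ratio 110/95."""
    rate = 20_000.0
    dt = 1000.0 / rate
    pre = int(100 / dt)
    step = int(500 / dt)
    post = int(100 / dt)
    v = np.concatenate([
        np.full(pre, -70.0),
        np.linspace(-70, -110, int(30 / dt)),
        np.linspace(-110, -95, int(70 / dt)),
        np.full(step - int(100 / dt), -95.0),
        np.full(post, -70.0),
    ])
    i = np.concatenate([np.zeros(pre), np.full(step, -200.0), np.zeros(post)])
    t = np.arange(v.size) * dt
    sm = T.sag_metrics(Sweep(t, v, i, rate))
    assert sm.sag_amplitude == pytest.approx(15.0, abs=0.1)
    assert sm.sag_ratio == pytest.approx(110.0 / 95.0, abs=1e-3)


def test_no_sag_conductance_gives_unity_ratio(ohmic_params):
    sweep, _ = simulate_sweep(ohmic_params, StimulusProtocol.sag_step(), 0.0, 0)
    sm = T.sag_metrics(sweep)
    assert sm.sag_amplitude == pytest.approx(0.0, abs=0.05)
    assert sm.sag_ratio == pytest.approx(1.0, abs=1e-3)


def test_sag_ratio_monotone_in_gh(arky_params):
    ratios = []
    for g_h in (0.0, 0.5, 1.0, 2.0, 4.0):
        p = CellParams(**{**arky_params.__dict__, "g_h": g_h})
        sweep, _ = simulate_sweep(p, StimulusProtocol.sag_step(), 0.0, 0)
        ratios.append(T.sag_metrics(sweep).sag_ratio)
    assert all(b > a for a, b in zip(ratios, ratios[1:]))
    assert ratios[0] == pytest.approx(1.0, abs=1e-3)


# ---------------------------------------------------------------------------
# Spontaneous rate / discharge / phase plot
# ---------------------------------------------------------------------------

def test_spontaneous_rate_count_over_time():
    """45 APs over 3 x 30 s -> 0.5 Hz."""
    rate = 10_000.0
    sweeps = []
    rng = np.random.default_rng(0)
    for k in range(3):
        n = int(30_000.0 * rate / 1000.0)
        t = np.arange(n) / rate * 1000.0
        v = np.full(n, -60.0)
        for ts in rng.uniform(500, 29_500, 15):
            j = int(ts / 1000 * rate)
            w = int(0.001 * rate)
            v[j - w:j + w] += 80.0 * np.hanning(2 * w)
        sweeps.append(Sweep(t, v, np.zeros(n), rate))
    r, firing = T.spontaneous_rate(sweeps)
    assert r == pytest.approx(0.5, abs=1e-6)
    assert firing


def test_silent_cell_rate_zero():
    r, firing = T.spontaneous_rate([_flat_sweep(ms=5000.0)])
    assert r == 0.0 and not firing


def test_generator_spont_rate_recovered(arky_params):
    arky_params.spont_rate = 15.0
    sweeps = [simulate_sweep(arky_params, StimulusProtocol.zero_current(30_000.0),
                             0.3, s)[0] for s in range(3)]
    r, _ = T.spontaneous_rate(sweeps)
    assert r == pytest.approx(15.0, rel=0.05)


def test_discharge_frequency_and_fi_slope(ohmic_params):
    sweeps = _step_family(ohmic_params, [-50, 200, 320, 400, 500], dur=500.0)
    df = T.discharge_frequencies(sweeps)
    top = T.highest_discharge_frequency(sweeps)
    assert top == df.frequency_Hz.iloc[-1] > 0
    slope = T.fI_slope(sweeps)
    assert slope > 0


def test_fi_slope_exact_three_points():
    """Frequencies {5, 10, 15} Hz at {150, 200, 250} pA -> 0.1 Hz/pA."""
    rate = 20_000.0
    dt = 1000.0 / rate
    sweeps = []
    for amp, freq in [(100.0, 0), (150.0, 5), (200.0, 10), (250.0, 15)]:
        n = int(1200 / dt)
        t = np.arange(n) * dt
        v = np.full(n, -70.0)
        i = np.zeros(n)
        on, off = int(100 / dt), int(1100 / dt)
        i[on:off] = amp
        for k in range(freq):  # freq APs inside the 1 s step
            j = on + int((k + 0.5) / max(freq, 1) * (off - on))
            w = int(0.0005 * rate)
            v[j - w:j + w] += 90.0 * np.hanning(2 * w)
        sweeps.append(Sweep(t, v, i, rate))
    assert T.fI_slope(sweeps) == pytest.approx(0.1, rel=1e-6)
    assert T.highest_discharge_frequency(sweeps) == pytest.approx(15.0)


def test_highest_frequency_nondecreasing_in_top_step(ohmic_params):
    tops = []
    for top_amp in (400.0, 500.0, 600.0):
        sweeps = _step_family(ohmic_params, [350.0, top_amp], dur=500.0)
        tops.append(T.highest_discharge_frequency(sweeps))
    assert tops == sorted(tops)


def test_phase_plot_constant_slope_and_length():
    rate = 20_000.0
    n = 1000
    t = np.arange(n) / rate * 1000.0
    v = -70.0 + 3.0 * t  # 3 mV/ms ramp
    sweep = Sweep(t, v, np.zeros(n), rate)
    vv, dvdt = T.phase_plot(sweep)
    assert vv.size == dvdt.size == n
    assert np.allclose(dvdt, 3.0, atol=1e-6)


def test_phase_plot_loop_area_positive(ohmic_params):
    sweep, _ = simulate_sweep(ohmic_params, StimulusProtocol.step(400.0, 300.0), 0.0, 0)
    v, dvdt = T.phase_plot(sweep)
    area = -float(np.trapezoid(dvdt, v))  # signed loop area
    assert abs(area) > 0


# ---------------------------------------------------------------------------
# Profile assembly / missing-value policy
# ---------------------------------------------------------------------------

def test_profile_missing_values_flagged_not_imputed(ohmic_params):
    prof = T.extract_profile("c1", "prototypic_PV", ramp_sweep=None,
                             step_sweeps=_step_family(ohmic_params, [-100, -50, 25]),
                             sag_sweep=None, zero_sweeps=None)
    assert np.isnan(prof.threshold)
    assert "no_ramp" in prof.flags
    assert "no_sag_step" in prof.flags
    assert np.isnan(prof.sag_ratio)
    row = prof.to_row()
    assert set(row) == set(T.PROFILE_COLUMNS)
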