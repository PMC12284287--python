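"""Whole-cohort generation: cells, sweep sets, pair tests and morphologies.

Emulates the study design: three labelled populations recorded with a
common protocol battery (ramp, step family, -200 pA sag step, zero-current
sweeps), reconstructed as SWC trees, and tested pairwise for chemical and
electrical connectivity within multi-patch sessions of nearby somata.
Default connection probabilities are 1.15% for prototypic-prototypic pairs
and 0 elsewhere; electrical coupling is absent unless overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gpephys.sweep import Sweep
from gpephys.morphology import Morphology
from gpephys.synth.cells import GROUP_MARKERS, CellParams, sample_cell
from gpephys.synth.morph import generate_swc
from gpephys.synth.sweeps import (
    Depression,
    GroundTruth,
    IpspKernel,
    StimulusProtocol,
    simulate_gap_pair,
    simulate_ipsp_train,
    simulate_sweep,
)

PROTOTYPIC_GROUPS = ("prototypic_PV", "prototypic_Nkx")
DISTANCE_RANGE_UM = (20.0, 186.0)  # somatic-distance envelope of tested pairs
SYNAPTIC_DELAY_MS = 1.0
N_AVERAGED_SWEEPS = 20  # pair-test repetitions entering the average
FIRST_IPSP_RANGE_MV = (1.2, 3.7)  # reported first-pulse amplitude range


@dataclass
class ConnectionProbabilities:
    proto_proto: float = 0.0115
    other: float = 0.0


@dataclass
class CellSweeps:
    """The per-cell protocol battery."""

    ramp: Sweep | None = None
    steps: list = field(default_factory=list)
    sag: Sweep | None = None
    zero: list = field(default_factory=list)
    ground_truth: GroundTruth | None = None


@dataclass
class PairSim:
    """One simulated directed pair test with its ground truth."""

    driver_id: str
    follower_id: str
    driver_group: str  # marker label
    follower_group: str
    distance_um: float
    slice_orientation: str
    driver_spike_times: np.ndarray  # ms
    follower_avg: Sweep
    gap_driver: Sweep
    gap_follower: Sweep
    connected: bool
    ipsp_amplitudes: np.ndarray  # ground truth, empty when unconnected
    coupling_coefficient: float = 0.0


@dataclass
class Cohort:
    cells: list
    cell_ids: list
    groups: list
    sweeps: dict  # cell_id -> CellSweeps
    morphologies: list
    pairs: list  # PairSim
    seed: int | None = None

    @property
    def connection_map(self) -> dict:
        return {
            (p.driver_id, p.follower_id): {
                "chemical": p.connected,
                "amplitude_mV": float(p.ipsp_amplitudes[0]) if p.connected else 0.0,
                "electrical": p.coupling_coefficient,
            }
            for p in self.pairs
        }


def sample_connection_map(pair_groups, p_connect: ConnectionProbabilities,
                          rng_seed=0) -> np.ndarray:
    """Bernoulli connection draws for a list of (driver, follower) groups."""
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    out = np.zeros(len(pair_groups), dtype=bool)
    for i, (ga, gb) in enumerate(pair_groups):
        p = (p_connect.proto_proto
             if ga in PROTOTYPIC_GROUPS and gb in PROTOTYPIC_GROUPS
             else p_connect.other)
        out[i] = rng.random() < p
    return out


def step_amplitudes_for(params: CellParams, n_steps: int = 8) -> np.ndarray:
    """Step family scaled to the cell's input resistance (rheobase multiples)."""
    base = params.rheobase
    mult = np.array([-1.2, -0.8, -0.4, -0.2, 1.1, 1.4, 1.7, 2.0])
    if n_steps != 8:
        neg = np.linspace(-1.2, -0.2, max(2, n_steps // 2))
        pos = np.linspace(1.1, 2.0, n_steps - neg.size)
        mult = np.concatenate([neg, pos])
    return np.round(mult * base, 1)


def simulate_cell_sweeps(params: CellParams, rng,
                         sampling_rate: float = 20_000.0,
                         noise_sd: float = 0.3,
                         n_steps: int = 8,
                         step_duration_ms: float = 1000.0,
                         ramp_duration_ms: float = 1000.0,
                         n_zero_sweeps: int = 3,
                         zero_duration_ms: float = 30_000.0,
                         include_zero: bool = True,
                         include_sag: bool = True) -> CellSweeps:
    """Simulate one cell's full protocol battery.

    The ramp reaches twice the analytic rheobase at its end; steps are
    rheobase multiples (four subthreshold hyperpolarizing, four
    suprathreshold).  Zero-current sweeps default to the 3 x 30 s
    spontaneous-rate protocol at 10 kHz.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = CellSweeps()
    slope = 2.0 * params.rheobase / ramp_duration_ms
    ramp = StimulusProtocol.ramp(slope, ramp_duration_ms, sampling_rate)
    out.ramp, gt = simulate_sweep(params, ramp, noise_sd, rng)
    out.ground_truth = gt
    for amp in step_amplitudes_for(params, n_steps):
        proto = StimulusProtocol.step(float(amp), step_duration_ms, sampling_rate)
        sweep, _ = simulate_sweep(params, proto, noise_sd, rng)
        out.steps.append(sweep)
    if include_sag:
        out.sag, _ = simulate_sweep(params, StimulusProtocol.sag_step(
            sampling_rate=sampling_rate), noise_sd, rng)
    if include_zero:
        for _ in range(n_zero_sweeps):
            z, zgt = simulate_sweep(
                params, StimulusProtocol.zero_current(zero_duration_ms), noise_sd, rng)
            out.zero.append(z)
    return out


def _sessions(indices: list[int], rng: np.random.Generator,
              max_size: int = 4) -> list[list[int]]:
    """Partition recorded cells into multi-patch sessions of 2-4 cells."""
    order = list(indices)
    rng.shuffle(order)
    sessions, i = [], 0
    while i < len(order):
        size = min(int(rng.integers(2, max_size + 1)), len(order) - i)
        if size >= 2:
            sessions.append(order[i:i + size])
        i += size
    return sessions


def simulate_pair(driver: CellParams, follower: CellParams, connected: bool,
                  rng, coupling_coefficient: float = 0.0,
                  noise_sd: float = 0.3,
                  sampling_rate: float = 20_000.0) -> tuple:
    """Simulate the follower average trace and gap sweeps of one pair test.

    The follower average carries noise attenuated by sqrt(20) (20-sweep
    averaging).  Returns (spike_times, follower_avg, gap_driver,
    gap_follower, ipsp_amplitudes, kernel).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    avg_noise = noise_sd / np.sqrt(N_AVERAGED_SWEEPS)
    spikes = 100.0 + np.arange(8) * 50.0  # driver AP peaks: 8 at 20 Hz
    if connected:
        U = float(rng.uniform(0.4, 0.6))
        first = float(rng.uniform(*FIRST_IPSP_RANGE_MV))
        kernel = IpspKernel(
            A1=first / U,
            tau_rise=float(rng.uniform(1.0, 2.0)),
            tau1=float(rng.uniform(10.0, 20.0)),
            tau2=float(rng.uniform(60.0, 120.0)),
            w2=float(rng.uniform(0.2, 0.4)),
        )
        depr = Depression(U=U, tau_rec=float(rng.uniform(150.0, 300.0)))
    else:
        kernel = IpspKernel(A1=0.0)
        depr = Depression()
    follower_avg, gt = simulate_ipsp_train(
        kernel, depr, noise_sd=avg_noise, rng_seed=rng,
        sampling_rate=sampling_rate,
        pulse_times=spikes + SYNAPTIC_DELAY_MS)
    gap_d, gap_f, _ = simulate_gap_pair(
        driver, follower, coupling_coefficient,
        noise_sd=avg_noise, rng_seed=rng,
        stimulus=StimulusProtocol.gap_step(sampling_rate=sampling_rate))
    amps = np.asarray(gt.ipsp_amplitudes) if connected else np.zeros(0)
    return spikes, follower_avg, gap_d, gap_f, amps, kernel


def generate_cohort(n_per_group: dict[str, int],
                    p_connect: ConnectionProbabilities | None = None,
                    rng_seed: int = 0,
                    sampling_rate: float = 20_000.0,
                    noise_sd: float = 0.3,
                    include_sweeps: bool = True,
                    include_zero: bool = False,
                    include_morphology: bool = True,
                    include_pairs: bool = True,
                    n_steps: int = 8,
                    zero_duration_ms: float = 30_000.0) -> Cohort:
    """Generate a labelled synthetic cohort with the study's structure.

    ``n_per_group`` maps group names to cell counts (each must be >= 1).
    A fixed seed yields a bit-identical cohort.  Zero-current sweeps are
    opt-in (they dominate runtime and only feed the spontaneous rate, which
    is not part of the 15-feature clustering matrix).
    """
    p_connect = p_connect or ConnectionProbabilities()
    for g, n in n_per_group.items():
        if n < 1:
            raise ValueError(f"need at least one cell in group {g!r}")
    rng = np.random.default_rng(rng_seed)
    cells, ids, groups = [], [], []
    for g, n in sorted(n_per_group.items()):
        for i in range(n):
            cells.append(sample_cell(g, rng))
            ids.append(f"{g}_{i:03d}")
            groups.append(g)

    sweeps: dict[str, CellSweeps] = {}
    if include_sweeps:
        for cid, params in zip(ids, cells):
            sweeps[cid] = simulate_cell_sweeps(
                params, rng, sampling_rate=sampling_rate, noise_sd=noise_sd,
                n_steps=n_steps, include_zero=include_zero,
                zero_duration_ms=zero_duration_ms)

    morphologies: list[Morphology] = []
    if include_morphology:
        for cid, params in zip(ids, cells):
            m = generate_swc(params, rng)
            m.cell_id = cid
            morphologies.append(m)

    pairs: list[PairSim] = []
    if include_pairs:
        by_group: dict[str, list[int]] = {}
        for k, g in enumerate(groups):
            by_group.setdefault(g, []).append(k)
        for g, idxs in sorted(by_group.items()):
            orientation_pool = (["sagittal", "coronal"]
                                if g == "prototypic_PV" else ["sagittal"])
            for session in _sessions(idxs, rng):
                orientation = orientation_pool[int(rng.integers(len(orientation_pool)))]
                for a in session:
                    for b in session:
                        if a == b:
                            continue
                        pg = (groups[a], groups[b])
                        connected = bool(sample_connection_map([pg], p_connect, rng)[0])
                        spikes, fav, gd, gf, amps, _ = simulate_pair(
                            cells[a], cells[b], connected, rng,
                            noise_sd=noise_sd, sampling_rate=sampling_rate)
                        pairs.append(PairSim(
                            driver_id=ids[a], follower_id=ids[b],
                            driver_group=GROUP_MARKERS[groups[a]],
                            follower_group=GROUP_MARKERS[groups[b]],
                            distance_um=float(rng.uniform(*DISTANCE_RANGE_UM)),
                            slice_orientation=orientation,
                            driver_spike_times=spikes,
                            follower_avg=fav, gap_driver=gd, gap_follower=gf,
                            connected=connected, ipsp_amplitudes=amps,
                        ))

    return Cohort(cells=cells, cell_ids=ids, groups=groups, sweeps=sweeps,
                  morphologies=morphologies, pairs=pairs,
                  seed=rng_seed if isinstance(rng_seed, int) else None)
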