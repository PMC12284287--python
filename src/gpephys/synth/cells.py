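"""Ground-truth cell parameters for the three recorded GPe populations.

Arkypallidal (FoxP2+) neurons are modelled with higher input resistance,
a more hyperpolarized spike threshold, slower and taller action potentials,
a larger sag conductance, lower spontaneous rates (with a sizeable silent
fraction) and smaller somata/thinner dendrites than the two prototypic
populations (PV+ and Nkx2.1+), which differ from each other only subtly in
AP shape.  Population means/SDs are not published for most features, so the
defaults below encode the qualitative orderings with realistic magnitudes
for mouse GPe; everything is overridable.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

GROUPS = ("arkypallidal", "prototypic_PV", "prototypic_Nkx")

#: canonical marker label per generator group (used in pair categorisation)
GROUP_MARKERS = {
    "arkypallidal": "FoxP2",
    "prototypic_PV": "PV",
    "prototypic_Nkx": "Nkx2.1",
}


@dataclass
class ApShape:
    """Piecewise-linear action-potential template parameters."""

    t_rise: float  # ms, threshold -> peak
    t_fall: float  # ms, peak -> threshold re-crossing
    V_peak: float  # mV
    fAHP_depth: float  # mV below threshold (positive number)
    t_fAHP: float  # ms, fall point -> AHP trough


@dataclass
class DendriteGeometry:
    n_primary: int
    mean_segment_len: float  # um, between consecutive branch points
    taper: float  # diameter loss per um of path length
    base_diameter: float  # um at the soma
    bifurcation_prob: float


@dataclass
class CellParams:
    """Single-compartment + template parameters of one synthetic neuron."""

    group: str
    R_in: float  # MOhm
    C_m: float  # pF
    E_L: float  # mV
    V_T: float  # mV, AP threshold
    g_h: float  # nS, sag (h-current) conductance scale
    tau_h: float  # ms, sag activation time constant
    E_h: float  # mV, sag reversal
    ap_shape: ApShape = field(default_factory=lambda: ApShape(0.3, 0.8, 15.0, 20.0, 1.5))
    spont_rate: float = 0.0  # Hz at 0 pA holding
    soma_radius: float = 7.0  # um
    dendrite_geometry: DendriteGeometry = field(
        default_factory=lambda: DendriteGeometry(5, 60.0, 0.005, 2.0, 0.45)
    )

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"unknown group {self.group!r}; expected one of {GROUPS}"
            )
        if self.R_in <= 0:
            raise ValueError("R_in must be positive")
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")
        if self.ap_shape.t_rise <= 0 or self.ap_shape.t_fall <= 0:
            raise ValueError("AP rise/fall times must be positive")
        if self.ap_shape.V_peak <= self.V_T:
            raise ValueError("V_peak must exceed the threshold V_T")
        if self.spont_rate < 0:
            raise ValueError("spont_rate must be non-negative")
        if not 0.0 <= self.dendrite_geometry.bifurcation_prob <= 1.0:
            raise ValueError("bifurcation_prob must lie in [0, 1]")

    @property
    def tau_m(self) -> float:
        """Membrane time constant in ms (R_in * C_m)."""
        return self.R_in * self.C_m / 1000.0

    @property
    def rheobase_passive(self) -> float:
        """Steady-state rheobase in pA for a purely ohmic membrane."""
        return (self.V_T - self.E_L) / self.R_in * 1000.0

    @property
    def rheobase(self) -> float:
        """Analytic steady-state rheobase in pA.

        Includes the sag conductance at its steady activations and the
        holding current that pins rest to E_L; reduces to the ohmic value
        (V_T - E_L)/R_in when g_h = 0.
        """
        def m_inf(v: float) -> float:
            return 1.0 / (1.0 + np.exp((v + 80.0) / 6.0))

        i_hold = self.g_h * m_inf(self.E_L) * (self.E_L - self.E_h)
        i_h_at_threshold = self.g_h * m_inf(self.V_T) * (self.V_T - self.E_h)
        return self.rheobase_passive + i_h_at_threshold - i_hold


# Group means.  CV/SDs of the sampling distributions are set in sample_cell.
_DEFAULTS: dict[str, dict] = {
    "arkypallidal": dict(
        R_in=350.0, C_m=60.0, E_L=-70.0, V_T=-50.0,
        g_h=1.5, tau_h=50.0, E_h=-30.0,
        ap_shape=dict(t_rise=0.45, t_fall=1.4, V_peak=25.0, fAHP_depth=18.0, t_fAHP=2.5),
        spont_rate=2.0, silent_fraction=0.40, soma_radius=5.0,
        dendrite_geometry=dict(n_primary=4, mean_segment_len=90.0, taper=0.004,
                               base_diameter=1.2, bifurcation_prob=0.30),
    ),
    "prototypic_PV": dict(
        R_in=120.0, C_m=100.0, E_L=-70.0, V_T=-42.0,
        g_h=0.4, tau_h=50.0, E_h=-30.0,
        ap_shape=dict(t_rise=0.25, t_fall=0.7, V_peak=14.0, fAHP_depth=22.0, t_fAHP=1.2),
        spont_rate=15.0, silent_fraction=0.05, soma_radius=7.0,
        dendrite_geometry=dict(n_primary=5, mean_segment_len=110.0, taper=0.004,
                               base_diameter=2.0, bifurcation_prob=0.30),
    ),
    "prototypic_Nkx": dict(
        R_in=120.0, C_m=100.0, E_L=-70.0, V_T=-42.0,
        g_h=0.4, tau_h=50.0, E_h=-30.0,
        # slightly faster rise and taller AP than PV+, deeper fAHP; the
        # shifts stay below one within-group SD so the two prototypic
        # populations overlap (they form one mixed cluster downstream)
        ap_shape=dict(t_rise=0.235, t_fall=0.7, V_peak=15.5, fAHP_depth=23.5, t_fAHP=1.2),
        spont_rate=15.0, silent_fraction=0.05, soma_radius=7.0,
        dendrite_geometry=dict(n_primary=5, mean_segment_len=110.0, taper=0.004,
                               base_diameter=2.0, bifurcation_prob=0.30),
    ),
}


def group_defaults(group: str) -> dict:
    """Return a deep copy of the default parameter means for ``group``."""
    if group not in _DEFAULTS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    return copy.deepcopy(_DEFAULTS[group])


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_cell(group: str, rng_seed=0, overrides: dict | None = None) -> CellParams:
    """Draw one cell's ground-truth parameters for ``group``.

    Positive scale parameters (resistance, capacitance, kinetics, geometry)
    are drawn log-normally with ~15% coefficient of variation around the
    group mean; voltages are drawn normally with a 2 mV SD.  A fixed seed
    gives an identical draw.  ``overrides`` replaces group means before
    sampling (nested dicts for ``ap_shape``/``dendrite_geometry``).
    """
    rng = _as_rng(rng_seed)
    d = group_defaults(group)
    if overrides:
        for key, val in overrides.items():
            if isinstance(val, dict):
                d[key].update(val)
            else:
                d[key] = val

    def lognorm(mean: float, cv: float = 0.15) -> float:
        sigma = np.sqrt(np.log(1.0 + cv**2))
        mu = np.log(mean) - sigma**2 / 2.0
        return float(np.exp(rng.normal(mu, sigma)))

    def norm(mean: float, sd: float = 2.0) -> float:
        return float(rng.normal(mean, sd))

    R_in = lognorm(d["R_in"])
    C_m = lognorm(d["C_m"])
    E_L = norm(d["E_L"])
    V_T = norm(d["V_T"])
    # keep the threshold drive positive even in the distribution tails
    V_T = max(V_T, E_L + 5.0)
    g_h = lognorm(d["g_h"], cv=0.30)
    tau_h = lognorm(d["tau_h"])
    ap = d["ap_shape"]
    shape = ApShape(
        t_rise=lognorm(ap["t_rise"]),
        t_fall=lognorm(ap["t_fall"]),
        V_peak=max(norm(ap["V_peak"]), V_T + 20.0),
        fAHP_depth=lognorm(ap["fAHP_depth"]),
        t_fAHP=lognorm(ap["t_fAHP"]),
    )
    silent = rng.random() < d["silent_fraction"]
    spont = 0.0 if silent else lognorm(d["spont_rate"], cv=0.40)
    geom = d["dendrite_geometry"]
    geometry = DendriteGeometry(
        n_primary=max(1, int(round(rng.normal(geom["n_primary"], 0.8)))),
        mean_segment_len=lognorm(geom["mean_segment_len"]),
        taper=lognorm(geom["taper"], cv=0.20),
        base_diameter=lognorm(geom["base_diameter"]),
        bifurcation_prob=float(np.clip(rng.normal(geom["bifurcation_prob"], 0.05), 0.0, 1.0)),
    )
    return CellParams(
        group=group, R_in=R_in, C_m=C_m, E_L=E_L, V_T=V_T,
        g_h=g_h, tau_h=tau_h, E_h=d["E_h"], ap_shape=shape,
        spont_rate=spont, soma_radius=lognorm(d["soma_radius"]),
        dendrite_geometry=geometry,
    )
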