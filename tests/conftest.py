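"""Shared fixtures: deterministic cells with known ground truth."""

import numpy as np
import pytest

from gpephys.synth.cells import ApShape, CellParams, DendriteGeometry


@pytest.fixture
def ohmic_params() -> CellParams:
    """A purely passive cell: exact Ohm's-law / RC ground truth."""
    return CellParams(
        group="prototypic_PV", R_in=100.0, C_m=100.0, E_L=-70.0, V_T=-40.0,
        g_h=0.0, tau_h=50.0, E_h=-30.0,
        ap_shape=ApShape(t_rise=0.25, t_fall=0.7, V_peak=15.0,
                         fAHP_depth=22.0, t_fAHP=1.2),
    )


@pytest.fixture
def arky_params() -> CellParams:
    """A deterministic arkypallidal-like cell with a sag conductance."""
    return CellParams(
        group="arkypallidal", R_in=350.0, C_m=60.0, E_L=-70.0, V_T=-50.0,
        g_h=1.5, tau_h=50.0, E_h=-30.0,
        ap_shape=ApShape(t_rise=0.45, t_fall=1.4, V_peak=25.0,
                         fAHP_depth=18.0, t_fAHP=2.5),
        spont_rate=2.0, soma_radius=5.0,
    )


@pytest.fixture
def y_geometry():
    """Deterministic branching geometry for morphology tests."""
    return DendriteGeometry(n_primary=5, mean_segment_len=60.0, taper=0.005,
                            base_diameter=2.0, bifurcation_prob=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
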