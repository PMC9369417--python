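"""Shared fixtures: reference optics, mobility regimes and lag grids."""

from __future__ import annotations

import numpy as np
import pytest

from fcsquant.synthetic import OpticsSpec, TripletSpec, make_lag_grid

W0_UM = 0.22
S_PAR = 4.0


def tau_from_d(d_um2_s: float, w0_um: float = W0_UM) -> float:
    """Diffusion time (s) for a diffusion coefficient (um^2/s)."""
    return w0_um**2 / (4.0 * d_um2_s)


@pytest.fixture
def optics() -> OpticsSpec:
    return OpticsSpec(w0_um=W0_UM, structural_parameter=S_PAR, confocal_volume_fl=0.57)


@pytest.fixture
def triplet() -> TripletSpec:
    return TripletSpec(dark_fraction=0.15, relaxation_time_s=20e-6)


@pytest.fixture
def lag_grid() -> np.ndarray:
    return make_lag_grid(1e-6, 2.0, 120)


@pytest.fixture
def two_component_params() -> dict:
    """A parameter set in the regime the pipeline targets."""
    return {
        "n_molecules": 20.85,
        "frac_fast": 0.596,
        "tau_fast_s": tau_from_d(12.25),
        "tau_slow_s": tau_from_d(0.15),
        "triplet_fraction": 0.15,
        "tau_triplet_s": 20e-6,
        "structural_parameter": S_PAR,
        "offset": 0.0,
    }
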