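"""Shared fixtures: canonical synthetic systems with known ground truth."""

import pytest

from nmrtitrate import (
    NOISELESS,
    DiproticSpec,
    SiteModel,
    TautomerSystemSpec,
    default_grid,
    simulate_diprotic,
    simulate_monoprotic,
    simulate_polyprotic,
    simulate_tautomeric,
)

import numpy as np


@pytest.fixture
def mono_site():
    """Single site, pKa 8.5, two reporters moving in opposite directions."""
    return SiteModel(
        pKa=8.5,
        delta_acid={"H6": 6.9, "H9": 8.9},
        delta_base={"H6": 6.3, "H9": 8.1},
    )


@pytest.fixture
def mono_series(mono_site):
    return simulate_monoprotic(mono_site, default_grid(8.5), NOISELESS)


@pytest.fixture
def tautomer_spec():
    """Coupled two-site system; ground truth ΔK = 10^(8.0−8.3) ≈ 0.501."""
    return TautomerSystemSpec(
        pKa_HO=8.0,
        pKa_HN=8.3,
        delta_start={"H6": 6.9, "H9": 4.8},
        delta_end={"H6": 6.3, "H9": 4.3},
    )


@pytest.fixture
def tautomer_series(tautomer_spec):
    return simulate_tautomeric(tautomer_spec, default_grid(8.0, 8.3), NOISELESS)


@pytest.fixture
def diprotic_spec():
    """Sequential two-step system, pKa 8 and 10 (K1/K2 = 100)."""
    return DiproticSpec(
        pKa1=8.0,
        pKa2=10.0,
        delta_H2A={"H6": 6.9, "H9": 4.8},
        delta_HA={"H6": 6.5, "H9": 4.75},
        delta_A={"H6": 6.4, "H9": 4.3},
    )


@pytest.fixture
def diprotic_series(diprotic_spec):
    return simulate_diprotic(diprotic_spec, default_grid(8.0, 10.0), NOISELESS)


def make_diprotic_ratio(ratio: float):
    """Two-step system with stepwise-constant quotient K1/K2 = ratio."""
    sep = np.log10(ratio)
    spec = DiproticSpec(
        pKa1=8.0,
        pKa2=8.0 + sep,
        delta_H2A={"H6": 6.9, "H9": 4.8},
        delta_HA={"H6": 6.5, "H9": 4.75},
        delta_A={"H6": 6.4, "H9": 4.3},
    )
    return simulate_diprotic(spec, default_grid(8.0, 8.0 + sep), NOISELESS)


@pytest.fixture
def four_state_series():
    """Compound-6-style ladder: rearrangement plus two deprotonations.

    Four spectroscopic states give three linear branches — two interior
    vertices — in the (H6, H5) pairing.
    """
    return simulate_polyprotic(
        [7.0, 9.0, 11.0],
        [
            {"H6": 6.9, "H5": 7.4},
            {"H6": 6.5, "H5": 7.35},
            {"H6": 6.45, "H5": 7.1},
            {"H6": 6.2, "H5": 7.0},
        ],
        np.linspace(4.5, 13.5, 37),
        NOISELESS,
    )
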