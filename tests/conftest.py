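"""Shared fixtures: small synthetic complexes and kinetics parameter sets."""

import numpy as np
import pytest

import siftkin as sk

# Wild-type and Y120P aminopeptidase / endopeptidase kinetic constants
# (kcat min^-1, Km µM, kcat/Km) used throughout the kinetics tests.
WT_AMINO = (0.646, 12.0, 0.052)
Y120P_AMINO = (4.37, 11.3, 0.398)
WT_ENDO = (0.11, 10.0, 0.018)
Y120P_ENDO = (1.13, 5.4, 0.21)


@pytest.fixture
def wt_points():
    """Noise-free triplicate saturation data from the WT aminopeptidase
    parameters with [E]0 = 1 µM (so Vmax equals kcat numerically)."""
    spec = sk.KineticsSpec(
        params=sk.HillParams(Vmax=WT_AMINO[0], Km=WT_AMINO[1], h=1.0),
        noise_cv=0.0, seed=0)
    return sk.simulate_kinetics(spec)


@pytest.fixture
def single_val_complex():
    """One Val residue with a single ligand carbon 3.5 Å from its CB."""
    spec = sk.ComplexSpec(planted=(sk.PlantedInteraction("hydrophobic"),))
    return sk.make_complex(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20240905)
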