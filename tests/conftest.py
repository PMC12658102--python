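"""Shared fixtures: small experiments, schemes and synthetic ensembles."""

import numpy as np
import pytest

from helixmer.equilibria import AssociationScheme
from helixmer.lamm_forward import CellExperiment, HydroSpecies


#: best-fit monomer-dimer-tetramer model of the weak CTD self-association:
#: stepwise Kds 2.4 mM and 2.7 µM, s = 1.54 / 2.43 / 3.94 S, 14 kDa monomer
MDT_KDS_UM = (2400.0, 2.7)
MDT_S = (1.54, 2.43, 3.94)
MONOMER_MASS_DA = 14000.0


@pytest.fixture(scope="session")
def mdt_scheme():
    return AssociationScheme.monomer_dimer_tetramer(*MDT_KDS_UM)


@pytest.fixture(scope="session")
def mdt_species(mdt_scheme):
    return [
        HydroSpecies(lab, s, mass_da=MONOMER_MASS_DA * n)
        for (lab, n), s in zip(mdt_scheme.species, MDT_S)
    ]


@pytest.fixture(scope="session")
def sv_experiment():
    """50 krpm run in a 6.0–7.2 cm cell with 50 scans over ~8 h."""
    return CellExperiment(
        meniscus_cm=6.0,
        bottom_cm=7.2,
        rpm=50000.0,
        scan_times_s=tuple(np.linspace(300.0, 30000.0, 50)),
    )


@pytest.fixture(scope="session")
def sv_experiment_small():
    """Coarse, fast variant for unit tests."""
    return CellExperiment(
        meniscus_cm=6.0,
        bottom_cm=7.2,
        rpm=50000.0,
        scan_times_s=tuple(np.linspace(600.0, 24000.0, 12)),
    )


@pytest.fixture(scope="session")
def fit_radii():
    """Usable optical window: excludes meniscus and bottom regions."""
    return np.linspace(6.03, 7.05, 180)
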