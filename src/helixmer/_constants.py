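"""Physical constants (CGS) and water property correlations.

Internal unit conventions used across the package:

* sedimentation coefficient ``s``: Svedberg (1 S = 1e-13 s)
* diffusion coefficient ``D``: cm^2/s
* radius: cm, time: s, concentration: µM monomer-equivalents
* density: g/mL, viscosity: poise (1 cP = 0.01 poise)
* molar mass: Da, partial specific volume: mL/g
"""

from __future__ import annotations

import numpy as np

#: Avogadro constant, 1/mol
N_A = 6.02214076e23
#: Boltzmann constant, erg/K
K_B = 1.380649e-16
#: molar gas constant, erg/(mol K)
R_GAS = 8.31446261815324e7
#: 1 Svedberg in seconds
SVEDBERG = 1e-13

#: density of water at 20 °C, g/mL
RHO_20W = 0.998203
#: viscosity of water at 20 °C, poise
ETA_20W = 1.002e-2


def water_density(temperature_c: float) -> float:
    """Density of air-free water in g/mL (Kell 1975 polynomial)."""
    t = float(temperature_c)
    num = (
        999.83952
        + 16.945176 * t
        - 7.9870401e-3 * t**2
        - 46.170461e-6 * t**3
        + 105.56302e-9 * t**4
        - 280.54253e-12 * t**5
    )
    return num / (1.0 + 16.879850e-3 * t) / 1000.0


def water_viscosity(temperature_c: float) -> float:
    """Viscosity of water in poise (CRC correlation, valid 0–100 °C)."""
    t = float(temperature_c)
    if t >= 20.0:
        # Swindells / CRC form anchored at 20 °C
        log_rel = (1.3272 * (20.0 - t) - 0.001053 * (20.0 - t) ** 2) / (t + 105.0)
        return ETA_20W * 10.0**log_rel
    # Hardy–Cottington form for 0–20 °C
    log10_eta_cp = 1301.0 / (998.333 + 8.1855 * (t - 20.0) + 0.00585 * (t - 20.0) ** 2) - 1.30233
    return 10.0**log10_eta_cp * 1e-2


def rpm_to_omega(rpm: float) -> float:
    """Rotor speed in rev/min to angular velocity in rad/s."""
    return 2.0 * np.pi * rpm / 60.0
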