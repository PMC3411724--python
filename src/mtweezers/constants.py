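"""Physical constants and unit conversions.

Internal unit contract
----------------------
The field/force module works in SI internally (m, T, N) and converts at the
API surface.  Everywhere else the package uses the conventions of the
magnetic-tweezers literature: lengths in micrometres (tether extensions,
bead radii) or millimetres (magnet heights), forces in piconewtons,
magnetic fields in millitesla, energies in units of k_BT (and joules on
request).
"""

import math

MU_0 = 4.0e-7 * math.pi  # vacuum permeability, T·m/A
K_B = 1.380649e-23  # Boltzmann constant, J/K

#: default assay temperature (22 °C), kelvin
DEFAULT_TEMPERATURE = 295.15


def kbt_joule(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B·T in joules (≈4.075e-21 J at 22 °C)."""
    return K_B * temperature


def kbt_pn_um(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy in pN·µm (1 J = 1e12 pN · 1e6 µm → 1e18 pN·µm)."""
    return K_B * temperature * 1e18


# unit conversions
PN_PER_N = 1e12
FN_PER_N = 1e15
M_PER_MM = 1e-3
M_PER_UM = 1e-6
MT_PER_T = 1e3
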