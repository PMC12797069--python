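"""Physical constants and unit conversions.

Unit contract used throughout the package: distances in angstroms (A),
times in picoseconds (ps), energies in kcal/mol, temperatures in kelvin.
Angular features are handled in degrees with period 360.
"""

import math

#: Boltzmann constant, kcal mol^-1 K^-1.
KB_KCAL_PER_MOL_K = 0.0019872041

#: Boltzmann constant, J K^-1 (SI), used only for the Stokes-Einstein relation.
KB_SI = 1.380649e-23

#: Dynamic viscosity of water at 300 K, Pa*s.
WATER_VISCOSITY_PA_S = 0.8937e-3

#: Conversion factor m^2/s -> A^2/ps  (1 m^2/s = 1e20 A^2 / 1e12 ps).
M2_PER_S_TO_A2_PER_PS = 1e8


def stokes_einstein_diffusion(temperature: float, radius_angstrom: float,
                              viscosity_pa_s: float = WATER_VISCOSITY_PA_S) -> float:
    """Diffusion coefficient of a sphere in water, in A^2/ps.

    D = kB*T / (6*pi*eta*R) for a sphere of Stokes radius R diffusing in a
    medium of viscosity eta.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if radius_angstrom <= 0:
        raise ValueError("stokes radius must be positive")
    radius_m = radius_angstrom * 1e-10
    d_si = KB_SI * temperature / (6.0 * math.pi * viscosity_pa_s * radius_m)
    return d_si * M2_PER_S_TO_A2_PER_PS
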