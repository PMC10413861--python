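"""Internal unit system and physical constants.

The package works internally in Å (length), ps (time) and kcal/mol (energy).
Temperatures are in kelvin and solvent viscosities are given in centipoise
(1 cP = 1 mPa·s, water at 25 °C is ~0.89 cP) and converted on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Boltzmann constant in kcal/mol/K
KB_KCAL_MOL_K = 0.0019872

# 1 centipoise expressed in kcal/mol * ps / Å^3:
#   1 cP = 1e-3 Pa·s = 1e-3 J·s/m^3
#   1 J = N_A/4184 kcal/mol, 1 s = 1e12 ps, 1 m^3 = 1e30 Å^3
_AVOGADRO = 6.02214076e23
CP_TO_INTERNAL = 1e-3 * (_AVOGADRO / 4184.0) * 1e12 / 1e30

FS_TO_PS = 1e-3


@dataclass(frozen=True)
class HydroEnvironment:
    """Solvent conditions entering the diffusion tensor.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin.
    viscosity_cp : float
        Solvent shear viscosity in centipoise.
    """

    temperature: float = 298.15
    viscosity_cp: float = 0.89
    kBT: float = field(init=False)
    viscosity: float = field(init=False)  # kcal/mol * ps / Å^3

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        if self.viscosity_cp <= 0:
            raise ValueError(f"viscosity must be > 0 cP, got {self.viscosity_cp}")
        object.__setattr__(self, "kBT", KB_KCAL_MOL_K * self.temperature)
        object.__setattr__(self, "viscosity", self.viscosity_cp * CP_TO_INTERNAL)
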