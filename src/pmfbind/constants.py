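"""Physical constants and thermodynamic parameters.

Values are pinned (not taken from scipy.constants at run time) so that binding
free energies round-trip bit-for-bit across platforms and versions.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant in kcal mol^-1 K^-1 (CODATA, truncated as conventionally
#: used in biomolecular free-energy work).
BOLTZMANN_KCAL = 1.9872041e-3

#: Avogadro constant, mol^-1 (exact, SI 2019).
AVOGADRO = 6.02214076e23

#: Litres per cubic angstrom.
LITER_PER_CUBIC_ANGSTROM = 1e-27

#: Physiological body temperature used throughout, K.
DEFAULT_TEMPERATURE = 310.15


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic parameters for converting a PMF into a dissociation constant.

    Parameters
    ----------
    temperature : float
        Absolute temperature in K. Default 310.15 K (body temperature).
    cylinder_radius : float
        Radius R in angstrom of the flat-bottom cylindrical restraint that caps
        lateral displacement of the ligand; the restraint defines the sampled
        volume per unit length, pi R^2, entering the effective K_D.
    standard_concentration : float
        Standard-state concentration c0 in mol/L (1 M by convention).
    boltzmann : float
        Boltzmann constant in kcal mol^-1 K^-1.
    avogadro : float
        Avogadro constant in mol^-1.
    """

    temperature: float = DEFAULT_TEMPERATURE
    cylinder_radius: float = 10.0
    standard_concentration: float = 1.0
    boltzmann: float = BOLTZMANN_KCAL
    avogadro: float = AVOGADRO

    def __post_init__(self) -> None:
        for name in ("temperature", "cylinder_radius", "standard_concentration",
                     "boltzmann", "avogadro"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ThermoParams.{name} must be strictly positive")

    @property
    def kt(self) -> float:
        """Thermal energy k_B*T in kcal/mol (0.6163 kcal/mol at 310.15 K)."""
        return self.boltzmann * self.temperature

    def as_dict(self) -> dict:
        return {
            "temperature_K": self.temperature,
            "cylinder_radius_A": self.cylinder_radius,
            "standard_concentration_M": self.standard_concentration,
            "boltzmann_kcal_per_mol_K": self.boltzmann,
            "avogadro_per_mol": self.avogadro,
        }
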