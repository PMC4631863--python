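"""Conversions linking binding free energy, inhibition constants, IC50 and
mass concentration.

All inhibition constants are carried in micromolar (µM) throughout the
package; conversion to/from molar happens only inside the formulas here.
Binding energies are in kcal/mol. The free-energy/constant link is the
exponential convention used by grid-based docking scoring functions:
``Ki[M] = exp(dG / (R * T))``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

__all__ = [
    "InhibitionMode",
    "ThermoSettings",
    "CompoundSpec",
    "DEFAULT_SETTINGS",
    "deltaG_to_ki",
    "ki_to_deltaG",
    "mass_to_molar",
    "ic50_to_ki",
]

#: micromolar per molar
M_TO_UM = 1.0e6


class InhibitionMode(str, enum.Enum):
    """Kinetic inhibition mechanism used by the IC50 → Ki conversion."""

    NONCOMPETITIVE = "noncompetitive"
    COMPETITIVE = "competitive"
    UNCOMPETITIVE = "uncompetitive"


@dataclass(frozen=True)
class ThermoSettings:
    """Gas constant and temperature for free-energy conversions.

    Defaults are R in kcal·mol⁻¹·K⁻¹ and T = 298.15 K, the convention of
    common docking scoring functions.
    """

    gas_constant_R: float = 1.98719e-3
    temperature_T: float = 298.15

    def __post_init__(self) -> None:
        if not (math.isfinite(self.gas_constant_R) and self.gas_constant_R > 0):
            raise ValueError(f"gas_constant_R must be positive and finite, got {self.gas_constant_R!r}")
        if not (math.isfinite(self.temperature_T) and self.temperature_T > 0):
            raise ValueError(f"temperature_T must be positive and finite, got {self.temperature_T!r}")

    @property
    def rt(self) -> float:
        """R·T in kcal/mol."""
        return self.gas_constant_R * self.temperature_T


DEFAULT_SETTINGS = ThermoSettings()


@dataclass(frozen=True)
class CompoundSpec:
    """A compound with a molecular weight and its mass fraction in an extract.

    ``mass_fraction_in_extract`` is the w/w fraction of the compound in the
    crude material an IC50 was measured on; 1.0 means pure compound.
    """

    name: str
    molecular_weight: float
    mass_fraction_in_extract: float = 1.0

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("name must be non-empty")
        if not (math.isfinite(self.molecular_weight) and self.molecular_weight > 0):
            raise ValueError(f"molecular_weight must be positive, got {self.molecular_weight!r}")
        if not (0.0 <= self.mass_fraction_in_extract <= 1.0):
            raise ValueError(
                f"mass_fraction_in_extract must lie in [0, 1], got {self.mass_fraction_in_extract!r}"
            )


def deltaG_to_ki(e_binding: float, settings: ThermoSettings = DEFAULT_SETTINGS) -> float:
    """Convert a binding free energy (kcal/mol) to an inhibition constant in µM.

    Ki[M] = exp(ΔG / RT); the return value is Ki in micromolar. Strictly
    increasing in ``e_binding`` (more negative energy → tighter binding →
    smaller Ki).
    """
    if not math.isfinite(e_binding):
        raise ValueError(f"e_binding must be finite, got {e_binding!r}")
    return math.exp(e_binding / settings.rt) * M_TO_UM


def ki_to_deltaG(ki_uM: float, settings: ThermoSettings = DEFAULT_SETTINGS) -> float:
    """Inverse of :func:`deltaG_to_ki`: Ki in µM → binding energy in kcal/mol."""
    if not (math.isfinite(ki_uM) and ki_uM > 0):
        raise ValueError(f"ki_uM must be positive and finite, got {ki_uM!r}")
    return settings.rt * math.log(ki_uM / M_TO_UM)


def mass_to_molar(
    conc_mg_per_mL: float,
    compound: CompoundSpec,
    use_mass_fraction: bool = False,
) -> float:
    """Convert a mass concentration (mg/mL) to micromolar.

    With ``use_mass_fraction`` the concentration is first scaled by the
    compound's mass fraction in the extract (i.e. only the compound's share
    of the dosed mass is counted); otherwise the whole mass is treated as
    the compound, which is the convention needed to reproduce bundled
    reference conversions.
    """
    if not (math.isfinite(conc_mg_per_mL) and conc_mg_per_mL >= 0):
        raise ValueError(f"conc_mg_per_mL must be non-negative, got {conc_mg_per_mL!r}")
    fraction = compound.mass_fraction_in_extract if use_mass_fraction else 1.0
    # mg/mL == g/L; dividing by g/mol gives mol/L, ×1e6 gives µM.
    return conc_mg_per_mL * fraction / compound.molecular_weight * M_TO_UM


def ic50_to_ki(
    ic50_uM: float,
    mode: InhibitionMode | str,
    substrate_conc_uM: float | None = None,
    km_uM: float | None = None,
) -> float:
    """Convert an IC50 (µM) to Ki (µM) under the classical mode-specific forms.

    noncompetitive:  Ki = IC50
    competitive:     Ki = IC50 / (1 + S/Km)
    uncompetitive:   Ki = IC50 / (1 + Km/S)

    ``substrate_conc_uM`` and ``km_uM`` are required for the competitive and
    uncompetitive forms and ignored for noncompetitive.
    """
    mode = InhibitionMode(mode)
    if not (math.isfinite(ic50_uM) and ic50_uM > 0):
        raise ValueError(f"ic50_uM must be positive and finite, got {ic50_uM!r}")
    if mode is InhibitionMode.NONCOMPETITIVE:
        return ic50_uM
    if substrate_conc_uM is None or km_uM is None:
        raise ValueError(
            f"{mode.value} IC50→Ki conversion requires both substrate_conc_uM and km_uM; "
            f"got substrate_conc_uM={substrate_conc_uM!r}, km_uM={km_uM!r}"
        )
    if not (substrate_conc_uM > 0 and km_uM > 0):
        raise ValueError("substrate_conc_uM and km_uM must be positive")
    if mode is InhibitionMode.COMPETITIVE:
        return ic50_uM / (1.0 + substrate_conc_uM / km_uM)
    return ic50_uM / (1.0 + km_uM / substrate_conc_uM)
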