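"""Two-state thermodynamics of self-complementary duplex formation.

The melting of a self-complementary duplex, 2S ⇌ D, is treated as a
two-state equilibrium with temperature-independent ΔH° and ΔS° (ΔCp = 0).
For this stoichiometry the van't Hoff relation between the melting
temperature and total strand concentration Ct is

    1/Tm = R ln(Ct) / ΔH° + ΔS° / ΔH°

(note Ct, not Ct/4 as for non-self-complementary duplexes), and

    ΔG°37 = ΔH° − 310.15 · ΔS°.

All energies are in kcal·mol⁻¹; internal temperatures are kelvin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GAS_CONSTANT",
    "T37",
    "CELSIUS_OFFSET",
    "ThermoParams",
    "dG37_from_dH_TdS",
    "tm_self_complementary",
    "fraction_duplexed",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
]

#: Gas constant, kcal·mol⁻¹·K⁻¹ (1.9872 cal·mol⁻¹·K⁻¹).
GAS_CONSTANT: float = 1.9872e-3
#: Reference temperature for ΔG°37, kelvin (37 °C).
T37: float = 310.15
CELSIUS_OFFSET: float = 273.15
#: Heat-capacity change between single strand and duplex — fixed at zero;
#: ΔH° and ΔS° are temperature-independent by assumption.
DELTA_CP: float = 0.0


def celsius_to_kelvin(t: float) -> float:
    return t + CELSIUS_OFFSET


def kelvin_to_celsius(t: float) -> float:
    return t - CELSIUS_OFFSET


@dataclass(frozen=True)
class ThermoParams:
    """Van't Hoff thermodynamics of one duplex, with standard errors.

    Attributes
    ----------
    dH : kcal·mol⁻¹
    dS : kcal·mol⁻¹·K⁻¹
    se_dH, se_TdS37, se_dG37 : standard errors (nan when undefined)
    label : free-text identifier
    """

    dH: float
    dS: float
    se_dH: float = float("nan")
    se_TdS37: float = float("nan")
    se_dG37: float = float("nan")
    label: str = ""

    @property
    def TdS37(self) -> float:
        """T·ΔS° at 310.15 K, kcal·mol⁻¹ (the tabulated entropy column)."""
        return T37 * self.dS

    @property
    def dG37(self) -> float:
        """ΔG°37 = ΔH° − 310.15·ΔS°, kcal·mol⁻¹."""
        return self.dH - T37 * self.dS

    def tm(self, ct: float) -> float:
        """Melting temperature (kelvin) at total strand concentration ct."""
        return tm_self_complementary(self.dH, self.dS, ct)


def dG37_from_dH_TdS(dH: float, TdS37: float) -> float:
    """ΔG°37 from ΔH° and the tabulated T·ΔS° (both kcal·mol⁻¹)."""
    return dH - TdS37


def tm_self_complementary(dH: float, dS: float, ct: float) -> float:
    """Melting temperature (kelvin) of a self-complementary duplex.

    Tm = ΔH° / (ΔS° + R ln Ct). Defined only for a formation-favorable
    duplex (ΔH° < 0) at a concentration where the denominator is negative.

    Parameters
    ----------
    dH, dS : formation enthalpy (kcal·mol⁻¹) and entropy (kcal·mol⁻¹·K⁻¹).
    ct : total strand concentration, mol·L⁻¹.
    """
    if ct <= 0:
        raise ValueError(f"Ct must be positive (got {ct})")
    if dH >= 0:
        raise ValueError(f"two-state melting requires dH < 0 (got {dH})")
    denom = dS + GAS_CONSTANT * math.log(ct)
    if denom >= 0:
        raise ValueError(
            f"dS + R ln Ct = {denom:.4g} >= 0: no physical melting "
            "temperature for these parameters"
        )
    return dH / denom


def fraction_duplexed(T: float, dH: float, dS: float, ct: float) -> float:
    """Fraction of strands in duplex form at temperature T (kelvin).

    Mass action for 2S ⇌ D with K = α / (2·Ct·(1−α)²), where α is the
    fraction of strands duplexed and K = exp(−ΔG°(T)/RT). The quadratic
    q·α² − (2q+1)·α + q = 0 with q = 2·K·Ct has a unique root in [0, 1];
    the numerically stable branch is used. At T = Tm (van't Hoff sense) q = 2
    and α = 1/2 exactly.
    """
    if T <= 0 or ct <= 0:
        raise ValueError("T and Ct must be positive")
    dG = dH - T * dS
    q = 2.0 * ct * math.exp(-dG / (GAS_CONSTANT * T))
    if q == 0.0:
        return 0.0
    # root of q a^2 - (2q+1) a + q, stable form: 2q / ((2q+1) + sqrt(4q+1))
    return 2.0 * q / ((2.0 * q + 1.0) + math.sqrt(4.0 * q + 1.0))
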