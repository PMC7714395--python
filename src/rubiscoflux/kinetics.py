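"""Rubisco carboxylation/oxygenation kinetics under substrate competition.

CO2 and O2 compete for the same rubisco active site, so each gas acts as a
competitive inhibitor of the other's reaction.  With Michaelis constants
K_C and K_O (uM) and turnover numbers kcat_C and kcat_O (1/s), the
per-active-site rates are

    v_C = kcat_C [CO2] / ([CO2] + K_C (1 + [O2]/K_O))
    v_O = kcat_O [O2]  / ([O2]  + K_O (1 + [CO2]/K_C))

Raising CO2 therefore both saturates carboxylation and suppresses
oxygenation, which is exactly the effect a CO2 concentrating mechanism
exploits.  The rate ratio obeys the specificity identity
v_C/v_O = S_C/O * [CO2]/[O2] with S_C/O = (kcat_C/K_C)/(kcat_O/K_O).

Concentrations are dissolved-gas concentrations in uM throughout; no
pH/temperature or Henry-law conversions are applied.  Kinetic constants are
required inputs — there is no default enzyme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RubiscoKinetics",
    "carboxylation_rate",
    "oxygenation_rate",
    "rate_curve_table",
    "specificity",
    "AMBIENT_O2_UM",
]

#: Dissolved O2 in air-equilibrated water at growth temperature (uM), the
#: default background for rate curves.
AMBIENT_O2_UM = 270.0


@dataclass(frozen=True)
class RubiscoKinetics:
    """Michaelis-Menten constants of one rubisco, all strictly positive."""

    kcat_C: float  # carboxylation turnover, 1/s
    K_C: float  # CO2 half-saturation, uM
    kcat_O: float  # oxygenation turnover, 1/s
    K_O: float  # O2 half-saturation, uM

    def __post_init__(self) -> None:
        for name in ("kcat_C", "K_C", "kcat_O", "K_O"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def _check_conc(co2, o2) -> None:
    if np.any(np.asarray(co2) < 0) or np.any(np.asarray(o2) < 0):
        raise ValueError("gas concentrations must be non-negative")


def carboxylation_rate(k: RubiscoKinetics, co2, o2):
    """Per-active-site carboxylation rate (1/s); accepts scalars or arrays."""
    _check_conc(co2, o2)
    co2 = np.asarray(co2, dtype=float)
    o2 = np.asarray(o2, dtype=float)
    v = k.kcat_C * co2 / (co2 + k.K_C * (1.0 + o2 / k.K_O))
    return float(v) if v.ndim == 0 else v


def oxygenation_rate(k: RubiscoKinetics, co2, o2):
    """Per-active-site oxygenation rate (1/s), roles of the gases swapped."""
    _check_conc(co2, o2)
    co2 = np.asarray(co2, dtype=float)
    o2 = np.asarray(o2, dtype=float)
    v = k.kcat_O * o2 / (o2 + k.K_O * (1.0 + co2 / k.K_C))
    return float(v) if v.ndim == 0 else v


def specificity(k: RubiscoKinetics) -> float:
    """S_C/O = (kcat_C/K_C) / (kcat_O/K_O), the catalytic-efficiency ratio."""
    return (k.kcat_C / k.K_C) / (k.kcat_O / k.K_O)


def rate_curve_table(
    k: RubiscoKinetics, co2_grid, o2: float = AMBIENT_O2_UM
) -> pd.DataFrame:
    """Rates over an ascending CO2 grid at a fixed O2 background.

    Returns a DataFrame with columns ``co2_uM, o2_uM, v_c, v_o``, one row
    per grid point.
    """
    grid = np.asarray(list(co2_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("co2_grid must be nonempty")
    if np.any(np.diff(grid) <= 0) and grid.size > 1:
        raise ValueError("co2_grid must be strictly ascending")
    return pd.DataFrame(
        {
            "co2_uM": grid,
            "o2_uM": float(o2),
            "v_c": carboxylation_rate(k, grid, o2),
            "v_o": oxygenation_rate(k, grid, o2),
        }
    )
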