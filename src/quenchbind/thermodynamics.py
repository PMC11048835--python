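"""Van't Hoff analysis of temperature-dependent binding constants.

A linear fit of log10 K_A against 1/T yields the binding enthalpy and
entropy,

    log10 K_A = -dH / (c R T) + dS / (c R),      c = ln 10

so dH = -c R slope and dS = c R intercept; the Gibbs energy at each
temperature is dG = dH - T dS.  The sign pattern of (dH, dS) indicates the
dominant intermolecular force (per the conventional thermodynamic rule
table), and dG < 0 / dH < 0 flag spontaneity and exothermicity.

Computation is in SI joules; report layers rescale to kJ/mol for dH and dG.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ValidationError

#: gas constant, J mol^-1 K^-1
R_GAS = 8.314


@dataclass(frozen=True)
class ThermoConstants:
    """Physical constants of the analysis.

    ``decadic`` is the ln(10) factor converting decadic to natural
    logarithms.  ``paper_faithful()`` uses the rounded 2.303 often printed
    in the applied literature; the difference is far below fit uncertainty.
    """

    r_gas: float = R_GAS
    decadic: float = math.log(10.0)

    @classmethod
    def paper_faithful(cls) -> "ThermoConstants":
        return cls(decadic=2.303)


@dataclass(frozen=True)
class VantHoffFit:
    """Binding thermodynamics from a van't Hoff regression."""

    delta_h: float  # J/mol
    delta_s: float  # J mol^-1 K^-1
    r_squared: float
    gibbs_by_temp: Mapping[float, float]  # T (K) -> dG (J/mol)
    force_label: str
    spontaneous: bool
    exothermic: bool


def fit_vant_hoff(
    ka_by_temp: Mapping[float, float],
    constants: ThermoConstants | None = None,
) -> VantHoffFit:
    """Least-squares van't Hoff fit of log10 K_A versus 1/T."""
    c = constants or ThermoConstants()
    if len(ka_by_temp) < 2:
        raise InsufficientDataError(
            f"need >=2 temperatures, got {len(ka_by_temp)}"
        )
    temps = np.array(sorted(ka_by_temp), dtype=float)
    kas = np.array([ka_by_temp[t] for t in temps], dtype=float)
    if np.any(kas <= 0) or np.any(temps <= 0):
        raise ValidationError("all K_A and temperatures must be > 0")
    x = 1.0 / temps
    y = np.log10(kas)
    if len(temps) == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        r2 = 1.0
    else:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue**2)
    dh = -c.decadic * c.r_gas * slope
    ds = c.decadic * c.r_gas * intercept
    gibbs_by_temp = {float(t): gibbs(dh, ds, float(t)) for t in temps}
    dg_min_t = gibbs_by_temp[float(temps[0])]
    spont, exo = spontaneity(dg_min_t, dh)
    return VantHoffFit(
        delta_h=dh,
        delta_s=ds,
        r_squared=r2,
        gibbs_by_temp=gibbs_by_temp,
        force_label=classify_forces(dh, ds),
        spontaneous=spont,
        exothermic=exo,
    )


def gibbs(delta_h: float, delta_s: float, t: float) -> float:
    """Gibbs energy dG = dH - T dS (J/mol)."""
    if not t > 0:
        raise ValidationError(f"temperature must be > 0 K, got {t}")
    return delta_h - t * delta_s


def classify_forces(delta_h: float, delta_s: float) -> str:
    """Dominant intermolecular force from the signs of (dH, dS).

    dH<0, dS>0 -> electrostatic; dH>0, dS>0 -> hydrophobic;
    dH<0, dS<0 -> hydrogen-bond/van-der-Waals; dH>0, dS<0 -> unclassified
    (no favourable canonical assignment).  Exact zeros are classified with
    the adjacent negative-dH rule and flagged.
    """
    if delta_h == 0 or delta_s == 0:
        warnings.warn(
            f"boundary case dH={delta_h}, dS={delta_s}: zero treated as negative",
            stacklevel=2,
        )
    h_neg = delta_h <= 0
    s_pos = delta_s > 0
    if h_neg and s_pos:
        return "electrostatic"
    if not h_neg and s_pos:
        return "hydrophobic"
    if h_neg and not s_pos:
        return "hydrogen-bond/van-der-Waals"
    return "unclassified"


def spontaneity(delta_g: float, delta_h: float) -> tuple[bool, bool]:
    """(spontaneous, exothermic) by strict inequalities dG < 0, dH < 0."""
    return (delta_g < 0, delta_h < 0)
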