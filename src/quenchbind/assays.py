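"""Functional-assay calculators for protein-polyphenol preparations.

Covers the routine wet-lab arithmetic around a conjugation study: the
Folin-Ciocalteu total-phenol standard curve and grafting efficiency, DPPH
radical scavenging, protein solubility, foam expansion/stability,
turbidimetric emulsification indices (EAI/ESI), and digestion
bioaccessibility.  Each calculator is a pure function over a small typed
record; percentages are not clamped to [0, 100] because out-of-range values
(negative scavenging, >100% foam expansion) are meaningful signals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError, QualityWarning

#: sentinel for an emulsion whose turbidity did not decay in 10 min
INFINITE_STABILITY = math.inf


@dataclass(frozen=True)
class StandardCurve:
    """Linear Folin-Ciocalteu calibration: absorbance = slope*conc + intercept."""

    slope: float  # absorbance per (mg/mL)
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class GraftingRecord:
    c_sample: float  # polyphenol content after dialysis, mg/mL
    c_reactant: float  # pre-dialysis content, mg/mL

    def validate(self) -> None:
        if self.c_sample < 0 or self.c_reactant <= 0:
            raise ValidationError(
                f"need c_sample >= 0 and c_reactant > 0, got {self.c_sample}, {self.c_reactant}"
            )


@dataclass(frozen=True)
class DpphRecord:
    a0: float  # DPPH + solvent control
    a1: float  # sample-without-DPPH blank
    a2: float  # sample + DPPH

    def validate(self) -> None:
        if not self.a0 > 0:
            raise ValidationError(f"a0 must be > 0, got {self.a0}")


@dataclass(frozen=True)
class SolubilityRecord:
    soluble: float
    total: float

    def validate(self) -> None:
        if not self.total > 0:
            raise ValidationError(f"total must be > 0, got {self.total}")
        if self.soluble > self.total:
            warnings.warn(
                f"soluble ({self.soluble}) exceeds total ({self.total})",
                QualityWarning,
                stacklevel=3,
            )


@dataclass(frozen=True)
class FoamRecord:
    v0: float  # initial volume, mL
    v: float  # after whipping
    v30: float  # after 30 min rest

    def validate(self) -> None:
        if not self.v0 > 0:
            raise ValidationError(f"v0 must be > 0, got {self.v0}")
        if not (self.v >= self.v30 >= 0):
            warnings.warn(
                f"expected v >= v30 >= 0, got v={self.v}, v30={self.v30}",
                QualityWarning,
                stacklevel=3,
            )


@dataclass(frozen=True)
class EmulsionRecord:
    a0: float  # absorbance at 0 min (500 nm, diluted)
    a10: float  # absorbance at 10 min
    df: float  # dilution factor
    l: float  # path length, m
    phi: float  # oil volume fraction
    c: float  # protein concentration, g/mL

    def validate(self) -> None:
        if not (self.l > 0 and self.phi > 0 and self.c > 0):
            raise ValidationError(
                f"need l, phi, c > 0; got {self.l}, {self.phi}, {self.c}"
            )


@dataclass(frozen=True)
class DigestionRecord:
    c_digesta: float  # post-intestinal concentration
    c_initial: float

    def validate(self) -> None:
        if not self.c_initial > 0:
            raise ValidationError(f"c_initial must be > 0, got {self.c_initial}")


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Least-squares calibration line through (concentration, absorbance) pairs."""
    if len(points) < 2:
        raise ValidationError("need >=2 calibration points")
    conc = np.array([p[0] for p in points], dtype=float)
    absb = np.array([p[1] for p in points], dtype=float)
    if np.all(conc == conc[0]):
        raise ValidationError("all calibration concentrations equal; fit is degenerate")
    if len(points) == 2:
        slope = (absb[1] - absb[0]) / (conc[1] - conc[0])
        return StandardCurve(float(slope), float(absb[0] - slope * conc[0]), 1.0)
    res = stats.linregress(conc, absb)
    return StandardCurve(float(res.slope), float(res.intercept), float(res.rvalue**2))


def conc_from_absorbance(curve: StandardCurve, absorbance: float) -> float:
    """Invert the calibration; negative concentrations clamp to 0 with a warning."""
    if curve.slope == 0:
        raise ValidationError("zero-slope curve is not invertible")
    conc = (absorbance - curve.intercept) / curve.slope
    if conc < 0:
        warnings.warn(
            f"absorbance {absorbance} below intercept; concentration clamped to 0",
            QualityWarning,
            stacklevel=2,
        )
        return 0.0
    return conc


def grafting_efficiency(rec: GraftingRecord) -> float:
    """Percent polyphenol retained after dialysis: 100 * C / C_0."""
    rec.validate()
    return 100.0 * rec.c_sample / rec.c_reactant


def dpph_scavenging(rec: DpphRecord, formula_variant: str = "blank-corrected") -> float:
    """DPPH radical scavenging activity, percent.

    ``blank-corrected`` (default, the Blois form): 100*(A0 - (A2 - A1))/A0,
    reading A1 as the sample-without-DPPH blank.  ``literal``:
    100*(A0 - A2 - A1)/A0.
    """
    rec.validate()
    if formula_variant == "blank-corrected":
        return 100.0 * (rec.a0 - (rec.a2 - rec.a1)) / rec.a0
    if formula_variant == "literal":
        return 100.0 * (rec.a0 - rec.a2 - rec.a1) / rec.a0
    raise ValidationError(f"unknown DPPH formula variant {formula_variant!r}")


def solubility(rec: SolubilityRecord) -> float:
    """Percent soluble protein: 100 * soluble / total."""
    rec.validate()
    return 100.0 * rec.soluble / rec.total


def foaming(rec: FoamRecord) -> tuple[float, float]:
    """Foam expansion and stability: FE = 100*V/V0, FS = 100*V30/V0."""
    rec.validate()
    return 100.0 * rec.v / rec.v0, 100.0 * rec.v30 / rec.v0


def emulsification(rec: EmulsionRecord) -> tuple[float, float]:
    """Turbidimetric emulsification indices.

    EAI (m^2/g) = 2 * 2.303 * A0 * DF / (L * phi * c) with L in metres and c
    in g/mL, exactly the printed unit convention (no hidden conversion).
    ESI (min) = A0 * 10 / (A0 - A10); a non-decaying emulsion (A10 >= A0
    with A0 == A10) returns the infinite-stability sentinel.
    """
    rec.validate()
    eai = 2.0 * 2.303 * rec.a0 * rec.df / (rec.l * rec.phi * rec.c)
    if rec.a0 == rec.a10:
        return eai, INFINITE_STABILITY
    esi = rec.a0 * 10.0 / (rec.a0 - rec.a10)
    return eai, esi


def bioaccessibility(rec: DigestionRecord) -> float:
    """Percent surviving simulated digestion: 100 * C_digesta / C_initial."""
    rec.validate()
    return 100.0 * rec.c_digesta / rec.c_initial
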