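"""Stern-Volmer quenching analysis and mechanism classification.

The Stern-Volmer relation

    F_0 / F = 1 + K_sv [Q] = 1 + K_q tau_0 [Q]

is fit by ordinary least squares of F_0/F against quencher concentration.
K_sv is the slope; the bimolecular quenching rate constant K_q = K_sv/tau_0
uses the unquenched fluorophore lifetime tau_0 (10 ns for tryptophan-based
protein emission unless overridden).

Mechanism: collisional (dynamic) quenching is diffusion-limited at about
2.0e10 L mol^-1 s^-1; an apparent K_q far above that limit indicates a
ground-state complex (static quenching).  A binding constant that falls with
temperature corroborates static quenching (complexes destabilise on
heating), while a K_sv that rises with temperature corroborates dynamic
quenching (faster diffusion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data_model_io import TitrationSeries
from .errors import InsufficientDataError, ValidationError

#: diffusion-limited collisional quenching rate constant, L mol^-1 s^-1
DIFFUSION_LIMIT_KQ = 2.0e10

#: fractional half-width of the indeterminate band around the limit
_KQ_BAND = 0.01

#: default unquenched fluorophore lifetime, seconds (10 ns)
DEFAULT_TAU0 = 1.0e-8


@dataclass(frozen=True)
class QuenchingFit:
    """Result of a Stern-Volmer fit at one temperature."""

    ksv: float  # L/mol
    intercept: float  # dimensionless, 1 if constrained
    kq: float  # L mol^-1 s^-1
    tau0: float  # s
    r_squared: float
    temperature: float  # K
    n_points: int
    used_corrected: bool
    mechanism: str | None = None  # set by classify_mechanism


@dataclass(frozen=True)
class MechanismCall:
    """Mechanism label with the primary rule and corroborating evidence kept apart."""

    label: str  # static | dynamic | indeterminate
    kq_rule: str  # verdict of the diffusion-limit comparison alone
    corroboration: tuple[str, ...] = ()


def fit_stern_volmer(
    series: TitrationSeries,
    constrain_intercept: bool = False,
    tau0: float = DEFAULT_TAU0,
) -> QuenchingFit:
    """Least-squares Stern-Volmer fit of F_0/F versus [Q].

    The free-intercept fit (default) is diagnostic: an intercept far from 1
    flags curvature or a bad F_0.  With ``constrain_intercept`` the model is
    forced through (0, 1), the textbook form.
    """
    series.validate()
    q = series.quencher_concs
    f = series.intensities
    if np.any(f <= 0):
        raise ValidationError("non-positive intensity in series")
    f0 = series.f0
    mask = q > 0
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"need >=3 points with [Q]>0, got {int(mask.sum())} at T={series.temperature} K"
        )
    x = q[mask]
    y = f0 / f[mask]
    if constrain_intercept:
        # minimise ||(y-1) - ksv*x||: ksv = <x,(y-1)>/<x,x>
        ksv = float(np.dot(x, y - 1.0) / np.dot(x, x))
        intercept = 1.0
        resid = y - (1.0 + ksv * x)
    else:
        res = stats.linregress(x, y)
        ksv, intercept = float(res.slope), float(res.intercept)
        resid = y - (intercept + ksv * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return QuenchingFit(
        ksv=ksv,
        intercept=intercept,
        kq=compute_kq(ksv, tau0),
        tau0=tau0,
        r_squared=min(max(r2, 0.0), 1.0),
        temperature=series.temperature,
        n_points=int(mask.sum()),
        used_corrected=series.is_corrected,
    )


def compute_kq(ksv: float, tau0: float = DEFAULT_TAU0) -> float:
    """Bimolecular quenching rate constant K_q = K_sv / tau_0."""
    if not tau0 > 0:
        raise ValidationError(f"tau0 must be > 0, got {tau0}")
    return ksv / tau0


def classify_mechanism(
    fits: Sequence[QuenchingFit],
    ka_by_temp: Mapping[float, float] | None = None,
) -> MechanismCall:
    """Classify quenching as static, dynamic or indeterminate.

    Primary rule: every apparent K_q above the 2.0e10 L mol^-1 s^-1 diffusion
    limit -> static; every K_q below it -> dynamic.  K_q values inside a
    +/-1% band around the limit (or a mixed verdict) are indeterminate by the
    primary rule and are resolved, when possible, by temperature trends:
    K_A decreasing with T supports static, K_sv increasing with T supports
    dynamic.  Trends are reported as corroboration even when the primary
    rule already decides.
    """
    if not fits:
        raise InsufficientDataError("need at least one quenching fit")
    fits = sorted(fits, key=lambda f: f.temperature)
    kqs = np.array([f.kq for f in fits])

    hi, lo = DIFFUSION_LIMIT_KQ * (1 + _KQ_BAND), DIFFUSION_LIMIT_KQ * (1 - _KQ_BAND)
    if np.all(kqs > hi):
        kq_rule = "static"
    elif np.all(kqs < lo):
        kq_rule = "dynamic"
    else:
        kq_rule = "indeterminate"

    corroboration: list[str] = []
    ka_supports = None
    if ka_by_temp is not None and len(ka_by_temp) >= 2:
        temps = sorted(ka_by_temp)
        kas = [ka_by_temp[t] for t in temps]
        if all(b < a for a, b in zip(kas, kas[1:])):
            ka_supports = "static"
            corroboration.append("K_A decreases with temperature (supports static)")
        elif all(b > a for a, b in zip(kas, kas[1:])):
            ka_supports = "dynamic"
            corroboration.append("K_A increases with temperature (supports dynamic)")
    ksv_supports = None
    if len(fits) >= 2:
        ksvs = [f.ksv for f in fits]
        if all(b > a for a, b in zip(ksvs, ksvs[1:])):
            ksv_supports = "dynamic"
            corroboration.append("K_sv increases with temperature (supports dynamic)")

    label = kq_rule
    if kq_rule == "indeterminate":
        if ka_supports is not None:
            label = ka_supports
        elif ksv_supports is not None:
            label = ksv_supports
    return MechanismCall(label=label, kq_rule=kq_rule, corroboration=tuple(corroboration))
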